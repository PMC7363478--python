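"""Experiment references, data paths, session persistence, benchmarking.

Sessions are identified by human-readable reference strings
``yyyy-mm-dd_seq_subject`` that map onto a ``subject/date/seq`` directory
under one or more data roots from a single paths config.  Completed
sessions are written as plain-text files (events JSONL, parameters JSON,
summary JSON) with deterministic formatting so identical sessions give
byte-identical files.
"""

from __future__ import annotations

import datetime
import json
import re
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .network import Network, UpdateRecord, _json_value, build_benchmark_network
from .runtime import ParamSet, SessionLog

__all__ = [
    "ExpRef",
    "PathsConfig",
    "format_exp_ref",
    "parse_exp_ref",
    "session_paths",
    "next_sequence",
    "write_session",
    "load_session",
    "bench",
    "BenchReport",
]


@dataclass(frozen=True)
class ExpRef:
    subject: str
    date: datetime.date
    sequence: int

    def __post_init__(self):
        if not self.subject:
            raise ValueError("exp ref subject must be nonempty")
        if "_" in self.subject:
            raise ValueError("exp ref subject may not contain '_'")
        if self.sequence < 1:
            raise ValueError("exp ref sequence must be >= 1")


def format_exp_ref(ref: ExpRef) -> str:
    return f"{ref.date.isoformat()}_{ref.sequence}_{ref.subject}"


_REF_RE = re.compile(r"^(\d{4}-\d{2}-\d{2})_(\d+)_(.+)$")


def parse_exp_ref(text: str) -> ExpRef:
    m = _REF_RE.match(text)
    if not m:
        raise ValueError(
            f"malformed experiment reference {text!r}: expected "
            "'yyyy-mm-dd_seq_subject'")
    date_s, seq_s, subject = m.groups()
    try:
        date = datetime.date.fromisoformat(date_s)
    except ValueError as exc:
        raise ValueError(
            f"malformed experiment reference {text!r}: bad date "
            f"({exc})") from None
    seq = int(seq_s)
    if seq < 1:
        raise ValueError(
            f"malformed experiment reference {text!r}: sequence must be >= 1")
    if "_" in subject:
        raise ValueError(
            f"malformed experiment reference {text!r}: subject may not "
            "contain '_'")
    return ExpRef(subject, date, seq)


@dataclass
class PathsConfig:
    """Ordered data roots; the first is the primary write target."""

    data_roots: list[Path]

    def __post_init__(self):
        if not self.data_roots:
            raise ValueError("paths config needs at least one data root")
        self.data_roots = [Path(p) for p in self.data_roots]

    @classmethod
    def from_yaml(cls, path) -> "PathsConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls([Path(p) for p in doc["data_roots"]])

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"data_roots": [str(p) for p in self.data_roots]},
                           fh, sort_keys=True)


def session_paths(config: PathsConfig, ref: ExpRef) -> list[Path]:
    """``<root>/<subject>/<date>/<seq>/`` for every root, primary first."""
    return [root / ref.subject / ref.date.isoformat() / str(ref.sequence)
            for root in config.data_roots]


def next_sequence(config: PathsConfig, subject: str,
                  date: datetime.date) -> int:
    """1 + the highest existing session sequence for subject/date under
    the primary root (1 if none exist)."""
    day_dir = config.data_roots[0] / subject / date.isoformat()
    if not day_dir.is_dir():
        return 1
    seqs = [int(p.name) for p in day_dir.iterdir()
            if p.is_dir() and p.name.isdigit()]
    return max(seqs, default=0) + 1


def _dump_json(obj: Any) -> str:
    return json.dumps(_json_value(obj), sort_keys=True, indent=1)


def write_session(log: SessionLog, paramset: ParamSet | None, ref: ExpRef,
                  config: PathsConfig) -> dict[str, Path]:
    """Write events JSONL, parameters JSON and a summary JSON into the
    primary session directory; returns the written paths."""
    out_dir = session_paths(config, ref)[0]
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        events_path = out_dir / "events.jsonl"
        with open(events_path, "w") as fh:
            fh.write(log.to_jsonl())
        params_path = out_dir / "parameters.json"
        with open(params_path, "w") as fh:
            fh.write((paramset or ParamSet()).to_json())
        summary_path = out_dir / "summary.json"
        with open(summary_path, "w") as fh:
            fh.write(_dump_json({
                "exp_ref": format_exp_ref(ref),
                "trial_count": log.trial_count,
                "end_reason": log.end_reason,
                "seed": log.seed,
                "n_events": len(log.entries),
            }))
    except OSError as exc:
        raise OSError(f"failed writing session under {out_dir}: {exc}") from exc
    return {"events": events_path, "parameters": params_path,
            "summary": summary_path}


def load_session(config: PathsConfig, ref: ExpRef
                 ) -> tuple[SessionLog, ParamSet, dict]:
    """Read a written session back; values equal the in-memory ones."""
    out_dir = session_paths(config, ref)[0]
    with open(out_dir / "summary.json") as fh:
        summary = json.load(fh)
    with open(out_dir / "events.jsonl") as fh:
        entries = [json.loads(line) for line in fh if line.strip()]
    log = SessionLog(
        entries=[(e["signal"], e["time"], e["value"]) for e in entries],
        trial_count=summary["trial_count"], end_reason=summary["end_reason"],
        seed=summary["seed"])
    paramset = ParamSet.load(out_dir / "parameters.json")
    return log, paramset, summary


# ---------------------------------------------------------------------------
# Benchmark harness
# ---------------------------------------------------------------------------

@dataclass
class BenchReport:
    n_nodes: int
    depth: int
    reps: int
    all_passed: bool
    failures: list[int]
    mean_propagation_s: float
    per_rep_s: list[float]

    def to_csv(self) -> str:
        lines = ["rep,n_emitted,elapsed_s"]
        for i, dt in enumerate(self.per_rep_s):
            ok = i not in self.failures
            lines.append(f"{i},{self.n_nodes if ok else 'FAIL'},{dt:.9f}")
        return "\n".join(lines) + "\n"


def bench(n_nodes: int, depth: int, reps: int, seed: int) -> BenchReport:
    """Propagation-correctness harness on a layered random network.

    Builds a seeded network of ``n_nodes`` over ``depth`` layers, posts
    to the origin ``reps`` times, and asserts that every node emits
    exactly once per post (wall-clock timings are reported, never
    asserted — they depend on the host).
    """
    net = Network()
    origin, ids = build_benchmark_network(net, n_nodes, depth, seed)
    failures = []
    per_rep = []
    for rep in range(reps):
        t0 = time.perf_counter()
        records: list[UpdateRecord] = net.post(origin, float(rep))
        per_rep.append(time.perf_counter() - t0)
        emitted = [r.node_id for r in records]
        if sorted(emitted) != sorted(ids):
            failures.append(rep)
    if failures:
        raise AssertionError(
            f"single-update invariant violated in reps {failures[:10]} "
            f"(of {reps})")
    return BenchReport(n_nodes, depth, reps, True, failures,
                       float(np.mean(per_rep)), per_rep)
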