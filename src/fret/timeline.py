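"""Multi-clock acquisition simulation and chrono-based time alignment.

Real acquisition setups timestamp events on several unsynchronized
clocks (a DAQ's scan clock, the stimulus computer's system clock, ...).
The alignment scheme modelled here uses a clocking square wave
("chrono"): at each flip the commanded system time and the acquired DAQ
stamp of the flip are both recorded, and their difference is the offset
of the DAQ clock at that moment.  Event stamps in the DAQ domain are
mapped into the unified (system) timebase by subtracting the offset of
the latest flip at or before the event — a piecewise-constant offset
model that tracks slow drift chunk by chunk.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ClockModel",
    "ChronoRecord",
    "AlignedEvent",
    "simulate_chrono",
    "to_unified",
    "align_events",
    "generate_pulse_train",
    "read_chrono_csv",
    "write_chrono_csv",
    "read_events_csv",
    "write_aligned_csv",
]


@dataclass
class ClockModel:
    """Affine model of an acquisition clock relative to system time.

    daq_time(t) = scale * t + offset + N(0, jitter**2)

    ``scale`` is unitless and close to 1 (drift = scale - 1, e.g. 1e-4
    for 100 ppm); ``offset`` and ``jitter`` are in seconds.
    """

    scale: float = 1.0
    offset: float = 0.0
    jitter: float = 0.0

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("clock scale must be positive")

    def daq_time(self, t_sys: float | np.ndarray,
                 rng: np.random.Generator | None = None):
        t = self.scale * np.asarray(t_sys, dtype=float) + self.offset
        if self.jitter > 0:
            if rng is None:
                raise ValueError("jitter > 0 requires an rng")
            t = t + rng.normal(0.0, self.jitter, size=np.shape(t))
        return t


@dataclass
class ChronoRecord:
    """One flip of the clocking square wave."""

    flip: int
    commanded_system_s: float  # system time when the flip was commanded
    daq_stamp_s: float         # DAQ scan stamp where the flip was seen

    @property
    def offset_s(self) -> float:
        return self.daq_stamp_s - self.commanded_system_s


@dataclass
class AlignedEvent:
    channel: str
    raw_stamp_s: float
    domain: str          # "daq" | "system"
    unified_s: float


def simulate_chrono(clock: ClockModel, chunk_period: float, duration: float,
                    seed: int | None = 0) -> list[ChronoRecord]:
    """Simulate chrono flips at every ``chunk_period`` over ``duration``
    seconds and record the per-flip offsets under ``clock``."""
    if chunk_period <= 0:
        raise ValueError("chunk_period must be positive")
    rng = np.random.default_rng(seed) if clock.jitter > 0 else None
    n = int(np.floor(duration / chunk_period)) + 1
    sys_times = np.arange(n) * chunk_period
    daq_times = clock.daq_time(sys_times, rng)
    return [ChronoRecord(k, float(sys_times[k]), float(daq_times[k]))
            for k in range(n)]


def to_unified(records: Sequence[ChronoRecord], raw: float) -> float:
    """Convert a DAQ-domain stamp into the unified (system) timebase.

    Uses the offset of the latest flip whose DAQ stamp is at or before
    ``raw``; stamps before the first flip use the first offset.
    """
    if not records:
        raise ValueError("need at least one chrono record")
    daq_stamps = np.array([r.daq_stamp_s for r in records])
    k = int(np.searchsorted(daq_stamps, raw, side="right")) - 1
    k = max(k, 0)
    return float(raw - records[k].offset_s)


def align_events(records: Sequence[ChronoRecord],
                 events: Iterable[tuple[str, float, str]]) -> list[AlignedEvent]:
    """Align (channel, raw_stamp, domain) events into unified time.

    System-domain stamps pass through unchanged (the unified timebase is
    the master system clock); DAQ-domain stamps are converted via the
    chrono offsets.
    """
    out = []
    for channel, raw, domain in events:
        raw = float(raw)
        if domain == "system":
            unified = raw
        elif domain == "daq":
            unified = to_unified(records, raw)
        else:
            raise ValueError(f"unknown clock domain {domain!r}")
        out.append(AlignedEvent(channel, raw, domain, unified))
    return out


def generate_pulse_train(rate: float, duty: float, duration: float,
                         sample_rate: float) -> np.ndarray:
    """Boolean sample vector of a periodic pulse train.

    ``rate`` in Hz, ``duty`` the high fraction of each period, sampled at
    ``sample_rate`` Hz for ``duration`` seconds.  The number of rising
    edges equals floor(rate * duration) (for duty < 1).
    """
    if rate * duration < 1:
        raise ValueError("rate * duration must be >= 1")
    if sample_rate < 2 * rate:
        raise ValueError("sample_rate must be at least 2 * rate")
    if not 0 < duty <= 1:
        raise ValueError("duty must be in (0, 1]")
    n = int(round(duration * sample_rate))
    if duty == 1.0:
        return np.ones(n, dtype=bool)
    # within-cycle position of sample k: (k * rate) mod sample_rate,
    # exact when the rates are commensurate; a sample exactly on the
    # duty boundary falls on the low side
    frac = np.mod(np.arange(n) * float(rate), float(sample_rate))
    threshold = duty * sample_rate
    return frac < threshold - 1e-9 * sample_rate


# -- CSV interfaces ---------------------------------------------------------

def write_chrono_csv(records: Sequence[ChronoRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["flip", "commanded_system_s", "daq_stamp_s"])
        for r in records:
            w.writerow([r.flip, repr(r.commanded_system_s), repr(r.daq_stamp_s)])


def read_chrono_csv(path) -> list[ChronoRecord]:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    return [ChronoRecord(int(r["flip"]), float(r["commanded_system_s"]),
                         float(r["daq_stamp_s"])) for r in rows]


def read_events_csv(path) -> list[tuple[str, float, str]]:
    """Events CSV: ``channel,raw_stamp_s,domain``."""
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    return [(r["channel"], float(r["raw_stamp_s"]), r["domain"]) for r in rows]


def write_aligned_csv(events: Sequence[AlignedEvent], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["channel", "raw_stamp_s", "domain", "unified_s"])
        for e in events:
            w.writerow([e.channel, repr(e.raw_stamp_s), e.domain,
                        repr(e.unified_s)])
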