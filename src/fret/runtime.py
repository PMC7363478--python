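"""Experiment-definition runtime.

An experiment is defined by a user function with up to seven positional
arguments::

    def expdef(t, events, params, visual, inputs, outputs, audio): ...

The function is called exactly once, at build time, to wire a reactive
network; it never runs during the session.  The runtime supplies the
origin signals (clock ``t``, epoch flags ``expStart`` / ``newTrial`` /
``expStop``, hardware input channels), resolves signal parameters
(global: one value per session; conditional: one of several condition
columns drawn per trial), then drives the network with a simulated clock
and a scripted input trace, logging every registered signal.
"""

from __future__ import annotations

import inspect
import json
import csv
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable

import numpy as np

from .network import Network, Signal, _json_value, truthy

__all__ = [
    "Registry",
    "ParamRegistry",
    "EventsRegistry",
    "ParamSet",
    "ExperimentHandle",
    "SessionLog",
    "build_experiment",
    "resolve_parameters",
    "advance_trial",
    "run_loop",
    "read_input_script",
    "write_input_script",
]


class Registry:
    """Assign-only keyed collection (events, visual stimuli, outputs,
    audio).  Attribute assignment registers an entry; registered signals
    are logged during the session."""

    def __init__(self, name: str):
        object.__setattr__(self, "_name", name)
        object.__setattr__(self, "entries", {})

    def __setattr__(self, key: str, value: Any) -> None:
        if key.startswith("_"):
            object.__setattr__(self, key, value)
            return
        self.entries[key] = value

    def __getattr__(self, key: str) -> Any:
        if key.startswith("_"):
            raise AttributeError(key)
        try:
            return self.entries[key]
        except KeyError:
            raise AttributeError(f"{self._name} has no entry {key!r}") from None


class EventsRegistry(Registry):
    """Events structure: exposes the runner-managed epoch origins
    (expStart, newTrial, expStop) and accepts user signal assignments —
    notably ``events.endTrial`` and ``events.expStop`` which the runner
    watches to sequence trials and end the session."""

    def __init__(self, expStart: Signal, newTrial: Signal, expStop: Signal):
        super().__init__("events")
        object.__setattr__(self, "_managed", {
            "expStart": expStart, "newTrial": newTrial, "expStop": expStop})
        object.__setattr__(self, "_user", {})

    def __setattr__(self, key: str, value: Any) -> None:
        if key.startswith("_"):
            object.__setattr__(self, key, value)
            return
        if not isinstance(value, Signal):
            raise TypeError(f"events.{key}: only signals can be registered")
        if key in ("expStop", "endTrial"):
            self._user[key] = value
        self.entries[key] = value

    def __getattr__(self, key: str) -> Any:
        if key.startswith("_"):
            raise AttributeError(key)
        if key in self.entries:
            return self.entries[key]
        if key in self._managed:
            return self._managed[key]
        raise AttributeError(f"events has no entry {key!r}")


class InputsRegistry(Registry):
    """Hardware-input structure: reading ``inputs.cursor`` lazily creates
    an origin signal for that channel."""

    def __init__(self, net: Network):
        super().__init__("inputs")
        object.__setattr__(self, "_net", net)

    def __getattr__(self, key: str) -> Signal:
        if key.startswith("_"):
            raise AttributeError(key)
        if key not in self.entries:
            self.entries[key] = self._net.origin(f"inputs.{key}")
        return self.entries[key]

    def __setattr__(self, key: str, value: Any) -> None:
        if key.startswith("_"):
            object.__setattr__(self, key, value)
            return
        raise TypeError("input channels are created by reading, not assigned")


def _columns_from(value: Any) -> tuple[list, bool]:
    """Interpret a parameter default as condition columns.

    A 2-D array with more than one column is a conditional parameter
    (one column drawn per trial, columns along the last axis); anything
    else is a global parameter with a single column.
    """
    arr = np.asarray(value)
    if arr.ndim == 2 and arr.shape[1] > 1:
        return [arr[:, j].tolist() for j in range(arr.shape[1])], True
    if arr.ndim == 2:
        return [arr[:, 0].tolist()], False
    return [value.tolist() if isinstance(value, np.ndarray) else value], False


class ParamSet:
    """Declared signal parameters: per name a list of condition columns
    and a conditional flag.  All conditional parameters must share the
    same number of columns (conditions stay coherent across parameters)."""

    def __init__(self, params: dict[str, dict] | None = None):
        self.params: dict[str, dict] = dict(params or {})

    def declare(self, name: str, value: Any) -> None:
        columns, conditional = _columns_from(value)
        self.params[name] = {"columns": columns, "conditional": conditional}

    def update(self, other: "ParamSet") -> None:
        self.params.update(other.params)

    def n_conditions(self) -> int:
        counts = {len(p["columns"]) for p in self.params.values()
                  if p["conditional"]}
        if not counts:
            return 0
        if len(counts) > 1:
            raise ValueError(
                "conditional parameters disagree on the number of "
                f"condition columns: {sorted(counts)}")
        return counts.pop()

    def validate(self) -> None:
        for name, p in self.params.items():
            if not p["columns"]:
                raise ValueError(f"parameter {name!r} has no columns")
        self.n_conditions()

    # -- persistence: {"name": {"columns": [[...]], "conditional": bool}}

    def to_json(self) -> str:
        return json.dumps(self.params, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ParamSet":
        return cls(json.loads(text))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "ParamSet":
        with open(path) as fh:
            return cls.from_json(fh.read())


class ParamRegistry(Registry):
    """Signal-parameters structure.

    Reading ``p.name`` lazily creates the parameter's origin signal (task
    code may read a parameter before declaring its default, as in the
    access-before-declare idiom of published task listings); assigning
    ``p.name = default`` declares the default columns on the already
    created signal.
    """

    def __init__(self, net: Network, paramset: ParamSet):
        super().__init__("params")
        object.__setattr__(self, "_net", net)
        object.__setattr__(self, "_paramset", paramset)

    def __getattr__(self, key: str) -> Signal:
        if key.startswith("_"):
            raise AttributeError(key)
        if key not in self.entries:
            self.entries[key] = self._net.origin(f"p.{key}")
        return self.entries[key]

    def __setattr__(self, key: str, value: Any) -> None:
        if key.startswith("_"):
            object.__setattr__(self, key, value)
            return
        if key not in self.entries:
            self.entries[key] = self._net.origin(f"p.{key}")
        if key not in self._paramset.params:  # external sets override defaults
            self._paramset.declare(key, value)


@dataclass
class SessionLog:
    """Everything a completed session recorded."""

    entries: list[tuple[str, float, Any]] = field(default_factory=list)
    trial_count: int = 0
    end_reason: str = ""
    seed: int = 0

    def values_of(self, name: str) -> list[Any]:
        return [v for n, _, v in self.entries if n == name]

    def times_of(self, name: str) -> list[float]:
        return [t for n, t, _ in self.entries if n == name]

    def to_jsonl(self) -> str:
        lines = [json.dumps({"signal": n, "time": t, "value": _json_value(v)},
                            separators=(",", ":"))
                 for n, t, v in self.entries]
        return "\n".join(lines) + ("\n" if lines else "")


@dataclass
class ExperimentHandle:
    net: Network
    t: Signal
    expStart: Signal
    newTrial: Signal
    expStop: Signal
    events: EventsRegistry
    params: ParamRegistry
    inputs: InputsRegistry
    outputs: Registry
    visual: Registry
    audio: Registry
    paramset: ParamSet
    seed: int
    clock_step: float
    duration: float
    trial_count: int = 0
    _param_rng: np.random.Generator | None = None
    _trial_conditions: list[int] = field(default_factory=list)
    log: SessionLog | None = None


def build_experiment(expdef: Callable, paramset: ParamSet | None = None,
                     seed: int = 0, clock_step: float = 0.01,
                     duration: float = np.inf) -> ExperimentHandle:
    """Create the network, call ``expdef`` once to wire it, and return a
    handle ready for :func:`run_loop`.

    ``expdef`` may accept up to seven positional arguments
    ``(t, events, params, visual, inputs, outputs, audio)``; trailing
    arguments it does not declare are simply not passed.  A ``paramset``
    given here overrides defaults the expdef declares.
    """
    net = Network()
    t = net.origin("t")
    expStart = net.origin("expStart")
    newTrial = net.origin("newTrial")
    expStop = net.origin("expStop")
    merged = ParamSet(dict((paramset or ParamSet()).params))
    events = EventsRegistry(expStart, newTrial, expStop)
    params = ParamRegistry(net, merged)
    inputs = InputsRegistry(net)
    outputs = Registry("outputs")
    visual = Registry("visual")
    audio = Registry("audio")

    args = [t, events, params, visual, inputs, outputs, audio]
    try:
        n_args = len([
            p for p in inspect.signature(expdef).parameters.values()
            if p.kind in (p.POSITIONAL_ONLY, p.POSITIONAL_OR_KEYWORD)])
    except (TypeError, ValueError):
        n_args = 7
    if n_args > 7:
        raise TypeError("an experiment definition takes at most 7 arguments")
    try:
        expdef(*args[:n_args])
    except Exception as exc:
        raise RuntimeError(
            f"experiment definition {getattr(expdef, '__name__', expdef)!r} "
            f"raised during construction: {exc}") from exc
    merged.validate()

    return ExperimentHandle(
        net=net, t=t, expStart=expStart, newTrial=newTrial, expStop=expStop,
        events=events, params=params, inputs=inputs, outputs=outputs,
        visual=visual, audio=audio, paramset=merged, seed=seed,
        clock_step=clock_step, duration=duration,
        _param_rng=np.random.default_rng(seed),
    )


def resolve_parameters(handle: ExperimentHandle,
                       trial_index: int) -> dict[str, Any]:
    """Parameter values for a given trial (1-based).

    Global parameters always take their single column.  Conditional
    parameters take column ``c``, where ``c`` is one shared uniform draw
    per trial from the handle's seeded RNG — the same condition index is
    used by every conditional parameter of that trial, and the sequence
    of indices is reproducible from the seed.
    """
    if trial_index < 1:
        raise ValueError("trial_index is 1-based")
    ps = handle.paramset
    ps.validate()
    n_cond = ps.n_conditions()
    while len(handle._trial_conditions) < trial_index:
        c = int(handle._param_rng.integers(n_cond)) if n_cond else 0
        handle._trial_conditions.append(c)
    c = handle._trial_conditions[trial_index - 1]
    out = {}
    for name, p in ps.params.items():
        col = p["columns"][c] if p["conditional"] else p["columns"][0]
        out[name] = col
    return out


def _post_params(handle: ExperimentHandle, values: dict[str, Any],
                 conditional_only: bool = False) -> None:
    for name, value in values.items():
        if conditional_only and not handle.paramset.params[name]["conditional"]:
            continue
        if name in handle.params.entries:
            handle.net.post(handle.params.entries[name], value)


def advance_trial(handle: ExperimentHandle) -> None:
    """Move to the next trial: bump the counter, draw and post fresh
    conditional-parameter values, then post the newTrial epoch."""
    handle.trial_count += 1
    values = resolve_parameters(handle, handle.trial_count)
    _post_params(handle, values, conditional_only=True)
    handle.net.post(handle.newTrial, True)


def run_loop(handle: ExperimentHandle,
             input_script: Iterable[tuple[float, str, Any]] = ()) -> SessionLog:
    """Drive the experiment with a simulated clock and scripted inputs.

    The loop posts parameter values and ``expStart``, starts trial 1,
    then advances simulated time by ``clock_step`` per iteration: input
    events due at or before the current time are posted to their channel
    origins (in script order), followed by the clock ``t``.  A truthy
    emission of the user's ``events.endTrial`` signal queues the next
    trial; a truthy ``events.expStop`` (or the duration cap) ends the
    session.  Returns the log of every registered signal.
    """
    script = sorted(input_script, key=lambda e: e[0]) if input_script else []
    for _, channel, _v in script:
        if channel not in handle.inputs.entries:
            raise ValueError(
                f"input script references unknown channel {channel!r}")

    log = SessionLog(seed=handle.seed)
    handle.log = log
    sim_time = 0.0
    flags = {"end_trial": False, "exp_stop": False}

    def make_logger(name):
        def cb(value):
            log.entries.append((name, sim_time, value))
        return cb

    watched: list[tuple[str, Signal]] = [
        ("expStart", handle.expStart), ("newTrial", handle.newTrial),
        ("expStop", handle.expStop)]
    for key, sig in handle.events.entries.items():
        if key not in ("expStop",):  # user expStop is bridged, logged as expStop
            watched.append((key, sig))
    for key, sig in handle.params.entries.items():
        watched.append((f"p.{key}", sig))
    listeners = [sig.on_value(make_logger(name)) for name, sig in watched]

    user_stop = handle.events._user.get("expStop")
    user_end_trial = handle.events._user.get("endTrial")
    if user_stop is not None:
        listeners.append(user_stop.on_value(
            lambda v: flags.__setitem__("exp_stop", flags["exp_stop"]
                                        or truthy(v))))
    if user_end_trial is not None:
        listeners.append(user_end_trial.on_value(
            lambda v: flags.__setitem__("end_trial", flags["end_trial"]
                                        or truthy(v))))

    try:
        # session prologue: parameters, expStart, first trial
        handle.trial_count = 1
        values = resolve_parameters(handle, 1)
        _post_params(handle, values)
        handle.net.post(handle.expStart, True)
        handle.net.post(handle.newTrial, True)

        script_pos = 0
        n_steps = (int(round(handle.duration / handle.clock_step))
                   if np.isfinite(handle.duration) else None)
        k = 0
        end_reason = "duration cap"
        while n_steps is None or k < n_steps:
            k += 1
            sim_time = k * handle.clock_step
            while (script_pos < len(script)
                   and script[script_pos][0] <= sim_time + 1e-12):
                _, channel, value = script[script_pos]
                handle.net.post(handle.inputs.entries[channel], value)
                script_pos += 1
                if flags["exp_stop"]:
                    break
            if flags["exp_stop"]:
                end_reason = "expStop"
                break
            handle.net.post(handle.t, sim_time)
            if flags["exp_stop"]:
                end_reason = "expStop"
                break
            if flags["end_trial"]:
                flags["end_trial"] = False
                advance_trial(handle)
                if flags["exp_stop"]:
                    end_reason = "expStop"
                    break
        if flags["exp_stop"]:
            end_reason = "expStop"
            handle.net.post(handle.expStop, True)
    finally:
        for lst in listeners:
            lst.detach()

    log.trial_count = handle.trial_count
    log.end_reason = end_reason
    return log


# -- input-script persistence -----------------------------------------------
# CSV with header time_s,channel,value_json

def read_input_script(path) -> list[tuple[float, str, Any]]:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    return [(float(r["time_s"]), r["channel"], json.loads(r["value_json"]))
            for r in rows]


def write_input_script(script: Iterable[tuple[float, str, Any]], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "channel", "value_json"])
        for t, channel, value in script:
            w.writerow([repr(float(t)), channel,
                        json.dumps(_json_value(value))])
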