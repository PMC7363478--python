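"""Reactive signal network.

A behavioral task is modelled as a directed acyclic graph of *signals*:
time-varying values connected by pure transformations.  Origin signals
(clock ticks, hardware inputs, epoch flags) are the only entry points for
new values; posting to an origin runs one *transaction* that propagates
the update through every dependent node.

Propagation here is deterministic and synchronous: nodes are created with
dense integer ids, every operator may only reference already-existing
signals, so ascending id order is a valid topological order and a single
pass per transaction updates each node at most once.  Posts issued from
inside a transaction (e.g. by a value listener) are queued FIFO and run
as subsequent transactions rather than nesting.
"""

from __future__ import annotations

import json
import logging
import math
import numbers
from collections import deque
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable

import numpy as np

logger = logging.getLogger("fret")

__all__ = [
    "EMPTY",
    "Network",
    "Signal",
    "Node",
    "UpdateRecord",
    "NodeError",
    "lift",
    "cond",
    "sfloor",
    "skip_repeats",
    "truthy",
    "deep_equal",
    "build_benchmark_network",
    "records_to_jsonl",
    "write_emission_log",
]


class _Empty:
    """Sentinel for 'no value yet'."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):  # pragma: no cover - cosmetic
        return "EMPTY"

    def __bool__(self):
        return False


EMPTY = _Empty()


class NodeError(RuntimeError):
    """A node's transfer function raised; the transaction is aborted."""


def truthy(v: Any) -> bool:
    """MATLAB-style truthiness: arrays are truthy iff nonempty and all
    elements truthy; numbers iff nonzero; strings iff nonempty."""
    if v is None or v is EMPTY:
        return False
    if isinstance(v, bool):
        return v
    if isinstance(v, numbers.Number):
        return v != 0
    if isinstance(v, np.ndarray):
        return v.size > 0 and bool(np.all(v.astype(bool)))
    if isinstance(v, str):
        return len(v) > 0
    if isinstance(v, (list, tuple)):
        return len(v) > 0 and all(truthy(x) for x in v)
    if isinstance(v, dict):
        return len(v) > 0
    return bool(v)


def deep_equal(a: Any, b: Any) -> bool:
    """Deep elementwise equality; shape mismatch means not equal."""
    if isinstance(a, np.ndarray) or isinstance(b, np.ndarray):
        a, b = np.asarray(a), np.asarray(b)
        return a.shape == b.shape and bool(np.array_equal(a, b))
    if isinstance(a, dict) and isinstance(b, dict):
        return a.keys() == b.keys() and all(deep_equal(a[k], b[k]) for k in a)
    if isinstance(a, (list, tuple)) and isinstance(b, (list, tuple)):
        return len(a) == len(b) and all(deep_equal(x, y) for x, y in zip(a, b))
    try:
        return bool(a == b)
    except Exception:
        return a is b


@dataclass
class UpdateRecord:
    node_id: int
    name: str
    tx: int
    value: Any


@dataclass
class Node:
    id: int
    name: str
    kind: str
    input_ids: list[int]
    transfer: Callable | None
    state: Any = None
    current_value: Any = EMPTY
    has_value: bool = False
    updated_in: int = -1


class Listener:
    """Handle returned by ``Signal.on_value``; supports ``detach()``."""

    def __init__(self, net: "Network", node_id: int, callback: Callable):
        self._net = net
        self._node_id = node_id
        self._callback = callback
        self._attached = True

    def detach(self) -> None:
        if self._attached:
            self._net._listeners[self._node_id].remove(self)
            self._attached = False


class Network:
    """A DAG of reactive nodes plus the transaction machinery."""

    def __init__(self):
        self.nodes: list[Node] = []
        self.transaction_counter = 0
        self._queue: deque[tuple[int, Any]] = deque()
        self._running = False
        self._listeners: dict[int, list[Listener]] = {}

    # -- construction -----------------------------------------------------

    def _add_node(self, name, kind, input_ids, transfer, state=None,
                  initial=EMPTY) -> "Signal":
        for i in input_ids:
            if not (0 <= i < len(self.nodes)):
                raise ValueError(f"unknown input node id {i}")
        node = Node(
            id=len(self.nodes), name=name, kind=kind,
            input_ids=list(input_ids), transfer=transfer, state=state,
        )
        if initial is not EMPTY:
            node.current_value = initial
            node.has_value = True
        self.nodes.append(node)
        return Signal(self, node.id)

    def origin(self, name: str) -> "Signal":
        """Create an input signal; its value is set externally via post."""
        if not name:
            raise ValueError("origin name must be nonempty")
        return self._add_node(name, "origin", [], None)

    # -- propagation ------------------------------------------------------

    def post(self, sig: "Signal", value: Any) -> list[UpdateRecord]:
        """Post ``value`` to an origin and run one transaction.

        Returns the emission records of that transaction.  A post issued
        while another transaction is running is queued and run afterwards;
        such re-entrant posts return an empty list (their records are
        produced when they actually run).
        """
        node = self.nodes[sig.node_id]
        if node.kind != "origin":
            raise ValueError(
                f"can only post to origin signals, not {node.kind} "
                f"node {node.id} ({node.name!r})")
        self._queue.append((sig.node_id, value))
        if self._running:
            return []
        self._running = True
        first: list[UpdateRecord] | None = None
        try:
            while self._queue:
                nid, v = self._queue.popleft()
                records = self._run_transaction(nid, v)
                if first is None:
                    first = records
        finally:
            self._running = False
        return first if first is not None else []

    def _run_transaction(self, origin_id: int, value: Any) -> list[UpdateRecord]:
        tx = self.transaction_counter
        self.transaction_counter += 1
        emitted: dict[int, Any] = {}
        records: list[UpdateRecord] = []

        def commit(node: Node, v: Any) -> None:
            node.current_value = v
            node.has_value = True
            node.updated_in = tx
            emitted[node.id] = v
            records.append(UpdateRecord(node.id, node.name, tx, v))

        commit(self.nodes[origin_id], value)
        for node in self.nodes[origin_id + 1:]:
            if node.transfer is None:
                continue
            if not any(i in emitted for i in node.input_ids):
                continue
            try:
                out = node.transfer(self, node, emitted)
            except NodeError:
                raise
            except Exception as exc:
                raise NodeError(
                    f"transfer of node {node.id} ({node.name!r}) failed: "
                    f"{exc}") from exc
            if out is not EMPTY:
                commit(node, out)
        # listeners fire after the transaction commits, in node-id order
        for nid in sorted(emitted):
            for lst in list(self._listeners.get(nid, ())):
                try:
                    lst._callback(emitted[nid])
                except Exception:
                    logger.exception(
                        "listener on node %d (%s) raised",
                        nid, self.nodes[nid].name)
        return records


class Signal:
    """Lightweight handle onto a network node; all operators live here."""

    __slots__ = ("network", "node_id")

    def __init__(self, network: Network, node_id: int):
        self.network = network
        self.node_id = node_id

    # -- introspection ----------------------------------------------------

    @property
    def node(self) -> Node:
        return self.network.nodes[self.node_id]

    @property
    def name(self) -> str:
        return self.node.name

    @property
    def has_value(self) -> bool:
        return self.node.has_value

    @property
    def value(self) -> Any:
        if not self.node.has_value:
            raise ValueError(f"signal {self.name!r} has no value yet")
        return self.node.current_value

    def __repr__(self):
        v = self.node.current_value if self.node.has_value else EMPTY
        return f"<Signal {self.node_id} {self.name!r} = {v!r}>"

    # -- operators --------------------------------------------------------

    def map(self, fn: Callable[[Any], Any], name: str | None = None) -> "Signal":
        """New signal applying ``fn`` to every emission of this signal."""
        return lift(fn, self, name=name or f"{self.name}.map")

    def scan(self, fn: Callable[[Any, Any], Any], seed: Any,
             name: str | None = None) -> "Signal":
        """Fold emissions into an accumulator: ``acc = fn(acc, new)``.

        The seed becomes the node's queryable current value but is not
        emitted; the first emission happens on the first input update.
        """
        net = self.network

        def transfer(net_, node, emitted):
            v = emitted[node.input_ids[0]]
            node.state = fn(node.state, v)
            return node.state

        sig = net._add_node(name or f"{self.name}.scan", "scan",
                            [self.node_id], transfer, state=seed, initial=seed)
        return sig

    def buffer(self, n: int, name: str | None = None) -> "Signal":
        """Sliding window of the last ``n`` emissions, stacked along the
        last axis (oldest first); emits only once the window is full."""
        if n < 1:
            raise ValueError("buffer length must be >= 1")

        def transfer(net_, node, emitted):
            v = emitted[node.input_ids[0]]
            node.state.append(v)
            if len(node.state) > n:
                node.state.pop(0)
            if len(node.state) < n:
                return EMPTY
            items = node.state
            if any(isinstance(x, np.ndarray) for x in items):
                return np.stack([np.asarray(x) for x in items], axis=-1)
            return np.array(items)

        return self.network._add_node(
            name or f"{self.name}.buffer({n})", "buffer",
            [self.node_id], transfer, state=[])

    def at(self, trigger: "Signal", name: str | None = None) -> "Signal":
        """Sample this signal's current value whenever ``trigger`` emits a
        truthy value.  Declines when the trigger is falsy, when this
        signal has no value yet, or when only this signal updates."""
        _check_same_net(self, trigger)
        value_id, trig_id = self.node_id, trigger.node_id

        def transfer(net_, node, emitted):
            if trig_id not in emitted or not truthy(emitted[trig_id]):
                return EMPTY
            src = net_.nodes[value_id]
            if not src.has_value:
                return EMPTY
            return src.current_value

        return self.network._add_node(
            name or f"{self.name}.at({trigger.name})", "at",
            [value_id, trig_id], transfer)

    def then(self, payload: Any, name: str | None = None) -> "Signal":
        """Emit ``payload`` (a constant or a signal's current value) each
        time this signal emits a truthy value."""
        trig_id = self.node_id
        inputs = [trig_id]
        if isinstance(payload, Signal):
            _check_same_net(self, payload)
            pay_id = payload.node_id
            inputs.append(pay_id)

            def transfer(net_, node, emitted):
                if trig_id not in emitted or not truthy(emitted[trig_id]):
                    return EMPTY
                src = net_.nodes[pay_id]
                return src.current_value if src.has_value else EMPTY
        else:
            def transfer(net_, node, emitted):
                if trig_id not in emitted or not truthy(emitted[trig_id]):
                    return EMPTY
                return payload

        return self.network._add_node(
            name or f"{self.name}.then", "then", inputs, transfer)

    def skip_repeats(self, name: str | None = None) -> "Signal":
        """Suppress consecutive duplicate emissions (deep elementwise
        equality); the first emission always passes."""

        def transfer(net_, node, emitted):
            v = emitted[node.input_ids[0]]
            if node.state is not EMPTY and deep_equal(node.state, v):
                return EMPTY
            node.state = v
            return v

        return self.network._add_node(
            name or f"skipRepeats({self.name})", "skiprepeats",
            [self.node_id], transfer, state=EMPTY)

    def __getitem__(self, key: str) -> "Signal":
        """Select a field from a signal of keyed records: emits
        ``parent[key]`` on every parent emission where the field is
        present; declines when absent.  No dedupe is applied."""

        def transfer(net_, node, emitted):
            rec = emitted[node.input_ids[0]]
            if isinstance(rec, dict):
                return rec[key] if key in rec else EMPTY
            if hasattr(rec, key):
                return getattr(rec, key)
            return EMPTY

        return self.network._add_node(
            f"{self.name}.{key}", "subscript", [self.node_id], transfer)

    def subscriptable(self) -> "Subscriptable":
        """Wrap so fields can be accessed with attribute syntax."""
        return Subscriptable(self)

    def on_value(self, callback: Callable[[Any], None]) -> Listener:
        """Invoke ``callback(value)`` after each transaction in which this
        signal emitted.  Callback errors are logged, never propagated."""
        lst = Listener(self.network, self.node_id, callback)
        self.network._listeners.setdefault(self.node_id, []).append(lst)
        return lst

    # -- lifted arithmetic / comparison ------------------------------------
    # __eq__ keeps Python identity semantics; use .eq() for a lifted
    # elementwise comparison signal.

    def __add__(self, other):
        return lift(lambda a, b: a + b, self, other, name=f"({self.name}+)")

    def __radd__(self, other):
        return lift(lambda a, b: b + a, self, other, name=f"(+{self.name})")

    def __sub__(self, other):
        return lift(lambda a, b: a - b, self, other, name=f"({self.name}-)")

    def __rsub__(self, other):
        return lift(lambda a, b: b - a, self, other, name=f"(-{self.name})")

    def __mul__(self, other):
        return lift(lambda a, b: a * b, self, other, name=f"({self.name}*)")

    def __rmul__(self, other):
        return lift(lambda a, b: b * a, self, other, name=f"(*{self.name})")

    def __truediv__(self, other):
        return lift(lambda a, b: a / b, self, other, name=f"({self.name}/)")

    def __rtruediv__(self, other):
        return lift(lambda a, b: b / a, self, other, name=f"(/{self.name})")

    def __neg__(self):
        return lift(lambda a: -a, self, name=f"(-{self.name})")

    def __lt__(self, other):
        return lift(lambda a, b: a < b, self, other, name=f"({self.name}<)")

    def __le__(self, other):
        return lift(lambda a, b: a <= b, self, other, name=f"({self.name}<=)")

    def __gt__(self, other):
        return lift(lambda a, b: a > b, self, other, name=f"({self.name}>)")

    def __ge__(self, other):
        return lift(lambda a, b: a >= b, self, other, name=f"({self.name}>=)")

    def eq(self, other):
        """Lifted equality (elementwise for arrays, strcmp-like for text)."""
        return lift(_eq, self, other, name=f"({self.name}==)")

    def ne(self, other):
        return lift(lambda a, b: not _eq_scalar(a, b)
                    if np.isscalar(a) and np.isscalar(b)
                    else np.asarray(a) != np.asarray(b),
                    self, other, name=f"({self.name}~=)")

    def __or__(self, other):
        return lift(lambda a, b: truthy(a) or truthy(b), self, other,
                    name=f"({self.name}|)")

    def __ror__(self, other):
        return lift(lambda a, b: truthy(b) or truthy(a), self, other,
                    name=f"(|{self.name})")

    def __and__(self, other):
        return lift(lambda a, b: truthy(a) and truthy(b), self, other,
                    name=f"({self.name}&)")

    def __rand__(self, other):
        return lift(lambda a, b: truthy(b) and truthy(a), self, other,
                    name=f"(&{self.name})")

    def __invert__(self):
        return lift(lambda a: not truthy(a), self, name=f"(~{self.name})")

    def __hash__(self):
        return hash((id(self.network), self.node_id))

    def __eq__(self, other):
        return (isinstance(other, Signal) and other.network is self.network
                and other.node_id == self.node_id)


def _eq_scalar(a, b):
    if isinstance(a, str) or isinstance(b, str):
        return a == b
    return a == b


def _eq(a, b):
    if isinstance(a, str) or isinstance(b, str):
        return a == b
    a_arr, b_arr = np.asarray(a), np.asarray(b)
    if a_arr.ndim == 0 and b_arr.ndim == 0:
        return bool(a_arr == b_arr)
    return a_arr == b_arr


class Subscriptable:
    """Attribute-style access onto a signal of keyed records: reading
    ``sub.field`` derives the field-selection signal (cached)."""

    def __init__(self, sig: Signal):
        object.__setattr__(self, "_sig", sig)
        object.__setattr__(self, "_cache", {})

    @property
    def signal(self) -> Signal:
        return self._sig

    def __getattr__(self, key: str) -> Signal:
        if key.startswith("_"):
            raise AttributeError(key)
        cache = self._cache
        if key not in cache:
            cache[key] = self._sig[key]
        return cache[key]


def _check_same_net(*sigs: Signal) -> None:
    nets = {id(s.network) for s in sigs if isinstance(s, Signal)}
    if len(nets) > 1:
        raise ValueError("cannot combine signals from different networks")


def lift(fn: Callable, *args: Any, name: str | None = None) -> Signal:
    """Apply a pure function over signals and constants.

    The result emits ``fn(*current values)`` whenever at least one signal
    argument emits, provided every signal argument has a value; constant
    arguments are captured as-is.
    """
    sig_args = [a for a in args if isinstance(a, Signal)]
    if not sig_args:
        raise ValueError("lift requires at least one Signal argument")
    _check_same_net(*sig_args)
    net = sig_args[0].network
    spec = [("sig", a.node_id) if isinstance(a, Signal) else ("const", a)
            for a in args]
    input_ids = [nid for tag, nid in spec if tag == "sig"]

    def transfer(net_, node, emitted):
        vals = []
        for tag, x in spec:
            if tag == "const":
                vals.append(x)
            else:
                src = net_.nodes[x]
                if not src.has_value:
                    return EMPTY
                vals.append(src.current_value)
        return fn(*vals)

    return net._add_node(name or getattr(fn, "__name__", "lift"),
                         "lift", input_ids, transfer)


def sfloor(sig: Signal) -> Signal:
    """Elementwise floor of a signal (integer-valued float result)."""
    return lift(lambda v: math.floor(v) if np.isscalar(v)
                else np.floor(v), sig, name=f"floor({sig.name})")


def skip_repeats(sig: Signal) -> Signal:
    return sig.skip_repeats()


def cond(*pairs: tuple[Any, Any], name: str | None = None) -> Signal:
    """First-match conditional selection over (predicate, value) pairs.

    On any input emission the pairs are scanned in order; the value of the
    first pair whose predicate is currently truthy (and whose value is
    available) is emitted.  With no truthy predicate the node declines;
    supply a final ``(True, default)`` pair for a catch-all.
    """
    if not pairs:
        raise ValueError("cond requires at least one (predicate, value) pair")
    sig_args = [x for p in pairs for x in p if isinstance(x, Signal)]
    if not sig_args:
        raise ValueError("cond requires at least one Signal among its pairs")
    _check_same_net(*sig_args)
    net = sig_args[0].network
    input_ids = sorted({s.node_id for s in sig_args})

    def current(net_, x, default):
        if isinstance(x, Signal):
            src = net_.nodes[x.node_id]
            return src.current_value if src.has_value else default
        return x

    def transfer(net_, node, emitted):
        for pred, val in pairs:
            if truthy(current(net_, pred, EMPTY)):
                v = current(net_, val, EMPTY)
                if v is not EMPTY:
                    return v
        return EMPTY

    return net._add_node(name or "cond", "cond", input_ids, transfer)


# -- benchmark-style layered networks -------------------------------------

def build_benchmark_network(net: Network, n_nodes: int, depth: int,
                            seed: int) -> tuple[Signal, list[int]]:
    """Build one origin plus ``n_nodes - 1`` lifted nodes spread as evenly
    as possible over ``depth`` layers; each node sums 1-2 inputs drawn
    uniformly (seeded) from the previous layer.

    Returns the origin signal and the list of all node ids created, in
    creation order.  Used to exercise the single-update and topological
    invariants on wide/deep graphs.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if n_nodes < depth:
        raise ValueError(
            f"n_nodes ({n_nodes}) must be >= depth ({depth})")
    rng = np.random.default_rng(seed)
    origin = net.origin("bench_origin")
    ids = [origin.node_id]
    remaining = n_nodes - 1
    sizes = [len(chunk) for chunk in np.array_split(np.arange(remaining), depth)]
    prev_layer = [origin]
    for layer_idx, size in enumerate(sizes, start=1):
        if size == 0:
            continue
        this_layer = []
        for j in range(size):
            k = int(rng.integers(1, 3))
            k = min(k, len(prev_layer))
            picks = rng.choice(len(prev_layer), size=k, replace=False)
            srcs = [prev_layer[int(i)] for i in picks]
            node = lift(lambda *vs: sum(vs) + 1, *srcs,
                        name=f"bench_L{layer_idx}_{j}")
            this_layer.append(node)
            ids.append(node.node_id)
        prev_layer = this_layer
    return origin, ids


# -- emission log export ----------------------------------------------------

def _json_value(v: Any) -> Any:
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, (np.bool_,)):
        return bool(v)
    if isinstance(v, np.integer):
        return int(v)
    if isinstance(v, np.floating):
        return float(v)
    if isinstance(v, dict):
        return {k: _json_value(x) for k, x in v.items()}
    if isinstance(v, (list, tuple)):
        return [_json_value(x) for x in v]
    return v


def records_to_jsonl(records: Iterable[UpdateRecord]) -> str:
    """Serialize emission records as JSON Lines (one object per record)."""
    lines = []
    for r in records:
        lines.append(json.dumps(
            {"node": r.node_id, "name": r.name, "tx": r.tx,
             "value": _json_value(r.value)},
            sort_keys=False, separators=(",", ":")))
    return "\n".join(lines) + ("\n" if lines else "")


def write_emission_log(records: Iterable[UpdateRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(records_to_jsonl(records))
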