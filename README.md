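# fret — functional reactive experiment toolkit

`fret` is a headless Python engine for designing and simulating
behavioral-neuroscience experiments in the functional-reactive style.
Instead of writing a state machine that polls hardware and mutates task
state, the experimenter declares a network of *signals* — time-varying
values such as the clock, a wheel position, a grating's orientation, or
a running score — and pure transformations between them. Posting a new
value to an input signal runs one deterministic transaction that
propagates through the dependency graph, so a task definition is a
concise, declarative record of the experiment and every session is
exactly reproducible from its seed and input trace.

The toolkit provides:

* **`fret.network`** — the reactive core: a DAG of signals with the
  stream operators used in task design (`map`, `scan`, `buffer`,
  `at`, `then`, `skip_repeats`, `cond`, field subscripting, lifted
  arithmetic/comparison), value listeners, and glitch-free propagation
  (each node updates at most once per transaction, in a topological
  order fixed by construction).
* **`fret.runtime`** — the experiment runner: a task is a function of up
  to seven arguments `(t, events, params, visual, inputs, outputs,
  audio)` called once to wire the network; the runner resolves global
  and per-trial conditional signal parameters, drives the clock,
  replays scripted hardware inputs, sequences trials on `endTrial`, and
  logs every registered signal until `expStop` or the duration cap.
* **`fret.stimulus`** — a visual-degree stimulus model (gratings and
  patches whose fields are signals) with a deterministic software
  rasterizer for tests and demos.
* **`fret.timeline`** — simulated multi-clock acquisition and
  chrono-based alignment: per-flip offsets `o_k = d_k − s_k` between a
  clocking square wave's DAQ stamp and its commanded system time map
  every event stamp into one unified timebase
  (`unified = raw − o_k` for the latest flip with `d_k ≤ raw`).
* **`fret.examples`** — two complete tasks run end-to-end by simulated
  agents: a reverse-correlation psychophysics experiment (report
  vertical gratings in a 10 Hz orientation/phase stream; a
  reaction-time-lagged histogram of the last 10 frames reveals the
  reported orientation) and Pong (cursor-driven paddle, game state in
  one `scan` fold, a trial per score, session ends at the target
  score).
* **`fret.session`** + a `fret` CLI — experiment reference strings
  (`yyyy-mm-dd_seq_subject`), path resolution from a single paths
  config, deterministic session persistence, and a propagation
  benchmark harness.

## Worked example

The reverse-correlation task in ~10 lines: a sampler ticks at 10 Hz,
each tick draws an orientation from `0:18:162` degrees, the one-hot
orientation mask is buffered over the last 10 frames, and every "ctrl"
press adds the buffered snapshot to a histogram:

```python
import numpy as np
from fret import Network, RingachConfig, build_ringach, lag_column

net = Network()
h = build_ringach(net, RingachConfig(seed=7))
for k in range(1, 1001):               # one simulated second, 1 ms steps
    net.post(h.t, k * 0.001)
net.post(h.key_events, {"Key": "ctrl"})  # one report
print(h.histogram.value.sum())           # -> 10.0 (one 10-frame snapshot)
```

Running the full five-minute session with a simulated observer who
reports every vertical grating 600 ms (six frames) late:

```sh
$ fret demo ringach --duration 300 --seed 7 --out demo
275 reports over 3001 frames; lag-6 peak at 90 deg -> demo/ringach_histogram.csv
```

The histogram CSV has one row per orientation and one column per frame
lag before the press. All 275 usable reports land on 90° in the lag-6
column — the observer's reaction time — while every other lag carries
the uniform stimulus draws (~27 counts per orientation):

```
orientation_deg,lag_10,lag_9,lag_8,lag_7,lag_6,lag_5,lag_4,lag_3,lag_2,lag_1
0.0,24,22,34,26,0,21,26,22,22,17
18.0,26,30,23,38,0,28,25,36,32,29
...
90.0,31,27,24,26,275,29,25,28,23,27
```

Pong with the tracking cursor bot, and the propagation benchmark:

```sh
$ fret demo pong --duration 600 --seed 5 --target-score 3 --out demo
session ended: expStop; trials 3; final score 3-0 -> demo/pong_scores.csv
$ fret bench --nodes 350 --depth 20 --reps 100 --seed 1
100/100 reps passed the single-update check on 350 nodes / 20 layers; mean propagation 0.543 ms
```

(Benchmark timings are reported for orientation only; the harness
asserts propagation correctness, never speed.)

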