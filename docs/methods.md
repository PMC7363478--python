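# Methods

## Propagation model

A network is a list of nodes with dense integer ids assigned in
creation order. Operators can only reference signals that already
exist, so every node's inputs have smaller ids than its own: the graph
is acyclic by construction and ascending id order is a valid
topological order. Posting a value to an origin runs one *transaction*:
the origin commits its value, then every later node whose inputs
include at least one emitter of this transaction runs its transfer
exactly once, either committing a value or declining. After the pass,
value listeners fire in node-id order with committed values.

Production reactive systems often propagate updates asynchronously via
callbacks; this engine deliberately makes propagation synchronous and
transactional so that a session is a pure function of (task definition,
seed, input script, clock step) and replays are byte-identical. Posts
issued from inside a transaction — by a listener or a transfer side
effect — are queued FIFO and run as subsequent transactions; nesting is
forbidden. A queued post returns an empty record list because its
transaction has not yet run.

Two conventions follow MATLAB semantics, since the task idioms this
engine targets were shaped by them: truthiness (numbers nonzero; arrays
truthy iff nonempty *and* all elements truthy) and equality for
`skip_repeats` (deep elementwise; shape mismatch means "changed").

Operator edge cases that matter downstream:

* `scan(fn, seed)` sets the node's current value to the seed *without*
  emitting, so `value.at(trigger)` over a scan output can sample the
  seed before the first accumulation.
* `buffer(n)` emits only once n emissions have occurred, always with a
  fixed shape (the accumulating histogram addition needs constant
  shape).
* `cond` scans its (predicate, value) pairs in order and declines when
  none is truthy; a `(True, default)` catch-all pair gives clamp-style
  selection.
* Field subscripting (`sig["Key"]`) declines when the field is absent
  and never dedupes; wrap with `skip_repeats` if change detection is
  wanted.
* Listener errors are logged and swallowed; transfer errors abort the
  transaction with the offending node named.

## Experiment runtime

A task definition runs exactly once, at build time. The runner owns
four origins — the clock `t` (seconds since session start), `expStart`,
`newTrial`, and `expStop` — plus one origin per hardware input channel,
created lazily when the task reads `inputs.<channel>`.

Signal parameters mirror the access-before-declare idiom: reading
`params.name` creates the parameter's origin; assigning a default
attaches columns to it. A default that is a 2-D array with more than
one column is *conditional* (columns along the last axis, one column
drawn per trial); anything else is *global* (one value per session).
All conditional parameters must agree on the column count, and a single
uniform draw per trial indexes every conditional parameter at once so
the condition stays coherent. Draws are uniform with replacement from
the session RNG; the index sequence is a deterministic function of the
seed. An externally supplied parameter set overrides task defaults
name-by-name.

The loop posts parameter values, `expStart`, and the first `newTrial`,
then advances simulated time by `clock_step` (default 0.01 s): script
events due at or before the current time are posted first (so a
scheduled hardware event is seen by the subsequent clock update), then
`t`. A truthy emission of the user's `events.endTrial` advances the
trial (fresh conditional draws, `newTrial` post); a truthy
`events.expStop` ends the session before any further trial advance, so
the final scoring trial is not followed by a phantom trial. With no
`endTrial` the session is a single trial. The duration cap posts
exactly `round(duration / clock_step)` clock updates.

## Stimulus model

The viewing model is linear small-angle: `px = deg * px_per_deg`, with
the screen center at (azimuth, altitude) = (0, 0). Grating pixels
follow

    I = 0.5 + 0.5 * contrast * color_ch * w(x, y)
        * cos(2*pi*sf*(x*cos(th) + y*sin(th)) + phase)

with orientation `th` the direction of the carrier wave vector
(counterclockwise from +azimuth), `sf` in cycles/degree, phase in
radians, and `w` either a Gaussian window `exp(-(x^2+y^2)/(2*sigma^2))`
or 1. Patches fill a rectangle or circle with their color. Elements
whose `show` field is falsy or valueless are skipped. Assigning a
signal to a field attaches a listener that marks the element dirty;
the `Renderer` returns the cached frame when nothing is dirty, which is
how "no change, bit-identical frame" is guaranteed. Phase is stored in
radians throughout; the degree-valued phase set of the psychophysics
task is converted where assigned. The grating-orientation estimator
used in tests recovers the carrier direction from the structure tensor
of the image gradient.

## Time alignment

An acquisition clock is modelled as `daq(t) = a*t + b + N(0, sigma^2)`
with drift `a − 1` (unitless), offset `b` and jitter `sigma` in
seconds. Chrono flips every `chunk_period`; each flip records the
offset `o_k = d_k − s_k`. Conversion is piecewise-constant: an event
uses the offset of the latest flip at or before it (events before the
first flip use the first offset). Holding rather than interpolating the
offset matches per-flip bookkeeping and gives the error bound
`|unified − true| ≤ |a−1| * chunk_period + 3*sigma` inside the
recording, which the tests assert at 100 ppm drift. System-domain
events pass through unchanged: the unified timebase *is* the master
system clock. Pulse trains are generated by modular arithmetic on
sample indices so edge counts are exact for commensurate rates; a
sample exactly on the duty boundary falls low.

## Simulated agents and what they do not show

The psychophysics observer is deterministic by default: every
presentation of the target orientation schedules a "ctrl" press
exactly `delay` seconds later (an optional Gaussian jitter parameter
exists for robustness checks). Sessions use a 0.01 s clock step, so
presses land on the step at their scheduled time and are posted before
that step's clock update; with a 0.6 s delay at 10 Hz the triggering
frame therefore sits exactly six frames back in the buffered window.
Counting from the most recent frame (`lag_column(hist, 6)`), all usable
reports fall on the target orientation at lag 6, and the other lags
carry the uniform stimulus draws. Real observers have variable reaction
times and miss rates, which would spread the lag-6 mass over
neighbouring lags and orientations — passing tests show the pipeline's
bookkeeping, not human psychophysics. Presses whose triggering frame
precedes window fill (at most the first three frames of a session) are
counted as reports but cannot contribute to the histogram.

Pong physics is a package design choice, since only the updated state
variables (ball angle/velocity/position, cpu paddle, scores) are fixed
by the task's structure. Defaults: 40×30 deg arena, ball radius 1 deg,
1×6 deg paddles at ±18 deg, ball speed 20 deg/s, game tick 0.02 s, cpu
paddle slew-limited to 10 deg/s, cursor gain 1. The ball reflects its
vertical component at |y| = arenaH/2 − ballR and its horizontal
component at a paddle plane when moving toward it within half a paddle
height; an off-center hit adds `offset * speed * sin(60°)` to the
vertical velocity, renormalized so speed is conserved. This deflection
is what makes sessions terminate: with pure mirror reflection a rally
between the tracking bot and the tracking cpu never redraws the serve
angle, so a shallow serve is returned forever by both sides. As a
backstop, a rally with no score for 20 s is re-served (no score).
Serves leave the center at a seeded uniform angle in (−60°, 60°) ∪
(120°, 240°). Scores are monotone; `endTrial` fires once per score
(dedupe of the score total), so scores always sum to completed trials
and the session ends exactly when a score reaches the target.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale: 2 s clock
ramps at 1 ms steps for the phase-frequency fit, 1 s for the sampler
rate, a 300 s observer session (~3000 frames, ~300 reports) for the
reverse-correlation peak, operator-oracle equivalence on 1000 random
streams, layered-graph invariants up to 500 nodes (including the
350-node/20-layer and 120-node/20-layer shapes), and Pong to a target
score of 3. These sizes make every property deterministic or
overwhelmingly stable under the fixed seeds while the whole suite runs
in seconds. Float boundaries in `floor(rate * t)` are benign at these
step sizes because binary rounding of `k * 0.001` lands at or above the
exact decimal, never below the next integer multiple.

## Known limitations

* No real hardware, rendering backend, audio synthesis, or networking:
  inputs are scripted or bot-driven, stimuli rasterize to arrays, audio
  and external outputs are log-only sinks.
* The delay/merge/keep-when family of stream operators is out of scope;
  tasks needing them can usually be expressed with `at`/`cond`/`scan`.
* Conditional parameters are drawn with replacement; balanced or
  exhaustive condition assortment is not implemented.
* Offset interpolation between chrono flips is piecewise-constant;
  linear interpolation would halve the drift term in the alignment
  bound but is left as an extension.
* The viewing model ignores physical screen geometry (distance,
  curvature); positions are linear in visual degrees.
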