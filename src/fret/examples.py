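"""Worked example tasks, run headlessly end-to-end.

Two classic interactive tasks exercise the whole stack:

* A reverse-correlation psychophysics task: a grating changes orientation
  and phase at 10 Hz, drawn uniformly from fixed sets; the observer hits
  the "ctrl" key whenever the grating looks vertical.  At every key press
  the one-hot orientation history of the last ``winlen`` frames is added
  into an orientations x frames histogram, whose peak exposes the
  reported orientation at the observer's reaction-time lag.

* Pong: the player's paddle follows the cursor (gain + clamp, sampled on
  a fixed game tick), the whole game state lives in one scan fold, a
  trial ends on every score, and the session ends when either side
  reaches the target score.

Both come with simulated agents (a fixed-delay observer; a
perfect-tracker or absent cursor bot) so sessions need no human.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable

import numpy as np

from .network import Network, Signal, cond, lift, sfloor
from .runtime import (
    ExperimentHandle, ParamSet, SessionLog, build_experiment, run_loop,
)

__all__ = [
    "RingachConfig",
    "RingachHandles",
    "RingachResult",
    "build_ringach",
    "simulated_observer",
    "run_ringach_session",
    "lag_column",
    "PongConfig",
    "make_pong_expdef",
    "update_game",
    "initial_game_state",
    "run_pong_session",
]


# ---------------------------------------------------------------------------
# Example 1: reverse-correlation psychophysics
# ---------------------------------------------------------------------------

@dataclass
class RingachConfig:
    """Stimulus constants: ten orientations 0..162 deg in 18 deg steps,
    four phases (90..360 deg), 10 Hz presentation, 10-frame window."""

    oris: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 180.0, 18.0))
    phases: np.ndarray = field(
        default_factory=lambda: np.arange(90.0, 361.0, 90.0))
    presentation_rate: float = 10.0  # Hz
    winlen: int = 10                 # frames
    seed: int = 0


@dataclass
class RingachHandles:
    t: Signal
    key_events: Signal
    reports: Signal
    sampler: Signal
    ori_idx: Signal
    phase_idx: Signal
    curr_ori: Signal
    curr_phase: Signal
    ori_mask: Signal
    ori_history: Signal
    histogram: Signal
    config: RingachConfig


def build_ringach(net: Network, config: RingachConfig) -> RingachHandles:
    """Wire the task network.

    ``sampler`` ticks at the presentation rate (dedupe of the floored
    scaled clock); each tick draws fresh 1-based indices into the
    orientation and phase sets; the one-hot orientation mask is buffered
    over ``winlen`` frames and, at each truthy report, the buffered
    snapshot is added into the accumulating histogram.
    """
    cfg = config
    oris = np.asarray(cfg.oris, dtype=float)
    phases = np.asarray(cfg.phases, dtype=float)
    rng = np.random.default_rng(cfg.seed)

    t = net.origin("t")
    key_events = net.origin("keyPresses")
    reports = key_events["Key"].eq("ctrl")
    sampler = sfloor(cfg.presentation_rate * t).skip_repeats(name="sampler")
    ori_idx = sampler.map(lambda _: int(rng.integers(1, oris.size + 1)),
                          name="oriIdx")
    phase_idx = sampler.map(lambda _: int(rng.integers(1, phases.size + 1)),
                            name="phaseIdx")
    curr_ori = ori_idx.map(lambda i: float(oris[i - 1]), name="currOri")
    curr_phase = phase_idx.map(lambda i: float(phases[i - 1]),
                               name="currPhase")
    ori_mask = lift(lambda o: oris == o, curr_ori, name="oriMask")
    ori_history = ori_mask.buffer(cfg.winlen, name="oriHistory")
    histogram = ori_history.at(reports).scan(
        np.add, np.zeros((oris.size, cfg.winlen)), name="histogram")
    return RingachHandles(t, key_events, reports, sampler, ori_idx, phase_idx,
                          curr_ori, curr_phase, ori_mask, ori_history,
                          histogram, cfg)


def lag_column(histogram: np.ndarray, lag_frames: int) -> np.ndarray:
    """Histogram counts at a given frame lag before the report (1-based:
    lag 1 is the most recent frame; buffered columns are oldest first)."""
    winlen = histogram.shape[1]
    if not 1 <= lag_frames <= winlen:
        raise ValueError("lag must be in 1..winlen")
    return histogram[:, winlen - lag_frames]


def simulated_observer(target_ori: float, delay: float
                       ) -> Callable[[Iterable[tuple[float, float]]],
                                     list[tuple[float, str, Any]]]:
    """Fixed-delay observer: given the (time, orientation) presentation
    trace, schedule a ctrl key event ``delay`` seconds after every
    presentation of ``target_ori``.  Returns an input-script fragment
    builder (entries ``(time, "keyboard", {"Key": "ctrl"})``)."""
    if delay < 0:
        raise ValueError("observer delay must be nonnegative")

    def make_script(trace: Iterable[tuple[float, float]]
                    ) -> list[tuple[float, str, Any]]:
        return [(t + delay, "keyboard", {"Key": "ctrl"})
                for t, ori in trace if ori == target_ori]

    return make_script


@dataclass
class RingachResult:
    histogram: np.ndarray
    report_count: int
    sampler_ticks: int
    curr_ori_trace: list[tuple[float, float]]
    config: RingachConfig


def run_ringach_session(config: RingachConfig, duration_s: float,
                        target_ori: float = 90.0,
                        observer_delay_s: float = 0.6,
                        clock_step: float = 0.01,
                        observer_jitter_s: float = 0.0) -> RingachResult:
    """Run the task for ``duration_s`` simulated seconds with the
    fixed-delay observer in the loop.

    The clock is posted every ``clock_step`` seconds; key events fall on
    the first step at or after their scheduled time and are posted before
    that step's clock update (so the frame presented at the scheduled
    press time is not yet in the buffered window — the press sees the
    ``winlen`` frames already shown).
    """
    net = Network()
    h = build_ringach(net, config)
    now = [0.0]
    pending: deque[float] = deque()
    jit_rng = (np.random.default_rng(config.seed + 1)
               if observer_jitter_s > 0 else None)
    trace: list[tuple[float, float]] = []
    counts = {"reports": 0, "ticks": 0}

    def on_ori(v):
        trace.append((now[0], v))
        if v == target_ori:
            d = observer_delay_s
            if jit_rng is not None:
                d = max(0.0, d + jit_rng.normal(0.0, observer_jitter_s))
            pending.append(now[0] + d)

    h.curr_ori.on_value(on_ori)
    h.sampler.on_value(lambda _v: counts.__setitem__(
        "ticks", counts["ticks"] + 1))
    h.reports.on_value(lambda v: counts.__setitem__(
        "reports", counts["reports"] + (1 if v else 0)))

    n_steps = int(round(duration_s / clock_step))
    for k in range(1, n_steps + 1):
        now[0] = k * clock_step
        while pending and pending[0] <= now[0] + 1e-12:
            pending.popleft()
            net.post(h.key_events, {"Key": "ctrl"})
        net.post(h.t, now[0])

    hist = np.array(h.histogram.node.current_value, dtype=float)
    return RingachResult(hist, counts["reports"], counts["ticks"], trace,
                         config)


# ---------------------------------------------------------------------------
# Example 2: Pong
# ---------------------------------------------------------------------------

@dataclass
class PongConfig:
    """Game constants, all in visual degrees / seconds."""

    t_update: float = 0.02            # game tick, s
    arena: tuple[float, float] = (40.0, 30.0)   # (w, h)
    ball_radius: float = 1.0
    paddle_dims: tuple[float, float] = (1.0, 6.0)  # (w, h)
    paddle_x: float = 18.0            # player at +x, cpu at -x
    ball_speed: float = 20.0          # deg/s
    cpu_speed: float = 10.0           # max cpu paddle speed, deg/s
    max_deflect_deg: float = 60.0     # paddle-edge deflection angle
    rally_timeout_s: float = 20.0     # re-serve a rally after this long
    cursor_gain: float = 1.0
    target_score: int = 5
    ball_colors: tuple = ((1.0, 1.0, 1.0), (1.0, 0.0, 0.0), (0.0, 0.0, 1.0))
    seed: int = 0


def _serve_angle(rng: np.random.Generator) -> float:
    """Random serve direction in (-60, 60) or (120, 240) degrees, so the
    ball always has substantial horizontal velocity."""
    u = float(rng.uniform(0.0, 240.0))
    return u - 60.0 if u < 120.0 else u


def initial_game_state(config: PongConfig,
                       rng: np.random.Generator) -> dict[str, Any]:
    return {
        "ballPos": (0.0, 0.0),
        "ballAngle": _serve_angle(rng),
        "ballVel": config.ball_speed,
        "cpuPaddleY": 0.0,
        "playerScore": 0,
        "cpuScore": 0,
        "rallySecs": 0.0,
    }


def update_game(state: dict[str, Any], player_paddle_y: float,
                config: PongConfig, rng: np.random.Generator
                ) -> dict[str, Any]:
    """One game tick: advance the ball, reflect off walls and paddles,
    score and re-serve when the ball leaves the arena, and move the cpu
    paddle toward the ball at its capped speed.

    Paddle hits deflect: the outgoing direction depends on where the
    ball strikes the paddle (center hit returns the ball straight back,
    edge hits send it off at up to ``max_deflect_deg``), which is what
    keeps rallies from locking into a periodic orbit.  Reflections
    change only the angle, so ball speed is conserved.
    """
    s = dict(state)
    dt = config.t_update
    half_w, half_h = config.arena[0] / 2, config.arena[1] / 2
    wall_y = half_h - config.ball_radius
    paddle_half_h = config.paddle_dims[1] / 2
    ang = math.radians(s["ballAngle"])
    vx, vy = s["ballVel"] * math.cos(ang), s["ballVel"] * math.sin(ang)
    x, y = s["ballPos"]
    nx, ny = x + vx * dt, y + vy * dt

    # vertical walls: reflect the vertical velocity component
    if ny > wall_y:
        ny = 2 * wall_y - ny
        vy = -vy
    elif ny < -wall_y:
        ny = -2 * wall_y - ny
        vy = -vy

    # paddle planes: reflect the horizontal component when the ball
    # crosses a plane moving toward it within reach of the paddle; an
    # off-center hit additionally deflects the vertical component
    px = config.paddle_x
    speed = s["ballVel"]
    kick = speed * math.sin(math.radians(config.max_deflect_deg))

    def _return(vy_in: float, offset: float, direction: float
                ) -> tuple[float, float]:
        vy_out = vy_in + offset * kick
        vy_out = float(np.clip(vy_out, -0.95 * speed, 0.95 * speed))
        vx_out = direction * math.sqrt(speed ** 2 - vy_out ** 2)
        return vx_out, vy_out

    if vx > 0 and x <= px <= nx and abs(ny - player_paddle_y) <= paddle_half_h:
        nx = 2 * px - nx
        vx, vy = _return(vy, (ny - player_paddle_y) / paddle_half_h, -1.0)
    elif vx < 0 and nx <= -px <= x and abs(ny - s["cpuPaddleY"]) <= paddle_half_h:
        nx = -2 * px - nx
        vx, vy = _return(vy, (ny - s["cpuPaddleY"]) / paddle_half_h, +1.0)

    # scoring: ball out on one side, the opposite side scores; re-serve.
    # A rally that drags on past the timeout is re-served without a
    # score so a session cannot stall on an unbreakable rally.
    rally_s = s.get("rallySecs", 0.0) + dt
    if nx > half_w:
        s["cpuScore"] = s["cpuScore"] + 1
        nx, ny, rally_s = 0.0, 0.0, 0.0
        s["ballAngle"] = _serve_angle(rng)
    elif nx < -half_w:
        s["playerScore"] = s["playerScore"] + 1
        nx, ny, rally_s = 0.0, 0.0, 0.0
        s["ballAngle"] = _serve_angle(rng)
    elif rally_s >= config.rally_timeout_s:
        nx, ny, rally_s = 0.0, 0.0, 0.0
        s["ballAngle"] = _serve_angle(rng)
    else:
        s["ballAngle"] = math.degrees(math.atan2(vy, vx))
    s["rallySecs"] = rally_s

    # cpu paddle tracks the ball, capped at cpu_speed
    step = np.clip(ny - s["cpuPaddleY"], -config.cpu_speed * dt,
                   config.cpu_speed * dt)
    s["cpuPaddleY"] = s["cpuPaddleY"] + float(step)
    s["ballPos"] = (nx, ny)
    return s


def make_pong_expdef(config: PongConfig) -> Callable:
    """Build the Pong experiment definition (the seven-argument task
    function); call it through :func:`fret.runtime.build_experiment`."""

    def pong_expdef(t, events, p, visStim, inputs, outputs, audio):
        from .stimulus import make_patch
        rng = np.random.default_rng(config.seed)
        half_h = config.arena[1] / 2

        cursor = inputs.cursor
        cursor_initial = events.expStart.map(lambda _v: 0.0,
                                             name="cursorInitialY")
        update_val = (cursor - cursor_initial) * config.cursor_gain
        paddle_bounds = cond(
            (update_val > half_h, half_h),
            (update_val < -half_h, -half_h),
            (True, update_val),
            name="playerPaddleBounds")
        tick = sfloor(t / config.t_update).skip_repeats().map(
            lambda _v: True, name="tUpdate")
        player_paddle_y = paddle_bounds.at(tick, name="playerPaddleY")

        init = initial_game_state(config, rng)
        game_data = player_paddle_y.scan(
            lambda s, yv: update_game(s, yv, config, rng), init,
            name="gameData").subscriptable()
        player_score = game_data.playerScore
        cpu_score = game_data.cpuScore

        # one trial per score: dedupe the running score total
        any_scored = (player_score + cpu_score).skip_repeats() > 0
        events.endTrial = any_scored.then(True)
        target = p.targetScore
        end_game = player_score.eq(target) | cpu_score.eq(target)
        events.expStop = end_game.then(True)
        events.playerScore = player_score
        events.cpuScore = cpu_score
        events.ballY = game_data.ballPos.map(lambda pos: pos[1], name="ballY")
        events.playerPaddleY = player_paddle_y

        arena = make_patch(t, "rectangle")
        arena.dims = config.arena
        arena.color = (0.0, 0.0, 0.0)
        ball = make_patch(t, "circle")
        ball.dims = (2 * config.ball_radius,)
        ball.color = p.ballColor
        ball.azimuth = game_data.ballPos.map(lambda pos: pos[0])
        ball.altitude = game_data.ballPos.map(lambda pos: pos[1])
        player_paddle = make_patch(t, "rectangle")
        player_paddle.dims = config.paddle_dims
        player_paddle.azimuth = config.paddle_x
        player_paddle.altitude = player_paddle_y
        cpu_paddle = make_patch(t, "rectangle")
        cpu_paddle.dims = config.paddle_dims
        cpu_paddle.azimuth = -config.paddle_x
        cpu_paddle.altitude = game_data.cpuPaddleY
        visStim.arena = arena
        visStim.ball = ball
        visStim.playerPaddle = player_paddle
        visStim.cpuPaddle = cpu_paddle

        # parameter defaults: conditional ball color (one column drawn
        # per trial), global target score
        p.ballColor = np.asarray(config.ball_colors, dtype=float).T
        p.targetScore = config.target_score

    return pong_expdef


def run_pong_session(config: PongConfig | None = None,
                     paramset: ParamSet | None = None,
                     seed: int = 0, duration_s: float = 600.0,
                     bot: str = "tracker"
                     ) -> tuple[SessionLog, ExperimentHandle]:
    """Run a full Pong session with a cursor bot.

    ``bot="tracker"`` posts the ball's y position back to the cursor
    after every game tick (a player that never misses); ``bot="absent"``
    leaves the cursor parked at 0.  The session ends when a score
    reaches the target, or at the duration cap.
    """
    config = config or PongConfig(seed=seed)
    handle = build_experiment(make_pong_expdef(config), paramset, seed=seed,
                              clock_step=config.t_update, duration=duration_s)
    cursor = handle.inputs.entries["cursor"]
    if bot == "tracker":
        handle.events.entries["ballY"].on_value(
            lambda yv: handle.net.post(cursor, yv / config.cursor_gain))
    elif bot != "absent":
        raise ValueError(f"unknown bot {bot!r}")
    script = [(config.t_update / 2, "cursor", 0.0)]
    log = run_loop(handle, script)
    return log, handle
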