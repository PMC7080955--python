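"""1-up-3-down adaptive staircase controlling the SOA of a TOJ block.

The SOA starts high (easy), drops by one step after every run of three
consecutive correct responses and rises by one step after every error. A
reversal is a change of direction between two successively *applied* moves;
the block terminates once a fixed reversal count is reached. The procedure
converges on the SOA at which P(correct) = 0.5^(1/3) ~ 0.794.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .observer import ObserverParams, StimulusEvent, simulate_response

_GRID_TOL = 1e-9


@dataclass(frozen=True)
class StaircaseConfig:
    """Staircase rule parameters; times in ms, on the display frame grid."""

    soa_start: float = 267.0
    step: float = 16.7
    n_down: int = 3
    n_up: int = 1
    max_reversals: int = 14
    soa_min: float = 16.7
    soa_max: float = 500.0
    frame_ms: float = 16.7
    max_trials: int = 10_000

    def __post_init__(self) -> None:
        # 0.05-frame slack admits conventionally rounded times (e.g. a 267 ms
        # start on a 60 Hz display, which is 16 frames = 267.2 ms exactly)
        for name in ("soa_start", "step"):
            v = getattr(self, name)
            if abs(v / self.frame_ms - round(v / self.frame_ms)) > 0.05:
                raise ValueError(f"{name}={v} is not a multiple of frame_ms={self.frame_ms}")
        if self.soa_min < self.frame_ms - _GRID_TOL:
            raise ValueError("soa_min must be at least one display frame")
        if self.max_reversals < 1:
            raise ValueError("max_reversals must be >= 1")


@dataclass
class StaircaseState:
    soa: float
    correct_streak: int = 0
    last_move: str = "none"  # {"down", "up", "none"}
    reversals: int = 0
    terminated: bool = False
    history: list = field(default_factory=list)  # (soa, correct) per trial

    @classmethod
    def initial(cls, cfg: StaircaseConfig) -> "StaircaseState":
        return cls(soa=cfg.soa_start)


def update_state(state: StaircaseState, correct: bool, cfg: StaircaseConfig) -> StaircaseState:
    """Apply one trial outcome at the state's current SOA; returns new state.

    An incorrect response raises the SOA by one step and resets the correct
    streak; the ``n_down``-th consecutive correct response lowers it by one
    step. Moves are clamped to [soa_min, soa_max]; a move fully absorbed by
    the clamp is not an applied move and cannot produce a reversal.
    """
    if state.terminated:
        raise RuntimeError("update_state called on a terminated staircase")

    soa = state.soa
    streak = state.correct_streak
    intended = None
    if correct:
        streak += 1
        if streak >= cfg.n_down:
            intended = "down"
            streak = 0
    else:
        intended = "up"
        streak = 0

    new_soa = soa
    applied = None
    if intended == "down":
        new_soa = max(soa - cfg.step, cfg.soa_min)
    elif intended == "up":
        new_soa = min(soa + cfg.step, cfg.soa_max)
    if intended is not None and abs(new_soa - soa) > _GRID_TOL:
        applied = intended

    reversals = state.reversals
    last_move = state.last_move
    if applied is not None:
        if last_move in ("down", "up") and applied != last_move:
            reversals += 1
        last_move = applied

    return replace(
        state,
        soa=new_soa,
        correct_streak=streak,
        last_move=last_move,
        reversals=reversals,
        terminated=reversals >= cfg.max_reversals,
        history=state.history + [(soa, bool(correct))],
    )


def run_block(
    obs: ObserverParams,
    condition: str,
    cfg: StaircaseConfig | None = None,
    rng: np.random.Generator | None = None,
    **labels,
) -> list[dict]:
    """Run one staircase block for an observer; returns per-trial records.

    Target side, cue side and target orientation are each drawn independently
    with probability 0.5. ``labels`` (e.g. participant/session/phase/block)
    are copied into every record. The trial on which the final reversal
    occurs is included; nothing after it.
    """
    cfg = cfg or StaircaseConfig()
    rng = rng if rng is not None else np.random.default_rng()
    state = StaircaseState.initial(cfg)
    trials: list[dict] = []
    while not state.terminated:
        if len(trials) >= cfg.max_trials:
            raise RuntimeError(
                f"staircase exceeded {cfg.max_trials} trials without terminating "
                f"(reversals={state.reversals}); pathological observer?"
            )
        first_side = "right" if rng.random() < 0.5 else "left"
        cue_side = "right" if rng.random() < 0.5 else "left"
        orientation = "vertical" if rng.random() < 0.5 else "horizontal"
        ev = StimulusEvent(
            first_side=first_side, cue_side=cue_side, condition=condition, soa=state.soa
        )
        response, correct = simulate_response(obs, ev, rng)
        trials.append(
            dict(
                **labels,
                condition=condition,
                trial=len(trials) + 1,
                cue_side=cue_side,
                first_side=first_side,
                signed_soa_ms=ev.signed_soa,
                response=response,
                correct=int(correct),
                orientation=orientation,
                reversals=state.reversals,  # reversals completed before this trial
            )
        )
        state = update_state(state, correct, cfg)
    return trials
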