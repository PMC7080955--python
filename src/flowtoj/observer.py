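"""Generative model of a temporal-order-judgement (TOJ) observer.

The observer reports which of two lateralised targets (left/right) appeared
first. Its behaviour is a lapse-contaminated logistic psychometric function of
the signed stimulus onset asynchrony (SOA; positive = right target first),
horizontally shifted by an attentional prior-entry term that depends on the
cue side and cue type (exogenous peripheral vs endogenous central).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

LN3 = math.log(3.0)

SIDES = ("left", "right")
CONDITIONS = ("endogenous", "exogenous")


@dataclass(frozen=True)
class ObserverParams:
    """Latent parameters of one simulated observer in one block.

    Parameters
    ----------
    scale_s : float
        Logistic scale of temporal discrimination in ms; the implied just
        noticeable difference is ``JND = scale_s * ln(3)``.
    lapse : float
        Stimulus-independent lapse probability in [0, 0.1]; a lapse trial
        draws "left"/"right" with equal probability.
    shift_exo, shift_endo : float
        Prior-entry shift of the point of subjective simultaneity in ms under
        an exogenous / endogenous cue. Positive values shift perception in
        favour of the cued side; negative values (attention repelled from the
        cue) are admitted because noisy session-level effects can reverse the
        cued advantage.
    """

    scale_s: float
    lapse: float = 0.0
    shift_exo: float = 0.0
    shift_endo: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.scale_s) and self.scale_s > 0):
            raise ValueError(f"scale_s must be finite and positive, got {self.scale_s}")
        if not (np.isfinite(self.lapse) and 0.0 <= self.lapse <= 0.1):
            raise ValueError(f"lapse must lie in [0, 0.1], got {self.lapse}")
        if not (np.isfinite(self.shift_exo) and np.isfinite(self.shift_endo)):
            raise ValueError("prior-entry shifts must be finite")

    @property
    def jnd(self) -> float:
        """Implied just noticeable difference in ms (75%-correct half-width)."""
        return self.scale_s * LN3

    def shift(self, condition: str) -> float:
        if condition == "exogenous":
            return self.shift_exo
        if condition == "endogenous":
            return self.shift_endo
        raise ValueError(f"unknown condition {condition!r}")

    @classmethod
    def from_jnd(cls, jnd: float, **kwargs) -> "ObserverParams":
        """Build an observer from a target JND in ms (scale_s = JND / ln 3)."""
        return cls(scale_s=jnd / LN3, **kwargs)


@dataclass(frozen=True)
class StimulusEvent:
    """One TOJ stimulus presentation.

    ``soa`` is the unsigned onset asynchrony in ms; ``signed_soa`` is positive
    when the right target leads.
    """

    first_side: str
    cue_side: str
    condition: str
    soa: float

    def __post_init__(self) -> None:
        if self.first_side not in SIDES:
            raise ValueError(f"first_side must be one of {SIDES}")
        if self.cue_side not in SIDES:
            raise ValueError(f"cue_side must be one of {SIDES}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if not (np.isfinite(self.soa) and self.soa > 0):
            raise ValueError(f"soa must be finite and positive, got {self.soa}")

    @property
    def signed_soa(self) -> float:
        return self.soa if self.first_side == "right" else -self.soa


def response_probability(obs: ObserverParams, ev: StimulusEvent) -> float:
    """Closed-form P("right first" response) for an observer and stimulus.

    P = lapse/2 + (1 - lapse) * logistic((signed_soa - mu_cue) / scale_s),
    where mu_cue = -shift for a right cue and +shift for a left cue: cueing a
    side makes that side's target be perceived earlier (prior entry), pulling
    the 50% point of the psychometric function away from the cued side.
    """
    shift = obs.shift(ev.condition)
    mu_cue = -shift if ev.cue_side == "right" else shift
    z = (ev.signed_soa - mu_cue) / obs.scale_s
    core = 0.5 * (1.0 + math.tanh(z / 2.0))  # numerically stable logistic CDF
    return obs.lapse / 2.0 + (1.0 - obs.lapse) * core


def simulate_response(
    obs: ObserverParams, ev: StimulusEvent, rng: np.random.Generator
) -> tuple[str, bool]:
    """Draw one response; returns (response side, correctness flag)."""
    p_right = response_probability(obs, ev)
    response = "right" if rng.random() < p_right else "left"
    return response, response == ev.first_side
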