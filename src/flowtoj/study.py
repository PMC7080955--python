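"""Generative model of a full multi-session flow/TOJ study.

Emulates a within-subject field study: N participants (athletes and
musicians), three sessions each, and in every session a pre- and a
post-performance TOJ measurement comprising one endogenous-cue and one
exogenous-cue staircase block, followed by a 26-item flow questionnaire.

The latent structure is a Gaussian hierarchical model. Per participant i,
session s, condition c (0 = endogenous, 1 = exogenous) and phase p
(0 = pre, 1 = post):

    JND_iscp = mu_jnd + u_i + v_is + b_jnd * c
               + p * (d_jnd + gamma_jnd * (f_is - flow_mean)) + e_iscp

with u_i ~ N(0, var_subject), v_is ~ N(0, var_session) and observation-level
e ~ N(0, var_residual), inflated by kappa in the post phase. The left/right
cued PSS distance follows the analogous two-level rule with a per-subject
random condition slope. f_is is the session's latent flow on the 1-5 Likert
scale (truncated normal). gamma_jnd and gamma_pss are the cross-level
moderation coefficients of interest: ms of pre-to-post change per unit flow.

Defaults reproduce the study conditions: 27 participants x 3 sessions,
variance components 331.62 / 152.93 / 343.18 ms^2 at the subject / session /
observation level, moderation gamma_jnd = -5.8 ms and gamma_pss = -21.31 ms
per flow unit, and a dropout rate expected to delete ~5 of the 162
(participant, session, phase) runs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .flow import N_ITEMS, LIKERT_MIN, LIKERT_MAX
from .observer import LN3, ObserverParams
from .staircase import StaircaseConfig, run_block

logger = logging.getLogger(__name__)

PHASES = ("pre", "post")
CONDITIONS = ("endogenous", "exogenous")


@dataclass(frozen=True)
class StudyConfig:
    """Study-level generative parameters (times in ms, flow in Likert units)."""

    n_participants: int = 27
    n_sessions: int = 3
    # JND rule (three-level)
    mu_jnd: float = 53.3
    cond_offset_jnd: float = 10.42
    delta_prepost_jnd: float = -5.36
    gamma_jnd: float = -5.8
    var_subject: float = 331.62
    var_session: float = 152.93
    var_residual: float = 343.18
    kappa: float = 1.0  # post-phase residual inflation
    # PSS-distance rule (two-level, random condition slope)
    mu_pss: float = 41.12
    cond_offset_pss: float = 64.12
    delta_prepost_pss: float = 6.84
    gamma_pss: float = -21.31
    var_subject_pss: float = 153.05
    var_cond_slope_pss: float = 1427.08
    cov_subject_cond_pss: float = 373.90
    var_residual_pss: float = 2053.72
    # flow and questionnaire
    flow_mean: float = 3.43
    flow_sd: float = 0.7
    sigma_item: float = 0.7
    control_q_mean: float = 3.33
    control_q_sd: float = 1.09
    # observer nuisance
    lapse: float = 0.02
    # design
    athlete_fraction: float = 11 / 27
    dropout_rate: float = 5 / 162  # per (participant, session, phase) run
    # three-way moderation (flow x prepost x condition); 0 = none, as observed
    gamma_jnd_condition: float = 0.0
    gamma_pss_condition: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("var_subject", "var_session", "var_residual", "var_subject_pss",
                     "var_cond_slope_pss", "var_residual_pss", "kappa"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        cov_bound = np.sqrt(self.var_subject_pss * self.var_cond_slope_pss)
        if abs(self.cov_subject_cond_pss) > cov_bound:
            raise ValueError("cov_subject_cond_pss violates positive-definiteness")
        if self.n_sessions < 1 or self.n_participants < 1:
            raise ValueError("need at least one participant and one session")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if not 0 <= self.lapse <= 0.1:
            raise ValueError("lapse must lie in [0, 0.1]")


@dataclass
class StudyData:
    """Everything one simulated study produces.

    ``latent`` holds the generating truth per (participant, session, phase,
    condition): true JND, true PSS distance, latent flow, domain. ``trials``
    and ``questionnaire`` are the observable tables (trials is None when the
    study was generated without staircase simulation). ``missing_runs`` lists
    the dropped (participant, session, phase) runs.
    """

    config: StudyConfig
    latent: pd.DataFrame
    questionnaire: pd.DataFrame
    trials: pd.DataFrame | None = None
    missing_runs: list[tuple] = dataclasses.field(default_factory=list)

    def true_estimates(self) -> pd.DataFrame:
        """Latent JND / PSS-distance values shaped like the estimator output.

        Bypasses staircase + psychometric fitting: the 'estimate' is the
        generating truth itself (which still contains the observation-level
        residual e). Useful for isolating the modelling stage in parameter-
        recovery studies.
        """
        rows = []
        for _, r in self.latent.iterrows():
            if r["dropped"]:
                continue
            base = dict(participant=r["participant"], session=r["session"],
                        phase=r["phase"], condition=r["condition"],
                        flagged=False, converged=True, n_trials=0)
            rows.append(dict(**base, cue_side="pooled", kind="JND", value=r["true_jnd"]))
            rows.append(dict(**base, cue_side="pooled", kind="PSS_distance",
                             value=r["true_pss_distance"]))
        return pd.DataFrame(rows)


def generate_afss(latent_flow: float, rng: np.random.Generator,
                  sigma_item: float = 0.7) -> np.ndarray:
    """26 Likert item responses around a latent flow level.

    item_j = clip(round(latent_flow + eta_j), 1, 5), eta_j ~ N(0, sigma^2);
    the item mean is a (boundary-bias aside) consistent estimator of the
    latent flow.
    """
    if not (LIKERT_MIN <= latent_flow <= LIKERT_MAX):
        raise ValueError("latent_flow must lie in [1, 5]")
    noisy = latent_flow + rng.normal(0.0, sigma_item, size=N_ITEMS)
    return np.clip(np.round(noisy), LIKERT_MIN, LIKERT_MAX).astype(int)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int) -> np.ndarray:
    out = np.empty(size)
    for i in range(size):
        for _ in range(1000):
            x = rng.normal(mean, sd)
            if lo <= x <= hi:
                out[i] = x
                break
        else:  # numerically extreme configs only
            out[i] = float(np.clip(rng.normal(mean, sd), lo, hi))
    return out


def generate_study(
    cfg: StudyConfig,
    rng: np.random.Generator | None = None,
    simulate_trials: bool = True,
    staircase_cfg: StaircaseConfig | None = None,
) -> StudyData:
    """Simulate one complete study.

    The RNG is forked per participant (``spawn``), so dropping or reordering
    participants leaves every other participant's data unchanged. Latent JND
    draws implying a non-positive logistic scale are resampled (residual only)
    and logged, never clamped.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    staircase_cfg = staircase_cfg or StaircaseConfig()
    n_ath = int(round(cfg.athlete_fraction * cfg.n_participants))
    part_rngs = rng.spawn(cfg.n_participants)

    latent_rows, trial_rows, q_rows, missing = [], [], [], []
    n_resampled = 0
    for i in range(cfg.n_participants):
        prng = part_rngs[i]
        pid = i + 1
        domain = "athlete" if i < n_ath else "musician"
        u_i = prng.normal(0.0, np.sqrt(cfg.var_subject))
        cov = np.array([
            [cfg.var_subject_pss, cfg.cov_subject_cond_pss],
            [cfg.cov_subject_cond_pss, cfg.var_cond_slope_pss],
        ])
        w_i, slope_i = prng.multivariate_normal(np.zeros(2), cov)
        flows = _truncated_normal(prng, cfg.flow_mean, cfg.flow_sd,
                                  LIKERT_MIN, LIKERT_MAX, cfg.n_sessions)
        for s in range(1, cfg.n_sessions + 1):
            v_is = prng.normal(0.0, np.sqrt(cfg.var_session))
            items = generate_afss(flows[s - 1], prng, cfg.sigma_item)
            # moderation acts on the *reported* global flow score: that score
            # is the covariate the hierarchical models regress on, so the
            # planted gammas are exactly the models' estimands (planting on
            # latent flow instead would dilute them by item measurement error)
            f_c = float(np.mean(items)) - cfg.flow_mean
            control_q = int(np.clip(np.round(
                prng.normal(cfg.control_q_mean, cfg.control_q_sd)), 1, 5))
            q_rows.append(dict(participant=pid, session=s,
                               **{f"item_{j+1}": items[j] for j in range(N_ITEMS)},
                               control_q=control_q))
            dropped = {ph: prng.random() < cfg.dropout_rate for ph in PHASES}
            for phase in PHASES:
                p = 1 if phase == "post" else 0
                if dropped[phase]:
                    missing.append((pid, s, phase))
                for ci, cond in enumerate(CONDITIONS):
                    post_term_j = p * (cfg.delta_prepost_jnd
                                       + (cfg.gamma_jnd + cfg.gamma_jnd_condition * ci) * f_c)
                    mean_jnd = (cfg.mu_jnd + u_i + v_is + cfg.cond_offset_jnd * ci
                                + post_term_j)
                    resid_sd = np.sqrt(cfg.var_residual * (cfg.kappa if p else 1.0))
                    true_jnd = mean_jnd + prng.normal(0.0, resid_sd)
                    while true_jnd <= staircase_cfg.frame_ms * 0.05:
                        # non-positive scale would break the observer; resample e
                        n_resampled += 1
                        true_jnd = mean_jnd + prng.normal(0.0, resid_sd)
                    post_term_p = p * (cfg.delta_prepost_pss
                                       + (cfg.gamma_pss + cfg.gamma_pss_condition * ci) * f_c)
                    mean_pss = (cfg.mu_pss + w_i + (cfg.cond_offset_pss + slope_i) * ci
                                + post_term_p)
                    true_dist = mean_pss + prng.normal(
                        0.0, np.sqrt(cfg.var_residual_pss))
                    latent_rows.append(dict(
                        participant=pid, session=s, phase=phase, condition=cond,
                        domain=domain, flow=flows[s - 1], true_jnd=true_jnd,
                        true_pss_distance=true_dist, dropped=dropped[phase]))
                    if simulate_trials and not dropped[phase]:
                        obs = ObserverParams(
                            scale_s=true_jnd / LN3, lapse=cfg.lapse,
                            shift_endo=true_dist / 2.0 if cond == "endogenous" else 0.0,
                            shift_exo=true_dist / 2.0 if cond == "exogenous" else 0.0,
                        )
                        trial_rows.extend(run_block(
                            obs, cond, staircase_cfg, prng,
                            participant=pid, session=s, phase=phase,
                            block=f"{phase}-{cond}", domain=domain))
    if n_resampled:
        logger.info("resampled %d residual draws implying non-positive JND", n_resampled)
    trials = pd.DataFrame(trial_rows) if simulate_trials else None
    return StudyData(config=cfg, latent=pd.DataFrame(latent_rows),
                     questionnaire=pd.DataFrame(q_rows), trials=trials,
                     missing_runs=missing)
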