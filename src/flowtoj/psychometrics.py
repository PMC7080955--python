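"""Psychometric-function fitting and JND/PSS estimation for TOJ data.

For each grouping of trials a plain two-parameter logistic regression of the
binary "right first" response on the signed SOA is fitted by maximum
likelihood, P = logistic(beta0 + beta1 * soa). From a converged fit:

* JND = ln(3) / beta1 — half the SOA distance between the 25% and 75% points
  (smaller = finer temporal resolution);
* PSS = -beta0 / beta1 — the SOA of maximal uncertainty (50% point), whose
  cue-side dependence indexes prior entry.

No lapse/guess asymptotes are fitted; lapses in the data attenuate the slope,
which is deliberate realism rather than a defect of the estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .observer import LN3

MAX_ITER = 100
REL_TOL = 1e-10


@dataclass(frozen=True)
class PsychometricFit:
    beta0: float
    beta1: float
    n_trials: int
    n_levels: int
    converged: bool
    loglik: float
    reason: str = ""


def _bernoulli_loglik(beta0: float, beta1: float, soa: np.ndarray, y: np.ndarray) -> float:
    eta = beta0 + beta1 * soa
    # log Lambda(eta)*y + log(1-Lambda(eta))*(1-y), stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_psychometric(signed_soa, response) -> PsychometricFit:
    """Newton/IRLS maximum-likelihood logistic fit of right-first responses.

    Parameters
    ----------
    signed_soa : array-like, ms (positive = right target first)
    response : array-like of {0, 1}, 1 = responded "right first"

    Degenerate inputs (fewer than two SOA levels, a single response class, or
    complete separation) yield ``converged=False`` with a reason instead of
    raising, so whole-study estimation never aborts mid-pipeline.
    """
    soa = np.asarray(signed_soa, dtype=float)
    y = np.asarray(response, dtype=float)
    n = soa.size
    levels = np.unique(soa)
    if n != y.size:
        raise ValueError("signed_soa and response lengths differ")

    def bail(reason: str) -> PsychometricFit:
        return PsychometricFit(np.nan, np.nan, n, levels.size, False, np.nan, reason)

    if levels.size < 2:
        return bail("fewer than 2 distinct SOA levels")
    if y.min() == y.max():
        return bail("single response class")
    # complete separation: some threshold on SOA predicts the response exactly
    lo, hi = soa[y == 0], soa[y == 1]
    if hi.min() > lo.max() or hi.max() < lo.min():
        return bail("complete separation")

    beta = np.zeros(2)
    X = np.column_stack([np.ones(n), soa])
    ll = _bernoulli_loglik(beta[0], beta[1], soa, y)
    converged = False
    for _ in range(MAX_ITER):
        eta = X @ beta
        p = expit(eta)
        w = p * (1.0 - p)
        grad = X.T @ (y - p)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return bail("singular information matrix")
        # step-halving line search keeps Newton monotone on flat likelihoods
        new_ll = -np.inf
        for _half in range(30):
            cand = beta + step
            new_ll = _bernoulli_loglik(cand[0], cand[1], soa, y)
            if new_ll >= ll - 1e-14:
                break
            step = step / 2.0
        beta = beta + step
        if abs(new_ll - ll) <= REL_TOL * (abs(ll) + REL_TOL):
            ll = new_ll
            converged = True
            break
        ll = new_ll
    if not converged:
        return bail("no convergence in %d iterations" % MAX_ITER)
    if not np.all(np.isfinite(beta)) or abs(beta[1]) > 1e3:
        # likelihood maximised at an effectively infinite slope
        return bail("quasi-separation (diverging slope)")
    return PsychometricFit(float(beta[0]), float(beta[1]), n, levels.size, True, ll)


def derive_estimates(fit: PsychometricFit) -> dict:
    """Closed-form JND and PSS (ms) from a converged logistic fit.

    A non-positive slope produces estimates flagged for downstream screening
    rather than an error: the robust exclusion stage decides their fate.
    """
    if not fit.converged:
        raise ValueError(f"cannot derive estimates from non-converged fit ({fit.reason})")
    jnd = LN3 / fit.beta1
    pss = -fit.beta0 / fit.beta1
    return {"jnd": jnd, "pss": pss, "flagged": fit.beta1 <= 0}


def _fit_group(df: pd.DataFrame) -> PsychometricFit:
    return fit_psychometric(df["signed_soa_ms"].to_numpy(), (df["response"] == "right").to_numpy())


def estimate_study(trials: pd.DataFrame) -> pd.DataFrame:
    """Estimate JND, cue-side PSS, and left-right PSS distance for a study.

    Per participant x session x phase x condition: one JND fit pooling both
    cue sides and one PSS fit per cue side; PSS_distance = PSS(left cued) -
    PSS(right cued) (positive = prior entry toward the cued side). A complete
    participant therefore contributes 12 JND and 24 PSS models over three
    sessions. Missing blocks simply yield no records; degenerate fits yield
    rows with NaN value and flagged=True.

    Returns a long-format table with columns participant, session, phase,
    condition, cue_side, kind, value, flagged, converged, n_trials.
    """
    required = {"participant", "session", "phase", "condition", "cue_side",
                "signed_soa_ms", "response"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table is missing columns: {sorted(missing)}")

    records = []
    for (pid, sess, phase, cond), block in trials.groupby(
        ["participant", "session", "phase", "condition"], sort=True
    ):
        key = dict(participant=pid, session=sess, phase=phase, condition=cond)
        fit = _fit_group(block)
        records.append(_record(key, "pooled", "JND", fit, "jnd"))
        pss_by_side = {}
        for side in ("left", "right"):
            sub = block[block["cue_side"] == side]
            sfit = _fit_group(sub) if len(sub) else None
            rec = _record(key, side, "PSS", sfit, "pss")
            pss_by_side[side] = rec
            records.append(rec)
        dl, dr = pss_by_side["left"], pss_by_side["right"]
        dist = dl["value"] - dr["value"]
        records.append(
            dict(**key, cue_side="pooled", kind="PSS_distance", value=dist,
                 flagged=bool(dl["flagged"] or dr["flagged"]),
                 converged=bool(dl["converged"] and dr["converged"]),
                 n_trials=int(dl["n_trials"] + dr["n_trials"]))
        )
    return pd.DataFrame.from_records(records)


def _record(key: dict, cue_side: str, kind: str, fit: PsychometricFit | None, which: str) -> dict:
    if fit is not None and fit.converged:
        est = derive_estimates(fit)
        value, flagged = est[which], est["flagged"]
        converged = True
    else:
        value, flagged, converged = np.nan, True, False
    n = int(fit.n_trials) if fit is not None else 0
    return dict(**key, cue_side=cue_side, kind=kind, value=value,
                flagged=bool(flagged), converged=converged, n_trials=n)
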