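"""Scoring of the 26-item Activity Flow State Scale (AFSS).

Nine subscales cover the flow dimensions (challenge-skill balance, clear
goals, unambiguous feedback, concentration, action-awareness merging, loss of
self-consciousness, sense of control, transformation of time, autotelic
experience). Items are 5-point Likert responses (1-5); the global flow score
is the plain mean of all 26 items. The published item->subscale assignment is
not reproduced here, so consecutive blocks with the published item counts are
used by default; the mapping is configurable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

N_ITEMS = 26
LIKERT_MIN, LIKERT_MAX = 1, 5

_SUBSCALE_SIZES = {
    "MAA": 3,  # merging actions and awareness
    "CG": 3,   # clear goals
    "CO": 4,   # concentration on task at hand
    "UF": 2,   # unambiguous feedback
    "CS": 3,   # challenge-skill balance
    "TT": 3,   # transformation of time
    "CN": 2,   # sense of control
    "SC": 3,   # loss of self-consciousness
    "AE": 3,   # autotelic experience
}


def _default_mapping() -> dict[str, list[int]]:
    mapping, start = {}, 0
    for name, k in _SUBSCALE_SIZES.items():
        mapping[name] = list(range(start, start + k))
        start += k
    return mapping


DEFAULT_SUBSCALES = _default_mapping()


def score_afss(items, mapping: dict[str, list[int]] | None = None) -> dict:
    """Score one respondent's 26 AFSS items.

    Returns ``{"global_flow": mean of all items, "subscales": {name: mean}}``.
    Raises ValueError on missing or out-of-range items (the caller rejects
    the record with the reason).
    """
    mapping = mapping or DEFAULT_SUBSCALES
    arr = np.asarray(items, dtype=float)
    if arr.shape != (N_ITEMS,):
        raise ValueError(f"expected {N_ITEMS} item responses, got shape {arr.shape}")
    if np.any(~np.isfinite(arr)):
        raise ValueError("missing (non-finite) item response")
    if np.any((arr < LIKERT_MIN) | (arr > LIKERT_MAX)) or np.any(arr != np.round(arr)):
        raise ValueError("item responses must be integers in 1..5")
    used = sorted(i for idx in mapping.values() for i in idx)
    if used != list(range(N_ITEMS)):
        raise ValueError("subscale mapping must partition items 0..25")
    return {
        "global_flow": float(arr.mean()),
        "subscales": {name: float(arr[idx].mean()) for name, idx in mapping.items()},
    }


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha, alpha = k/(k-1) * (1 - sum(var_i) / var_total).

    ``item_matrix`` is respondents x items. All variances use the sample
    (n-1) denominator. Zero total-score variance makes alpha undefined and
    raises ValueError.
    """
    X = np.asarray(item_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 respondents and 2 items")
    k = X.shape[1]
    item_vars = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def score_table(questionnaire: pd.DataFrame,
                mapping: dict[str, list[int]] | None = None) -> pd.DataFrame:
    """Score a per-(participant, session) questionnaire table.

    Expects columns participant, session, item_1..item_26 and optionally
    control_q. Invalid rows are dropped; the reasons are collected in the
    returned frame's ``attrs["rejected"]`` list.
    """
    item_cols = [f"item_{j}" for j in range(1, N_ITEMS + 1)]
    missing = [c for c in ["participant", "session", *item_cols] if c not in questionnaire]
    if missing:
        raise ValueError(f"questionnaire table is missing columns: {missing}")
    rows, rejected = [], []
    for _, row in questionnaire.iterrows():
        try:
            scored = score_afss(row[item_cols].to_numpy(dtype=float), mapping)
        except ValueError as exc:
            rejected.append(
                (row["participant"], row["session"], str(exc))
            )
            continue
        out = {"participant": row["participant"], "session": row["session"],
               "global_flow": scored["global_flow"]}
        out.update({f"sub_{name}": v for name, v in scored["subscales"].items()})
        if "control_q" in questionnaire:
            out["control_q"] = row["control_q"]
        rows.append(out)
    result = pd.DataFrame(rows)
    result.attrs["rejected"] = rejected
    return result
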