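"""Robust median/MAD screening of derived JND and PSS estimates.

Values farther than ``k`` scaled median absolute deviations from the median
are excluded (default k = 2.5 with the Gaussian consistency constant
b = 1.4826, under which ~1.24% of clean normal data is excluded). JND values
are screened pooled across the whole study; PSS screening operates on the
per-(participant, session, condition) post-minus-pre difference of the
left/right cued PSS distance, and an excluded difference removes both its
pre and post rows.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

DEFAULT_K = 2.5
MAD_CONSISTENCY = 1.4826


def mad_mask(values, k: float = DEFAULT_K, b: float = MAD_CONSISTENCY) -> np.ndarray:
    """Boolean exclusion mask: True where |x - median| > k * b * MAD.

    NaNs are always excluded (non-converged fits enter screening as missing
    values and can never survive it). If the MAD is zero the rule is
    degenerate and nothing finite is excluded (with a warning).
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 3:
        raise ValueError("need at least 3 finite values for MAD screening")
    med = np.median(x[finite])
    mad = np.median(np.abs(x[finite] - med))
    exclude = ~finite
    if mad == 0:
        warnings.warn("MAD is zero (over half the values identical); no finite value excluded")
        return exclude
    exclude[finite] = np.abs(x[finite] - med) > k * b * mad
    return exclude


def screen_estimates(
    estimates: pd.DataFrame, k: float = DEFAULT_K, b: float = MAD_CONSISTENCY
) -> tuple[pd.DataFrame, dict]:
    """Apply the study's two screening rules to an estimates table.

    Returns (screened table, report). The report holds per-family counts,
    exclusion fractions, and the keys removed.
    """
    est = estimates.copy()
    report: dict = {}

    # --- JND: pool every JND value in the study ---
    jnd_idx = est.index[est["kind"] == "JND"]
    jnd_excl = mad_mask(est.loc[jnd_idx, "value"].to_numpy(), k, b)
    drop_jnd = jnd_idx[jnd_excl]
    report["jnd"] = {
        "n": int(len(jnd_idx)),
        "excluded": int(jnd_excl.sum()),
        "fraction": float(jnd_excl.mean()) if len(jnd_idx) else 0.0,
    }

    # --- PSS distance: screen pooled post-minus-pre differences ---
    dist = est[est["kind"] == "PSS_distance"]
    wide = dist.pivot_table(
        index=["participant", "session", "condition"],
        columns="phase", values="value", aggfunc="first", dropna=False,
    )
    for col in ("pre", "post"):
        if col not in wide:
            wide[col] = np.nan
    diff = (wide["post"] - wide["pre"]).to_numpy()
    finite = np.isfinite(diff)  # runs missing a phase cannot be screened
    diff_excl = np.zeros_like(finite)
    diff_excl[finite] = mad_mask(diff[finite], k, b)
    bad_keys = set(map(tuple, np.asarray(wide.index.to_list(), dtype=object)[diff_excl]))
    key_tuples = list(zip(dist["participant"], dist["session"], dist["condition"]))
    drop_dist = dist.index[[kt in bad_keys for kt in key_tuples]]
    report["pss_distance"] = {
        "n_differences": int(finite.sum()),
        "excluded_differences": int(diff_excl.sum()),
        "fraction": float(diff_excl.sum() / finite.sum()) if finite.any() else 0.0,
        "rows_removed": int(len(drop_dist)),
    }
    report["excluded_keys"] = {
        "jnd": est.loc[drop_jnd, ["participant", "session", "phase", "condition"]]
        .to_records(index=False).tolist(),
        "pss_distance": sorted(bad_keys),
    }
    screened = est.drop(index=drop_jnd.union(drop_dist))
    return screened, report


def format_report(report: dict) -> str:
    j, p = report["jnd"], report["pss_distance"]
    lines = [
        "Robust screening report (median +/- 2.5 scaled MADs)",
        f"  JND: {j['excluded']} of {j['n']} estimates excluded "
        f"({100 * j['fraction']:.1f}%)",
        f"  PSS distance: {p['excluded_differences']} of {p['n_differences']} "
        f"post-pre differences excluded ({100 * p['fraction']:.1f}%), "
        f"removing {p['rows_removed']} rows",
    ]
    return "\n".join(lines)
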