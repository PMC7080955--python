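"""Hierarchical moderation models for JND and PSS-distance estimates.

The scientific question is cross-level moderation: does a session's
self-reported flow level moderate the pre-to-post change of a perceptual
parameter? The response enters a Gaussian mixed model

    value ~ 1 + condition + flow_c + prepost + prepost:flow_c  (fixed)

with, for the JND, random intercepts for subjects and for sessions nested in
subjects (three levels: measurements in sessions in subjects), and, for the
left/right cued PSS distance, a per-subject random intercept and random
condition slope with free covariance (two levels). ``flow_c`` is grand-mean
centred flow; ``prepost`` is 0 pre / 1 post; ``condition`` is 0 endogenous /
1 exogenous; ``domain`` is 0 musician / 1 athlete. The coefficient of
``prepost:flow_c`` is the moderation effect in ms per flow unit.

Estimation is delegated to statsmodels' ``MixedLM`` (REML for reported
coefficients, ML for likelihood-ratio comparisons); this module adds the
model/results surface, Wald inference conventions, LRTs and the variance
partition of the fully unconditional model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.formula.api as smf

Z95 = 1.96  # Wald 95% convention

_TERM_MAP = {
    "condition": "condition",
    "flow": "flow_c",
    "prepost": "prepost",
    "prepost:flow": "prepost:flow_c",
    "domain": "domain",
    "prepost:domain": "prepost:domain",
    "prepost:flow:condition": "prepost:flow_c:condition",
    "prepost:flow:control_q": "prepost:flow_c:control_q",
}

DEFAULT_TERMS = ("condition", "flow", "prepost", "prepost:flow")

REQUIRED_COLUMNS = ("participant", "session", "prepost", "condition", "flow", "value")


def prepare_model_table(
    estimates: pd.DataFrame,
    flow_scores: pd.DataFrame,
    kind: str,
    domains: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join screened estimates with flow scores into the tidy modelling table.

    ``kind`` selects "JND" or "PSS_distance" rows. Rows lacking a flow score
    or a finite estimate are dropped listwise. Returns columns participant,
    session, prepost, condition, flow, flow_c, value [, domain, control_q].
    """
    sel = estimates[estimates["kind"] == kind].copy()
    sel["prepost"] = (sel["phase"] == "post").astype(int)
    sel["condition"] = (sel["condition"] == "exogenous").astype(int)
    cols = ["participant", "session", "global_flow"]
    if "control_q" in flow_scores:
        cols.append("control_q")
    merged = sel.merge(flow_scores[cols], on=["participant", "session"], how="left")
    merged = merged.rename(columns={"global_flow": "flow"})
    if domains is not None:
        dom = domains[["participant", "domain"]].drop_duplicates()
        merged = merged.merge(dom, on="participant", how="left")
        merged["domain"] = (merged["domain"] == "athlete").astype(int)
    merged = merged.dropna(subset=["flow", "value"])
    merged["flow_c"] = merged["flow"] - merged["flow"].mean()
    keep = ["participant", "session", "prepost", "condition", "flow", "flow_c", "value"]
    for extra in ("domain", "control_q"):
        if extra in merged:
            keep.append(extra)
    return merged[keep].reset_index(drop=True)


@dataclass
class FlowModerationResults:
    """Fitted mixed-model results (statsmodels-style surface).

    ``params``/``bse``/``tvalues``/``pvalues``/``conf_int`` cover the fixed
    effects; CIs are Wald (estimate +/- 1.96 SE), p-values from t statistics
    on residual degrees of freedom (n_obs - rank of the fixed design).
    ``vcomp`` maps variance-component names to ms^2.
    """

    model: "FlowModerationModel"
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    vcomp: dict
    llf: float
    n_obs: int
    n_params: int
    group_counts: dict
    reml: bool
    converged: bool
    singular: bool
    df_resid: int
    _sm_result: object = None

    def summary(self) -> str:
        lines = [
            f"Flow moderation model ({self.model.kind.upper()} response), "
            f"{'REML' if self.reml else 'ML'}",
            "",
            f"{'Predictor':<22}{'Estimate':>10}{'Std.Err':>10}"
            f"{'CI 2.5%':>10}{'CI 97.5%':>10}{'t':>8}{'P':>9}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<22}{self.params[name]:>10.2f}{self.bse[name]:>10.2f}"
                f"{self.conf_int.loc[name, 'lower']:>10.2f}"
                f"{self.conf_int.loc[name, 'upper']:>10.2f}"
                f"{self.tvalues[name]:>8.2f}{self.pvalues[name]:>9.3g}"
            )
        lines.append("")
        lines.append("Random effects (variances, ms^2):")
        for name, v in self.vcomp.items():
            lines.append(f"  {name:<28}{v:>10.2f}")
        lines.append(f"Num. obs. {self.n_obs}")
        for name, c in self.group_counts.items():
            lines.append(f"Num. groups: {name} {c}")
        if self.singular:
            lines.append("WARNING: fit is singular (a variance component is ~0)")
        if not self.converged:
            lines.append("WARNING: optimizer did not report convergence")
        return "\n".join(lines)

    def plot_moderation(self, ax=None):
        """Predicted pre/post response vs flow (fixed effects only)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        data = self.model.data
        grid = np.linspace(data["flow"].min(), data["flow"].max(), 50)
        grid_c = grid - data["flow"].mean()
        p = self.params
        cond = float(data["condition"].mean())
        for prepost, label in ((0, "pre"), (1, "post")):
            yhat = (p.get("Intercept", 0.0) + p.get("condition", 0.0) * cond
                    + p.get("flow_c", 0.0) * grid_c
                    + p.get("prepost", 0.0) * prepost
                    + p.get("prepost:flow_c", 0.0) * prepost * grid_c)
            ax.plot(grid, yhat, label=label)
        ax.set_xlabel("global flow score")
        ax.set_ylabel(f"{self.model.kind.upper()} (ms)")
        ax.legend(title="phase")
        return ax


class FlowModerationModel:
    """Mixed model for one response kind ("jnd" or "pss") on a tidy table.

    Parameters
    ----------
    data : DataFrame
        Columns participant, session, prepost, condition, flow, value and
        optionally flow_c, domain, control_q. ``flow_c`` is computed by
        grand-mean centring when absent.
    kind : {"jnd", "pss"}
        Selects the random-effect structure: three-level nested intercepts
        for "jnd", subject intercept + condition slope for "pss".
    terms : sequence of fixed-effect terms
        Subset of {condition, flow, prepost, prepost:flow, domain,
        prepost:domain, prepost:flow:condition, prepost:flow:control_q};
        () gives the fully unconditional (intercept-only) model.
    """

    def __init__(self, data: pd.DataFrame, kind: str = "jnd",
                 terms=DEFAULT_TERMS, random_slope: bool = True):
        missing = [c for c in REQUIRED_COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"model table is missing columns: {missing}")
        if kind not in ("jnd", "pss"):
            raise ValueError("kind must be 'jnd' or 'pss'")
        if data["participant"].nunique() < 2:
            raise ValueError("need at least 2 subjects")
        unknown = [t for t in terms if t not in _TERM_MAP]
        if unknown:
            raise ValueError(f"unknown fixed terms: {unknown}")
        self.data = data.copy()
        if "flow_c" not in self.data:
            self.data["flow_c"] = self.data["flow"] - self.data["flow"].mean()
        self.kind = kind
        self.random_slope = random_slope  # pss only: per-subject condition slope
        self.terms = tuple(terms)
        rhs = " + ".join(_TERM_MAP[t] for t in terms) if terms else "1"
        self.formula = f"value ~ {rhs}"

    @classmethod
    def from_study(cls, estimates: pd.DataFrame, flow_scores: pd.DataFrame,
                   kind: str = "jnd", domains: pd.DataFrame | None = None,
                   terms=DEFAULT_TERMS, random_slope: bool = True) -> "FlowModerationModel":
        table = prepare_model_table(
            estimates, flow_scores,
            "JND" if kind == "jnd" else "PSS_distance", domains)
        return cls(table, kind=kind, terms=terms, random_slope=random_slope)

    def _build(self):
        if self.kind == "jnd":
            return smf.mixedlm(self.formula, self.data, groups=self.data["participant"],
                               re_formula="1",
                               vc_formula={"session": "0 + C(session)"})
        re_formula = "1 + condition" if self.random_slope else "1"
        return smf.mixedlm(self.formula, self.data, groups=self.data["participant"],
                           re_formula=re_formula)

    def fit(self, reml: bool = True, **fit_kws) -> FlowModerationResults:
        import warnings

        mod = self._build()
        res = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # boundary/convergence chatter handled below
            for method, maxiter in (("lbfgs", 200), ("bfgs", 200), ("powell", 1000)):
                try:
                    cand = mod.fit(reml=reml, method=method, maxiter=maxiter, **fit_kws)
                except Exception:
                    continue
                if res is None or (cand.converged and not res.converged):
                    res = cand
                if res.converged:
                    break
            if res is None:
                raise RuntimeError("mixed-model optimisation failed under all methods")
        fe = res.fe_params
        bse = res.bse_fe
        k_fe = len(fe)
        df_resid = int(len(self.data) - k_fe)
        tvals = fe / bse
        pvals = pd.Series(2 * stats.t.sf(np.abs(tvals), df_resid), index=fe.index)
        ci = pd.DataFrame({"lower": fe - Z95 * bse, "upper": fe + Z95 * bse})

        sigma2 = float(res.scale)
        vcomp: dict[str, float] = {}
        if self.kind == "jnd":
            vcomp["Var: subject"] = float(res.cov_re.iloc[0, 0])
            vcomp["Var: session:subject"] = float(res.vcomp[0]) if len(res.vcomp) else 0.0
        elif self.random_slope:
            vcomp["Var: subject (Intercept)"] = float(res.cov_re.iloc[0, 0])
            vcomp["Var: subject condition"] = float(res.cov_re.iloc[1, 1])
            vcomp["Cov: subject (Intercept) condition"] = float(res.cov_re.iloc[0, 1])
        else:
            vcomp["Var: subject"] = float(res.cov_re.iloc[0, 0])
        vcomp["sigma2"] = sigma2

        n_cov = mod.k_re * (mod.k_re + 1) // 2 + (len(res.vcomp) if res.vcomp is not None else 0)
        n_params = k_fe + n_cov + 1  # +1 for sigma^2
        groups = {"subject": int(self.data["participant"].nunique())}
        if self.kind == "jnd":
            groups["session:subject"] = int(
                self.data.groupby(["participant", "session"]).ngroups)
        singular = any(
            v < 1e-8 * max(sigma2, 1.0)
            for k, v in vcomp.items() if k.startswith("Var"))
        return FlowModerationResults(
            model=self, params=fe, bse=bse, tvalues=tvals, pvalues=pvals,
            conf_int=ci, vcomp=vcomp, llf=float(res.llf), n_obs=int(len(self.data)),
            n_params=n_params, group_counts=groups, reml=reml,
            converged=bool(res.converged), singular=singular,
            df_resid=df_resid, _sm_result=res)


def fit_lmm(data: pd.DataFrame, kind: str = "jnd", terms=DEFAULT_TERMS,
            reml: bool = True, random_slope: bool = True) -> FlowModerationResults:
    """Fit one hierarchical linear model (thin wrapper over the model class)."""
    return FlowModerationModel(data, kind=kind, terms=terms,
                               random_slope=random_slope).fit(reml=reml)


def fit_moderation_models(jnd_data: pd.DataFrame, pss_data: pd.DataFrame,
                          reml: bool = True) -> dict:
    """The study's two headline models: flow-moderated pre-to-post change of
    the JND (three-level) and of the cued-PSS distance (two-level)."""
    return {
        "jnd": fit_lmm(jnd_data, kind="jnd", reml=reml),
        "pss": fit_lmm(pss_data, kind="pss", reml=reml),
    }


def lrt_compare(m0: FlowModerationResults, m1: FlowModerationResults) -> dict:
    """Likelihood-ratio test of nested ML fits on identical rows.

    Returns {"chi2", "df", "p"}; refuses REML fits, non-nested term sets and
    differing row counts.
    """
    if m0.reml or m1.reml:
        raise ValueError("LRT requires ML fits (reml=False)")
    if m0.n_obs != m1.n_obs:
        raise ValueError("models were fitted on different numbers of rows")
    if m0.n_params > m1.n_params:
        m0, m1 = m1, m0
    if not set(m0.model.terms) <= set(m1.model.terms):
        raise ValueError("fixed-effect terms are not nested")
    chi2 = max(0.0, 2.0 * (m1.llf - m0.llf))
    df = m1.n_params - m0.n_params
    if df < 1:
        raise ValueError("models have identical parameter counts")
    return {"chi2": chi2, "df": df, "p": float(stats.chi2.sf(chi2, df))}


def variance_partition(unconditional: FlowModerationResults) -> dict:
    """Proportion of total variance at each level of an intercept-only fit."""
    v = unconditional.vcomp
    total = sum(val for key, val in v.items()
                if key.startswith("Var") or key == "sigma2")
    if total <= 0:
        raise ValueError("total variance is zero; partition undefined")
    shares = {}
    for key, val in v.items():
        if key == "sigma2":
            shares["residual"] = val / total
        elif key.startswith("Var"):
            name = key.split(":", 1)[1].strip() if ":" in key else key
            shares[name] = val / total
    return shares
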