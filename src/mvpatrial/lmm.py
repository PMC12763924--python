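"""Univariate comparison arm: repeated-measures linear mixed models.

One model per PA variable, fitted by REML:

    Y = b0 + b1*time7 + b2*time18 + b3*time7*group + b4*time18*group + b5*wear
        + u_preschool + u_child + e

b3 and b4 are the 7- and 18-month between-group effects. Baseline imbalance
is absorbed by *excluding* the group main effect (both arms share the
baseline mean), wear time enters as a time-varying main effect, and random
intercepts for child (nested in preschool) and preschool capture the
repeated-measures and cluster structure. The preschool intraclass
correlation is var_preschool / (var_preschool + var_child + var_residual).

Effects are additionally standardized (SMD) against the pooled baseline SD
of the outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["LMMResult", "fit_lmm", "compute_icc", "lmm_smd", "fit_lmm_table"]


@dataclass
class LMMResult:
    outcome: str
    beta7: float
    beta7_se: float
    beta7_ci: tuple[float, float]
    beta18: float
    beta18_se: float
    beta18_ci: tuple[float, float]
    var_preschool: float
    var_child: float
    var_residual: float
    n_obs: int
    n_children: int
    n_preschools: int
    converged: bool
    singular: bool = False

    @property
    def icc_preschool(self) -> float | None:
        return compute_icc(self.var_preschool, self.var_child, self.var_residual)


def compute_icc(
    var_preschool: float, var_child: float, var_residual: float
) -> float | None:
    """Preschool-level intraclass correlation from the variance components."""
    if min(var_preschool, var_child, var_residual) < 0:
        raise ValueError("variance components must be non-negative")
    total = var_preschool + var_child + var_residual
    if total == 0:
        return None
    return var_preschool / total


def lmm_smd(effect_min_per_day: float, sd_reference: float) -> float:
    """Standardize a min/day effect against a reference (pooled baseline) SD."""
    if sd_reference <= 0:
        raise ValueError("sd_reference must be positive")
    return effect_min_per_day / sd_reference


def fit_lmm(
    table: pd.DataFrame,
    outcome: str,
    baseline_label: str = "baseline",
    time_labels: tuple[str, str] = ("7mo", "18mo"),
    ci_level: float = 0.95,
) -> LMMResult:
    """REML fit of the dummy-time interaction mixed model for one outcome.

    ``table`` is the long-format trial table. Requires >= 2 preschools and
    children observed at >= 1 timepoint (children contribute whatever rows
    they have; the model handles unbalanced panels). Boundary (zero)
    variance estimates are reported as 0 with ``singular=True``.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    df = table.dropna(subset=[outcome]).copy()
    df["time7"] = (df["timepoint"] == time_labels[0]).astype(float)
    df["time18"] = (df["timepoint"] == time_labels[1]).astype(float)
    df["grp"] = df["group"].astype(float)
    if df["preschool_id"].nunique() < 2:
        raise ValueError("need at least 2 preschools")

    formula = (
        f"Q('{outcome}') ~ time7 + time18 + time7:grp + time18:grp + wear_minutes"
    )
    model = sm.MixedLM.from_formula(
        formula,
        groups="preschool_id",
        re_formula="1",
        vc_formula={"child": "0 + C(child_id)"},
        data=df,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            res = model.fit(reml=True, method="lbfgs", maxiter=200)
            if not res.converged:
                res = model.fit(reml=True, method="powell", maxiter=500)
        except np.linalg.LinAlgError as err:
            raise RuntimeError(f"mixed model failed for {outcome}: {err}") from err
    if not res.converged:
        raise RuntimeError(
            f"mixed model did not converge for {outcome}: "
            f"{getattr(res, 'convergence_info', 'no diagnostics')}"
        )

    z = stats.norm.ppf(0.5 + ci_level / 2)
    fe = res.fe_params
    se = res.bse_fe
    b7 = float(fe["time7:grp"])
    b18 = float(fe["time18:grp"])
    s7 = float(se["time7:grp"])
    s18 = float(se["time18:grp"])
    var_ps = float(np.asarray(res.cov_re)[0, 0])
    var_child = float(np.asarray(res.vcomp).ravel()[0]) if res.vcomp.size else 0.0
    var_resid = float(res.scale)
    singular = var_ps < 1e-8 or var_child < 1e-8
    return LMMResult(
        outcome=outcome,
        beta7=b7,
        beta7_se=s7,
        beta7_ci=(b7 - z * s7, b7 + z * s7),
        beta18=b18,
        beta18_se=s18,
        beta18_ci=(b18 - z * s18, b18 + z * s18),
        var_preschool=max(var_ps, 0.0),
        var_child=max(var_child, 0.0),
        var_residual=var_resid,
        n_obs=len(df),
        n_children=df["child_id"].nunique(),
        n_preschools=df["preschool_id"].nunique(),
        converged=bool(res.converged),
        singular=singular,
    )


def fit_lmm_table(
    table: pd.DataFrame,
    variables: list[str],
    population: str = "ITT",
    baseline_label: str = "baseline",
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Fit the mixed model per variable; mirror the trial-report layout.

    One output row per variable x follow-up with the min/day estimate, CI,
    SMD (standardized by the pooled baseline SD of that variable) and the
    preschool ICC. Per-protocol restricts to control children plus
    high-fidelity intervention preschools before fitting.
    """
    population = population.upper()
    df = table
    if population == "PP":
        df = df[(df["group"] == 0) | df["high_fidelity"].astype(bool)]
    base = df[df["timepoint"] == baseline_label]
    rows = []
    for v in variables:
        sd_ref = float(base[v].std(ddof=1))
        res = fit_lmm(df, v, baseline_label=baseline_label, ci_level=ci_level)
        for tp, est, ci in (
            ("7mo", res.beta7, res.beta7_ci),
            ("18mo", res.beta18, res.beta18_ci),
        ):
            rows.append(
                {
                    "variable": v,
                    "timepoint": tp,
                    "population": population,
                    "estimate": est,
                    "ci_low": ci[0],
                    "ci_high": ci[1],
                    "smd": lmm_smd(est, sd_ref),
                    "smd_ci_low": lmm_smd(ci[0], sd_ref),
                    "smd_ci_high": lmm_smd(ci[1], sd_ref),
                    "icc_preschool": res.icc_preschool,
                    "significant": ci[0] > 0 or ci[1] < 0,
                    "n_children": res.n_children,
                }
            )
    return pd.DataFrame(rows)
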