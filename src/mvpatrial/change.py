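"""Residualized change scores and analysis-population construction.

The multivariate analysis models change over time as the residual of the
follow-up value regressed on the baseline value (per variable, with
intercept), computed on the analysis population for that follow-up:

* intention-to-treat (ITT): every child with a valid baseline and the
  requested follow-up measurement;
* per-protocol (PP): control children plus children from intervention
  preschools that reported high/very-high implementation fidelity.

Residualizing on baseline removes regression-to-the-mean and baseline
imbalance from the change metric; by construction the residuals have mean
zero and zero sample correlation with baseline.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["residualized_change", "build_change_table"]


def residualized_change(
    baseline: np.ndarray, followup: np.ndarray
) -> np.ndarray:
    """Residuals of the OLS regression (with intercept) of follow-up on baseline.

    Falls back to the centered follow-up (with a warning) when the baseline
    has zero variance, in which case no baseline adjustment is estimable.
    """
    x = np.asarray(baseline, dtype=float)
    y = np.asarray(followup, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("baseline and followup must be paired 1-d vectors")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    xc = x - x.mean()
    sxx = xc @ xc
    if sxx <= 0:
        warnings.warn(
            "baseline has zero variance; returning centered follow-up",
            stacklevel=2,
        )
        return y - y.mean()
    beta = (xc @ (y - y.mean())) / sxx
    return y - y.mean() - beta * xc


def build_change_table(
    table: pd.DataFrame,
    followup: str,
    population: str = "ITT",
    variables: list[str] | None = None,
    baseline_label: str = "baseline",
) -> pd.DataFrame:
    """Residualized-change table for one follow-up and analysis population.

    ``table`` is the long-format trial table (child x timepoint rows with
    ``child_id``, ``preschool_id``, ``group``, ``high_fidelity``,
    ``timepoint``, ``wear_minutes``, ``overall_cpm`` and descriptor columns).
    Returns one row per analyzable child with columns: identifiers, ``group``,
    residualized change per variable (same names), ``wear_change``
    (follow-up minus baseline wear) and ``baseline_cpm``. Residualization is
    performed after population subsetting. Complete-case per follow-up; no
    imputation.
    """
    population = population.upper()
    if population not in ("ITT", "PP"):
        raise ValueError("population must be 'ITT' or 'PP'")
    base = table[table["timepoint"] == baseline_label].set_index("child_id")
    fup = table[table["timepoint"] == followup].set_index("child_id")
    if fup.empty:
        raise ValueError(f"no rows at follow-up {followup!r}")
    common = base.index.intersection(fup.index)
    if common.empty:
        raise ValueError("no children with both baseline and follow-up")
    base = base.loc[common]
    fup = fup.loc[common]
    if population == "PP":
        keep = (base["group"] == 0) | base["high_fidelity"].astype(bool)
        base, fup = base[keep], fup[keep]

    if variables is None:
        meta = {
            "child_id", "preschool_id", "group", "high_fidelity", "timepoint",
            "wear_minutes", "overall_cpm",
        }
        variables = [c for c in table.columns if c not in meta]

    out = pd.DataFrame(
        {
            "child_id": base.index,
            "preschool_id": base["preschool_id"].to_numpy(),
            "group": base["group"].to_numpy(),
            "wear_change": fup["wear_minutes"].to_numpy()
            - base["wear_minutes"].to_numpy(),
            "baseline_cpm": base["overall_cpm"].to_numpy(),
        }
    )
    for v in variables:
        out[v] = residualized_change(
            base[v].to_numpy(), fup[v].to_numpy()
        )
    out.attrs["population"] = population
    out.attrs["timepoint"] = followup
    out.attrs["variables"] = list(variables)
    return out
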