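"""Multivariate pattern analysis engine.

PLS1 (NIPALS) regression of a binary group indicator on the intensity-
spectrum change scores, with

* autoscaling and covariate projection (sequential rank-one removal of
  covariate-associated variance from every variable and the outcome),
* Monte Carlo resampling validation of the number of components: repeated
  random 50/50 calibration/validation splits, a component retained when it
  improves out-of-sample explained variance in more than half the splits,
* target projection of the multi-component model onto the single predictive
  direction t_TP = X b / ||b||, yielding a per-variable multivariate
  correlation coefficient r_j = corr(x_j, t_TP) * corr(t_TP, y) that reduces
  to the bivariate Pearson correlation when X has one column,
* percentile confidence intervals for r_j over Monte Carlo half-sample
  refits, and
* conversion to effect sizes: SMD_j = r_j / 0.5 (0.5 being the SD of a
  balanced binary group coded 0/1) and min/day_j = SMD_j * SD(x_j).

Clustering is deliberately not modelled here; for cluster designs a
conservative CI level (99%) compensates for the unadjusted standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardizeParams",
    "PLSModel",
    "ValidationResult",
    "TargetProjectionResult",
    "EffectPattern",
    "standardize",
    "covariate_project",
    "pls1_fit",
    "mc_validate",
    "target_project",
    "resample_effect_cis",
    "to_effect_pattern",
    "run_mvpa",
    "ci_widening_factor",
    "BINARY_GROUP_SD",
]

#: SD of a balanced binary variable coded 0/1 — the standardizer that turns a
#: multivariate correlation into an SMD.
BINARY_GROUP_SD = 0.5


def ci_widening_factor(level_hi: float = 0.99, level_lo: float = 0.95) -> float:
    """Relative widening of a normal-theory CI when raising the level.

    E.g. moving from 95% to 99% intervals widens them by
    z_{.995}/z_{.975} - 1 ~ 32%.
    """
    z_hi = stats.norm.ppf(0.5 + level_hi / 2)
    z_lo = stats.norm.ppf(0.5 + level_lo / 2)
    return z_hi / z_lo - 1.0


# ---------------------------------------------------------------------------
# Preprocessing


@dataclass
class StandardizeParams:
    means: np.ndarray
    sds: np.ndarray
    kept: list[int]
    dropped: list[int]
    y_mean: float
    y_sd: float


def standardize(
    X: np.ndarray, y: np.ndarray, ddof: int = 1
) -> tuple[np.ndarray, np.ndarray, StandardizeParams]:
    """Autoscale columns of X and y to mean 0, SD 1; drop zero-variance columns."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=ddof)
    kept = [j for j in range(X.shape[1]) if sds[j] > 0]
    dropped = [j for j in range(X.shape[1]) if sds[j] <= 0]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} zero-variance column(s): {dropped}",
            stacklevel=2,
        )
    y_sd = y.std(ddof=ddof)
    if y_sd <= 0:
        raise ValueError("outcome has zero variance")
    Xs = (X[:, kept] - means[kept]) / sds[kept]
    ys = (y - y.mean()) / y_sd
    return Xs, ys, StandardizeParams(means, sds, kept, dropped, y.mean(), y_sd)


def covariate_project(
    X: np.ndarray, y: np.ndarray, C: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Remove covariate-associated variance from X and y by projection.

    Covariates are handled sequentially: each (centered) covariate is
    projected out of every column of X, the outcome and the remaining
    covariates — a chain of rank-one projections equivalent to least-squares
    residualization on the span of [intercept, covariates]. Residuals are
    centered and uncorrelated with every covariate.
    """
    X = np.asarray(X, dtype=float)
    X = X - X.mean(axis=0)
    y = np.asarray(y, dtype=float)
    y = y - y.mean()
    C = np.asarray(C, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    C = C.copy()
    for k in range(C.shape[1]):
        c = C[:, k] - C[:, k].mean()
        cc = c @ c
        if cc <= 1e-12 * len(c):
            raise ValueError(f"covariate {k} has (near-)zero variance")
        X -= np.outer(c, (c @ X) / cc)
        y = y - c * ((c @ y) / cc)
        if k + 1 < C.shape[1]:
            C[:, k + 1 :] -= np.outer(c, (c @ C[:, k + 1 :]) / cc)
    return X, y


# ---------------------------------------------------------------------------
# PLS1 (NIPALS)


@dataclass
class PLSModel:
    """Fitted PLS1 decomposition (on centered/scaled data)."""

    weights: np.ndarray  # W, (p, A)
    scores: np.ndarray  # T, (n, A)
    x_loadings: np.ndarray  # P, (p, A)
    y_loadings: np.ndarray  # q, (A,)
    coef: np.ndarray  # b, (p,)
    n_components: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef

    def r2(self, X: np.ndarray, y: np.ndarray) -> float:
        res = y - self.predict(X)
        tot = y - y.mean()
        return 1.0 - (res @ res) / (tot @ tot)


def pls1_fit(X: np.ndarray, y: np.ndarray, A: int) -> PLSModel:
    """NIPALS PLS1 with standard deflation of X (and y).

    Assumes centered (typically autoscaled) inputs. If the residual X block
    runs out of covariance with y before A components, the model is
    truncated with a warning. At A = rank(X), the coefficient vector equals
    the least-squares solution.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if A < 1:
        raise ValueError("need at least one component")
    if A > min(n - 1, p):
        warnings.warn(
            f"A={A} exceeds min(n-1, p)={min(n - 1, p)}; truncating",
            stacklevel=2,
        )
        A = min(n - 1, p)
    Xa = X.copy()
    ya = y.copy()
    W = np.zeros((p, A))
    T = np.zeros((n, A))
    P = np.zeros((p, A))
    q = np.zeros(A)
    a_eff = 0
    for a in range(A):
        w = Xa.T @ ya
        nw = np.linalg.norm(w)
        if nw <= 1e-12 * max(1.0, np.linalg.norm(ya)):
            warnings.warn(
                f"no remaining covariance after {a} component(s); truncating",
                stacklevel=2,
            )
            break
        w /= nw
        t = Xa @ w
        tt = t @ t
        if tt <= 1e-24:
            break
        pvec = Xa.T @ t / tt
        qa = (ya @ t) / tt
        Xa -= np.outer(t, pvec)
        ya = ya - qa * t
        W[:, a], T[:, a], P[:, a], q[a] = w, t, pvec, qa
        a_eff = a + 1
    W, T, P, q = W[:, :a_eff], T[:, :a_eff], P[:, :a_eff], q[:a_eff]
    if a_eff == 0:
        raise ValueError("X carries no covariance with y")
    coef = W @ np.linalg.solve(P.T @ W, q)
    return PLSModel(W, T, P, q, coef, a_eff)


# ---------------------------------------------------------------------------
# Monte Carlo validation


@dataclass
class ValidationResult:
    """Monte Carlo component-selection evidence.

    ``explained_variance`` holds the out-of-sample explained variance (as a
    fraction) per repetition for 0..A_max components (column 0 — the
    mean-only model — is zero by definition). ``win_fraction[a-1]`` is the
    share of repetitions in which a components beat a-1.
    """

    reps: int
    split_fraction: float
    threshold: float
    explained_variance: np.ndarray  # (reps, A_max + 1)
    win_fraction: np.ndarray  # (A_max,)
    selected_components: int
    predictive: bool
    validated_explained_variance_pct: float | None
    n_redrawn: int = 0


def _oos_explained_variance(
    X_cal, y_cal, X_val, y_val, A_max: int
) -> np.ndarray:
    """Out-of-sample explained variance for 1..A_max components.

    The calibration fold is re-centered; validation residual sums of squares
    are referenced to the calibration mean (the A=0 prediction).
    """
    mx = X_cal.mean(axis=0)
    my = y_cal.mean()
    Xc, yc = X_cal - mx, y_cal - my
    Xv, yv = X_val - mx, y_val - my
    ss0 = yv @ yv
    out = np.full(A_max, -np.inf)
    try:
        model = pls1_fit(Xc, yc, A_max)
    except ValueError:
        return out
    # evaluate nested sub-models from the single fit
    for a in range(1, model.n_components + 1):
        W, P, q = model.weights[:, :a], model.x_loadings[:, :a], model.y_loadings[:a]
        b = W @ np.linalg.solve(P.T @ W, q)
        res = yv - Xv @ b
        out[a - 1] = 1.0 - (res @ res) / ss0
    out[model.n_components :] = out[model.n_components - 1]
    return out


def mc_validate(
    X: np.ndarray,
    y: np.ndarray,
    A_max: int,
    reps: int = 1000,
    frac: float = 0.5,
    threshold: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> ValidationResult:
    """Select the number of PLS components by Monte Carlo resampling.

    Each repetition holds out ``1 - frac`` of the subjects as an external
    validation set; component a is retained iff the a-component model beats
    the (a-1)-component model on validation explained variance in more than
    ``threshold`` of the repetitions, and the selected order is the largest
    such prefix. The model is declared non-predictive when no component
    passes. The validated explained variance is the median out-of-sample
    explained variance at the selected order, in percent.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError("need n >= 10 for Monte Carlo validation")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_cal = max(int(round(frac * n)), 2)
    ev = np.zeros((reps, A_max + 1))
    n_redrawn = 0
    for r in range(reps):
        for _attempt in range(100):
            perm = rng.permutation(n)
            cal, val = perm[:n_cal], perm[n_cal:]
            if np.std(y[val]) > 0 and np.std(y[cal]) > 0:
                break
            n_redrawn += 1
        else:
            raise RuntimeError("could not draw a non-degenerate split")
        ev[r, 1:] = _oos_explained_variance(X[cal], y[cal], X[val], y[val], A_max)
    win = (ev[:, 1:] > ev[:, :-1]).mean(axis=0)
    selected = 0
    for a in range(A_max):
        if win[a] > threshold:
            selected = a + 1
        else:
            break
    predictive = selected >= 1
    vev = float(np.median(ev[:, selected]) * 100.0) if predictive else None
    return ValidationResult(
        reps=reps,
        split_fraction=frac,
        threshold=threshold,
        explained_variance=ev,
        win_fraction=win,
        selected_components=selected,
        predictive=predictive,
        validated_explained_variance_pct=vev,
        n_redrawn=n_redrawn,
    )


# ---------------------------------------------------------------------------
# Target projection and effect patterns


@dataclass
class TargetProjectionResult:
    target_scores: np.ndarray  # t_TP, (n,)
    target_loadings: np.ndarray  # p_TP, (p,)
    r: np.ndarray  # multivariate correlation per variable, (p,)


def _corr(a: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation of vector a with each column of B (B may be 1-d)."""
    a = a - a.mean()
    B = np.asarray(B, dtype=float)
    one_d = B.ndim == 1
    if one_d:
        B = B[:, None]
    B = B - B.mean(axis=0)
    denom = np.linalg.norm(a) * np.linalg.norm(B, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (a @ B) / denom, 0.0)
    return float(r[0]) if one_d else r


def target_project(
    model: PLSModel, X: np.ndarray, y: np.ndarray
) -> TargetProjectionResult:
    """Rotate a PLS model onto its single predictive direction.

    t_TP = X b / ||b||; p_TP = X' t_TP / (t_TP' t_TP). The multivariate
    correlation of variable j is corr(x_j, t_TP) * corr(t_TP, y): its
    association with the predictive direction, attenuated by how well that
    direction predicts the outcome. With a single explanatory variable this
    is exactly the bivariate Pearson correlation with y.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    nb = np.linalg.norm(model.coef)
    if nb <= 0:
        raise ValueError("zero coefficient vector: no predictive direction")
    t_tp = X @ model.coef / nb
    p_tp = X.T @ t_tp / (t_tp @ t_tp)
    r = _corr(t_tp, X) * _corr(t_tp, y)
    return TargetProjectionResult(t_tp, p_tp, r)


def resample_effect_cis(
    X: np.ndarray,
    y: np.ndarray,
    A: int,
    level: float = 0.99,
    reps: int = 1000,
    frac: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Percentile CIs for the multivariate correlations from half-sample refits.

    Each repetition refits the A-component model on a random calibration
    half and recomputes the per-variable multivariate correlations there;
    the CI is the percentile interval of the resampling distribution.
    Returns (r_samples, ci_low, ci_high). Fails if fewer than 100
    repetitions succeed.
    """
    if level not in (0.95, 0.99):
        raise ValueError("CI level must be 0.95 or 0.99")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_cal = max(int(round(frac * n)), 3)
    samples = []
    for _r in range(reps):
        idx = rng.permutation(n)[:n_cal]
        Xc = X[idx] - X[idx].mean(axis=0)
        yc = y[idx] - y[idx].mean()
        if yc.std() <= 0:
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = pls1_fit(Xc, yc, A)
            tp = target_project(model, Xc, yc)
        except (ValueError, np.linalg.LinAlgError):
            continue
        samples.append(tp.r)
    if len(samples) < 100:
        raise RuntimeError(
            f"only {len(samples)} successful resampling repetitions (< 100)"
        )
    r_samples = np.array(samples)
    alpha = 1.0 - level
    lo = np.percentile(r_samples, 100 * alpha / 2, axis=0)
    hi = np.percentile(r_samples, 100 * (1 - alpha / 2), axis=0)
    return r_samples, lo, hi


@dataclass
class EffectPattern:
    """Per-variable effect sizes derived from a target-projected model."""

    table: pd.DataFrame
    descriptor: str | None = None
    timepoint: str | None = None
    population: str | None = None
    ci_level: float = 0.99


def to_effect_pattern(
    variables: list[str],
    r: np.ndarray,
    ci_low: np.ndarray,
    ci_high: np.ndarray,
    sds: np.ndarray | None = None,
    ci_level: float = 0.99,
    **meta,
) -> EffectPattern:
    """Convert multivariate correlations to SMDs and optional min/day effects.

    SMD_j = r_j / 0.5; minutes_j = SMD_j * sd_j (sd_j the SD of the
    corresponding PA variable, on whatever scale the analysis used). CIs are
    mapped through the same affine transforms. A variable is flagged
    significant when its CI excludes zero.
    """
    r = np.asarray(r, dtype=float)
    smd = r / BINARY_GROUP_SD
    smd_lo = np.asarray(ci_low) / BINARY_GROUP_SD
    smd_hi = np.asarray(ci_high) / BINARY_GROUP_SD
    tab = pd.DataFrame(
        {
            "variable": variables,
            "r": r,
            "r_ci_low": ci_low,
            "r_ci_high": ci_high,
            "smd": smd,
            "smd_ci_low": smd_lo,
            "smd_ci_high": smd_hi,
            "significant": (np.asarray(ci_low) > 0) | (np.asarray(ci_high) < 0),
        }
    )
    if sds is not None:
        sds = np.asarray(sds, dtype=float)
        if np.any(sds[np.isfinite(sds)] < 0):
            raise ValueError("variable SDs must be positive")
        tab["minutes"] = smd * sds
        tab["minutes_ci_low"] = smd_lo * sds
        tab["minutes_ci_high"] = smd_hi * sds
    return EffectPattern(table=tab, ci_level=ci_level, **meta)


# ---------------------------------------------------------------------------
# Full chain


@dataclass
class MVPAResult:
    validation: ValidationResult
    pattern: EffectPattern | None
    model: PLSModel | None
    dropped_variables: list[str] = field(default_factory=list)


def run_mvpa(
    change_table: pd.DataFrame,
    variables: list[str] | None = None,
    covariates: tuple[str, ...] = ("wear_change", "baseline_cpm"),
    outcome: str = "group",
    a_max: int | None = None,
    reps: int = 1000,
    frac: float = 0.5,
    threshold: float = 0.5,
    ci_level: float = 0.99,
    ci_reps: int = 1000,
    seed: int = 0,
) -> MVPAResult:
    """The full multivariate pattern analysis on a change table.

    Autoscales the change scores and group indicator, projects out the
    covariates (change in wear time, then baseline total activity), selects
    the number of PLS components by Monte Carlo resampling, and — when a
    predictive model exists — target-projects it into per-variable
    multivariate correlations with percentile resampling CIs and SMD /
    min-per-day effect sizes. Min/day effects use the SD of each variable's
    (covariate-adjusted) change score.
    """
    if variables is None:
        variables = change_table.attrs.get("variables")
    if variables is None:
        raise ValueError("variables must be given or present in table attrs")
    rng = np.random.default_rng(seed)
    X = change_table[list(variables)].to_numpy(dtype=float)
    y = change_table[outcome].to_numpy(dtype=float)
    C = change_table[list(covariates)].to_numpy(dtype=float)

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        Xs, ys, params = standardize(X, y)
    kept_vars = [variables[j] for j in params.kept]
    dropped = [variables[j] for j in params.dropped]
    Xp, yp = covariate_project(Xs, ys, C)
    sds = Xp.std(axis=0, ddof=1) * params.sds[params.kept]  # adjusted-change SD, min/day

    if a_max is None:
        a_max = min(len(kept_vars), 10)
    validation = mc_validate(
        Xp, yp, a_max, reps=reps, frac=frac, threshold=threshold, seed=rng
    )
    if not validation.predictive:
        return MVPAResult(validation, None, None, dropped)

    model = pls1_fit(Xp, yp, validation.selected_components)
    tp = target_project(model, Xp, yp)
    _, lo, hi = resample_effect_cis(
        Xp, yp, validation.selected_components, level=ci_level,
        reps=ci_reps, frac=frac, seed=rng,
    )
    pattern = to_effect_pattern(
        kept_vars, tp.r, lo, hi, sds=sds, ci_level=ci_level,
        timepoint=change_table.attrs.get("timepoint"),
        population=change_table.attrs.get("population"),
    )
    return MVPAResult(validation, pattern, model, dropped)
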