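"""Control-standardized phenotypic trajectory analysis.

Newly founded laboratory populations are assayed in synchrony with
long-established control populations, and every analysis works on
deviations from the synchronous control mean: trajectories use the plain
difference (mean_exp - mean_ctrl), while the evolutionary-rate versus
early-differentiation analysis uses the relative deviation
(mean_exp - mean_ctrl) / mean_ctrl.  A population's evolutionary rate is
the OLS slope of its standardized trait value against generation; its early
differentiation d0 is the relative deviation at the foundation's first
assayed generation.  The rate-vs-d0 regression quantifies the convergence
law "farther from the control, faster the response".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assoc_stats import ols_slope
from .karyo_io import CONTROL_LABEL, validate_pheno_assay


@dataclass(frozen=True)
class TrajectorySlope:
    foundation: str
    replicate: str
    trait: str
    slope: float
    intercept: float
    n_generations: int


@dataclass(frozen=True)
class EarlyDifferentiation:
    foundation: str
    replicate: str
    trait: str
    d0: float


@dataclass
class RateRegressionResult:
    pooled_slope: float
    pooled_intercept: float
    pooled_p_value: float
    group_slopes: dict
    homogeneity_F: float
    homogeneity_p: float
    n: int


def standardize_to_control(assays: pd.DataFrame, mode: str = "difference") -> pd.DataFrame:
    """Per replicate x generation x trait deviation from the control mean.

    ``mode="difference"`` returns mean_exp - mean_ctrl; ``mode="relative"``
    divides that difference by the control mean.  Returns columns
    foundation, replicate, generation, trait, value.
    """
    if mode not in ("difference", "relative"):
        raise ValueError(f"unknown mode {mode!r}")
    assays = validate_pheno_assay(assays)
    is_ctrl = assays["foundation"] == CONTROL_LABEL
    ctrl = (
        assays[is_ctrl]
        .groupby(["generation", "trait"])["value"]
        .mean()
        .rename("ctrl_mean")
    )
    exp = (
        assays[~is_ctrl]
        .groupby(["foundation", "replicate", "generation", "trait"], as_index=False)["value"]
        .mean()
    )
    exp = exp.join(ctrl, on=["generation", "trait"])
    if exp["ctrl_mean"].isna().any():
        bad = exp.loc[exp["ctrl_mean"].isna()].iloc[0]
        raise ValueError(
            f"no synchronous control for generation {bad['generation']}, trait {bad['trait']!r}"
        )
    if mode == "relative" and (exp["ctrl_mean"] == 0).any():
        bad = exp.loc[exp["ctrl_mean"] == 0].iloc[0]
        raise ValueError(
            f"control mean is zero for generation {bad['generation']}, trait {bad['trait']!r}"
        )
    diff = exp["value"] - exp["ctrl_mean"]
    exp["value"] = diff if mode == "difference" else diff / exp["ctrl_mean"]
    return exp.drop(columns="ctrl_mean")


def trajectory_slope(
    standardized: pd.DataFrame,
    generation_cap: dict | None = None,
) -> list[TrajectorySlope]:
    """OLS slope of standardized value on generation, one per replicate x trait.

    ``generation_cap`` maps trait -> last generation to include (e.g. male
    body size truncated where terminal assays are missing).
    """
    out = []
    for (fnd, rep, trait), sub in standardized.groupby(["foundation", "replicate", "trait"]):
        if generation_cap and trait in generation_cap:
            sub = sub[sub["generation"] <= generation_cap[trait]]
        sub = sub.sort_values("generation")
        if len(sub) < 2:
            raise ValueError(f"need >= 2 generations for {fnd}/{rep} trait {trait!r}")
        b, a = ols_slope(sub["generation"], sub["value"])
        out.append(TrajectorySlope(fnd, rep, trait, b, a, len(sub)))
    return out


def early_differentiation(
    assays: pd.DataFrame,
    first_generation: dict | int,
) -> list[EarlyDifferentiation]:
    """Relative deviation from control at each foundation's first assayed
    generation; ``first_generation`` is an int or {foundation: generation}."""
    rel = standardize_to_control(assays, mode="relative")
    out = []
    for (fnd, rep, trait), sub in rel.groupby(["foundation", "replicate", "trait"]):
        gen = first_generation[fnd] if isinstance(first_generation, dict) else first_generation
        at = sub[sub["generation"] == gen]
        if at.empty:
            raise ValueError(f"no assay at generation {gen} for {fnd}/{rep} trait {trait!r}")
        out.append(EarlyDifferentiation(fnd, rep, trait, float(at["value"].mean())))
    return out


def rate_regression(
    slopes: list[TrajectorySlope],
    early: list[EarlyDifferentiation],
    group_by: str = "foundation",
) -> RateRegressionResult:
    """Regression of evolutionary rate on early differentiation.

    Fits the pooled OLS of slope b on d0 across matched (foundation,
    replicate, trait) records, per-group slopes, and an extra-sum-of-squares
    F-test comparing the common-slope model (group intercepts + shared d0
    slope) against group-specific slopes.
    """
    sl = pd.DataFrame([vars(s) for s in slopes])
    ed = pd.DataFrame([vars(e) for e in early])
    df = sl.merge(ed, on=["foundation", "replicate", "trait"], how="inner")
    if df.empty:
        raise ValueError("no matched (foundation, replicate, trait) records")
    if np.allclose(df["d0"], df["d0"].iloc[0]):
        raise ValueError("degenerate early differentiation: all d0 equal")
    y = df["slope"].to_numpy(float)
    x = df["d0"].to_numpy(float)
    fit = stats.linregress(x, y)
    groups = df[group_by].astype(str)
    labels = sorted(groups.unique())
    group_slopes = {}
    for g in labels:
        sub = df[groups == g]
        if sub["d0"].nunique() > 1:
            group_slopes[g] = float(stats.linregress(sub["d0"], sub["slope"]).slope)
        else:
            group_slopes[g] = np.nan
    # common-slope vs group-specific-slope fixed-effects comparison
    if len(labels) >= 2:
        G = pd.get_dummies(groups).to_numpy(float)
        X0 = np.column_stack([G, x])  # group intercepts + shared slope
        X1 = np.column_stack([G, G * x[:, None]])  # group intercepts + slopes
        rss0 = _rss(X0, y)
        rss1 = _rss(X1, y)
        df_extra = len(labels) - 1
        df_resid = len(y) - X1.shape[1]
        tol = 1e-12 * max(float(y @ y), 1.0)  # perfect-fit guard
        if df_resid <= 0:
            F, p = np.nan, np.nan
        elif rss1 <= tol:
            F = 0.0 if rss0 - rss1 <= tol else np.inf
            p = 1.0 if F == 0.0 else 0.0
        else:
            F = ((rss0 - rss1) / df_extra) / (rss1 / df_resid)
            F = max(F, 0.0)
            p = float(stats.f.sf(F, df_extra, df_resid))
    else:
        F, p = np.nan, np.nan
    return RateRegressionResult(
        pooled_slope=float(fit.slope),
        pooled_intercept=float(fit.intercept),
        pooled_p_value=float(fit.pvalue),
        group_slopes=group_slopes,
        homogeneity_F=F,
        homogeneity_p=p,
        n=len(df),
    )


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)
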