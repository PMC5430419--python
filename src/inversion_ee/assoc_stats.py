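"""Replicated contingency tests and transformed-frequency slope analysis.

Covers three replicate-level analyses of arrangement-frequency change:

* the Cochran-Mantel-Haenszel chi-square combining one 2x2 table per
  replicate (focal arrangement vs all others, initial vs final generation);
* ordinary least-squares slopes of variance-stabilized (arcsine-square-root)
  frequencies against generation, one per replicate population; and
* a balanced fixed-effects two-way ANOVA (Year x Location, replicates as
  error term) comparing those slopes between foundations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .karyo_io import POOLED_LABEL


@dataclass(frozen=True)
class CMHResult:
    statistic: float
    p_value: float
    df: int = 1


@dataclass(frozen=True)
class SlopeRecord:
    foundation: str
    replicate: str
    chromosome: str
    arrangement: str
    slope: float
    intercept: float
    n_points: int


def cmh_statistic(tables, continuity: bool = False) -> CMHResult:
    """Cochran-Mantel-Haenszel chi-square over K stratified 2x2 tables.

    ``tables`` is an iterable of 2x2 arrays [[a, b], [c, d]] with rows =
    (focal arrangement, all others) and columns = (initial, final
    generation).  M^2 = (|sum_k (a_k - E a_k)| - correction)^2 / sum_k V_k
    with the hypergeometric mean and variance from each stratum's margins;
    strata with a zero margin contribute nothing.
    """
    dev = 0.0
    var = 0.0
    used = 0
    for t in tables:
        t = np.asarray(t, dtype=float)
        if t.shape != (2, 2) or np.any(t < 0):
            raise ValueError(f"each stratum must be a non-negative 2x2 table, got {t}")
        a = t[0, 0]
        r1, r2 = t.sum(axis=1)
        c1, c2 = t.sum(axis=0)
        n = t.sum()
        if 0 in (r1, r2, c1, c2):
            continue
        dev += a - r1 * c1 / n
        var += r1 * r2 * c1 * c2 / (n * n * (n - 1))
        used += 1
    if used == 0 or var == 0:
        raise ValueError("all strata degenerate (zero margin or no variance)")
    num = abs(dev) - (0.5 if continuity else 0.0)
    num = max(num, 0.0)
    m2 = num * num / var
    return CMHResult(statistic=m2, p_value=float(stats.chi2.sf(m2, df=1)))


def stratified_table(
    counts: pd.DataFrame,
    foundation: str,
    chromosome: str,
    arrangement: str,
    initial_generation: int,
    final_generation: int,
) -> list[np.ndarray]:
    """Build the replicate-stratified 2x2 tables for one arrangement.

    Each replicate present at both generations contributes one stratum
    [[focal_initial, focal_final], [others_initial, others_final]].  When the
    initial generation precedes replication (only a pooled sample exists),
    the final-generation replicates are summed and the comparison collapses
    to a single pooled-vs-pooled stratum.
    """
    sub = counts[
        (counts["foundation"] == foundation)
        & (counts["chromosome"] == chromosome)
        & (counts["generation"].isin([initial_generation, final_generation]))
    ]
    if sub.empty:
        raise ValueError(
            f"no counts for {foundation} chromosome {chromosome} at generations "
            f"{initial_generation}/{final_generation}"
        )
    tables = []
    for rep in sorted(sub["replicate"].unique()):
        rep_rows = sub[sub["replicate"] == rep]
        cols = []
        for gen in (initial_generation, final_generation):
            g = rep_rows[rep_rows["generation"] == gen]
            if g.empty:
                break
            focal = int(g.loc[g["arrangement"] == arrangement, "count"].sum())
            total = int(g["count"].sum())
            cols.append((focal, total - focal))
        if len(cols) == 2:
            tables.append(np.array([[cols[0][0], cols[1][0]], [cols[0][1], cols[1][1]]]))
    if not tables:
        # pre-replication start: pooled initial sample vs summed final sample
        ini = sub[(sub["generation"] == initial_generation) & (sub["replicate"] == POOLED_LABEL)]
        fin = sub[(sub["generation"] == final_generation) & (sub["replicate"] != POOLED_LABEL)]
        if ini.empty or fin.empty:
            raise ValueError("no replicate sampled at both generations")
        cells = []
        for g in (ini, fin):
            focal = int(g.loc[g["arrangement"] == arrangement, "count"].sum())
            total = int(g["count"].sum())
            cells.append((focal, total - focal))
        tables.append(np.array([[cells[0][0], cells[1][0]], [cells[0][1], cells[1][1]]]))
    return tables


def arcsine_transform(p, mode: str = "sqrt"):
    """Variance-stabilizing transform: arcsin(sqrt(p)) ("sqrt", default) or
    plain arcsin(p) ("raw")."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    if mode == "sqrt":
        return np.arcsin(np.sqrt(p))
    if mode == "raw":
        return np.arcsin(p)
    raise ValueError(f"unknown transform mode {mode!r}")


def ols_slope(x, y) -> tuple[float, float]:
    """Least-squares slope and intercept of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need >= 2 paired points")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def arcsine_slope(
    freqs: pd.DataFrame,
    foundation: str,
    replicate: str,
    chromosome: str,
    arrangement: str,
    mode: str = "sqrt",
    include_pooled_start: bool = True,
) -> SlopeRecord:
    """OLS slope of transformed frequency against generation for one replicate.

    The pre-replication (pooled) sample supplies the replicate's earliest
    point when ``include_pooled_start`` is set, mirroring the shared origin
    of the three replicates.
    """
    reps = [replicate] + ([POOLED_LABEL] if include_pooled_start else [])
    sub = freqs[
        (freqs["foundation"] == foundation)
        & (freqs["replicate"].isin(reps))
        & (freqs["chromosome"] == chromosome)
        & (freqs["arrangement"] == arrangement)
    ].sort_values("generation")
    if len(sub) < 2:
        raise ValueError(
            f"need >= 2 assayed generations for {foundation}/{replicate} {arrangement}"
        )
    y = arcsine_transform(sub["p"].to_numpy(), mode=mode)
    slope, intercept = ols_slope(sub["generation"].to_numpy(), y)
    return SlopeRecord(
        foundation=foundation, replicate=replicate, chromosome=chromosome,
        arrangement=arrangement, slope=slope, intercept=intercept, n_points=len(sub),
    )


def anova_two_factor(values: pd.DataFrame) -> pd.DataFrame:
    """Balanced fixed-effects two-way ANOVA on replicate-level values.

    ``values`` has columns year, location, replicate, value; the design must
    be balanced (r >= 2 replicates in each of the four year x location
    cells).  Year, Location and Year x Location are each tested against the
    among-replicate-within-cell mean square on (1, 4(r-1)) df.  With balance,
    Type I and Type III sums of squares coincide.
    """
    required = {"year", "location", "replicate", "value"}
    if not required <= set(values.columns):
        raise ValueError(f"values must have columns {sorted(required)}")
    years = sorted(values["year"].unique())
    locs = sorted(values["location"].unique())
    if len(years) != 2 or len(locs) != 2:
        raise ValueError("design must have exactly 2 years and 2 locations")
    sizes = values.groupby(["year", "location"])["value"].size()
    if len(sizes) != 4 or sizes.nunique() != 1 or sizes.iloc[0] < 2:
        raise ValueError("unbalanced design: need r >= 2 replicates in every cell")
    r = int(sizes.iloc[0])
    v = values["value"].to_numpy(float)
    grand = v.mean()
    cell = values.groupby(["year", "location"])["value"].mean()
    ymean = values.groupby("year")["value"].mean()
    lmean = values.groupby("location")["value"].mean()
    ss_year = 2 * r * float(((ymean - grand) ** 2).sum())
    ss_loc = 2 * r * float(((lmean - grand) ** 2).sum())
    ss_cells = r * float(((cell - grand) ** 2).sum())
    ss_int = ss_cells - ss_year - ss_loc
    cell_of = values.set_index(["year", "location"]).index
    resid = v - cell.loc[cell_of].to_numpy(float)
    ss_err = float((resid ** 2).sum())
    df_err = 4 * (r - 1)
    ms_err = ss_err / df_err
    rows = []
    for name, ss in (("Year", ss_year), ("Location", ss_loc), ("Year:Location", ss_int)):
        ss = max(ss, 0.0)
        if ms_err == 0:
            f = 0.0 if ss == 0 else np.inf
            p = 1.0 if ss == 0 else 0.0
        else:
            f = ss / ms_err
            p = float(stats.f.sf(f, 1, df_err))
        rows.append({"effect": name, "ss": ss, "df": 1, "F": f, "p_value": p})
    rows.append({"effect": "Residual", "ss": ss_err, "df": df_err, "F": np.nan, "p_value": np.nan})
    return pd.DataFrame(rows)
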