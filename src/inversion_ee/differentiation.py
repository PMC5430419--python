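"""Weir-Cockerham-style differentiation of arrangement frequencies.

Each chromosome is treated as one multiallelic haploid locus: every scored
chromosome is a single allele copy (one larva per assayed male reveals one
paternal chromosome), so there are no heterozygosity terms.  Variance
components are estimated by the method of moments from one-way (theta-p,
populations) or nested two-way (theta-f, foundations with replicate
populations nested inside) ANOVAs on allele-indicator variables, and
combined across alleles and loci as a ratio of sums.  Negative estimates are
reported as computed, following the usual moment-estimator convention.

Uncertainty is available either as a percentile bootstrap over loci (noisy
with only the five chromosomes of D. subobscura) or, preferably, as a
permutation test that shuffles sampled chromosomes among populations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import karyo_io


@dataclass
class ThetaResult:
    level: str  # "population" or "foundation-hierarchical"
    theta: float
    sigma2_among_top: float
    sigma2_among_within: float
    sigma2_within: float
    n_loci: int
    ci_low: float | None = None
    ci_high: float | None = None
    per_locus: dict = field(default_factory=dict)


def _locus_matrix(counts: pd.DataFrame, group_cols) -> tuple[np.ndarray, list]:
    """Counts pivoted to a (groups x alleles) matrix for one chromosome."""
    pivot = counts.pivot_table(
        index=group_cols, columns="arrangement", values="count",
        aggfunc="sum", fill_value=0,
    )
    return pivot.to_numpy(float), list(pivot.index)


def _oneway_components(allele_counts: np.ndarray) -> tuple[float, float]:
    """Per-locus (sigma2_among, sigma2_within) summed over alleles.

    ``allele_counts``: (r populations x k alleles) haploid counts.  Moment
    equations of the one-way random-effects ANOVA on allele indicators:
    MSP = sum_i n_i (p_i - pbar)^2 / (r-1),  MSG = sum_i n_i p_i q_i / (N - r),
    n_c = (N - sum n_i^2 / N) / (r - 1), sigma2_a = (MSP - MSG)/n_c.
    """
    n_i = allele_counts.sum(axis=1)
    keep = n_i > 0
    allele_counts = allele_counts[keep]
    n_i = n_i[keep]
    r = len(n_i)
    if r < 2:
        raise ValueError("need >= 2 populations with samples at the locus")
    N = n_i.sum()
    p_i = allele_counts / n_i[:, None]
    pbar = allele_counts.sum(axis=0) / N
    nc = (N - (n_i ** 2).sum() / N) / (r - 1)
    msp = (n_i[:, None] * (p_i - pbar) ** 2).sum(axis=0) / (r - 1)
    msg = (n_i[:, None] * p_i * (1 - p_i)).sum(axis=0) / (N - r)
    sigma_a = (msp - msg) / nc
    sigma_w = msg
    return float(sigma_a.sum()), float(sigma_w.sum())


def _nested_components(allele_counts: np.ndarray, foundation_of: np.ndarray) -> tuple[float, float, float]:
    """Per-locus (sigma2_foundation, sigma2_replicate, sigma2_within) summed
    over alleles, from the unbalanced two-level nested ANOVA on indicators.

    ``allele_counts``: (replicates x alleles) haploid counts;
    ``foundation_of``: foundation index per replicate row.
    """
    n_ij = allele_counts.sum(axis=1)
    keep = n_ij > 0
    allele_counts, n_ij, foundation_of = allele_counts[keep], n_ij[keep], foundation_of[keep]
    fnds = np.unique(foundation_of)
    a = len(fnds)
    if a < 2:
        raise ValueError("need >= 2 foundations")
    b_total = len(n_ij)
    N = n_ij.sum()
    p_ij = allele_counts / n_ij[:, None]
    # foundation totals
    n_i = np.array([n_ij[foundation_of == f].sum() for f in fnds])
    if any((foundation_of == f).sum() < 2 for f in fnds):
        raise ValueError("every foundation needs >= 2 replicate populations")
    c_i = np.array([allele_counts[foundation_of == f].sum(axis=0) for f in fnds])
    p_i = c_i / n_i[:, None]
    pbar = allele_counts.sum(axis=0) / N

    df_a = a - 1
    df_b = b_total - a
    df_w = N - b_total
    ss_a = (n_i[:, None] * (p_i - pbar) ** 2).sum(axis=0)
    p_fnd_of = p_i[np.searchsorted(fnds, foundation_of)]
    ss_b = (n_ij[:, None] * (p_ij - p_fnd_of) ** 2).sum(axis=0)
    ss_w = (n_ij[:, None] * p_ij * (1 - p_ij)).sum(axis=0)
    ms_a, ms_b, ms_w = ss_a / df_a, ss_b / df_b, ss_w / df_w

    # expected-mean-square coefficients for the unbalanced nested design
    sum_nij2_over_ni = sum(
        (n_ij[foundation_of == f] ** 2).sum() / n_i[k] for k, f in enumerate(fnds)
    )
    c1 = (N - sum_nij2_over_ni) / df_b
    c2 = (sum_nij2_over_ni - (n_ij ** 2).sum() / N) / df_a
    c3 = (N - (n_i ** 2).sum() / N) / df_a

    sigma_w = ms_w
    sigma_b = (ms_b - ms_w) / c1
    sigma_a = (ms_a - ms_w - c2 * sigma_b) / c3
    return float(sigma_a.sum()), float(sigma_b.sum()), float(sigma_w.sum())


def theta_p(counts: pd.DataFrame, population_cols=("foundation",)) -> ThetaResult:
    """Differentiation between populations (theta-p) at one generation.

    ``population_cols`` define the population label (e.g. foundation, or
    foundation+replicate); each chromosome is a locus and components are
    combined across loci as a ratio of sums.
    """
    counts = karyo_io.validate_karyotype_counts(counts)
    if counts["generation"].nunique() != 1:
        raise ValueError("theta_p expects counts restricted to one generation")
    num = den = 0.0
    per_locus = {}
    n_loci = 0
    for chrom, sub in counts.groupby("chromosome"):
        mat, _ = _locus_matrix(sub, list(population_cols))
        try:
            s_a, s_w = _oneway_components(mat)
        except ValueError:
            warnings.warn(f"chromosome {chrom}: fewer than 2 sampled populations; locus dropped")
            continue
        num += s_a
        den += s_a + s_w
        tot = s_a + s_w
        per_locus[chrom] = s_a / tot if tot > 0 else np.nan
        n_loci += 1
    if n_loci == 0 or den == 0:
        raise ValueError("no usable locus")
    return ThetaResult(
        level="population", theta=num / den,
        sigma2_among_top=num, sigma2_among_within=0.0, sigma2_within=den - num,
        n_loci=n_loci, per_locus=per_locus,
    )


def theta_f_hierarchical(counts: pd.DataFrame) -> ThetaResult:
    """Hierarchical differentiation among foundations (theta-f).

    Three-level decomposition (among foundations / among replicate
    populations within foundations / within populations);
    theta_f = sigma2_foundation / sigma2_total, ratio-of-sums over alleles
    and loci.
    """
    counts = karyo_io.validate_karyotype_counts(counts)
    if counts["generation"].nunique() != 1:
        raise ValueError("theta_f expects counts restricted to one generation")
    s_a_tot = s_b_tot = s_w_tot = 0.0
    per_locus = {}
    n_loci = 0
    for chrom, sub in counts.groupby("chromosome"):
        mat, idx = _locus_matrix(sub, ["foundation", "replicate"])
        fnd = np.array([f for f, _ in idx])
        _, fnd_codes = np.unique(fnd, return_inverse=True)
        s_a, s_b, s_w = _nested_components(mat, fnd_codes)
        s_a_tot += s_a
        s_b_tot += s_b
        s_w_tot += s_w
        tot = s_a + s_b + s_w
        per_locus[chrom] = s_a / tot if tot > 0 else np.nan
        n_loci += 1
    total = s_a_tot + s_b_tot + s_w_tot
    if n_loci == 0 or total == 0:
        raise ValueError("no usable locus")
    return ThetaResult(
        level="foundation-hierarchical", theta=s_a_tot / total,
        sigma2_among_top=s_a_tot, sigma2_among_within=s_b_tot, sigma2_within=s_w_tot,
        n_loci=n_loci, per_locus=per_locus,
    )


def _theta_of(counts: pd.DataFrame, level: str) -> float:
    if level == "pop":
        return theta_p(counts).theta
    if level == "hier":
        return theta_f_hierarchical(counts).theta
    raise ValueError(f"unknown level {level!r}")


def theta_ci(
    counts: pd.DataFrame,
    level: str,
    resamples: int,
    rng: np.random.Generator,
    mode: str = "bootstrap",
    alpha: float = 0.05,
):
    """Bootstrap CI over loci, or permutation p-value for theta > 0.

    bootstrap mode resamples chromosomes (loci) with replacement and returns
    a percentile interval; permutation mode shuffles which population each
    sampled chromosome copy belongs to (sample sizes preserved) and returns
    the proportion of permuted theta values >= the observed one.
    """
    if resamples < 100:
        warnings.warn("fewer than 100 resamples gives an unstable interval")
    counts = karyo_io.validate_karyotype_counts(counts)
    observed = _theta_of(counts, level)
    loci = sorted(counts["chromosome"].unique())
    if mode == "bootstrap":
        if len(loci) < 2:
            raise ValueError("bootstrap over loci needs >= 2 chromosomes; use permutation mode")
        vals = []
        for _ in range(resamples):
            pick = rng.choice(loci, size=len(loci), replace=True)
            parts = []
            for j, chrom in enumerate(pick):
                part = counts[counts["chromosome"] == chrom].copy()
                part["chromosome"] = f"locus{j}"  # keep duplicates distinct
                parts.append(part)
            vals.append(_theta_of(pd.concat(parts, ignore_index=True), level))
        lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
        return float(lo), float(hi)
    if mode == "permutation":
        group_cols = ["foundation", "replicate", "generation"]
        hits = 0
        for _ in range(resamples):
            parts = []
            for chrom, sub in counts.groupby("chromosome"):
                # explode to individual chromosome copies, shuffle group labels
                alleles = np.repeat(sub["arrangement"].to_numpy(), sub["count"].to_numpy())
                groups = np.repeat(
                    np.arange(len(sub)), sub["count"].to_numpy()
                )
                meta = sub[group_cols].to_numpy()
                perm = rng.permutation(alleles)
                df = pd.DataFrame(meta[groups], columns=group_cols)
                df["chromosome"] = chrom
                df["arrangement"] = perm
                df["count"] = 1
                parts.append(
                    df.groupby(group_cols + ["chromosome", "arrangement"], as_index=False)["count"].sum()
                )
            shuffled = pd.concat(parts, ignore_index=True)
            if _theta_of(shuffled, level) >= observed:
                hits += 1
        return float((hits + 1) / (resamples + 1))
    raise ValueError(f"unknown mode {mode!r}")
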