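"""Empirical drift-null test for selection on arrangement frequencies.

For every replicate population and chromosome, the observed start-generation
sample frequencies are taken as the true initial state and B neutral
Wright-Fisher trajectories are simulated to the end generation under the
census-linked Ne ramp.  Optionally each simulated end state is karyotyped
with the observed terminal sample size, so the null distribution includes
the same sampling noise as the observed end frequency.  The empirical
p-value of an arrangement is the proportion of simulated end values at least
as extreme as the observed one, in the observed direction of change;
Benjamini-Yekutieli FDR correction is applied across the tests of a
foundation, and a foundation is called as under selection for an arrangement
when at least two of its three replicates remain significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import karyo_io
from .karyo_io import KARYO_GROUP, POOLED_LABEL
from .wright_fisher import FitnessSpec, build_ne_trajectory, sample_karyotypes, simulate_trajectory

RESULT_COLUMNS = [
    "foundation", "replicate", "chromosome", "arrangement",
    "p_observed_start", "p_observed_end", "direction",
    "p_empirical", "q_value", "significant", "degenerate_null", "foundation_call",
]


@dataclass(frozen=True)
class DriftTestConfig:
    """Tuning knobs of the drift test.

    iterations:
        number B of neutral trajectories per replicate x chromosome.
    alpha:
        FDR level for significance calls.
    start_generation / end_generation:
        per-foundation maps (or single ints) giving the generations whose
        samples anchor the test.
    include_terminal_sampling:
        draw a karyotype sample of the observed terminal n from every
        simulated trajectory, so the null includes terminal sampling noise.
    fdr_family:
        "foundation" pools all arrangement x replicate p-values of one
        foundation into a single FDR family; "replicate" corrects each
        replicate separately across its arrangements.
    pseudocount:
        if True, use (count + 1)/(B + 1) so p-values are strictly positive.
    """

    iterations: int = 9999
    alpha: float = 0.05
    start_generation: int | dict = 2
    end_generation: int | dict = 25
    include_terminal_sampling: bool = True
    fdr_family: str = "foundation"
    pseudocount: bool = False
    ne_fraction_start: float = 0.10
    ne_fraction_end: float = 0.30

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.fdr_family not in ("foundation", "replicate"):
            raise ValueError(f"unknown fdr_family {self.fdr_family!r}")

    def generation_for(self, which: str, foundation: str) -> int:
        val = self.start_generation if which == "start" else self.end_generation
        if isinstance(val, dict):
            return int(val[foundation])
        return int(val)


def empirical_pvalue(observed_end: float, simulated_end, direction: str,
                     pseudocount: bool = False) -> float:
    """Proportion of simulated end values at least as extreme as observed.

    "increase": share of simulations >= observed; "decrease": share <=
    observed; ties count as extreme.  "none" (no observed change) returns 1.
    """
    sims = np.asarray(simulated_end, dtype=float)
    if sims.size == 0:
        raise ValueError("empty simulation set")
    if direction == "increase":
        count = int(np.sum(sims >= observed_end))
    elif direction == "decrease":
        count = int(np.sum(sims <= observed_end))
    elif direction == "none":
        return 1.0
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if pseudocount:
        return (count + 1) / (sims.size + 1)
    return count / sims.size


def adjust_fdr_by(pvalues, alpha: float = 0.05):
    """Benjamini-Yekutieli step-up FDR under arbitrary dependence.

    With c(m) = sum_{i<=m} 1/i, rejects the largest k with
    p_(k) <= k * alpha / (m * c(m)); returns (q_values, reject) aligned with
    the input order, q-values capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_by")
    return q, reject


def replicate_consensus(significant_flags) -> bool:
    """Foundation-level call: at least two replicates significant after FDR."""
    flags = list(significant_flags)
    if len(flags) < 2:
        import warnings

        warnings.warn("fewer than 2 replicates available; foundation call is False")
        return False
    return sum(bool(f) for f in flags) >= 2


def _start_group(counts: pd.DataFrame, foundation: str, replicate: str,
                 chromosome: str, generation: int) -> pd.DataFrame:
    """Start-generation counts for a replicate, falling back to the pooled
    pre-replication sample when the replicate was not yet split."""
    sel = counts[
        (counts["foundation"] == foundation)
        & (counts["generation"] == generation)
        & (counts["chromosome"] == chromosome)
    ]
    own = sel[sel["replicate"] == replicate]
    if len(own):
        return own
    return sel[sel["replicate"] == POOLED_LABEL]


def run_drift_test(
    counts: pd.DataFrame,
    census: dict[int, int],
    config: DriftTestConfig,
    rng: np.random.Generator,
    arrangements=None,
) -> pd.DataFrame:
    """Run the drift-null test for every replicate x chromosome x arrangement.

    Parameters
    ----------
    counts:
        validated karyotype count table containing the start- and
        end-generation samples.
    census:
        {generation: census size}; gaps filled by carry-forward.
    arrangements:
        optional collection of (chromosome, arrangement) pairs to test
        (normally the output of :func:`karyo_io.common_arrangements`); by
        default every arrangement present at both endpoints is tested.

    Returns one row per tested arrangement with empirical p, BY q-value,
    significance at ``config.alpha`` and the foundation consensus call.
    """
    counts = karyo_io.validate_karyotype_counts(counts)
    freqs = karyo_io.counts_to_frequencies(counts)
    rows = []
    for foundation in sorted(counts["foundation"].unique()):
        t0 = config.generation_for("start", foundation)
        tend = config.generation_for("end", foundation)
        ne = build_ne_trajectory(
            census, t0, tend,
            f_start=config.ne_fraction_start, f_end=config.ne_fraction_end,
        )
        fnd_end = counts[
            (counts["foundation"] == foundation) & (counts["generation"] == tend)
        ]
        if fnd_end.empty:
            raise ValueError(f"no end-generation ({tend}) data for foundation {foundation}")
        replicates = sorted(r for r in fnd_end["replicate"].unique() if r != POOLED_LABEL)
        for replicate in replicates:
            for chromosome in sorted(fnd_end["chromosome"].unique()):
                start = _start_group(counts, foundation, replicate, chromosome, t0)
                end = fnd_end[
                    (fnd_end["replicate"] == replicate)
                    & (fnd_end["chromosome"] == chromosome)
                ]
                if start.empty or end.empty:
                    raise ValueError(
                        f"missing start or end sample for {foundation}/{replicate}"
                        f" chromosome {chromosome}"
                    )
                # joint frequency vector over the union of arrangements
                labels = sorted(set(start["arrangement"]) | set(end["arrangement"]))
                sc = start.set_index("arrangement")["count"].reindex(labels, fill_value=0)
                ec = end.set_index("arrangement")["count"].reindex(labels, fill_value=0)
                p_start = sc.to_numpy(float) / sc.sum()
                n_end = int(ec.sum())
                p_end = ec.to_numpy(float) / n_end
                traj = simulate_trajectory(
                    p_start, ne, FitnessSpec.neutral(len(labels)),
                    rng=rng, n_replicates=config.iterations,
                )
                sim_end = traj.final  # (B, k)
                if config.include_terminal_sampling:
                    sim_end = sample_karyotypes(sim_end, n_end, rng) / n_end
                tested = labels if arrangements is None else [
                    a for a in labels if (chromosome, a) in set(arrangements)
                ]
                for arr in tested:
                    i = labels.index(arr)
                    delta = p_end[i] - p_start[i]
                    if delta > 0:
                        direction = "increase"
                    elif delta < 0:
                        direction = "decrease"
                    else:
                        direction = "none"
                    pval = empirical_pvalue(
                        p_end[i], sim_end[:, i], direction,
                        pseudocount=config.pseudocount,
                    )
                    rows.append({
                        "foundation": foundation,
                        "replicate": replicate,
                        "chromosome": chromosome,
                        "arrangement": arr,
                        "p_observed_start": p_start[i],
                        "p_observed_end": p_end[i],
                        "direction": direction,
                        "p_empirical": pval,
                        "degenerate_null": bool(p_start[i] == 0.0 and direction == "increase"),
                    })
    results = pd.DataFrame(rows)
    if results.empty:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    results = attach_fdr(results, config)
    return attach_consensus(results)[RESULT_COLUMNS]


def attach_fdr(results: pd.DataFrame, config: DriftTestConfig) -> pd.DataFrame:
    """Add BY q-values and significance flags, FDR family per config."""
    results = results.copy()
    family_cols = ["foundation"] if config.fdr_family == "foundation" else ["foundation", "replicate"]
    results["q_value"] = np.nan
    results["significant"] = False
    for _, idx in results.groupby(family_cols).groups.items():
        q, rej = adjust_fdr_by(results.loc[idx, "p_empirical"], alpha=config.alpha)
        results.loc[idx, "q_value"] = q
        results.loc[idx, "significant"] = rej
    return results


def attach_consensus(results: pd.DataFrame) -> pd.DataFrame:
    """Add the foundation-level call (>= 2 significant replicates)."""
    results = results.copy()
    call = (
        results.groupby(["foundation", "chromosome", "arrangement"])["significant"]
        .apply(lambda flags: replicate_consensus(flags) if len(flags) >= 2 else False)
    )
    results["foundation_call"] = [
        call.loc[(f, c, a)]
        for f, c, a in zip(results["foundation"], results["chromosome"], results["arrangement"])
    ]
    return results
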