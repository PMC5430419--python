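import numpy as np
import pandas as pd
import pytest

from inversion_ee.differentiation import (
    theta_ci,
    theta_f_hierarchical,
    theta_p,
)


def _counts(records):
    """records: (foundation, replicate, generation, chromosome, {arr: count})"""
    rows = []
    for fnd, rep, gen, chrom, d in records:
        for arr, c in d.items():
            rows.append({"foundation": fnd, "replicate": rep, "generation": gen,
                         "chromosome": chrom, "arrangement": arr, "count": c})
    return pd.DataFrame(rows)


def oneway_oracle(pop_alleles):
    """Brute-force WC haploid variance components from individual indicator
    vectors: explicit ANOVA sums of squares per allele, then the moment
    equations.  ``pop_alleles``: list of allele-label arrays, one per pop."""
    alleles = sorted(set(np.concatenate(pop_alleles)))
    n_i = np.array([len(a) for a in pop_alleles], float)
    N, r = n_i.sum(), len(pop_alleles)
    nc = (N - (n_i**2).sum() / N) / (r - 1)
    s_a = s_w = 0.0
    for al in alleles:
        ind = [np.asarray(a) == al for a in pop_alleles]
        means = np.array([v.mean() for v in ind])
        grand = np.concatenate(ind).mean()
        msp = float((n_i * (means - grand) ** 2).sum()) / (r - 1)
        ssw = sum(((v - v.mean()) ** 2).sum() for v in ind)
        msg = ssw / (N - r)
        s_a += (msp - msg) / nc
        s_w += msg
    return s_a, s_w


class TestThetaP:
    def test_fixed_differences_give_one(self):
        counts = _counts([
            ("A", "R1", 1, "O", {"O_ST": 50}),
            ("B", "R1", 1, "O", {"O_3+4": 50}),
        ])
        assert theta_p(counts).theta == pytest.approx(1.0)

    def test_identical_samples_nonpositive(self):
        counts = _counts([
            ("A", "R1", 1, "O", {"O_ST": 30, "O_3+4": 70}),
            ("B", "R1", 1, "O", {"O_ST": 30, "O_3+4": 70}),
        ])
        assert theta_p(counts).theta <= 0.0

    def test_matches_indicator_variable_oracle(self, rng):
        pops = []
        records = []
        for i, (c1, c2, c3) in enumerate([(40, 30, 20), (10, 55, 35), (60, 10, 5)]):
            d = {"O_ST": c1, "O_3+4": c2, "O_3+4+7": c3}
            records.append((f"P{i}", "R1", 1, "O", d))
            pops.append(np.repeat(list(d), list(d.values())))
        res = theta_p(_counts(records))
        s_a, s_w = oneway_oracle(pops)
        assert res.sigma2_among_top == pytest.approx(s_a, abs=1e-9)
        assert res.sigma2_within == pytest.approx(s_w, abs=1e-9)
        assert res.theta == pytest.approx(s_a / (s_a + s_w), abs=1e-9)

    def test_biallelic_reduction(self):
        """k=2 multiallelic estimate equals the classical haploid biallelic
        formula theta = (MSP - MSG) / (MSP + (nc - 1) MSG)."""
        n = np.array([80.0, 120.0])
        x = np.array([30.0, 80.0])  # focal-allele counts
        counts = _counts([
            ("A", "R1", 1, "O", {"a": 30, "b": 50}),
            ("B", "R1", 1, "O", {"a": 80, "b": 40}),
        ])
        p = x / n
        N = n.sum()
        pbar = x.sum() / N
        nc = (N - (n**2).sum() / N) / 1
        msp = float((n * (p - pbar) ** 2).sum())
        msg = float((n * p * (1 - p)).sum()) / (N - 2)
        expected = (msp - msg) / (msp + (nc - 1) * msg)
        assert theta_p(counts).theta == pytest.approx(expected, abs=1e-12)

    def test_label_order_invariance(self):
        a = _counts([
            ("A", "R1", 1, "O", {"x": 20, "y": 30, "z": 50}),
            ("B", "R1", 1, "O", {"x": 40, "y": 40, "z": 20}),
        ])
        b = _counts([
            ("A", "R1", 1, "O", {"z": 50, "x": 20, "y": 30}),
            ("B", "R1", 1, "O", {"y": 40, "z": 20, "x": 40}),
        ])
        assert theta_p(a).theta == pytest.approx(theta_p(b).theta, abs=1e-12)

    def test_count_doubling_nearly_invariant(self):
        base = _counts([
            ("A", "R1", 1, "O", {"x": 60, "y": 40}),
            ("B", "R1", 1, "O", {"x": 30, "y": 70}),
        ])
        doubled = base.assign(count=base["count"] * 2)
        assert abs(theta_p(base).theta - theta_p(doubled).theta) < 0.01

    def test_multiple_generations_rejected(self, toy_counts):
        with pytest.raises(ValueError, match="one generation"):
            theta_p(toy_counts)


def nested_oracle(foundations):
    """Brute-force nested ANOVA on allele indicators.

    ``foundations``: list of foundations, each a list of replicate
    allele-label arrays.  Returns (sigma_a, sigma_b, sigma_w) summed over
    alleles, solving the unbalanced expected-mean-square equations.
    """
    all_alleles = sorted({al for f in foundations for r in f for al in r})
    n_ij, fidx = [], []
    for i, f in enumerate(foundations):
        for r in f:
            n_ij.append(len(r))
            fidx.append(i)
    n_ij = np.array(n_ij, float)
    fidx = np.array(fidx)
    a = len(foundations)
    b = len(n_ij)
    N = n_ij.sum()
    n_i = np.array([n_ij[fidx == i].sum() for i in range(a)])
    df_a, df_b, df_w = a - 1, b - a, N - b
    sum_nij2_over_ni = sum((n_ij[fidx == i] ** 2).sum() / n_i[i] for i in range(a))
    c1 = (N - sum_nij2_over_ni) / df_b
    c2 = (sum_nij2_over_ni - (n_ij**2).sum() / N) / df_a
    c3 = (N - (n_i**2).sum() / N) / df_a
    s_a = s_b = s_w = 0.0
    for al in all_alleles:
        reps = [np.asarray(r) == al for f in foundations for r in f]
        grand = np.concatenate(reps).mean()
        rep_means = np.array([r.mean() for r in reps])
        fnd_means = np.array([
            np.concatenate([reps[j] for j in range(b) if fidx[j] == i]).mean()
            for i in range(a)
        ])
        ss_a = float((n_i * (fnd_means - grand) ** 2).sum())
        ss_b = float((n_ij * (rep_means - fnd_means[fidx]) ** 2).sum())
        ss_w = sum(((r - r.mean()) ** 2).sum() for r in reps)
        ms_a, ms_b, ms_w = ss_a / df_a, ss_b / df_b, ss_w / df_w
        sw = ms_w
        sb = (ms_b - ms_w) / c1
        sa = (ms_a - ms_w - c2 * sb) / c3
        s_a, s_b, s_w = s_a + sa, s_b + sb, s_w + sw
    return s_a, s_b, s_w


class TestThetaFHierarchical:
    def _two_by_two(self, table):
        records = []
        founds = []
        for fnd, reps in table.items():
            frecs = []
            for rep, d in reps.items():
                records.append((fnd, rep, 6, "O", d))
                frecs.append(np.repeat(list(d), list(d.values())))
            founds.append(frecs)
        return _counts(records), founds

    def test_identical_everywhere_near_zero(self):
        counts, _ = self._two_by_two({
            "A": {"R1": {"x": 30, "y": 70}, "R2": {"x": 30, "y": 70}},
            "B": {"R1": {"x": 30, "y": 70}, "R2": {"x": 30, "y": 70}},
        })
        assert theta_f_hierarchical(counts).theta <= 0.05

    def test_fixed_between_foundations_gives_one(self):
        counts, _ = self._two_by_two({
            "A": {"R1": {"x": 50}, "R2": {"x": 50}},
            "B": {"R1": {"y": 50}, "R2": {"y": 50}},
        })
        assert theta_f_hierarchical(counts).theta == pytest.approx(1.0)

    def test_matches_nested_anova_oracle(self):
        counts, founds = self._two_by_two({
            "A": {"R1": {"x": 35, "y": 45}, "R2": {"x": 20, "y": 75}},
            "B": {"R1": {"x": 60, "y": 21}, "R2": {"x": 70, "y": 30}},
        })
        res = theta_f_hierarchical(counts)
        s_a, s_b, s_w = nested_oracle(founds)
        assert res.sigma2_among_top == pytest.approx(s_a, abs=1e-9)
        assert res.sigma2_among_within == pytest.approx(s_b, abs=1e-9)
        assert res.sigma2_within == pytest.approx(s_w, abs=1e-9)
        assert res.theta == pytest.approx(s_a / (s_a + s_b + s_w), abs=1e-9)

    def test_single_replicate_rejected(self):
        counts, _ = self._two_by_two({
            "A": {"R1": {"x": 30, "y": 70}},
            "B": {"R1": {"x": 50, "y": 50}, "R2": {"x": 45, "y": 55}},
        })
        with pytest.raises(ValueError, match="2 replicate"):
            theta_f_hierarchical(counts)


class TestThetaCI:
    def _multi_locus(self):
        return _counts([
            ("A", "R1", 1, "O", {"x": 40, "y": 60}),
            ("B", "R1", 1, "O", {"x": 70, "y": 30}),
            ("A", "R1", 1, "E", {"u": 20, "v": 80}),
            ("B", "R1", 1, "E", {"u": 50, "v": 50}),
        ])

    def test_bootstrap_reproducible(self):
        counts = self._multi_locus()
        cis = [
            theta_ci(counts, "pop", 200, np.random.default_rng(3))
            for _ in range(2)
        ]
        assert cis[0] == cis[1]

    def test_single_locus_bootstrap_directs_to_permutation(self):
        counts = self._multi_locus()
        one = counts[counts["chromosome"] == "O"]
        with pytest.raises(ValueError, match="permutation"):
            theta_ci(one, "pop", 200, np.random.default_rng(0))

    def test_permutation_pvalue_in_range(self):
        counts = self._multi_locus()
        p = theta_ci(counts, "pop", 99, np.random.default_rng(1), mode="permutation")
        assert 0 < p <= 1

    def test_permutation_detects_strong_differentiation(self):
        counts = _counts([
            ("A", "R1", 1, "O", {"x": 100}),
            ("B", "R1", 1, "O", {"y": 100}),
            ("A", "R1", 1, "E", {"u": 100}),
            ("B", "R1", 1, "E", {"v": 100}),
        ])
        p = theta_ci(counts, "pop", 99, np.random.default_rng(2), mode="permutation")
        assert p <= 0.05

    def test_few_resamples_warn(self):
        with pytest.warns(UserWarning):
            theta_ci(self._multi_locus(), "pop", 50, np.random.default_rng(0))
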