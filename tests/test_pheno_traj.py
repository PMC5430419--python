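import numpy as np
import pandas as pd
import pytest

from inversion_ee.pheno_traj import (
    EarlyDifferentiation,
    TrajectorySlope,
    early_differentiation,
    rate_regression,
    standardize_to_control,
    trajectory_slope,
)


def _assay(records):
    """records: (foundation, replicate, generation, trait, values)"""
    rows = []
    for fnd, rep, gen, trait, values in records:
        for i, v in enumerate(values):
            rows.append({"foundation": fnd, "replicate": rep, "generation": gen,
                         "trait": trait, "individual_id": f"{fnd}{rep}{gen}{i}",
                         "value": v})
    return pd.DataFrame(rows)


class TestStandardize:
    def test_difference_and_relative_modes(self):
        df = _assay([
            ("F1", "R1", 6, "F1-7", [50.0, 50.0]),
            ("CONTROL", "TA", 6, "F1-7", [40.0, 40.0]),
        ])
        diff = standardize_to_control(df, "difference")
        rel = standardize_to_control(df, "relative")
        assert diff["value"].iloc[0] == pytest.approx(10.0)
        assert rel["value"].iloc[0] == pytest.approx(0.25)

    def test_equal_means_give_zero(self):
        df = _assay([
            ("F1", "R1", 6, "RF", [60.0, 62.0]),
            ("CONTROL", "TA", 6, "RF", [61.0, 61.0]),
        ])
        for mode in ("difference", "relative"):
            assert standardize_to_control(df, mode)["value"].iloc[0] == pytest.approx(0.0)

    def test_group_mean_arithmetic_multi_replicate(self):
        df = _assay([
            ("F1", "R1", 6, "RF", [10.0, 20.0]),
            ("F1", "R2", 6, "RF", [30.0, 50.0]),
            ("CONTROL", "TA", 6, "RF", [5.0, 15.0]),
        ])
        out = standardize_to_control(df, "difference").set_index("replicate")["value"]
        assert out.loc["R1"] == pytest.approx(15.0 - 10.0)
        assert out.loc["R2"] == pytest.approx(40.0 - 10.0)

    def test_zero_control_mean_rejected_in_relative(self):
        df = _assay([
            ("F1", "R1", 6, "RF", [1.0]),
            ("CONTROL", "TA", 6, "RF", [1.0, -1.0]),
        ])
        with pytest.raises(ValueError, match="zero"):
            standardize_to_control(df, "relative")

    def test_additive_shift_invariance_in_difference_mode(self):
        df = _assay([
            ("F1", "R1", 6, "RF", [10.0, 20.0]),
            ("F1", "R1", 11, "RF", [12.0, 24.0]),
            ("CONTROL", "TA", 6, "RF", [5.0]),
            ("CONTROL", "TA", 11, "RF", [6.0]),
        ])
        shifted = df.assign(value=df["value"] + 37.0)
        a = standardize_to_control(df, "difference")["value"]
        b = standardize_to_control(shifted, "difference")["value"]
        assert a.to_numpy() == pytest.approx(b.to_numpy())


class TestTrajectorySlope:
    def _std(self, points):
        return pd.DataFrame([
            {"foundation": "F1", "replicate": "R1", "trait": "RF",
             "generation": g, "value": v} for g, v in points
        ])

    def test_two_point_slope(self):
        [rec] = trajectory_slope(self._std([(0, 0.0), (10, 5.0)]))
        assert rec.slope == pytest.approx(0.5)

    def test_flat_series(self):
        [rec] = trajectory_slope(self._std([(0, 1.0), (5, 1.0), (9, 1.0)]))
        assert rec.slope == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equation_oracle(self, rng):
        pts = [(g, rng.normal()) for g in range(7)]
        [rec] = trajectory_slope(self._std(pts))
        x = np.array([p[0] for p in pts], float)
        y = np.array([p[1] for p in pts], float)
        expected = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        assert rec.slope == pytest.approx(expected, abs=1e-12)

    def test_generation_shift_invariance(self, rng):
        pts = [(g, rng.normal()) for g in range(5)]
        [a] = trajectory_slope(self._std(pts))
        [b] = trajectory_slope(self._std([(g + 13, v) for g, v in pts]))
        assert a.slope == pytest.approx(b.slope, abs=1e-12)

    def test_generation_cap(self):
        std = self._std([(0, 0.0), (10, 5.0), (20, -100.0)])
        [rec] = trajectory_slope(std, generation_cap={"RF": 10})
        assert rec.slope == pytest.approx(0.5)
        assert rec.n_generations == 2

    def test_single_point_rejected(self):
        with pytest.raises(ValueError, match="2 generations"):
            trajectory_slope(self._std([(0, 1.0)]))


class TestEarlyDifferentiation:
    def test_relative_deviation_at_first_generation(self):
        df = _assay([
            ("F1", "R1", 6, "RF", [30.0]),
            ("CONTROL", "TA", 6, "RF", [40.0]),
        ])
        [rec] = early_differentiation(df, 6)
        assert rec.d0 == pytest.approx(-0.25)

    def test_per_foundation_first_generation(self):
        df = _assay([
            ("F10", "R1", 6, "RF", [50.0]),
            ("F13", "R1", 5, "RF", [30.0]),
            ("CONTROL", "TA", 6, "RF", [40.0]),
            ("CONTROL", "TA", 5, "RF", [40.0]),
        ])
        recs = {r.foundation: r.d0 for r in early_differentiation(df, {"F10": 6, "F13": 5})}
        assert recs["F10"] == pytest.approx(0.25)
        assert recs["F13"] == pytest.approx(-0.25)

    def test_missing_first_generation_rejected(self):
        df = _assay([
            ("F1", "R1", 6, "RF", [30.0]),
            ("CONTROL", "TA", 6, "RF", [40.0]),
        ])
        with pytest.raises(ValueError, match="no assay"):
            early_differentiation(df, 5)


def _matched(slopes_by_key, d0_by_key):
    slopes = [TrajectorySlope(f, r, t, b, 0.0, 5) for (f, r, t), b in slopes_by_key.items()]
    early = [EarlyDifferentiation(f, r, t, d) for (f, r, t), d in d0_by_key.items()]
    return slopes, early


class TestRateRegression:
    def test_exact_proportionality_recovered(self):
        """b = -0.1 * d0 in every group: pooled slope -0.1, homogeneity F ~ 0."""
        d0s, bs = {}, {}
        for g, fnd in enumerate(["A", "B"]):
            for i in range(4):
                key = (fnd, f"R{i}", "RF")
                d0 = 0.2 + 0.1 * i + 0.05 * g
                d0s[key] = d0
                bs[key] = -0.1 * d0
        slopes, early = _matched(bs, d0s)
        res = rate_regression(slopes, early)
        assert res.pooled_slope == pytest.approx(-0.1, abs=1e-12)
        assert res.homogeneity_F == pytest.approx(0.0, abs=1e-9)
        assert res.group_slopes["A"] == pytest.approx(-0.1, abs=1e-12)

    def test_null_slope_within_three_se(self, rng):
        """With b independent of d0 the pooled slope is ~0 on average."""
        estimates = []
        for _ in range(50):
            d0s, bs = {}, {}
            for i in range(12):
                key = ("A", f"R{i}", "RF")
                d0s[key] = rng.normal()
                bs[key] = rng.normal()
            slopes, early = _matched(bs, d0s)
            estimates.append(rate_regression(slopes, early).pooled_slope)
        est = np.array(estimates)
        assert abs(est.mean()) < 3 * est.std() / np.sqrt(est.size)

    def test_matches_design_matrix_oracle(self, rng):
        d0s, bs = {}, {}
        for fnd in ("A", "B", "C"):
            for i in range(5):
                key = (fnd, f"R{i}", "RF")
                d0s[key] = rng.normal()
                bs[key] = rng.normal()
        slopes, early = _matched(bs, d0s)
        res = rate_regression(slopes, early)
        y = np.array([s.slope for s in slopes])
        x = np.array([e.d0 for e in early])
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert res.pooled_slope == pytest.approx(beta[1], abs=1e-9)
        # homogeneity F from explicit restricted/full projections
        G = pd.get_dummies([s.foundation for s in slopes]).to_numpy(float)
        X0 = np.column_stack([G, x])
        X1 = np.column_stack([G, G * x[:, None]])
        rss = lambda M: float(np.sum((y - M @ np.linalg.lstsq(M, y, rcond=None)[0]) ** 2))
        F = ((rss(X0) - rss(X1)) / 2) / (rss(X1) / (len(y) - X1.shape[1]))
        assert res.homogeneity_F == pytest.approx(F, abs=1e-9)

    def test_degenerate_d0_rejected(self):
        slopes, early = _matched(
            {("A", "R1", "RF"): 0.1, ("A", "R2", "RF"): 0.2},
            {("A", "R1", "RF"): 0.5, ("A", "R2", "RF"): 0.5},
        )
        with pytest.raises(ValueError, match="degenerate"):
            rate_regression(slopes, early)

    def test_unmatched_records_rejected(self):
        slopes, _ = _matched({("A", "R1", "RF"): 0.1}, {})
        _, early = _matched({}, {("B", "R9", "RF"): 0.3})
        with pytest.raises(ValueError, match="matched"):
            rate_regression(slopes, early)
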