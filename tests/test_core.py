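import numpy as np
import pytest
from scipy import integrate, stats

from zodet.core import (
    DetectionParams,
    adjust_p,
    call_outliers,
    control_stats,
    fold_change,
    normality_screen,
    storey_qvalues,
    z_to_p,
    zscore,
)
from zodet.io import ValidationError
from zodet.simulate import SimulationConfig, simulate_dataset

from conftest import make_design, make_matrix


def normal_tail_2sided(z):
    """Independent oracle: numerical integration of the N(0,1) density."""
    density = lambda t: np.exp(-t * t / 2) / np.sqrt(2 * np.pi)
    upper, _ = integrate.quad(density, abs(z), np.inf)
    return 2 * upper


class TestControlStats:
    def test_two_point_mean_and_sample_sd(self):
        m = make_matrix([[1.0, 3.0]], samples=["c0", "c1"])
        st = control_stats(m, ["c0", "c1"])
        assert st.mu.iloc[0] == 2.0
        assert st.sigma.iloc[0] == pytest.approx(np.sqrt(2.0))
        assert st.n_controls == 2

    def test_exclude_nonmember_is_noop(self, rng):
        m = make_matrix(rng.standard_normal((5, 4)))
        a = control_stats(m, ["s0", "s1", "s2"])
        b = control_stats(m, ["s0", "s1", "s2"], exclude="s3")
        assert np.array_equal(a.mu, b.mu) and np.array_equal(a.sigma, b.sigma)

    def test_matches_bruteforce_summation(self, rng):
        vals = rng.standard_normal((50, 10))
        m = make_matrix(vals)
        st = control_stats(m, m.sample_ids)
        for i in range(50):
            mean = sum(vals[i]) / 10
            var = sum((x - mean) ** 2 for x in vals[i]) / 9
            assert st.mu.iloc[i] == pytest.approx(mean, abs=1e-12)
            assert st.sigma.iloc[i] == pytest.approx(var ** 0.5, rel=1e-12)

    def test_fewer_than_two_controls_rejected(self):
        m = make_matrix([[1.0, 2.0]], samples=["c0", "c1"])
        with pytest.raises(ValidationError, match="at least 2"):
            control_stats(m, ["c0", "c1"], exclude="c0")


class TestZscore:
    @pytest.mark.parametrize("e, mu, sigma, expected", [
        (5.0, 5.0, 2.0, 0.0),          # at the centre
        (9.0, 5.0, 2.0, 2.0),          # mu + 2 sigma
        (-1.5, 0.0, 1.0, -1.5),        # standard-normal controls
        (3.0, 3.0, 0.0, 0.0),          # degenerate sigma, no deviation
    ])
    def test_definition(self, e, mu, sigma, expected):
        assert zscore(e, mu, sigma) == expected

    def test_sigma_zero_deviation_is_signed_infinity(self):
        assert zscore(4.0, 3.0, 0.0) == np.inf
        assert zscore(2.0, 3.0, 0.0) == -np.inf
        assert z_to_p(np.inf) == 0.0

    def test_sign_matches_fold_change(self, rng):
        e = rng.standard_normal(100)
        mu = rng.standard_normal(100)
        sigma = rng.uniform(0.1, 2.0, 100)
        assert np.array_equal(np.sign(zscore(e, mu, sigma)),
                              np.sign(fold_change(e, mu)))


class TestPValues:
    @pytest.mark.parametrize("z, expected", [(0.0, 1.0), (1.959964, 0.05),
                                             (-4.891638, 1e-6)])
    def test_two_sided_tail_against_integration_oracle(self, z, expected):
        oracle = normal_tail_2sided(z)
        p = z_to_p(z)
        assert p == pytest.approx(oracle, rel=1e-9)
        assert p == pytest.approx(expected, rel=5e-4)  # 4 significant figures

    def test_bonferroni_caps_at_one(self):
        assert adjust_p([0.001], "bonferroni", m=20_000)[0] == 1.0

    def test_bonferroni_equals_direct_formula_and_dominates_raw(self, rng):
        p = rng.uniform(size=300)
        adj = adjust_p(p, "bonferroni")
        assert np.array_equal(adj, np.minimum(1.0, p * 300))
        assert (adj >= p).all()

    def test_qvalue_null_saturation(self):
        assert np.array_equal(storey_qvalues(np.ones(50)), np.ones(50))

    def test_qvalue_monotone_in_sorted_order(self, rng):
        p = rng.uniform(size=500)
        q = storey_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
        assert ((q >= 0) & (q <= 1)).all()

    def test_qvalue_no_larger_than_bonferroni(self, rng):
        p = np.concatenate([rng.uniform(0, 1e-4, 20), rng.uniform(size=480)])
        q = storey_qvalues(p)
        bonf = np.minimum(1.0, p * p.size)
        assert (q <= bonf + 1e-12).all()

    def test_unknown_method_lists_options(self):
        with pytest.raises(ValidationError, match="raw, bonferroni, qvalue"):
            adjust_p([0.5], "holm")

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValidationError):
            adjust_p([1.5], "raw")


class TestFoldChange:
    def test_log2_difference(self):
        assert fold_change(7.0, 7.0) == 0.0
        assert fold_change(9.0, 7.0) == 2.0  # 4-fold on the linear scale


class TestCallOutliers:
    def _cohort(self, test_value, rng, n_probes=10):
        vals = rng.standard_normal((n_probes, 21))
        vals[0, 20] = test_value  # probe p0 of the single experimental sample
        m = make_matrix(vals, samples=[f"c{i}" for i in range(20)] + ["e0"])
        d = make_design([f"c{i}" for i in range(20)], ["e0"])
        return m, d

    def test_far_outlier_called_up(self, rng):
        m, d = self._cohort(8.0, rng)
        calls, summary = call_outliers(
            m, d, DetectionParams(p_threshold=0.01, fc_threshold=1.0))
        hit = [c for c in calls if c.probe_id == "p0"]
        assert len(hit) == 1
        assert hit[0].direction == "up" and hit[0].sample_id == "e0"
        assert summary[0].probe_id == "p0" and summary[0].count == 1

    def test_both_gates_required(self, rng):
        m, d = self._cohort(8.0, rng)
        calls, _ = call_outliers(
            m, d, DetectionParams(p_threshold=0.01, fc_threshold=9.0))
        assert [c for c in calls if c.probe_id == "p0"] == []

    def test_target_not_on_test_side_rejected(self, small_cohort):
        matrix, design = small_cohort
        with pytest.raises(ValidationError, match="test side"):
            call_outliers(matrix, design, DetectionParams(), target="c0")

    def test_target_restricts_to_one_sample(self, small_cohort):
        matrix, design = small_cohort
        calls, _ = call_outliers(
            matrix, design, DetectionParams(p_threshold=0.5, fc_threshold=0.0),
            target="e1")
        assert {c.sample_id for c in calls} <= {"e1"}

    def test_leave_one_out_honesty(self, rng):
        # a control equal to the mean of the others must score z = 0 everywhere
        vals = rng.standard_normal((20, 10))
        vals[:, 0] = vals[:, 1:].mean(axis=1)
        ctl = [f"c{i}" for i in range(10)]
        m = make_matrix(vals, samples=ctl)
        d = make_design(ctl, [])
        st = control_stats(m, ctl, exclude="c0")
        z = zscore(m.values["c0"].to_numpy(), st.mu.to_numpy(),
                   st.sigma.to_numpy())
        assert np.allclose(z, 0.0, atol=1e-10)
        calls, _ = call_outliers(
            m, d, DetectionParams(p_threshold=0.999999, fc_threshold=0.0,
                                  mode="control_vs_control"), target="c0")
        assert calls == []

    @pytest.mark.parametrize("mode, n_tested", [
        ("test_vs_control", 5), ("test_vs_all", 5), ("test_vs_test", 5),
        ("control_vs_control", 20), ("control_vs_all", 20),
    ])
    def test_modes_pick_the_right_test_side(self, small_cohort, mode, n_tested):
        matrix, design = small_cohort
        calls, _ = call_outliers(
            matrix, design,
            DetectionParams(p_threshold=1.0, fc_threshold=0.0, mode=mode))
        assert len({c.sample_id for c in calls}) == n_tested

    def test_spiked_cells_recovered_against_truth(self):
        # oracle: direct threshold check on the simulation's truth table
        cfg = SimulationConfig(n_genes=500, n_controls=50, n_experimental=50,
                               n_outlier_genes=10, seed=7)
        matrix, design, truth = simulate_dataset(cfg)
        calls, _ = call_outliers(
            matrix, design,
            DetectionParams(p_threshold=0.01, fc_threshold=0.5))
        called = {(c.probe_id, c.sample_id, c.direction) for c in calls}
        strong = truth.table[truth.table.p_target < 1e-4]
        for row in strong.itertuples():
            assert (row.probe_id, row.sample_id, row.direction) in called


class TestNormalityScreen:
    def test_gaussian_probes_pass_at_nominal_rate(self, rng):
        # Monte-Carlo calibration of the Lilliefors null: 1,000 probes of
        # n = 100 i.i.d. normal draws, screened at alpha 0.05 uncorrected
        m = make_matrix(rng.standard_normal((1000, 100)))
        report = normality_screen(m, alpha=0.05, correction="raw")
        assert report["normal"].mean() >= 0.94

    def test_two_point_mass_flagged_non_normal(self):
        row = np.r_[np.zeros(50), np.ones(50)]
        m = make_matrix(np.tile(row, (2, 1)) + [[0.0], [1.0]])
        report = normality_screen(m, alpha=0.05, correction="bonferroni")
        assert not report["normal"].any()

    def test_constant_probe_degenerate(self, rng):
        vals = np.vstack([np.full(30, 2.5), rng.standard_normal(30)])
        report = normality_screen(make_matrix(vals), alpha=0.05)
        assert report.loc["p0", "p_value"] == 0.0
        assert not report.loc["p0", "normal"]

    def test_too_few_samples_rejected(self, rng):
        m = make_matrix(rng.standard_normal((5, 3)))
        with pytest.raises(ValidationError, match="4 samples"):
            normality_screen(m)
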