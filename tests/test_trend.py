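"""Williams trend screen: PAVA, statistic, permutation null, screen behavior."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pfosber.matrix import ExpressionMatrix
from pfosber.synthetic import SyntheticDesign, generate_expression_matrix
from pfosber.trend import (
    pava_monotone_means,
    permutation_pvalue,
    screen_probes,
    williams_statistic,
)

DOSES = np.repeat([0.0, 10.0, 100.0, 1000.0], 4)


class TestPava:
    def test_hand_example(self):
        out = pava_monotone_means([0.0, 1.0, 0.4, 0.8], [1, 1, 1, 1], "increasing")
        np.testing.assert_allclose(out, [0.0, 0.7, 0.7, 0.8])

    def test_monotone_input_is_fixed_point(self):
        means = [0.0, 0.5, 1.2, 2.0]
        np.testing.assert_allclose(pava_monotone_means(means, [4] * 4, "increasing"), means)

    def test_single_group(self):
        np.testing.assert_allclose(pava_monotone_means([3.2], [4], "decreasing"), [3.2])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pava_monotone_means([], [], "increasing")

    @given(
        means=st.lists(st.floats(-10, 10), min_size=1, max_size=8),
        ns=st.integers(1, 5),
        direction=st.sampled_from(["increasing", "decreasing"]),
    )
    @settings(max_examples=100, derandomize=True)
    def test_monotone_idempotent_mean_preserving(self, means, ns, direction):
        w = [ns] * len(means)
        out = pava_monotone_means(means, w, direction)
        diffs = np.diff(out)
        assert np.all(diffs >= -1e-9) if direction == "increasing" else np.all(diffs <= 1e-9)
        np.testing.assert_allclose(pava_monotone_means(out, w, direction), out, atol=1e-9)
        assert np.average(out, weights=w) == pytest.approx(np.average(means, weights=w), abs=1e-9)

    def test_matches_sklearn_isotonic(self):
        from sklearn.isotonic import IsotonicRegression

        rng = np.random.default_rng(0)
        for _ in range(20):
            means = rng.normal(size=6)
            w = rng.integers(1, 6, size=6).astype(float)
            ours = pava_monotone_means(means, w, "increasing")
            ref = IsotonicRegression().fit_transform(np.arange(6), means, sample_weight=w)
            np.testing.assert_allclose(ours, ref, atol=1e-9)


class TestWilliamsStatistic:
    def test_flat_row_zero(self):
        t, sd = williams_statistic(np.full(16, 5.0), DOSES)
        assert t == 0.0 and sd == 0.0

    def test_sign_symmetry(self):
        rng = np.random.default_rng(1)
        row = rng.normal(8, 0.3, 16) + np.repeat([0, 0.2, 0.5, 1.0], 4)
        t_up, _ = williams_statistic(row, DOSES)
        t_dn, _ = williams_statistic(-row, DOSES)
        assert abs(t_up) == pytest.approx(abs(t_dn), rel=1e-12)
        assert t_up == pytest.approx(-t_dn, rel=1e-12)

    def test_shift_invariance(self):
        rng = np.random.default_rng(2)
        row = rng.normal(0, 0.3, 16)
        t0, _ = williams_statistic(row, DOSES)
        t1, _ = williams_statistic(row + 100.0, DOSES)
        assert t0 == pytest.approx(t1, rel=1e-9)

    def test_monotone_means_formula(self):
        # group means 0/0.5/1.0/1.5, s² = 0.04, n = 4 → t = 1.5/sqrt(0.04/2);
        # deviations scaled so the pooled within-group variance is exactly 0.04
        dev = np.array([0.2, -0.2, 0.2, -0.2])
        dev = dev * np.sqrt(0.04 / (4 * 0.16 / 12))
        row = np.concatenate([m + dev for m in (0.0, 0.5, 1.0, 1.5)])
        t, sd = williams_statistic(row, DOSES)
        assert sd**2 == pytest.approx(0.04, rel=1e-9)
        assert t == pytest.approx(1.5 / np.sqrt(0.04 * 0.5), rel=1e-9)
        assert t == pytest.approx(10.61, abs=0.01)


class TestPermutationPvalue:
    def test_add_one_lower_bound(self):
        rng = np.random.default_rng(3)
        p = permutation_pvalue(rng.normal(size=16), DOSES, B=100, seed=0)
        assert p >= 1 / 101

    def test_strong_responder_hits_floor(self):
        row = np.repeat([0.0, 2.0, 4.0, 6.0], 4) + np.random.default_rng(4).normal(0, 0.1, 16)
        assert permutation_pvalue(row, DOSES, B=500, seed=0) == pytest.approx(1 / 501)

    def test_deterministic_under_seed(self):
        row = np.random.default_rng(5).normal(size=16)
        assert permutation_pvalue(row, DOSES, seed=11) == permutation_pvalue(row, DOSES, seed=11)


class TestScreen:
    def test_defaults_match_screen_parameters(self):
        import inspect

        sig = inspect.signature(screen_probes)
        assert sig.parameters["alpha"].default == 0.05
        assert sig.parameters["fc_threshold"].default == 1.5
        assert sig.parameters["B"].default == 500

    def test_requires_control_group(self):
        # the container itself refuses a design without a vehicle-control group
        conc = np.repeat([10.0, 100.0], 4)
        with pytest.raises(ValueError):
            ExpressionMatrix(["g0"], np.random.default_rng(0).normal(size=(1, 8)), conc)

    def test_passes_needs_both_pvalue_and_foldchange(self, flat_matrix):
        res = screen_probes(flat_matrix, B=200, seed=0)
        fc_ok = res["max_abs_log2fc"] >= np.log2(1.5)
        p_ok = res["perm_p"] < 0.05
        assert (res["passes"] == (fc_ok & p_ok)).all()

    def test_sensitivity_on_strong_responders(self):
        """≥45 of 50 strong planted responders among 500 genes are recovered."""
        d = SyntheticDesign(n_genes=500, responder_fraction=0.1, noise_sd=0.15, seed=21)
        mat, truths = generate_expression_matrix(d)
        res = screen_probes(mat, seed=21).set_index("gene_id")
        responders = [t.gene_id for t in truths if t.is_responder]
        assert len(responders) == 50
        assert res.loc[responders, "passes"].sum() >= 45
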