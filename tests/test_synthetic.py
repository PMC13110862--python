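"""Generator ground truth: determinism, planted curves, analytic BMC oracle."""

import numpy as np
import pytest

from pfosber.synthetic import (
    SyntheticDesign,
    TruthRecord,
    apical_table_to_matrix,
    generate_apical_table,
    generate_expression_matrix,
    printed_values_fixture,
    true_bmc,
    truth_table,
)


def grid_search_bmc(truth, bmr_sd=1.0, dmax=1e4, n=100_000):
    """Brute-force oracle: first dose on a dense grid reaching the BMR."""
    d = np.linspace(0, dmax, n)
    delta = np.abs(truth.mean_at(d) - truth.mean_at(0.0))
    target = bmr_sd * truth.params["sigma"]
    idx = np.flatnonzero(delta >= target)
    if idx.size == 0:
        return None
    i = idx[0]
    # linear refinement between the bracketing grid points
    x0, x1 = d[i - 1], d[i]
    y0, y1 = delta[i - 1], delta[i]
    return x0 + (target - y0) / (y1 - y0) * (x1 - x0)


class TestDesignValidation:
    def test_concentration_grid_must_increase_and_include_zero(self):
        with pytest.raises(ValueError):
            SyntheticDesign(concentrations=(0.0, 100.0, 10.0))
        with pytest.raises(ValueError):
            SyntheticDesign(concentrations=(10.0, 100.0))

    def test_responder_fraction_bounds(self):
        with pytest.raises(ValueError):
            SyntheticDesign(responder_fraction=1.5)

    def test_micromolar_boundary_conversion(self):
        d = SyntheticDesign(concentrations=(0.0, 0.01, 0.1, 1.0), concentration_unit="uM")
        assert d.concentrations == (0.0, 10.0, 100.0, 1000.0)


class TestGenerateMatrix:
    def test_shape_and_determinism(self):
        d = SyntheticDesign(n_genes=30, responder_fraction=0.2, seed=42)
        m1, t1 = generate_expression_matrix(d)
        m2, t2 = generate_expression_matrix(d)
        assert m1.values.shape == (30, 16)
        np.testing.assert_array_equal(m1.values, m2.values)
        assert [r.true_bmc for r in t1] == [r.true_bmc for r in t2]

    def test_null_design_all_flat(self):
        d = SyntheticDesign(n_genes=50, responder_fraction=0.0, noise_sd=0.1, seed=1)
        mat, truths = generate_expression_matrix(d)
        assert not any(t.is_responder for t in truths)
        # row means deviate from the planted baseline only by noise
        baselines = np.array([t.params["baseline"] for t in truths])
        dev = mat.values.mean(axis=1) - baselines
        assert np.all(np.abs(dev) < 5 * 0.1 / np.sqrt(16))

    def test_nonresponder_mean_converges_to_baseline(self):
        d = SyntheticDesign(n_genes=5, responder_fraction=0.0, n_replicates=100,
                            noise_sd=0.3, seed=2)
        mat, truths = generate_expression_matrix(d)
        baselines = np.array([t.params["baseline"] for t in truths])
        dev = np.abs(mat.values.mean(axis=1) - baselines)
        assert np.all(dev < 5 * 0.3 / np.sqrt(400))

    def test_hill_responders_bmc_within_range(self):
        d = SyntheticDesign(n_genes=100, responder_fraction=1.0, noise_sd=0.25, seed=9)
        _, truths = generate_expression_matrix(
            d, models=("Hill",), amplitude_range=(2.0, 2.0), ec50_range=(20.0, 500.0)
        )
        bmcs = [t.true_bmc for t in truths]
        assert all(b is not None and 0 < b < 1000 for b in bmcs)


class TestTrueBmc:
    def test_linear_closed_form(self):
        t = TruthRecord("g", True, "Linear", {"beta0": 8, "beta1": 0.004, "sigma": 0.2}, 1)
        assert true_bmc(t) == pytest.approx(0.2 / 0.004)

    def test_hill_hand_inversion(self):
        # v=2, n=1, k=100, sigma=0.25: x = 0.125, bmc = 100*(0.125/0.875)
        t = TruthRecord("g", True, "Hill",
                        {"gamma": 8, "v": 2.0, "k": 100.0, "n": 1.0, "sigma": 0.25}, 1)
        assert true_bmc(t) == pytest.approx(100 * 0.125 / 0.875, rel=1e-9)
        assert true_bmc(t) == pytest.approx(14.29, rel=1e-3)

    def test_unreachable_amplitude_returns_none(self):
        t = TruthRecord("g", True, "Hill",
                        {"gamma": 8, "v": 0.1, "k": 100.0, "n": 1.0, "sigma": 0.25}, 1)
        assert true_bmc(t) is None

    def test_non_responder_rejected(self):
        t = TruthRecord("g", False, None, {"baseline": 8, "sigma": 0.2}, 0)
        with pytest.raises(ValueError):
            true_bmc(t)

    def test_analytic_matches_grid_oracle(self):
        """Every planted BMC agrees with a 1e5-point grid search within 0.1%."""
        d = SyntheticDesign(n_genes=60, responder_fraction=1.0, noise_sd=0.25, seed=13)
        _, truths = generate_expression_matrix(d)
        checked = 0
        for t in truths:
            if t.true_bmc is None or t.true_bmc > 9e3:
                continue
            oracle = grid_search_bmc(t)
            assert oracle == pytest.approx(t.true_bmc, rel=1e-3)
            checked += 1
        assert checked >= 50


class TestApicalTable:
    SPECS = {
        "estradiol": {"model_id": "Hill",
                      "params": {"gamma": 100.0, "v": -40.0, "k": 150.0, "n": 1.0},
                      "noise_sd": 2.0},
        "viability": {"model_id": "flat", "params": {"baseline": 95.0}, "noise_sd": 1.0},
    }

    def test_structure_and_determinism(self):
        d = SyntheticDesign(seed=3)
        t1 = generate_apical_table(d, self.SPECS)
        t2 = generate_apical_table(d, self.SPECS)
        assert len(t1) == 2 * 4 * 4
        assert t1.equals(t2)
        t3 = generate_apical_table(SyntheticDesign(seed=4), self.SPECS)
        assert not t1.equals(t3)

    def test_flat_endpoint_group_means_equal_within_noise(self):
        d = SyntheticDesign(seed=3, n_replicates=8)
        tab = generate_apical_table(d, {"v": {"model_id": "flat",
                                              "params": {"baseline": 95.0},
                                              "noise_sd": 1.0}})
        gm = tab.groupby("concentration_nM")["value"].mean()
        assert gm.max() - gm.min() < 5 * 1.0 / np.sqrt(8) * 2

    def test_empty_specs_rejected(self):
        with pytest.raises(ValueError):
            generate_apical_table(SyntheticDesign(), {})

    def test_monotone_endpoint_survives_trend_screen(self):
        from pfosber.trend import screen_probes

        d = SyntheticDesign(seed=3)
        tab = generate_apical_table(d, self.SPECS)
        mat = apical_table_to_matrix(tab)
        res = screen_probes(mat, B=200, seed=3)
        res = res.set_index("gene_id")
        assert bool(res.loc["estradiol", "passes"])
        assert not bool(res.loc["viability", "passes"])


def test_truth_table_roundtrips_columns(small_matrix):
    _, truths = small_matrix
    df = truth_table(truths)
    assert set(df.columns) >= {"gene_id", "is_responder", "model_id", "true_bmc"}
    assert df["is_responder"].sum() == sum(t.is_responder for t in truths)


def test_printed_fixture_selected_constants():
    fx = printed_values_fixture()
    assert fx["ART_ref_median"] == 3.5
    assert fx["occupational_ref"] == (303.6, 877.3, 13942.7)
    assert fx["fu_plasma"] == 0.0033
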