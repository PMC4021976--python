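"""Per-solution observables and ensemble statistics."""

import numpy as np
import pandas as pd
import pytest

import gliaflux as gf
from gliaflux.observables import (
    ConditionalCurve,
    basal_calibration,
    ccls_flux_neuron_side,
    conditional_average,
    correlation_histograms,
    ogi_distribution,
    pearson_matrix,
    piecewise_slopes,
)


def _nu_with(brain_net, **fluxes):
    nu = np.zeros(brain_net.n_reactions)
    for rid, v in fluxes.items():
        nu[brain_net.reaction_index(rid)] = v
    return nu


class TestScalarObservables:
    def test_ogi_of_full_oxidation_is_exactly_six(self, brain_net):
        nu = gf.full_oxidation_flux(brain_net, 0.01)
        assert gf.compute_ogi(nu, brain_net) == 6.0

    def test_ogi_of_pure_glycolysis_is_zero(self, brain_net):
        nu = _nu_with(brain_net, GLC_in=1.0, GLCT_c_e=1.0, GLCT_e_n=1.0)
        assert gf.compute_ogi(nu, brain_net) == 0.0

    def test_ogi_arithmetic(self, brain_net):
        nu = _nu_with(brain_net, GLC_in=1.0, O2_in=5.5)
        assert gf.compute_ogi(nu, brain_net) == pytest.approx(5.5)

    def test_ogi_requires_positive_glucose(self, brain_net):
        with pytest.raises(ValueError):
            gf.compute_ogi(np.zeros(brain_net.n_reactions), brain_net)

    def test_vcyc_is_the_glutamine_synthetase_component(self, brain_net,
                                                        basal_ensemble):
        nu = _nu_with(brain_net, GS_a=0.07)
        assert gf.compute_vcyc(nu, brain_net) == 0.07
        _, ens = basal_ensemble
        j = brain_net.reaction_index("GS_a")
        for row in ens.solutions[::100]:
            assert gf.compute_vcyc(row, brain_net) == row[j]

    def test_vcyc_fails_fast_without_the_role(self):
        mb = gf.make_minibrain()
        with pytest.raises(gf.MissingRoleError):
            gf.compute_vcyc(np.zeros(mb.n_reactions), mb)

    def test_neuronal_oxidative_glucose_is_half_pdh(self, brain_net):
        assert gf.compute_cmr_glc_ox_n(_nu_with(brain_net, PDH_n=1.0),
                                       brain_net) == 0.5
        assert gf.compute_cmr_glc_ox_n(_nu_with(brain_net, PDH_n=0.0),
                                       brain_net) == 0.0

    def test_glucose_partition_arithmetic(self, brain_net):
        nu = _nu_with(brain_net, GLC_in=1.0, GLCT_c_a=0.3, GLCT_e_a=0.2)
        assert gf.glucose_partition(nu, brain_net) == pytest.approx(0.5)
        nu_all = _nu_with(brain_net, GLC_in=1.0, GLCT_c_a=1.0)
        assert gf.glucose_partition(nu_all, brain_net) == pytest.approx(1.0)

    def test_partition_spans_a_wide_range(self, brain_net, basal_ensemble):
        """Either cell can absorb most of the glucose at a fixed uptake."""
        _, ens = basal_ensemble
        rec = gf.compute_observables(ens, brain_net)
        frac = rec["astro_glc_fraction"]
        assert frac.between(-1e-9, 1 + 1e-9).all()
        assert frac.min() < 0.2 and frac.max() > 0.8

    def test_ccls_sign_convention(self, brain_net):
        anls = _nu_with(brain_net, LACT_a=0.4)
        assert gf.ccls_flux(anls, brain_net) == pytest.approx(0.4)
        nals = _nu_with(brain_net, LACT_n=0.3, LACT_a=-0.3)
        assert gf.ccls_flux(nals, brain_net) == pytest.approx(-0.3)
        assert ccls_flux_neuron_side(nals, brain_net) == pytest.approx(-0.3)
        assert gf.ccls_flux(np.zeros(brain_net.n_reactions), brain_net) == 0.0

    @pytest.mark.parametrize(
        "vcyc, expected",
        [(5e-7, "silent"), (0.06, "active"), (1e-6, "silent")],
    )
    def test_activity_classification_threshold(self, brain_net, vcyc, expected):
        nu = _nu_with(brain_net, GS_a=vcyc)
        assert gf.classify_active(nu, brain_net) == expected

    def test_oxygen_consumption_counts_only_consuming_reactions(self, brain_net):
        nu = _nu_with(brain_net, O2T_c_n=1.0, OXN_n=1.0, ROS_n=0.5)
        # 0.5 O2 per NADH oxidized + 1 per ROS event; transport not counted
        assert gf.oxygen_consumption(nu, brain_net, "neuron") == pytest.approx(1.0)
        assert gf.oxygen_consumption(nu, brain_net, "astrocyte") == 0.0


class TestConditionalCurves:
    def test_constant_y_gives_flat_zero_error_curve(self):
        rec = pd.DataFrame({"x": np.linspace(0, 1, 100), "y": 3.0,
                            "active": True})
        curve = conditional_average(rec, "x", "y", "all", bins=5)
        np.testing.assert_allclose(curve.y_means, 3.0)
        np.testing.assert_allclose(curve.y_standard_errors, 0.0)
        assert (curve.counts >= 1).all()

    def test_linear_relation_recovered(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, 4000)
        rec = pd.DataFrame({"x": x, "y": 2 * x + rng.normal(0, 0.05, x.size),
                            "active": True})
        curve = conditional_average(rec, "x", "y", "all", bins=20)
        slope = np.polyfit(curve.x_centers, curve.y_means, 1)[0]
        assert slope == pytest.approx(2.0, abs=0.05)

    def test_active_condition_halves_counts(self):
        rec = pd.DataFrame({"x": np.tile(np.linspace(0, 1, 50), 2),
                            "y": 1.0,
                            "active": [True] * 50 + [False] * 50})
        c_all = conditional_average(rec, "x", "y", "all", bins=5)
        c_act = conditional_average(rec, "x", "y", "active", bins=5)
        assert c_all.counts.sum() == 100 and c_act.counts.sum() == 50

    def test_empty_selection_raises(self):
        rec = pd.DataFrame({"x": [1.0], "y": [1.0], "active": [False]})
        with pytest.raises(ValueError):
            conditional_average(rec, "x", "y", "active")


class TestPiecewiseSlopes:
    @staticmethod
    def _curve(x, y, se=None):
        se = np.zeros_like(x) if se is None else se
        return ConditionalCurve(np.asarray(x, float), np.asarray(y, float),
                                np.asarray(se, float),
                                np.ones(len(x), dtype=int))

    def test_exact_piecewise_linear_recovery(self):
        x = np.linspace(0, 2, 21)
        brk = 1.0
        y = np.where(x <= brk, 0.7 * x, 0.7 * brk + 0.3 * (x - brk))
        lo, hi = piecewise_slopes(self._curve(x, y), brk)
        assert lo == pytest.approx(0.7, abs=1e-9)
        assert hi == pytest.approx(0.3, abs=1e-9)

    def test_pure_line_gives_equal_slopes(self):
        x = np.linspace(0, 2, 15)
        lo, hi = piecewise_slopes(self._curve(x, 1.3 * x + 2), 1.0)
        assert lo == pytest.approx(hi) == pytest.approx(1.3)

    def test_noisy_recovery_within_two_standard_errors(self):
        rng = np.random.default_rng(7)
        x = np.linspace(0, 2, 40)
        sigma = 0.02
        y = np.where(x <= 1, 0.7 * x, 0.7 + 0.3 * (x - 1)) + rng.normal(
            0, sigma, x.size)
        se = np.full(x.size, sigma)
        lo, hi = piecewise_slopes(self._curve(x, y, se), 1.0)
        # analytic WLS slope standard error on each half
        for slope, ref, half in ((lo, 0.7, x <= 1), (hi, 0.3, x > 1)):
            se_slope = sigma / np.sqrt(np.sum((x[half] - x[half].mean()) ** 2))
            assert abs(slope - ref) < 2 * se_slope * 2  # 2 se, small-n margin

    def test_insufficient_bins_raise(self):
        with pytest.raises(ValueError):
            piecewise_slopes(self._curve([0, 1, 2], [0, 1, 2]), 0.1)


class TestPearson:
    def _net_and_solutions(self, brain_net, K=200, seed=0):
        rng = np.random.default_rng(seed)
        sol = np.zeros((K, brain_net.n_reactions))
        return rng, sol

    def test_duplicated_columns_correlate_perfectly(self, brain_net):
        rng, sol = self._net_and_solutions(brain_net)
        base = rng.normal(1, 0.3, 200)
        ja, jb = brain_net.reaction_index("HK_n"), brain_net.reaction_index("HK_a")
        sol[:, ja] = base
        sol[:, jb] = base
        sol[:, brain_net.reaction_index("GS_a")] = 1.0
        cm = pearson_matrix(sol, brain_net, "all")
        assert cm.values[ja, jb] == pytest.approx(1.0)

    def test_independent_columns_are_uncorrelated(self, brain_net):
        K = 2000
        rng = np.random.default_rng(1)
        sol = np.zeros((K, brain_net.n_reactions))
        ja, jb = brain_net.reaction_index("HK_n"), brain_net.reaction_index("HK_a")
        sol[:, ja] = rng.normal(size=K)
        sol[:, jb] = rng.normal(size=K)
        cm = pearson_matrix(sol, brain_net, "all")
        assert abs(cm.values[ja, jb]) < 3 / np.sqrt(K)

    def test_matrix_symmetric_unit_diagonal_null_masked(self, brain_net,
                                                        basal_ensemble):
        _, ens = basal_ensemble
        cm = pearson_matrix(ens, brain_net, "all")
        keep = ~cm.null_mask
        vals = cm.values[np.ix_(keep, keep)]
        np.testing.assert_allclose(vals, vals.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(vals), 1.0, atol=1e-12)
        assert np.nanmax(np.abs(vals)) <= 1 + 1e-12
        # constant (zero-variance) reactions are masked, not NaN noise
        assert cm.null_mask[brain_net.reaction_index("CK_n")]

    def test_histogram_groups_cover_cell_pairs(self, brain_net, basal_ensemble):
        _, ens = basal_ensemble
        cm = pearson_matrix(ens, brain_net, "all")
        hists = correlation_histograms(cm, brain_net)
        assert set(hists) == {"within_neuron", "within_astrocyte",
                              "between_cells"}
        for edges, dens in hists.values():
            assert np.isfinite(dens).all()

    def test_small_subset_raises(self, brain_net):
        sol = np.zeros((5, brain_net.n_reactions))
        with pytest.raises(ValueError):
            pearson_matrix(sol, brain_net, "all")


class TestDistributionsAndCalibration:
    def test_ogi_histogram_normalizes_and_matches_mean(self, brain_net,
                                                       basal_ensemble):
        _, ens = basal_ensemble
        edges, density, mean, se = ogi_distribution(ens, brain_net)
        widths = np.diff(edges)
        assert np.sum(density * widths) == pytest.approx(1.0)
        sol = ens.solutions
        direct = np.mean([gf.compute_ogi(row, brain_net) for row in sol[::20]])
        assert mean == pytest.approx(sol[:, brain_net.role_column("O2_to_c")].mean()
                                     / 0.15, rel=1e-12)
        assert abs(direct - mean) < 0.2

    def test_identical_solutions_occupy_single_bin(self, brain_net):
        nu = gf.full_oxidation_flux(brain_net, 0.01)
        ens = gf.SolutionEnsemble(
            solutions=np.tile(nu, (50, 1)), glucose_level=0.01,
            config=gf.SamplerConfig(), reaction_ids=[r.id for r in
                                                     brain_net.reactions],
            iterations=np.zeros(50, dtype=np.int64), residuals=np.zeros(50),
        )
        edges, density, mean, se = ogi_distribution(ens, brain_net)
        assert (density > 0).sum() == 1
        assert mean == pytest.approx(6.0)
        assert se == 0.0

    def test_linear_sweep_crosses_at_known_uptake(self):
        g = np.linspace(0.04, 0.12, 9)
        ogi = 5.5 + (0.08 - g) * 50  # linear, crosses 5.5 at 0.08
        g_star, g_act = basal_calibration(g, ogi)
        assert g_star == pytest.approx(0.08)
        assert g_act == pytest.approx(0.08 * 1.15)

    def test_unbracketed_sweep_raises(self):
        with pytest.raises(ValueError):
            basal_calibration([0.1, 0.2], [4.0, 3.0])


from hypothesis import given, settings, strategies as st


@settings(deadline=None, derandomize=True, max_examples=30)
@given(
    st.lists(st.floats(0, 1), min_size=12, max_size=60),
    st.integers(min_value=2, max_value=6),
)
def test_bin_means_recompose_to_global_mean(xs, nbins):
    """Count-weighted bin means of y equal the overall mean of y."""
    x = np.asarray(xs)
    y = np.sin(3 * x) + x  # arbitrary deterministic response
    rec = pd.DataFrame({"x": x, "y": y, "active": True})
    curve = conditional_average(rec, "x", "y", "all", bins=nbins)
    recomposed = np.sum(curve.y_means * curve.counts) / curve.counts.sum()
    assert recomposed == pytest.approx(y.mean(), rel=1e-9, abs=1e-12)
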