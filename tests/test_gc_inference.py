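import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from netgc.gc_inference import (by_fdr, deviance_map, fit_full_model,
                                fit_reduced_model, infer_network,
                                select_lambda, two_stage_oracle)
from netgc.source_model import SourceSpace
from netgc.synthetic_data import (make_var2_model, simulate_source_activity)

from conftest import SMALL_LABELS, make_planted_recording


@pytest.fixture(scope="module")
def planted10(space10):
    edges = {(0, 5), (3, 1), (7, 2), (8, 9), (4, 6)}
    model, x, gain, rec = make_planted_recording(space10, edges, seed=11,
                                                 n_samples=600)
    return edges, model, x, gain, rec


@pytest.fixture(scope="module")
def fitted10(planted10, space10):
    edges, model, x, gain, rec = planted10
    fit, statmap, network = infer_network(
        rec.data, gain, space10.node_to_patch, lam=5.0, q=0.001)
    return edges, fit, statmap, network


class TestFitFullModel:
    def test_coefficients_close_to_truth_with_identity_gain(self):
        space = SourceSpace.from_labels(SMALL_LABELS[:3], k_components=1)
        model = make_var2_model(space, {(0, 1), (2, 0)}, 0.5, seed=7,
                                pole_radius_range=(0.75, 0.9))
        x = simulate_source_activity(model, 2750, seed=8)
        fit = fit_full_model(x, np.eye(3), space.node_to_patch, lam=0.0,
                             tol=1e-9, max_iter=200)
        est = np.hstack([fit.a1, fit.a2])
        true = np.hstack([model.a1, model.a2])
        rmse = np.sqrt(np.mean((est - true) ** 2))
        assert rmse < 0.1
        # and close to the OLS fit on the true sources (the oracle route)
        Z = np.vstack([x[:, 1:-1], x[:, :-2]])
        ols = np.linalg.solve(Z @ Z.T, Z @ x[:, 2:].T).T
        assert np.sqrt(np.mean((est - ols) ** 2)) < 0.05

    def test_objective_trace_is_monotone(self, fitted10):
        _, fit, _, _ = fitted10
        assert np.all(np.diff(fit.trace) >= -1e-8)

    def test_huge_penalty_shrinks_cross_blocks(self, planted10, space10):
        edges, model, x, gain, rec = planted10
        fit = fit_full_model(rec.data, gain, space10.node_to_patch,
                             lam=1e7, tol=1e-8, max_iter=60)
        off = ~np.eye(10, dtype=bool)
        assert np.max(np.abs(fit.a1[off])) < 1e-3
        assert np.max(np.abs(fit.a2[off])) < 1e-3

    def test_unsupported_order_rejected(self, planted10, space10):
        _, _, _, gain, rec = planted10
        with pytest.raises(ValueError, match="order 2"):
            fit_full_model(rec.data, gain, space10.node_to_patch, order=1)

    def test_dimension_mismatch_rejected(self, space10):
        with pytest.raises(ValueError):
            fit_full_model(np.zeros((4, 100)), np.zeros((5, 10)),
                           space10.node_to_patch)


class TestReducedModel:
    def test_reduced_loglik_nested_below_full(self, fitted10, planted10,
                                              space10):
        edges, fit, _, _ = fitted10
        _, _, _, gain, rec = planted10
        red = fit_reduced_model(fit, (0, 5), rec.data, gain)
        assert red.objective <= fit.objective + 1e-6
        # constrained block is exactly zero
        assert red.a1[5, 0] == 0.0 and red.a2[5, 0] == 0.0

    def test_self_pair_rejected(self, fitted10, planted10):
        _, fit, _, _ = fitted10
        _, _, _, gain, rec = planted10
        with pytest.raises(ValueError, match="self-pair"):
            fit_reduced_model(fit, (2, 2), rec.data, gain)


class TestDevianceMap:
    def test_all_pairs_nonnegative_with_chisq_pvalues(self, fitted10):
        _, _, statmap, _ = fitted10
        t = statmap.table
        assert len(t) == 90  # 10 * 9 ordered pairs
        assert (t.deviance >= 0).all()
        assert ((t.p >= 0) & (t.p <= 1)).all()
        assert (t.df == 2).all()
        # p is the chi-square upper tail: for df=2, p = exp(-D/2)
        assert np.allclose(t.p, np.exp(-t.deviance / 2), rtol=1e-10)

    def test_worked_chi_square_example(self):
        assert stats.chi2.sf(13.8155, 2) == pytest.approx(0.001, rel=1e-3)

    def test_planted_edges_have_smallest_pvalues(self, fitted10):
        edges, _, statmap, _ = fitted10
        t = statmap.table.sort_values("p")
        top = set(zip(t.src.iloc[:3], t.dst.iloc[:3]))
        assert top <= edges


class TestNullCalibration:
    def test_well_calibrated_map_untouched(self):
        from netgc.gc_inference import GCStatMap, calibrate_null_scale
        import pandas as pd
        rng = np.random.default_rng(0)
        d = stats.chi2.rvs(2, size=60, random_state=1)
        t = pd.DataFrame({"src": 0, "dst": 1, "deviance": d, "df": 2,
                          "p": stats.chi2.sf(d, 2)})
        out = calibrate_null_scale(GCStatMap(table=t)).table
        # scale floors at 1, so a chi-square-consistent map keeps its p's
        assert (out["null_scale"] >= 1.0).all()
        assert np.allclose(out["p_cal"],
                           stats.chi2.sf(d / out["null_scale"], 2))

    def test_inflated_map_rescaled_to_null_median(self):
        from netgc.gc_inference import GCStatMap, calibrate_null_scale
        import pandas as pd
        d = 3.0 * stats.chi2.rvs(2, size=200, random_state=2)  # 3x inflation
        t = pd.DataFrame({"src": 0, "dst": 1, "deviance": d, "df": 2,
                          "p": stats.chi2.sf(d, 2)})
        out = calibrate_null_scale(GCStatMap(table=t)).table
        scale = out["null_scale"].iloc[0]
        assert scale == pytest.approx(3.0, rel=0.25)
        # recalibrated deviances have a chi-square-consistent median
        assert np.median(d / scale) == pytest.approx(
            stats.chi2.ppf(0.5, 2), rel=1e-9)


class TestByFdr:
    def test_all_ones_reject_nothing(self):
        assert by_fdr(np.ones(10), 0.05).sum() == 0

    def test_worked_three_pvalue_example(self):
        # c(3) = 11/6; BY thresholds at q=0.05: k*0.05/(3*11/6)
        mask = by_fdr([0.0001, 0.02, 0.9], q=0.05)
        assert mask.tolist() == [True, False, False]

    def test_ties_at_threshold_all_rejected(self):
        # both copies of the passing value must be rejected together
        mask = by_fdr([0.0001, 0.0001, 0.9, 0.9], q=0.05)
        assert mask.tolist() == [True, True, False, False]

    def test_matches_statsmodels_step_up(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(size=30) ** 3
            ours = by_fdr(p, 0.05)
            ref = multipletests(p, alpha=0.05, method="fdr_by")[0]
            assert np.array_equal(ours, ref)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=40), st.floats(min_value=0.001, max_value=0.2),
           st.floats(min_value=0.2, max_value=0.999))
    def test_rejections_monotone_in_q(self, p, q1, frac):
        q0 = q1 * frac  # q0 < q1
        r0, r1 = by_fdr(p, q0), by_fdr(p, q1)
        assert np.all(r1 | ~r0)  # rejections at q0 are a subset

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            by_fdr([0.1, 1.2], 0.05)
        with pytest.raises(ValueError):
            by_fdr([0.1], 1.5)


class TestOracleAndInvariances:
    @pytest.mark.parametrize("seed,n_patches", [(5, 4), (6, 5), (9, 5)])
    def test_pipeline_equals_oracle_on_noiseless_identity_gain(
            self, seed, n_patches):
        """With known sources observed directly, the sensor-space fit and
        the brute-force two-model VAR oracle detect the same network."""
        space = SourceSpace.from_labels(SMALL_LABELS[:n_patches],
                                        k_components=1)
        rng = np.random.default_rng(seed)
        pairs = [(s, d) for s in range(n_patches) for d in range(n_patches)
                 if s != d]
        edges = {pairs[i] for i in rng.choice(len(pairs), 3, replace=False)}
        model = make_var2_model(space, edges, 0.5, seed=seed,
                                pole_radius_range=(0.75, 0.9))
        x = simulate_source_activity(model, 1200, seed=seed + 50)
        _, _, net = infer_network(x, np.eye(n_patches),
                                  space.node_to_patch, lam=0.0, q=0.001)
        _, oracle_net = two_stage_oracle(x, space.node_to_patch, alpha=0.001)
        assert net.edges == oracle_net.edges

    def test_sensor_scaling_leaves_network_unchanged(self, planted10,
                                                     space10, fitted10):
        _, _, _, gain, rec = planted10
        _, _, _, base_net = fitted10
        _, _, scaled_net = infer_network(rec.data * 137.0, gain,
                                         space10.node_to_patch, lam=5.0,
                                         q=0.001)
        assert scaled_net.edges == base_net.edges

    def test_screening_keeps_family_size(self, planted10, space10):
        _, _, _, gain, rec = planted10
        _, statmap, net = infer_network(rec.data, gain,
                                        space10.node_to_patch, lam=5.0,
                                        q=0.001, screen_floor=0.05,
                                        max_iter=150, tol=1e-8)
        assert len(statmap.table) == 90
        assert net.m == 90


def test_select_lambda_returns_grid_member(planted10, space10):
    _, _, _, gain, rec = planted10
    grid = (0.0, 5.0, 50.0)
    lam = select_lambda(rec.data, gain, space10.node_to_patch, grid=grid,
                        max_iter=60, tol=1e-7)
    assert lam in grid
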