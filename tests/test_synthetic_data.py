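import numpy as np
import pytest

from netgc.recording import read_recording, write_recording
from netgc.source_model import SourceSpace, orient_hemispheres, roi_classes
from netgc.synthetic_data import (CohortScenario, VARModel, make_cohort,
                                  make_forward_model, make_var2_model,
                                  read_edge_lists, simulate_recording,
                                  simulate_source_activity, write_edge_lists)
from netgc.clinical_stats import classify_all
from netgc.network_summary import summarize_bilateral

from conftest import SMALL_LABELS


class TestMakeVar2Model:
    def test_empty_edge_set_is_block_diagonal(self, space5):
        m = make_var2_model(space5, set(), 0.5, seed=0)
        off = ~np.eye(5, dtype=bool)
        assert np.all(m.a1[off] == 0) and np.all(m.a2[off] == 0)
        assert m.spectral_radius < 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_stationary_by_eigendecomposition(self, space10, seed):
        """Companion spectral radius < 1, checked by direct eigenvalues."""
        rng = np.random.default_rng(seed)
        pairs = [(s, d) for s in range(10) for d in range(10) if s != d]
        edges = {pairs[i] for i in rng.choice(len(pairs), 6, replace=False)}
        m = make_var2_model(space10, edges, coupling_strength=1.5, seed=seed)
        n = m.n_nodes
        comp = np.zeros((2 * n, 2 * n))
        comp[:n, :n] = m.a1
        comp[:n, n:] = m.a2
        comp[n:, :n] = np.eye(n)
        assert np.max(np.abs(np.linalg.eigvals(comp))) < 1.0

    def test_cross_blocks_nonzero_exactly_on_edges(self, space5):
        edges = {(0, 2), (3, 1)}
        m = make_var2_model(space5, edges, 0.5, seed=1)
        for s in range(5):
            for d in range(5):
                if s == d:
                    continue
                present = (m.a1[d, s] != 0) or (m.a2[d, s] != 0)
                assert present == ((s, d) in edges)

    def test_same_seed_is_bit_identical(self, space5):
        a = make_var2_model(space5, {(0, 1)}, 0.5, seed=7)
        b = make_var2_model(space5, {(0, 1)}, 0.5, seed=7)
        assert np.array_equal(a.a1, b.a1) and np.array_equal(a.a2, b.a2)
        assert np.array_equal(a.q, b.q)

    def test_self_pair_rejected(self, space5):
        with pytest.raises(ValueError, match="self-pair"):
            make_var2_model(space5, {(2, 2)}, 0.5, seed=0)

    def test_nonpositive_coupling_rejected(self, space5):
        with pytest.raises(ValueError):
            make_var2_model(space5, set(), 0.0, seed=0)


class TestSimulateSourceActivity:
    def test_white_noise_when_coefficients_zero(self):
        n = 3
        model = VARModel(a1=np.zeros((n, n)), a2=np.zeros((n, n)),
                         q=np.eye(n), node_to_patch=np.arange(n))
        x = simulate_source_activity(model, 10_000, seed=0)
        for i in range(n):
            r1 = np.corrcoef(x[i, :-1], x[i, 1:])[0, 1]
            assert abs(r1) < 0.05

    def test_ar2_variance_matches_yule_walker(self):
        # univariate AR(2); closed-form stationary variance as oracle
        a1, a2, s2 = 0.5, -0.3, 1.0
        model = VARModel(a1=np.array([[a1]]), a2=np.array([[a2]]),
                         q=np.array([[s2]]), node_to_patch=np.zeros(1, int))
        x = simulate_source_activity(model, 50_000, seed=1)
        var_yw = s2 * (1 - a2) / ((1 + a2) * ((1 - a2) ** 2 - a1 ** 2))
        assert np.var(x) == pytest.approx(var_yw, rel=0.10)

    def test_balanced_model_has_unit_variances(self, space5):
        m = make_var2_model(space5, {(0, 2)}, 0.5, seed=3)
        x = simulate_source_activity(m, 30_000, seed=4)
        assert np.allclose(x.var(axis=1), 1.0, atol=0.15)

    def test_seed_determinism(self, space5):
        m = make_var2_model(space5, set(), 0.5, seed=0)
        a = simulate_source_activity(m, 100, seed=9)
        b = simulate_source_activity(m, 100, seed=9)
        assert np.array_equal(a, b)

    def test_nonstationary_model_rejected(self):
        model = VARModel(a1=np.array([[1.2]]), a2=np.array([[0.0]]),
                         q=np.eye(1), node_to_patch=np.zeros(1, int))
        with pytest.raises(ValueError, match="not stationary"):
            simulate_source_activity(model, 10)


class TestForwardModel:
    def test_default_shape_matches_157_channel_array(self):
        space = SourceSpace.from_labels(SMALL_LABELS[:4], k_components=4)
        gain = make_forward_model(space)
        assert gain.shape == (157, 16)

    def test_single_patch_signal_lies_in_patch_span(self):
        space = SourceSpace.from_labels(["cuneus"], k_components=4)
        gain = make_forward_model(space, n_sensors=20, seed=0)
        x = np.random.default_rng(0).standard_normal((4, 50))
        y = gain @ x
        proj = gain @ np.linalg.lstsq(gain, y, rcond=None)[0]
        assert np.max(np.abs(y - proj)) < 1e-10

    def test_within_patch_columns_more_correlated_than_between(self):
        space = SourceSpace.from_labels(SMALL_LABELS[:6], k_components=4)
        gain = make_forward_model(space, n_sensors=64, seed=1)
        def block(i):
            return gain[:, 4 * i:4 * (i + 1)]
        within = np.abs(np.corrcoef(block(0).T)[np.triu_indices(4, 1)]).mean()
        between = np.abs(block(0).T @ block(1)).mean()
        assert within > 0.3 > between

    def test_determinism_and_min_sensors(self, space5):
        a = make_forward_model(space5, 16, seed=5)
        b = make_forward_model(space5, 16, seed=5)
        assert np.array_equal(a, b)
        with pytest.raises(ValueError):
            make_forward_model(space5, 1)


class TestSimulateRecording:
    def test_noiseless_recording_is_exact_projection(self, space5):
        x = np.random.default_rng(0).standard_normal((5, 100))
        gain = make_forward_model(space5, 12, seed=0)
        rec = simulate_recording(x, gain, 0.0, 50.0)
        assert np.array_equal(rec.data, gain @ x)

    def test_noise_sd_calibrated(self):
        gain = np.zeros((4, 2))
        rec = simulate_recording(np.zeros((2, 50_000)), gain, 2.5, 50.0,
                                 seed=1)
        assert np.std(rec.data) == pytest.approx(2.5, rel=0.05)

    def test_dimension_mismatch_rejected(self, space5):
        gain = make_forward_model(space5, 12, seed=0)
        with pytest.raises(ValueError, match="columns"):
            simulate_recording(np.zeros((4, 10)), gain, 0.1, 50.0)

    def test_hdf5_roundtrip_preserves_metadata(self, tmp_path):
        rec = simulate_recording(
            np.random.default_rng(0).standard_normal((2, 30)),
            np.eye(2), 0.1, 250.0,
            metadata=dict(subject_id="patient_03", visit=2, group="patient",
                          lesion_hemisphere="right"), seed=0)
        path = tmp_path / "rec.h5"
        write_recording(path, rec)
        back = read_recording(path)
        assert np.array_equal(back.data, rec.data)
        assert back.fs == rec.fs
        assert (back.subject_id, back.visit, back.group,
                back.lesion_hemisphere) == ("patient_03", 2, "patient",
                                            "right")
        assert back.channel_names == rec.channel_names


@pytest.fixture(scope="module")
def small_cohort():
    space = SourceSpace.from_labels(SMALL_LABELS[:6] * 2, k_components=1)
    scenario = CohortScenario(fs=50.0, duration_s=8.0, n_sensors=12, seed=5)
    return space, scenario, make_cohort(scenario, space)


class TestMakeCohort:
    def test_zero_fpc_fraction_boundary(self):
        space = SourceSpace.from_labels(SMALL_LABELS[:6] * 2, k_components=1)
        scenario = CohortScenario(
            n_patients=2, n_controls=1, fs=50.0, duration_s=5.0,
            n_sensors=10, n_edges=20,
            fpc_link_fraction={"patient": (0.0, 0.3, 0.3),
                               "control": (0.3, 0.3, 0.3)},
            favourable_ids=("patient_01",), seed=0)
        _, gt, _ = make_cohort(scenario, space)
        classes = roi_classes(space)
        for sid in ("patient_01", "patient_02"):
            for s, d in gt.edge_set(sid, 1):
                assert classes[s] == "nonFPC" and classes[d] == "nonFPC"

    def test_ground_truth_fractions_match_targets(self, small_cohort):
        space, scenario, (recs, gt, clin) = small_cohort
        classes = roi_classes(space)
        for grp, visit in (("patient", 1), ("patient", 2), ("control", 2)):
            fracs = [
                np.mean([("FPC" in (classes[s], classes[d]))
                         for s, d in es])
                for (sid, v), es in gt.edges.items()
                if v == visit and gt.group[sid] == grp
            ]
            target = scenario.fpc_link_fraction[grp][visit - 1]
            # binomial sampling tolerance at n_edges per network
            se = np.sqrt(target * (1 - target) / scenario.n_edges)
            assert abs(np.mean(fracs) - target) < 4 * se

    def test_recovery_classifier_recovers_favourable_ids(self, small_cohort):
        _, scenario, (recs, gt, clin) = small_cohort
        labels = classify_all(clin)
        got = set(labels[labels.favourable]["patient"])
        assert got == set(scenario.favourable_ids)

    def test_favourable_patients_reduce_interhemispheric_share(
            self, small_cohort):
        space, scenario, (recs, gt, clin) = small_cohort
        hemi = [p.hemisphere for p in space.patches]
        def ih_share(sid, visit):
            es = gt.edge_set(sid, visit)
            return np.mean([hemi[s] != hemi[d] for s, d in es])
        fav = list(scenario.favourable_ids)
        unfav = [s for s in scenario.patient_ids if s not in fav]
        fav_v3 = np.mean([ih_share(s, 3) for s in fav])
        unfav_v3 = np.mean([ih_share(s, 3) for s in unfav])
        assert fav_v3 < unfav_v3

    def test_metadata_and_edge_list_roundtrip(self, small_cohort, tmp_path):
        _, scenario, (recs, gt, clin) = small_cohort
        assert len(recs) == (scenario.n_patients + scenario.n_controls) * 3
        controls = [r for r in recs if r.group == "control"]
        assert all(r.lesion_hemisphere is None for r in controls)
        path = tmp_path / "gt.tsv"
        write_edge_lists(path, gt)
        back = read_edge_lists(path)
        assert back == gt.edges

    def test_generation_is_seed_deterministic(self):
        space = SourceSpace.from_labels(SMALL_LABELS[:6] * 2, k_components=1)
        scen = CohortScenario(n_patients=1, n_controls=1, fs=50.0,
                              duration_s=4.0, n_sensors=8,
                              favourable_ids=(), seed=42)
        r1, g1, c1 = make_cohort(scen, space)
        r2, g2, c2 = make_cohort(scen, space)
        assert g1.edges == g2.edges
        assert all(np.array_equal(a.data, b.data) for a, b in zip(r1, r2))
        assert c1.equals(c2)

    def test_infeasible_fraction_target_rejected(self):
        space = SourceSpace.from_labels(["cuneus", "insula"] * 2,
                                        k_components=1)  # no FPC patches
        scen = CohortScenario(n_patients=1, n_controls=0, fs=50.0,
                              duration_s=4.0, n_sensors=8, n_edges=8,
                              favourable_ids=(), seed=0)
        with pytest.raises(ValueError, match="infeasible"):
            make_cohort(scen, space)

    def test_invalid_scenarios_rejected(self):
        with pytest.raises(ValueError, match="favourable_ids"):
            CohortScenario(favourable_ids=("nobody",))
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            CohortScenario(fpc_link_fraction={
                "patient": (1.5, 0.3, 0.3), "control": (0.3, 0.3, 0.3)})
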