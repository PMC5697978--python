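"""Synthetic generator: determinism, planted structure, round-trips."""
import dataclasses

import numpy as np
import pytest

from conftest import tiny_parcellation
from cognet.morphometry import asymmetry_index
from cognet.synthetic import (
    CONTROL,
    PATIENT,
    SimulationConfig,
    SizingError,
    generate_bold,
    generate_fa_skeleton,
    generate_label_map,
    nearest_psd_correlation,
    planted_correlation_matrix,
    simulate_node_signals,
    skeleton_mask,
)


def _thal_labels(cfg):
    spec = cfg.parcellation["thalamus"]
    return spec["labels"]["L"], spec["labels"]["R"]


class TestLabelMap:
    def test_small_parcellation_produces_exactly_its_labels(self):
        parc = {
            "a": {"labels": {"L": 1, "R": 2}, "tissue": "GM", "weight": 1.0},
            "b": {"labels": {"L": 3, "R": 4}, "tissue": "GM", "weight": 1.0},
        }
        cfg = SimulationConfig(
            grid_shape=(20, 20, 20), total_labeled_voxels=400,
            parcellation=parc, base_connectivity={}, weakened_links={}, seed=0,
        )
        vol = generate_label_map(cfg)
        assert set(np.unique(vol.data)) == {0, 1, 2, 3, 4}

    def test_zero_asymmetry_gives_equal_thalami(self, small_sim_config):
        cfg = dataclasses.replace(small_sim_config, thalamus_asymmetry=0.0)
        counts = generate_label_map(cfg).voxel_counts()
        lab_l, lab_r = _thal_labels(cfg)
        assert counts[lab_l] == counts[lab_r]

    def test_planted_asymmetry_solves_the_ai_formula(self, small_sim_config):
        # AI = 0.4 with 250 thalamic voxels: V_R = 100 -> V_L = 150
        cfg = dataclasses.replace(
            small_sim_config,
            thalamus_asymmetry=0.4,
            region_voxel_counts={r: (250 if r == "thalamus" else 50)
                                 for r in small_sim_config.parcellation},
        )
        counts = generate_label_map(cfg).voxel_counts()
        lab_l, lab_r = _thal_labels(cfg)
        assert (counts[lab_l], counts[lab_r]) == (150, 100)

    @pytest.mark.parametrize("ai", [0.0, 0.089, 0.188, 0.4, 1.0])
    def test_asymmetry_round_trip_within_one_voxel(self, small_sim_config, ai):
        cfg = dataclasses.replace(small_sim_config, thalamus_asymmetry=ai)
        counts = generate_label_map(cfg).voxel_counts()
        lab_l, lab_r = _thal_labels(cfg)
        v_l, v_r = counts[lab_l], counts[lab_r]
        recovered = asymmetry_index(v_l, v_r)
        # one-voxel quantization bound on |dAI/dV| ~ 4 / (V_L + V_R)
        assert abs(recovered - ai) <= 4.0 / (v_l + v_r)

    def test_grid_too_small_raises_sizing_error(self, small_sim_config):
        cfg = dataclasses.replace(
            small_sim_config, grid_shape=(4, 4, 4), total_labeled_voxels=500
        )
        with pytest.raises(SizingError):
            generate_label_map(cfg)

    def test_patient_and_control_fractions_follow_planted_means(self):
        cfg = SimulationConfig(parcellation=tiny_parcellation(),
                               base_connectivity={}, weakened_links={},
                               total_labeled_voxels=4000, seed=5)
        gm = {kind: [] for kind in (CONTROL, PATIENT)}
        for kind in gm:
            for i in range(20):
                counts = generate_label_map(cfg, kind, i).voxel_counts()
                gm_vox = sum(
                    c for lab, c in counts.items()
                    if cfg.tissue_by_label()[lab] == "GM"
                )
                gm[kind].append(gm_vox / sum(counts.values()))
        assert np.mean(gm[CONTROL]) == pytest.approx(0.453, abs=0.01)
        assert np.mean(gm[PATIENT]) == pytest.approx(0.435, abs=0.02)


class TestBold:
    def test_same_seed_reproduces_identical_arrays(self, small_sim_config):
        labels = generate_label_map(small_sim_config)
        b1, p1 = generate_bold(small_sim_config, labels, CONTROL, 1)
        b2, p2 = generate_bold(small_sim_config, labels, CONTROL, 1)
        np.testing.assert_array_equal(b1.data, b2.data)
        np.testing.assert_array_equal(p1.cardiac, p2.cardiac)

    def test_subject_streams_survive_cohort_extension(self, small_sim_config):
        labels = generate_label_map(small_sim_config)
        b1, _ = generate_bold(small_sim_config, labels, CONTROL, 2)
        bigger = dataclasses.replace(small_sim_config, n_controls=40)
        b2, _ = generate_bold(bigger, labels, CONTROL, 2)
        np.testing.assert_array_equal(b1.data, b2.data)

    def test_perfectly_correlated_regions_share_their_signal(self):
        parc = tiny_parcellation()
        cfg = SimulationConfig(
            parcellation=parc, grid_shape=(10, 10, 8), total_labeled_voxels=500,
            base_connectivity={("region_a_L", "region_a_R"): 1 - 1e-12},
            weakened_links={}, confound_amplitude=0.0, noise_sd=0.0, seed=3,
        )
        labels = generate_label_map(cfg)
        bold, _ = generate_bold(cfg, labels, CONTROL, 0)
        s_l = bold.data[labels.data == 1].mean(axis=0)
        s_r = bold.data[labels.data == 2].mean(axis=0)
        assert np.corrcoef(s_l, s_r)[0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_planted_correlation_recovered_over_many_subjects(self):
        cfg = SimulationConfig(
            parcellation=tiny_parcellation(), n_timepoints=150,
            base_connectivity={("region_a_L", "region_b_R"): 0.8},
            weakened_links={}, seed=11,
        )
        nodes = cfg.node_names
        i, j = nodes.index("region_a_L"), nodes.index("region_b_R")
        rs = []
        for s in range(200):
            sig, _, _ = simulate_node_signals(cfg, CONTROL, s)
            rs.append(np.corrcoef(sig[i], sig[j])[0, 1])
        assert np.mean(rs) == pytest.approx(0.8, abs=0.05)

    def test_physio_trace_is_the_exact_confound_regressor(self, small_sim_config):
        labels = generate_label_map(small_sim_config)
        bold, physio = generate_bold(small_sim_config, labels, CONTROL, 0)
        assert physio.time_s[0] == 0.0
        assert physio.time_s[-1] == pytest.approx(
            (small_sim_config.n_timepoints - 1) * small_sim_config.tr_seconds
        )
        assert np.all(np.abs(physio.cardiac) <= 1.0)


class TestPsdRepair:
    def test_contradictory_targets_are_repaired_to_psd_unit_diagonal(self):
        c = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        assert np.linalg.eigvalsh(c).min() < 0
        fixed = nearest_psd_correlation(c)
        assert np.linalg.eigvalsh(fixed).min() >= -1e-12
        np.testing.assert_allclose(np.diag(fixed), 1.0)

    def test_patient_weakened_links_enter_the_target(self):
        parc = tiny_parcellation()
        cfg = SimulationConfig(
            parcellation=parc,
            base_connectivity={("region_a_L", "region_a_R"): 0.7},
            weakened_links={0: [("region_a_L", "region_a_R", 0.0)]},
            seed=2,
        )
        nodes = cfg.node_names
        i, j = nodes.index("region_a_L"), nodes.index("region_a_R")
        assert planted_correlation_matrix(cfg, CONTROL, 0)[i, j] == pytest.approx(0.7)
        assert planted_correlation_matrix(cfg, PATIENT, 0)[i, j] == pytest.approx(0.0)


class TestFASkeleton:
    def test_control_skeleton_respects_the_wm_threshold(self, small_sim_config):
        fa = generate_fa_skeleton(small_sim_config, CONTROL, 0)
        assert np.all(fa.fa[fa.skeleton_mask] >= 0.2)
        assert np.all(fa.fa[fa.skeleton_mask] <= 1.0)

    def test_off_skeleton_is_exactly_zero(self, small_sim_config):
        fa = generate_fa_skeleton(small_sim_config, PATIENT, 0)
        assert np.all(fa.fa[~fa.skeleton_mask] == 0.0)

    def test_lesion_depth_is_planted(self, small_sim_config):
        cfg = dataclasses.replace(small_sim_config, lesion_radius=4)
        depths = []
        for i in range(20):
            fa = generate_fa_skeleton(cfg, PATIENT, i)
            assert fa.lesion_mask is not None and fa.lesion_mask.sum() > 0
            depths.append(cfg.fa_mean - fa.fa[fa.lesion_mask].mean())
        assert np.mean(depths) == pytest.approx(cfg.lesion_depth, abs=0.02)

    def test_skeleton_mask_is_a_fixed_function_of_the_grid(self):
        m1 = skeleton_mask((12, 12, 10))
        m2 = skeleton_mask((12, 12, 10))
        np.testing.assert_array_equal(m1, m2)
        assert m1.sum() > 0
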