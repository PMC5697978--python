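"""Normative bands, abnormal-link flagging and group statistics."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import matrix_from_links
from cognet.normative import (
    REDUCED,
    UNDEFINED,
    NormativeError,
    calibrated_null_mean,
    deficit_ttest,
    fit_normative,
    flag_abnormal,
    frequency_map,
    network_correlations,
)

NODES4 = ("a_L", "a_R", "b_L", "b_R")  # 6 links


def _controls(link_rows, network="net"):
    return [
        matrix_from_links(row, NODES4, subject_id=f"c{i}", network=network)
        for i, row in enumerate(link_rows)
    ]


class TestFit:
    def test_identical_controls_give_zero_sd(self):
        ctrls = _controls([[0.3] * 6] * 5)
        model = fit_normative(ctrls)
        np.testing.assert_allclose(model.sd_r, 0.0)
        np.testing.assert_allclose(model.mean_r, 0.3)

    def test_two_controls_hand_computation(self):
        model = fit_normative(_controls([[0.2] * 6, [0.6] * 6]))
        assert model.mean_r[0] == pytest.approx(0.4)
        assert model.sd_r[0] == pytest.approx(0.28284271, abs=1e-6)

    def test_nan_links_drop_per_link_with_recorded_n(self):
        rows = [[0.2] * 6, [0.4] * 6, [0.6] * 6]
        ctrls = _controls(rows)
        ctrls[0].r[0, 1] = ctrls[0].r[1, 0] = np.nan
        model = fit_normative(ctrls)
        assert model.n_per_link[0] == 2
        assert model.mean_r[0] == pytest.approx(0.5)

    def test_single_control_stratum_is_an_error(self):
        ctrls = _controls([[0.2] * 6, [0.4] * 6, [0.6] * 6])
        sex = {"c0": "F", "c1": "F", "c2": "M"}
        with pytest.raises(NormativeError, match="unmodelable"):
            fit_normative(ctrls, stratify_by_sex=True, sex_labels=sex)

    def test_stratified_fit_returns_one_model_per_sex(self):
        ctrls = _controls([[0.2] * 6, [0.4] * 6, [0.5] * 6, [0.7] * 6])
        sex = {"c0": "F", "c1": "M", "c2": "F", "c3": "M"}
        models = fit_normative(ctrls, stratify_by_sex=True, sex_labels=sex)
        assert set(models) == {"F", "M"}
        assert models["F"].stratum == "F"
        assert models["F"].mean_r[0] == pytest.approx(0.35)


class TestFlag:
    def _model(self):
        return fit_normative(_controls([[0.2] * 6, [0.4] * 6, [0.6] * 6]))

    def test_patient_at_the_mean_has_zero_abnormal(self):
        model = self._model()
        patient = matrix_from_links(model.mean_r, NODES4, "p0")
        rep = flag_abnormal(patient, model)
        assert rep.abnormal_count == 0 and rep.reduced_count == 0

    def test_three_sigma_below_is_reduced(self):
        model = self._model()
        values = model.mean_r.copy()
        values[2] = model.mean_r[2] - 3 * model.sd_r[2]
        rep = flag_abnormal(matrix_from_links(values, NODES4, "p0"), model)
        assert rep.reduced_count == 1 and rep.status[2] == REDUCED

    def test_nan_link_is_undefined_and_not_counted(self):
        model = self._model()
        values = model.mean_r.copy()
        patient = matrix_from_links(values, NODES4, "p0")
        patient.r[0, 1] = patient.r[1, 0] = np.nan
        rep = flag_abnormal(patient, model)
        assert rep.status[0] == UNDEFINED
        assert rep.n_defined == 5 and rep.abnormal_count == 0

    def test_network_mismatch_is_a_contract_error(self):
        model = self._model()
        patient = matrix_from_links(model.mean_r, NODES4, "p0", network="other")
        with pytest.raises(NormativeError):
            flag_abnormal(patient, model)

    @given(
        link=st.integers(0, 5),
        drop=st.floats(0.05, 1.5),
    )
    def test_lowering_a_link_never_decreases_reduced_count(self, link, drop):
        model = self._model()
        rng = np.random.default_rng(0)
        base = model.mean_r + rng.normal(0, 0.2, size=6)
        before = flag_abnormal(
            matrix_from_links(np.clip(base, -1, 1), NODES4, "p"), model
        ).reduced_count
        lowered = base.copy()
        lowered[link] -= drop
        after = flag_abnormal(
            matrix_from_links(np.clip(lowered, -1, 1), NODES4, "p"), model
        ).reduced_count
        assert after >= before


class TestFrequencyAndStats:
    def _reports(self, deltas):
        model = fit_normative(_controls([[0.2] * 6, [0.4] * 6, [0.6] * 6]))
        reports = []
        for i, d in enumerate(deltas):
            values = model.mean_r + np.asarray(d)
            reports.append(
                flag_abnormal(matrix_from_links(values, NODES4, f"p{i}"), model)
            )
        return reports

    def test_frequency_counts_patients_per_link(self):
        big = 5.0  # >> 2 SD
        reports = self._reports(
            [[-big, 0, 0, 0, 0, 0], [-big, 0, 0, 0, 0, 0], [0, -big, 0, 0, 0, 0]]
        )
        fmap = frequency_map(reports, reduced_only=True)
        assert fmap.counts[0] == 2 and fmap.counts[1] == 1
        assert np.all(fmap.counts <= fmap.n_patients)

    def test_empty_cohort_gives_all_zero_map(self):
        fmap = frequency_map([])
        assert fmap.counts.size == 0 and fmap.n_patients == 0

    def test_zero_variance_counts_report_degenerate_t(self):
        reports = self._reports([[-5, 0, 0, 0, 0, 0]] * 4)
        res = deficit_ttest(reports, null_mean=1.0)
        assert res.zero_variance and res.t == 0.0 and np.isnan(res.p)
        assert res.mean == 1.0

    def test_two_patient_hand_computation(self):
        reports = self._reports(
            [[-5, -5, 0, 0, 0, 0], [-5, -5, -5, -5, 0, 0]]
        )
        res = deficit_ttest(reports, null_mean=0.0)
        assert res.mean == pytest.approx(3.0)
        assert res.sd == pytest.approx(np.sqrt(2.0), abs=1e-9)

    def test_calibrated_null_mean_is_half_tail_times_links(self):
        model = fit_normative(_controls([[0.2] * 6, [0.4] * 6]))
        expected = 6 * 0.02275  # per-link one-sided 2-sigma tail
        assert calibrated_null_mean(model) == pytest.approx(expected, rel=1e-3)

    def test_identical_count_vectors_correlate_perfectly(self):
        reports = self._reports(
            [[-5, 0, 0, 0, 0, 0], [-5, -5, 0, 0, 0, 0], [-5, -5, -5, 0, 0, 0]]
        )
        names, r, p = network_correlations({"x": reports, "y": reports})
        assert r[0, 1] == pytest.approx(1.0)
        np.testing.assert_allclose(np.diag(r), 1.0)
        np.testing.assert_allclose(r, r.T)

    def test_too_few_patients_for_correlations(self):
        reports = self._reports([[0] * 6, [0] * 6])
        with pytest.raises(NormativeError):
            network_correlations({"x": reports, "y": reports})

    def test_mismatched_patient_sets_rejected(self):
        a = self._reports([[0] * 6, [0] * 6, [0] * 6])
        b = self._reports([[0] * 6, [0] * 6, [0] * 6])
        b[0].subject_id = "other"
        with pytest.raises(NormativeError):
            network_correlations({"x": a, "y": b})
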