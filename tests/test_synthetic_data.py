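import numpy as np
import pandas as pd
import pytest

from pulsebp import synthetic_data as sd
from pulsebp.errors import EmptySessionError, InvalidParameterError


class TestGenerateSubject:
    def test_deterministic_for_fixed_seed(self):
        assert sd.generate_subject(7) == sd.generate_subject(7)

    @pytest.mark.parametrize("seed", [0, 1, 5, 42, 1234])
    def test_age_within_study_range(self, seed):
        assert 13.0 <= sd.generate_subject(seed).age <= 18.0

    def test_bmi_is_weight_over_height_squared(self):
        profile = sd.SubjectProfile(
            subject_id="S",
            age=15.0,
            height=1.60,
            weight=51.2,
            arterial_path_length=0.8,
            baseline_dbp=75.0,
            baseline_sbp=120.0,
            coupling=sd._default_coupling(120.0, 75.0),
        )
        assert profile.bmi == pytest.approx(20.0, abs=1e-9)

    def test_physiological_invariants_enforced(self):
        with pytest.raises(InvalidParameterError):
            sd.SubjectProfile(
                subject_id="S",
                age=15.0,
                height=1.6,
                weight=50.0,
                arterial_path_length=0.8,
                baseline_dbp=120.0,
                baseline_sbp=75.0,  # SBP below DBP
                coupling=sd._default_coupling(75.0, 120.0),
            )


class TestGenerateSession:
    def test_bit_identical_for_fixed_inputs(self, subject):
        spec = sd.SessionSpec(state="rest", duration=20.0, seed=5)
        a = sd.generate_session(subject, spec)
        b = sd.generate_session(subject, spec)
        np.testing.assert_array_equal(a.ppg, b.ppg)
        np.testing.assert_array_equal(a.ecg, b.ecg)
        np.testing.assert_array_equal(a.abp, b.abp)
        pd.testing.assert_frame_equal(a.truth_beats, b.truth_beats)

    def test_truth_times_ordered_and_bp_consistent(self, rest_record):
        tb = rest_record.truth_beats
        assert (tb["r_time"].diff().dropna() > 0).all()
        assert (tb["ppg_onset_time"] > tb["r_time"]).all()
        assert (tb["ppg_peak_time"] > tb["ppg_onset_time"]).all()
        assert (tb["true_sbp"] > tb["true_dbp"]).all()
        assert rest_record.t.size == round(rest_record.spec.duration * rest_record.spec.fs)

    def test_noiseless_law_is_affine(self, subject):
        # with zero noise and zero interaction weight, SBP must be an exact
        # affine function of (1/PAT, AM, RR)
        coupling = {
            k: sd.LawCoefficients(
                intercept=v.intercept,
                slope_inv_pat=v.slope_inv_pat,
                slope_am=v.slope_am,
                slope_rr=v.slope_rr,
                interaction=0.0,
                pat_threshold=v.pat_threshold,
                noise_sd=0.0,
            )
            for k, v in subject.coupling.items()
        }
        profile = sd.SubjectProfile(
            subject_id="S-affine",
            age=subject.age,
            height=subject.height,
            weight=subject.weight,
            arterial_path_length=subject.arterial_path_length,
            baseline_dbp=subject.baseline_dbp,
            baseline_sbp=subject.baseline_sbp,
            coupling=coupling,
        )
        rec = sd.generate_session(profile, sd.SessionSpec(state="rest", duration=40.0, seed=9))
        tb = rec.truth_beats
        design = np.column_stack(
            [np.ones(len(tb)), 1.0 / tb["true_pat"], tb["amplitude"], tb["rr"]]
        )
        coef, *_ = np.linalg.lstsq(design, tb["true_sbp"].to_numpy(), rcond=None)
        resid = tb["true_sbp"].to_numpy() - design @ coef
        assert np.max(np.abs(resid)) < 1e-9

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_wbt_raises_mean_sbp(self, subject, seed):
        rest = sd.generate_session(subject, sd.SessionSpec(state="rest", duration=60.0, seed=seed))
        wbt = sd.generate_session(subject, sd.SessionSpec(state="wbt", duration=60.0, seed=seed))
        assert wbt.truth_beats["true_sbp"].mean() > rest.truth_beats["true_sbp"].mean()

    def test_too_short_session_rejected(self, subject):
        with pytest.raises(EmptySessionError):
            sd.generate_session(subject, sd.SessionSpec(state="rest", duration=1.0, seed=0))


class TestInjectArtifacts:
    def test_empty_spec_is_identity(self, rest_record):
        out = sd.inject_artifacts(rest_record, [])
        np.testing.assert_array_equal(out.ppg, rest_record.ppg)
        assert out.excluded_intervals == []

    def test_flat_line_has_zero_variance(self, rest_record):
        out = sd.inject_artifacts(
            rest_record, [sd.ArtifactSpec("flat_line", 10.0, 1.0, channel="ppg")]
        )
        fs = rest_record.fs
        window = out.ppg[int(10.0 * fs) : int(11.0 * fs)]
        assert np.ptp(window) == 0.0
        assert (10.0, 11.0) in [(round(a, 6), round(b, 6)) for a, b in out.excluded_intervals]
        # truth annotations must be untouched
        pd.testing.assert_frame_equal(out.truth_beats, rest_record.truth_beats)

    def test_flat_peak_caps_window_at_quantile(self, rest_record):
        fs = rest_record.fs
        pre = rest_record.ppg[int(20.0 * fs) : int(22.0 * fs)]
        out = sd.inject_artifacts(
            rest_record,
            [sd.ArtifactSpec("flat_peak", 20.0, 2.0, clip_quantile=0.95, channel="ppg")],
        )
        window = out.ppg[int(20.0 * fs) : int(22.0 * fs)]
        assert np.max(window) == pytest.approx(np.quantile(pre, 0.95), rel=1e-12)

    def test_out_of_range_artifact_warns_and_skips(self, rest_record):
        with pytest.warns(UserWarning):
            out = sd.inject_artifacts(
                rest_record, [sd.ArtifactSpec("flat_line", 1e6, 1.0, channel="ppg")]
            )
        np.testing.assert_array_equal(out.ppg, rest_record.ppg)


class TestGroundTruthBeatTable:
    def test_one_row_per_beat(self, rest_record):
        table = sd.ground_truth_beat_table(rest_record)
        assert len(table) == rest_record.n_beats

    def test_mbp_identity_rowwise(self, rest_record):
        table = sd.ground_truth_beat_table(rest_record)
        np.testing.assert_allclose(
            table["MBP"], (table["SBP"] + 2.0 * table["DBP"]) / 3.0, atol=1e-12
        )

    def test_noiseless_refit_recovers_law(self):
        # least squares on the noiseless interacting law recovers the
        # generating coefficients essentially exactly
        base = sd.generate_subject(4)
        coupling = {
            k: sd.LawCoefficients(
                intercept=v.intercept,
                slope_inv_pat=v.slope_inv_pat,
                slope_am=v.slope_am,
                slope_rr=v.slope_rr,
                interaction=v.interaction,
                pat_threshold=v.pat_threshold,
                noise_sd=0.0,
            )
            for k, v in base.coupling.items()
        }
        profile = sd.SubjectProfile(
            subject_id="S-noiseless",
            age=base.age,
            height=base.height,
            weight=base.weight,
            arterial_path_length=base.arterial_path_length,
            baseline_dbp=base.baseline_dbp,
            baseline_sbp=base.baseline_sbp,
            coupling=coupling,
        )
        rec = sd.generate_session(profile, sd.SessionSpec(state="rest", duration=60.0, seed=2))
        table = sd.ground_truth_beat_table(rec)
        law = coupling["sbp"]
        pat = table["true_pat"].to_numpy()
        design = np.column_stack(
            [
                np.ones(len(table)),
                1.0 / pat,
                table["amplitude"],
                table["rr"],
                (pat < law.pat_threshold) * table["amplitude"],
            ]
        )
        coef, *_ = np.linalg.lstsq(design, table["SBP"].to_numpy(), rcond=None)
        expected = [
            law.intercept,
            law.slope_inv_pat,
            law.slope_am,
            law.slope_rr,
            law.interaction,
        ]
        np.testing.assert_allclose(coef, expected, atol=1e-6)


class TestRoundTrip:
    def test_write_read_record(self, subject, tmp_path):
        rec = sd.generate_session(subject, sd.SessionSpec(state="wbt", duration=15.0, seed=8))
        sd.write_record(rec, tmp_path / "rec")
        back = sd.read_record(tmp_path / "rec")
        np.testing.assert_allclose(back.ppg, rec.ppg, atol=1e-6)
        assert back.spec == rec.spec
        assert back.profile.subject_id == rec.profile.subject_id
        pd.testing.assert_frame_equal(
            back.truth_beats, rec.truth_beats, check_exact=False, rtol=1e-12
        )
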