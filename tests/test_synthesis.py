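"""Record synthesis: noise classes, defocus model, calibration sets, file IO."""

import numpy as np
import pytest

from rbscreen import (
    EyeOptics,
    FocusState,
    NoiseSpec,
    defocus_split,
    effective_defocus,
    phss,
    read_record,
    synthesize_record,
    write_record,
)
from rbscreen.focus import focus_goodness
from rbscreen.synthesis import (
    DEFAULT_BLUR_SCALE_D,
    annulus_fraction_at_goodness,
    make_calibration_set,
)


class TestEffectiveDefocus:
    def test_cyclopleged_best_focus_arithmetic(self):
        # +1.00 D cycloplegic refraction, target at 33.3 cm (3.00 D):
        # +4.00 D of trial lens puts the eye in focus
        f = FocusState(stimulus_vergence_D=3.0, refraction_D=1.0,
                       lens_power_D=4.0, cyclopleged=True)
        assert effective_defocus(f) == pytest.approx(0.0)

    def test_tonic_accommodation_shifts_best_focus(self):
        # +0.75 D of unrelaxable tonic tone: only +3.25 D of lens needed
        f = FocusState(stimulus_vergence_D=3.0, refraction_D=1.0,
                       lens_power_D=3.25, tonic_D=0.75)
        assert effective_defocus(f) == pytest.approx(0.0)

    def test_all_zero(self):
        assert effective_defocus(
            FocusState(stimulus_vergence_D=0.0)
        ) == pytest.approx(0.0)


class TestDefocusSplit:
    def test_best_focus_floor(self):
        assert defocus_split(0.0) <= 0.01

    def test_even_function(self):
        assert defocus_split(1.0) == pytest.approx(defocus_split(-1.0))

    def test_monotone_in_blur(self):
        d = np.linspace(0, 4, 30)
        f = np.array([defocus_split(x) for x in d])
        assert (np.diff(f) > 0).all() and f[-1] < 1.0

    def test_goodness_threshold_arithmetic(self):
        # splitting 17.5 % of the light onto the annulus puts the direct
        # intensity statistic exactly at the 0.65 pass level
        assert focus_goodness(1 - 0.175, 0.175) == pytest.approx(0.65)

    def test_power_split_inversion(self):
        # channel powers go as the squared amplitude split; the fraction at
        # which the pipeline statistic reads 0.65 solves a quadratic
        f = annulus_fraction_at_goodness(0.65)
        C, A = (1 - f) ** 2, f**2
        assert focus_goodness(C, A) == pytest.approx(0.65, abs=1e-12)
        # blur scale is calibrated so this happens at 1.0 D of defocus
        assert defocus_split(1.0, DEFAULT_BLUR_SCALE_D) == pytest.approx(f, abs=1e-12)


class TestSynthesizeRecord:
    def test_shape_and_determinism(self, cfg):
        eyes = (EyeOptics(), EyeOptics())
        r1 = synthesize_record(eyes, cfg=cfg, seed=5)
        r2 = synthesize_record(eyes, cfg=cfg, seed=5)
        assert r1.samples.shape == (4, 6000)
        np.testing.assert_array_equal(r1.samples, r2.samples)
        r3 = synthesize_record(eyes, cfg=cfg, seed=6)
        assert np.abs(r1.samples - r3.samples).max() > 0

    def test_silent_eyes_and_no_noise_give_zero(self, cfg):
        eye = EyeOptics(corneal_retardance_deg=0.0, henle_retardance_deg=0.0,
                        depolarized_fraction=0.0)
        rec = synthesize_record(
            (eye, eye), noise=NoiseSpec(0.0, 0, 0.0, 0.0), cfg=cfg, seed=0
        )
        assert np.abs(rec.samples).max() < 1e-12

    def test_noise_only_record_annihilated_by_phss(self, cfg):
        # background + line interference, no white noise, no signal:
        # both repeat over one scan period, so PhSS removes them exactly
        eye = EyeOptics(corneal_retardance_deg=0.0, henle_retardance_deg=0.0,
                        depolarized_fraction=0.0)
        noise = NoiseSpec(background_amp=1.0, background_harmonics=6,
                          line_amp=0.5, white_sigma=0.0)
        rec = synthesize_record((eye, eye), noise=noise, cfg=cfg, seed=3)
        residual = phss(rec).samples
        assert np.abs(residual).max() <= 1e-9 * np.abs(rec.samples).max()

    def test_center_plus_annulus_recovers_signal_share(self, cfg):
        # without noise, center and annulus of one eye sum to the full
        # polarization signal regardless of the defocus split
        eye = EyeOptics()
        quiet = NoiseSpec(0.0, 0, 0.0, 0.0)
        focused = synthesize_record((eye, eye), cfg=cfg, noise=quiet, seed=1)
        blurred = synthesize_record(
            (eye, eye),
            focus=(FocusState(stimulus_vergence_D=1.2, cyclopleged=True),) * 2,
            cfg=cfg, noise=quiet, seed=1,
        )
        np.testing.assert_allclose(
            focused.samples[0] + focused.samples[1],
            blurred.samples[0] + blurred.samples[1],
            atol=1e-12,
        )


class TestCalibrationSet:
    def test_structure_and_labels(self, calibration_frame):
        counts = calibration_frame.label.value_counts()
        assert counts["CF"] == 120
        assert counts["paraCF"] == 480
        assert calibration_frame.label.isin(["CF", "paraCF"]).all()

    def test_single_subject_counts(self):
        df = make_calibration_set(n_subjects=1, seed=0, records_per_condition=2)
        assert (df.label == "CF").sum() == 4  # 2 records x 2 eyes

    def test_feature_separation_gate(self, calibration_frame):
        med_cf = calibration_frame.loc[calibration_frame.label == "CF", "r_cf"].median()
        med_para = calibration_frame.loc[
            calibration_frame.label == "paraCF", "r_cf"
        ].median()
        assert med_cf > 3 * med_para


class TestRecordIO:
    def test_round_trip(self, cfg, tmp_path):
        eyes = (EyeOptics(), EyeOptics(fixation_offset_deg=(1.5, 0.0)))
        rec = synthesize_record(eyes, cfg=cfg, seed=9,
                                meta={"subject": 1, "record": 4})
        path = write_record(rec, tmp_path / "rec.csv")
        back = read_record(path)
        np.testing.assert_allclose(back.samples, rec.samples, atol=1e-12)
        assert back.cfg == rec.cfg
        assert back.meta == rec.meta
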