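"""Forward simulator: dose-response models, noise statistics, cohorts,
membrane rendering."""

import io

import numpy as np
import pytest

from vfaquant import (
    GeneratorConfig, POWER_MODELS, REPORTING_LIMITS, TrueSample,
    calibration_signals, cohort_frame, default_spotmap, forward_signal,
    population_cv_from_triplicate_cv, render_membrane_pair, sample_cohort,
    simulate_features,
)
from vfaquant.layout import CKMB, CTNI, NTPROBNP


class TestForwardSignal:
    @pytest.mark.parametrize("biomarker,modality", list(POWER_MODELS))
    def test_matches_power_law_below_saturation(self, biomarker, modality):
        a, k = POWER_MODELS[(biomarker, modality)]
        # below any saturation the signal is the pure power law
        conc = 100.0
        assert forward_signal(conc, biomarker, modality) == pytest.approx(
            a * conc ** k, rel=0.02)

    def test_ckmb_printed_model_value(self):
        # 0.0002 * (1e4)**0.6901 evaluated directly
        assert forward_signal(1e4, CKMB, "Color") == pytest.approx(0.1152, abs=5e-4)

    def test_zero_conc_returns_blank_baseline(self, config):
        for b, m in POWER_MODELS:
            assert forward_signal(0.0, b, m, config=config) == \
                config.blank_baseline[m]

    def test_unsupported_pair_rejected(self):
        with pytest.raises(ValueError, match="unsupported"):
            forward_signal(10.0, CKMB, "CL")

    def test_negative_conc_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            forward_signal(-1.0, CKMB, "Color")

    @pytest.mark.parametrize("biomarker,modality", list(POWER_MODELS))
    def test_noise_free_monotone_pre_saturation(self, biomarker, modality):
        grid = np.logspace(0, 3.9, 40)  # below the 1e4 CL plateau onset
        vals = [forward_signal(c, biomarker, modality) for c in grid]
        assert np.all(np.diff(vals) > 0)

    def test_cl_saturates_while_colorimetric_increases(self, config):
        a, k = POWER_MODELS[(CTNI, "CL")]
        plateau = a * config.cl_saturation_onset ** k
        d = forward_signal(1e6, CTNI, "CL") - forward_signal(1e5, CTNI, "CL")
        assert 0 < d < 0.05 * plateau
        assert forward_signal(1e6, CTNI, "Color") > forward_signal(1e5, CTNI, "Color")

    def test_replicate_cv_converges_to_configured(self, config, rng):
        cv_cfg = config.replicate_cv_pct[CKMB]
        n = 10_000
        vals = np.array([forward_signal(1e4, CKMB, "Color", noise_on=True,
                                        config=config, rng=rng)
                         for _ in range(n)])
        cv_emp = 100.0 * vals.std(ddof=1) / vals.mean()
        se = cv_cfg / np.sqrt(2 * n)
        assert abs(cv_emp - cv_cfg) < 3 * se

    def test_triplicate_protocol_mean_cv_matches_reported(self, config):
        # the population CV defaults are debiased so that the 3-replicate
        # sample CV averages to the reported value (c4 correction)
        rng = np.random.default_rng(5)
        cvs = []
        for _ in range(400):
            df = calibration_signals(CKMB, "Color", config, rng=rng)
            per_conc = df.groupby("conc")["signal"].apply(
                lambda s: 100 * s.std(ddof=1) / s.mean())
            cvs.append(per_conc.mean())
        assert np.mean(cvs) == pytest.approx(3.0, abs=0.15)

    def test_population_cv_debias_factor(self):
        # c4(3) = sqrt(pi)/2
        assert population_cv_from_triplicate_cv(3.0) == pytest.approx(
            3.0 / (np.sqrt(np.pi) / 2))


class TestCohort:
    def test_duplicates_share_concentrations(self):
        cfg = GeneratorConfig(seed=1, n_patients=1, duplicates_per_sample=2)
        samples = sample_cohort(cfg)
        assert len(samples) == 2
        assert samples[0].conc == samples[1].conc
        assert samples[0].patient_id == samples[1].patient_id
        assert samples[0].matrix_factor == samples[1].matrix_factor

    def test_seeding_contract(self):
        a = cohort_frame(sample_cohort(GeneratorConfig(seed=4, n_patients=10)))
        b = cohort_frame(sample_cohort(GeneratorConfig(seed=4, n_patients=10)))
        c = cohort_frame(sample_cohort(GeneratorConfig(seed=5, n_patients=10)))
        assert a.equals(b)
        assert not a.equals(c)

    def test_csv_byte_identical_under_fixed_seed(self):
        def dump(seed):
            buf = io.StringIO()
            cohort_frame(sample_cohort(GeneratorConfig(seed=seed, n_patients=8))
                         ).to_csv(buf, index=False)
            return buf.getvalue()
        assert dump(9) == dump(9)

    def test_censored_fraction_matches_cohort_composition(self):
        # expected censored cTnI fraction is 20/92; binomial check at large n
        cfg = GeneratorConfig(seed=2, n_patients=3000, duplicates_per_sample=1)
        truth = cohort_frame(sample_cohort(cfg))
        p = 20 / 92
        se = np.sqrt(p * (1 - p) / 3000)
        assert abs(truth["cTnI_censored"].mean() - p) < 3 * se

    def test_censored_implies_below_limit(self):
        truth = cohort_frame(sample_cohort(GeneratorConfig(seed=3, n_patients=200)))
        for b, limit in REPORTING_LIMITS.items():
            flagged = truth[truth[f"{b}_censored"]]
            assert (flagged[b] < limit).all()
            assert (truth[b] >= 0).all()

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError, match="fraction"):
            GeneratorConfig(below_limit_frac={CTNI: 1.5, CKMB: 0.5,
                                              NTPROBNP: 0.5})


class TestRendering:
    def _blank_sample(self):
        zeros = {b: 0.0 for b in REPORTING_LIMITS}
        return TrueSample("blank", 1, 1, zeros, {b: True for b in zeros}, 1.0)

    def test_all_zero_sample_rois_match_background(self):
        cfg = GeneratorConfig(seed=6, blank_baseline={"Color": 0.0, "CL": 0.0},
                              pos_ctrl_signal={"Color": 0.0, "CL": 0.0})
        sm = default_spotmap(cfg.image_size)
        bg, assay = render_membrane_pair(self._blank_sample(), sm, "Color", cfg)
        bg_level = cfg.background_level * 255
        for spot in sm.spots:
            rr, cc = np.ogrid[:bg.shape[0], :bg.shape[1]]
            mask = (rr - spot.center_xy[0]) ** 2 + (cc - spot.center_xy[1]) ** 2 \
                <= sm.roi_radius_px ** 2
            assert assay[..., 1][mask].mean() == pytest.approx(
                bg_level, abs=2 * cfg.pixel_noise_sd)

    def test_contrast_confined_to_modality_channel(self, config):
        sm = default_spotmap(config.image_size)
        rng = config.rng()
        sample = sample_cohort(GeneratorConfig(seed=8, n_patients=1))[0]
        for modality, ch in (("Color", 1), ("CL", 2)):
            bg, assay = render_membrane_pair(sample, sm, modality, config, rng)
            pos = sm.spots_for("posCtrl")[0]
            rr, cc = np.ogrid[:bg.shape[0], :bg.shape[1]]
            mask = (rr - pos.center_xy[0]) ** 2 + (cc - pos.center_xy[1]) ** 2 \
                <= sm.roi_radius_px ** 2
            deficit = {c: bg[..., c][mask].mean() - assay[..., c][mask].mean()
                       for c in range(3)}
            assert deficit[ch] > 50  # strong positive-control contrast
            for c in set(range(3)) - {ch}:
                assert abs(deficit[c]) < 2  # other channels untouched

    def test_too_small_image_rejected(self, config):
        sm = default_spotmap(config.image_size)
        sample = self._blank_sample()
        with pytest.raises(ValueError, match="too small"):
            render_membrane_pair(sample, sm, "Color", config,
                                 offset=(200, 0))


def test_simulate_features_has_ten_signal_columns(small_cohort_tables):
    features, truth = small_cohort_tables
    signal_cols = [c for c in features.columns if c.startswith("X_")]
    assert len(signal_cols) == 10
    assert len(features) == len(truth)
    assert (features[signal_cols].to_numpy() < 1.0).all()
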