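"""Image registration, ROI measurement, Eq.-style normalisation and
alike-spot averaging."""

import logging

import numpy as np
import pandas as pd
import pytest

from vfaquant import (GeneratorConfig, default_spotmap, render_membrane_pair,
                      sample_cohort)
from vfaquant.extraction import (
    IncompleteCartridgeError, InvalidBackgroundError, aggregate_conditions,
    extract_features, locate_spots, measure_intensities, normalize_signal,
)
from vfaquant.layout import CONDITIONS, FEATURE_COLUMNS, feature_column
from vfaquant.synth import TrueSample, forward_signal, REPORTING_LIMITS


@pytest.mark.parametrize("s,b,expected", [
    (100.0, 100.0, 0.0),
    (50.0, 100.0, 0.5),
    (110.0, 100.0, -0.1),   # negative absorption retained, not clipped
])
def test_normalize_signal(s, b, expected):
    assert normalize_signal(s, b) == pytest.approx(expected)


def test_normalize_rejects_nonpositive_background():
    with pytest.raises(InvalidBackgroundError):
        normalize_signal(1.0, 0.0)


class TestMeasure:
    def test_uniform_image_mean(self):
        sm = default_spotmap(256)
        img = np.full((256, 256, 3), 100, dtype=np.uint8)
        rois, _ = locate_spots(img, img, sm)
        table = measure_intensities(img, img, rois, "Color")
        assert np.allclose(table["s"], 100.0)
        assert len(table) == 16

    def test_half_and_half_roi_mean(self):
        sm = default_spotmap(256)
        img = np.full((256, 256, 3), 100, dtype=np.uint8)
        rois, _ = locate_spots(img, img, sm)
        roi0 = rois[0]
        rr, cc = np.ogrid[:256, :256]
        mask = (rr - roi0.center_xy[0]) ** 2 + (cc - roi0.center_xy[1]) ** 2 \
            <= roi0.radius_px ** 2
        idx = np.argwhere(mask)
        half = img.copy()
        for r, c in idx[: len(idx) // 2]:      # exactly half the ROI pixels
            half[r, c, :] = 200
        table = measure_intensities(img, half, [roi0], "Color")
        want = 100 + 100 * (len(idx) // 2) / len(idx)
        assert table["s"].iloc[0] == pytest.approx(want, abs=1e-9)
        assert want == pytest.approx(150.0, abs=0.5)


class TestRegistration:
    def _render(self, offset):
        cfg = GeneratorConfig(seed=17, n_patients=1)
        rng = cfg.rng()
        sample = sample_cohort(cfg, rng)[0]
        sm = default_spotmap(cfg.image_size)
        return (*render_membrane_pair(sample, sm, "Color", cfg, rng,
                                      offset=offset), sm)

    def test_zero_offset_recovered(self):
        bg, assay, sm = self._render((0, 0))
        _, shift = locate_spots(bg, assay, sm)
        assert shift == (0, 0)

    def test_known_offset_recovered(self):
        bg, assay, sm = self._render((3, -2))
        rois, shift = locate_spots(bg, assay, sm)
        assert shift == (3, -2)
        assert rois[0].center_xy == (sm.spots[0].center_xy[0] + 3,
                                     sm.spots[0].center_xy[1] - 2)

    def test_blank_image_falls_back_to_nominal_grid(self, caplog):
        cfg = GeneratorConfig(seed=17, blank_baseline={"Color": 0.0, "CL": 0.0},
                              pos_ctrl_signal={"Color": 0.0, "CL": 0.0})
        zeros = {b: 0.0 for b in REPORTING_LIMITS}
        sample = TrueSample("b", 1, 1, zeros, {b: True for b in zeros}, 1.0)
        sm = default_spotmap(cfg.image_size)
        bg, assay = render_membrane_pair(sample, sm, "Color", cfg)
        with caplog.at_level(logging.WARNING, logger="vfaquant.extraction"):
            _, shift = locate_spots(bg, assay, sm)
        assert shift == (0, 0)
        assert any("falling back" in r.message for r in caplog.records)


class TestAggregate:
    def _table(self, values_by_cond):
        rows = []
        for m in ("Color", "CL"):
            for cond in CONDITIONS:
                for j, x in enumerate(values_by_cond.get((cond, m), [0.0])):
                    rows.append({"condition": cond, "modality": m,
                                 "s": (1 - x) * 100.0, "b": 100.0,
                                 "spot_id": j})
        return pd.DataFrame(rows)

    def test_mean_of_repeats(self):
        table = self._table({("cTnI", "Color"): [0.10, 0.12, 0.11, 0.11]})
        fv = aggregate_conditions(table, "c1")
        assert fv[feature_column("cTnI", "Color")] == pytest.approx(0.11)

    def test_exactly_ten_entries(self):
        fv = aggregate_conditions(self._table({}), "c1")
        assert sorted(k for k in fv.index if k.startswith("X_")) == \
            sorted(FEATURE_COLUMNS)

    def test_permutation_invariance(self):
        t1 = self._table({("cTnI", "Color"): [0.1, 0.2, 0.3]})
        t2 = t1.iloc[::-1].reset_index(drop=True)
        pd.testing.assert_series_equal(aggregate_conditions(t1, "c"),
                                       aggregate_conditions(t2, "c"))

    def test_missing_condition_rejected(self):
        table = self._table({})
        table = table[table["condition"] != "posCtrl"]
        with pytest.raises(IncompleteCartridgeError):
            aggregate_conditions(table, "c1")


def test_render_extract_round_trip_within_pixel_noise():
    """Extracted averaged signals recover the programmed cartridge-level
    signals to within ~2 SDs of the ROI-mean pixel noise."""
    cfg = GeneratorConfig(seed=29, n_patients=10, spot_cv_pct=1e-9,
                          replicate_cv_pct={"cTnI": 1e-9, "CK-MB": 1e-9,
                                            "NT-proBNP": 1e-9},
                          control_cv_pct=1e-9, matrix_cv_pct=1e-9)
    rng = cfg.rng()
    samples = sample_cohort(cfg, rng)[:10]
    sm = default_spotmap(cfg.image_size)
    bg_level = cfg.background_level * 255
    n_px = np.pi * sm.roi_radius_px ** 2
    # 1 - s/b with independent pixel noise on both images; quantisation adds
    # ~0.29 DN per pixel
    sd_pix = np.sqrt(cfg.pixel_noise_sd ** 2 + 0.29 ** 2)
    sd_xbar = np.sqrt(2) * sd_pix / (bg_level * np.sqrt(n_px))
    errs = []
    for sample in samples:
        imgs = {m: render_membrane_pair(sample, sm, m, cfg, rng)
                for m in ("Color", "CL")}
        fv = extract_features(imgs["Color"][0], imgs["Color"][1],
                              imgs["CL"][0], imgs["CL"][1], sm, sample.sample_id)
        for m in ("Color", "CL"):
            for cond in ("cTnI", "CK-MB", "NT-proBNP"):
                if (cond, m) in cfg.power_models:
                    want = forward_signal(sample.conc[cond], cond, m, config=cfg)
                    got = fv[feature_column(cond, m)]
                    errs.append(abs(got - want))
    assert np.mean(errs) < 2 * sd_xbar
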