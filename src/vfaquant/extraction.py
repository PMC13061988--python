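"""From image pairs (or raw spot tables) to per-cartridge feature vectors.

The measurement chain is: register the assay image against the known wax
layout (rigid integer-pixel shift), average pixels in each circular ROI on
the modality's channel (green for colorimetric, blue for CL), normalise by
the pre-assay background image,

    X = 1 - s / b,

and average alike spots within each immunoreaction condition, yielding the
ten-element feature vector (5 conditions x 2 modalities).  Negative X
values (s > b) are retained so QC and the downstream models see the raw
distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .layout import (
    CONDITIONS, CONDITION_MULTIPLICITY, MODALITIES, SpotMap, feature_column,
)

logger = logging.getLogger(__name__)

_CHANNEL = {"Color": 1, "CL": 2}  # green / blue


class SegmentationError(RuntimeError):
    """Registration shift exceeded the configured bound."""


class InvalidBackgroundError(ValueError):
    """Background intensity b <= 0 cannot normalise a signal."""


class IncompleteCartridgeError(ValueError):
    """A condition has no valid spot to average."""


@dataclass(frozen=True)
class ROI:
    spot_id: int
    condition: str
    center_xy: tuple[int, int]
    radius_px: float


def _disk_mask(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def _absorption_image(bg: np.ndarray, assay: np.ndarray, modality: str) -> np.ndarray:
    ch = _CHANNEL[modality]
    b = bg[..., ch].astype(float)
    s = assay[..., ch].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = 1.0 - s / b
    return np.nan_to_num(a, nan=0.0, posinf=0.0, neginf=0.0)


def locate_spots(bg: np.ndarray, assay: np.ndarray, spotmap: SpotMap,
                 modality: str = "Color", max_shift: int = 8,
                 min_mean_absorption: float = 0.01) -> tuple[list[ROI], tuple[int, int]]:
    """Register the layout template and return measurement ROIs.

    The absorption image ``1 - assay/bg`` is scored against the nominal
    disk template over all integer shifts within ``max_shift``; the argmax
    shift wins.  If even the best shift accumulates less absorption than
    ``min_mean_absorption`` per template pixel (e.g. a blank membrane with
    no control signal), registration falls back to the nominal grid with a
    logged warning.  The positive-control spots guarantee signal on any
    valid assay, so the fallback indicates a degenerate input.
    """
    a = _absorption_image(bg, assay, modality)
    shape = a.shape
    # register with full printed-radius disks (a matched filter with a
    # unique optimum); the shrunken ROI alone would tie across small shifts
    masks = [_disk_mask(shape, s.center_xy, s.radius_px)
             for s in spotmap.spots]
    template_area = int(sum(m.sum() for m in masks))

    best_score, best_shift = -np.inf, (0, 0)
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            shifted = np.roll(np.roll(a, -dy, axis=0), -dx, axis=1)
            score = sum(float(shifted[m].sum()) for m in masks)
            if score > best_score:
                best_score, best_shift = score, (dy, dx)

    if best_score < min_mean_absorption * template_area:
        logger.warning(
            "registration found no spot signal (best score %.3g); "
            "falling back to nominal grid", best_score)
        best_shift = (0, 0)
    dy, dx = best_shift
    rois = [ROI(s.spot_id, s.condition,
                (s.center_xy[0] + dy, s.center_xy[1] + dx),
                spotmap.roi_radius_px)
            for s in spotmap.spots]
    for r in rois:
        if not (r.radius_px <= r.center_xy[0] < shape[0] - r.radius_px
                and r.radius_px <= r.center_xy[1] < shape[1] - r.radius_px):
            raise SegmentationError(f"ROI {r.spot_id} outside image after shift {best_shift}")
    return rois, best_shift


def measure_intensities(bg: np.ndarray, assay: np.ndarray, rois: list[ROI],
                        modality: str) -> pd.DataFrame:
    """Mean ROI intensities s (assay) and b (background) on the modality channel."""
    if bg.shape != assay.shape:
        raise ValueError("background and assay images must share a shape")
    ch = _CHANNEL[modality]
    rows = []
    for roi in rois:
        mask = _disk_mask(bg.shape[:2], roi.center_xy, roi.radius_px)
        if not mask.any():
            raise ValueError(f"ROI {roi.spot_id} outside image bounds")
        rows.append({"spot_id": roi.spot_id, "condition": roi.condition,
                     "modality": modality,
                     "s": float(assay[..., ch][mask].mean()),
                     "b": float(bg[..., ch][mask].mean())})
    return pd.DataFrame(rows)


def normalize_signal(s: float, b: float) -> float:
    """Absorption signal X = 1 - s/b; negative values are retained."""
    if b <= 0:
        raise InvalidBackgroundError(f"background intensity must be > 0, got {b}")
    return 1.0 - s / b


def aggregate_conditions(spot_table: pd.DataFrame,
                         cartridge_id: str = "") -> pd.Series:
    """Average alike spots into the ten-element feature vector.

    ``spot_table`` needs columns condition, modality, s, b (both modalities
    present).  Returns a Series with the ten ``X_<cond>_<modality>`` entries
    plus ``cartridge_id``.
    """
    out: dict[str, object] = {"cartridge_id": cartridge_id}
    for modality in MODALITIES:
        sub = spot_table[spot_table["modality"] == modality]
        for condition in CONDITIONS:
            rows = sub[sub["condition"] == condition]
            if len(rows) == 0:
                raise IncompleteCartridgeError(
                    f"no spots for condition {condition} / {modality}")
            x = [normalize_signal(s, b) for s, b in zip(rows["s"], rows["b"])]
            out[feature_column(condition, modality)] = float(np.mean(x))
    return pd.Series(out)


def extract_features(bg_color: np.ndarray, assay_color: np.ndarray,
                     bg_cl: np.ndarray, assay_cl: np.ndarray,
                     spotmap: SpotMap, cartridge_id: str = "",
                     max_shift: int = 8) -> pd.Series:
    """Full image-pair route: register, measure, normalise, aggregate."""
    tables = []
    for bg, assay, modality in ((bg_color, assay_color, "Color"),
                                (bg_cl, assay_cl, "CL")):
        rois, _ = locate_spots(bg, assay, spotmap, modality, max_shift=max_shift)
        tables.append(measure_intensities(bg, assay, rois, modality))
    return aggregate_conditions(pd.concat(tables, ignore_index=True), cartridge_id)


def features_from_spot_table(table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a per-spot CSV (cartridge_id, spot_id, condition, modality, s, b)."""
    rows = [aggregate_conditions(grp, cartridge_id=cid)
            for cid, grp in table.groupby("cartridge_id", sort=True)]
    return pd.DataFrame(rows).reset_index(drop=True)
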