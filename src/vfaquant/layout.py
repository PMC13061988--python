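"""Geometric and semantic layout of the sensing membrane.

The membrane carries 16 reaction spots on a 4x4 grid plus one non-reaction
vent spot.  Each reaction spot is coated for one immunoreaction condition:
four cTnI spots, three CK-MB, three NT-proBNP, two positive-control spots
(anti-detection-antibody IgG, a universal signal) and four negative-control
spots (buffer only, baseline).  The layout is fixed by cartridge fabrication,
so downstream segmentation registers images against this template rather
than detecting blobs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Canonical condition identifiers used across the package.
CTNI = "cTnI"
CKMB = "CK-MB"
NTPROBNP = "NT-proBNP"
POS_CTRL = "posCtrl"
NEG_CTRL = "negCtrl"

CONDITIONS = (CTNI, CKMB, NTPROBNP, POS_CTRL, NEG_CTRL)
MODALITIES = ("Color", "CL")

#: Required number of spot repeats per condition.
CONDITION_MULTIPLICITY = {CTNI: 4, CKMB: 3, NTPROBNP: 3, POS_CTRL: 2, NEG_CTRL: 4}


@dataclass(frozen=True)
class Spot:
    spot_id: int          # 1..16
    row: int              # 0..3 grid row
    col: int              # 0..3 grid column
    center_xy: tuple[int, int]  # (row_px, col_px), origin top-left, 0-based
    radius_px: float      # printed spot radius in pixels
    condition: str


@dataclass(frozen=True)
class SpotMap:
    """Layout of the 16 reaction spots plus the vent spot.

    ``roi_fraction`` shrinks the measurement ROI relative to the printed
    spot radius so wax-edge pixels are excluded from intensity averaging.
    """

    spots: tuple[Spot, ...]
    vent_xy: tuple[int, int]
    vent_radius_px: float
    image_shape: tuple[int, int]
    roi_fraction: float = 0.7

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(self.spots) != 16:
            raise ValueError(f"expected 16 reaction spots, got {len(self.spots)}")
        counts: dict[str, int] = {}
        for s in self.spots:
            counts[s.condition] = counts.get(s.condition, 0) + 1
        if counts != CONDITION_MULTIPLICITY:
            raise ValueError(
                f"condition multiplicities {counts} != required {CONDITION_MULTIPLICITY}"
            )
        # pairwise disjoint ROIs (full printed radius, conservative)
        for i, a in enumerate(self.spots):
            for b in self.spots[i + 1:]:
                d = np.hypot(a.center_xy[0] - b.center_xy[0],
                             a.center_xy[1] - b.center_xy[1])
                if d < a.radius_px + b.radius_px:
                    raise ValueError(f"spots {a.spot_id} and {b.spot_id} overlap")

    @property
    def roi_radius_px(self) -> float:
        return self.spots[0].radius_px * self.roi_fraction

    def spots_for(self, condition: str) -> tuple[Spot, ...]:
        return tuple(s for s in self.spots if s.condition == condition)


# Default assignment of conditions to the 4x4 grid (row-major).  The vent
# sits outside the grid in the lower-right margin.
_DEFAULT_GRID = (
    CTNI, CTNI, CTNI, CTNI,
    CKMB, CKMB, CKMB, POS_CTRL,
    NTPROBNP, NTPROBNP, NTPROBNP, POS_CTRL,
    NEG_CTRL, NEG_CTRL, NEG_CTRL, NEG_CTRL,
)


def default_spotmap(image_size: int = 256, spot_radius_px: float = 14.0,
                    pitch_px: int = 52, margin_px: int = 42) -> SpotMap:
    """Build the default 4x4 layout centered in a square image."""
    spots = []
    for idx, cond in enumerate(_DEFAULT_GRID):
        r, c = divmod(idx, 4)
        center = (margin_px + r * pitch_px, margin_px + c * pitch_px)
        spots.append(Spot(spot_id=idx + 1, row=r, col=c, center_xy=center,
                          radius_px=spot_radius_px, condition=cond))
    vent = (image_size - 22, image_size - 22)
    return SpotMap(spots=tuple(spots), vent_xy=vent, vent_radius_px=8.0,
                   image_shape=(image_size, image_size))


def feature_column(condition: str, modality: str) -> str:
    """Column name for an averaged absorption signal, e.g. ``X_cTnI_CL``."""
    return f"X_{condition}_{modality}"


#: The ten averaged-signal columns (5 conditions x 2 modalities).
FEATURE_COLUMNS = tuple(
    feature_column(c, m) for m in MODALITIES for c in CONDITIONS
)
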