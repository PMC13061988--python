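"""Synthetic cohorts, dual-mode spot signals, and rendered membrane images.

This module forward-simulates the assay so that every downstream stage
(extraction, QC, calibration, cascade training) can be exercised without
patient data.  The signal model is the dose-response structure observed for
the three cardiac biomarkers:

* colorimetric CK-MB, NT-proBNP and cTnI signals follow power laws
  ``y = a * conc**k`` over their calibration ranges;
* the chemiluminescent (CL) cTnI channel follows its power law at low
  concentration and saturates above ~1e4 pg/mL (modelled with a
  generalised-Hill soft plateau, see :func:`forward_signal`);
* replicate (cartridge-to-cartridge) variability is multiplicative
  lognormal noise with a configured coefficient of variation;
* each patient sample carries one lognormal matrix-effect factor shared by
  every spot of both duplicate cartridges, mimicking serum-composition
  effects;
* positive-control spots produce a fixed high signal, negative controls sit
  at the blank baseline.

Noise parameterisation
----------------------
Replicate variability in assay studies is conventionally reported as the
mean sample CV of triplicates.  The sample standard deviation of n=3 draws
underestimates the population sigma by the factor c4(3) = sqrt(pi)/2, so a
generator whose *population* CV equalled the reported number would produce
triplicate CVs ~11% too small.  ``GeneratorConfig`` therefore stores
population CVs, and :func:`population_cv_from_triplicate_cv` converts a
reported triplicate CV into the population value; the defaults are the
reported per-biomarker CVs (3.0%, 1.5%, 4.5%) passed through that
conversion, so the simulated triplicate protocol reproduces the reported
numbers in expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .layout import (
    CKMB, CTNI, MODALITIES, NEG_CTRL, NTPROBNP, POS_CTRL,
    SpotMap, default_spotmap, feature_column,
)

__all__ = [
    "POWER_MODELS", "REPORTED_TRIPLICATE_CV", "REPORTING_LIMITS",
    "CALIBRATION_GRIDS", "GeneratorConfig", "TrueSample",
    "population_cv_from_triplicate_cv", "sample_cohort", "cohort_frame",
    "forward_signal", "calibration_signals", "simulate_features",
    "render_membrane_pair",
]

#: Power-law dose-response models (prefactor a, exponent k) per
#: (biomarker, modality), signal = a * conc**k on each assay's range.
POWER_MODELS: dict[tuple[str, str], tuple[float, float]] = {
    (CKMB, "Color"): (0.0002, 0.6901),
    (NTPROBNP, "Color"): (0.0001, 0.6752),
    (CTNI, "CL"): (0.0742, 0.2744),
    (CTNI, "Color"): (0.0179, 0.2739),
}

#: Reported mean triplicate CVs (%) per biomarker (colorimetric for CK-MB
#: and NT-proBNP, CL for cTnI).
REPORTED_TRIPLICATE_CV = {CKMB: 3.0, NTPROBNP: 1.5, CTNI: 4.5}

#: Reference-assay reporting limits in pg/mL; ground truth below these is
#: left-censored ("< limit").
REPORTING_LIMITS = {CTNI: 4.0, CKMB: 50.0, NTPROBNP: 10.0}

#: Spiked calibration concentration grids (pg/mL), log-spaced over each
#: assay's quantifiable span.
CALIBRATION_GRIDS = {
    CKMB: tuple(np.logspace(np.log10(500.0), 5, 8)),
    NTPROBNP: tuple(np.logspace(np.log10(40.0), np.log10(4.0e4), 8)),
    CTNI: tuple(np.logspace(0, 6, 10)),
}

# Expected sample-SD bias of n i.i.d. normal draws: E[s] = c4(n) * sigma.
def _c4(n: int) -> float:
    return math.sqrt(2.0 / (n - 1)) * math.gamma(n / 2) / math.gamma((n - 1) / 2)


def population_cv_from_triplicate_cv(reported_cv_pct: float, n: int = 3) -> float:
    """Population CV (%) whose n-replicate sample CV averages ``reported_cv_pct``."""
    return reported_cv_pct / _c4(n)


@dataclass(frozen=True)
class TrueSample:
    """Ground truth for one cartridge (one duplicate of one patient sample)."""

    sample_id: str
    patient_id: int
    replicate_id: int
    conc: dict[str, float]          # biomarker -> pg/mL
    censored: dict[str, bool]       # biomarker -> below reporting limit
    matrix_factor: float


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the forward simulator.

    ``replicate_cv_pct`` are population CVs of the multiplicative
    cartridge-level replicate noise (see module docstring for why the
    defaults are the reported triplicate CVs divided by c4(3)).
    ``below_limit_frac`` are the expected fractions of patients whose true
    concentration falls below each reference assay's reporting limit,
    matching the clinical cohort composition (20/92 cTnI, 58/92 CK-MB,
    33/92 NT-proBNP).
    """

    n_patients: int = 92
    duplicates_per_sample: int = 2
    power_models: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(POWER_MODELS))
    cl_saturation_onset: float = 1.0e4   # pg/mL, cTnI CL plateau onset
    cl_saturation_sharpness: float = 4.0  # generalised-Hill exponent
    replicate_cv_pct: dict[str, float] = field(default_factory=lambda: {
        b: population_cv_from_triplicate_cv(cv)
        for b, cv in REPORTED_TRIPLICATE_CV.items()
    })
    control_cv_pct: float = population_cv_from_triplicate_cv(3.0)
    spot_cv_pct: float = 1.0             # spot-to-spot within a membrane
    matrix_cv_pct: float = 10.0          # sample-level matrix effect
    pos_ctrl_signal: dict[str, float] = field(
        default_factory=lambda: {"Color": 0.5, "CL": 0.5})
    blank_baseline: dict[str, float] = field(
        default_factory=lambda: {"Color": 0.005, "CL": 0.005})
    below_limit_frac: dict[str, float] = field(default_factory=lambda: {
        CTNI: 20 / 92, CKMB: 58 / 92, NTPROBNP: 33 / 92})
    conc_range: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        CTNI: (4.0, 1.0e5), CKMB: (50.0, 1.0e5), NTPROBNP: (10.0, 4.0e4)})
    below_limit_floor: float = 0.02      # below-limit conc >= floor*limit
    background_level: float = 0.82       # fraction of full scale
    pixel_noise_sd: float = 2.0          # digital numbers (8-bit scale)
    image_size: int = 256
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        for b, cv in self.replicate_cv_pct.items():
            if cv <= 0:
                raise ValueError(f"replicate CV for {b} must be > 0")
        for b, f in self.below_limit_frac.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"below-limit fraction for {b} outside [0,1]")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _lognormal_factor(rng: np.random.Generator, cv_pct: float, size=None):
    """Mean-one multiplicative lognormal noise with the given CV (%)."""
    cv = cv_pct / 100.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, size=size)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def sample_cohort(config: GeneratorConfig,
                  rng: np.random.Generator | None = None) -> list[TrueSample]:
    """Draw a patient cohort and expand it into duplicate cartridges.

    Per biomarker, each patient is below the reporting limit with the
    configured probability; concentrations are log-uniform within the
    below-limit or quantifiable range accordingly.  Duplicates share the
    patient's concentrations and matrix factor.
    """
    if rng is None:
        rng = config.rng()
    samples: list[TrueSample] = []
    for pid in range(1, config.n_patients + 1):
        conc: dict[str, float] = {}
        censored: dict[str, bool] = {}
        for b, limit in REPORTING_LIMITS.items():
            below = rng.random() < config.below_limit_frac[b]
            if below:
                lo, hi = config.below_limit_floor * limit, limit
            else:
                lo, hi = config.conc_range[b]
            conc[b] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            censored[b] = bool(below)
        mf = float(_lognormal_factor(rng, config.matrix_cv_pct))
        for rep in range(1, config.duplicates_per_sample + 1):
            samples.append(TrueSample(
                sample_id=f"P{pid:04d}R{rep}", patient_id=pid, replicate_id=rep,
                conc=dict(conc), censored=dict(censored), matrix_factor=mf))
    return samples


def cohort_frame(samples: list[TrueSample]) -> pd.DataFrame:
    """Tabulate a cohort: one row per cartridge, pg/mL plus censor flags."""
    rows = []
    for s in samples:
        row = {"sample_id": s.sample_id, "patient_id": s.patient_id,
               "replicate_id": s.replicate_id, "matrix_factor": s.matrix_factor}
        for b in REPORTING_LIMITS:
            row[b] = s.conc[b]
            row[f"{b}_censored"] = s.censored[b]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# forward signal model
# ---------------------------------------------------------------------------

def _saturating_power(conc: float, a: float, k: float,
                      onset: float, sharpness: float) -> float:
    # Generalised-Hill soft minimum between the power law p = a*conc**k and
    # the plateau S = a*onset**k:  y = S / (1 + (S/p)**h)**(1/h).
    # For p << S this returns p (the power law); for p >> S it returns S.
    if conc == 0.0:
        return 0.0
    p = a * conc ** k
    s_max = a * onset ** k
    return s_max / (1.0 + (s_max / p) ** sharpness) ** (1.0 / sharpness)


def forward_signal(conc: float, biomarker: str, modality: str,
                   matrix_factor: float = 1.0, noise_on: bool = False,
                   config: GeneratorConfig | None = None,
                   rng: np.random.Generator | None = None) -> float:
    """Noise-free or noisy absorption signal for one analyte channel.

    Noise-free mode returns ``a * conc**k`` (the cTnI/CL channel passes
    through the saturating transform); ``conc == 0`` returns the configured
    blank baseline.  Noise mode multiplies by a mean-one lognormal factor at
    the biomarker's replicate CV and by ``matrix_factor``.
    """
    if config is None:
        config = GeneratorConfig()
    if conc < 0:
        raise ValueError(f"concentration must be >= 0, got {conc}")
    key = (biomarker, modality)
    if key not in config.power_models:
        raise ValueError(f"unsupported (biomarker, modality) pair {key}")
    a, k = config.power_models[key]
    if conc == 0.0:
        clean = config.blank_baseline[modality]
    elif key == (CTNI, "CL"):
        clean = _saturating_power(conc, a, k, config.cl_saturation_onset,
                                  config.cl_saturation_sharpness)
    else:
        clean = a * conc ** k
    if not noise_on:
        return float(clean)
    if rng is None:
        rng = config.rng()
    noise = float(_lognormal_factor(rng, config.replicate_cv_pct[biomarker]))
    return float(clean * noise * matrix_factor)


def control_signal(condition: str, modality: str, config: GeneratorConfig,
                   matrix_factor: float = 1.0, noise_on: bool = False,
                   rng: np.random.Generator | None = None) -> float:
    """Signal of a positive- or negative-control spot."""
    if condition == POS_CTRL:
        clean = config.pos_ctrl_signal[modality]
    elif condition == NEG_CTRL:
        clean = config.blank_baseline[modality]
    else:
        raise ValueError(f"not a control condition: {condition}")
    if not noise_on:
        return float(clean)
    if rng is None:
        rng = config.rng()
    noise = float(_lognormal_factor(rng, config.control_cv_pct))
    return float(clean * noise * matrix_factor)


def calibration_signals(biomarker: str, modality: str,
                        config: GeneratorConfig | None = None,
                        n_replicates: int = 3,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Noisy replicate signals at each calibration concentration.

    Emulates the spiked-serum calibration protocol: ``n_replicates``
    independent cartridges per grid concentration (no matrix effect —
    calibration uses one serum pool).
    """
    if config is None:
        config = GeneratorConfig()
    if rng is None:
        rng = config.rng()
    rows = []
    for conc in CALIBRATION_GRIDS[biomarker]:
        for rep in range(1, n_replicates + 1):
            sig = forward_signal(conc, biomarker, modality, noise_on=True,
                                 config=config, rng=rng)
            rows.append({"conc": float(conc), "replicate": rep, "signal": sig})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cartridge-level feature simulation (signal-table route)
# ---------------------------------------------------------------------------

def _cartridge_channel_signal(sample: TrueSample, condition: str, modality: str,
                              config: GeneratorConfig,
                              rng: np.random.Generator) -> float:
    """Cartridge-level signal for one condition/modality channel."""
    if condition in (POS_CTRL, NEG_CTRL):
        return control_signal(condition, modality, config,
                              matrix_factor=sample.matrix_factor,
                              noise_on=True, rng=rng)
    if (condition, modality) in config.power_models:
        return forward_signal(sample.conc[condition], condition, modality,
                              matrix_factor=sample.matrix_factor,
                              noise_on=True, config=config, rng=rng)
    # analyte with no response in this modality (e.g. CK-MB under CL):
    # baseline only.
    return float(config.blank_baseline[modality]
                 * _lognormal_factor(rng, config.control_cv_pct)
                 * sample.matrix_factor)


def simulate_features(samples: list[TrueSample],
                      config: GeneratorConfig | None = None,
                      rng: np.random.Generator | None = None,
                      spotmap: SpotMap | None = None) -> pd.DataFrame:
    """Simulate the ten averaged absorption signals per cartridge.

    Replicate noise acts at the cartridge x condition x modality level
    (assay/flow variability is shared by alike spots); small independent
    spot-to-spot noise is applied before averaging over each condition's
    spot repeats.
    """
    if config is None:
        config = GeneratorConfig()
    if rng is None:
        rng = config.rng()
    if spotmap is None:
        spotmap = default_spotmap(config.image_size)
    rows = []
    for s in samples:
        row: dict[str, object] = {"cartridge_id": s.sample_id,
                                  "patient_id": s.patient_id,
                                  "replicate_id": s.replicate_id}
        for modality in MODALITIES:
            for condition in (CTNI, CKMB, NTPROBNP, POS_CTRL, NEG_CTRL):
                base = _cartridge_channel_signal(s, condition, modality, config, rng)
                n_spots = len(spotmap.spots_for(condition))
                per_spot = base * _lognormal_factor(rng, config.spot_cv_pct, n_spots)
                row[feature_column(condition, modality)] = float(per_spot.mean())
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------

def _disk_mask(shape: tuple[int, int], center: tuple[float, float],
               radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def render_membrane_pair(sample: TrueSample, spotmap: SpotMap, modality: str,
                         config: GeneratorConfig | None = None,
                         rng: np.random.Generator | None = None,
                         offset: tuple[int, int] = (0, 0)):
    """Render (background, assay) RGB images for one cartridge and modality.

    The background image is uniform illumination plus Gaussian pixel noise.
    In the assay image each spot attenuates its modality's channel (green
    for colorimetric, blue for CL) so that the ROI mean equals
    ``background * (1 - signal)``; ``offset`` rigidly shifts all spots to
    exercise registration.
    """
    if config is None:
        config = GeneratorConfig()
    if rng is None:
        rng = config.rng()
    if config.bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    dtype = np.uint8 if config.bit_depth == 8 else np.uint16
    full = 255.0 if config.bit_depth == 8 else 65535.0
    scale = full / 255.0  # pixel_noise_sd is specified on the 8-bit scale
    shape = spotmap.image_shape
    for spot in spotmap.spots:
        r0, c0 = spot.center_xy[0] + offset[0], spot.center_xy[1] + offset[1]
        if not (spot.radius_px <= r0 < shape[0] - spot.radius_px
                and spot.radius_px <= c0 < shape[1] - spot.radius_px):
            raise ValueError("image too small to contain all shifted ROIs")

    bg_level = config.background_level * full
    noise_sd = config.pixel_noise_sd * scale
    bg = bg_level + rng.normal(0.0, noise_sd, size=(*shape, 3))

    assay = bg_level + rng.normal(0.0, noise_sd, size=(*shape, 3))
    channel = 1 if modality == "Color" else 2  # green / blue
    for spot in spotmap.spots:
        base = _cartridge_channel_signal(sample, spot.condition, modality, config, rng)
        sig = base * float(_lognormal_factor(rng, config.spot_cv_pct))
        center = (spot.center_xy[0] + offset[0], spot.center_xy[1] + offset[1])
        mask = _disk_mask(shape, center, spot.radius_px)
        assay[..., channel][mask] *= (1.0 - sig)
    return (np.clip(bg, 0, full).astype(dtype),
            np.clip(assay, 0, full).astype(dtype))
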