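"""Concentration-signal calibration: power-law and 4-PL fits, inversion,
detection limits (LoB/LoD) and replicate CV.

The power law ``y = a * x**k`` is fit by ordinary least squares of
log10(y) on log10(x) (convex, reproducible, the standard approach for
power-law dose response).  The four-parameter logistic

    y = D + (A - D) / (1 + (x / C)**B)

is fit by multi-start nonlinear least squares; A is the low-concentration
asymptote, D the plateau, C the inflection concentration and B the slope.

Detection limits follow the blank-based convention: the limit of blank is
mean(blank signals) + 1.645 * SD(blank signals), converted to concentration
through the calibration curve; the limit of detection adds 1.645 * SD of
the lowest-concentration replicate measurements, with every replicate
signal inverted to concentration units first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = ["CalibrationModel", "DetectionLimits", "fit_power", "fit_4pl",
           "forward", "invert_calibration", "compute_limits", "compute_cv"]


class FitFailureError(RuntimeError):
    pass


class OutOfRangeError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationModel:
    form: str                       # "power" or "fourPL"
    params: dict[str, float]        # power: a, k ; fourPL: A, B, C, D
    r2: float
    biomarker: str = ""
    modality: str = ""
    conc_range: tuple[float, float] = (0.0, float("inf"))


@dataclass(frozen=True)
class DetectionLimits:
    lob: float                      # pg/mL
    lod: float                      # pg/mL
    cv_pct: dict[float, float] = field(default_factory=dict)


def _as_xy(points) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(points, dtype=float)
    return arr[:, 0], arr[:, 1]


def fit_power(points, biomarker: str = "", modality: str = "") -> CalibrationModel:
    """Least-squares fit of log10(signal) on log10(conc); R^2 on the log-log scale."""
    x, y = _as_xy(points)
    if len(x) < 2:
        raise ValueError("need at least 2 points")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power fit requires conc > 0 and signal > 0")
    lx, ly = np.log10(x), np.log10(y)
    res = stats.linregress(lx, ly)
    r2 = 1.0 if np.allclose(ly, ly[0]) else float(res.rvalue ** 2)
    return CalibrationModel(
        form="power",
        params={"a": float(10.0 ** res.intercept), "k": float(res.slope)},
        r2=r2, biomarker=biomarker, modality=modality,
        conc_range=(float(x.min()), float(x.max())))


def _fourpl(x, A, B, C, D):
    return D + (A - D) / (1.0 + (x / C) ** B)


def fit_4pl(points, biomarker: str = "", modality: str = "",
            n_starts: int = 8) -> CalibrationModel:
    """Multi-start nonlinear least squares of the 4-PL curve."""
    x, y = _as_xy(points)
    if len(x) < 5:
        raise ValueError("need at least 5 points for a 4-PL fit")
    if np.ptp(y) == 0:
        raise FitFailureError("degenerate fit: all signals equal")
    spread = np.ptp(y)
    c_grid = np.exp(np.linspace(np.log(x[x > 0].min() + 1e-12),
                                np.log(x.max()), n_starts))
    best, best_cost = None, np.inf
    for c0 in c_grid:
        for b0 in (1.0, -1.0):
            p0 = (float(y.min()), b0, float(c0), float(y.max()))
            try:
                # silence exploration noise (negative C trials, singular
                # covariance) from the multi-start search
                import warnings
                with np.errstate(all="ignore"), warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, _ = optimize.curve_fit(_fourpl, x, y, p0=p0,
                                                 maxfev=20000)
            except (RuntimeError, ValueError):
                continue
            resid = y - _fourpl(x, *popt)
            cost = float(resid @ resid)
            if cost < best_cost and popt[2] > 0:
                best, best_cost = popt, cost
    if best is None:
        raise FitFailureError("4-PL fit failed to converge from all starts")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - best_cost / ss_tot if ss_tot > 0 else 1.0
    A, B, C, D = (float(v) for v in best)
    return CalibrationModel(form="fourPL", params={"A": A, "B": B, "C": C, "D": D},
                            r2=float(r2), biomarker=biomarker, modality=modality,
                            conc_range=(float(x.min()), float(x.max())))


def forward(model: CalibrationModel, conc) -> np.ndarray | float:
    conc = np.asarray(conc, dtype=float)
    if model.form == "power":
        out = model.params["a"] * conc ** model.params["k"]
    elif model.form == "fourPL":
        out = _fourpl(conc, *(model.params[p] for p in "ABCD"))
    else:
        raise ValueError(f"unknown model form {model.form}")
    return float(out) if out.ndim == 0 else out


def invert_calibration(model: CalibrationModel, signal: float) -> float:
    """Unique concentration with forward(model, conc) == signal."""
    if model.form == "power":
        a, k = model.params["a"], model.params["k"]
        if k == 0:
            raise OutOfRangeError("constant power model is not invertible")
        if signal <= 0:
            raise OutOfRangeError(f"signal {signal} outside invertible range (>0)")
        return float((signal / a) ** (1.0 / k))
    A, B, C, D = (model.params[p] for p in "ABCD")
    lo, hi = (A, D) if A < D else (D, A)
    if not lo < signal < hi:
        raise OutOfRangeError(
            f"signal {signal} outside the open 4-PL range ({lo:.6g}, {hi:.6g})")
    return float(C * ((A - D) / (signal - D) - 1.0) ** (1.0 / B))


def compute_limits(blank_signals, lowest_conc_signals,
                   model: CalibrationModel) -> DetectionLimits:
    """LoB and LoD in concentration units.

    LoB = invert(mean(blanks) + 1.645 * SD(blanks)); LoD = LoB + 1.645 * SD
    of the lowest-concentration replicates after inverting each replicate
    signal to concentration.
    """
    blanks = np.asarray(blank_signals, dtype=float)
    lows = np.asarray(lowest_conc_signals, dtype=float)
    if len(blanks) < 3 or len(lows) < 3:
        raise ValueError("need >= 3 blank and >= 3 low-concentration replicates")
    lob_signal = float(blanks.mean() + 1.645 * blanks.std(ddof=1))
    lob = invert_calibration(model, lob_signal)
    low_concs = np.array([invert_calibration(model, s) for s in lows])
    lod = lob + 1.645 * float(low_concs.std(ddof=1))
    return DetectionLimits(lob=float(lob), lod=float(lod))


def compute_cv(replicate_values) -> float:
    """Coefficient of variation, 100 * sample SD / mean (%)."""
    v = np.asarray(replicate_values, dtype=float)
    if len(v) < 2:
        raise ValueError("need >= 2 replicates")
    m = v.mean()
    if m == 0:
        raise ValueError("zero mean: CV undefined")
    return float(100.0 * v.std(ddof=1) / m)
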