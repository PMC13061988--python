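"""Evaluation metrics and the single-signal power-fit baseline.

The cascade is scored per biomarker by classification accuracy (with a
confusion matrix over that biomarker's ranges), Pearson correlation between
quantified and true concentrations (undetermined/negative samples are
excluded and counted separately), and the mean per-patient duplicate CV.

As a comparison baseline, :func:`powerfit_baseline` inverts one
biomarker-specific calibration curve on the designated single signal
(colorimetric for CK-MB and NT-proBNP, CL for cTnI) with no learning — the
classical calibration-curve readout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import CalibrationModel, compute_cv, invert_calibration
from .cascade import BIOMARKERS, CLASS_LABELS
from .layout import CKMB, CTNI, NTPROBNP, feature_column

#: Designated single-signal channel per biomarker for the baseline readout.
BASELINE_CHANNEL = {
    CKMB: feature_column(CKMB, "Color"),
    NTPROBNP: feature_column(NTPROBNP, "Color"),
    CTNI: feature_column(CTNI, "CL"),
}


def classification_report(predicted, true, labels) -> tuple[float, pd.DataFrame]:
    """Accuracy and confusion matrix (rows: true label, cols: predicted)."""
    predicted = list(predicted)
    true = list(true)
    if len(predicted) != len(true):
        raise ValueError("length mismatch")
    extra = (set(predicted) | set(true)) - set(labels)
    if extra:
        raise ValueError(f"labels outside class set: {sorted(extra)}")
    cm = pd.DataFrame(0, index=list(labels), columns=list(labels))
    for t, p in zip(true, predicted):
        cm.loc[t, p] += 1
    acc = float(np.trace(cm.to_numpy()) / len(true)) if true else np.nan
    return acc, cm


def correlation_report(predicted_conc, true_conc, log_scale: bool = False) -> float:
    """Pearson r between predicted and true concentrations.

    Computed on the linear pg/mL scale by default; ``log_scale=True``
    correlates log10 concentrations instead (useful when values span
    decades).  Requires >= 3 pairs and nonzero variance on both sides.
    """
    p = np.asarray(predicted_conc, dtype=float)
    t = np.asarray(true_conc, dtype=float)
    if len(p) < 3:
        raise ValueError("need >= 3 quantified pairs")
    if log_scale:
        p, t = np.log10(p), np.log10(t)
    if p.std() == 0 or t.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(stats.pearsonr(p, t).statistic)


def duplicate_cv(predictions: pd.DataFrame, biomarker: str) -> tuple[float, int]:
    """Mean per-patient CV (%) of quantified duplicate predictions.

    ``predictions`` needs ``patient_id``, ``<b>_status`` and ``<b>_conc``
    columns.  Patients with fewer than two quantified replicates are
    skipped; returns (mean CV, number of patients skipped).
    """
    cvs, skipped = [], 0
    for _, grp in predictions.groupby("patient_id"):
        vals = grp.loc[grp[f"{biomarker}_status"] == "quantified",
                       f"{biomarker}_conc"].to_numpy(float)
        if len(vals) < 2 or vals.mean() == 0:
            skipped += 1
            continue
        cvs.append(compute_cv(vals))
    return (float(np.mean(cvs)) if cvs else np.nan), skipped


def powerfit_baseline(features: pd.DataFrame | pd.Series,
                      model: CalibrationModel, biomarker: str) -> np.ndarray:
    """Invert the designated single signal through a power calibration.

    Signals outside the model's invertible range raise (for scalar input)
    or yield NaN (for a table), e.g. a saturated cTnI CL signal above the
    plateau of the fitted curve.
    """
    channel = BASELINE_CHANNEL[biomarker]
    if isinstance(features, pd.Series):
        return invert_calibration(model, float(features[channel]))
    out = np.full(len(features), np.nan)
    for i, s in enumerate(features[channel].to_numpy(float)):
        try:
            out[i] = invert_calibration(model, s)
        except ValueError:
            pass
    return out


@dataclass(frozen=True)
class BiomarkerReport:
    biomarker: str
    accuracy: float
    confusion: pd.DataFrame
    pearson_r: float
    n_quantified: int
    n_undetermined: int
    n_negative: int
    mean_duplicate_cv_pct: float


def evaluate_cascade(predictions: pd.DataFrame, truth: pd.DataFrame,
                     log_scale: bool = False) -> dict[str, BiomarkerReport]:
    """Full per-biomarker report for cascade predictions vs ground truth.

    ``truth`` carries ``sample_id``, concentrations and censor flags; the
    correlation uses quantified, non-censored samples only.
    """
    from .cascade import class_label
    df = predictions.merge(truth, left_on="cartridge_id", right_on="sample_id",
                           suffixes=("", "_truth"))
    reports = {}
    for b in BIOMARKERS:
        true_labels = [class_label(b, c) for c in df[b]]
        acc, cm = classification_report(df[f"{b}_class"], true_labels,
                                        CLASS_LABELS[b])
        quant = (df[f"{b}_status"] == "quantified") & ~df[f"{b}_censored"]
        r = np.nan
        if quant.sum() >= 3:
            r = correlation_report(df.loc[quant, f"{b}_conc"],
                                   df.loc[quant, b], log_scale=log_scale)
        cv, _ = duplicate_cv(df, b) if "patient_id" in df else (np.nan, 0)
        reports[b] = BiomarkerReport(
            biomarker=b, accuracy=acc, confusion=cm, pearson_r=r,
            n_quantified=int((df[f"{b}_status"] == "quantified").sum()),
            n_undetermined=int((df[f"{b}_status"] == "undetermined").sum()),
            n_negative=int((df[f"{b}_status"] == "negative").sum()),
            mean_duplicate_cv_pct=cv)
    return reports


def report_frame(reports: dict[str, BiomarkerReport]) -> pd.DataFrame:
    rows = [{"biomarker": r.biomarker, "accuracy": r.accuracy,
             "pearson_r": r.pearson_r, "n_quantified": r.n_quantified,
             "n_undetermined": r.n_undetermined, "n_negative": r.n_negative,
             "mean_duplicate_cv_pct": r.mean_duplicate_cv_pct}
            for r in reports.values()]
    return pd.DataFrame(rows)
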