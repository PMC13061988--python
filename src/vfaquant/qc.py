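"""Digital quality control on the control-spot channels (3-sigma rule).

A cartridge fails QC if any of its four control channels — positive and
negative control in each modality — falls outside mean +/- 3 standard
deviations of that channel's distribution over the study batch.  The
interval is closed at the boundary so that pass/fail does not depend on
floating-point rounding; a channel with zero batch SD passes only on exact
equality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .layout import MODALITIES, NEG_CTRL, POS_CTRL, feature_column

#: The four control channels inspected by QC.
CONTROL_CHANNELS = tuple(feature_column(c, m)
                         for c in (POS_CTRL, NEG_CTRL) for m in MODALITIES)


@dataclass(frozen=True)
class ControlReference:
    """Per-channel mean and sample SD of the control signals in a batch."""

    mean: dict[str, float]
    sd: dict[str, float]
    n_cartridges: int

    def interval(self, channel: str, n_sigma: float = 3.0) -> tuple[float, float]:
        m, s = self.mean[channel], self.sd[channel]
        return m - n_sigma * s, m + n_sigma * s


def fit_control_reference(features: pd.DataFrame) -> ControlReference:
    """Fit the batch reference (sample SD, n-1 denominator) from >= 2 cartridges."""
    if len(features) < 2:
        raise ValueError("need at least 2 cartridges to fit a control reference")
    mean = {c: float(features[c].mean()) for c in CONTROL_CHANNELS}
    sd = {c: float(features[c].std(ddof=1)) for c in CONTROL_CHANNELS}
    return ControlReference(mean=mean, sd=sd, n_cartridges=len(features))


def qc_filter(fv: pd.Series, ref: ControlReference,
              n_sigma: float = 3.0) -> tuple[str, list[str]]:
    """Return ('pass'|'fail', [violated channels]) for one cartridge."""
    reasons = []
    for channel in CONTROL_CHANNELS:
        lo, hi = ref.interval(channel, n_sigma)
        v = float(fv[channel])
        if not (lo <= v <= hi):
            reasons.append(channel)
    return ("fail" if reasons else "pass"), reasons


def qc_batch(features: pd.DataFrame, ref: ControlReference | None = None,
             leave_one_out: bool = False, n_sigma: float = 3.0) -> pd.DataFrame:
    """Apply QC to a batch, adding qc_status and qc_reason columns.

    By default the reference is fit on the full batch including the
    cartridge under test (matching a retrospective whole-study analysis);
    ``leave_one_out=True`` refits the reference without each cartridge.
    """
    out = features.copy()
    if leave_one_out:
        statuses, reasons = [], []
        for i in range(len(features)):
            r = fit_control_reference(features.drop(features.index[i]))
            status, why = qc_filter(features.iloc[i], r, n_sigma)
            statuses.append(status)
            reasons.append(";".join(why))
        out["qc_status"] = statuses
        out["qc_reason"] = reasons
        return out
    r = ref if ref is not None else fit_control_reference(features)
    violated = {}
    for ch in CONTROL_CHANNELS:
        lo, hi = r.interval(ch, n_sigma)
        v = features[ch].to_numpy(float)
        violated[ch] = ~((v >= lo) & (v <= hi))
    any_bad = np.logical_or.reduce(list(violated.values()))
    out["qc_status"] = np.where(any_bad, "fail", "pass")
    out["qc_reason"] = [
        ";".join(ch for ch in CONTROL_CHANNELS if violated[ch][i]) if bad else ""
        for i, bad in enumerate(any_bad)]
    return out
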