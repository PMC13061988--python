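"""Range-gated classification -> quantification cascade with agreement QA.

Each biomarker is handled by one shallow classifier that assigns a
concentration range, followed by a per-range quantifier:

* CK-MB: classes <500 / >=500 pg/mL; the <500 class is reported
  "negative" (below the clinically relevant region), >=500 is quantified.
* NT-proBNP: classes <125 / >=125 pg/mL; <125 reported "negative".
* cTnI: classes <40 / 40-1000 / >1000 pg/mL; every class is quantified
  (cTnI is never reported negative).

Quantified concentrations are cross-checked against the assigned range: a
prediction more than 5% outside a finite range boundary (relative to the
boundary value; bounds at 0 or infinity can never be violated) marks the
sample "undetermined" and the concentration is withheld.

The default model specifications carry the per-model optimal feature
subsets found by backward elimination on the clinical study (see
:mod:`vfaquant.features`), e.g. the CK-MB quantifier consumes only the
CK-MB colorimetric signal, while the cTnI >1000 quantifier combines
colorimetric and CL channels to sidestep CL saturation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .layout import CKMB, CTNI, NTPROBNP, NEG_CTRL, POS_CTRL, feature_column as fc
from .nn import ModelSpec, TrainedModel, train_model
from .synth import REPORTING_LIMITS

BIOMARKERS = (CKMB, NTPROBNP, CTNI)

#: Ordered class labels per biomarker.
CLASS_LABELS = {
    CKMB: ("<500", ">=500"),
    NTPROBNP: ("<125", ">=125"),
    CTNI: ("<40", "40-1000", ">1000"),
}

#: Concentration bounds (pg/mL) of each class range.
RANGE_BOUNDS = {
    CKMB: {"<500": (0.0, 500.0), ">=500": (500.0, np.inf)},
    NTPROBNP: {"<125": (0.0, 125.0), ">=125": (125.0, np.inf)},
    CTNI: {"<40": (0.0, 40.0), "40-1000": (40.0, 1000.0),
           ">1000": (1000.0, np.inf)},
}

#: Ranges that are reported "negative" without quantification.
NEGATIVE_RANGES = {CKMB: ("<500",), NTPROBNP: ("<125",), CTNI: ()}

#: Agreement tolerance of the classification/quantification cross-check,
#: relative to the violated range boundary.
CROSSCHECK_TOL = 0.05

_COLOR5 = (fc(CTNI, "Color"), fc(NTPROBNP, "Color"), fc(CKMB, "Color"),
           fc(POS_CTRL, "Color"), fc(NEG_CTRL, "Color"))
_CTNI6 = (fc(CTNI, "Color"), fc(POS_CTRL, "Color"), fc(NEG_CTRL, "Color"),
          fc(CTNI, "CL"), fc(POS_CTRL, "CL"), fc(NEG_CTRL, "CL"))

#: Full feature sets available to each biomarker's models.
FULL_FEATURE_SETS = {CKMB: _COLOR5, NTPROBNP: _COLOR5, CTNI: _CTNI6}


def default_model_specs(classifier_epochs: int = 400,
                        quantifier_epochs: int = 2000) -> dict[str, ModelSpec]:
    """The eight networks with their published architectures and the
    backward-elimination-optimal feature subsets as defaults."""
    specs = {}
    # --- classifiers: BN + ReLU + dropout, CCE, N_b=4, lr *0.99 / 10 epochs
    specs["class_CK-MB"] = ModelSpec(
        name="class_CK-MB", biomarker=CKMB, stage="classifier",
        features=_COLOR5, hidden=(128, 64, 32), dropout=0.6, loss="cce",
        n_classes=2, batchnorm=True, batch_size=4, lr=1e-3,
        lr_factor=0.99, lr_period=10, max_epochs=classifier_epochs)
    specs["class_NT-proBNP"] = ModelSpec(
        name="class_NT-proBNP", biomarker=NTPROBNP, stage="classifier",
        features=(fc(NTPROBNP, "Color"), fc(CKMB, "Color"), fc(POS_CTRL, "Color")),
        hidden=(64, 32), dropout=0.4, loss="cce", n_classes=2, batchnorm=True,
        batch_size=4, lr=1e-2, lr_factor=0.99, lr_period=10,
        max_epochs=classifier_epochs)
    specs["class_cTnI"] = ModelSpec(
        name="class_cTnI", biomarker=CTNI, stage="classifier",
        features=(fc(CTNI, "Color"), fc(POS_CTRL, "Color"), fc(NEG_CTRL, "Color"),
                  fc(CTNI, "CL"), fc(POS_CTRL, "CL")),
        hidden=(128, 64), dropout=0.4, loss="cce", n_classes=3, batchnorm=True,
        batch_size=4, lr=3e-3, lr_factor=0.99, lr_period=10,
        max_epochs=classifier_epochs)
    # --- quantifiers: ReLU + dropout, N_b=20, lr 1e-3 *0.5 / 50 epochs,
    #     early stop after 200 epochs without a 1e-4 improvement
    common = dict(stage="quantifier", batch_size=20, lr=1e-3, lr_factor=0.5,
                  lr_period=50, max_epochs=quantifier_epochs, patience=200,
                  min_delta=1e-4)
    specs["quant_CK-MB_>=500"] = ModelSpec(
        name="quant_CK-MB_>=500", biomarker=CKMB, range_label=">=500",
        features=(fc(CKMB, "Color"),), hidden=(128, 32), dropout=0.3,
        loss="mse", target_transform="scale", target_scale=500.0, **common)
    specs["quant_NT-proBNP_>=125"] = ModelSpec(
        name="quant_NT-proBNP_>=125", biomarker=NTPROBNP, range_label=">=125",
        features=(fc(CTNI, "Color"), fc(NTPROBNP, "Color"), fc(CKMB, "Color"),
                  fc(NEG_CTRL, "Color")),
        hidden=(128, 32), dropout=0.4, loss="rmsle",
        target_transform="scale", target_scale=125.0, **common)
    specs["quant_cTnI_<40"] = ModelSpec(
        name="quant_cTnI_<40", biomarker=CTNI, range_label="<40",
        features=(fc(CTNI, "CL"), fc(NEG_CTRL, "CL")), hidden=(128, 64),
        dropout=0.1, loss="mse", target_transform="zscore", **common)
    specs["quant_cTnI_40-1000"] = ModelSpec(
        name="quant_cTnI_40-1000", biomarker=CTNI, range_label="40-1000",
        features=(fc(CTNI, "CL"),), hidden=(128, 64), dropout=0.1,
        loss="mse", target_transform="zscore", **common)
    specs["quant_cTnI_>1000"] = ModelSpec(
        name="quant_cTnI_>1000", biomarker=CTNI, range_label=">1000",
        features=(fc(CTNI, "Color"), fc(POS_CTRL, "Color"), fc(NEG_CTRL, "Color"),
                  fc(CTNI, "CL"), fc(NEG_CTRL, "CL")),
        hidden=(128, 64), dropout=0.1, loss="mse",
        target_transform="zscore", **common)
    return specs


def class_label(biomarker: str, conc: float) -> str:
    """Ground-truth range label; lower bounds closed (conc == 40 -> 40-1000)."""
    labels = CLASS_LABELS[biomarker]
    bounds = RANGE_BOUNDS[biomarker]
    for label in reversed(labels):
        lo, _ = bounds[label]
        if lo <= 0:
            continue
        # ">1000" is open at its lower bound; ">=500", ">=125" and the
        # middle "40-1000" range are closed (conc == 1000 -> "40-1000").
        hit = conc > lo if label.startswith(">") and not label.startswith(">=") \
            else conc >= lo
        if hit:
            return label
    return labels[0]


def class_index(biomarker: str, conc: float) -> int:
    return CLASS_LABELS[biomarker].index(class_label(biomarker, conc))


@dataclass
class TrainedCascade:
    classifiers: dict[str, TrainedModel]            # biomarker -> model
    quantifiers: dict[str, dict[str, TrainedModel]]  # biomarker -> range -> model
    seed: int


def train_cascade(features: pd.DataFrame, truth: pd.DataFrame,
                  seed: int = 0,
                  specs: dict[str, ModelSpec] | None = None) -> TrainedCascade:
    """Train all eight models on a merged feature/ground-truth table.

    ``features`` must carry a ``cartridge_id`` column plus the ten signal
    columns; ``truth`` carries ``sample_id``, per-biomarker concentrations
    and ``<biomarker>_censored`` flags.  Censored samples contribute to
    classifier training (lowest class) but are excluded from quantifier
    training for that biomarker.
    """
    if specs is None:
        specs = default_model_specs()
    df = features.merge(truth, left_on="cartridge_id", right_on="sample_id")
    if len(df) == 0:
        raise ValueError("no overlap between features and ground truth")
    classifiers: dict[str, TrainedModel] = {}
    quantifiers: dict[str, dict[str, TrainedModel]] = {b: {} for b in BIOMARKERS}
    for name, spec in specs.items():
        b = spec.biomarker
        if spec.stage == "classifier":
            y = np.array([class_index(b, c) for c in df[b]])
            X = df.loc[:, list(spec.features)].to_numpy(float)
            classifiers[b] = train_model(spec, X, y, seed=seed)
        else:
            in_range = np.array([class_label(b, c) == spec.range_label
                                 for c in df[b]])
            usable = in_range & ~df[f"{b}_censored"].to_numpy(bool)
            sub = df[usable]
            X = sub.loc[:, list(spec.features)].to_numpy(float)
            quantifiers[b][spec.range_label] = train_model(
                spec, X, sub[b].to_numpy(float), seed=seed)
    return TrainedCascade(classifiers=classifiers, quantifiers=quantifiers,
                          seed=seed)


def _crosscheck(biomarker: str, range_label: str, conc: float,
                tol: float = CROSSCHECK_TOL) -> bool:
    """True if the quantified value agrees with the assigned range."""
    lo, hi = RANGE_BOUNDS[biomarker][range_label]
    if lo > 0 and conc < lo * (1.0 - tol):
        return False
    if np.isfinite(hi) and conc > hi * (1.0 + tol):
        return False
    return True


def predict_cascade(features: pd.DataFrame,
                    cascade: TrainedCascade) -> pd.DataFrame:
    """Per-cartridge cascade predictions.

    Output columns per biomarker: ``<b>_class`` (assigned range),
    ``<b>_status`` in {quantified, negative, undetermined} and ``<b>_conc``
    (pg/mL; NaN unless quantified).  Quantified concentrations are floored
    at zero.
    """
    out = pd.DataFrame({"cartridge_id": features["cartridge_id"].to_numpy()})
    for b in BIOMARKERS:
        clf = cascade.classifiers[b]
        Xc = features.loc[:, list(clf.spec.features)].to_numpy(float)
        cls_idx = clf.predict_class(Xc)
        labels = [CLASS_LABELS[b][i] for i in cls_idx]
        status, conc = [], []
        for i, label in enumerate(labels):
            if label in NEGATIVE_RANGES[b]:
                status.append("negative")
                conc.append(np.nan)
                continue
            quant = cascade.quantifiers[b].get(label)
            if quant is None:
                raise KeyError(f"no quantifier trained for {b} range {label}")
            Xq = features.iloc[[i]].loc[:, list(quant.spec.features)].to_numpy(float)
            c = max(float(quant.predict(Xq)[0]), 0.0)
            if _crosscheck(b, label, c):
                status.append("quantified")
                conc.append(c)
            else:
                status.append("undetermined")
                conc.append(np.nan)
        out[f"{b}_class"] = labels
        out[f"{b}_status"] = status
        out[f"{b}_conc"] = conc
    return out


# ---------------------------------------------------------------------------
# persistence: npz weights + json manifest
# ---------------------------------------------------------------------------

def save_cascade(cascade: TrainedCascade, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cascade.seed, "models": {}}
    for b, model in cascade.classifiers.items():
        _save_model(model, outdir, f"class_{b}", manifest)
    for b, ranges in cascade.quantifiers.items():
        for label, model in ranges.items():
            _save_model(model, outdir, f"quant_{b}_{label}", manifest)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _save_model(model: TrainedModel, outdir: Path, key: str, manifest: dict) -> None:
    arrays = {f"p_{k}": v for k, v in model.params.items()}
    arrays.update({f"bn_{k}": np.asarray(v) for k, v in model.bn_stats.items()})
    arrays["x_mean"] = model.x_mean
    arrays["x_sd"] = model.x_sd
    fname = f"{key}.npz".replace(">", "ge").replace("<", "lt")
    np.savez(outdir / fname, **arrays)
    s = model.spec
    manifest["models"][key] = {
        "file": fname, "biomarker": s.biomarker, "stage": s.stage,
        "range_label": s.range_label, "features": list(s.features),
        "hidden": list(s.hidden), "dropout": s.dropout, "loss": s.loss,
        "n_classes": s.n_classes, "batchnorm": s.batchnorm, "l2": s.l2,
        "batch_size": s.batch_size, "lr": s.lr, "lr_factor": s.lr_factor,
        "lr_period": s.lr_period, "max_epochs": s.max_epochs,
        "patience": s.patience, "min_delta": s.min_delta,
        "target_transform": s.target_transform, "target_scale": s.target_scale,
        "target": {"kind": model.target.kind, "scale": model.target.scale,
                   "mean": model.target.mean, "sd": model.target.sd},
        "best_epoch": model.best_epoch, "seed": model.seed,
    }


def load_cascade(indir: str | Path) -> TrainedCascade:
    from .nn import TargetTransform
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    classifiers: dict[str, TrainedModel] = {}
    quantifiers: dict[str, dict[str, TrainedModel]] = {b: {} for b in BIOMARKERS}
    for key, m in manifest["models"].items():
        data = np.load(indir / m["file"])
        params = {k[2:]: data[k] for k in data.files if k.startswith("p_")}
        bn = {k[3:]: (float(data[k]) if data[k].ndim == 0 else data[k])
              for k in data.files if k.startswith("bn_")}
        spec = ModelSpec(
            name=key, biomarker=m["biomarker"], stage=m["stage"],
            features=tuple(m["features"]), hidden=tuple(m["hidden"]),
            dropout=m["dropout"], loss=m["loss"], n_classes=m["n_classes"],
            range_label=m["range_label"], batchnorm=m["batchnorm"], l2=m["l2"],
            batch_size=m["batch_size"], lr=m["lr"], lr_factor=m["lr_factor"],
            lr_period=m["lr_period"], max_epochs=m["max_epochs"],
            patience=m["patience"], min_delta=m["min_delta"],
            target_transform=m["target_transform"], target_scale=m["target_scale"])
        t = m["target"]
        model = TrainedModel(
            spec=spec, params=params, bn_stats=bn, x_mean=data["x_mean"],
            x_sd=data["x_sd"],
            target=TargetTransform(t["kind"], t["scale"], t["mean"], t["sd"]),
            loss_trace=[], best_epoch=m["best_epoch"], seed=m["seed"])
        if spec.stage == "classifier":
            classifiers[spec.biomarker] = model
        else:
            quantifiers[spec.biomarker][spec.range_label] = model
    return TrainedCascade(classifiers=classifiers, quantifiers=quantifiers,
                          seed=manifest["seed"])
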