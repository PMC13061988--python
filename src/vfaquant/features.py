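"""Greedy iterative backward feature elimination over immunoreaction
conditions.

Starting from a model's complete feature set (five colorimetric conditions
for CK-MB/NT-proBNP models, six colorimetric+CL conditions for cTnI
models), each round retrains the model on every leave-one-out subset of the
current best subset and keeps the winner, down to single features.  The
returned subset is the global best over *all* evaluated subsets.  For a
starting set of p features this evaluates exactly 1 + p + (p-1) + ... + 2 =
p(p+1)/2 candidates.

The criterion is training accuracy for classifiers (maximised) or the
training loss for quantifiers (minimised), evaluated on the training set.
Every candidate is retrained from the same base seed so that criterion
differences reflect the features, not initialisation.  Ties prefer the
smaller subset, then lexicographic feature order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .nn import ModelSpec, TrainedModel, train_model

logger = logging.getLogger(__name__)


def _criterion(spec: ModelSpec, model: TrainedModel, X: np.ndarray,
               y: np.ndarray) -> float:
    if spec.stage == "classifier":
        return float((model.predict_class(X) == y).mean())  # training accuracy
    # quantifiers: final (best) training loss on transformed targets
    from .nn import _eval_loss
    return _eval_loss(model.spec, model.params, model.bn_stats,
                      model._standardize(X), model.target.apply(y))


def apply_subset(features: pd.DataFrame | pd.Series, subset) -> np.ndarray:
    """Extract the subset's columns, in subset order."""
    subset = list(subset)
    if isinstance(features, pd.Series):
        missing = [c for c in subset if c not in features.index]
        if missing:
            raise KeyError(f"unknown feature identifiers {missing}")
        return features.loc[subset].to_numpy(float)
    missing = [c for c in subset if c not in features.columns]
    if missing:
        raise KeyError(f"unknown feature identifiers {missing}")
    return features.loc[:, subset].to_numpy(float)


@dataclass(frozen=True)
class EliminationResult:
    best_subset: tuple[str, ...]
    best_criterion: float
    trace: pd.DataFrame   # iteration, subset, criterion, kept


def backward_eliminate(spec: ModelSpec, features: pd.DataFrame,
                       y: np.ndarray, seed: int = 0) -> EliminationResult:
    """Run backward elimination for one model specification.

    ``spec.features`` defines the full starting set; ``features`` must
    contain those columns and ``y`` the labels/targets.  Failed candidate
    trainings are recorded in the trace and skipped with a warning.
    """
    maximize = spec.stage == "classifier"
    sign = 1.0 if maximize else -1.0
    y = np.asarray(y)

    def evaluate(subset: tuple[str, ...]) -> float | None:
        sub_spec = replace(spec, features=subset)
        X = apply_subset(features, subset)
        try:
            model = train_model(sub_spec, X, y, seed=seed)
        except Exception as exc:  # candidate failure: skip, keep going
            logger.warning("candidate %s failed: %s", subset, exc)
            return None
        return _criterion(sub_spec, model, X, y)

    rows = []
    current = tuple(spec.features)
    best_subset, best_crit = None, -np.inf
    iteration = 0

    def record(subset, crit, kept):
        rows.append({"iteration": iteration, "subset": "|".join(subset),
                     "n_features": len(subset),
                     "criterion": crit, "kept": kept})

    def better(crit, subset, ref_crit, ref_subset) -> bool:
        if ref_subset is None:
            return True
        if sign * crit != sign * ref_crit:
            return sign * crit > sign * ref_crit
        if len(subset) != len(ref_subset):
            return len(subset) < len(ref_subset)
        return tuple(sorted(subset)) < tuple(sorted(ref_subset))

    crit = evaluate(current)
    if crit is None:
        raise RuntimeError("training failed on the full feature set")
    record(current, crit, True)
    best_subset, best_crit = current, crit

    while len(current) > 1:
        iteration += 1
        candidates = [tuple(f for f in current if f != drop) for drop in current]
        round_best, round_crit = None, None
        for cand in candidates:
            c = evaluate(cand)
            record(cand, c if c is not None else np.nan, False)
            if c is None:
                continue
            if round_best is None or better(c, cand, round_crit, round_best):
                round_best, round_crit = cand, c
        if round_best is None:
            break
        for row in rows[::-1]:
            if row["iteration"] == iteration and row["subset"] == "|".join(round_best):
                row["kept"] = True
                break
        if better(round_crit, round_best, best_crit, best_subset):
            best_subset, best_crit = round_best, round_crit
        current = round_best

    return EliminationResult(best_subset=best_subset, best_criterion=best_crit,
                             trace=pd.DataFrame(rows))
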