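"""k-fold cross-validation of the distance model with two metrics.

Prediction accuracy is the Pearson correlation coefficient between the
predicted and actual distances of a held-out fold, expressed in percent
(signed; 100 means perfectly linearly related, which is the criterion the
reference protocol uses even though it is insensitive to affine bias).
Average error is the mean absolute difference in millimetres (RMSE
available).  Folds are a seeded uniform shuffle into k near-equal disjoint
parts; per-fold metrics are reported with their mean and sample SD (ddof=1,
n = k).  An optional grouped mode keeps all trials of one subject in the
same fold to avoid leaking subject effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import json
import numpy as np
from scipy import stats
from sklearn.model_selection import GroupKFold, KFold

from .errors import ConstantTruth, LengthMismatch
from .nerve_model import FeatureRecord, FitConfig, Variant, fit_model

__all__ = ["CVReport", "prediction_accuracy", "average_error", "cross_validate"]


def _paired(predicted, actual) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape or p.ndim != 1:
        raise LengthMismatch(
            f"predicted and actual must be 1-D and equal length "
            f"(got {p.shape} vs {a.shape})"
        )
    return p, a


def prediction_accuracy(predicted, actual) -> float:
    """Signed Pearson correlation between prediction and truth, in percent."""
    p, a = _paired(predicted, actual)
    if p.size < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.ptp(a) == 0.0:
        raise ConstantTruth("actual distances are constant; correlation undefined")
    r = stats.pearsonr(p, a).statistic
    return float(100.0 * r)


def average_error(predicted, actual, *, metric: str = "mae") -> float:
    """Mean absolute (default) or root-mean-square prediction error, mm."""
    p, a = _paired(predicted, actual)
    if p.size < 1:
        raise LengthMismatch("need at least one pair")
    resid = p - a
    if metric == "mae":
        return float(np.mean(np.abs(resid)))
    if metric == "rmse":
        return float(np.sqrt(np.mean(resid**2)))
    raise ValueError(f"unknown metric '{metric}' (use 'mae' or 'rmse')")


@dataclass
class CVReport:
    """Cross-validation outcome: per-fold metrics and their summary."""

    k: int
    seed: int
    variant: str
    fold_accuracy: list[float]
    fold_error: list[float]
    mean_accuracy: float
    sd_accuracy: float
    mean_error: float
    sd_error: float
    fold_assignments: list[int]          # record index -> fold
    oof_predictions: list[float]         # out-of-fold prediction per record
    failed_folds: list[int] = field(default_factory=list)
    metric: str = "mae"

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def cross_validate(
    records: Sequence[FeatureRecord],
    variant: Variant = "extended",
    k: int = 10,
    seed: int = 0,
    *,
    fit_config: FitConfig | None = None,
    metric: str = "mae",
    group_by_subject: bool = False,
) -> CVReport:
    """Seeded k-fold cross-validation of the distance model.

    Shuffles the records into ``k`` near-equal disjoint folds, fits the
    requested variant on each training remainder and scores its predictions
    on the held-out fold with both metrics.  A fold whose fit raises is
    flagged in ``failed_folds`` (its metrics are NaN) rather than aborting
    the run.  With ``group_by_subject`` the split keeps each subject's
    records together (GroupKFold; deterministic, ignores the seed).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(records) < k:
        raise ValueError(f"need at least k={k} records, got {len(records)}")
    fit_config = fit_config or FitConfig(seed=seed)

    records = list(records)
    n = len(records)
    if group_by_subject:
        groups = np.array([r.subject if r.subject is not None else i
                           for i, r in enumerate(records)])
        splitter = GroupKFold(n_splits=k)
        splits = splitter.split(np.zeros(n), groups=groups)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(n))

    fold_assignments = np.full(n, -1, dtype=int)
    oof = np.full(n, np.nan)
    fold_accuracy: list[float] = []
    fold_error: list[float] = []
    failed: list[int] = []

    for fold, (train_idx, test_idx) in enumerate(splits):
        fold_assignments[test_idx] = fold
        train = [records[i] for i in train_idx]
        test = [records[i] for i in test_idx]
        actual = np.array([r.distance_mm for r in test], dtype=float)
        try:
            model = fit_model(train, variant, fit_config)
            pred = model.predict(test)
        except Exception:
            failed.append(fold)
            fold_accuracy.append(np.nan)
            fold_error.append(np.nan)
            continue
        oof[test_idx] = pred
        fold_accuracy.append(prediction_accuracy(pred, actual))
        fold_error.append(average_error(pred, actual, metric=metric))

    acc = np.asarray(fold_accuracy)
    err = np.asarray(fold_error)
    ok = ~np.isnan(acc)
    return CVReport(
        k=k,
        seed=seed,
        variant=variant,
        fold_accuracy=[float(a) for a in acc],
        fold_error=[float(e) for e in err],
        mean_accuracy=float(np.mean(acc[ok])) if ok.any() else float("nan"),
        sd_accuracy=float(np.std(acc[ok], ddof=1)) if ok.sum() > 1 else float("nan"),
        mean_error=float(np.mean(err[ok])) if ok.any() else float("nan"),
        sd_error=float(np.std(err[ok], ddof=1)) if ok.sum() > 1 else float("nan"),
        fold_assignments=fold_assignments.tolist(),
        oof_predictions=[float(p) for p in oof],
        failed_folds=failed,
        metric=metric,
    )
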