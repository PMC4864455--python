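"""Held-out precision calibration and fusion of experimental/computational scores.

Raw FCS and computational-predictor scores live on incomparable scales.  To
fuse them, each score is first mapped to a precision: alleles are split into
10 random folds and, for each held-out allele with raw score s, the
calibrated score is the precision among *training* alleles whose score is at
least s.  The calibrated scores (FCS' and PolyPhen2'-style) are then
combined by one of seven rules: minimum, maximum, mean, or a weighted mean
w1..w4 putting 90/80/70/60% of the weight on the experimental score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateSetError, InputError

COMBINE_WEIGHTS = {"w1": 0.9, "w2": 0.8, "w3": 0.7, "w4": 0.6}
COMBINE_METHODS = ("min", "max", "mean", "w1", "w2", "w3", "w4")

#: Attempts at drawing folds in which every training split holds both classes.
MAX_FOLD_REDRAWS = 100


@dataclass
class CalibrationModel:
    n_folds: int = 10
    seed: int = 0
    fold_assignment: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise InputError("n_folds must be >= 2")


@dataclass
class CalibratedScore:
    value: float
    source: str = ""


def _draw_folds(n: int, labels: np.ndarray, model: CalibrationModel) -> np.ndarray:
    """Random fold labels such that every training split keeps both classes."""
    rng = np.random.default_rng(model.seed)
    for _ in range(MAX_FOLD_REDRAWS):
        folds = rng.permutation(np.arange(n) % model.n_folds)
        ok = True
        for f in range(model.n_folds):
            train = labels[folds != f]
            if train.size == 0 or train.min() == train.max():
                ok = False
                break
        if ok:
            return folds
    raise DegenerateSetError(
        "could not draw folds with both classes in every training split"
    )


def training_precision(train_scores: np.ndarray, train_labels: np.ndarray, cutoff: float) -> float:
    """Precision among training alleles scoring at or above ``cutoff``.

    When no training allele passes the cutoff, the value is the training
    prior — the limit of the precision definition as the passing set grows
    to the whole training set.
    """
    passing = train_scores >= cutoff
    if not passing.any():
        return float(np.mean(train_labels))
    return float(np.mean(train_labels[passing]))


def calibrate(scores, labels, model: CalibrationModel, source: str = "") -> list[CalibratedScore]:
    """Held-out precision calibration of one scorer.

    Returns calibrated scores aligned with the input order.  Deterministic
    given the model seed.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float).astype(int)
    if s.shape != y.shape or s.ndim != 1:
        raise InputError("scores and labels must be equal-length 1-D arrays")
    if y.min() == y.max():
        raise DegenerateSetError("calibration needs both classes")
    if model.fold_assignment is not None:
        folds = np.asarray(model.fold_assignment)
        if folds.shape != s.shape:
            raise InputError("fold_assignment length mismatch")
    else:
        folds = _draw_folds(s.size, y, model)
    prime = source + "'" if source else "calibrated"
    out = np.empty(s.size)
    for f in np.unique(folds):
        train = folds != f
        ts, ty = s[train], y[train]
        for i in np.nonzero(folds == f)[0]:
            out[i] = training_precision(ts, ty, s[i])
    return [CalibratedScore(value=float(v), source=prime) for v in out]


def combine(fcs_prime, pp2_prime, method: str):
    """Combine two calibrated scores; accepts scalars or arrays."""
    if method not in COMBINE_METHODS:
        raise InputError(f"unknown combine method {method!r}")
    a = np.asarray(
        [x.value for x in fcs_prime] if _is_calibrated_list(fcs_prime) else getattr(fcs_prime, "value", fcs_prime),
        dtype=float,
    )
    b = np.asarray(
        [x.value for x in pp2_prime] if _is_calibrated_list(pp2_prime) else getattr(pp2_prime, "value", pp2_prime),
        dtype=float,
    )
    if ((a < 0) | (a > 1) | (b < 0) | (b > 1)).any():
        raise InputError("calibrated scores must lie in [0, 1]")
    if method == "min":
        out = np.minimum(a, b)
    elif method == "max":
        out = np.maximum(a, b)
    elif method == "mean":
        out = (a + b) / 2.0
    else:
        w = COMBINE_WEIGHTS[method]
        out = w * a + (1.0 - w) * b
    return float(out) if out.ndim == 0 else out


def _is_calibrated_list(x) -> bool:
    return isinstance(x, (list, tuple)) and x and isinstance(x[0], CalibratedScore)
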