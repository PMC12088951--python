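"""Predictive-quality metrics and repeated K-fold cross-validation.

The model is judged by the mean absolute percentage error (MAPE) between the
predicted recovery/loss curve and held-out data, with the customary
interpretability bands (<10% highly accurate, 10–20% good, 20–50% reasonable,
>50% inaccurate; below 20% the model is considered suitable). Cross-validation
repeatedly partitions the replicate traces into K folds, estimates rates from
the training folds' average curve, predicts the validation grid with the
closed-form solution, and scores against the validation fold's average curve.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from . import cme
from .expfit import average_trace, fit_exponential, plateau_estimate, turnover_rate
from .traces import Modality, TraceSet

__all__ = [
    "MapeBand",
    "CVResult",
    "mape",
    "rmse",
    "interpret_mape",
    "kfold_cv",
]

#: Observations with |value| below this are excluded from MAPE (e.g. the exact
#: zero at t=0 of an ideal recovery curve).
MAPE_ZERO_TOL = 1e-12


class MapeBand(enum.Enum):
    """Forecasting-quality bands for MAPE (%); lower edges inclusive."""

    HIGHLY_ACCURATE = "Highly accurate"
    GOOD = "Good"
    REASONABLE = "Reasonable"
    INACCURATE = "Inaccurate"

    @property
    def label(self) -> str:
        return self.value


def mape(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Mean absolute percentage error, in percent.

    Points whose observed value is (numerically) zero are excluded before
    averaging; it is an error if nothing remains.
    """
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape or pred.size == 0:
        raise ValueError("predicted and observed must be nonempty arrays of equal shape")
    keep = np.abs(obs) > MAPE_ZERO_TOL
    if not keep.any():
        raise ValueError("all observed points are zero; MAPE undefined")
    return float(100.0 * np.mean(np.abs(pred[keep] - obs[keep]) / np.abs(obs[keep])))


def rmse(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Root-mean-square error, in the units of the intensities."""
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape or pred.size == 0:
        raise ValueError("predicted and observed must be nonempty arrays of equal shape")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def interpret_mape(m: float) -> MapeBand:
    """Map a MAPE value (%) onto its interpretability band."""
    if m < 0:
        raise ValueError(f"MAPE must be nonnegative, got {m}")
    if m < 10.0:
        return MapeBand.HIGHLY_ACCURATE
    if m < 20.0:
        return MapeBand.GOOD
    if m < 50.0:
        return MapeBand.REASONABLE
    return MapeBand.INACCURATE


@dataclass(frozen=True)
class CVResult:
    """Aggregate of repeated K-fold cross-validation."""

    k: int
    reps: int
    mape_mean: float
    mape_se: float
    per_rep_mape: tuple[float, ...]
    seed: int

    @property
    def band(self) -> MapeBand:
        return interpret_mape(self.mape_mean)


def _predict(rates: cme.DynamicRates, modality: Modality, times: np.ndarray) -> np.ndarray:
    if modality is Modality.FRAP:
        return cme.predict_frap(rates, times)
    return cme.predict_flap(rates, times)


def kfold_cv(
    traceset: TraceSet,
    k: int,
    reps: int,
    seed: int,
    *,
    m: int = 1,
    plateau: str = "fit",
    per_replicate: bool = False,
    exterior_plateau: bool | None = None,
) -> CVResult:
    """Repeated K-fold cross-validation of the closed-form model.

    Per repetition the replicate indices are shuffled with the seeded
    generator and split into ``k`` folds whose sizes differ by at most one.
    For each fold, rates are estimated from the training folds (average curve
    → exponential fit → inversion) and the closed-form prediction is scored by
    MAPE against the validation fold's average curve (or against each
    validation replicate when ``per_replicate``). The repetition's MAPE is the
    mean over folds; the result aggregates repetitions with mean and standard
    error. Fully reproducible given ``seed``.
    """
    n = len(traceset)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if n < k:
        raise ValueError(f"number of traces ({n}) must be >= k ({k})")
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    rng = np.random.default_rng(seed)
    modality = traceset.modality
    per_rep: list[float] = []
    for _ in range(reps):
        order = rng.permutation(n)
        folds = np.array_split(order, k)
        fold_mapes = []
        for fold in folds:
            val_idx = set(int(i) for i in fold)
            train = TraceSet(
                tuple(tr for i, tr in enumerate(traceset) if i not in val_idx),
                protein=traceset.protein,
            )
            val = TraceSet(
                tuple(tr for i, tr in enumerate(traceset) if i in val_idx),
                protein=traceset.protein,
            )
            train_avg = average_trace(train)
            fit = fit_exponential(train_avg)
            k_t = turnover_rate(fit)
            n_bar, _ = plateau_estimate(fit, train_avg, plateau=plateau, m=m,
                                        exterior_plateau=exterior_plateau)
            rates = cme.dynamic_rates(k_t, n_bar)
            if per_replicate:
                scores = []
                for tr in val:
                    pred = _predict(rates, modality, tr.times)
                    scores.append(mape(pred, tr.intensities))
                fold_mapes.append(float(np.mean(scores)))
            else:
                val_avg = average_trace(val)
                pred = _predict(rates, modality, val_avg.times)
                fold_mapes.append(mape(pred, val_avg.intensities))
        per_rep.append(float(np.mean(fold_mapes)))
    arr = np.asarray(per_rep)
    se = float(arr.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0
    return CVResult(
        k=k,
        reps=reps,
        mape_mean=float(arr.mean()),
        mape_se=se,
        per_rep_mape=tuple(per_rep),
        seed=seed,
    )
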