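"""Sensitivity/specificity estimation and threshold choice from the mixture.

With the mixture fitted, the classification rates for "has a clonal
relative" at a candidate threshold t are areas under the weighted
component densities over the observed distance range (t1, t2):

    TP = lambda1 * [F1(t)  - F1(t1)]      FN = lambda1 * [F1(t2) - F1(t)]
    FP = lambda2 * [F2(t)  - F2(t1)]      TN = lambda2 * [F2(t2) - F2(t)]

with F_i the component CDFs (closed form: Gaussian error function or
regularized lower incomplete gamma — no quadrature in the hot path).
Sensitivity is TP/(TP+FN), specificity TN/(TN+FP), and the reported
threshold maximizes their (optionally weighted) average over a uniform
grid strictly inside (t1, t2), where t1 and t2 are the minimum and maximum
of the distance-to-nearest sample. Ties resolve to the smallest t, which
favors specificity at equal objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateModelError
from .mixture import MixtureModel

__all__ = [
    "ConfusionAreas",
    "ThresholdResult",
    "confusion_areas",
    "sen_spc",
    "estimated_curves",
    "find_threshold",
    "threshold_report",
]

DEFAULT_GRID_SIZE = 1000
# component mass below this inside (t1, t2) makes SEN/SPC meaningless
_MASS_FLOOR = 1e-12


@dataclass(frozen=True)
class ConfusionAreas:
    """Probability-mass confusion rates at threshold t within [t1, t2]."""

    tp: float
    fn: float
    fp: float
    tn: float
    t: float
    t1: float
    t2: float


def confusion_areas(model: MixtureModel, t: float, t1: float, t2: float) -> ConfusionAreas:
    """Areas under the weighted component densities split at t."""
    if not (t1 <= t <= t2):
        raise ValueError(f"threshold {t} outside [{t1}, {t2}]")
    f1_t1, f1_t, f1_t2 = model.comp1.cdf([t1, t, t2])
    f2_t1, f2_t, f2_t2 = model.comp2.cdf([t1, t, t2])
    return ConfusionAreas(
        tp=model.lambda1 * float(f1_t - f1_t1),
        fn=model.lambda1 * float(f1_t2 - f1_t),
        fp=model.lambda2 * float(f2_t - f2_t1),
        tn=model.lambda2 * float(f2_t2 - f2_t),
        t=t,
        t1=t1,
        t2=t2,
    )


def sen_spc(areas: ConfusionAreas) -> tuple[float, float]:
    """Sensitivity TP/(TP+FN) and specificity TN/(TN+FP)."""
    pos = areas.tp + areas.fn
    neg = areas.tn + areas.fp
    if pos <= _MASS_FLOOR:
        raise DegenerateModelError(
            "component 1 has no mass in (t1, t2); sensitivity undefined"
        )
    if neg <= _MASS_FLOOR:
        raise DegenerateModelError(
            "component 2 has no mass in (t1, t2); specificity undefined"
        )
    return areas.tp / pos, areas.tn / neg


def estimated_curves(
    model: MixtureModel, grid: np.ndarray, t1: float, t2: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized SEN(t) and SPC(t) over a grid of thresholds.

    Grid values are clamped into [t1, t2]. Points where a component has no
    mass in (t1, t2) come back as NaN.
    """
    grid = np.clip(np.asarray(grid, dtype=float), t1, t2)
    f1_t1, f1_t2 = model.comp1.cdf([t1, t2])
    f2_t1, f2_t2 = model.comp2.cdf([t1, t2])
    mass1 = model.lambda1 * (f1_t2 - f1_t1)
    mass2 = model.lambda2 * (f2_t2 - f2_t1)
    sen = (
        model.lambda1 * (model.comp1.cdf(grid) - f1_t1) / mass1
        if mass1 > _MASS_FLOOR
        else np.full(grid.shape, np.nan)
    )
    spc = (
        model.lambda2 * (f2_t2 - model.comp2.cdf(grid)) / mass2
        if mass2 > _MASS_FLOOR
        else np.full(grid.shape, np.nan)
    )
    return np.asarray(sen, dtype=float), np.asarray(spc, dtype=float)


@dataclass
class ThresholdResult:
    """Chosen threshold plus the SEN/SPC curves it was selected from."""

    threshold: float
    t1: float
    t2: float
    grid: np.ndarray
    sen_curve: np.ndarray
    spc_curve: np.ndarray
    sensitivity: float
    specificity: float
    objective: float
    weight: float = 0.5


def find_threshold(
    model: MixtureModel,
    x,
    grid_size: int = DEFAULT_GRID_SIZE,
    weight: float = 0.5,
) -> ThresholdResult:
    """Choose t in (min x, max x) maximizing w*SEN(t) + (1-w)*SPC(t).

    The objective is evaluated on ``grid_size`` uniform points strictly
    inside the interval (endpoints excluded); ties go to the smallest t.
    The default weight 0.5 is the average of sensitivity and specificity.
    """
    if grid_size < 100:
        raise ValueError("grid_size must be at least 100")
    if not 0.0 <= weight <= 1.0:
        raise ValueError("weight must lie in [0, 1]")
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise DegenerateModelError("empty distance vector")
    t1, t2 = float(x.min()), float(x.max())
    if not t2 > t1:
        raise DegenerateModelError("distance vector has zero range")
    grid = np.linspace(t1, t2, grid_size + 2)[1:-1]
    sen, spc = estimated_curves(model, grid, t1, t2)
    objective = weight * sen + (1.0 - weight) * spc
    if np.all(np.isnan(objective)):
        raise DegenerateModelError("objective undefined on the whole grid")
    idx = int(np.nanargmax(objective))  # first occurrence == smallest t on ties
    return ThresholdResult(
        threshold=float(grid[idx]),
        t1=t1,
        t2=t2,
        grid=grid,
        sen_curve=sen,
        spc_curve=spc,
        sensitivity=float(sen[idx]),
        specificity=float(spc[idx]),
        objective=float(objective[idx]),
        weight=weight,
    )


def threshold_report(model: MixtureModel, result: ThresholdResult) -> dict:
    """JSON-ready summary of a fitted model and its chosen threshold."""
    return {
        "t1": result.t1,
        "t2": result.t2,
        "threshold": result.threshold,
        "family1": model.comp1.family,
        "family2": model.comp2.family,
        "lambda1": model.lambda1,
        "lambda2": model.lambda2,
        "phi1": list(model.comp1.params),
        "phi2": list(model.comp2.params),
        "log_likelihood": model.log_likelihood,
        "sensitivity": result.sensitivity,
        "specificity": result.specificity,
        "n_distances": model.n,
    }
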