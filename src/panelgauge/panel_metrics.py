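"""Panel evaluation metrics: least-squares R² and angular distance.

Two measurements of how well panel-based TMB (x) tracks WES-based TMB
(y) across a cohort:

* the coefficient of determination R² of the least-squares line
  y = a·x + b — the mainstream concordance measure, dominated by the
  cohort's highest-TMB patients because each patient enters through its
  squared residual (a patient at k× the TMB of another, with the same
  relative bias, contributes ≈ k² times the squared residual);
* the mean angular distance θ = Σθᵢ/n with
  θᵢ = |π/4 − arctan(yᵢ/xᵢ)| — the deviation of each patient's (x, y)
  point from the identity direction in polar coordinates.  θᵢ is scale
  invariant, so every patient is weighted equally regardless of TMB.

The slope/intercept/R² closed forms are implemented directly (not
delegated to a stats library) so the pipeline is self-contained and can
be cross-checked against an independent solver in the test suite.

Degenerate-input conventions (logged per occurrence):

* (x, y) = (0, 0): θ = 0 — a patient with zero mutations correctly
  estimated as zero is a perfect prediction; arctan(y/x) is 0/0 there.
* x = 0, y > 0: θ = π/4, the arctan limit — the panel detected nothing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .tmb_core import PairedTMB

logger = logging.getLogger(__name__)

#: Relative tolerance for the identity assertions (residual sum ≈ 0 etc.).
IDENTITY_RTOL = 1e-9

HYPERMUTATION_INCLUDED = "hypermutation_included"
NON_HYPERMUTATION = "non_hypermutation"


class DegenerateFitError(ValueError):
    """The regression is undefined (fewer than two points or constant x)."""


class UndefinedMetricError(ValueError):
    """R² is undefined because y has zero variance."""


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


@dataclass(frozen=True)
class PolarPoint:
    radius: float
    angle: float


@dataclass(frozen=True)
class PanelEvaluation:
    """Metric bundle for one panel on one dataset split.

    Regression fields are NaN when the split is too small or degenerate
    for a least-squares fit; mean_angular_distance is always defined for
    a non-empty split.
    """

    dataset_label: str
    n_patients: int
    slope: float
    intercept: float
    r_squared: float
    mean_angular_distance: float
    accuracy: float = math.nan


def _as_xy(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    return x, y


def fit_linear(x: Sequence[float], y: Sequence[float]) -> LinearFit:
    """Least-squares line y = a·x + b via the closed-form normal equations.

    a = Σ(xᵢ−x̄)(yᵢ−ȳ) / Σ(xᵢ−x̄)²,  b = ȳ − a·x̄.
    """
    x, y = _as_xy(x, y)
    if x.size < 2:
        raise DegenerateFitError(f"need at least 2 points, got {x.size}")
    xbar, ybar = x.mean(), y.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    if sxx == 0.0:
        raise DegenerateFitError("x is constant; slope undefined")
    slope = float(np.sum((x - xbar) * (y - ybar)) / sxx)
    return LinearFit(slope=slope, intercept=float(ybar - slope * xbar))


def r_squared(x: Sequence[float], y: Sequence[float]) -> float:
    """Coefficient of determination 1 − Σ(yᵢ−a·xᵢ−b)² / Σ(yᵢ−ȳ)²."""
    x, y = _as_xy(x, y)
    fit = fit_linear(x, y)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise UndefinedMetricError("y has zero variance; R² undefined")
    ssr = float(np.sum((y - fit.predict(x)) ** 2))
    return 1.0 - ssr / sst


def to_polar(x: float, y: float) -> PolarPoint:
    """Polar transform of a non-negative TMB pair: r = √(x²+y²), φ = arctan(y/x).

    Conventions: (0, 0) → φ = π/4 (so θ = 0); (0, y>0) → φ = π/2.
    """
    if x < 0 or y < 0:
        raise ValueError(f"TMB values must be non-negative, got ({x}, {y})")
    if x == 0 and y == 0:
        logger.debug("to_polar(0, 0): angle convention π/4 applied")
        return PolarPoint(radius=0.0, angle=math.pi / 4)
    return PolarPoint(radius=math.hypot(x, y), angle=math.atan2(y, x))


def angular_distance(x: float, y: float) -> float:
    """θ = |π/4 − arctan(y/x)| for one patient, in radians ∈ [0, π/4]."""
    return abs(math.pi / 4 - to_polar(x, y).angle)


def angular_distances(x: Sequence[float], y: Sequence[float]) -> np.ndarray:
    """Vectorised :func:`angular_distance` with the same conventions."""
    x, y = _as_xy(x, y)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("TMB values must be non-negative")
    theta = np.abs(np.pi / 4 - np.arctan2(y, x))
    both_zero = (x == 0) & (y == 0)
    n_zero = int(both_zero.sum())
    if n_zero:
        logger.debug("angular_distances: θ=0 convention applied to %d (0,0) pairs", n_zero)
        theta = np.where(both_zero, 0.0, theta)
    return theta


def mean_angular_distance(pairs: Iterable[PairedTMB]) -> float:
    """θ̄ = Σθᵢ/n over the cohort; every patient weighted equally."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("mean_angular_distance of an empty cohort is undefined")
    x = np.array([p.panel_tmb for p in pairs])
    y = np.array([p.wes_tmb for p in pairs])
    return float(angular_distances(x, y).mean())


def bias_to_theta(relative_bias: float) -> float:
    """Angular distance of a panel under/over-estimating by ``relative_bias``.

    A panel underestimating WES TMB by a fraction β places the patient at
    x = (1−β)·y, i.e. y/x = 1/(1−β), giving θ = |π/4 − arctan(1/(1−β))|.
    By arctan(r) + arctan(1/r) = π/2 this equals the overestimation case
    |π/4 − arctan(1−β)|.  β = 0.20 → 0.1107; β = 0.10 → 0.0526.
    """
    if not 0.0 < relative_bias < 1.0:
        raise ValueError(f"relative_bias must be in (0, 1), got {relative_bias}")
    return abs(math.pi / 4 - math.atan(1.0 / (1.0 - relative_bias)))


def bias_ratio(pair: PairedTMB) -> float:
    """panel_tmb / wes_tmb; NaN (undefined, logged) when wes_tmb = 0."""
    if pair.wes_tmb == 0:
        logger.debug(
            "bias_ratio undefined for patient %s (wes_tmb = 0)", pair.patient_id
        )
        return math.nan
    return pair.panel_tmb / pair.wes_tmb


def classification_accuracy(
    pairs: Iterable[PairedTMB],
    threshold: float,
    band: tuple[float, float] | None = None,
) -> float:
    """Fraction of patients classified TMB-high/low concordantly by panel and WES.

    TMB-high means TMB ≥ ``threshold`` on both axes.  When ``band``
    = (lo, hi) is given, only patients with wes_tmb in the closed
    interval [lo, hi] are scored; an empty band yields NaN.
    """
    if not threshold > 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    pairs = list(pairs)
    if band is not None:
        lo, hi = band
        if lo > hi:
            raise ValueError(f"band lower bound {lo} exceeds upper bound {hi}")
        pairs = [p for p in pairs if lo <= p.wes_tmb <= hi]
    if not pairs:
        logger.warning("classification_accuracy: no patients in band %s", band)
        return math.nan
    agree = sum(
        (p.panel_tmb >= threshold) == (p.wes_tmb >= threshold) for p in pairs
    )
    return agree / len(pairs)


def _evaluate_split(
    pairs: list[PairedTMB],
    label: str,
    threshold: float | None,
    band: tuple[float, float] | None,
) -> PanelEvaluation:
    x = np.array([p.panel_tmb for p in pairs])
    y = np.array([p.wes_tmb for p in pairs])
    theta = float(angular_distances(x, y).mean())
    slope = intercept = r2 = math.nan
    try:
        fit = fit_linear(x, y)
        slope, intercept = fit.slope, fit.intercept
        r2 = r_squared(x, y)
    except (DegenerateFitError, UndefinedMetricError) as exc:
        logger.warning("%s: regression undefined (%s); θ still reported", label, exc)
    accuracy = (
        classification_accuracy(pairs, threshold, band)
        if threshold is not None
        else math.nan
    )
    return PanelEvaluation(
        dataset_label=label,
        n_patients=len(pairs),
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        mean_angular_distance=theta,
        accuracy=accuracy,
    )


def evaluate_panel(
    pairs: Iterable[PairedTMB],
    split_hypermutation: bool = True,
    threshold: float | None = None,
    band: tuple[float, float] | None = None,
) -> list[PanelEvaluation]:
    """Evaluate one panel on the full cohort and, optionally, without
    hypermutated patients.

    Returns one :class:`PanelEvaluation` for the hypermutation-included
    dataset and, when ``split_hypermutation``, a second for the
    non-hypermutation subset.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("cannot evaluate a panel on an empty cohort")
    out = [_evaluate_split(pairs, HYPERMUTATION_INCLUDED, threshold, band)]
    if split_hypermutation:
        non_hyper = [p for p in pairs if not p.hypermutated]
        if non_hyper:
            out.append(_evaluate_split(non_hyper, NON_HYPERMUTATION, threshold, band))
        else:
            logger.warning("all patients hypermutated; no non-hypermutation split")
    return out


def evaluations_to_frame(evaluations, panel_name: str | None = None):
    """Tidy table of evaluations (one row per dataset split)."""
    import pandas as pd

    rows = []
    for ev in evaluations:
        row = {
            "dataset_label": ev.dataset_label,
            "n": ev.n_patients,
            "slope": ev.slope,
            "intercept": ev.intercept,
            "r_squared": ev.r_squared,
            "mean_theta": ev.mean_angular_distance,
            "accuracy": ev.accuracy,
        }
        if panel_name is not None:
            row = {"panel": panel_name, **row}
        rows.append(row)
    return pd.DataFrame(rows)
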