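"""Scalar intensity-derived assays.

Corrected total cell fluorescence (CTCF), pulse-chase degradation
normalization, fold change of summary intensities, and ratiometric pH
calibration (dual-excitation 340/380 nm ratio against clamped-buffer pH)
with inverse extrapolation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError, UndefinedResultError
from .image_quant import as_image

__all__ = [
    "CtcfInput",
    "TimeCourse",
    "CalibrationCurve",
    "PhEstimate",
    "ctcf",
    "ctcf_from_image",
    "degradation_fractions",
    "fold_change",
    "fit_ph_calibration",
    "ph_from_ratio",
]


@dataclass(frozen=True)
class CtcfInput:
    """Operands of CTCF = integrated_density - cell_area * background_mean.

    ``cell_area`` is in pixels and ``background_mean`` is the per-pixel mean
    intensity of a signal-free region (the ImageJ "Measure" convention); the
    caller is responsible for keeping the two in the same unit system.
    """

    integrated_density: float
    cell_area: float
    background_mean: float

    def __post_init__(self) -> None:
        if not (self.cell_area > 0):
            raise InvalidArgumentError("cell_area must be positive")
        if self.integrated_density < 0:
            raise InvalidArgumentError("integrated_density must be >= 0")


def ctcf(inp: CtcfInput) -> float:
    """Corrected total cell fluorescence.

    CTCF = integrated density − (cell area × mean background fluorescence).
    A negative result (background region brighter than the cell average) is
    returned as-is with a warning, never clamped.
    """
    value = inp.integrated_density - inp.cell_area * inp.background_mean
    if value < 0:
        warnings.warn(
            "negative CTCF: background region brighter than the cell mean",
            stacklevel=2,
        )
    return float(value)


def ctcf_from_image(img, cell_mask: np.ndarray, background_mask: np.ndarray) -> float:
    """Measure the CTCF operands on an image and evaluate the formula.

    ``cell_mask`` selects the cell region (integrated density = sum of its
    pixels; area = its pixel count); ``background_mask`` selects a
    signal-free region whose mean intensity estimates the per-pixel
    background.
    """
    image = as_image(img)
    cell = np.asarray(cell_mask, dtype=bool)
    bg = np.asarray(background_mask, dtype=bool)
    if cell.shape != image.shape or bg.shape != image.shape:
        raise InvalidArgumentError("masks must match the image shape")
    if not cell.any() or not bg.any():
        raise InvalidArgumentError("cell and background masks must be non-empty")
    inp = CtcfInput(
        integrated_density=float(image.data[cell].sum()),
        cell_area=float(cell.sum()),
        background_mean=float(image.data[bg].mean()),
    )
    return ctcf(inp)


@dataclass(frozen=True)
class TimeCourse:
    """Ordered (time, mean intensity) pairs including the time-0 pulse."""

    times_min: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=np.float64)
        y = np.asarray(self.intensities, dtype=np.float64)
        if t.size != y.size or t.size < 1:
            raise InvalidArgumentError("times and intensities must pair up")
        if np.any(np.diff(t) <= 0):
            raise InvalidArgumentError("times must strictly increase")
        if t[0] != 0:
            raise InvalidArgumentError("time course must start at the t=0 pulse")
        if np.any(y < 0):
            raise InvalidArgumentError("intensities must be >= 0")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "intensities", y)


def degradation_fractions(tc: TimeCourse) -> list[tuple]:
    """Residual fraction at each chase time, normalized to the t=0 pulse.

    fraction(t) = intensity(t) / intensity(0), so fraction(0) = 1.  Scale
    invariant: multiplying the whole course by k > 0 changes nothing.

    Raises
    ------
    UndefinedResultError
        If the pulse intensity is zero.
    """
    pulse = tc.intensities[0]
    if pulse <= 0:
        raise UndefinedResultError("zero pulse intensity: fractions undefined")
    return [(float(t), float(y / pulse)) for t, y in zip(tc.times_min, tc.intensities)]


def fold_change(treated_mean: float, control_mean: float) -> float:
    """Ratio of a treated-condition mean intensity to the control mean.

    Raises
    ------
    UndefinedResultError
        If the control mean is not strictly positive.
    """
    if not (control_mean > 0):
        raise UndefinedResultError("control mean must be positive")
    return float(treated_mean) / float(control_mean)


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted ratio = slope * pH + intercept relation.

    Fitted over clamped buffers spanning ``ph_range`` (default pH 4-6, the
    near-linear response window of the dye); ``residual_se`` is the
    standard error of the residuals (0 for a 2-point fit).
    """

    slope: float
    intercept: float
    residual_se: float
    n_points: int
    ph_range: tuple = (4.0, 6.0)

    def predict(self, ph) -> np.ndarray:
        return self.slope * np.asarray(ph, dtype=np.float64) + self.intercept


@dataclass(frozen=True)
class PhEstimate:
    """A pH inferred from a fluorescence ratio; ``in_range`` is False when
    the value falls outside the calibration range (extrapolation)."""

    ph: float
    in_range: bool


def fit_ph_calibration(readings) -> CalibrationCurve:
    """Ordinary least-squares line of 340/380 ratio on buffer pH.

    ``readings`` is a DataFrame with columns ``ph`` and ``ratio_340_380``
    (or any two-column table interpreted as (pH, ratio)).

    Raises
    ------
    InvalidArgumentError
        With fewer than 2 distinct pH values the line is unidentifiable.
    """
    if isinstance(readings, pd.DataFrame):
        if "ph" in readings.columns and "ratio_340_380" in readings.columns:
            ph = readings["ph"].to_numpy(dtype=np.float64)
            ratio = readings["ratio_340_380"].to_numpy(dtype=np.float64)
        else:
            ph = readings.iloc[:, 0].to_numpy(dtype=np.float64)
            ratio = readings.iloc[:, 1].to_numpy(dtype=np.float64)
    else:
        arr = np.asarray(readings, dtype=np.float64)
        ph, ratio = arr[:, 0], arr[:, 1]
    if np.unique(ph).size < 2:
        raise InvalidArgumentError("need >= 2 distinct pH values to fit a line")
    xm = ph - ph.mean()
    slope = float(np.dot(xm, ratio) / np.dot(xm, xm))
    intercept = float(ratio.mean() - slope * ph.mean())
    resid = ratio - (slope * ph + intercept)
    n = ph.size
    residual_se = float(np.sqrt(np.dot(resid, resid) / (n - 2))) if n > 2 else 0.0
    return CalibrationCurve(
        slope=slope,
        intercept=intercept,
        residual_se=residual_se,
        n_points=int(n),
        ph_range=(float(ph.min()), float(ph.max())),
    )


def ph_from_ratio(curve: CalibrationCurve, ratio: float) -> PhEstimate:
    """Invert the calibration line: pH = (ratio − intercept) / slope.

    A result outside the calibration pH range is returned with
    ``in_range=False`` rather than rejected — the measured condition may
    genuinely sit outside the buffer series.

    Raises
    ------
    UndefinedResultError
        If the calibration slope is zero (non-invertible).
    """
    if curve.slope == 0 or not math.isfinite(curve.slope):
        raise UndefinedResultError("zero or non-finite calibration slope")
    ph = (float(ratio) - curve.intercept) / curve.slope
    lo, hi = curve.ph_range
    tol = 1e-9  # don't flag round-trip noise at the range boundaries
    return PhEstimate(ph=ph, in_range=bool(lo - tol <= ph <= hi + tol))
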