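"""Pearson and Manders colocalization coefficients for two-channel images.

Mirrors the common ImageJ/JaCOP workflow: optional per-channel
maximum-entropy thresholding, then the pixel-wise Pearson product-moment
correlation and the thresholded Manders overlap fractions M1/M2.

Conventions
-----------
M1 is the fraction of supra-threshold channel-A intensity found in
B-positive pixels: M1 = sum(A over A > thrA and B > thrB) / sum(A over
A > thrA); M2 swaps the channels.  Restricting the numerator to the
intersection (as JaCoP does for thresholded Manders) keeps both
coefficients in [0, 1] by construction — they are never clamped after the
fact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateInputError, InvalidArgumentError, UndefinedResultError
from .image_quant import as_image, kapur_threshold

__all__ = [
    "ColocResult",
    "pearson_coefficient",
    "manders_coefficients",
    "coloc_pipeline",
]


@dataclass(frozen=True)
class ColocResult:
    pearson_r: float
    manders_m1: float
    manders_m2: float
    threshold_a: float
    threshold_b: float
    n_pixels: int
    pcc_mode: str  # "union" (supra-threshold union) or "whole"


def _paired(a, b) -> tuple[np.ndarray, np.ndarray]:
    da = as_image(a).data
    db = as_image(b).data
    if da.shape != db.shape:
        raise InvalidArgumentError(
            f"channel shapes differ: {da.shape} vs {db.shape}"
        )
    return da, db


def pearson_coefficient(a, b, mask: np.ndarray | None = None) -> float:
    """Pearson product-moment correlation of two channels over ``mask``
    (whole image if None).

    Raises
    ------
    DegenerateInputError
        If fewer than 2 pixels are selected or either channel has zero
        variance within the mask.
    """
    da, db = _paired(a, b)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != da.shape:
            raise InvalidArgumentError("mask shape must match the images")
        x = da[mask]
        y = db[mask]
    else:
        x = da.ravel()
        y = db.ravel()
    if x.size < 2:
        raise DegenerateInputError("need at least 2 pixels for a correlation")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.dot(xc, xc))
    sy = float(np.dot(yc, yc))
    if sx == 0.0 or sy == 0.0:
        raise DegenerateInputError("zero variance in a channel within the mask")
    r = float(np.dot(xc, yc) / np.sqrt(sx * sy))
    return max(-1.0, min(1.0, r))


def manders_coefficients(a, b, thr_a: float, thr_b: float) -> tuple[float, float]:
    """Thresholded Manders overlap coefficients (M1, M2).

    M1 = sum(A | A > thr_a and B > thr_b) / sum(A | A > thr_a);
    M2 = sum(B | A > thr_a and B > thr_b) / sum(B | B > thr_b).
    Classic (unthresholded) Manders is the special case thr_a = thr_b = 0
    for nonnegative images.

    Raises
    ------
    UndefinedResultError
        If a denominator channel has no supra-threshold signal.
    """
    da, db = _paired(a, b)
    a_pos = da > thr_a
    b_pos = db > thr_b
    denom1 = float(da[a_pos].sum())
    denom2 = float(db[b_pos].sum())
    if denom1 <= 0.0:
        raise UndefinedResultError("channel A has no supra-threshold signal")
    if denom2 <= 0.0:
        raise UndefinedResultError("channel B has no supra-threshold signal")
    m1 = float(da[b_pos & a_pos].sum()) / denom1
    m2 = float(db[a_pos & b_pos].sum()) / denom2
    return m1, m2


def coloc_pipeline(a, b, auto_threshold: bool = True, pcc_mode: str = "union") -> ColocResult:
    """Threshold (optionally) and compute both colocalization coefficients.

    With ``auto_threshold`` each channel gets its own maximum-entropy
    threshold before the Manders coefficients.  The Pearson coefficient is
    computed on raw intensities either over the union of the two
    supra-threshold masks (``pcc_mode="union"``, the default) or over the
    whole frame (``pcc_mode="whole"``); the mode used is recorded in the
    result.  Without ``auto_threshold`` both thresholds are 0 and the PCC is
    whole-frame.
    """
    da, db = _paired(a, b)
    if pcc_mode not in ("union", "whole"):
        raise InvalidArgumentError("pcc_mode must be 'union' or 'whole'")
    if auto_threshold:
        thr_a = kapur_threshold(da)
        thr_b = kapur_threshold(db)
    else:
        thr_a = thr_b = 0.0
        pcc_mode = "whole"
    m1, m2 = manders_coefficients(da, db, thr_a, thr_b)
    if pcc_mode == "union":
        mask = (da > thr_a) | (db > thr_b)
        try:
            r = pearson_coefficient(da, db, mask=mask)
            n_pixels = int(mask.sum())
        except DegenerateInputError:
            # e.g. noiseless full overlap: constant within the union mask;
            # fall back to the whole frame and record it
            pcc_mode = "whole"
            r = pearson_coefficient(da, db)
            n_pixels = da.size
    if pcc_mode == "whole":
        r = pearson_coefficient(da, db)
        n_pixels = da.size
    return ColocResult(
        pearson_r=r,
        manders_m1=m1,
        manders_m2=m2,
        threshold_a=float(thr_a),
        threshold_b=float(thr_b),
        n_pixels=n_pixels,
        pcc_mode=pcc_mode,
    )
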