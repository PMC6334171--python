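"""Two-component colour deconvolution of DAPI / RedDot1 micrographs.

Each pixel's background-subtracted channel vector is modelled as a
nonnegative mixture of two DNA classes (organellar and nuclear), whose
per-channel signatures are estimated from user-marked reference regions.
Solving the 2x2 linear system per pixel separates AT-rich from GC-rich
DNA and guides compartment segmentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import nnls

from .rasters import FieldImage

__all__ = [
    "ReferenceRegions",
    "SignatureMatrix",
    "UnmixedField",
    "estimate_background",
    "estimate_signatures",
    "unmix",
    "CONDITION_WARN_THRESHOLD",
    "CLIPPED_WARN_THRESHOLD",
]

#: condition number above which the two class signatures are flagged as
#: poorly separable (similar AT content of nucleus and organelle)
CONDITION_WARN_THRESHOLD = 30.0
#: warn when more than this fraction of pixels needed negative-solution clipping
CLIPPED_WARN_THRESHOLD = 0.05


@dataclass
class ReferenceRegions:
    """Manually marked masks of organellar-like and nuclear-like pixels."""

    organellar: np.ndarray
    nuclear: np.ndarray
    background: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.organellar = np.asarray(self.organellar, dtype=bool)
        self.nuclear = np.asarray(self.nuclear, dtype=bool)
        if self.organellar.shape != self.nuclear.shape:
            raise ValueError("reference masks must share a shape")
        if not self.organellar.any():
            raise ValueError("organellar reference mask is empty")
        if not self.nuclear.any():
            raise ValueError("nuclear reference mask is empty")
        if np.any(self.organellar & self.nuclear):
            raise ValueError("reference masks must be disjoint")
        if self.background is not None:
            self.background = np.asarray(self.background, dtype=bool)
            if self.background.shape != self.organellar.shape:
                raise ValueError("background mask must share the image shape")
            if np.any(self.background & (self.organellar | self.nuclear)):
                raise ValueError("background mask overlaps a reference mask")


@dataclass
class SignatureMatrix:
    """2x2 mixing matrix: rows = channels (DAPI, RedDot1), columns = classes
    (organellar, nuclear), columns normalised to unit sum."""

    matrix: np.ndarray
    condition_number: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (2, 2):
            raise ValueError("signature matrix must be 2x2")
        if np.any(self.matrix < 0):
            raise ValueError("signature columns must be nonnegative")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise ValueError("signature columns must be normalised to unit sum")

    @classmethod
    def from_columns(cls, organellar: np.ndarray, nuclear: np.ndarray) -> "SignatureMatrix":
        m = np.column_stack([organellar, nuclear]).astype(float)
        if np.any(m < 0):
            raise ValueError("signature columns must be nonnegative")
        sums = m.sum(axis=0)
        if np.any(sums <= 0):
            raise ValueError("a signature column sums to zero")
        m = m / sums
        with np.errstate(divide="ignore"):
            cond = float(np.linalg.cond(m))
        return cls(matrix=m, condition_number=cond)


@dataclass
class UnmixedField:
    """Per-pixel class densities (arbitrary DNA units) from unmixing."""

    organellar: np.ndarray
    nuclear: np.ndarray
    clipped_fraction: float

    def __post_init__(self) -> None:
        if self.organellar.shape != self.nuclear.shape:
            raise ValueError("class rasters must share a shape")
        if not 0.0 <= self.clipped_fraction <= 1.0:
            raise ValueError("clipped_fraction must be in [0, 1]")


def estimate_background(
    field: FieldImage, background_mask: Optional[np.ndarray] = None
) -> np.ndarray:
    """Per-channel background level, as ``array([dapi, reddot])``.

    With a mask: the per-channel median over the mask (robust under shot
    noise).  Without: the per-channel 5th percentile of the whole raster,
    a rough floor that is only exact for noise-free images with enough
    empty area.  A masked estimate exceeding twice the no-mask estimate is
    flagged (the mask likely covers cell interior).
    """
    if background_mask is not None:
        background_mask = np.asarray(background_mask, dtype=bool)
        if not background_mask.any():
            raise ValueError("background mask is empty")
        est = np.array([
            float(np.median(field.dapi[background_mask])),
            float(np.median(field.reddot[background_mask])),
        ])
        rough = np.array([
            float(np.percentile(field.dapi, 5)),
            float(np.percentile(field.reddot, 5)),
        ])
        if np.any(est > 2.0 * np.maximum(rough, 1e-12)):
            warnings.warn(
                "masked background estimate exceeds 2x the whole-image percentile "
                "estimate; the mask may cover cell interior",
                stacklevel=2,
            )
        return est
    return np.array([
        float(np.percentile(field.dapi, 5)),
        float(np.percentile(field.reddot, 5)),
    ])


def estimate_signatures(
    field: FieldImage,
    refs: ReferenceRegions,
    background: np.ndarray,
) -> SignatureMatrix:
    """Estimate the class signature matrix from reference regions.

    Each class column is the median background-subtracted (DAPI, RedDot1)
    vector over its reference mask (median, not mean, for robustness to
    bright speckles in heterogeneous nucleoid texture), normalised to unit
    column sum.  Warns when the condition number exceeds
    :data:`CONDITION_WARN_THRESHOLD` — the situation where nuclear and
    organellar DNA have similar base composition and colour deconvolution
    degrades.
    """
    background = np.asarray(background, dtype=float)
    cols = []
    for name, mask in (("organellar", refs.organellar), ("nuclear", refs.nuclear)):
        med = np.array([
            float(np.median(field.dapi[mask])) - background[0],
            float(np.median(field.reddot[mask])) - background[1],
        ])
        if np.all(med <= 0):
            raise ValueError(
                f"{name} reference region has nonpositive median signal in both channels"
            )
        cols.append(np.clip(med, 0.0, None))
    sig = SignatureMatrix.from_columns(*cols)
    if sig.condition_number > CONDITION_WARN_THRESHOLD:
        warnings.warn(
            f"signature condition number {sig.condition_number:.3g} exceeds "
            f"{CONDITION_WARN_THRESHOLD:g}: DNA classes are poorly separable",
            stacklevel=2,
        )
    return sig


def unmix(
    field: FieldImage,
    sig: SignatureMatrix,
    background: np.ndarray,
    solver: str = "clip",
) -> UnmixedField:
    """Per-pixel linear unmixing into organellar and nuclear densities.

    Solves ``sig.matrix @ d = channels - background`` at every pixel.  The
    default solver takes the unconstrained 2x2 solution and clips negative
    components to zero, reporting the fraction of pixels clipped (warning
    above :data:`CLIPPED_WARN_THRESHOLD`); ``solver='nnls'`` replaces the
    clipped pixels with true nonnegative least-squares solutions as a
    verification mode.
    """
    if solver not in ("clip", "nnls"):
        raise ValueError(f"unknown solver {solver!r}")
    a = sig.matrix
    det = np.linalg.det(a)
    if not np.isfinite(sig.condition_number) or abs(det) < 1e-12:
        raise ValueError("signature matrix is singular; classes cannot be unmixed")

    background = np.asarray(background, dtype=float)
    y = field.channels - background[:, None, None]
    flat = y.reshape(2, -1)
    d = np.linalg.solve(a, flat)

    negative = np.any(d < 0, axis=0)
    clipped_fraction = float(np.mean(negative))
    if solver == "nnls" and negative.any():
        for idx in np.flatnonzero(negative):
            d[:, idx] = nnls(a, flat[:, idx])[0]
    else:
        d = np.clip(d, 0.0, None)

    if clipped_fraction > CLIPPED_WARN_THRESHOLD:
        warnings.warn(
            f"{clipped_fraction:.1%} of pixels required negative-solution handling; "
            "signatures or background may be off",
            stacklevel=2,
        )
    shape = field.shape
    return UnmixedField(
        organellar=d[0].reshape(shape),
        nuclear=d[1].reshape(shape),
        clipped_fraction=clipped_fraction,
    )
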