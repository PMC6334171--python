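"""Compartment segmentation and integrated-intensity proportion estimation.

The organellar proportion of total cellular DNA is measured per cell as
the fraction of integrated, background-subtracted RedDot1 signal falling
in the organellar compartment versus the nucleus, and pooled across
cells as mean +/- standard error.  RedDot1 is the quantitation channel
because its response is nearly composition-independent; DAPI serves only
to separate the DNA classes.  An optional correction divides each
compartment's RedDot1 signal by the fitted dye response at the
compartment's apparent AT fraction (inferred from the DAPI:RedDot1
ratio), converting signal proportions into DNA proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import binary_erosion
from skimage.filters import gaussian, threshold_otsu
from skimage.morphology import remove_small_objects
from skimage.segmentation import expand_labels

from .dye_response import DyeResponseModel, predict
from .rasters import (
    LABEL_BACKGROUND,
    LABEL_NUCLEUS,
    LABEL_ORGANELLE,
    FieldImage,
    validate_labels,
)
from .unmixing import ReferenceRegions, UnmixedField, estimate_background

__all__ = [
    "ProportionEstimate",
    "CellMeasurement",
    "segment_compartments",
    "integrated_signal",
    "proportion_per_cell",
    "pool_proportions",
    "quantify_field",
    "measurement_masks",
    "reference_regions_from_labels",
    "background_mask_from_labels",
]

_SEGMENT_SIGMA = 1.0
_MIN_OBJECT_PX = 10


@dataclass(frozen=True)
class ProportionEstimate:
    """Pooled organellar signal proportion: mean p, SE across cells, cell count."""

    p: float
    se: float
    n_cells: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must be in [0, 1]")
        if self.se < 0:
            raise ValueError("se must be >= 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


@dataclass(frozen=True)
class CellMeasurement:
    """Per-cell integrated signals and organellar proportion."""

    organelle_signal: float
    nucleus_signal: float
    p: float
    organelle_at: Optional[float] = None
    nucleus_at: Optional[float] = None


def segment_compartments(unmixed: UnmixedField) -> np.ndarray:
    """Automatic compartment masks from an unmixed field.

    Per class: Gaussian smoothing (sigma 1 px), Otsu threshold, removal of
    components below 10 px.  Pixels claimed by both classes go to the one
    with larger smoothed density.  Returns a label raster (1 nucleus,
    2 organelle).  This automatic mode stands in for manual area selection
    and cannot distinguish a host nucleus from the cell's own nucleus; use
    a manual label raster (code 3) for that.
    """
    masks = {}
    smoothed = {}
    for name, raster in (("organellar", unmixed.organellar), ("nuclear", unmixed.nuclear)):
        sm = gaussian(raster, sigma=_SEGMENT_SIGMA, preserve_range=True)
        if not np.any(sm > 0):
            raise ValueError(f"segmentation failed: {name} class raster is empty")
        mask = sm > threshold_otsu(sm)
        mask = remove_small_objects(mask, min_size=_MIN_OBJECT_PX)
        if not mask.any():
            raise ValueError(f"segmentation failed: no {name} component of >= "
                             f"{_MIN_OBJECT_PX} px survived thresholding")
        masks[name] = mask
        smoothed[name] = sm

    labels = np.zeros(unmixed.organellar.shape, dtype=np.uint8)
    org_wins = smoothed["organellar"] >= smoothed["nuclear"]
    labels[masks["nuclear"]] = LABEL_NUCLEUS
    labels[masks["organellar"]] = LABEL_ORGANELLE
    both = masks["nuclear"] & masks["organellar"]
    labels[both & ~org_wins] = LABEL_NUCLEUS
    return labels


def integrated_signal(
    field: FieldImage, background: np.ndarray, mask: np.ndarray
) -> float:
    """Total background-subtracted RedDot1 signal over a mask.

    Per-pixel negatives after subtraction are clipped at zero.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("integration mask is empty")
    bg = np.asarray(background, dtype=float)[1]
    return float(np.clip(field.reddot[mask] - bg, 0.0, None).sum())


def proportion_per_cell(org_signal: float, nuc_signal: float) -> float:
    """Organellar fraction p = org / (org + nuc) of one cell's signal."""
    if org_signal < 0 or nuc_signal < 0:
        raise ValueError("signals must be nonnegative")
    total = org_signal + nuc_signal
    if total <= 0:
        raise ValueError("total signal is zero; proportion undefined")
    return org_signal / total


def pool_proportions(per_cell_p: list[float]) -> ProportionEstimate:
    """Pool per-cell proportions: mean and standard error (sd / sqrt(n)).

    A single cell yields se = 0 and a warning — one observation carries no
    spread information.
    """
    p = np.asarray(per_cell_p, dtype=float)
    if p.size == 0:
        raise ValueError("no per-cell proportions to pool")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    n = int(p.size)
    if n == 1:
        warnings.warn("pooling a single cell: standard error reported as 0", stacklevel=2)
        return ProportionEstimate(float(p[0]), 0.0, 1)
    se = float(np.std(p, ddof=1) / np.sqrt(n))
    return ProportionEstimate(float(np.mean(p)), se, n)


def measurement_masks(labels: np.ndarray, expand_px: int = 4) -> dict[int, np.ndarray]:
    """Expand compartment labels into surrounding background for integration.

    Widefield blur pushes part of each compartment's flux just outside its
    geometric footprint; expanding every label by ``expand_px`` (nearest
    label wins, so compartments never merge) recovers those tails, the way
    a generous manual area selection would.  Returns a mask per label code
    present (host nucleus included, so its expanded area is excluded from
    the others).
    """
    labels = validate_labels(labels)
    expanded = expand_labels(labels, distance=expand_px) if expand_px > 0 else labels
    return {
        int(code): expanded == code
        for code in np.unique(labels)
        if code != LABEL_BACKGROUND
    }


def reference_regions_from_labels(labels: np.ndarray, erode_px: int = 1) -> ReferenceRegions:
    """Reference regions for signature estimation from a label raster.

    Erodes the nuclear and organellar labels by ``erode_px`` to keep the
    reference pixels away from blurred compartment edges, mimicking
    representative manual area selection.  Falls back to the uneroded mask
    if erosion empties it.
    """
    labels = validate_labels(labels)

    def core(mask: np.ndarray) -> np.ndarray:
        if erode_px > 0:
            eroded = binary_erosion(mask, iterations=erode_px)
            if eroded.any():
                return eroded
        return mask

    return ReferenceRegions(
        organellar=core(labels == LABEL_ORGANELLE),
        nuclear=core(labels == LABEL_NUCLEUS),
        background=background_mask_from_labels(labels),
    )


def background_mask_from_labels(labels: np.ndarray, margin_px: int = 6) -> np.ndarray:
    """Background pixels at least ``margin_px`` away from any compartment."""
    labels = validate_labels(labels)
    empty = labels == LABEL_BACKGROUND
    mask = binary_erosion(empty, iterations=margin_px)
    return mask if mask.any() else empty


def _apparent_at(
    dapi_signal: float,
    reddot_signal: float,
    dapi_model: DyeResponseModel,
    reddot_model: DyeResponseModel,
) -> float:
    """Invert the DAPI:RedDot1 signal ratio to an apparent AT fraction.

    For affine responses the ratio r(at) = f_dapi(at) / f_red(at) is
    monotone, giving the closed form at = (r*a_r - a_d) / (b_d - r*b_r);
    the result is clamped to [0, 1].  Assumes equal channel exposure gain.
    """
    if reddot_signal <= 0:
        raise ValueError("cannot infer AT fraction from nonpositive RedDot1 signal")
    r = dapi_signal / reddot_signal
    denom = dapi_model.slope - r * reddot_model.slope
    if abs(denom) < 1e-12:
        return 0.5
    at = (r * reddot_model.intercept - dapi_model.intercept) / denom
    return float(np.clip(at, 0.0, 1.0))


def quantify_field(
    field: FieldImage,
    labels: np.ndarray,
    background: Optional[np.ndarray] = None,
    expand_px: int = 4,
    dapi_model: Optional[DyeResponseModel] = None,
    reddot_model: Optional[DyeResponseModel] = None,
) -> CellMeasurement:
    """Measure one cell's organellar proportion from a field and label raster.

    Labels follow the package code scheme; host-nucleus pixels (code 3)
    and their expanded surroundings are excluded from both terms.  When
    ``background`` is None it is estimated as the median over background
    pixels far from any compartment.  When both dye models are given, each
    compartment's RedDot1 signal is divided by the predicted response at
    its apparent AT fraction, so the returned proportion estimates the DNA
    proportion rather than the raw signal proportion.
    """
    labels = validate_labels(labels)
    if background is None:
        background = estimate_background(field, background_mask_from_labels(labels))
    masks = measurement_masks(labels, expand_px=expand_px)
    for code, name in ((LABEL_NUCLEUS, "nucleus"), (LABEL_ORGANELLE, "organelle")):
        if code not in masks:
            raise ValueError(f"label raster has no {name} (code {code}) pixels")

    org = integrated_signal(field, background, masks[LABEL_ORGANELLE])
    nuc = integrated_signal(field, background, masks[LABEL_NUCLEUS])

    at_org = at_nuc = None
    if dapi_model is not None and reddot_model is not None:
        bg_d = float(np.asarray(background, dtype=float)[0])
        correction = {}
        for code in (LABEL_ORGANELLE, LABEL_NUCLEUS):
            m = masks[code]
            dapi_sig = float(np.clip(field.dapi[m] - bg_d, 0.0, None).sum())
            red_sig = org if code == LABEL_ORGANELLE else nuc
            at = _apparent_at(dapi_sig, red_sig, dapi_model, reddot_model)
            correction[code] = predict(reddot_model, at)
            if code == LABEL_ORGANELLE:
                at_org = at
            else:
                at_nuc = at
        org /= correction[LABEL_ORGANELLE]
        nuc /= correction[LABEL_NUCLEUS]

    return CellMeasurement(
        organelle_signal=org,
        nucleus_signal=nuc,
        p=proportion_per_cell(org, nuc),
        organelle_at=at_org,
        nucleus_at=at_nuc,
    )
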