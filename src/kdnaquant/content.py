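"""Absolute organellar DNA content from proportions and genome sizes.

Given the measured organellar fraction p of total cellular DNA signal
and an independently known diploid nuclear genome size N (Mbp), the
organellar DNA amount is

    M_org = N * p / (1 - p),

with a first-order (delta-method) standard error N * se_p / (1 - p)^2.
Composition sensitivity of the quantitation dye adds a multiplicative
systematic band obtained by extremising f(assumed_at) / f(at) over
at in [0, 1].  The module also carries the small arithmetic used for
cross-checks: kDNA network size from minicircle/maxicircle composition,
electron-microscopy volume-scaling ratios, and picogram conversion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .dye_response import DyeResponseModel, predict
from .quantify import ProportionEstimate

__all__ = [
    "GenomeEntry",
    "ContentEstimate",
    "NetworkComposition",
    "EmDiameters",
    "GENOME_TABLE",
    "organellar_content",
    "content_se",
    "apply_at_bias",
    "network_size",
    "em_content_ratio",
    "pg_to_mbp",
    "organelle_nuclear_ratio",
    "infer_content",
]


@dataclass(frozen=True)
class GenomeEntry:
    """Diploid nuclear genome size of one species, in Mbp."""

    species: str
    nuclear_mbp: float
    source_note: str = ""

    def __post_init__(self) -> None:
        if not self.nuclear_mbp > 0:
            raise ValueError("nuclear_mbp must be positive")


#: Diploid nuclear genome sizes (Mbp) used by the inference stage.  The
#: endosymbiont entry assumes both nuclei in the host cell are diploid; its
#: haploid-nucleus variant (9.5 Mbp) is available via the ploidy note.
GENOME_TABLE: tuple[GenomeEntry, ...] = (
    GenomeEntry("T_brucei", 77.9, "diploid core genome + minichromosomes"),
    GenomeEntry("T_borreli", 51.6, "diploid assembly size"),
    GenomeEntry("Perkinsela", 19.0, "both nuclei diploid; haploid variant 9.5"),
    GenomeEntry("D_papillatum", 180.0, "diploid assembly size, approximate"),
)


@dataclass(frozen=True)
class ContentEstimate:
    """Absolute organellar DNA amount with propagated SE and AT-bias band.

    ``bias_low``/``bias_high`` are multiplicative bounds: the true amount
    lies in [organelle_mbp * bias_low, organelle_mbp * bias_high] under
    worst-case base composition of the quantified DNA.
    """

    organelle_mbp: float
    se_mbp: float
    bias_low: float = 1.0
    bias_high: float = 1.0

    def __post_init__(self) -> None:
        if self.organelle_mbp < 0:
            raise ValueError("organelle_mbp must be >= 0")
        if self.se_mbp < 0:
            raise ValueError("se_mbp must be >= 0")
        if not (self.bias_low <= 1.0 <= self.bias_high):
            raise ValueError("bias bounds must bracket 1")


@dataclass(frozen=True)
class NetworkComposition:
    """kDNA network composition: minicircle/maxicircle counts and sizes (kbp)."""

    n_minicircles: int
    minicircle_kbp: float
    n_maxicircles: int
    maxicircle_kbp: float

    def __post_init__(self) -> None:
        if self.n_minicircles < 0 or self.n_maxicircles < 0:
            raise ValueError("circle counts must be >= 0")
        if self.minicircle_kbp <= 0 or self.maxicircle_kbp <= 0:
            raise ValueError("circle lengths must be positive")


@dataclass(frozen=True)
class EmDiameters:
    """Measured cross-section diameters (um) of a DNA-containing structure.

    Either individual diameters or a (mean, sd, n) summary may be supplied.
    """

    diameters: Optional[tuple[float, ...]] = None
    summary_mean: Optional[float] = None
    summary_sd: Optional[float] = None
    summary_n: Optional[int] = None

    @classmethod
    def from_values(cls, diameters: Sequence[float]) -> "EmDiameters":
        d = tuple(float(x) for x in diameters)
        if not d or any(x <= 0 for x in d):
            raise ValueError("diameters must be a nonempty list of positive values")
        return cls(diameters=d)

    @classmethod
    def from_summary(cls, mean: float, sd: float, n: int) -> "EmDiameters":
        if mean <= 0 or sd < 0 or n < 1:
            raise ValueError("need mean > 0, sd >= 0, n >= 1")
        return cls(summary_mean=float(mean), summary_sd=float(sd), summary_n=int(n))

    @property
    def n(self) -> int:
        return len(self.diameters) if self.diameters is not None else int(self.summary_n)

    @property
    def mean(self) -> float:
        if self.diameters is not None:
            return float(np.mean(self.diameters))
        return float(self.summary_mean)

    @property
    def sem(self) -> float:
        if self.diameters is not None:
            if len(self.diameters) == 1:
                return 0.0
            return float(np.std(self.diameters, ddof=1) / np.sqrt(len(self.diameters)))
        if self.summary_n == 1:
            return 0.0
        return float(self.summary_sd / np.sqrt(self.summary_n))


def organellar_content(nuclear_mbp: float, p: float) -> float:
    """Organellar DNA amount (Mbp): nuclear_mbp * p / (1 - p).

    ``p`` is the organellar fraction of total cellular DNA; the conversion
    diverges as p -> 1 and is rejected at p >= 1.
    """
    if not nuclear_mbp > 0:
        raise ValueError("nuclear_mbp must be positive")
    if not 0.0 <= p < 1.0:
        raise ValueError(f"proportion p={p} must lie in [0, 1)")
    return nuclear_mbp * p / (1.0 - p)


def content_se(nuclear_mbp: float, p: float, se_p: float) -> float:
    """Delta-method SE of the content conversion: nuclear_mbp * se_p / (1-p)^2."""
    if not nuclear_mbp > 0:
        raise ValueError("nuclear_mbp must be positive")
    if not 0.0 <= p < 1.0:
        raise ValueError(f"proportion p={p} must lie in [0, 1)")
    if se_p < 0:
        raise ValueError("se_p must be >= 0")
    return nuclear_mbp * se_p / (1.0 - p) ** 2


def apply_at_bias(
    model: DyeResponseModel, assumed_at: float = 0.5
) -> tuple[float, float]:
    """Multiplicative content bounds from composition sensitivity of the dye.

    Quantitation assuming AT fraction ``assumed_at`` mis-scales an amount of
    true composition ``at`` by f(assumed_at)/f(at); extremising over
    at in [0, 1] (endpoints, for an affine response) yields
    (bias_low, bias_high), which always bracket 1.
    """
    base = predict(model, assumed_at)
    if base <= 0:
        raise ValueError(f"response at assumed_at={assumed_at} is nonpositive")
    ratios = []
    for endpoint in (0.0, 1.0):
        f = predict(model, endpoint)
        if f <= 0:
            raise ValueError(f"response at AT={endpoint} is nonpositive; bias unbounded")
        ratios.append(base / f)
    return (min(min(ratios), 1.0), max(max(ratios), 1.0))


def network_size(comp: NetworkComposition) -> float:
    """Total kDNA network size in Mbp from circle counts and lengths (kbp)."""
    kbp = (comp.n_minicircles * comp.minicircle_kbp
           + comp.n_maxicircles * comp.maxicircle_kbp)
    return kbp / 1000.0


def em_content_ratio(
    diam_a: EmDiameters, diam_b: EmDiameters
) -> tuple[float, float, float]:
    """DNA content ratio implied by EM cross-section diameters.

    Assuming similar shape and packing density, content scales with
    volume, so the point ratio is (mean_a / mean_b)**3.  The uncertainty
    interval propagates each mean's SEM to first order: the relative SE of
    the cubed ratio is 3 * sqrt((sem_a/mean_a)^2 + (sem_b/mean_b)^2).
    Returns (ratio, low, high).
    """
    ma, mb = diam_a.mean, diam_b.mean
    if ma <= 0 or mb <= 0:
        raise ValueError("mean diameters must be positive")
    ratio = (ma / mb) ** 3
    rel = 3.0 * np.sqrt((diam_a.sem / ma) ** 2 + (diam_b.sem / mb) ** 2)
    return (float(ratio), float(ratio * (1.0 - rel)), float(ratio * (1.0 + rel)))


def pg_to_mbp(pg: float) -> float:
    """Convert picograms of DNA to Mbp using 0.001 pg per Mbp."""
    if pg < 0:
        raise ValueError("pg must be >= 0")
    return pg * 1000.0


def organelle_nuclear_ratio(organelle_mbp: float, nuclear_mbp: float) -> float:
    """How many times the organellar DNA amount exceeds the nuclear one."""
    if organelle_mbp < 0 or not nuclear_mbp > 0:
        raise ValueError("amounts must be nonnegative with nuclear_mbp > 0")
    return organelle_mbp / nuclear_mbp


def infer_content(
    nuclear_mbp: float,
    proportion: ProportionEstimate,
    reddot_model: Optional[DyeResponseModel] = None,
    assumed_at: float = 0.5,
) -> ContentEstimate:
    """Full content estimate: conversion, delta-method SE, AT-bias band."""
    mbp = organellar_content(nuclear_mbp, proportion.p)
    se = content_se(nuclear_mbp, proportion.p, proportion.se)
    if reddot_model is not None:
        lo, hi = apply_at_bias(reddot_model, assumed_at)
    else:
        lo = hi = 1.0
    return ContentEstimate(organelle_mbp=mbp, se_mbp=se, bias_low=lo, bias_high=hi)
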