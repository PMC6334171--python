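"""Synthetic calibration tables and two-channel micrographs with ground truth.

This module is the forward model of the whole experiment: cells carry a
known amount of nuclear and organellar DNA of known AT fraction, each
compartment is painted as a uniform-density shape, the two dye channels
are formed as

    channel(x) = background + gain * sum_compartments f_dye(AT) * density(x)

blurred by an isotropic Gaussian kernel (widefield out-of-focus haze),
optionally corrupted by shot noise (Poisson on signal + background),
additive Gaussian read noise, and digitised to the detector bit depth.
Every render returns the exact ground truth (per-class density maps, a
label raster, and the true organellar DNA proportion), so every stage of
the analysis pipeline can be tested against known answers.

Species-like presets reproduce the study conditions for the organisms of
interest: a trypanosome-like cell with a compact dot-like kinetoplast, two
cells with dispersed multi-blob organellar DNA, and an endosymbiont-like
cell whose organellar DNA dwarfs its nucleus (optionally with an adjacent
host nucleus to be excluded from quantitation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from .dye_response import CalibrationRecord
from .rasters import (
    LABEL_HOST,
    LABEL_NUCLEUS,
    LABEL_ORGANELLE,
    FieldImage,
)

__all__ = [
    "DyeResponseTruth",
    "DAPI_TRUTH",
    "REDDOT1_TRUTH",
    "Ellipse",
    "Disk",
    "CellSpec",
    "OpticsSpec",
    "GroundTruth",
    "simulate_calibration",
    "render_field",
    "SpeciesPreset",
    "SPECIES_PRESETS",
    "make_species_cell",
]


@dataclass(frozen=True)
class DyeResponseTruth:
    """True affine dye response f(AT) = intercept + slope*AT, with f(1) = 1."""

    dye_name: str
    intercept: float
    slope: float

    def __post_init__(self) -> None:
        if self.intercept < 0:
            raise ValueError("intercept must be >= 0")
        if self.intercept + self.slope <= 0:
            raise ValueError("response at AT=1 must be positive")
        if abs(self.intercept + self.slope - 1.0) > 1e-9:
            raise ValueError("truth must be normalised so intercept + slope = 1")

    def response(self, at: float) -> float:
        if not 0.0 <= at <= 1.0:
            raise ValueError(f"AT fraction {at} outside [0, 1]")
        return self.intercept + self.slope * at


#: AT-selective minor-groove binder: no signal on pure GC, maximal on pure AT.
DAPI_TRUTH = DyeResponseTruth("DAPI", 0.0, 1.0)
#: Weakly composition-sensitive intercalator: 70% of maximal signal on pure GC.
REDDOT1_TRUTH = DyeResponseTruth("RedDot1", 0.70, 0.30)


def simulate_calibration(
    truth: list[DyeResponseTruth],
    at_fractions: list[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[CalibrationRecord]:
    """Simulate a plate-reader calibration series of annealed oligos.

    One record per (oligo AT fraction, dye).  ``noise_sd`` is the relative
    (multiplicative) measurement noise; with ``noise_sd = 0`` the values
    equal the true affine response exactly.  The default AT series of the
    assay is 21 oligos from 0 to 100% AT in 5% steps, i.e.
    ``np.linspace(0, 1, 21)``.
    """
    if len(at_fractions) == 0:
        raise ValueError("at_fractions must be nonempty")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = np.random.default_rng(seed)
    records = []
    for at in at_fractions:
        for t in truth:
            value = t.response(float(at))
            if noise_sd > 0:
                value *= 1.0 + rng.normal(0.0, noise_sd)
            records.append(CalibrationRecord(float(at), t.dye_name, float(value)))
    return records


# ---------------------------------------------------------------------------
# geometry


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse: centre (row, col) and semi-axes in pixels."""

    row: float
    col: float
    r_row: float
    r_col: float

    def rasterize(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        rr, cc = draw_ellipse(self.row, self.col, self.r_row, self.r_col, shape=None)
        _check_inside(rr, cc, shape, "ellipse")
        return rr, cc


@dataclass(frozen=True)
class Disk:
    row: float
    col: float
    radius: float

    def rasterize(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        rr, cc = draw_disk((self.row, self.col), self.radius, shape=None)
        _check_inside(rr, cc, shape, "disk")
        return rr, cc


Shape = Union[Ellipse, Disk]
#: organelle geometry is either a single compact disk or a set of dispersed blobs
OrganelleGeometry = Union[Disk, tuple[Disk, ...]]


def _check_inside(rr: np.ndarray, cc: np.ndarray, shape: tuple[int, int], what: str) -> None:
    if rr.size == 0:
        raise ValueError(f"{what} rasterises to zero pixels")
    if rr.min() < 0 or cc.min() < 0 or rr.max() >= shape[0] or cc.max() >= shape[1]:
        raise ValueError(f"{what} extends outside the {shape[0]}x{shape[1]} raster")


@dataclass(frozen=True)
class CellSpec:
    """One cell: DNA amounts (Mbp), AT fractions, and compartment geometry.

    The organelle geometry is either a compact disk (the dot-like
    periflagellar kinetoplast) or a tuple of disks (organellar DNA
    dispersed through a reticulated mitochondrion).  An optional host
    nucleus (label 3) models an endosymbiont inside a host cell; it is
    excluded from the true organellar proportion.
    """

    nucleus_mbp: float
    organelle_mbp: float
    nucleus_at: float
    organelle_at: float
    nucleus_geom: Ellipse
    organelle_geom: OrganelleGeometry
    host_nucleus_mbp: float = 0.0
    host_nucleus_at: float = 0.5
    host_nucleus_geom: Optional[Ellipse] = None

    def __post_init__(self) -> None:
        for name in ("nucleus_mbp", "organelle_mbp", "host_nucleus_mbp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("nucleus_at", "organelle_at", "host_nucleus_at"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.host_nucleus_mbp > 0 and self.host_nucleus_geom is None:
            raise ValueError("host_nucleus_mbp > 0 requires host_nucleus_geom")

    @property
    def organelle_disks(self) -> tuple[Disk, ...]:
        if isinstance(self.organelle_geom, Disk):
            return (self.organelle_geom,)
        return tuple(self.organelle_geom)


@dataclass(frozen=True)
class OpticsSpec:
    """Widefield imaging forward-model parameters.

    ``counts_per_mbp`` sets the photon budget: total detector counts
    contributed by 1 Mbp of DNA at unit dye response and unit channel gain.
    ``channel_gain`` is the free relative exposure scaling of the (DAPI,
    RedDot1) channels.  ``digitize`` rounds to integer counts and clips to
    the detector bit depth, as a real camera does; turn it off to obtain
    the exact analog forward model.
    """

    shape: tuple[int, int] = (128, 128)
    pixel_size: float = 0.1
    blur_sigma: float = 1.0
    background_level: float = 100.0
    shot_noise: bool = True
    read_noise_sd: float = 2.0
    bit_depth: int = 16
    counts_per_mbp: float = 20000.0
    channel_gain: tuple[float, float] = (1.0, 1.0)
    digitize: bool = True

    def __post_init__(self) -> None:
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.counts_per_mbp <= 0:
            raise ValueError("counts_per_mbp must be positive")


@dataclass
class GroundTruth:
    """Exact truth attached to a rendered field.

    ``density_maps`` hold pre-blur DNA density (Mbp/pixel) per class
    ('organellar', 'nuclear', 'host'); ``labels`` is the compartment
    raster; ``p_true`` the organellar fraction of cellular DNA (host
    nucleus excluded); ``p_signal`` the organellar fraction of RedDot1
    signal the dyes would report, which differs from ``p_true`` when the
    compartments differ in AT content.
    """

    density_maps: dict[str, np.ndarray]
    labels: np.ndarray
    p_true: float
    p_signal: float
    seed: int


def _paint(
    labels: np.ndarray,
    density: np.ndarray,
    shape_list: list[Shape],
    label_code: int,
    mbp: float,
    raster_shape: tuple[int, int],
) -> None:
    """Paint shapes with uniform total ``mbp``, enforcing non-overlap."""
    all_rr: list[np.ndarray] = []
    all_cc: list[np.ndarray] = []
    for s in shape_list:
        rr, cc = s.rasterize(raster_shape)
        all_rr.append(rr)
        all_cc.append(cc)
    rr = np.concatenate(all_rr)
    cc = np.concatenate(all_cc)
    if np.any(labels[rr, cc] != 0):
        raise ValueError("compartment shapes overlap")
    labels[rr, cc] = label_code
    density[rr, cc] += mbp / rr.size


def render_field(
    cells: list[CellSpec],
    truth: list[DyeResponseTruth],
    optics: OpticsSpec = OpticsSpec(),
    seed: int = 0,
) -> tuple[FieldImage, GroundTruth]:
    """Render a two-channel field and its exact ground truth.

    ``truth`` must contain responses for both dyes ('DAPI' and 'RedDot1').
    The noise-free channel value at a pixel is background plus the sum over
    compartments of f_dye(AT) * density, convolved with the Gaussian blur
    kernel; shot noise (when on) is Poisson on signal plus background,
    followed by Gaussian read noise and digitisation.  The number of pixels
    clipped at the top of the detector range per channel is reported in
    ``FieldImage.meta['clipped_pixels']``.
    """
    if not cells:
        raise ValueError("need at least one cell")
    by_dye = {t.dye_name: t for t in truth}
    missing = {"DAPI", "RedDot1"} - set(by_dye)
    if missing:
        raise ValueError(f"dye truth missing for {sorted(missing)}")

    shape = tuple(optics.shape)
    labels = np.zeros(shape, dtype=np.uint8)
    density = {
        "nuclear": np.zeros(shape),
        "organellar": np.zeros(shape),
        "host": np.zeros(shape),
    }
    # per-compartment records: (class name, AT fraction, density map painted alone)
    compartments: list[tuple[float, np.ndarray]] = []

    def add(shapes: list[Shape], code: int, cls: str, mbp: float, at: float) -> None:
        if mbp <= 0 and cls == "host":
            return
        one = np.zeros(shape)
        _paint(labels, one, shapes, code, mbp, shape)
        density[cls] += one
        compartments.append((at, one))

    for cell in cells:
        add([cell.nucleus_geom], LABEL_NUCLEUS, "nuclear", cell.nucleus_mbp, cell.nucleus_at)
        add(list(cell.organelle_disks), LABEL_ORGANELLE, "organellar",
            cell.organelle_mbp, cell.organelle_at)
        if cell.host_nucleus_geom is not None:
            add([cell.host_nucleus_geom], LABEL_HOST, "host",
                cell.host_nucleus_mbp, cell.host_nucleus_at)

    rng = np.random.default_rng(seed)
    channels = []
    clipped = []
    for gain, dye in zip(optics.channel_gain, ("DAPI", "RedDot1")):
        f = by_dye[dye]
        signal = np.zeros(shape)
        for at, dens in compartments:
            signal += f.response(at) * dens
        signal *= gain * optics.counts_per_mbp
        if optics.blur_sigma > 0:
            signal = gaussian_filter(signal, optics.blur_sigma, mode="constant")
        ideal = signal + optics.background_level
        if optics.shot_noise:
            img = rng.poisson(ideal).astype(float)
        else:
            img = ideal
        if optics.read_noise_sd > 0:
            img = img + rng.normal(0.0, optics.read_noise_sd, size=shape)
        full_scale = 2**optics.bit_depth - 1
        n_clip = int(np.sum(img > full_scale))
        if optics.digitize:
            img = np.clip(np.rint(img), 0, full_scale)
        else:
            img = np.clip(img, 0, None)
        channels.append(img)
        clipped.append(n_clip)

    org = sum(c.organelle_mbp for c in cells)
    nuc = sum(c.nucleus_mbp for c in cells)
    total = org + nuc
    p_true = org / total if total > 0 else 0.0
    f_red = by_dye["RedDot1"]
    org_sig = sum(f_red.response(c.organelle_at) * c.organelle_mbp for c in cells)
    nuc_sig = sum(f_red.response(c.nucleus_at) * c.nucleus_mbp for c in cells)
    sig_total = org_sig + nuc_sig
    p_signal = org_sig / sig_total if sig_total > 0 else 0.0

    field = FieldImage(
        dapi=channels[0],
        reddot=channels[1],
        pixel_size=optics.pixel_size,
        meta={
            "seed": int(seed),
            "clipped_pixels": {"DAPI": clipped[0], "RedDot1": clipped[1]},
            "background_level": optics.background_level,
        },
    )
    gt = GroundTruth(density_maps=density, labels=labels, p_true=float(p_true),
                     p_signal=float(p_signal), seed=int(seed))
    return field, gt


# ---------------------------------------------------------------------------
# species-like presets


@dataclass(frozen=True)
class SpeciesPreset:
    """Study conditions for one organism: genome sizes, AT fractions, geometry style."""

    name: str
    nuclear_mbp: float
    p_true: float
    nucleus_at: float
    organelle_at: float
    organelle_style: str  # "disk" or "dispersed"
    nucleus_radii: tuple[float, float] = (9.0, 12.0)
    organelle_radius: float = 4.0
    host_mbp: float = 0.0
    host_at: float = 0.45

    @property
    def organelle_mbp(self) -> float:
        return self.nuclear_mbp * self.p_true / (1.0 - self.p_true)


SPECIES_PRESETS: dict[str, SpeciesPreset] = {
    # Trypanosome-like: tiny AT-rich dot-like kinetoplast beside a larger nucleus.
    "T_brucei": SpeciesPreset("T_brucei", nuclear_mbp=77.9, p_true=0.0509,
                              nucleus_at=0.53, organelle_at=0.75,
                              organelle_style="disk", organelle_radius=4.0),
    # Bodonid-like: kinetoplast DNA about as massive as the nucleus, dispersed.
    "T_borreli": SpeciesPreset("T_borreli", nuclear_mbp=51.6, p_true=0.491,
                               nucleus_at=0.55, organelle_at=0.72,
                               organelle_style="dispersed", organelle_radius=3.0),
    # Diplonemid-like: organellar DNA exceeds the nucleus and is GC-richer.
    "D_papillatum": SpeciesPreset("D_papillatum", nuclear_mbp=180.0, p_true=0.587,
                                  nucleus_at=0.55, organelle_at=0.42,
                                  organelle_style="dispersed", organelle_radius=3.0),
    # Endosymbiont-like: organellar DNA dominates a reduced GC-rich nucleus;
    # an adjacent host nucleus can be added with include_host.
    "Perkinsela": SpeciesPreset("Perkinsela", nuclear_mbp=19.0, p_true=0.928,
                                nucleus_at=0.45, organelle_at=0.78,
                                organelle_style="disk",
                                nucleus_radii=(5.0, 6.0), organelle_radius=14.0,
                                host_mbp=150.0),
}


def make_species_cell(
    preset: SpeciesPreset | str,
    rng: np.random.Generator | None = None,
    shape: tuple[int, int] = (128, 128),
    amount_cv: float = 0.05,
    include_host: bool = False,
) -> CellSpec:
    """Build one cell from a species preset.

    Per-cell DNA amounts are jittered lognormally with coefficient of
    variation ``amount_cv`` (cell-cycle and replication-state variation);
    geometry is fixed, with nucleus and organelle placed well apart on the
    raster.  Pass ``amount_cv=0`` (or no rng) for the exact nominal cell.
    """
    if isinstance(preset, str):
        preset = SPECIES_PRESETS[preset]
    rows, cols = shape

    def jitter(mean: float) -> float:
        if rng is None or amount_cv <= 0 or mean == 0:
            return mean
        sigma = np.sqrt(np.log1p(amount_cv**2))
        return float(mean * rng.lognormal(-(sigma**2) / 2.0, sigma))

    r_mid = rows * 0.5
    nucleus = Ellipse(r_mid, cols * 0.33, *preset.nucleus_radii)
    org_centre = (r_mid, cols * 0.72)
    if preset.organelle_style == "disk":
        organelle: OrganelleGeometry = Disk(*org_centre, preset.organelle_radius)
    elif preset.organelle_style == "dispersed":
        angles = np.linspace(0.0, 2.0 * np.pi, 6, endpoint=False)
        spread = min(rows, cols) * 0.12
        organelle = tuple(
            Disk(org_centre[0] + spread * np.sin(a), org_centre[1] + spread * np.cos(a),
                 preset.organelle_radius)
            for a in angles
        )
    else:
        raise ValueError(f"unknown organelle_style {preset.organelle_style!r}")

    host_geom = None
    host_mbp = 0.0
    if include_host:
        if preset.host_mbp <= 0:
            raise ValueError(f"preset {preset.name!r} has no host nucleus")
        host_geom = Ellipse(rows * 0.18, cols * 0.5, 9.0, 13.0)
        host_mbp = jitter(preset.host_mbp)

    return CellSpec(
        nucleus_mbp=jitter(preset.nuclear_mbp),
        organelle_mbp=jitter(preset.organelle_mbp),
        nucleus_at=preset.nucleus_at,
        organelle_at=preset.organelle_at,
        nucleus_geom=nucleus,
        organelle_geom=organelle,
        host_nucleus_mbp=host_mbp,
        host_nucleus_at=preset.host_at,
        host_nucleus_geom=host_geom,
    )
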