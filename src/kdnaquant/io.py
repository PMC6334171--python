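"""Readers and writers for the pipeline's on-disk formats.

Fields are stored as a two-page 16-bit grayscale TIFF plus a YAML
sidecar recording channel order, pixel size and provenance (the sidecar
is mandatory on read — channel order is never assumed).  Label rasters
are 8-bit TIFFs restricted to codes {0,1,2,3}.  Tables (calibration,
genome sizes, per-cell measurements) are plain CSV; reports are sorted
key-value YAML so reruns are byte-identical.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field as dataclass_field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from .content import GenomeEntry
from .dye_response import CalibrationRecord, DyeResponseModel
from .rasters import CHANNELS, FieldImage, validate_labels

CALIBRATION_COLUMNS = ("at_fraction", "dye", "fluorescence")
GENOME_COLUMNS = ("species", "diploid_mbp", "ploidy_note")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def write_field(path: str | Path, field: FieldImage) -> Path:
    """Write a field as a 2-page uint16 TIFF plus a YAML sidecar."""
    path = Path(path)
    stack = np.rint(field.channels)
    if stack.min() < 0 or stack.max() > 65535:
        raise ValueError("field counts outside the uint16 range; cannot serialise")
    tifffile.imwrite(path, stack.astype(np.uint16))
    sidecar = {
        "channels": list(CHANNELS),
        "pixel_size_um": float(field.pixel_size),
        **{k: v for k, v in field.meta.items()},
    }
    _sidecar_path(path).write_text(yaml.safe_dump(sidecar, sort_keys=True))
    return path


def read_field(path: str | Path) -> FieldImage:
    """Read a field TIFF; requires its sidecar to establish channel order."""
    path = Path(path)
    sc = _sidecar_path(path)
    if not sc.exists():
        raise ValueError(
            f"missing sidecar {sc}: channel order cannot be assumed for {path}"
        )
    meta = yaml.safe_load(sc.read_text())
    channels = meta.pop("channels", None)
    if channels is None or set(channels) != set(CHANNELS):
        raise ValueError(f"{sc}: sidecar must list channels {list(CHANNELS)}")
    stack = tifffile.imread(path).astype(float)
    if stack.ndim != 3 or stack.shape[0] != 2:
        raise ValueError(f"{path}: expected a 2-channel TIFF stack, got shape {stack.shape}")
    order = [channels.index(c) for c in CHANNELS]
    pixel_size = float(meta.pop("pixel_size_um", 0.1))
    return FieldImage(dapi=stack[order[0]], reddot=stack[order[1]],
                      pixel_size=pixel_size, meta=meta)


def write_labels(path: str | Path, labels: np.ndarray) -> Path:
    path = Path(path)
    tifffile.imwrite(path, validate_labels(labels))
    return path


def read_labels(path: str | Path) -> np.ndarray:
    path = Path(path)
    arr = tifffile.imread(path)
    try:
        return validate_labels(arr, name=str(path))
    except ValueError as err:
        raise ValueError(str(err)) from None


def write_calibration_table(path: str | Path, records: list[CalibrationRecord]) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [(r.at_fraction, r.dye, r.fluorescence) for r in records],
        columns=list(CALIBRATION_COLUMNS),
    )
    # %.17g keeps write->read round trips exact to the last ulp
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_calibration_table(path: str | Path) -> list[CalibrationRecord]:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(CALIBRATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: calibration table missing columns {sorted(missing)}")
    return [
        CalibrationRecord(float(r.at_fraction), str(r.dye), float(r.fluorescence))
        for r in df.itertuples()
    ]


def read_genome_table(path: str | Path) -> list[GenomeEntry]:
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(GENOME_COLUMNS[:2]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: genome table missing columns {sorted(missing)}")
    note = "ploidy_note" if "ploidy_note" in df.columns else None
    return [
        GenomeEntry(str(r.species), float(r.diploid_mbp),
                    str(getattr(r, note)) if note else "")
        for r in df.itertuples()
    ]


def write_genome_table(path: str | Path, entries: list[GenomeEntry]) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [(e.species, e.nuclear_mbp, e.source_note) for e in entries],
        columns=list(GENOME_COLUMNS),
    )
    df.to_csv(path, index=False)
    return path


def write_report(path: str | Path, data: dict[str, Any]) -> Path:
    """Write a report as sorted key-value YAML (deterministic bytes)."""
    path = Path(path)
    path.write_text(yaml.safe_dump(_plain(data), sort_keys=True))
    return path


def read_report(path: str | Path) -> dict[str, Any]:
    return yaml.safe_load(Path(path).read_text())


def _plain(obj: Any) -> Any:
    """Recursively convert numpy scalars/arrays to plain Python for YAML."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_unmixed(path_prefix: str | Path, organellar: np.ndarray,
                  nuclear: np.ndarray) -> tuple[Path, Path]:
    """Write unmixed class rasters as 32-bit float TIFFs."""
    prefix = Path(path_prefix)
    p_org = prefix.with_name(prefix.name + "_organellar.tif")
    p_nuc = prefix.with_name(prefix.name + "_nuclear.tif")
    tifffile.imwrite(p_org, organellar.astype(np.float32))
    tifffile.imwrite(p_nuc, nuclear.astype(np.float32))
    return p_org, p_nuc


def model_report(model: DyeResponseModel) -> dict[str, Any]:
    return asdict(model)


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration (mirrors the CLI flags)."""

    out_dir: str
    seed: int = 0
    preset: str = "T_brucei"
    n_fields: int = 20
    noise: bool = True
    blur_sigma: float = 1.0
    segmentation: str = "manual"  # "manual" (label rasters) or "auto"
    at_correction: bool = True
    assumed_at: float = 0.5
    calibration_noise_sd: float = 0.02
    amount_cv: float = 0.05
    include_host: bool = False
    images: list[str] = dataclass_field(default_factory=list)
    masks: list[str] = dataclass_field(default_factory=list)
    calibration_table: Optional[str] = None
    genome_table: Optional[str] = None
    species: Optional[str] = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        if "out_dir" not in raw:
            raise ValueError(f"{path}: config must set out_dir")
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)
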