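"""Reading and writing of images, label masks, sidecar metadata, configuration
files and collated measurement tables.

All file-format dialect decisions live here:

* images are regular raster files (PNG/TIFF/JPEG); multi-channel inputs are
  collapsed to grayscale by the channel mean;
* acquisition metadata (microns-per-pixel scale, laterality, location) travels
  in a JSON sidecar named ``<image stem>.json`` next to the image;
* label masks are single-channel PNGs with the project-wide encoding
  0=background, 1=artery, 2=vein, 3=artery/vein crossing, 4=optic disc
  (fovea and binary-vessel masks are separate 0/1 PNGs);
* the collated measurement table is UTF-8 CSV ('.' decimal, ',' separator)
  with an optional XLSX mirror;
* configuration files are plain ``key = value`` text.

All writes are atomic (temp file + rename) so an interrupted batch never
leaves a partially written table or mask behind.
"""

from __future__ import annotations

import dataclasses
import json
import os
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

from .errors import ConfigError, DecodeError, EncodingError, ShapeError

#: canonical label values for the multi-class mask
LABEL_BACKGROUND = 0
LABEL_ARTERY = 1
LABEL_VEIN = 2
LABEL_CROSSING = 3
LABEL_DISC = 4
VALID_LABELS = frozenset(
    {LABEL_BACKGROUND, LABEL_ARTERY, LABEL_VEIN, LABEL_CROSSING, LABEL_DISC}
)

LATERALITIES = ("right", "left", "unknown")
LOCATIONS = ("macula", "disc", "unknown")

IMAGE_SUFFIXES = (".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SLOImage:
    """A grayscale en face SLO image plus acquisition metadata.

    Coordinates are 0-based (row, col) with the origin at the top-left;
    public outputs always spell out (x=col, y=row).  When
    ``scale_um_per_px`` is absent, every downstream length/area is reported
    in pixel space and flagged as such.
    """

    pixels: np.ndarray
    scale_um_per_px: float | None = None
    laterality: str = "unknown"
    location: str = "unknown"
    image_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ShapeError(
                f"SLO image must be 2-D after grayscale collapse, got shape "
                f"{self.pixels.shape}"
            )
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise ShapeError("SLO image pixels must be finite and non-negative")
        if self.scale_um_per_px is not None and self.scale_um_per_px <= 0:
            raise ShapeError("scale_um_per_px must be positive when given")
        if self.laterality not in LATERALITIES:
            raise ShapeError(f"laterality must be one of {LATERALITIES}")
        if self.location not in LOCATIONS:
            raise ShapeError(f"location must be one of {LOCATIONS}")

    @property
    def height_px(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width_px(self) -> int:
        return int(self.pixels.shape[1])


@dataclass
class LabelMask:
    """Multi-class label image sharing the encoding above."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ShapeError(f"label mask must be 2-D, got {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise EncodingError("label mask must be integer valued")
        bad = set(np.unique(self.labels)) - VALID_LABELS
        if bad:
            raise EncodingError(
                f"label mask contains values outside the encoding "
                f"{sorted(VALID_LABELS)}: {sorted(int(b) for b in bad)}"
            )

    @property
    def artery(self) -> np.ndarray:
        """Artery support including crossings."""
        return (self.labels == LABEL_ARTERY) | (self.labels == LABEL_CROSSING)

    @property
    def vein(self) -> np.ndarray:
        """Vein support including crossings."""
        return (self.labels == LABEL_VEIN) | (self.labels == LABEL_CROSSING)

    @property
    def vessel(self) -> np.ndarray:
        """All-vessel support: artery ∪ vein ∪ crossing."""
        return self.artery | self.vein

    @property
    def disc(self) -> np.ndarray:
        return self.labels == LABEL_DISC


@dataclass
class PipelineConfig:
    """Run-time options of the analysis pipeline with their defaults.

    The post-processing and metric parameters are stated at the 768×768
    working scale; they are rescaled with image resolution where noted.
    """

    input_dir: str = ""
    output_dir: str = ""
    skip_on_error: bool = False
    save_segmentations: bool = True
    scale_um_per_px: float | None = None
    laterality: str | None = None
    location: str | None = None
    # analysis parameters
    threshold: float = 0.5
    postprocess_min_area_px: int = 10
    postprocess_max_gap_px: int = 3
    metrics_min_segment_len: int = 10
    metrics_knudtson_n: int = 6
    metrics_aggregation: str = "length_weighted"  # or "mean"
    metrics_fd_on_skeleton: bool = False
    zones_boundary_rule: str = "clip"  # or "midpoint"
    zones_shape: str = "circular"  # or "elliptical"
    zones_exclude_disc_from_whole: bool = False
    vesselness_scales: tuple = (1.0, 2.0, 4.0, 8.0)
    baseline: bool = False
    masks_dir: str | None = None


#: mapping from config-file keys (dotted where grouped) to dataclass fields
_CONFIG_KEYS = {
    "input_dir": "input_dir",
    "output_dir": "output_dir",
    "skip_on_error": "skip_on_error",
    "save_segmentations": "save_segmentations",
    "scale_um_per_px": "scale_um_per_px",
    "laterality": "laterality",
    "location": "location",
    "threshold": "threshold",
    "postprocess.min_area_px": "postprocess_min_area_px",
    "postprocess.max_gap_px": "postprocess_max_gap_px",
    "metrics.min_segment_len": "metrics_min_segment_len",
    "metrics.knudtson_n": "metrics_knudtson_n",
    "metrics.aggregation": "metrics_aggregation",
    "metrics.fd_on_skeleton": "metrics_fd_on_skeleton",
    "zones.boundary_rule": "zones_boundary_rule",
    "zones.shape": "zones_shape",
    "zones.exclude_disc_from_whole": "zones_exclude_disc_from_whole",
    "baseline": "baseline",
    "masks_dir": "masks_dir",
}


# ---------------------------------------------------------------------------
# atomic writes
# ---------------------------------------------------------------------------


def _atomic_write_bytes(path: Path, data: bytes) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _atomic_save_png(path: Path, array: np.ndarray) -> None:
    import io as _io

    img = Image.fromarray(array)
    buf = _io.BytesIO()
    fmt = "PNG"
    suffix = Path(path).suffix.lower()
    if suffix in (".tif", ".tiff"):
        fmt = "TIFF"
    elif suffix in (".jpg", ".jpeg"):
        fmt = "JPEG"
    img.save(buf, format=fmt)
    _atomic_write_bytes(Path(path), buf.getvalue())


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------


def sidecar_path(image_path: str | Path) -> Path:
    return Path(image_path).with_suffix(".json")


def read_slo_image(
    path: str | Path, metadata_overrides: Mapping | None = None
) -> SLOImage:
    """Read a raster image plus optional JSON sidecar metadata.

    ``metadata_overrides`` (keys ``scale_um_per_px``, ``laterality``,
    ``location``) take precedence over sidecar values.  Absent metadata stays
    absent/unknown; nothing is guessed at read time.
    """
    path = Path(path)
    if not path.exists():
        raise DecodeError(f"image file does not exist: {path}")
    try:
        with Image.open(path) as img:
            arr = np.asarray(img)
    except (UnidentifiedImageError, OSError, SyntaxError) as exc:
        raise DecodeError(f"could not decode image file {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr.astype(float).mean(axis=2)
    if arr.ndim != 2:
        raise ShapeError(f"image {path} is not 2-D after grayscale collapse")

    meta: dict = {}
    sc = sidecar_path(path)
    if sc.exists():
        try:
            meta = json.loads(sc.read_text())
        except json.JSONDecodeError as exc:
            raise DecodeError(f"could not parse sidecar {sc}: {exc}") from exc
    if metadata_overrides:
        meta.update({k: v for k, v in metadata_overrides.items() if v is not None})

    return SLOImage(
        pixels=arr.astype(float),
        scale_um_per_px=meta.get("scale_um_per_px"),
        laterality=meta.get("laterality") or "unknown",
        location=meta.get("location") or "unknown",
        image_id=str(meta.get("image_id") or path.stem),
    )


def write_image(path: str | Path, pixels: np.ndarray) -> None:
    """Write a grayscale image as 8-bit PNG/TIFF (lossless, atomic)."""
    arr = np.asarray(pixels)
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    _atomic_save_png(Path(path), arr)


def write_sidecar(path: str | Path, metadata: Mapping) -> None:
    data = {k: v for k, v in dict(metadata).items() if v is not None}
    _atomic_write_bytes(
        sidecar_path(path), (json.dumps(data, indent=1) + "\n").encode()
    )


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------


def read_mask(path: str | Path, expected_shape: tuple | None = None) -> LabelMask:
    """Read a multi-class label mask and validate encoding and shape."""
    path = Path(path)
    try:
        with Image.open(path) as img:
            arr = np.asarray(img)
    except (UnidentifiedImageError, OSError, FileNotFoundError) as exc:
        raise DecodeError(f"could not decode mask file {path}: {exc}") from exc
    if arr.ndim != 2:
        raise ShapeError(f"mask {path} must be single channel, got {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise EncodingError(f"mask {path} must be integer valued")
    if expected_shape is not None and tuple(arr.shape) != tuple(expected_shape):
        raise ShapeError(
            f"mask {path} has shape {arr.shape}, expected {tuple(expected_shape)}"
        )
    return LabelMask(labels=arr.astype(np.int64))


def write_mask(mask: LabelMask | np.ndarray, path: str | Path) -> None:
    """Write a label mask (or any small-integer array) as 8-bit PNG."""
    labels = mask.labels if isinstance(mask, LabelMask) else np.asarray(mask)
    _atomic_save_png(Path(path), labels.astype(np.uint8))


def read_binary_mask(path: str | Path, expected_shape: tuple | None = None) -> np.ndarray:
    """Read a single-channel mask as boolean (any nonzero pixel is True)."""
    path = Path(path)
    try:
        with Image.open(path) as img:
            arr = np.asarray(img)
    except (UnidentifiedImageError, OSError, FileNotFoundError) as exc:
        raise DecodeError(f"could not decode mask file {path}: {exc}") from exc
    if arr.ndim != 2:
        raise ShapeError(f"mask {path} must be single channel, got {arr.shape}")
    if expected_shape is not None and tuple(arr.shape) != tuple(expected_shape):
        raise ShapeError(
            f"mask {path} has shape {arr.shape}, expected {tuple(expected_shape)}"
        )
    return arr > 0


def write_binary_mask(mask: np.ndarray, path: str | Path) -> None:
    _atomic_save_png(Path(path), (np.asarray(mask) > 0).astype(np.uint8) * 255)


# ---------------------------------------------------------------------------
# metrics table
# ---------------------------------------------------------------------------

#: frozen column order of the collated table; (x=col, y=row) spelled out
TABLE_COLUMNS = [
    "image_id",
    "laterality",
    "location",
    "units",
    "scale_um_per_px",
    "fovea_x_px",
    "fovea_y_px",
    "disc_x_px",
    "disc_y_px",
    "disc_diameter_px",
    "vessel_class",
    "roi",
    "vessel_density",
    "fractal_dimension",
    "global_caliber",
    "local_caliber",
    "tortuosity_density",
    "CRAE",
    "CRVE",
    "AVR",
    "n_segments",
]


def records_to_frame(records: Sequence) -> pd.DataFrame:
    """Stack MetricsRecord-like objects (anything with ``to_row``) row-wise."""
    rows = []
    for rec in records:
        row = rec.to_row() if hasattr(rec, "to_row") else dict(rec)
        rows.append({col: row.get(col) for col in TABLE_COLUMNS})
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def write_metrics_table(
    records: Sequence, path: str | Path, xlsx_mirror: bool = False
) -> pd.DataFrame:
    """Write the collated measurement table: one row per
    (image, vessel class, region of interest).

    CSV is always written (atomically); an ``.xlsx`` mirror with the same
    stem is written when requested and openpyxl is installed.
    """
    if len(records) == 0:
        warnings.warn("writing a header-only metrics table: no records")
    frame = records_to_frame(records)
    csv_bytes = frame.to_csv(index=False).encode()
    _atomic_write_bytes(Path(path), csv_bytes)
    if xlsx_mirror:
        try:
            frame.to_excel(Path(path).with_suffix(".xlsx"), index=False)
        except ImportError:  # pragma: no cover - openpyxl optional
            warnings.warn("openpyxl not installed; skipping xlsx mirror")
    return frame


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def _parse_value(field_name: str, raw: str):
    raw = raw.strip()
    hints = {f.name: f.type for f in dataclasses.fields(PipelineConfig)}
    default = getattr(PipelineConfig(), field_name)
    if raw.lower() in ("none", "null"):
        return None
    if raw == "":
        return "" if isinstance(default, str) else None
    if isinstance(default, bool) or "bool" in str(hints.get(field_name, "")):
        if raw.lower() in ("true", "1", "yes", "on"):
            return True
        if raw.lower() in ("false", "0", "no", "off"):
            return False
        raise ValueError(f"expected a boolean, got {raw!r}")
    if isinstance(default, int) and not isinstance(default, bool):
        return int(raw)
    if isinstance(default, float) or field_name == "scale_um_per_px":
        return float(raw)
    return raw


def read_config(path: str | Path) -> PipelineConfig:
    """Parse a plain-text ``key = value`` configuration file.

    Unknown keys warn (never error); blank lines and ``#`` comments are
    ignored; unparseable lines raise :class:`ConfigError` with the line
    number.  Unspecified keys keep their documented defaults.
    """
    cfg = PipelineConfig()
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if "=" not in stripped:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, value = stripped.partition("=")
        key = key.strip()
        if key not in _CONFIG_KEYS:
            warnings.warn(f"{path}:{lineno}: unknown config key {key!r} ignored")
            continue
        field_name = _CONFIG_KEYS[key]
        try:
            setattr(cfg, field_name, _parse_value(field_name, value))
        except ValueError as exc:
            raise ConfigError(f"{path}:{lineno}: bad value for {key!r}: {exc}") from exc
    return cfg


def write_config(cfg: PipelineConfig, path: str | Path) -> None:
    """Write a config file that :func:`read_config` round-trips exactly."""
    lines = []
    for key, field_name in _CONFIG_KEYS.items():
        value = getattr(cfg, field_name)
        if value is None:
            value = "none"
        lines.append(f"{key} = {value}")
    _atomic_write_bytes(Path(path), ("\n".join(lines) + "\n").encode())


#: stem suffixes reserved for pipeline artifacts living next to images
MASK_STEM_SUFFIXES = ("_labels", "_fovea", "_vessel", "_overlay", "_corrected")


def list_images(directory: str | Path) -> list[Path]:
    """Supported images in a directory, lexicographically sorted by name.

    Files following the mask/visualization naming conventions
    (``*_labels.png`` etc.) are not treated as analyzable images.
    """
    directory = Path(directory)
    return sorted(
        (
            p
            for p in directory.iterdir()
            if p.suffix.lower() in IMAGE_SUFFIXES
            and not any(p.stem.endswith(s) for s in MASK_STEM_SUFFIXES)
        ),
        key=lambda p: p.name,
    )
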