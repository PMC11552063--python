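"""End-to-end per-image analysis and batch orchestration.

For each image: read (+ sidecar metadata) -> segmentation bundle (corrected
masks if present, else user-supplied masks, else the classical baseline) ->
threshold at 0.5 and post-process -> landmarks -> laterality/location
(user metadata wins, otherwise inferred) -> regions of interest -> vascular
metrics -> per-image outputs (metrics rows, process log, metadata JSON,
segmentation masks and an overlay visualization when requested).

Batch mode processes a directory in lexicographic filename order, collates
all rows into one CSV (optionally mirrored to XLSX) and can skip over files
that fail.  Re-running an unchanged batch produces a byte-identical collated
CSV.  A corrected mask saved as ``<stem>_labels_corrected.png`` inside the
image's output folder takes precedence on the next run and changes only that
image's rows.
"""

from __future__ import annotations

import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io_formats, landmarks, metrics, segmentation, zones
from .errors import SlovascError
from .io_formats import (
    LABEL_ARTERY,
    LABEL_CROSSING,
    LABEL_DISC,
    LABEL_VEIN,
    PipelineConfig,
    SLOImage,
)


@dataclass
class ProcessLog:
    image_id: str
    entries: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    status: str = "ok"  # ok | skipped | failed
    failed_stage: str | None = None
    cause: str | None = None

    def add(self, stage: str, message: str) -> None:
        self.entries.append((time.strftime("%Y-%m-%dT%H:%M:%S"), stage, message))

    def warn(self, message: str) -> None:
        self.warnings.append(message)

    def fail(self, stage: str, cause: str) -> None:
        self.status = "failed"
        self.failed_stage = stage
        self.cause = cause
        self.add(stage, f"FAILED: {cause}")

    def to_text(self) -> str:
        lines = [f"image: {self.image_id}", f"status: {self.status}"]
        if self.failed_stage:
            lines.append(f"failed stage: {self.failed_stage} ({self.cause})")
        lines += [f"{t}  [{stage}] {msg}" for t, stage, msg in self.entries]
        lines += [f"warning: {w}" for w in self.warnings]
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# mask discovery
# ---------------------------------------------------------------------------


def _discover_masks(image_path: Path, config: PipelineConfig, output_dir: Path | None):
    """(mask_paths, provenance): corrected masks in the image's output folder
    beat user-supplied masks, which beat the baseline."""
    stem = image_path.stem
    if output_dir is not None:
        folder = output_dir / stem
        corrected = folder / f"{stem}_labels_corrected.png"
        if corrected.exists():
            paths = {"labels": corrected}
            fov = folder / f"{stem}_fovea_corrected.png"
            if fov.exists():
                paths["fovea"] = fov
            elif config.masks_dir and (Path(config.masks_dir) / f"{stem}_fovea.png").exists():
                paths["fovea"] = Path(config.masks_dir) / f"{stem}_fovea.png"
            return paths, "corrected"
    if config.masks_dir:
        mdir = Path(config.masks_dir)
        lab = mdir / f"{stem}_labels.png"
        if lab.exists():
            paths = {"labels": lab}
            if (mdir / f"{stem}_fovea.png").exists():
                paths["fovea"] = mdir / f"{stem}_fovea.png"
            if (mdir / f"{stem}_vessel.png").exists():
                paths["vessel"] = mdir / f"{stem}_vessel.png"
            return paths, "external"
    return None, "baseline"


# ---------------------------------------------------------------------------
# single image
# ---------------------------------------------------------------------------


def run_single(
    image_path: str | Path,
    config: PipelineConfig | None = None,
    output_dir: str | Path | None = None,
) -> tuple[list, ProcessLog, dict]:
    """Analyze one image; returns (metric records, process log, artifacts).

    ``artifacts`` carries the post-processed masks, landmarks and ROIs so
    callers (tests, the overlay renderer) can inspect intermediate state.
    """
    config = config or PipelineConfig()
    image_path = Path(image_path)
    output_dir = Path(output_dir) if output_dir else None
    log = ProcessLog(image_id=image_path.stem)
    artifacts: dict = {}

    stage = "read"
    try:
        overrides = {
            "scale_um_per_px": config.scale_um_per_px,
            "laterality": config.laterality,
            "location": config.location,
        }
        image = io_formats.read_slo_image(image_path, metadata_overrides=overrides)
        log.add(stage, f"{image.height_px}x{image.width_px} px, scale="
                f"{image.scale_um_per_px or 'unknown'}")

        stage = "segment"
        mask_paths, provenance = _discover_masks(image_path, config, output_dir)
        if mask_paths is not None:
            bundle = segmentation.ingest_bundle(image, mask_paths, provenance=provenance)
        else:
            bundle = segmentation.baseline_bundle(
                image, scales=config.vesselness_scales, threshold=config.threshold
            )
        log.add(stage, f"provenance={bundle.provenance}")

        stage = "postprocess"
        shape = image.pixels.shape
        min_area = int(round(landmarks.scaled_param(
            config.postprocess_min_area_px, shape, quadratic=True)))
        max_gap = int(round(landmarks.scaled_param(config.postprocess_max_gap_px, shape)))
        masks = {}
        for name, prob in bundle.maps().items():
            if prob is None:
                masks[name] = np.zeros(shape, dtype=bool)
                continue
            binary = landmarks.binarize(prob, config.threshold)
            binary = landmarks.clean_mask(binary, min_area)
            if name in ("vessel", "artery", "vein"):
                binary = landmarks.bridge_gaps(binary, max_gap)
            masks[name] = binary
        # harmonization: the all-vessel map covers artery ∪ vein
        masks["vessel"] |= masks["artery"] | masks["vein"]
        artifacts["masks"] = masks

        stage = "landmarks"
        fovea = landmarks.fovea_centroid(masks["fovea"])
        disc = landmarks.fit_disc(masks["disc"])
        artifacts["fovea"], artifacts["disc"] = fovea, disc
        log.add(stage, f"fovea present={fovea.present}, disc present={disc.present}")

        stage = "infer"
        lat_inf, loc_inf = landmarks.infer_laterality_location(fovea, disc, shape)
        laterality = image.laterality if image.laterality != "unknown" else lat_inf
        location = image.location if image.location != "unknown" else loc_inf
        if not fovea.present and not disc.present:
            log.warn("no landmarks detected; laterality/location unknown")
        log.add(stage, f"laterality={laterality}, location={location}")

        stage = "zones"
        roi_list = zones.rois_for_location(
            location,
            disc,
            shape,
            shape=config.zones_shape,
            exclude_disc_from_whole=config.zones_exclude_disc_from_whole,
        )
        artifacts["rois"] = roi_list

        stage = "metrics"
        min_seg = int(round(landmarks.scaled_param(config.metrics_min_segment_len, shape)))
        metadata = {
            "laterality": laterality,
            "location": location,
            "scale_um_per_px": image.scale_um_per_px,
            "fovea_x_px": round(fovea.x_px, 3) if fovea.present else None,
            "fovea_y_px": round(fovea.y_px, 3) if fovea.present else None,
            "disc_x_px": round(disc.center_x_px, 3) if disc.present else None,
            "disc_y_px": round(disc.center_y_px, 3) if disc.present else None,
            "disc_diameter_px": round(disc.diameter_D_px, 3) if disc.present else None,
        }
        records = metrics.compute_all(
            {"all": masks["vessel"], "artery": masks["artery"], "vein": masks["vein"]},
            roi_list,
            scale_um_per_px=image.scale_um_per_px,
            image_id=image.image_id,
            min_segment_len=min_seg,
            aggregation=config.metrics_aggregation,
            knudtson_n=config.metrics_knudtson_n,
            boundary_rule=config.zones_boundary_rule,
            fd_on_skeleton=config.metrics_fd_on_skeleton,
            metadata=metadata,
        )
        log.add(stage, f"{len(records)} records across {len(roi_list)} ROIs")

        stage = "write"
        if output_dir is not None:
            _write_outputs(image, image_path, config, output_dir, masks, records,
                           fovea, disc, roi_list, location, log)
    except Exception as exc:
        log.fail(stage, f"{type(exc).__name__}: {exc}")
        if output_dir is not None:
            _write_log(output_dir, image_path.stem, log)
        raise
    if output_dir is not None:
        _write_log(output_dir, image_path.stem, log)
    return records, log, artifacts


def _write_log(output_dir: Path, stem: str, log: ProcessLog) -> None:
    folder = output_dir / stem
    folder.mkdir(parents=True, exist_ok=True)
    io_formats._atomic_write_bytes(folder / f"{stem}_log.txt", log.to_text().encode())


def _write_outputs(image, image_path, config, output_dir, masks, records,
                   fovea, disc, rois, location, log) -> None:
    import json

    stem = image_path.stem
    folder = output_dir / stem
    folder.mkdir(parents=True, exist_ok=True)
    io_formats.write_metrics_table(records, folder / f"{stem}_metrics.csv")
    meta = records[0].metadata if records else {}
    io_formats._atomic_write_bytes(
        folder / f"{stem}_metadata.json",
        (json.dumps(meta, indent=1, default=float) + "\n").encode(),
    )
    if config.save_segmentations:
        labels = np.zeros(image.pixels.shape, dtype=np.uint8)
        labels[masks["disc"]] = LABEL_DISC
        labels[masks["artery"] & ~masks["vein"]] = LABEL_ARTERY
        labels[masks["vein"] & ~masks["artery"]] = LABEL_VEIN
        labels[masks["artery"] & masks["vein"]] = LABEL_CROSSING
        io_formats.write_mask(labels, folder / f"{stem}_labels.png")
        io_formats.write_binary_mask(masks["vessel"], folder / f"{stem}_vessel.png")
        io_formats.write_binary_mask(masks["fovea"], folder / f"{stem}_fovea.png")
        vis_dir = output_dir / "visualizations"
        vis_dir.mkdir(parents=True, exist_ok=True)
        render_overlay(image, masks, fovea, disc, rois, location,
                       vis_dir / f"{stem}_overlay.png")
        log.add("write", "masks and overlay saved")


# ---------------------------------------------------------------------------
# overlay visualization
# ---------------------------------------------------------------------------


def render_overlay(image: SLOImage, masks: dict, fovea, disc, rois, location,
                   path: str | Path) -> None:
    """Segmentation quality-check figure: arteries red, veins blue,
    crossings magenta, disc outline yellow, fovea marker green, and zone
    rings for disc-centered scans."""
    from scipy import ndimage as ndi

    gray = image.pixels
    lo, hi = gray.min(), gray.max()
    base = ((gray - lo) / (hi - lo) * 255 if hi > lo else gray).astype(np.uint8)
    rgb = np.stack([base] * 3, axis=2).astype(float)

    def paint(sel, color, alpha=0.55):
        for ch in range(3):
            rgb[..., ch][sel] = (1 - alpha) * rgb[..., ch][sel] + alpha * color[ch]

    paint(masks["artery"] & ~masks["vein"], (255, 40, 40))
    paint(masks["vein"] & ~masks["artery"], (60, 80, 255))
    paint(masks["artery"] & masks["vein"], (255, 0, 255))
    if masks["disc"].any():
        outline = masks["disc"] ^ ndi.binary_erosion(masks["disc"])
        paint(ndi.binary_dilation(outline), (255, 220, 0), alpha=1.0)
    if fovea.present:
        r, c = int(round(fovea.y_px)), int(round(fovea.x_px))
        h, w = base.shape
        rr = slice(max(0, r - 8), min(h, r + 9))
        cc = slice(max(0, c - 8), min(w, c + 9))
        rgb[rr, c, :] = (0, 255, 0)
        rgb[r, cc, :] = (0, 255, 0)
    if location == "disc" and disc.present:
        yy, xx = np.mgrid[0 : base.shape[0], 0 : base.shape[1]]
        r = np.hypot(yy - disc.center_y_px, xx - disc.center_x_px)
        D = disc.diameter_D_px
        for lo_d, hi_d, color in (
            (1.0, 1.5, (255, 80, 80)),  # zone B bounds
            (0.5, 2.5, (80, 200, 255)),  # zone C bounds
        ):
            for bound in (lo_d * D, hi_d * D):
                ring = np.abs(r - bound) <= 1.0
                paint(ring, color, alpha=1.0)
    from PIL import Image

    import io as _io

    buf = _io.BytesIO()
    Image.fromarray(np.clip(rgb, 0, 255).astype(np.uint8)).save(buf, format="PNG")
    io_formats._atomic_write_bytes(Path(path), buf.getvalue())


# ---------------------------------------------------------------------------
# batch
# ---------------------------------------------------------------------------


def run_batch(
    input_dir: str | Path, config: PipelineConfig | None = None,
    output_dir: str | Path | None = None,
):
    """Process every supported image in ``input_dir`` (lexicographic order).

    Returns (collated DataFrame, list of ProcessLogs, summary dict).  With
    ``skip_on_error`` a failing image is logged as skipped and the batch
    continues; otherwise the first failure propagates.
    """
    config = config or PipelineConfig()
    input_dir = Path(input_dir)
    output_dir = Path(output_dir or config.output_dir or (input_dir / "output"))
    images = io_formats.list_images(input_dir)
    if not images:
        raise SlovascError(f"no supported images found in {input_dir}")
    all_records: list = []
    logs: list[ProcessLog] = []
    summary = {"ok": 0, "skipped": 0, "failed": 0}
    for img_path in images:
        try:
            records, log, _ = run_single(img_path, config, output_dir)
            all_records.extend(records)
            logs.append(log)
            summary["ok"] += 1
        except Exception:
            if not config.skip_on_error:
                summary["failed"] += 1
                raise
            log = ProcessLog(image_id=img_path.stem, status="skipped")
            log.warn(traceback.format_exc(limit=1).strip())
            logs.append(log)
            summary["skipped"] += 1
    frame = io_formats.write_metrics_table(
        all_records, output_dir / "collated_metrics.csv", xlsx_mirror=False
    )
    return frame, logs, summary
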