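"""End-to-end orchestration: load or simulate, preprocess, reconstruct,
segment, track, quantify, report.

File layout convention: ``<input_dir>/<position>/<frame>/`` containing either
``TL.tif``/``TR.tif``/``BL.tif``/``BR.tif`` or a 4-page ``stack.tif`` (page
order TL, TR, BL, BR), plus an optional ``phase.tif`` (radians). Outputs per
frame are 32-bit float DF/E/QDF TIFFs and an integer label TIFF, plus a
per-run cell table CSV, an SNR JSON report and a manifest echoing the
configuration, the package version and the scaling factor actually used.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
import yaml
from pydantic import BaseModel, Field

from . import __version__
from .config import OpticalConfig
from .core import (
    QuadrantStack,
    calibrate_c,
    compute_darkfield,
    compute_edge,
    default_edge_mask,
)
from .cells import (
    DebrisThresholds,
    SegmentationConfig,
    TrackingConfig,
    compute_snr,
    filter_debris,
    per_cell_signals,
    segment_cells,
    track_cells,
)
from .errors import ConfigError, DataError
from .phantom import (
    bead_scene,
    make_population,
    make_shape_sequence,
    render_phase,
    render_quadrants,
    shape_change_base_scene,
)

logger = logging.getLogger("qdf")

QUADRANT_FILES = ("TL.tif", "TR.tif", "BL.tif", "BR.tif")
DEMO_NAMES = ("beads", "shape_change", "two_populations")


class PreprocessToggles(BaseModel):
    """Which conditioning steps run, and with what parameters."""

    rescale: bool = False
    bit_divisor: int = 16
    reference_path: Optional[str] = None
    remove_quadrant_background: bool = False
    remove_edge_background: bool = False
    polynomial_order: int = 8


class SegmentationParams(BaseModel):
    smooth_sigma_px: float = 2.0
    phase_threshold_rad: float = 0.2
    min_seed_separation_px: int = 10
    min_area_px: int = 64

    def to_config(self) -> SegmentationConfig:
        return SegmentationConfig(**self.model_dump())


class TrackingParams(BaseModel):
    max_disp_px: float = 20.0
    memory: int = 1


class DebrisParams(BaseModel):
    min_area_px: float = 0.0
    max_area_px: float = float("inf")
    min_track_length: int = 0
    min_mean_phase: float = 0.0
    min_mean_df: float = 0.0
    min_mean_qdf: float = 0.0

    def to_thresholds(self) -> DebrisThresholds:
        return DebrisThresholds(**self.model_dump())


class RunConfig(BaseModel):
    """Full configuration of one pipeline run."""

    input_dir: str
    output_dir: str
    optics: OpticalConfig = Field(default_factory=OpticalConfig)
    preprocess: PreprocessToggles = Field(default_factory=PreprocessToggles)
    segmentation: SegmentationParams = Field(default_factory=SegmentationParams)
    tracking: TrackingParams = Field(default_factory=TrackingParams)
    debris: DebrisParams = Field(default_factory=DebrisParams)
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls(**data)


def _load_stack(frame_dir: Path, optics: OpticalConfig) -> QuadrantStack:
    multi = frame_dir / "stack.tif"
    if multi.exists():
        return QuadrantStack.from_tiff(multi, bit_depth=optics.bit_depth)
    paths = [frame_dir / name for name in QUADRANT_FILES]
    missing = [p for p in paths if not p.exists()]
    if missing:
        raise DataError(
            f"missing quadrant file(s) in {frame_dir}: "
            + ", ".join(p.name for p in missing)
        )
    return QuadrantStack.from_quadrant_tiffs(*paths, bit_depth=optics.bit_depth)


def _preprocess_stack(stack: QuadrantStack, toggles: PreprocessToggles) -> QuadrantStack:
    from .preprocess import rescale_bit_depth, subtract_reference

    images = list(stack.images)
    if toggles.rescale:
        images = [rescale_bit_depth(im, toggles.bit_divisor) for im in images]
    if toggles.reference_path:
        ref_path = Path(toggles.reference_path)
        if not ref_path.exists():
            raise DataError(f"reference stack not found: {ref_path}")
        ref = QuadrantStack.from_tiff(ref_path)
        ref_images = ref.images
        if toggles.rescale:
            ref_images = [rescale_bit_depth(im, toggles.bit_divisor) for im in ref_images]
        images = [subtract_reference(im, r) for im, r in zip(images, ref_images)]
    return stack.replace_images(images)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full flow for every position and frame under ``input_dir``.

    Returns a summary dict with output paths and headline numbers. The
    scaling factor c is resolved once on the first frame of each position
    (``"auto"`` triggers least-squares calibration on the default edge mask
    restricted to segmented objects) and reused across that position's
    frames.
    """
    from .preprocess import fit_background, remove_background

    in_dir = Path(config.input_dir)
    if not in_dir.is_dir():
        raise ConfigError(f"input_dir does not exist: {in_dir}")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    positions = sorted(p for p in in_dir.iterdir() if p.is_dir())
    if not positions:
        raise DataError(f"no position directories under {in_dir}")

    all_records = []
    snr_reports: dict[str, dict] = {}
    c_used: dict[str, float] = {}
    seg_cfg = config.segmentation.to_config()
    for pos in positions:
        frames = sorted(d for d in pos.iterdir() if d.is_dir())
        if not frames:
            raise DataError(f"no frame directories under {pos}")
        pos_records = []
        c_value: float | None = None if config.optics.c == "auto" else float(config.optics.c)
        for f_idx, frame_dir in enumerate(frames):
            t0 = time.perf_counter()
            stack = _load_stack(frame_dir, config.optics)
            stack = _preprocess_stack(stack, config.preprocess)
            phase_path = frame_dir / "phase.tif"
            phase = tifffile.imread(str(phase_path)) if phase_path.exists() else None
            labels = (
                segment_cells(phase, seg_cfg)
                if phase is not None
                else segment_cells(compute_darkfield(stack) / 4.0, seg_cfg)
            )
            object_mask = labels > 0
            if config.preprocess.remove_quadrant_background:
                images = [
                    remove_background(
                        im, fit_background(im, object_mask, order=config.preprocess.polynomial_order)
                    )
                    for im in stack.images
                ]
                stack = stack.replace_images(images)
            df = compute_darkfield(stack)
            edge = compute_edge(stack)
            if config.preprocess.remove_edge_background:
                edge = remove_background(
                    edge, fit_background(edge, object_mask, order=config.preprocess.polynomial_order)
                )
            if c_value is None:
                mask = default_edge_mask(stack, object_mask if object_mask.any() else None)
                c_value = calibrate_c(stack, mask).c
                logger.info("%s: calibrated c = %.4f", pos.name, c_value)
            qdf = c_value * df - edge
            out_frame = out_dir / pos.name / frame_dir.name
            out_frame.mkdir(parents=True, exist_ok=True)
            for name, im in (("DF", df), ("E", edge), ("QDF", qdf)):
                tifffile.imwrite(str(out_frame / f"{name}.tif"), im.astype(np.float32))
            tifffile.imwrite(str(out_frame / "labels.tif"), labels.astype(np.int32))
            recs = per_cell_signals(
                labels, df, qdf, phase_image=phase, optics=config.optics, frame=f_idx
            )
            recs.insert(0, "position", pos.name)
            pos_records.append(recs)
            try:
                rep = compute_snr(qdf, labels)
                snr_reports[f"{pos.name}/{frame_dir.name}"] = {
                    "threshold": rep.threshold,
                    "noise_sigma": rep.noise_sigma,
                    "per_cell_snr": rep.per_cell_snr,
                    "mean": rep.mean,
                    "std": rep.std,
                }
            except DataError as exc:
                logger.debug("%s/%s: SNR skipped (%s)", pos.name, frame_dir.name, exc)
            logger.info(
                "%s/%s: %d cells, %.2fs",
                pos.name, frame_dir.name, len(recs), time.perf_counter() - t0,
            )
        c_used[pos.name] = c_value
        pos_table = pd.concat(pos_records, ignore_index=True)
        if len(pos_table):
            pos_table = track_cells(
                pos_table,
                max_disp_px=config.tracking.max_disp_px,
                memory=config.tracking.memory,
            )
        all_records.append(pos_table)

    cells_table = pd.concat(all_records, ignore_index=True)
    if len(cells_table):
        cells_table = filter_debris(cells_table, config.debris.to_thresholds())
        logger.info(
            "debris filter flagged %d / %d records",
            int(cells_table["debris"].sum()), len(cells_table),
        )
    csv_path = out_dir / "cells.csv"
    cells_table.to_csv(csv_path, index=False, float_format="%.10g")
    snr_path = out_dir / "snr.json"
    snr_path.write_text(json.dumps(snr_reports, indent=1, sort_keys=True))
    manifest = {
        "config": json.loads(config.model_dump_json()),
        "version": __version__,
        "seed": config.seed,
        "c_used": c_used,
        "n_records": int(len(cells_table)),
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return {
        "cells_csv": csv_path,
        "snr_json": snr_path,
        "manifest": manifest_path,
        "c_used": c_used,
        "n_records": int(len(cells_table)),
    }


# ---------------------------------------------------------------------------
# in-memory analysis helpers (no file I/O) — the same stages run_pipeline
# composes, exposed for scripting and simulation studies


def analyze_scene(
    scene,
    optics: OpticalConfig | None = None,
    background_order: int = 2,
    c: float | None = None,
    segmentation: SegmentationConfig | None = None,
):
    """Render one scene and run it through the standard analysis chain.

    Segments the matching phase image, removes a polynomial background from
    each quadrant image (fitted outside the segmented cells), calibrates c on
    the default edge mask unless a value is supplied, reconstructs DF/E/QDF
    and quantifies per-cell signals. Returns a dict with the intermediate
    products (stack, truth, labels, df, edge, qdf, c, table).
    """
    from .preprocess import fit_background, remove_background

    optics = optics or OpticalConfig()
    stack, truth = render_quadrants(scene, optics)
    phase = render_phase(scene, optics)
    labels = segment_cells(phase, segmentation)
    object_mask = labels > 0
    images = [
        remove_background(im, fit_background(im, object_mask, order=background_order))
        for im in stack.images
    ]
    corrected = stack.replace_images(images)
    if c is None:
        mask = default_edge_mask(corrected, object_mask if object_mask.any() else None)
        c = calibrate_c(corrected, mask).c
    df = compute_darkfield(corrected)
    edge = compute_edge(corrected)
    qdf = c * df - edge
    table = per_cell_signals(labels, df, qdf, phase_image=phase, optics=optics)
    return {
        "stack": corrected,
        "truth": truth,
        "phase": phase,
        "labels": labels,
        "df": df,
        "edge": edge,
        "qdf": qdf,
        "c": c,
        "table": table,
    }


def population_totals(scenes, optics: OpticalConfig | None = None, background_order: int = 2):
    """Per-cell total DF and QDF across a list of single-cell scenes.

    Calibrates c once, on the first scene, and reuses it — one instrument,
    one scaling factor. Scenes where segmentation does not find exactly one
    cell are dropped. Returns (total_df, total_qdf, c) arrays/float.
    """
    c = None
    out_df, out_qdf = [], []
    for scene in scenes:
        res = analyze_scene(scene, optics=optics, background_order=background_order, c=c)
        c = res["c"]
        if len(res["table"]) == 1:
            out_df.append(float(res["table"]["total_df"].iloc[0]))
            out_qdf.append(float(res["table"]["total_qdf"].iloc[0]))
    return np.asarray(out_df), np.asarray(out_qdf), c


# ---------------------------------------------------------------------------
# demo datasets


def _write_frame(frame_dir: Path, scene, optics: OpticalConfig, with_phase: bool = True):
    frame_dir.mkdir(parents=True, exist_ok=True)
    stack, truth = render_quadrants(scene, optics)
    for name, im in zip(("TL", "TR", "BL", "BR"), stack.images):
        tifffile.imwrite(str(frame_dir / f"{name}.tif"), im.astype(np.uint16))
    if with_phase:
        phase = render_phase(scene, optics)
        tifffile.imwrite(str(frame_dir / "phase.tif"), phase.astype(np.float32))
    tifffile.imwrite(
        str(frame_dir / "truth_labels.tif"), truth.cell_label_image.astype(np.int32)
    )
    sidecar = {
        "per_cell_puncta_total": {str(k): v for k, v in truth.per_cell_puncta_total.items()},
        "deposited_total": truth.deposited_total,
    }
    (frame_dir / "truth.json").write_text(json.dumps(sidecar, indent=1))
    scene.to_json(frame_dir / "scene.json")
    return truth


def demo_datasets(
    name: str,
    seed: int,
    out_dir,
    n_cells_per_population: int = 40,
    optics: OpticalConfig | None = None,
) -> Path:
    """Materialise a named phantom suite, ready for :func:`run_pipeline`.

    ``beads`` — one clean and one imperfect (internal punctum) bead position;
    ``shape_change`` — a 5-frame flat-to-round single-cell time series with
    conserved puncta content; ``two_populations`` — two cell populations
    differing 3x in puncta density (``popA``/``popB`` subdirectories).
    """
    if name not in DEMO_NAMES:
        raise ConfigError(f"unknown demo dataset {name!r}; options: {', '.join(DEMO_NAMES)}")
    optics = optics or OpticalConfig()
    out_dir = Path(out_dir)
    if name == "beads":
        clean = bead_scene(noise_sigma=0.5, background_level=2.0, seed=seed)
        imperfect = bead_scene(
            punctum_amplitude=2000.0, noise_sigma=0.5, background_level=2.0, seed=seed + 1
        )
        _write_frame(out_dir / "pos000" / "t000", clean, optics, with_phase=False)
        _write_frame(out_dir / "pos001" / "t000", imperfect, optics, with_phase=False)
    elif name == "shape_change":
        base = shape_change_base_scene(seed=seed)
        seq = make_shape_sequence(base, n_frames=5, shape_range=(0.1, 0.9), seed=seed)
        for i, scene in enumerate(seq.frames):
            _write_frame(out_dir / "pos000" / f"t{i:03d}", scene, optics)
    else:
        base_density = 0.01
        for sub, density, pop_seed in (
            ("popA", base_density, seed),
            ("popB", 3.0 * base_density, seed + 1),
        ):
            scenes = make_population(n_cells_per_population, density, seed=pop_seed)
            for i, scene in enumerate(scenes):
                _write_frame(out_dir / sub / f"pos{i:03d}" / "t000", scene, optics)
    return out_dir
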