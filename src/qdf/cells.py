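"""Single-cell segmentation, tracking and quantification.

Cells are segmented from the quantitative-phase image with a seeded
watershed, tracked over time by Crocker-Grier-style minimum-displacement
linking, and quantified per cell and frame: projected area, dry mass via the
specific refractive increment, total darkfield and (zero-clipped) total QDF,
their mass-normalised forms, debris flags, and the per-cell puncta
signal-to-noise ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from skimage.feature import peak_local_max
from skimage.morphology import dilation, disk
from skimage.segmentation import watershed

from .config import OpticalConfig
from .errors import ConfigError, DataError


@dataclass
class SegmentationConfig:
    """Watershed parameters (all in config, none hard-coded downstream).

    The phase landscape is Gaussian-smoothed, thresholded into a foreground
    mask, seeded at local maxima, and flooded on the inverted smoothed phase
    restricted to the mask, separating touching cells.
    """

    smooth_sigma_px: float = 2.0
    phase_threshold_rad: float = 0.2
    min_seed_separation_px: int = 10
    min_area_px: int = 64


def segment_cells(
    phase_image: np.ndarray, config: SegmentationConfig | None = None
) -> np.ndarray:
    """Watershed segmentation of a background-corrected phase image.

    Returns an integer label image (0 = background, labels contiguous from 1).
    An all-background image yields an all-zero label image, not an error.
    """
    cfg = config or SegmentationConfig()
    phase = np.asarray(phase_image, dtype=np.float64)
    smoothed = ndimage.gaussian_filter(phase, cfg.smooth_sigma_px)
    mask = smoothed > cfg.phase_threshold_rad
    if not mask.any():
        return np.zeros(phase.shape, dtype=np.int32)
    peaks = peak_local_max(
        smoothed,
        min_distance=cfg.min_seed_separation_px,
        threshold_abs=cfg.phase_threshold_rad,
        labels=mask,
    )
    markers = np.zeros(phase.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    labels = watershed(-smoothed, markers=markers, mask=mask)
    # drop small objects, relabel contiguously from 1
    out = np.zeros_like(labels, dtype=np.int32)
    nxt = 1
    for lbl in range(1, labels.max() + 1):
        sel = labels == lbl
        if sel.sum() >= cfg.min_area_px:
            out[sel] = nxt
            nxt += 1
    return out


@dataclass
class TrackingConfig:
    """Frame-to-frame linking parameters."""

    max_disp_px: float = 20.0
    memory: int = 1


def track_cells(
    records: pd.DataFrame,
    max_disp_px: float = 20.0,
    memory: int = 1,
) -> pd.DataFrame:
    """Link per-frame cell records into tracks (Crocker-Grier style).

    Minimises total squared centroid displacement per frame pair via the
    Hungarian algorithm, with links gated at ``max_disp_px``; a track may skip
    up to ``memory`` missing frames before it is retired. Unlinkable cells
    start new tracks. Requires columns ``frame``, ``label``, ``centroid_row``,
    ``centroid_col``; returns a copy with a ``track_id`` column.
    """
    required = {"frame", "label", "centroid_row", "centroid_col"}
    if not required.issubset(records.columns):
        raise DataError(f"records need columns {sorted(required)}")
    out = records.copy().reset_index(drop=True)
    out["track_id"] = -1
    if len(out) == 0:
        return out
    big = 1e12
    gate2 = float(max_disp_px) ** 2
    next_track = 0
    # active track state: track_id -> (row, col, last_frame)
    active: dict[int, tuple[float, float, int]] = {}
    for frame in sorted(out["frame"].unique()):
        idx = out.index[out["frame"] == frame].to_numpy()
        pts = out.loc[idx, ["centroid_row", "centroid_col"]].to_numpy(dtype=float)
        # retire tracks that have been unseen longer than the memory allows
        active = {
            t: s for t, s in active.items() if frame - s[2] <= memory + 1
        }
        track_ids = list(active.keys())
        n_det, n_trk = len(idx), len(track_ids)
        if n_trk and n_det:
            # classic augmented assignment: real links in the top-left block,
            # births/deaths on gate-cost diagonals, free bottom-right filler
            cost = np.full((n_det + n_trk, n_trk + n_det), big)
            for j, t in enumerate(track_ids):
                tr, tc, _ = active[t]
                d2 = (pts[:, 0] - tr) ** 2 + (pts[:, 1] - tc) ** 2
                cost[:n_det, j] = np.where(d2 <= gate2, d2, big)
            cost[:n_det, n_trk:][np.eye(n_det, dtype=bool)] = gate2
            cost[n_det:, :n_trk][np.eye(n_trk, dtype=bool)] = gate2
            cost[n_det:, n_trk:] = 0.0
            rows, cols = linear_sum_assignment(cost)
            assigned = {}
            for r, cidx in zip(rows, cols):
                if r < n_det and cidx < n_trk and cost[r, cidx] < big:
                    assigned[r] = track_ids[cidx]
            for k, det_idx in enumerate(idx):
                if k in assigned:
                    t = assigned[k]
                else:
                    t = next_track
                    next_track += 1
                out.loc[det_idx, "track_id"] = t
                active[t] = (pts[k, 0], pts[k, 1], frame)
        else:
            for k, det_idx in enumerate(idx):
                t = next_track
                next_track += 1
                out.loc[det_idx, "track_id"] = t
                active[t] = (pts[k, 0], pts[k, 1], frame)
    return out


def compute_dry_mass(
    phase_image: np.ndarray,
    label_image: np.ndarray,
    optics: OpticalConfig,
) -> pd.Series:
    """Per-cell dry mass in picograms from integrated phase.

    Standard QPI relation: mass = sum(phi) * (lambda / 2 pi) * pixel_area /
    alpha, with phi the phase in radians and alpha the specific refractive
    increment (m^3/kg). sum(phi) * lambda / 2 pi is integrated optical path
    length (m); times pixel area (m^2) it is an integrated volume-index
    product (m^3); divided by alpha it is mass (kg), reported as pg.
    """
    if optics.wavelength_nm <= 0 or optics.pixel_size_um <= 0:
        raise ConfigError("wavelength and pixel size must be set and positive")
    phase = np.asarray(phase_image, dtype=np.float64)
    labels = np.asarray(label_image)
    if phase.shape != labels.shape:
        raise DataError("phase and label image shapes differ")
    ids = np.unique(labels)
    ids = ids[ids > 0]
    lam_m = optics.wavelength_nm * 1e-9
    px_area_m2 = (optics.pixel_size_um * 1e-6) ** 2
    alpha = optics.refractive_increment_m3_per_kg
    factor_pg = lam_m / (2.0 * np.pi) * px_area_m2 / alpha * 1e15
    sums = ndimage.sum_labels(phase, labels, ids) if ids.size else np.array([])
    return pd.Series(np.asarray(sums) * factor_pg, index=ids.astype(int), name="dry_mass_pg")


def per_cell_signals(
    label_image: np.ndarray,
    df: np.ndarray,
    qdf: np.ndarray,
    phase_image: np.ndarray | None = None,
    optics: OpticalConfig | None = None,
    frame: int = 0,
) -> pd.DataFrame:
    """Per-cell record table for one frame.

    ``total_df`` sums the darkfield over the label; ``total_qdf`` sums
    ``max(QDF, 0)`` — negatives from noise or imperfect calibration carry no
    puncta information and would bias totals downward. With a phase image and
    optics, dry mass and the mass-normalised signals are added.
    """
    labels = np.asarray(label_image)
    df = np.asarray(df, dtype=np.float64)
    qdf = np.asarray(qdf, dtype=np.float64)
    if labels.shape != df.shape or labels.shape != qdf.shape:
        raise DataError("label, DF and QDF images must share a shape")
    ids = np.unique(labels)
    ids = ids[ids > 0]
    qdf_pos = np.maximum(qdf, 0.0)
    rows = []
    optics = optics or OpticalConfig()
    masses = None
    if phase_image is not None:
        masses = compute_dry_mass(phase_image, labels, optics)
    for lbl in ids:
        sel = labels == lbl
        area_px = int(sel.sum())
        area_um2 = area_px * optics.pixel_area_um2
        com = ndimage.center_of_mass(sel)
        rec = {
            "frame": frame,
            "label": int(lbl),
            "area_px": area_px,
            "area_um2": area_um2,
            "centroid_row": com[0],
            "centroid_col": com[1],
            "total_df": float(df[sel].sum()),
            "total_qdf": float(qdf_pos[sel].sum()),
            "mean_df": float(df[sel].mean()),
            "mean_qdf": float(qdf_pos[sel].mean()),
        }
        if phase_image is not None:
            mass = float(masses.loc[int(lbl)])
            rec["mean_phase"] = float(np.asarray(phase_image)[sel].mean())
            rec["dry_mass_pg"] = mass
            rec["mass_per_area_pg_per_um2"] = mass / area_um2 if area_um2 > 0 else np.nan
            rec["qdf_per_mass"] = rec["total_qdf"] / mass if mass > 0 else np.nan
            rec["df_per_mass"] = rec["total_df"] / mass if mass > 0 else np.nan
        rows.append(rec)
    return pd.DataFrame(rows)


@dataclass
class DebrisThresholds:
    """Debris rejection rules: a record failing any criterion is flagged.

    Defaults pass everything; set the bounds that apply to your data.
    """

    min_area_px: float = 0.0
    max_area_px: float = np.inf
    min_track_length: int = 0
    min_mean_phase: float = 0.0
    min_mean_df: float = 0.0
    min_mean_qdf: float = 0.0


def filter_debris(records: pd.DataFrame, thresholds: DebrisThresholds) -> pd.DataFrame:
    """Flag (never delete) records violating the debris criteria.

    Criteria: area bounds, minimum track length, and minimum per-cell mean
    phase shift, darkfield and QDF. Returns a copy with a boolean ``debris``
    column; a flagged record keeps its data for inspection.
    """
    out = records.copy()
    bad = (out["area_px"] < thresholds.min_area_px) | (
        out["area_px"] > thresholds.max_area_px
    )
    if thresholds.min_track_length > 0 and "track_id" in out.columns:
        lengths = out.groupby("track_id")["frame"].transform("nunique")
        bad |= lengths < thresholds.min_track_length
    for col, thr in (
        ("mean_phase", thresholds.min_mean_phase),
        ("mean_df", thresholds.min_mean_df),
        ("mean_qdf", thresholds.min_mean_qdf),
    ):
        if thr > 0:
            if col not in out.columns:
                raise DataError(f"threshold on {col!r} set but column missing")
            bad |= out[col] < thr
    out["debris"] = bad.to_numpy()
    return out


@dataclass
class SnrReport:
    """Per-cell puncta signal-to-noise on a QDF image.

    ``threshold`` is 4x the 99th percentile of the background QDF;
    ``noise_sigma`` the standard deviation of the background outside cells;
    per-cell SNR is the mean above-threshold QDF inside the cell divided by
    the noise. Reported as mean +/- std over cells.
    """

    threshold: float
    noise_sigma: float
    per_cell_snr: dict[int, float] = field(default_factory=dict)

    @property
    def mean(self) -> float:
        vals = list(self.per_cell_snr.values())
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def std(self) -> float:
        vals = list(self.per_cell_snr.values())
        return float(np.std(vals)) if vals else float("nan")


def compute_snr(
    qdf: np.ndarray,
    label_image: np.ndarray,
    dilation_px: int = 3,
    border_px: int = 5,
) -> SnrReport:
    """Puncta SNR: signal from thresholded QDF inside cells over background noise.

    The background region is everything outside the cell labels dilated by
    ``dilation_px`` (guarding against halo leakage), excluding a
    ``border_px``-wide image margin. The signal mask is QDF above 4x the 99th
    percentile of that background; its intersection with each cell label
    gives that cell's puncta signal.
    """
    qdf = np.asarray(qdf, dtype=np.float64)
    labels = np.asarray(label_image)
    if qdf.shape != labels.shape:
        raise DataError("QDF and label image shapes differ")
    fg = labels > 0
    if dilation_px > 0:
        fg = dilation(fg, disk(dilation_px))
    background = ~fg
    if border_px > 0:
        border = np.zeros_like(background)
        border[border_px:-border_px, border_px:-border_px] = True
        background &= border
    bg_vals = qdf[background]
    if bg_vals.size == 0:
        raise DataError("background region is empty")
    noise = float(np.std(bg_vals))
    if noise == 0.0:
        raise DataError("background has zero variance; SNR undefined")
    threshold = 4.0 * float(np.percentile(bg_vals, 99.0))
    signal_mask = qdf > threshold
    per_cell: dict[int, float] = {}
    for lbl in np.unique(labels[labels > 0]):
        sel = (labels == lbl) & signal_mask
        if sel.any():
            per_cell[int(lbl)] = float(qdf[sel].mean() / noise)
    return SnrReport(threshold=threshold, noise_sigma=noise, per_cell_snr=per_cell)
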