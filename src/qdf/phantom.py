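"""Synthetic quadrant-darkfield phantoms.

Parametric forward model producing four quadrant-illuminated darkfield images
(plus a matching phase image and ground-truth masks) from a scene description,
so every downstream stage — preprocessing, reconstruction, segmentation,
quantification, statistics — is testable without a microscope.

Physics caricature, one parameter per object:

* Large boundaries (cell edges, bead rims) refract light directionally. A
  boundary pixel with outward normal pointing toward quadrant Q deposits the
  directional fraction ``g`` of its light into the image illuminated from the
  *diagonally opposite* quadrant (raster convention: row 0 top, column 0 left;
  normal toward top-left -> bottom-right illumination image). The remaining
  ``1 - g`` is split equally across all four images.
* Sub-wavelength puncta scatter into a broad Mie-like cone; with ``g = 0``
  they contribute equally to all four images.
* ``edge_leak`` models residual diffraction appearing on the far side of an
  object: a fraction of the directional deposit lands in the diagonally
  opposite image, which lowers the effective edge-matching factor c to
  ``1 - 2 * leak`` on pure edges.

The anisotropy parameter interpolates linearly between isotropic (g=0) and
fully directional (g=1); no Mie series is computed. Light is conserved: g and
leak redistribute a deposit across the four images, never change its total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config import OpticalConfig
from .core import QuadrantStack
from .errors import ConfigError, DataError
from .preprocess import _design_matrix

# image index order TL, TR, BL, BR; a normal pointing toward quadrant q
# deposits into image 3 - q (the diagonally opposite illumination)
_TL, _TR, _BL, _BR = 0, 1, 2, 3


@dataclass
class CircleBoundary:
    """Closed circular contour refracting light at its rim.

    ``amplitude`` is the peak deposit (counts) at the rim centreline;
    ``edge_width_px`` is the Gaussian half-width of the rim cross-section.
    ``phase_total`` is the integrated phase (rad * px) of the enclosed cell
    body, used by :func:`render_phase`.
    """

    center: tuple[float, float]  # (row, col)
    radius: float
    amplitude: float
    edge_width_px: float = 1.5
    anisotropy: float = 1.0
    edge_leak: float = 0.0
    phase_total: float = 0.0


@dataclass
class SegmentBoundary:
    """Straight boundary segment with a fixed outward normal."""

    p0: tuple[float, float]
    p1: tuple[float, float]
    normal: tuple[float, float]  # (d_row, d_col), outward
    amplitude: float
    edge_width_px: float = 1.5
    anisotropy: float = 1.0
    edge_leak: float = 0.0


@dataclass
class Punctum:
    """Small near-isotropic scatterer (Gaussian spot).

    ``amplitude`` is the *total* deposited light (counts) summed over the four
    quadrant images; ``radius_px`` is the Gaussian sigma. Puncta are isotropic
    unless both ``anisotropy > 0`` and an outward ``normal`` are given.
    """

    center: tuple[float, float]
    amplitude: float
    radius_px: float = 1.2
    anisotropy: float = 0.0
    normal: Optional[tuple[float, float]] = None
    phase_total: float = 0.0


@dataclass
class Scene:
    """Full description of one synthetic field of view."""

    canvas_shape: tuple[int, int]
    boundaries: list = field(default_factory=list)
    puncta: list = field(default_factory=list)
    background_level: float = 0.0
    noise_sigma: float = 0.0
    polynomial_background: Optional[np.ndarray] = None  # coeffs, total-degree order
    seed: int = 0

    def validate(self) -> None:
        h, w = self.canvas_shape
        if self.background_level < 0 or self.noise_sigma < 0:
            raise ConfigError("background level and noise sigma must be >= 0")
        for b in self.boundaries:
            if b.amplitude < 0:
                raise ConfigError("boundary amplitude must be >= 0")
            if not 0 <= b.anisotropy <= 1:
                raise ConfigError("anisotropy must lie in [0, 1]")
            if not 0 <= b.edge_leak < 0.5:
                raise ConfigError("edge_leak must lie in [0, 0.5)")
            if isinstance(b, CircleBoundary):
                r, c = b.center
                margin = b.radius + 3 * b.edge_width_px
                if not (margin <= r <= h - 1 - margin and margin <= c <= w - 1 - margin):
                    raise ConfigError("circle boundary extends outside the canvas")
        for p in self.puncta:
            if p.amplitude < 0:
                raise ConfigError("punctum amplitude must be >= 0")
            if not 0 <= p.anisotropy <= 1:
                raise ConfigError("anisotropy must lie in [0, 1]")
            r, c = p.center
            if not (0 <= r <= h - 1 and 0 <= c <= w - 1):
                raise ConfigError("punctum centre lies outside the canvas")

    # -- JSON round-trip ---------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "canvas_shape": list(self.canvas_shape),
            "background_level": self.background_level,
            "noise_sigma": self.noise_sigma,
            "seed": self.seed,
            "boundaries": [],
            "puncta": [],
        }
        for b in self.boundaries:
            if isinstance(b, CircleBoundary):
                d["boundaries"].append(
                    {"kind": "circle", "center": list(b.center), "radius": b.radius,
                     "amplitude": b.amplitude, "edge_width_px": b.edge_width_px,
                     "anisotropy": b.anisotropy, "edge_leak": b.edge_leak,
                     "phase_total": b.phase_total}
                )
            else:
                d["boundaries"].append(
                    {"kind": "segment", "p0": list(b.p0), "p1": list(b.p1),
                     "normal": list(b.normal), "amplitude": b.amplitude,
                     "edge_width_px": b.edge_width_px, "anisotropy": b.anisotropy,
                     "edge_leak": b.edge_leak}
                )
        for p in self.puncta:
            d["puncta"].append(
                {"center": list(p.center), "amplitude": p.amplitude,
                 "radius_px": p.radius_px, "anisotropy": p.anisotropy,
                 "normal": None if p.normal is None else list(p.normal),
                 "phase_total": p.phase_total}
            )
        if self.polynomial_background is not None:
            d["polynomial_background"] = np.asarray(self.polynomial_background).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Scene":
        boundaries = []
        for b in d.get("boundaries", []):
            if b["kind"] == "circle":
                boundaries.append(CircleBoundary(
                    center=tuple(b["center"]), radius=b["radius"], amplitude=b["amplitude"],
                    edge_width_px=b["edge_width_px"], anisotropy=b["anisotropy"],
                    edge_leak=b["edge_leak"], phase_total=b.get("phase_total", 0.0)))
            else:
                boundaries.append(SegmentBoundary(
                    p0=tuple(b["p0"]), p1=tuple(b["p1"]), normal=tuple(b["normal"]),
                    amplitude=b["amplitude"], edge_width_px=b["edge_width_px"],
                    anisotropy=b["anisotropy"], edge_leak=b["edge_leak"]))
        puncta = [Punctum(
            center=tuple(p["center"]), amplitude=p["amplitude"], radius_px=p["radius_px"],
            anisotropy=p["anisotropy"],
            normal=None if p.get("normal") is None else tuple(p["normal"]),
            phase_total=p.get("phase_total", 0.0)) for p in d.get("puncta", [])]
        poly = d.get("polynomial_background")
        return cls(
            canvas_shape=tuple(d["canvas_shape"]), boundaries=boundaries, puncta=puncta,
            background_level=d.get("background_level", 0.0),
            noise_sigma=d.get("noise_sigma", 0.0),
            polynomial_background=None if poly is None else np.asarray(poly, dtype=float),
            seed=d.get("seed", 0))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Scene":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class GroundTruth:
    """Pixel-exact truth for a rendered scene.

    ``edge_mask`` and ``puncta_mask`` are disjoint (edge wins on overlap);
    ``cell_label_image`` labels filled circle interiors 1..n in scene order.
    """

    edge_mask: np.ndarray
    puncta_mask: np.ndarray
    cell_label_image: np.ndarray
    per_cell_puncta_total: dict[int, float]
    per_cell_phase_total: dict[int, float]
    deposited_total: float
    puncta_total: float


@dataclass
class ShapeSequence:
    """Flat-to-round time series of one cell with conserved puncta content."""

    frames: list[Scene]
    shape_parameters: np.ndarray
    conserved_puncta_total: float


def _pointing_quadrant(ny: np.ndarray, nx: np.ndarray) -> np.ndarray:
    """Quadrant a normal points toward: 0=TL, 1=TR, 2=BL, 3=BR.

    Zero components tie-break toward top/left (treated as negative).
    """
    return (ny > 0).astype(np.int8) * 2 + (nx > 0).astype(np.int8)


def _deposit_channels(channels, deposit, pointing, g, leak):
    """Split a deposit field over the four quadrant images.

    Isotropic fraction (1-g)/4 to each image; directional fraction g to the
    image diagonally opposite the pointing quadrant, minus the symmetric leak
    which lands back in the pointing quadrant's image.
    """
    iso = (1.0 - g) / 4.0 * deposit
    for q in range(4):
        channels[q] += iso
    if g > 0:
        direct = g * deposit
        for q in range(4):
            sel = pointing == q
            if not np.any(sel):
                continue
            channels[3 - q][sel] += (1.0 - leak) * direct[sel]
            channels[q][sel] += leak * direct[sel]


def _circle_deposit(shape, b: CircleBoundary):
    h, w = shape
    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    dy = rows - b.center[0]
    dx = cols - b.center[1]
    dist = np.hypot(dy, dx)
    band = np.abs(dist - b.radius) <= 4.0 * b.edge_width_px
    deposit = np.zeros(shape)
    deposit[band] = b.amplitude * np.exp(
        -((dist[band] - b.radius) ** 2) / (2.0 * b.edge_width_px**2)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        ny = np.where(dist > 0, dy / np.maximum(dist, 1e-12), 0.0)
        nx = np.where(dist > 0, dx / np.maximum(dist, 1e-12), 0.0)
    return deposit, _pointing_quadrant(ny, nx)


def _segment_deposit(shape, b: SegmentBoundary):
    h, w = shape
    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    p0 = np.asarray(b.p0, dtype=float)
    p1 = np.asarray(b.p1, dtype=float)
    seg = p1 - p0
    length2 = float(seg @ seg)
    t = ((rows - p0[0]) * seg[0] + (cols - p0[1]) * seg[1]) / max(length2, 1e-12)
    t = np.clip(t, 0.0, 1.0)
    near_r = p0[0] + t * seg[0]
    near_c = p0[1] + t * seg[1]
    dist = np.hypot(rows - near_r, cols - near_c)
    deposit = np.where(
        dist <= 4.0 * b.edge_width_px,
        b.amplitude * np.exp(-(dist**2) / (2.0 * b.edge_width_px**2)),
        0.0,
    )
    q = _pointing_quadrant(np.asarray(b.normal[0]), np.asarray(b.normal[1]))
    pointing = np.full(shape, int(q), dtype=np.int8)
    return deposit, pointing


def _punctum_deposit(shape, p: Punctum):
    h, w = shape
    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    d2 = (rows - p.center[0]) ** 2 + (cols - p.center[1]) ** 2
    kernel = np.exp(-d2 / (2.0 * p.radius_px**2))
    total = kernel.sum()
    if total <= 0:
        return np.zeros(shape), np.zeros(shape, dtype=np.int8)
    # normalised so the deposit sums exactly to the stated amplitude,
    # regardless of canvas truncation
    deposit = p.amplitude * kernel / total
    if p.normal is not None:
        q = int(_pointing_quadrant(np.asarray(p.normal[0]), np.asarray(p.normal[1])))
    else:
        q = 0
    return deposit, np.full(shape, q, dtype=np.int8)


def ground_truth(scene: Scene) -> GroundTruth:
    """Pixel-exact masks and per-cell totals for a scene, rendering-free."""
    shape = scene.canvas_shape
    edge_field = np.zeros(shape)
    circle_labels = np.zeros(shape, dtype=np.int32)
    label = 0
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
    per_cell_phase: dict[int, float] = {}
    for b in scene.boundaries:
        if isinstance(b, CircleBoundary):
            dep, _ = _circle_deposit(shape, b)
            edge_field += dep
            label += 1
            inside = (rows - b.center[0]) ** 2 + (cols - b.center[1]) ** 2 <= b.radius**2
            circle_labels[inside & (circle_labels == 0)] = label
            per_cell_phase[label] = float(b.phase_total)
        else:
            dep, _ = _segment_deposit(shape, b)
            edge_field += dep
    edge_mask = edge_field > 1e-3 * edge_field.max() if edge_field.max() > 0 else edge_field > 0

    puncta_mask = np.zeros(shape, dtype=bool)
    per_cell_puncta: dict[int, float] = {lbl: 0.0 for lbl in range(1, label + 1)}
    puncta_total = 0.0
    for p in scene.puncta:
        rr = int(round(p.center[0]))
        cc = int(round(p.center[1]))
        rad = max(1, int(np.ceil(2.5 * p.radius_px)))
        d2 = (rows - p.center[0]) ** 2 + (cols - p.center[1]) ** 2
        puncta_mask |= d2 <= rad**2
        owner = int(circle_labels[rr, cc])
        if owner > 0:
            per_cell_puncta[owner] += p.amplitude
            per_cell_phase[owner] = per_cell_phase.get(owner, 0.0) + p.phase_total
        puncta_total += p.amplitude
    puncta_mask &= ~edge_mask
    deposited = float(edge_field.sum()) + puncta_total
    return GroundTruth(
        edge_mask=edge_mask,
        puncta_mask=puncta_mask,
        cell_label_image=circle_labels,
        per_cell_puncta_total=per_cell_puncta,
        per_cell_phase_total=per_cell_phase,
        deposited_total=deposited,
        puncta_total=puncta_total,
    )


def render_quadrants(
    scene: Scene,
    optics: OpticalConfig | None = None,
    quantize: bool = True,
) -> tuple[QuadrantStack, GroundTruth]:
    """Render the four quadrant-illuminated darkfield images of a scene.

    With ``quantize`` (default) pixel values are clipped to
    ``[0, 2**bit_depth - 1]`` and rounded to integers, emulating the camera.
    ``quantize=False`` returns the unclipped floating-point fields, which
    conserve the deposited light exactly.
    """
    scene.validate()
    optics = optics or OpticalConfig()
    h, w = scene.canvas_shape
    channels = [np.zeros((h, w)) for _ in range(4)]
    for b in scene.boundaries:
        if isinstance(b, CircleBoundary):
            deposit, pointing = _circle_deposit((h, w), b)
        else:
            deposit, pointing = _segment_deposit((h, w), b)
        _deposit_channels(channels, deposit, pointing, b.anisotropy, b.edge_leak)
    for p in scene.puncta:
        deposit, pointing = _punctum_deposit((h, w), p)
        g = p.anisotropy if p.normal is not None else 0.0
        _deposit_channels(channels, deposit, pointing, g, 0.0)

    if scene.background_level:
        for ch in channels:
            ch += scene.background_level
    if scene.polynomial_background is not None:
        coeffs = np.asarray(scene.polynomial_background, dtype=float)
        order = _order_from_coeffs(coeffs)
        rows, cols = np.mgrid[0:h, 0:w]
        surface = (_design_matrix(rows.ravel(), cols.ravel(), (h, w), order) @ coeffs).reshape(h, w)
        for ch in channels:
            ch += surface
    if scene.noise_sigma > 0:
        rng = np.random.default_rng(scene.seed)
        for ch in channels:
            ch += rng.normal(0.0, scene.noise_sigma, size=(h, w))
    if quantize:
        top = float(2**optics.bit_depth - 1)
        channels = [
            np.floor(np.clip(ch, 0.0, top) + 0.5).astype(np.int64) for ch in channels
        ]
    stack = QuadrantStack(
        *channels, bit_depth=optics.bit_depth, validate_nonnegative=quantize
    )
    return stack, ground_truth(scene)


def _order_from_coeffs(coeffs: np.ndarray) -> int:
    n = coeffs.size
    order = 0
    while (order + 1) * (order + 2) // 2 < n:
        order += 1
    if (order + 1) * (order + 2) // 2 != n:
        raise ConfigError(
            f"polynomial_background length {n} is not a triangular coefficient count"
        )
    return order


def render_phase(
    scene: Scene,
    optics: OpticalConfig | None = None,
    noise_sigma: float = 0.0,
) -> np.ndarray:
    """Render the matching quantitative-phase image (radians).

    Each circular boundary becomes one smooth cell blob whose integrated
    phase equals the boundary's ``phase_total``; normalisation makes the
    integral exact regardless of canvas truncation, so conservation holds as
    the cell rounds up (smaller support, higher peak). Puncta add small bumps
    of integrated phase ``phase_total`` each.
    """
    scene.validate()
    h, w = scene.canvas_shape
    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    phase = np.zeros((h, w))
    for b in scene.boundaries:
        if not isinstance(b, CircleBoundary) or b.phase_total <= 0:
            continue
        sigma = b.radius / 2.0
        kernel = np.exp(
            -((rows - b.center[0]) ** 2 + (cols - b.center[1]) ** 2) / (2.0 * sigma**2)
        )
        phase += b.phase_total * kernel / kernel.sum()
    for p in scene.puncta:
        if p.phase_total <= 0:
            continue
        kernel = np.exp(
            -((rows - p.center[0]) ** 2 + (cols - p.center[1]) ** 2)
            / (2.0 * p.radius_px**2)
        )
        phase += p.phase_total * kernel / kernel.sum()
    if noise_sigma > 0:
        rng = np.random.default_rng(scene.seed + 1)
        phase = phase + rng.normal(0.0, noise_sigma, size=(h, w))
    return phase


def make_shape_sequence(
    base: Scene,
    n_frames: int,
    shape_range: tuple[float, float],
    seed: int = 0,
) -> ShapeSequence:
    """Interpolate one cell from flat to rounded with conserved puncta.

    The shape parameter s in [0, 1] (0 flat, 1 rounded) shrinks the boundary
    radius by up to 45%, raises the rim brightness (rounded edges act as
    stronger lenses, factor 1 + 2s), and pulls puncta toward the centroid in
    proportion to the radius. Puncta amplitudes — and hence the summed puncta
    content — are identical in every frame, as is the cell's integrated phase.
    """
    if n_frames < 2:
        raise ConfigError("n_frames must be >= 2")
    lo, hi = shape_range
    if not (0 <= lo <= 1 and 0 <= hi <= 1):
        raise ConfigError("shape_range must lie within [0, 1]")
    cells = [b for b in base.boundaries if isinstance(b, CircleBoundary)]
    if not cells:
        raise ConfigError("base scene needs at least one circular boundary")
    cell0 = cells[0]
    s_values = np.linspace(lo, hi, n_frames)
    frames = []
    for i, s in enumerate(s_values):
        radius = cell0.radius * (1.0 - 0.45 * s)
        scale = radius / cell0.radius
        boundary = CircleBoundary(
            center=cell0.center,
            radius=radius,
            amplitude=cell0.amplitude * (1.0 + 2.0 * s),
            edge_width_px=cell0.edge_width_px,
            anisotropy=cell0.anisotropy,
            edge_leak=cell0.edge_leak,
            phase_total=cell0.phase_total,
        )
        puncta = [
            Punctum(
                center=(
                    cell0.center[0] + (p.center[0] - cell0.center[0]) * scale,
                    cell0.center[1] + (p.center[1] - cell0.center[1]) * scale,
                ),
                amplitude=p.amplitude,
                radius_px=p.radius_px,
                anisotropy=p.anisotropy,
                normal=p.normal,
                phase_total=p.phase_total,
            )
            for p in base.puncta
        ]
        frames.append(
            Scene(
                canvas_shape=base.canvas_shape,
                boundaries=[boundary],
                puncta=puncta,
                background_level=base.background_level,
                noise_sigma=base.noise_sigma,
                polynomial_background=base.polynomial_background,
                seed=seed + i,
            )
        )
    total = float(sum(p.amplitude for p in base.puncta))
    return ShapeSequence(
        frames=frames, shape_parameters=s_values, conserved_puncta_total=total
    )


@dataclass
class PopulationConfig:
    """Distributions for a simulated cell population (one cell per scene).

    Cell radii and rim brightnesses are lognormal — rim brightness broadly so
    (sigma_log 0.7), reflecting the strong shape dependence of darkfield edge
    signal; punctum brightnesses are lognormal with moderate spread. Puncta
    counts per cell are Poisson with mean ``density * projected area``.
    """

    radius_median_px: float = 20.0
    radius_sigma_log: float = 0.15
    edge_amp_median: float = 190.0
    edge_amp_sigma_log: float = 0.7
    edge_width_px: float = 1.5
    edge_anisotropy: float = 1.0
    edge_leak: float = 0.05
    punctum_amp_median: float = 250.0
    punctum_amp_sigma_log: float = 0.35
    punctum_radius_px: float = 1.2
    punctum_max_radial_frac: float = 0.75
    punctum_phase_total: float = 0.5
    phase_per_area: float = 2.0  # rad per px^2 of cell area
    background_level: float = 10.0
    noise_sigma: float = 1.0
    canvas_pad_px: int = 16


def make_population(
    n_cells: int,
    puncta_density: float,
    seed: int,
    config: PopulationConfig | None = None,
) -> list[Scene]:
    """Draw a population of single-cell scenes with the stated puncta density.

    ``puncta_density`` is the mean number of puncta per px^2 of projected cell
    area; per-cell counts are Poisson(density * pi * R^2). Fully reproducible
    under ``seed``.
    """
    if n_cells < 1:
        raise ConfigError("n_cells must be >= 1")
    if puncta_density < 0:
        raise ConfigError("puncta_density must be >= 0")
    cfg = config or PopulationConfig()
    rng = np.random.default_rng(seed)
    scenes = []
    for i in range(n_cells):
        radius = cfg.radius_median_px * np.exp(rng.normal(0.0, cfg.radius_sigma_log))
        margin = int(np.ceil(radius + 3 * cfg.edge_width_px)) + cfg.canvas_pad_px
        h = w = 2 * margin + 1
        center = (margin, margin)
        area = np.pi * radius**2
        boundary = CircleBoundary(
            center=center,
            radius=radius,
            amplitude=cfg.edge_amp_median * np.exp(rng.normal(0.0, cfg.edge_amp_sigma_log)),
            edge_width_px=cfg.edge_width_px,
            anisotropy=cfg.edge_anisotropy,
            edge_leak=cfg.edge_leak,
            phase_total=cfg.phase_per_area * area,
        )
        n_puncta = rng.poisson(puncta_density * area)
        puncta = []
        for _ in range(n_puncta):
            rad = radius * cfg.punctum_max_radial_frac * np.sqrt(rng.uniform())
            theta = rng.uniform(0.0, 2.0 * np.pi)
            puncta.append(
                Punctum(
                    center=(center[0] + rad * np.sin(theta), center[1] + rad * np.cos(theta)),
                    amplitude=cfg.punctum_amp_median
                    * np.exp(rng.normal(0.0, cfg.punctum_amp_sigma_log)),
                    radius_px=cfg.punctum_radius_px,
                    phase_total=cfg.punctum_phase_total,
                )
            )
        scenes.append(
            Scene(
                canvas_shape=(h, w),
                boundaries=[boundary],
                puncta=puncta,
                background_level=cfg.background_level,
                noise_sigma=cfg.noise_sigma,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return scenes


# ---------------------------------------------------------------------------
# canonical phantom scenes


def bead_scene(
    canvas: int = 96,
    radius: float = 20.0,
    amplitude: float = 1000.0,
    edge_leak: float = 0.0,
    punctum_amplitude: float = 0.0,
    background_level: float = 0.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> Scene:
    """A 20 um polystyrene-bead phantom (radius 20 px at 0.5 um/px).

    The rim refracts fully directionally (g=1). ``punctum_amplitude > 0`` adds
    a central isotropic imperfection, mimicking the internal defects visible
    in some real beads.
    """
    center = (canvas / 2.0, canvas / 2.0)
    puncta = []
    if punctum_amplitude > 0:
        puncta.append(
            Punctum(center=(center[0] + 2.0, center[1] - 3.0), amplitude=punctum_amplitude)
        )
    return Scene(
        canvas_shape=(canvas, canvas),
        boundaries=[
            CircleBoundary(
                center=center,
                radius=radius,
                amplitude=amplitude,
                anisotropy=1.0,
                edge_leak=edge_leak,
            )
        ],
        puncta=puncta,
        background_level=background_level,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def cell_scene(
    canvas: int = 128,
    radius: float = 22.0,
    edge_amplitude: float = 120.0,
    n_puncta: int = 8,
    punctum_amplitude: float = 1100.0,
    punctum_radius_px: float = 1.2,
    max_radial_frac: float = 0.8,
    edge_leak: float = 0.05,
    background_level: float = 10.0,
    noise_sigma: float = 1.0,
    phase_per_area: float = 2.0,
    seed: int = 0,
) -> Scene:
    """A single-cell phantom with puncta whose peak brightness matches the rim.

    Intensity-matched edges and puncta are the regime where threshold-based
    digital edge detection struggles: removing all edge signal also removes
    puncta. Some puncta sit near the rim (up to ``max_radial_frac`` of the
    radius).
    """
    rng = np.random.default_rng(seed)
    center = (canvas / 2.0, canvas / 2.0)
    area = np.pi * radius**2
    puncta = []
    for k in range(n_puncta):
        rad = radius * max_radial_frac * np.sqrt((k + 0.5) / n_puncta)
        theta = rng.uniform(0.0, 2.0 * np.pi)
        puncta.append(
            Punctum(
                center=(center[0] + rad * np.sin(theta), center[1] + rad * np.cos(theta)),
                amplitude=punctum_amplitude * np.exp(rng.normal(0.0, 0.2)),
                radius_px=punctum_radius_px,
                phase_total=0.5,
            )
        )
    return Scene(
        canvas_shape=(canvas, canvas),
        boundaries=[
            CircleBoundary(
                center=center,
                radius=radius,
                amplitude=edge_amplitude,
                anisotropy=1.0,
                edge_leak=edge_leak,
                phase_total=phase_per_area * area,
            )
        ],
        puncta=puncta,
        background_level=background_level,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def shape_change_base_scene(
    canvas: int = 160,
    radius: float = 30.0,
    edge_amplitude: float = 250.0,
    n_puncta: int = 20,
    punctum_amplitude: float = 600.0,
    background_level: float = 5.0,
    noise_sigma: float = 0.5,
    seed: int = 0,
) -> Scene:
    """Base scene for the flat-to-round time series (puncta-rich cell)."""
    rng = np.random.default_rng(seed)
    center = (canvas / 2.0, canvas / 2.0)
    area = np.pi * radius**2
    puncta = []
    for k in range(n_puncta):
        rad = radius * 0.7 * np.sqrt((k + 0.5) / n_puncta)
        theta = rng.uniform(0.0, 2.0 * np.pi)
        puncta.append(
            Punctum(
                center=(center[0] + rad * np.sin(theta), center[1] + rad * np.cos(theta)),
                amplitude=punctum_amplitude * np.exp(rng.normal(0.0, 0.2)),
                phase_total=0.5,
            )
        )
    return Scene(
        canvas_shape=(canvas, canvas),
        boundaries=[
            CircleBoundary(
                center=center,
                radius=radius,
                amplitude=edge_amplitude,
                anisotropy=1.0,
                edge_leak=0.05,
                phase_total=2.0 * area,
            )
        ],
        puncta=puncta,
        background_level=background_level,
        noise_sigma=noise_sigma,
        seed=seed,
    )
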