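"""Quadrant darkfield reconstruction.

A quadrant darkfield acquisition captures four darkfield images of the same
field of view, each illuminated from one quadrant of the LED annulus (top-left,
top-right, bottom-left, bottom-right). Large refracting structures such as cell
edges bend light directionally (Snell refraction), so their signal appears only
under the illumination quadrant opposing the local surface normal; wavelength-
scale puncta scatter into a broad Mie cone and appear under all four.

The combination exploits this asymmetry. All operations are pixel-wise:

    DF  = TL + TR + BL + BR          (conventional darkfield)
    E   = |TL - BR| + |BL - TR|      (edge image)
    QDF = c * DF - E                 (quadrant darkfield)

where ``c`` is a system-specific scaling factor (typically 0.8-1.0) matching
the darkfield edge intensity to E before subtraction. Directional edge signal
survives in E and cancels in QDF; isotropic puncta signal cancels in E and
survives in QDF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import ConfigError, DataError

QUADRANT_ORDER = ("TL", "TR", "BL", "BR")


@dataclass
class QuadrantStack:
    """Four co-registered darkfield images of one field of view.

    ``tl``/``tr``/``bl``/``br`` are the images captured under top-left,
    top-right, bottom-left and bottom-right quadrant illumination, in raster
    convention (row 0 at the top, column 0 at the left).
    """

    tl: np.ndarray
    tr: np.ndarray
    bl: np.ndarray
    br: np.ndarray
    bit_depth: int = 12
    exposure_ms: float = 220.0
    gain_db: float = 25.0
    validate_nonnegative: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        self.tl = np.asarray(self.tl)
        self.tr = np.asarray(self.tr)
        self.bl = np.asarray(self.bl)
        self.br = np.asarray(self.br)
        shapes = {im.shape for im in self.images}
        if len(shapes) != 1:
            raise DataError(f"quadrant images have mismatched shapes: {sorted(shapes)}")
        if self.validate_nonnegative and any(np.min(im) < 0 for im in self.images):
            raise DataError("quadrant images contain negative pixel values")

    @property
    def images(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        return (self.tl, self.tr, self.bl, self.br)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.tl.shape

    def as_array(self) -> np.ndarray:
        """Stack the four images into a (4, H, W) array in TL, TR, BL, BR order."""
        return np.stack(self.images, axis=0)

    def replace_images(self, images, validate_nonnegative: bool = False) -> "QuadrantStack":
        tl, tr, bl, br = images
        return QuadrantStack(
            tl, tr, bl, br,
            bit_depth=self.bit_depth,
            exposure_ms=self.exposure_ms,
            gain_db=self.gain_db,
            validate_nonnegative=validate_nonnegative,
        )

    def to_tiff(self, path) -> None:
        """Write as a 4-page TIFF, page order TL, TR, BL, BR."""
        tifffile.imwrite(str(path), self.as_array(), photometric='minisblack')

    @classmethod
    def from_tiff(cls, path, **kwargs) -> "QuadrantStack":
        """Read a 4-page TIFF (page order TL, TR, BL, BR)."""
        arr = tifffile.imread(str(path))
        if arr.ndim != 3 or arr.shape[0] != 4:
            raise DataError(f"{path}: expected a 4-page quadrant TIFF, got shape {arr.shape}")
        return cls(arr[0], arr[1], arr[2], arr[3], **kwargs)

    @classmethod
    def from_quadrant_tiffs(cls, tl, tr, bl, br, **kwargs) -> "QuadrantStack":
        """Read four single-page TIFFs (paths with _TL/_TR/_BL/_BR suffixes)."""
        ims = []
        for p in (tl, tr, bl, br):
            if not Path(p).exists():
                raise DataError(f"missing quadrant file: {p}")
            ims.append(tifffile.imread(str(p)))
        return cls(*ims, **kwargs)


@dataclass
class ReconstructionResult:
    """Derived darkfield, edge and QDF images plus the scaling factor used.

    ``qdf`` retains signed values; negatives (noise or imperfect calibration
    where E > c*DF) are preserved for diagnostics unless ``clip_negative``.
    """

    df: np.ndarray
    edge: np.ndarray
    qdf: np.ndarray
    c: float
    clip_negative: bool

    def write(self, out_dir, prefix: str = "") -> dict[str, Path]:
        """Write DF/E/QDF as 32-bit float TIFFs; returns the paths."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, im in (("DF", self.df), ("E", self.edge), ("QDF", self.qdf)):
            p = out_dir / f"{prefix}{name}.tif"
            tifffile.imwrite(str(p), im.astype(np.float32))
            paths[name] = p
        return paths


@dataclass
class CalibrationResult:
    """Least-squares estimate of the scaling factor c on an edge pixel set."""

    c: float
    residual_edge_fraction: float  # sum((c*DF - E)^2) / sum(E^2) over the mask
    n_pixels: int

    def __float__(self) -> float:
        return self.c


def _as_float(stack: QuadrantStack) -> tuple[np.ndarray, ...]:
    # widen to float64 so 4x a 16-bit range cannot overflow
    return tuple(im.astype(np.float64, copy=False) for im in stack.images)


def compute_darkfield(stack: QuadrantStack) -> np.ndarray:
    """Conventional darkfield: pixel-wise sum of the four quadrant images."""
    tl, tr, bl, br = _as_float(stack)
    return tl + tr + bl + br


def compute_edge(stack: QuadrantStack) -> np.ndarray:
    """Edge image E = |TL - BR| + |BL - TR|, pixel-wise.

    E captures direction-dependent signal: diagonally opposed illumination
    pairs see the same isotropic scatterers but opposite edge arcs, so the
    differences cancel puncta and keep edges.
    """
    tl, tr, bl, br = _as_float(stack)
    return np.abs(tl - br) + np.abs(bl - tr)


def compute_qdf(stack: QuadrantStack, c: float, clip_negative: bool = False) -> ReconstructionResult:
    """QDF = c * DF - E, pixel-wise.

    Parameters
    ----------
    c : float
        Scaling factor matching darkfield edge intensity to E; must be > 0.
    clip_negative : bool
        If True, negative QDF values are clipped to zero in the returned
        image. Default keeps signed values for diagnostics.
    """
    c = float(c)
    if not c > 0:
        raise ConfigError(f"scaling factor c must be positive, got {c}")
    df = compute_darkfield(stack)
    edge = compute_edge(stack)
    qdf = c * df - edge
    if clip_negative:
        qdf = np.maximum(qdf, 0.0)
    return ReconstructionResult(df=df, edge=edge, qdf=qdf, c=c, clip_negative=clip_negative)


def calibrate_c(stack: QuadrantStack, edge_mask: np.ndarray) -> CalibrationResult:
    """Least-squares calibration of c on a set of edge pixels.

    Minimises ``sum((c*DF - E)^2)`` over the masked pixels, giving the closed
    form ``c = sum(DF*E) / sum(DF**2)``. The scaling factor is system-specific;
    it is determined empirically so that the scaled darkfield matches the edge
    image on object edges.

    Parameters
    ----------
    edge_mask : bool array
        Pixels considered pure edge signal. See :func:`default_edge_mask` for
        an automatic choice.
    """
    edge_mask = np.asarray(edge_mask, dtype=bool)
    if edge_mask.shape != stack.shape:
        raise DataError("edge_mask shape does not match the quadrant stack")
    n = int(edge_mask.sum())
    if n == 0:
        raise DataError("edge mask is empty; cannot calibrate c")
    df = compute_darkfield(stack)[edge_mask]
    edge = compute_edge(stack)[edge_mask]
    denom = float(np.sum(df * df))
    if denom == 0.0:
        raise DataError("darkfield is zero on every masked pixel; cannot calibrate c")
    c = float(np.sum(df * edge) / denom)
    e_energy = float(np.sum(edge * edge))
    resid = float(np.sum((c * df - edge) ** 2) / e_energy) if e_energy > 0 else 0.0
    return CalibrationResult(c=c, residual_edge_fraction=resid, n_pixels=n)


def default_edge_mask(
    stack: QuadrantStack,
    object_mask: np.ndarray | None = None,
    percentile: float = 95.0,
) -> np.ndarray:
    """Default calibration pixel set: the brightest edge-image pixels.

    Pixels where E exceeds its ``percentile``-th percentile, restricted to
    ``object_mask`` (segmented objects) when given.
    """
    edge = compute_edge(stack)
    if object_mask is not None:
        object_mask = np.asarray(object_mask, dtype=bool)
        if object_mask.shape != edge.shape:
            raise DataError("object_mask shape does not match the quadrant stack")
        vals = edge[object_mask]
        if vals.size == 0:
            raise DataError("object mask is empty")
        thresh = np.percentile(vals, percentile)
        return (edge > thresh) & object_mask
    thresh = np.percentile(edge, percentile)
    return edge > thresh


def resolve_c(stack: QuadrantStack, config_c, edge_mask: np.ndarray | None = None) -> float:
    """Resolve the config's c: numeric value passes through, "auto" calibrates.

    With ``"auto"`` and no ``edge_mask``, the default 95th-percentile edge
    mask over the whole image is used.
    """
    if config_c != "auto":
        return float(config_c)
    if edge_mask is None:
        edge_mask = default_edge_mask(stack)
    return calibrate_c(stack, edge_mask).c
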