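"""Image conditioning applied before reconstruction and quantification.

Three steps, individually toggleable:

1. bit rescaling — raw frames are divided by a power-of-two divisor (default
   16, i.e. 16-bit container down to the camera's native 12 bits) and rounded
   to the nearest integer;
2. empty-reference subtraction — a stack captured at an empty stage position
   is subtracted to remove the stray-light background;
3. masked polynomial background removal — a bivariate polynomial (total degree
   <= 8 by default) is fitted to non-object pixels only and subtracted from
   the whole image, flattening slow illumination gradients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DataError


def rescale_bit_depth(image: np.ndarray, divisor: int = 16) -> np.ndarray:
    """Divide by ``divisor`` and round to the nearest integer.

    Rounding is half-away-from-zero on the nonnegative camera counts
    (x.5 -> x+1), the usual camera-pipeline behaviour, not banker's rounding.
    """
    if divisor < 1:
        raise ConfigError("divisor must be >= 1")
    image = np.asarray(image)
    return np.floor(image / divisor + 0.5).astype(np.int64)


def subtract_reference(image: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Pixel-wise difference in floating point; negatives are preserved.

    Clipping would bias the downstream polynomial background fit, so the
    signed difference is kept.
    """
    image = np.asarray(image, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if image.shape != reference.shape:
        raise DataError(
            f"image shape {image.shape} does not match reference shape {reference.shape}"
        )
    return image - reference


def n_poly_terms(order: int) -> int:
    """Number of bivariate monomials x^i y^j with total degree i + j <= order."""
    return (order + 1) * (order + 2) // 2


def _design_matrix(rows: np.ndarray, cols: np.ndarray, shape, order: int) -> np.ndarray:
    # coordinates normalised to [-1, 1]^2 for conditioning
    h, w = shape
    y = 2.0 * rows / max(h - 1, 1) - 1.0
    x = 2.0 * cols / max(w - 1, 1) - 1.0
    columns = []
    for total in range(order + 1):
        for i in range(total + 1):
            j = total - i
            columns.append((y**i) * (x**j))
    return np.stack(columns, axis=1)


@dataclass
class BackgroundModel:
    """Fitted 2-D polynomial background surface.

    ``coefficients`` are ordered by total degree (constant first), over image
    coordinates normalised to [-1, 1]^2. The fit uses only pixels outside
    ``object_mask``.
    """

    polynomial_order: int
    coefficients: np.ndarray
    image_shape: tuple[int, int]
    residual_rms: float
    n_fit_pixels: int

    def evaluate(self) -> np.ndarray:
        """Evaluate the fitted surface over the full image grid."""
        h, w = self.image_shape
        rows, cols = np.mgrid[0:h, 0:w]
        a = _design_matrix(rows.ravel(), cols.ravel(), self.image_shape, self.polynomial_order)
        return (a @ self.coefficients).reshape(h, w)


def fit_background(
    image: np.ndarray,
    object_mask: np.ndarray | None = None,
    order: int = 8,
    max_fit_pixels: int = 100_000,
    seed: int = 0,
) -> BackgroundModel:
    """Least-squares polynomial fit to background (non-object) pixels.

    Parameters
    ----------
    object_mask : bool array, optional
        True on object pixels, which are excluded from the fit. ``None``
        fits on every pixel.
    order : int
        Total degree of the bivariate polynomial (default 8).
    max_fit_pixels : int
        The fit is heavily over-determined; above this count the background
        pixels are uniformly subsampled (seeded) to bound cost.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise DataError("fit_background expects a 2-D image")
    if object_mask is None:
        bg = np.ones(image.shape, dtype=bool)
    else:
        object_mask = np.asarray(object_mask, dtype=bool)
        if object_mask.shape != image.shape:
            raise DataError("object_mask shape does not match image")
        bg = ~object_mask
    rows, cols = np.nonzero(bg)
    n_terms = n_poly_terms(order)
    if rows.size < n_terms:
        raise DataError(
            f"only {rows.size} background pixels available; "
            f"an order-{order} fit needs at least {n_terms}"
        )
    if rows.size > max_fit_pixels:
        rng = np.random.default_rng(seed)
        keep = rng.choice(rows.size, size=max_fit_pixels, replace=False)
        keep.sort()
        rows, cols = rows[keep], cols[keep]
    a = _design_matrix(rows, cols, image.shape, order)
    b = image[rows, cols]
    coeffs, *_ = np.linalg.lstsq(a, b, rcond=None)
    resid = a @ coeffs - b
    rms = float(np.sqrt(np.mean(resid**2)))
    return BackgroundModel(
        polynomial_order=order,
        coefficients=coeffs,
        image_shape=image.shape,
        residual_rms=rms,
        n_fit_pixels=rows.size,
    )


def remove_background(image: np.ndarray, model: BackgroundModel) -> np.ndarray:
    """Subtract the fitted surface from every pixel (objects included)."""
    image = np.asarray(image, dtype=np.float64)
    if image.shape != model.image_shape:
        raise DataError(
            f"image shape {image.shape} does not match fitted shape {model.image_shape}"
        )
    return image - model.evaluate()


def correct_background(
    image: np.ndarray,
    object_mask: np.ndarray | None = None,
    order: int = 8,
    seed: int = 0,
) -> np.ndarray:
    """Convenience: fit on background pixels and subtract in one call."""
    return remove_background(image, fit_background(image, object_mask, order=order, seed=seed))
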