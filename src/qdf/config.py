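"""Optical system configuration.

Holds the acquisition parameters the reconstruction and quantification steps
need: illumination wavelength, pixel size, objective NA, the darkfield
illumination annulus (expressed as multiples of the objective NA), the
edge-matching scaling factor ``c`` and the camera bit depth, plus the specific
refractive increment used to convert integrated phase to dry mass.
"""

from __future__ import annotations

from typing import Literal, Union

from pydantic import BaseModel, field_validator

from .errors import ConfigError


class OpticalConfig(BaseModel):
    """Acquisition geometry and calibration constants.

    Parameters
    ----------
    wavelength_nm : float
        Illumination wavelength in nanometres.
    pixel_size_um : float
        Size of one camera pixel at the sample plane, in micrometres.
    objective_na : float
        Numerical aperture of the imaging objective.
    illumination_na_range : (float, float)
        Inner and outer radius of the darkfield LED annulus, in units of the
        objective NA. Darkfield requires both > 1 so unscattered light misses
        the objective.
    c : float or "auto"
        Scaling factor matching darkfield edge intensity to the edge image
        before subtraction. ``"auto"`` requests least-squares calibration on a
        designated field of view; a numeric value bypasses calibration.
    bit_depth : int
        Camera (or rescaled) bit depth; pixel values live in
        ``[0, 2**bit_depth - 1]``.
    refractive_increment_m3_per_kg : float
        Specific refractive increment relating refractive-index excess to dry
        mass concentration.
    """

    wavelength_nm: float = 525.0
    pixel_size_um: float = 0.5
    objective_na: float = 0.25
    illumination_na_range: tuple[float, float] = (1.05, 1.33)
    c: Union[float, Literal["auto"]] = "auto"
    bit_depth: int = 12
    refractive_increment_m3_per_kg: float = 1.8e-4

    @field_validator("wavelength_nm", "pixel_size_um", "objective_na")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ConfigError("optical parameters must be positive")
        return v

    @field_validator("bit_depth")
    @classmethod
    def _bit_depth_positive(cls, v: int) -> int:
        if v < 1:
            raise ConfigError("bit_depth must be >= 1")
        return v

    @field_validator("c")
    @classmethod
    def _c_range(cls, v):
        if v != "auto" and not (0 < float(v) <= 2):
            raise ConfigError("scaling factor c must lie in (0, 2] or be 'auto'")
        return v

    @field_validator("illumination_na_range")
    @classmethod
    def _annulus(cls, v):
        lo, hi = v
        if not (0 < lo < hi):
            raise ConfigError("illumination_na_range must be increasing and positive")
        return v

    @property
    def max_count(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um**2
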