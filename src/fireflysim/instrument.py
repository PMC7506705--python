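"""Forward model of the FIREFLY imaging spectrometer.

FIREFLY is a pushbroom imaging spectrometer with 2160 spectral bands over
670-780 nm (0.0512 nm sampling) and 266 cross-track spatial pixels, read out
on a 16-bit TE-cooled sCMOS detector.  This module encodes its characterized
properties as a configurable forward model:

* a linear band-index -> wavelength map,
* a spatial/spectral polynomial surface for the full width at half maximum
  (FWHM) of the spectral response, clipped to the observed 0.12-0.2 nm range,
* a linear radiometric response (DN per W m-2 sr-1 nm-1) with a linear
  uncertainty model,
* a power-law shot-noise model sigma = a * R**b in radiance units,
* a dark-current model with a symmetric spectral "smile" (100 DN at the
  center of the spectral axis, 105 DN at the ends, 115 DN at the detector
  corners) and Gaussian frame-to-frame variability.

All band and spatial-pixel indices are 1-based, matching the instrument's
own numbering.  Radiances are in mW m-2 sr-1 nm-1 throughout the package;
the response model (quoted per W) is converted internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple, Union

import numpy as np

from .exceptions import DomainError

__all__ = [
    "BandGrid",
    "FwhmSurface",
    "ResponseModel",
    "NoiseModel",
    "DarkModel",
    "InstrumentModel",
    "FWHM_TO_SIGMA",
]

#: Conversion factor between a Gaussian FWHM and its standard deviation,
#: 2*sqrt(2*ln 2).
FWHM_TO_SIGMA = 2.354820045030949

ArrayLike = Union[float, int, np.ndarray]


@dataclass(frozen=True)
class BandGrid:
    """Linear band-index to wavelength map (1-based band indices)."""

    n_bands: int = 2160
    n_pixels: int = 266
    slope: float = 5.12e-2       # nm per band
    intercept: float = 670.12    # nm

    def __post_init__(self) -> None:
        if self.n_bands < 1 or self.n_pixels < 1:
            raise DomainError("n_bands and n_pixels must be positive")
        if self.slope <= 0:
            raise DomainError("band-map slope must be positive (wavelength "
                              "strictly increasing with band index)")

    @property
    def wavelengths(self) -> np.ndarray:
        """Band-center wavelengths for all bands, in nm."""
        return self.intercept + self.slope * np.arange(1, self.n_bands + 1)

    @property
    def wavelength_range(self) -> Tuple[float, float]:
        return (self.intercept + self.slope,
                self.intercept + self.slope * self.n_bands)

    def band_wavelength(self, band_index: ArrayLike) -> ArrayLike:
        """Wavelength in nm of 1-based ``band_index``."""
        b = np.asarray(band_index)
        if np.any(b < 1) or np.any(b > self.n_bands):
            raise DomainError(
                f"band index must be in [1, {self.n_bands}], got {band_index}")
        w = self.intercept + self.slope * b
        return float(w) if np.isscalar(band_index) else w

    def nearest_band(self, wavelength: ArrayLike) -> ArrayLike:
        """1-based band index whose center is closest to ``wavelength``."""
        b = np.rint((np.asarray(wavelength) - self.intercept) / self.slope)
        b = np.clip(b, 1, self.n_bands).astype(int)
        return int(b) if np.isscalar(wavelength) else b

    def check_pixel(self, pixel: ArrayLike) -> None:
        p = np.asarray(pixel)
        if np.any(p < 1) or np.any(p > self.n_pixels):
            raise DomainError(
                f"spatial pixel must be in [1, {self.n_pixels}], got {pixel}")


@dataclass(frozen=True)
class FwhmSurface:
    """Polynomial FWHM surface over (spatial pixel D, wavelength W).

    The characterized fit, as printed, contains two linear D terms and is
    degenerate; the default reading treats the first term as quadratic
    (c_d2 * D**2).  The literal reading (both terms linear) is selectable
    with ``form="literal"``.  Either way the evaluated value is clipped to
    the observed [clip_lo, clip_hi] range.
    """

    c_d2: float = 2e-6
    c_d: float = -7e-4
    c_w: float = -7e-4
    c_0: float = 0.76405
    clip_lo: float = 0.12        # nm
    clip_hi: float = 0.2         # nm
    residual_sd: float = 7.32e-3  # nm
    form: str = "quadratic"      # "quadratic" | "literal"

    def __post_init__(self) -> None:
        if not self.clip_lo < self.clip_hi:
            raise DomainError("clip_lo must be < clip_hi")
        if self.form not in ("quadratic", "literal"):
            raise DomainError(f"unknown FWHM surface form {self.form!r}")

    def evaluate(self, pixel: ArrayLike, wavelength: ArrayLike,
                 clip: bool = True) -> ArrayLike:
        d = np.asarray(pixel, dtype=float)
        w = np.asarray(wavelength, dtype=float)
        if self.form == "quadratic":
            raw = self.c_d2 * d**2 + self.c_d * d + self.c_w * w + self.c_0
        else:
            raw = (self.c_d2 + self.c_d) * d + self.c_w * w + self.c_0
        out = np.clip(raw, self.clip_lo, self.clip_hi) if clip else raw
        scalar = np.isscalar(pixel) and np.isscalar(wavelength)
        return float(out) if scalar else out


@dataclass(frozen=True)
class ResponseModel:
    """Linear radiometric response and response uncertainty vs wavelength.

    ``slope``/``intercept`` give the band response in DN per W m-2 sr-1 nm-1;
    ``uncertainty_slope``/``uncertainty_intercept`` give the response-fit
    uncertainty in DN as a linear function of wavelength.
    """

    slope: float = -185.67
    intercept: float = 173943.0
    uncertainty_slope: float = 2e-4
    uncertainty_intercept: float = -0.1005
    linearity_tolerance: float = 0.003
    dn_max: int = 65535

    def response_at(self, wavelength: ArrayLike) -> ArrayLike:
        """Responsivity in DN per (W m-2 sr-1 nm-1)."""
        _check_wavelength(wavelength)
        r = self.slope * np.asarray(wavelength, dtype=float) + self.intercept
        return float(r) if np.isscalar(wavelength) else r

    def response_per_mw(self, wavelength: ArrayLike) -> ArrayLike:
        """Responsivity in DN per (mW m-2 sr-1 nm-1)."""
        return self.response_at(wavelength) / 1000.0

    def uncertainty_at(self, wavelength: ArrayLike) -> ArrayLike:
        """Response-fit uncertainty in DN."""
        _check_wavelength(wavelength)
        u = (self.uncertainty_slope * np.asarray(wavelength, dtype=float)
             + self.uncertainty_intercept)
        return float(u) if np.isscalar(wavelength) else u


def _check_wavelength(wavelength: ArrayLike,
                      lo: float = 665.0, hi: float = 785.0) -> None:
    w = np.asarray(wavelength, dtype=float)
    if np.any(w < lo) or np.any(w > hi):
        raise DomainError(
            f"wavelength must be within the instrument domain [{lo}, {hi}] nm")


@dataclass(frozen=True)
class NoiseModel:
    """Shot-noise power law sigma(R) = amplitude * R**exponent.

    ``units_mode`` selects the amplitude convention:

    * ``"physical-anchored"`` (default): the amplitude is rescaled so the
      model reproduces the characterized anchor pair (R=16.88 -> sigma=0.4,
      both in mW m-2 sr-1 nm-1) while keeping the characterized exponent.
    * ``"printed"``: the amplitude is the characterized fit value 365.99,
      which is internally inconsistent with the anchor pair and kept only
      for traceability.
    """

    exponent: float = 0.5295
    units_mode: str = "physical-anchored"
    amplitude: Optional[float] = None   # derived from units_mode when None

    #: anchor pair reproduced in physical-anchored mode
    anchor_radiance: float = 16.88
    anchor_sigma: float = 0.4
    printed_amplitude: float = 365.99

    def __post_init__(self) -> None:
        if not 0.0 < self.exponent < 1.0:
            raise DomainError("noise exponent must be in (0, 1)")
        if self.units_mode not in ("physical-anchored", "printed"):
            raise DomainError(f"unknown units_mode {self.units_mode!r}")
        if self.amplitude is None:
            if self.units_mode == "physical-anchored":
                amp = self.anchor_sigma / self.anchor_radiance ** self.exponent
            else:
                amp = self.printed_amplitude
            object.__setattr__(self, "amplitude", amp)

    def sigma(self, radiance: ArrayLike) -> ArrayLike:
        """Expected standard deviation at ``radiance`` (same units)."""
        r = np.asarray(radiance, dtype=float)
        if np.any(r < 0):
            raise DomainError("radiance must be non-negative")
        s = self.amplitude * r ** self.exponent
        return float(s) if np.isscalar(radiance) else s


@dataclass(frozen=True)
class DarkModel:
    """Dark current in DN: symmetric spectral smile, flat spatially.

    The profile is a parabola over the spectral axis through ``center_dn``
    at the central band and ``edge_dn`` at bands 1 and n_bands; the four
    detector corners (pixel in {1, n_pixels} and band in {1, n_bands})
    override to ``corner_dn``.  Frame-to-frame variability is Gaussian with
    standard deviation ``sd_dn``.
    """

    center_dn: float = 100.0
    edge_dn: float = 105.0
    corner_dn: float = 115.0
    sd_dn: float = 2.0

    def __post_init__(self) -> None:
        if not (self.corner_dn >= self.edge_dn >= self.center_dn):
            raise DomainError("require corner_dn >= edge_dn >= center_dn")
        if self.sd_dn < 0:
            raise DomainError("sd_dn must be >= 0")

    def level(self, pixel: ArrayLike, band_index: ArrayLike,
              grid: BandGrid) -> ArrayLike:
        """Mean dark DN for (pixel, band); broadcasts over inputs."""
        grid.check_pixel(pixel)
        b = np.asarray(band_index, dtype=float)
        if np.any(b < 1) or np.any(b > grid.n_bands):
            raise DomainError(
                f"band index must be in [1, {grid.n_bands}], got {band_index}")
        center = 0.5 * (1 + grid.n_bands)
        half_span = center - 1.0
        smile = (self.center_dn
                 + (self.edge_dn - self.center_dn)
                 * ((b - center) / half_span) ** 2)
        p = np.asarray(pixel)
        corner = ((np.isin(p, (1, grid.n_pixels)))
                  & (np.isin(np.asarray(band_index), (1, grid.n_bands))))
        out = np.where(corner, self.corner_dn, smile)
        scalar = np.isscalar(pixel) and np.isscalar(band_index)
        return float(out) if scalar else out


@dataclass(frozen=True)
class InstrumentModel:
    """The complete FIREFLY forward model.

    Composes the band grid, FWHM surface, radiometric response, shot-noise
    and dark-current models, and provides radiance <-> DN conversion.
    """

    grid: BandGrid = field(default_factory=BandGrid)
    fwhm: FwhmSurface = field(default_factory=FwhmSurface)
    response: ResponseModel = field(default_factory=ResponseModel)
    noise: NoiseModel = field(default_factory=NoiseModel)
    dark: DarkModel = field(default_factory=DarkModel)

    # ------------------------------------------------------------------ #
    # thin pass-throughs, kept for a flat operational surface
    # ------------------------------------------------------------------ #
    def band_wavelength(self, band_index: ArrayLike) -> ArrayLike:
        return self.grid.band_wavelength(band_index)

    def fwhm_at(self, spatial_pixel: ArrayLike, wavelength: ArrayLike,
                clip: bool = True) -> ArrayLike:
        self.grid.check_pixel(spatial_pixel)
        _check_wavelength(wavelength, lo=self.grid.intercept - 0.2, hi=781.0)
        return self.fwhm.evaluate(spatial_pixel, wavelength, clip=clip)

    def response_at(self, wavelength: ArrayLike
                    ) -> Tuple[ArrayLike, ArrayLike]:
        """(responsivity in DN per W m-2 sr-1 nm-1, uncertainty in DN)."""
        return (self.response.response_at(wavelength),
                self.response.uncertainty_at(wavelength))

    def noise_sigma(self, radiance: ArrayLike) -> ArrayLike:
        return self.noise.sigma(radiance)

    def dark_level(self, spatial_pixel: ArrayLike,
                   band_index: ArrayLike) -> ArrayLike:
        return self.dark.level(spatial_pixel, band_index, self.grid)

    # ------------------------------------------------------------------ #
    # DN simulation
    # ------------------------------------------------------------------ #
    def dark_frames(self, n_frames: int, seed: Optional[int] = None,
                    pixels: Optional[np.ndarray] = None,
                    bands: Optional[np.ndarray] = None,
                    quantize: bool = True) -> np.ndarray:
        """Simulate ``n_frames`` dark frames of shape (frames, pixels, bands).

        Each detector element draws from N(dark mean, sd_dn); DN are rounded
        to integers unless ``quantize=False``.
        """
        pixels = np.arange(1, self.grid.n_pixels + 1) if pixels is None \
            else np.asarray(pixels)
        bands = np.arange(1, self.grid.n_bands + 1) if bands is None \
            else np.asarray(bands)
        mean = self.dark_level(pixels[:, None], bands[None, :])
        rng = np.random.default_rng(seed)
        frames = rng.normal(mean, self.dark.sd_dn,
                            size=(n_frames,) + mean.shape)
        return np.rint(frames) if quantize else frames

    def radiance_to_dn(self, radiance: np.ndarray, spatial_pixel: int,
                       seed: Optional[int] = None, add_noise: bool = True,
                       band_indices: Optional[np.ndarray] = None,
                       return_saturation: bool = False):
        """Convert a per-band radiance spectrum (mW m-2 sr-1 nm-1) to DN.

        DN = round(clip(response*R + dark + N(0, sigma_DN), 0, dn_max)) where
        sigma_DN is the shot-noise sigma converted to DN through the
        responsivity.  Saturated elements are flagged (via
        ``return_saturation=True``), never raised.
        """
        radiance = np.asarray(radiance, dtype=float)
        if np.any(radiance < 0):
            raise DomainError("radiance must be non-negative")
        if band_indices is None:
            if radiance.shape[-1] != self.grid.n_bands:
                raise DomainError(
                    f"expected {self.grid.n_bands} bands, got "
                    f"{radiance.shape[-1]}; pass band_indices for subsets")
            band_indices = np.arange(1, self.grid.n_bands + 1)
        wavelengths = self.band_wavelength(np.asarray(band_indices))
        resp = self.response.response_per_mw(wavelengths)
        dark = self.dark_level(spatial_pixel, np.asarray(band_indices))
        signal = resp * radiance + dark
        if add_noise:
            sigma_dn = self.noise.sigma(radiance) * resp
            rng = np.random.default_rng(seed)
            signal = signal + rng.normal(0.0, 1.0, radiance.shape) * sigma_dn
        dn_max = self.response.dn_max
        saturated = signal > dn_max
        dn = np.rint(np.clip(signal, 0, dn_max)).astype(np.uint16)
        if return_saturation:
            return dn, saturated
        return dn

    def dn_to_radiance(self, dn: np.ndarray, spatial_pixel: int,
                       band_indices: Optional[np.ndarray] = None
                       ) -> np.ndarray:
        """Invert :meth:`radiance_to_dn`: subtract dark, divide by response."""
        dn = np.asarray(dn, dtype=float)
        if band_indices is None:
            band_indices = np.arange(1, self.grid.n_bands + 1)
        wavelengths = self.band_wavelength(np.asarray(band_indices))
        resp = self.response.response_per_mw(wavelengths)
        dark = self.dark_level(spatial_pixel, np.asarray(band_indices))
        return (dn - dark) / resp

    # ------------------------------------------------------------------ #
    # construction from configuration mappings
    # ------------------------------------------------------------------ #
    @classmethod
    def from_mapping(cls, mapping: dict) -> "InstrumentModel":
        """Build an instrument from a nested dict (see data/instrument_defaults.yaml)."""
        from .config import build_instrument
        return build_instrument(mapping)

    def with_noise_off(self) -> "InstrumentModel":
        """Copy of this instrument whose dark has zero variability (for
        deterministic DN simulation use ``add_noise=False`` instead)."""
        return replace(self, dark=replace(self.dark, sd_dn=0.0))
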