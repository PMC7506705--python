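"""Direct and indirect SIF retrieval, NDVI masking, emission-curve fitting.

Direct retrieval subtracts a known (or estimated) non-SIF radiance baseline
band-by-band; the residual is SIF.  Indirect (Fraunhofer-line-discrimination
style) retrieval uses the SIF-free proportional depth k of an absorption
feature: with observed valley v and peak p radiances,

    F = (v - k * p) / (1 - k)

which recovers an additive signal F exactly, is insensitive to any influence
that scales both bands equally, and amplifies influences that act on the
bands unequally by 1/(1 - k).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .exceptions import DegenerateFeatureError, DomainError
from .sif import SifParameters, default_sif_params, sif_value

__all__ = ["RetrievalResult", "direct_retrieve", "indirect_retrieve",
           "ndvi", "fit_sif_params"]

#: NDVI window bounds, nm (red, NIR); configurable via the ndvi() arguments
NDVI_RED = (670.0, 680.0)
NDVI_NIR = (770.0, 780.0)


@dataclass(frozen=True)
class RetrievalResult:
    """Per-band or per-feature SIF estimates plus a fitted emission curve."""

    wavelengths: np.ndarray
    estimates: np.ndarray
    method: str                      # "direct" | "indirect"
    params: Optional[SifParameters] = None
    ssr: float = np.nan

    def __post_init__(self) -> None:
        if self.method not in ("direct", "indirect"):
            raise DomainError(f"unknown method {self.method!r}")
        if not np.all(np.isfinite(self.estimates)):
            raise DomainError("estimates must be finite")
        if np.isfinite(self.ssr) and self.ssr < 0:
            raise DomainError("ssr must be >= 0")

    def fitted_curve(self, wavelengths: np.ndarray) -> np.ndarray:
        if self.params is None:
            raise DomainError("no fitted parameters on this result")
        return sif_value(np.asarray(wavelengths, dtype=float), self.params)

    def summary(self) -> str:
        lines = [f"SIF retrieval ({self.method}): "
                 f"{len(self.estimates)} estimates"]
        if self.params is not None:
            p = self.params
            lines.append(
                f"  fitted apex_740 = {p.apex_740:.4f} mW m-2 sr-1 nm-1, "
                f"scale_psi = {p.scale_psi:.4f}, "
                f"scale_psii = {p.scale_psii:.4f}")
            lines.append(f"  ssr = {self.ssr:.6g} (mW m-2 sr-1 nm-1)^2")
        return "\n".join(lines)


def direct_retrieve(observed: np.ndarray,
                    nonsif_baseline: np.ndarray) -> np.ndarray:
    """Per-band SIF = observed - baseline."""
    observed = np.asarray(observed, dtype=float)
    baseline = np.asarray(nonsif_baseline, dtype=float)
    if observed.shape != baseline.shape:
        raise DomainError(
            f"shape mismatch: observed {observed.shape} vs baseline "
            f"{baseline.shape}")
    return observed - baseline


def indirect_retrieve(valley_obs, peak_obs, k):
    """SIF at the valley wavelength: F = (v - k*p)/(1 - k)."""
    k = np.asarray(k, dtype=float)
    if np.any(k >= 1.0) or np.any(k <= 0.0):
        raise DegenerateFeatureError(
            "proportional depth k must be in (0, 1)")
    v = np.asarray(valley_obs, dtype=float)
    p = np.asarray(peak_obs, dtype=float)
    out = (v - k * p) / (1.0 - k)
    scalar = all(np.isscalar(x) for x in (valley_obs, peak_obs))
    return float(out) if scalar and out.ndim == 0 else out


def ndvi(spectrum: np.ndarray, wavelengths: np.ndarray,
         red_window: Tuple[float, float] = NDVI_RED,
         nir_window: Tuple[float, float] = NDVI_NIR) -> float:
    """(NIR - red)/(NIR + red) from band-window mean radiances.

    Returns NaN (undefined) when the denominator is zero.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)
    if spectrum.shape != wavelengths.shape:
        raise DomainError("spectrum and wavelengths must align")
    red_sel = (wavelengths >= red_window[0]) & (wavelengths <= red_window[1])
    nir_sel = (wavelengths >= nir_window[0]) & (wavelengths <= nir_window[1])
    if not red_sel.any() or not nir_sel.any():
        raise DomainError("spectrum does not cover the NDVI windows")
    red = spectrum[red_sel].mean()
    nir = spectrum[nir_sel].mean()
    denom = nir + red
    if denom == 0:
        return float("nan")
    return float((nir - red) / denom)


def fit_sif_params(estimates: Sequence[Tuple[float, float, float]],
                   base_params: Optional[SifParameters] = None,
                   n_starts: int = 5, seed: Optional[int] = 0,
                   method: str = "indirect") -> RetrievalResult:
    """Least-squares fit of the SIF emission curve to per-feature estimates.

    ``estimates`` is a sequence of (wavelength nm, SIF estimate, weight);
    weights are typically 1/sigma^2 from the noise model (pass 1.0 for an
    unweighted fit).  Free parameters are (apex_740, scale_psi, scale_psii)
    with the shape constants held at ``base_params`` (default calibration).
    The two scale factors enter only through their ratio (the curve is
    renormalized at 740 nm), so a bounded multistart solver is used and the
    best of ``n_starts`` seeded starts is kept.
    """
    est = np.asarray([(w, s) for w, s, _ in estimates], dtype=float)
    weights = np.asarray([wt for _, _, wt in estimates], dtype=float)
    if len(est) < 3:
        raise DomainError("need >= 3 estimates to fit 3 parameters")
    from .features import classify_regions
    region_sets = {frozenset(classify_regions(w)) for w in est[:, 0]}
    if len(region_sets) < 2:
        raise DomainError(
            "estimates must span >= 2 spectral regions for a stable fit")
    if np.any(weights < 0):
        raise DomainError("weights must be >= 0")
    base = base_params or default_sif_params()
    wl, target = est[:, 0], est[:, 1]
    sqrt_w = np.sqrt(weights)

    def model(theta):
        apex, s_psi, s_psii = theta
        p = replace(base, apex_740=apex, scale_psi=s_psi, scale_psii=s_psii)
        return sif_value(wl, p)

    def resid(theta):
        return sqrt_w * (model(theta) - target)

    apex0 = float(np.clip(np.max(target, initial=0.0), 0.0, None))
    starts = [np.array([apex0, base.scale_psi, base.scale_psii])]
    rng = np.random.default_rng(seed)
    for _ in range(max(0, n_starts - 1)):
        starts.append(np.array([apex0 * rng.uniform(0.3, 2.0) + 1e-3,
                                rng.uniform(0.05, 1.0),
                                rng.uniform(0.05, 1.0)]))
    best = None
    for x0 in starts:
        sol = least_squares(resid, x0, bounds=([0, 0, 0], [np.inf, 1, 1]))
        if best is None or sol.cost < best.cost:
            best = sol
    apex, s_psi, s_psii = best.x
    fitted = replace(base, apex_740=float(apex),
                     scale_psi=float(np.clip(s_psi, 0, 1)),
                     scale_psii=float(np.clip(s_psii, 0, 1)))
    ssr = float(np.sum((model(best.x) - target) ** 2))
    return RetrievalResult(wavelengths=wl, estimates=target, method=method,
                           params=fitted, ssr=ssr)
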