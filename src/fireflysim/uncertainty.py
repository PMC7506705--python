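"""Influence application, error propagation, aggregation and CV residuals.

The error behaviour of the two retrieval archetypes under additive
influences follows directly from their algebra.  With the indirect form
F = (v - k p)/(1 - k):

* a uniform influence u on both bands changes F by exactly u (and a direct
  retrieval by exactly u per band);
* an influence only on the valley changes F by u_v/(1 - k) — amplified,
  growing with k; only on the peak, by -k u_p/(1 - k);
* a sloped influence m*(lambda - pivot) pivoted at the valley gives an
  error -k m d/(1 - k) where d is the signed valley-to-peak distance
  (positive when the peak is redward), hence negative when the slope raises
  the peak relative to the valley;
* independent Gaussian band noise (sigma_v, sigma_p) propagates to a
  Gaussian indirect error with SD sqrt(sigma_v^2 + k^2 sigma_p^2)/(1 - k).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DomainError
from .instrument import InstrumentModel, NoiseModel
from .retrieval import fit_sif_params, indirect_retrieve, RetrievalResult
from .sif import SifParameters, sif_value

__all__ = ["Influence", "apply_influence", "indirect_error_closed_form",
           "indirect_error_sd", "monte_carlo_ci", "aggregate_and_fit",
           "paired_aggregation_experiment", "cv_residual"]


@dataclass(frozen=True)
class Influence:
    """A confounding influence: uniform, sloped, or random.

    Exactly one kind is active.  ``u`` is the additive radiance of a
    uniform influence; ``m``/``pivot_nm`` define a sloped influence
    m*(lambda - pivot); a random influence draws per-band Gaussian noise
    with fixed ``sigma`` or radiance-dependent sigma from ``noise_model``.
    """

    kind: str                      # "uniform" | "slope" | "random"
    u: float = 0.0
    m: float = 0.0                 # radiance per nm
    pivot_nm: float = 670.0
    sigma: Optional[float] = None
    noise_model: Optional[NoiseModel] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "slope", "random"):
            raise DomainError(f"unknown influence kind {self.kind!r}")
        if self.kind == "random" and self.sigma is None \
                and self.noise_model is None:
            raise DomainError("random influence needs sigma or noise_model")


def apply_influence(spectrum: np.ndarray, wavelengths: np.ndarray,
                    influence: Influence,
                    rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Return the perturbed spectrum (the input is never modified)."""
    spectrum = np.asarray(spectrum, dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)
    if spectrum.shape[-1] != wavelengths.shape[-1]:
        raise DomainError("spectrum and wavelengths must align")
    if influence.kind == "uniform":
        return spectrum + influence.u
    if influence.kind == "slope":
        return spectrum + influence.m * (wavelengths - influence.pivot_nm)
    rng = rng or np.random.default_rng(influence.seed)
    if influence.noise_model is not None:
        sigma = influence.noise_model.sigma(np.clip(spectrum, 0, None))
    else:
        sigma = influence.sigma
    return spectrum + rng.normal(0.0, 1.0, spectrum.shape) * sigma


def indirect_error_closed_form(m: float, delta_signed: float,
                               k: float) -> float:
    """Indirect-retrieval error from a sloped influence pivoted at the
    valley: error = -k * m * delta_signed / (1 - k).

    ``delta_signed`` > 0 when the peak lies redward of the valley; the sign
    convention makes the error negative whenever the slope raises the peak
    relative to the valley.
    """
    if not 0.0 < k < 1.0:
        raise DomainError("k must be in (0, 1)")
    return -k * m * delta_signed / (1.0 - k)


def indirect_error_sd(sigma_v: float, sigma_p: float, k: float) -> float:
    """Closed-form SD of the indirect error under independent Gaussian band
    noise: sqrt(sigma_v^2 + k^2 sigma_p^2) / (1 - k)."""
    if not 0.0 < k < 1.0:
        raise DomainError("k must be in (0, 1)")
    return float(np.sqrt(sigma_v ** 2 + (k * sigma_p) ** 2) / (1.0 - k))


def monte_carlo_ci(valley_radiance: float, peak_radiance: float, k: float,
                   noise_model: Optional[NoiseModel],
                   n_max: int, reps: int = 1,
                   seed: Optional[int] = 0) -> pd.DataFrame:
    """Running-mean 95% CI half-width vs cumulative sample count.

    Draws noisy (valley, peak) pairs around the supplied radiances,
    retrieves SIF per draw in direct mode (valley residual) and indirect
    mode (FLD), and reports the half-width 1.96 * s_n / sqrt(n) of the
    95% confidence interval on the running mean, averaged over ``reps``
    independent repetitions.  A ``None`` noise model means zero noise.
    """
    if n_max < 1:
        raise DomainError("n_max must be >= 1")
    rng = np.random.default_rng(seed)
    if noise_model is None:
        sig_v = sig_p = 0.0
    else:
        sig_v = noise_model.sigma(valley_radiance)
        sig_p = noise_model.sigma(peak_radiance)
    n = np.arange(1, n_max + 1)
    half_d = np.zeros(n_max)
    half_i = np.zeros(n_max)
    if sig_v == 0.0 and sig_p == 0.0:
        return pd.DataFrame({"n": n, "ci_direct": half_d,
                             "ci_indirect": half_i})
    for _ in range(reps):
        v = valley_radiance + rng.normal(0.0, sig_v, n_max)
        p = peak_radiance + rng.normal(0.0, sig_p, n_max)
        direct = v - valley_radiance
        indirect = indirect_retrieve(v, p, k)
        for draws, out in ((direct, half_d), (indirect, half_i)):
            cum = np.cumsum(draws)
            cum2 = np.cumsum(draws ** 2)
            mean = cum / n
            var = np.maximum(cum2 / n - mean ** 2, 0.0)
            sd = np.sqrt(var * n / np.maximum(n - 1, 1))
            out += 1.96 * sd / np.sqrt(n)
    return pd.DataFrame({"n": n, "ci_direct": half_d / reps,
                         "ci_indirect": half_i / reps})


# --------------------------------------------------------------------- #
# spatial aggregation
# --------------------------------------------------------------------- #

def _vegetation_pixels(scene, ndvi_threshold: float) -> np.ndarray:
    from .retrieval import ndvi as _ndvi
    keep = []
    for i, px in enumerate(scene.pixels):
        if _ndvi(scene.radiance[i], scene.wavelengths) > ndvi_threshold:
            keep.append(i)
    return np.asarray(keep, dtype=int)


def aggregate_and_fit(scene, factor: int, method: str = "indirect",
                      seed: Optional[int] = 0,
                      features: Optional[Sequence] = None,
                      instrument: Optional[InstrumentModel] = None,
                      ndvi_threshold: float = 0.0,
                      noise_model: Optional[NoiseModel] = None
                      ) -> RetrievalResult:
    """Retrieve per-feature SIF on factor^2 vegetation pixels, average the
    estimates, and fit the emission curve.

    The scene's noise-free radiance is the baseline; measurement noise is
    drawn here (per ``seed``) from ``noise_model`` (default: the instrument
    shot-noise model), so repeated calls with different seeds emulate
    repeated acquisitions.  SIF-free pixels are excluded by an NDVI
    threshold before aggregation.
    """
    from .features import find_features
    instrument = instrument or InstrumentModel()
    noise_model = noise_model or instrument.noise
    if factor < 1:
        raise DomainError("factor must be >= 1")
    veg = _vegetation_pixels(scene, ndvi_threshold)
    n_need = factor ** 2
    if len(veg) < n_need:
        raise DomainError(
            f"need {n_need} vegetation pixels for factor {factor}, "
            f"scene has {len(veg)}")
    veg = veg[:n_need]

    ref_row = veg[0]
    baseline_sif = scene.truth.iloc[ref_row]
    # SIF-free baseline at the reference pixel: radiance minus true SIF
    sif_p = None
    if baseline_sif["has_sif"]:
        from .sif import default_sif_params
        cfg_sif = default_sif_params()
        sif_p = SifParameters(**{**cfg_sif.to_dict(),
                                 "apex_740": baseline_sif["sif_apex_740"]})
    truth_curve = 0.0 if sif_p is None \
        else sif_value(scene.wavelengths, sif_p)
    baseline = scene.radiance[ref_row] - truth_curve
    if features is None:
        features = [f for f in find_features(baseline, instrument=instrument)
                    if f.k < 0.95]
    rng = np.random.default_rng(seed)

    rows = []
    for f in features:
        iv, ip = f.valley_band - 1, f.peak_band - 1
        wl_v = scene.wavelengths[iv]
        ests = []
        for row in veg:
            v = scene.radiance[row, iv]
            p = scene.radiance[row, ip]
            v_n = v + rng.normal(0.0, noise_model.sigma(v))
            p_n = p + rng.normal(0.0, noise_model.sigma(p))
            if method == "indirect":
                ests.append(indirect_retrieve(v_n, p_n, f.k))
            else:
                ests.append(v_n - baseline[iv])
        est = float(np.mean(ests))
        if method == "indirect":
            sd1 = indirect_error_sd(noise_model.sigma(scene.radiance[ref_row, iv]),
                                    noise_model.sigma(scene.radiance[ref_row, ip]),
                                    f.k)
        else:
            sd1 = noise_model.sigma(scene.radiance[ref_row, iv])
        sd = max(sd1 / np.sqrt(n_need), 1e-12)
        rows.append((float(wl_v), est, 1.0 / sd ** 2))
    return fit_sif_params(rows, seed=seed, method=method)


def paired_aggregation_experiment(scene, factor: int, reps: int,
                                  seed: int = 0,
                                  instrument: Optional[InstrumentModel] = None
                                  ) -> pd.DataFrame:
    """Repeat aggregate_and_fit for both methods on shared seeds; one row
    per rep with the direct and indirect fitted-curve SSRs."""
    rows = []
    child = np.random.SeedSequence(seed).spawn(reps)
    for r in range(reps):
        s = int(child[r].generate_state(1)[0] % (2 ** 31))
        res_d = aggregate_and_fit(scene, factor, "direct", seed=s,
                                  instrument=instrument)
        res_i = aggregate_and_fit(scene, factor, "indirect", seed=s,
                                  instrument=instrument)
        rows.append({"rep": r, "ssr_direct": res_d.ssr,
                     "ssr_indirect": res_i.ssr})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------- #
# observed-vs-expected variation
# --------------------------------------------------------------------- #

def cv_residual(series: np.ndarray, noise_model: NoiseModel,
                window: int = 100, p_threshold: float = 0.01) -> np.ndarray:
    """Observed-minus-expected per-band coefficient of variation after
    trend trimming.

    ``series`` is (n_repeats, n_bands) radiance of a stable target.  The
    series is split into windows of ``window`` repeats; windows whose mean
    radiance shows a linear time trend significant at ``p_threshold`` are
    dropped (they represent changing irradiance, not noise).  The per-band
    CV of the surviving repeats minus the noise-model CV sigma(R)/R is
    returned.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2 or series.shape[0] < 100:
        raise DomainError("series must be (>=100 repeats, n_bands)")
    n = series.shape[0]
    keep = np.zeros(n, dtype=bool)
    n_windows = n // window
    t = np.arange(window)
    for w in range(n_windows):
        sl = slice(w * window, (w + 1) * window)
        mean_trace = series[sl].mean(axis=1)
        res = stats.linregress(t, mean_trace)
        if res.pvalue >= p_threshold:
            keep[sl] = True
    if not keep.any():
        raise DomainError("all windows were trimmed as trending")
    surv = series[keep]
    mean = surv.mean(axis=0)
    sd = surv.std(axis=0, ddof=1)
    observed_cv = np.where(mean > 0, sd / mean, np.nan)
    expected_cv = np.where(mean > 0, noise_model.sigma(np.clip(mean, 0, None))
                           / mean, np.nan)
    return observed_cv - expected_cv


def trimmed_windows(series: np.ndarray, window: int = 100,
                    p_threshold: float = 0.01) -> np.ndarray:
    """Boolean mask over windows: True where the window was trimmed."""
    series = np.asarray(series, dtype=float)
    n_windows = series.shape[0] // window
    t = np.arange(window)
    out = np.zeros(n_windows, dtype=bool)
    for w in range(n_windows):
        sl = slice(w * window, (w + 1) * window)
        res = stats.linregress(t, series[sl].mean(axis=1))
        out[w] = res.pvalue < p_threshold
    return out
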