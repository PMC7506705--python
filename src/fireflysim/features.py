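"""Absorption-feature discovery, regions, depths, and peak-drift tracking.

A feature is a (valley band, peak band) pair: the valley is a strict local
minimum of band radiance; the peak is the band within +-3 bands of the
valley that yields the lowest valley/peak radiance ratio (the deepest
feature).  The proportional depth k = valley/peak is in (0, 1): k near 0 is
a deep feature, k near 1 a shallow one.  No two features may share a peak;
conflicts are resolved in favour of the deeper feature, with the other
valley re-searched against the remaining window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import DegenerateFeatureError, DomainError
from .instrument import InstrumentModel
from . import scene as _scene

__all__ = [
    "AbsorptionFeature", "find_features", "feature_depth",
    "classify_regions", "track_peak_drift", "oxygen_feature",
    "catalogue_to_frame", "subsampled_depth_loss", "SEARCH_WINDOW",
]

#: half-width of the peak search window around a valley, in bands
SEARCH_WINDOW = 3

#: spectral region tags with their wavelength intervals (nm); intervals are
#: closed at their printed endpoints, except that the split-window excludes
#: the endpoints it shares with the oxygen-A region
REGIONS: Dict[str, Tuple[float, float]] = {
    "O2A": (759.0, 770.5),
    "O2B": (686.0, 715.0),
    "water_vapor": (-np.inf, 747.0),
    "leaf_slope": (686.0, 756.0),
    "polynomial_sif": (774.0, np.inf),
}


@dataclass(frozen=True)
class AbsorptionFeature:
    """A valley/peak band pair with its baseline proportional depth."""

    valley_band: int
    peak_band: int
    k: float
    regions: frozenset = frozenset()
    pixel: Optional[int] = None

    def __post_init__(self) -> None:
        sep = abs(self.peak_band - self.valley_band)
        if not 1 <= sep <= SEARCH_WINDOW:
            raise DomainError(
                f"valley/peak separation must be in [1, {SEARCH_WINDOW}] "
                f"bands, got {sep}")
        if not 0.0 < self.k < 1.0:
            raise DegenerateFeatureError(f"k must be in (0, 1), got {self.k}")


def classify_regions(wavelength: float) -> frozenset:
    """Region tags applicable at ``wavelength`` (overlaps allowed;
    'unflagged' when nothing else applies, so every wavelength has >= 1 tag).
    """
    tags = {name for name, (lo, hi) in REGIONS.items()
            if lo <= wavelength <= hi}
    # split window flanks the O2-A feature; the shared endpoints 759.0 and
    # 770.5 belong to O2A
    if 756.0 <= wavelength < 759.0 or 770.5 < wavelength <= 774.5:
        tags.add("split_window")
    if "polynomial_sif" in tags and wavelength == 774.0:
        # the polynomial region is open at 774 nm
        tags.discard("polynomial_sif")
    if not tags:
        tags.add("unflagged")
    return frozenset(tags)


def _local_minima(values: np.ndarray) -> np.ndarray:
    """Indices of strict local minima (plateau ties break to no feature)."""
    v = values
    return np.nonzero((v[1:-1] < v[:-2]) & (v[1:-1] < v[2:]))[0] + 1


def find_features(spectrum: np.ndarray,
                  pixel: Optional[int] = None,
                  instrument: Optional[InstrumentModel] = None,
                  band_indices: Optional[np.ndarray] = None
                  ) -> List[AbsorptionFeature]:
    """Discover absorption features in a per-band radiance spectrum.

    ``band_indices`` gives the 1-based band ids of ``spectrum``'s entries
    (defaults to the full instrument grid, in which case the spectrum length
    must equal n_bands).  Returned features are sorted by valley band and
    carry region tags when an instrument is given (default instrument
    otherwise).
    """
    spectrum = np.asarray(spectrum, dtype=float)
    instrument = instrument or InstrumentModel()
    if band_indices is None:
        if spectrum.shape[-1] != instrument.grid.n_bands:
            raise DomainError(
                f"spectrum length {spectrum.shape[-1]} != n_bands "
                f"{instrument.grid.n_bands}; pass band_indices for subsets")
        band_indices = np.arange(1, instrument.grid.n_bands + 1)
    band_indices = np.asarray(band_indices)

    valleys = _local_minima(spectrum)
    # candidate (valley, peak) pairs: per valley, peaks ranked by ascending
    # valley/peak ratio (deepest first)
    candidates = {}
    n = len(spectrum)
    for v in valleys:
        lo = max(0, v - SEARCH_WINDOW)
        hi = min(n, v + SEARCH_WINDOW + 1)
        window = [j for j in range(lo, hi)
                  if j != v and spectrum[j] > spectrum[v]]
        # lower band index wins ratio ties
        window.sort(key=lambda j: (spectrum[v] / spectrum[j], j))
        if window:
            candidates[v] = window

    # greedy assignment, deepest feature first, guarantees unique peaks
    order = sorted(candidates,
                   key=lambda v: spectrum[v] / spectrum[candidates[v][0]])
    taken: set = set()
    features = []
    for v in order:
        peak = next((j for j in candidates[v] if j not in taken), None)
        if peak is None:
            continue    # no admissible peak left: valley dropped
        taken.add(peak)
        k = spectrum[v] / spectrum[peak]
        wl = float(instrument.band_wavelength(int(band_indices[v])))
        features.append(AbsorptionFeature(
            valley_band=int(band_indices[v]), peak_band=int(band_indices[peak]),
            k=float(k), regions=classify_regions(wl), pixel=pixel))
    features.sort(key=lambda f: f.valley_band)
    return features


def feature_depth(spectrum: np.ndarray, feature: AbsorptionFeature,
                  band_indices: Optional[np.ndarray] = None) -> float:
    """Proportional depth k = valley radiance / peak radiance."""
    spectrum = np.asarray(spectrum, dtype=float)
    if band_indices is None:
        band_indices = np.arange(1, len(spectrum) + 1)
    band_indices = np.asarray(band_indices)
    iv = np.nonzero(band_indices == feature.valley_band)[0]
    ip = np.nonzero(band_indices == feature.peak_band)[0]
    if len(iv) == 0 or len(ip) == 0:
        raise DomainError("feature bands not present in spectrum")
    peak = spectrum[ip[0]]
    if peak <= 0:
        raise DegenerateFeatureError(
            f"peak radiance must be > 0, got {peak}")
    return float(spectrum[iv[0]] / peak)


def oxygen_feature(spectrum: np.ndarray, which: str,
                   instrument: Optional[InstrumentModel] = None,
                   band_indices: Optional[np.ndarray] = None,
                   pixel: Optional[int] = None):
    """The oxygen A or B band treated as a single broad feature.

    The valley is the minimum-radiance band inside the oxygen region
    (O2-A: 759-770.5 nm, O2-B: 686-690 nm); the peak is the maximum-radiance
    band on the unabsorbed shoulder just blueward of the band head.  Returns
    ``(valley_band, peak_band, k)``; this pair is wider than the +-3-band
    Fraunhofer window, so it is not an :class:`AbsorptionFeature`.
    """
    if which not in ("o2a", "o2b"):
        raise DomainError("which must be 'o2a' or 'o2b'")
    instrument = instrument or InstrumentModel()
    spectrum = np.asarray(spectrum, dtype=float)
    if band_indices is None:
        band_indices = np.arange(1, instrument.grid.n_bands + 1)
    band_indices = np.asarray(band_indices)
    wl = np.asarray(instrument.band_wavelength(band_indices))
    region = _scene.O2A_REGION if which == "o2a" else _scene.O2B_REGION
    shoulder = _scene.O2A_SHOULDER if which == "o2a" else _scene.O2B_SHOULDER
    in_region = np.nonzero((wl >= region[0]) & (wl <= region[1]))[0]
    in_shoulder = np.nonzero((wl >= shoulder[0]) & (wl < shoulder[1]))[0]
    if len(in_region) == 0 or len(in_shoulder) == 0:
        raise DomainError("spectrum does not cover the oxygen windows")
    valley = in_region[np.argmin(spectrum[in_region])]
    peak = in_shoulder[np.argmax(spectrum[in_shoulder])]
    if spectrum[peak] <= 0:
        raise DegenerateFeatureError("oxygen shoulder radiance must be > 0")
    k = float(spectrum[valley] / spectrum[peak])
    return int(band_indices[valley]), int(band_indices[peak]), k


def catalogue_to_frame(features: Sequence[AbsorptionFeature],
                       instrument: Optional[InstrumentModel] = None
                       ) -> pd.DataFrame:
    """Tabulate a feature catalogue (the CSV export form)."""
    instrument = instrument or InstrumentModel()
    rows = []
    for f in features:
        rows.append({
            "pixel": f.pixel,
            "valley_band": f.valley_band,
            "valley_nm": float(instrument.band_wavelength(f.valley_band)),
            "peak_band": f.peak_band,
            "peak_nm": float(instrument.band_wavelength(f.peak_band)),
            "k": f.k,
            "regions": ";".join(sorted(f.regions)),
        })
    return pd.DataFrame(rows)


def track_peak_drift(spectra: Sequence[np.ndarray],
                     features: Sequence[AbsorptionFeature],
                     band_indices: Optional[np.ndarray] = None
                     ) -> pd.DataFrame:
    """Track where each feature's local peak lands across acquisitions.

    For each feature and each spectrum, the radiance maximum within +-3
    bands of the nominal peak is located; the reported offset is the signed
    band distance from the modal located band across acquisitions.  The
    tracking is meaningful for prominent features whose summit dominates
    its neighbourhood (nominal peaks that sit on a monotone slope pin to
    the window edge and cannot register drift).  A feature whose offsets
    move monotonically with a net change is flagged as a candidate
    spectral shift.  Missing features are recorded as NaN.
    """
    if len(spectra) < 2:
        raise DomainError("need at least 2 spectra to track drift")
    spectra = [np.asarray(s, dtype=float) for s in spectra]
    n = len(spectra[0])
    if band_indices is None:
        band_indices = np.arange(1, n + 1)
    band_indices = np.asarray(band_indices)
    pos_of = {int(b): i for i, b in enumerate(band_indices)}

    rows = []
    for f in features:
        nominal = pos_of.get(f.peak_band)
        located = []
        for s in spectra:
            if nominal is None or len(s) != n:
                located.append(np.nan)
                continue
            lo = max(0, nominal - SEARCH_WINDOW)
            hi = min(len(s), nominal + SEARCH_WINDOW + 1)
            located.append(band_indices[lo + int(np.argmax(s[lo:hi]))])
        arr = np.asarray(located, dtype=float)
        finite = arr[np.isfinite(arr)]
        if len(finite):
            vals, counts = np.unique(finite, return_counts=True)
            mode = vals[np.argmax(counts)]
            offsets = arr - mode
        else:
            offsets = arr
        fin = offsets[np.isfinite(offsets)]
        diffs = np.diff(fin)
        monotone = (len(fin) >= 2 and fin[-1] != fin[0]
                    and (np.all(diffs >= 0) or np.all(diffs <= 0)))
        row = {"valley_band": f.valley_band, "peak_band": f.peak_band,
               "shift_flag": bool(monotone)}
        row.update({f"acq_{i}": offsets[i] for i in range(len(spectra))})
        rows.append(row)
    return pd.DataFrame(rows)


def subsampled_depth_loss(spectrum: np.ndarray,
                          instrument: Optional[InstrumentModel] = None,
                          factor: int = 2) -> pd.DataFrame:
    """Proportional-depth loss when the band sampling comb is decimated.

    Each full-resolution feature is re-measured as a coarse observer would
    see it: the valley is the lowest retained sample adjacent to the true
    valley band, the peak the highest retained sample inside the same
    +-3-band spectral search window (the window is a wavelength span, so it
    does not widen when the sampling coarsens).  Depth strength is 1 - k;
    the loss fraction (strength_full - strength_coarse)/strength_full is
    non-negative by construction — a coarser comb can only miss extrema —
    and equals 1 for features that disappear entirely.
    """
    if factor < 2:
        raise DomainError("decimation factor must be >= 2")
    instrument = instrument or InstrumentModel()
    spectrum = np.asarray(spectrum, dtype=float)
    full = find_features(spectrum, instrument=instrument)
    n = len(spectrum)
    on_comb = np.zeros(n, dtype=bool)
    on_comb[::factor] = True
    rows = []
    for f in full:
        strength_full = 1.0 - f.k
        if strength_full <= 0:
            continue
        iv = f.valley_band - 1
        near_valley = [j for j in range(max(0, iv - factor + 1),
                                        min(n, iv + factor))
                       if on_comb[j]]
        lo = max(0, iv - SEARCH_WINDOW)
        hi = min(n, iv + SEARCH_WINDOW + 1)
        in_window = [j for j in range(lo, hi) if on_comb[j]]
        if not near_valley or not in_window:
            continue
        valley_c = float(np.min(spectrum[near_valley]))
        peak_c = float(np.max(spectrum[in_window]))
        k_c = valley_c / peak_c if peak_c > 0 else 1.0
        strength_coarse = max(0.0, 1.0 - k_c)
        rows.append({"valley_band": f.valley_band, "k_full": f.k,
                     "k_coarse": k_c,
                     "loss": (strength_full - strength_coarse)
                     / strength_full})
    return pd.DataFrame(rows)
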