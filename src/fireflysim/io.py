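"""ENVI BSQ cube I/O, scene persistence, tabular exports.

Cubes are stored in the ENVI dialect ubiquitous in imaging spectroscopy:
a raw binary file in band-sequential (BSQ) order plus a text ``.hdr``
sidecar carrying samples/lines/bands, the data type, and the explicit
wavelength list (so the 1-based band convention can never leak into a file
ambiguously).  DN cubes are uint16, radiance cubes float32.  A scene is
persisted as a radiance cube, a DN cube, a truth CSV and a small JSON
metadata file.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .exceptions import FormatError
from .scene import SceneCube

__all__ = ["write_envi", "read_envi", "save_scene", "load_scene"]

_DTYPE_CODES = {np.dtype(np.float32): 4, np.dtype(np.uint16): 12}
_CODE_DTYPES = {4: np.dtype(np.float32), 12: np.dtype(np.uint16)}


def write_envi(path, data: np.ndarray, wavelengths: np.ndarray,
               description: str = "fireflysim cube") -> None:
    """Write a (pixels, bands) array as ENVI BSQ (lines=1) with header.

    ``path`` is the binary file; the header is written to ``path + '.hdr'``.
    """
    path = Path(path)
    data = np.ascontiguousarray(data)
    dtype = data.dtype
    if dtype not in _DTYPE_CODES:
        raise FormatError(
            f"unsupported dtype {dtype}; use float32 (radiance) or uint16 (DN)")
    n_pixels, n_bands = data.shape
    if len(wavelengths) != n_bands:
        raise FormatError(
            f"wavelength list length {len(wavelengths)} != bands {n_bands}")
    # BSQ: band-major on disk, (bands, lines, samples)
    bsq = data.T.reshape(n_bands, 1, n_pixels)
    bsq.astype(dtype).tofile(path)
    wl = ", ".join(f"{w:.6f}" for w in wavelengths)
    header = (
        "ENVI\n"
        f"description = {{{description}}}\n"
        f"samples = {n_pixels}\n"
        "lines = 1\n"
        f"bands = {n_bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[dtype]}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{{wl}}}\n")
    Path(str(path) + ".hdr").write_text(header)


def _parse_header(text: str) -> dict:
    # ENVI headers are key = value lines; {}-wrapped values may span lines
    body = text.replace("\r\n", "\n")
    fields = {}
    buf = ""
    for line in body.split("\n"):
        buf += line + "\n"
        if buf.count("{") > buf.count("}"):
            continue
        if "=" in buf:
            key, val = buf.split("=", 1)
            fields[key.strip().lower()] = val.strip()
        buf = ""
    return fields


def read_envi(path) -> Tuple[np.ndarray, dict]:
    """Read an ENVI BSQ cube back to ((pixels, bands) array, header dict).

    The header dict includes a parsed ``wavelength`` float array.
    """
    path = Path(path)
    hdr_path = Path(str(path) + ".hdr")
    if not hdr_path.exists():
        raise FileNotFoundError(f"missing ENVI header: {hdr_path}")
    if not path.exists():
        raise FileNotFoundError(f"missing ENVI binary: {path}")
    fields = _parse_header(hdr_path.read_text())
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:
        raise FormatError(f"{hdr_path}: missing header field {exc}") from exc
    if interleave != "bsq":
        raise FormatError(f"{hdr_path}: only BSQ interleave is supported")
    if code not in _CODE_DTYPES:
        raise FormatError(f"{hdr_path}: unsupported data type code {code}")
    dtype = _CODE_DTYPES[code]
    raw = np.fromfile(path, dtype=dtype)
    expected = samples * lines * bands
    if raw.size != expected:
        raise FormatError(
            f"{path}: binary holds {raw.size} values but header implies "
            f"{expected} (samples*lines*bands)")
    wavelengths = None
    if "wavelength" in fields:
        inner = fields["wavelength"].strip().strip("{}")
        wavelengths = np.array([float(x) for x in inner.split(",") if x.strip()])
        if len(wavelengths) != bands:
            raise FormatError(
                f"{hdr_path}: wavelength list length {len(wavelengths)} != "
                f"bands {bands}")
    data = raw.reshape(bands, lines, samples)[:, 0, :].T.copy()
    header = dict(fields)
    header["wavelength"] = wavelengths
    return data, header


def save_scene(base_path, cube: SceneCube) -> dict:
    """Persist a scene as radiance + DN cubes, truth CSV and metadata JSON.

    Returns a dict of the written paths.
    """
    base = Path(base_path)
    base.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "radiance": str(base) + ".rad.bsq",
        "dn": str(base) + ".dn.bsq",
        "truth": str(base) + ".truth.csv",
        "meta": str(base) + ".meta.json",
    }
    write_envi(paths["radiance"], cube.radiance.astype(np.float32),
               cube.wavelengths, description="fireflysim radiance")
    write_envi(paths["dn"], cube.dn.astype(np.uint16),
               cube.wavelengths, description="fireflysim DN")
    cube.truth.to_csv(paths["truth"], index=False)
    meta = {
        "pixels": [int(p) for p in cube.pixels],
        "band_indices": [int(cube.band_indices[0]),
                         int(cube.band_indices[-1])],
        "seed": None if cube.config is None else cube.config.seed,
        "noise_on": None if cube.config is None else cube.config.noise_on,
    }
    Path(paths["meta"]).write_text(json.dumps(meta, indent=1))
    return paths


def load_scene(base_path) -> SceneCube:
    """Load a scene written by :func:`save_scene` (config is not restored)."""
    base = Path(base_path)
    radiance, hdr = read_envi(str(base) + ".rad.bsq")
    dn, _ = read_envi(str(base) + ".dn.bsq")
    truth = pd.read_csv(str(base) + ".truth.csv")
    meta = json.loads(Path(str(base) + ".meta.json").read_text())
    b0, b1 = meta["band_indices"]
    return SceneCube(
        pixels=np.asarray(meta["pixels"]),
        band_indices=np.arange(b0, b1 + 1),
        wavelengths=hdr["wavelength"],
        radiance=radiance.astype(float),
        dn=dn.astype(np.uint16),
        truth=truth, config=None)
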