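"""Raster I/O: PolSARpro C3 flat-binary directories, multiband TIFF, label maps.

The 9-band TIFF layout used for covariance rasters is, in band order:
C11, C22, C33, Re C12, Im C12, Re C13, Im C13, Re C23, Im C23
(real power diagonals first, then the upper-triangle complex entries).
Files are plain (non-georeferenced) TIFFs.
"""

from __future__ import annotations

import os
import re
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .core import CovarianceImage, LabelMap

__all__ = [
    "read_c3_directory",
    "read_c3_tiff",
    "write_c3_tiff",
    "read_labelmap",
    "write_labelmap",
    "write_edge_strength",
    "read_covariance",
    "write_scene_sidecar",
]

# (band name, row, col, component) for the 9-band layout
_C3_BANDS = [
    ("C11", 0, 0, "real"),
    ("C22", 1, 1, "real"),
    ("C33", 2, 2, "real"),
    ("C12_real", 0, 1, "real"),
    ("C12_imag", 0, 1, "imag"),
    ("C13_real", 0, 2, "real"),
    ("C13_imag", 0, 2, "imag"),
    ("C23_real", 1, 2, "real"),
    ("C23_imag", 1, 2, "imag"),
]


def _assemble(bands: np.ndarray, looks: float, date_tag: str) -> CovarianceImage:
    h, w = bands.shape[1:]
    data = np.zeros((h, w, 3, 3), dtype=complex)
    for band, (_, i, j, comp) in zip(bands, _C3_BANDS):
        data[..., i, j] += band if comp == "real" else 1j * band
    # mirror the upper triangle to enforce Hermitian symmetry
    for i in range(3):
        for j in range(i + 1, 3):
            data[..., j, i] = np.conj(data[..., i, j])
    return CovarianceImage(data, looks=looks, date_tag=date_tag)


def _flatten(cov: CovarianceImage) -> np.ndarray:
    out = np.empty((9,) + cov.shape, dtype=np.float32)
    for k, (_, i, j, comp) in enumerate(_C3_BANDS):
        entry = cov.data[..., i, j]
        out[k] = np.real(entry) if comp == "real" else np.imag(entry)
    return out


def _parse_polsarpro_config(path: Path) -> tuple[int, int]:
    """Extract (rows, cols) from a PolSARpro config.txt.

    The file is a loose key/value text format; the integer following the
    ``Nrow`` / ``Ncol`` keys is taken, wherever it appears.
    """
    text = path.read_text()
    dims = {}
    for key in ("Nrow", "Ncol"):
        m = re.search(rf"{key}\s*[\r\n:=]+\s*(\d+)", text)
        if m is None:
            raise ValueError(f"could not find {key} in {path}")
        dims[key] = int(m.group(1))
    return dims["Nrow"], dims["Ncol"]


def read_c3_directory(path: str | os.PathLike, looks: float = 1.0,
                      date_tag: str | None = None) -> CovarianceImage:
    """Read a PolSARpro-style C3 directory of flat little-endian float32 files."""
    p = Path(path)
    rows, cols = _parse_polsarpro_config(p / "config.txt")
    bands = np.empty((9, rows, cols), dtype=np.float32)
    for k, (name, _, _, _) in enumerate(_C3_BANDS):
        raw = np.fromfile(p / f"{name}.bin", dtype="<f4")
        if raw.size != rows * cols:
            raise ValueError(
                f"{name}.bin has {raw.size} samples, expected {rows}x{cols}"
            )
        bands[k] = raw.reshape(rows, cols)
    return _assemble(bands, looks, date_tag if date_tag is not None else p.name)


def read_c3_tiff(path: str | os.PathLike, looks: float = 1.0,
                 date_tag: str | None = None) -> CovarianceImage:
    """Read a 9-band float TIFF covariance raster (band order in module docstring)."""
    arr = np.asarray(tifffile.imread(path))
    if arr.ndim != 3:
        raise ValueError(f"expected a 9-band raster, got shape {arr.shape}")
    if arr.shape[0] != 9 and arr.shape[2] == 9:
        arr = np.moveaxis(arr, 2, 0)
    if arr.shape[0] != 9:
        raise ValueError(f"expected 9 bands, got shape {arr.shape}")
    tag = date_tag if date_tag is not None else Path(path).stem
    return _assemble(arr.astype(np.float32), looks, tag)


def write_c3_tiff(path: str | os.PathLike, cov: CovarianceImage) -> None:
    tifffile.imwrite(path, _flatten(cov), photometric="minisblack")


def read_covariance(path: str | os.PathLike, looks: float = 1.0,
                    date_tag: str | None = None) -> CovarianceImage:
    """Dispatch on path type: C3 directory or 9-band TIFF."""
    if Path(path).is_dir():
        return read_c3_directory(path, looks=looks, date_tag=date_tag)
    return read_c3_tiff(path, looks=looks, date_tag=date_tag)


def read_labelmap(path: str | os.PathLike) -> LabelMap:
    arr = np.asarray(tifffile.imread(path))
    if arr.ndim != 2:
        raise ValueError(f"label map must be single-band, got shape {arr.shape}")
    return LabelMap(arr.astype(np.int32))


def write_labelmap(path: str | os.PathLike, lbl: LabelMap) -> None:
    """Write a label map as 32-bit integer TIFF, or ASCII PGM for .pgm paths."""
    path = Path(path)
    if path.suffix.lower() == ".pgm":
        lab = lbl.labels
        if lab.max(initial=0) > 65535:
            raise ValueError("PGM supports region ids up to 65535; use TIFF")
        with open(path, "w") as fh:
            fh.write(f"P2\n{lbl.width} {lbl.height}\n{max(int(lab.max()), 1)}\n")
            for row in lab:
                fh.write(" ".join(str(int(v)) for v in row) + "\n")
    else:
        tifffile.imwrite(path, lbl.labels.astype(np.int32))


def write_edge_strength(path: str | os.PathLike, strength: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(strength, dtype=np.float32))


def write_scene_sidecar(path: str | os.PathLike, meta: dict) -> None:
    """YAML sidecar describing a simulated scene (sigmas serialised re/im)."""
    with open(path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
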