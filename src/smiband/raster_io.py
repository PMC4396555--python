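"""Hyperspectral raster I/O.

Cubes travel on disk as ENVI rasters (a raw binary payload next to a text
``.hdr`` header, in any of the BSQ/BIL/BIP interleaves) or as a compressed
NumPy ``.npz`` container; label maps as CSV grids, PGM rasters, or
single-band ENVI files.  Every reader normalises to a band-last
``(row, col, band)`` array with 0-based indices, so the rest of the package
never sees interleave or byte-order details.

Supported ENVI data types are 1 (uint8), 2 (int16), 12 (uint16) and
4 (float32) — the codes that cover the common airborne-sensor
distributions.  Anything else is rejected with a :class:`FormatError`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "HyperspectralCube",
    "LabelMap",
    "FormatError",
    "CorruptionError",
    "read_cube",
    "write_cube",
    "read_label_map",
    "write_label_map",
]


class FormatError(ValueError):
    """An on-disk artefact cannot be understood (bad header, bad dialect)."""


class CorruptionError(ValueError):
    """Header metadata contradicts the payload (e.g. size mismatch)."""


_ENVI_TO_DTYPE = {
    1: np.dtype(np.uint8),
    2: np.dtype(np.int16),
    4: np.dtype(np.float32),
    12: np.dtype(np.uint16),
}
_DTYPE_TO_ENVI = {dt: code for code, dt in _ENVI_TO_DTYPE.items()}


@dataclass
class HyperspectralCube:
    """An H x W x B stack of co-registered intensity rasters.

    ``data`` is band-last: ``data[r, c, b]`` is the intensity of band ``b``
    at pixel ``(r, c)``.  Intensities must be finite and there must be at
    least two bands (a one-band image has nothing to select among).
    """

    data: np.ndarray
    band_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be (H, W, B), got shape {self.data.shape}")
        if self.data.shape[2] < 2:
            raise ValueError("a cube needs at least 2 bands")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube intensities must all be finite")
        if self.band_names is not None:
            self.band_names = [str(n) for n in self.band_names]
            if len(self.band_names) != self.data.shape[2]:
                raise ValueError("band_names length must equal the band count")

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    @property
    def band_count(self) -> int:
        return self.data.shape[2]

    def band(self, index: int) -> np.ndarray:
        """Return band ``index`` as an (H, W) view."""
        return self.data[:, :, index]


@dataclass
class LabelMap:
    """An H x W raster of integer class labels; 0 is background, never a class."""

    labels: np.ndarray
    class_names: list[str] | None = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise ValueError(f"label map must be 2-D, got shape {labels.shape}")
        if not np.issubdtype(labels.dtype, np.integer):
            flt = np.asarray(labels, dtype=float)
            if not np.all(np.isfinite(flt)) or not np.all(flt == np.floor(flt)):
                raise ValueError("labels must be integers")
            labels = flt.astype(np.int64)
        if labels.size and labels.min() < 0:
            raise ValueError("labels must be >= 0 (0 = background)")
        self.labels = labels.astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def classes(self) -> np.ndarray:
        """Sorted array of the class ids present (background excluded)."""
        vals = np.unique(self.labels)
        return vals[vals > 0]

    @property
    def n_background(self) -> int:
        return int(np.count_nonzero(self.labels == 0))


# --------------------------------------------------------------------------
# ENVI header handling


def _header_path(payload: Path) -> Path:
    cand = Path(str(payload) + ".hdr")
    if cand.exists():
        return cand
    alt = payload.with_suffix(".hdr")
    if alt.exists():
        return alt
    raise FormatError(f"no ENVI header found for {payload} (tried {cand} and {alt})")


def _parse_envi_header(text: str) -> dict[str, str]:
    lines = text.splitlines()
    if not lines or not lines[0].strip().upper().startswith("ENVI"):
        raise FormatError("not an ENVI header (missing 'ENVI' magic line)")
    fields: dict[str, str] = {}
    i = 1
    while i < len(lines):
        line = lines[i]
        i += 1
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        value = value.strip()
        if value.startswith("{"):
            while "}" not in value and i < len(lines):
                value += " " + lines[i].strip()
                i += 1
            value = value.strip("{} ").strip()
        fields[key.strip().lower()] = value
    return fields


def _require_int(fields: dict[str, str], key: str) -> int:
    if key not in fields:
        raise FormatError(f"ENVI header is missing required field '{key}'")
    try:
        return int(fields[key])
    except ValueError as exc:
        raise FormatError(f"ENVI header field '{key}' is not an integer: {fields[key]!r}") from exc


def _read_envi_array(path: Path) -> tuple[np.ndarray, list[str] | None]:
    """Read an ENVI raster into a band-last (H, W, B) array."""
    hdr = _parse_envi_header(_header_path(path).read_text())
    w = _require_int(hdr, "samples")
    h = _require_int(hdr, "lines")
    b = _require_int(hdr, "bands")
    code = _require_int(hdr, "data type")
    if code not in _ENVI_TO_DTYPE:
        raise FormatError(
            f"unsupported ENVI data type {code}; supported codes: "
            f"{sorted(_ENVI_TO_DTYPE)} (uint8, int16, float32, uint16)"
        )
    dtype = _ENVI_TO_DTYPE[code]
    if int(hdr.get("byte order", "0")) == 1:
        dtype = dtype.newbyteorder(">")
    interleave = hdr.get("interleave", "bsq").strip().lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise FormatError(f"unknown interleave {interleave!r}")
    offset = int(hdr.get("header offset", "0"))

    raw = np.fromfile(path, dtype=dtype, offset=offset)
    if raw.size != h * w * b:
        raise CorruptionError(
            f"payload holds {raw.size} values but header declares "
            f"{h} lines x {w} samples x {b} bands = {h * w * b}"
        )
    if interleave == "bsq":
        arr = raw.reshape(b, h, w).transpose(1, 2, 0)
    elif interleave == "bil":
        arr = raw.reshape(h, b, w).transpose(0, 2, 1)
    else:  # bip
        arr = raw.reshape(h, w, b)
    arr = np.ascontiguousarray(arr.astype(dtype.newbyteorder("=")))

    names: list[str] | None = None
    if "band names" in hdr:
        names = [n.strip() for n in hdr["band names"].split(",") if n.strip()]
        if len(names) != b:
            raise FormatError("band names count does not match the band count")
    return arr, names


def _storage_dtype(arr: np.ndarray) -> np.dtype:
    if arr.dtype in _DTYPE_TO_ENVI:
        return arr.dtype
    if np.issubdtype(arr.dtype, np.floating):
        return np.dtype(np.float32)
    if np.issubdtype(arr.dtype, np.integer):
        lo, hi = int(arr.min()), int(arr.max())
        if lo >= 0 and hi <= 255:
            return np.dtype(np.uint8)
        if lo >= 0 and hi <= 65535:
            return np.dtype(np.uint16)
        if -32768 <= lo and hi <= 32767:
            return np.dtype(np.int16)
    raise FormatError(f"cannot store dtype {arr.dtype} in the supported ENVI dialect")


def _write_envi(arr: np.ndarray, path: Path, band_names: list[str] | None) -> None:
    dtype = _storage_dtype(arr)
    h, w, b = arr.shape
    payload = np.ascontiguousarray(arr.astype(dtype).transpose(2, 0, 1))  # BSQ
    payload.tofile(path)
    lines = [
        "ENVI",
        f"samples = {w}",
        f"lines = {h}",
        f"bands = {b}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_DTYPE_TO_ENVI[dtype]}",
        "interleave = bsq",
        "byte order = 0",
    ]
    if band_names:
        lines.append("band names = {" + ", ".join(band_names) + "}")
    Path(str(path) + ".hdr").write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# Public cube I/O


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "npz" if path.suffix == ".npz" else "envi"


def read_cube(path: str | Path, format: str | None = None) -> HyperspectralCube:
    """Read a cube from ENVI or the ``.npz`` container, normalised band-last."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "npz":
        with np.load(path, allow_pickle=False) as npz:
            if "data" not in npz:
                raise FormatError("npz container lacks a 'data' array")
            data = npz["data"]
            names = [str(n) for n in npz["band_names"]] if "band_names" in npz else None
        return HyperspectralCube(data, band_names=names)
    if fmt == "envi":
        arr, names = _read_envi_array(path)
        return HyperspectralCube(arr, band_names=names)
    raise FormatError(f"unknown cube format {fmt!r}")


def write_cube(cube: HyperspectralCube, path: str | Path, format: str | None = None) -> None:
    """Write a cube as ENVI (BSQ payload + header) or ``.npz``.

    Integer cubes round-trip bit-exactly; float cubes are stored as
    float32, so round-trips are exact only within that representation.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "npz":
        if cube.band_names is not None:
            np.savez_compressed(path, data=cube.data, band_names=np.array(cube.band_names))
        else:
            np.savez_compressed(path, data=cube.data)
    elif fmt == "envi":
        _write_envi(cube.data, path, cube.band_names)
    else:
        raise FormatError(f"unknown cube format {fmt!r}")


# --------------------------------------------------------------------------
# Label maps


def read_label_map(path: str | Path, format: str | None = None) -> LabelMap:
    """Read a label raster from CSV, PGM, or a single-band ENVI file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".csv": "csv", ".pgm": "pgm"}.get(path.suffix, "envi")
    if format == "csv":
        grid = np.loadtxt(path, delimiter=",", dtype=float, ndmin=2)
        return LabelMap(grid)
    if format == "pgm":
        return LabelMap(np.asarray(iio.imread(path)))
    if format == "envi":
        arr, _ = _read_envi_array(path)
        if arr.shape[2] != 1:
            raise FormatError(f"label raster must be single-band, got {arr.shape[2]} bands")
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("ENVI label raster must hold integers")
        return LabelMap(arr[:, :, 0])
    raise FormatError(f"unknown label-map format {format!r}")


def write_label_map(label_map: LabelMap, path: str | Path) -> None:
    """Write a label map as a CSV grid of integers."""
    np.savetxt(Path(path), label_map.labels, fmt="%d", delimiter=",")
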