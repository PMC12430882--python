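"""File formats: ENVI cubes, compressed array containers, 16-bit RGB images.

Cubes travel either as an ENVI-style plain-text header (``.hdr``, wavelength
field mandatory, nanometres) next to a band-sequential binary (``.raw``), or
as a single compressed ``.npz`` container with a JSON metadata sidecar.  Both
round-trip bit-exactly.  RGB images are written as 16-bit PNG (quantised with
an explicit scale recorded in a JSON sidecar) or as float TIFF (lossless).
"""

from __future__ import annotations

import json
import re
import struct
import zlib
from pathlib import Path

import numpy as np
import tifffile

from .core import (IlluminantCube, RadianceCube, ReflectanceCube, RGBImage,
                   WavelengthGrid)

__all__ = ["read_cube", "write_cube", "read_rgb", "write_rgb"]

_CUBE_KINDS = {
    "reflectance": ReflectanceCube,
    "radiance": RadianceCube,
    "illuminant": IlluminantCube,
}

_ENVI_DTYPES = {"4": np.float32, "5": np.float64}
_ENVI_CODES = {np.dtype(np.float32): "4", np.dtype(np.float64): "5"}


def _kind_of(cube) -> str:
    for kind, cls in _CUBE_KINDS.items():
        if type(cube) is cls:
            return kind
    raise TypeError(f"unsupported cube type {type(cube).__name__}")


# ---------------------------------------------------------------------------
# ENVI (.hdr + .raw, band-sequential)


def _write_envi(cube, header_path: Path) -> None:
    values = cube.values
    h, w, b = values.shape
    dtype = values.dtype if values.dtype in (np.float32, np.float64) else np.float64
    data = np.ascontiguousarray(values.transpose(2, 0, 1).astype(dtype))  # BSQ
    raw_path = header_path.with_suffix(".raw")
    data.tofile(raw_path)
    wavelengths = ", ".join(f"{x:.6f}" for x in cube.grid.band_centers)
    header = "\n".join(
        [
            "ENVI",
            f"description = {{specrec {_kind_of(cube)} cube}}",
            f"samples = {w}",
            f"lines = {h}",
            f"bands = {b}",
            "header offset = 0",
            "file type = ENVI Standard",
            f"data type = {_ENVI_CODES[np.dtype(dtype)]}",
            "interleave = bsq",
            "byte order = 0",
            "wavelength units = Nanometers",
            f"wavelength = {{ {wavelengths} }}",
            "",
        ]
    )
    header_path.write_text(header)


def _parse_envi_header(text: str) -> dict:
    if not text.lstrip().startswith("ENVI"):
        raise ValueError("not an ENVI header (missing ENVI magic)")
    fields: dict[str, str] = {}
    # join brace-delimited multi-line values, then split on '='
    for match in re.finditer(r"^([\w ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)$",
                             text, flags=re.M | re.S):
        key = match.group(1).strip().lower()
        value = match.group(2).strip()
        fields[key] = value.strip("{} \n")
    return fields


def _read_envi(header_path: Path):
    fields = _parse_envi_header(header_path.read_text())
    try:
        h, w, b = (int(fields[k]) for k in ("lines", "samples", "bands"))
        dtype = _ENVI_DTYPES[fields["data type"]]
    except KeyError as exc:
        raise ValueError(f"malformed ENVI header: missing {exc}") from exc
    if fields.get("interleave", "bsq").lower() != "bsq":
        raise ValueError("only band-sequential (bsq) interleave is supported")
    if "wavelength" not in fields:
        raise ValueError("ENVI header lacks the mandatory wavelength field")
    wavelengths = np.array([float(x) for x in fields["wavelength"].split(",")])
    if wavelengths.size != b:
        raise ValueError(
            f"header lists {wavelengths.size} wavelengths for {b} bands"
        )
    raw_path = header_path.with_suffix(".raw")
    data = np.fromfile(raw_path, dtype=dtype)
    if data.size != h * w * b:
        raise ValueError(
            f"data file holds {data.size} values, header implies {h * w * b}"
        )
    values = data.reshape(b, h, w).transpose(1, 2, 0)
    kind_match = re.search(r"specrec (\w+) cube", fields.get("description", ""))
    kind = kind_match.group(1) if kind_match else "reflectance"
    grid = WavelengthGrid(wavelengths)
    return _CUBE_KINDS.get(kind, ReflectanceCube)(values, grid)


# ---------------------------------------------------------------------------
# compressed container (.npz + .json sidecar)


def _write_container(cube, path: Path) -> None:
    np.savez_compressed(path, values=cube.values,
                        wavelength_nm=cube.grid.band_centers)
    sidecar = {
        "kind": _kind_of(cube),
        "wavelength_nm": list(map(float, cube.grid.band_centers)),
        "wavelength_units": "nanometers",
        "layout": "HWB, row-major, 0-based indices",
        "writer": "specrec",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def _read_container(path: Path):
    with np.load(path) as archive:
        values = archive["values"]
        wavelengths = archive["wavelength_nm"]
    kind = "reflectance"
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        kind = meta.get("kind", kind)
        if "wavelength_nm" in meta and not np.allclose(
            meta["wavelength_nm"], wavelengths
        ):
            raise ValueError("sidecar wavelengths disagree with container")
    if values.shape[-1] != wavelengths.size:
        raise ValueError(
            f"container has {values.shape[-1]} bands but "
            f"{wavelengths.size} wavelengths"
        )
    return _CUBE_KINDS[kind](values, WavelengthGrid(wavelengths))


def write_cube(cube, path) -> None:
    """Write a cube; format chosen by extension (``.hdr`` ENVI or ``.npz``)."""
    path = Path(path)
    if path.suffix == ".hdr":
        _write_envi(cube, path)
    elif path.suffix == ".npz":
        _write_container(cube, path)
    else:
        raise ValueError(f"unrecognised cube extension {path.suffix!r}")


def read_cube(path):
    """Read a cube written by :func:`write_cube`; returns the typed cube."""
    path = Path(path)
    if path.suffix == ".hdr":
        return _read_envi(path)
    if path.suffix == ".npz":
        return _read_container(path)
    raise ValueError(f"unrecognised cube extension {path.suffix!r}")


# ---------------------------------------------------------------------------
# RGB images
#
# 16-bit RGB PNG is written/read by a minimal codec here (IHDR + one IDAT of
# unfiltered scanlines + IEND): the common imaging stacks in this environment
# only encode 8-bit RGB PNG, and our files are plain truecolour with no
# interlacing or palette.


def _png_chunk(tag: bytes, payload: bytes) -> bytes:
    return (struct.pack(">I", len(payload)) + tag + payload
            + struct.pack(">I", zlib.crc32(tag + payload)))


def _write_png16(codes: np.ndarray, path: Path) -> None:
    h, w, _ = codes.shape
    ihdr = struct.pack(">IIBBBBB", w, h, 16, 2, 0, 0, 0)  # 16-bit truecolour
    rows = codes.astype(">u2")
    raw = b"".join(b"\x00" + rows[r].tobytes() for r in range(h))
    path.write_bytes(
        b"\x89PNG\r\n\x1a\n"
        + _png_chunk(b"IHDR", ihdr)
        + _png_chunk(b"IDAT", zlib.compress(raw, 6))
        + _png_chunk(b"IEND", b"")
    )


def _read_png16(path: Path) -> np.ndarray:
    blob = path.read_bytes()
    if blob[:8] != b"\x89PNG\r\n\x1a\n":
        raise ValueError(f"{path} is not a PNG file")
    pos, ihdr, idat = 8, None, b""
    while pos < len(blob):
        (length,) = struct.unpack(">I", blob[pos : pos + 4])
        tag = blob[pos + 4 : pos + 8]
        payload = blob[pos + 8 : pos + 8 + length]
        if tag == b"IHDR":
            ihdr = struct.unpack(">IIBBBBB", payload)
        elif tag == b"IDAT":
            idat += payload
        elif tag == b"IEND":
            break
        pos += 12 + length
    if ihdr is None:
        raise ValueError("PNG without IHDR chunk")
    w, h, depth, color, _, _, interlace = ihdr
    if depth != 16 or color != 2 or interlace:
        raise ValueError(
            f"unsupported PNG: need 16-bit non-interlaced RGB, "
            f"got depth {depth}, colour type {color}"
        )
    raw = zlib.decompress(idat)
    stride = 1 + w * 6
    rows = []
    for r in range(h):
        line = raw[r * stride : (r + 1) * stride]
        if line[0] != 0:
            raise ValueError(f"unsupported PNG filter type {line[0]}")
        rows.append(np.frombuffer(line[1:], dtype=">u2"))
    return np.stack(rows).reshape(h, w, 3).astype(np.uint16)


def write_rgb(image: RGBImage, path, scale: float | None = None) -> None:
    """Write a linear RGB image.

    ``.png``: 16-bit integers, value = round(v / scale · 65535); the scale
    (default: the image maximum, 1.0 for all-zero images) is recorded in a
    JSON sidecar.  ``.tif``/``.tiff``: float32 TIFF, lossless.
    """
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, image.values.astype(np.float32),
                         photometric="rgb")
        return
    if path.suffix != ".png":
        raise ValueError(f"unsupported RGB extension {path.suffix!r}")
    if scale is None:
        peak = float(image.values.max())
        scale = peak if peak > 0 else 1.0
    encoded = np.round(np.clip(image.values / scale, 0, 1) * 65535)
    _write_png16(encoded.astype(np.uint16), path)
    path.with_suffix(".json").write_text(json.dumps({"scale": scale}))


def read_rgb(path) -> RGBImage:
    """Read an RGB image written by :func:`write_rgb` back to linear values."""
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        return RGBImage(tifffile.imread(path).astype(float))
    if path.suffix != ".png":
        raise ValueError(f"unsupported RGB extension {path.suffix!r}")
    codes = _read_png16(path)
    scale = 1.0
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        scale = float(json.loads(sidecar.read_text())["scale"])
    return RGBImage(codes.astype(float) / 65535 * scale)
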