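"""Minimal ENVI image I/O: plain-text ``.hdr`` header plus raw binary data.

Supports the three standard interleaves (BIL, BIP, BSQ), little/big endian,
and the common numeric data types. Wavelengths are parsed from the header's
``wavelength = { ... }`` block; when a header states only a start/end pair
(non-standard but seen in practice), a linear grid with inclusive endpoints
is interpolated.
"""
from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .containers import Hypercube
from .errors import ContractError

# ENVI "data type" codes -> numpy dtypes
_DTYPES = {1: "u1", 2: "i2", 3: "i4", 4: "f4", 5: "f8", 12: "u2", 13: "u4", 14: "i8"}
_DTYPE_CODES = {np.dtype(v): k for k, v in _DTYPES.items()}


def _parse_header(text: str) -> dict:
    """Parse ENVI key = value pairs; braces delimit multi-line lists."""
    if not text.lstrip().upper().startswith("ENVI"):
        raise ContractError("not an ENVI header (missing ENVI magic line)")
    fields: dict[str, str] = {}
    # collapse brace blocks onto single lines first
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def _parse_list(value: str) -> list[float]:
    return [float(tok) for tok in value.strip("{} \t").split(",") if tok.strip()]


def read_envi(hdr_path: str | Path, kind: str = "reflectance") -> Hypercube:
    """Read an ENVI header/binary pair into a :class:`Hypercube`."""
    hdr_path = Path(hdr_path)
    fields = _parse_header(hdr_path.read_text())
    samples = int(fields["samples"])  # columns
    lines = int(fields["lines"])  # rows
    bands = int(fields["bands"])
    interleave = fields.get("interleave", "bsq").lower()
    dtype = np.dtype(_DTYPES[int(fields.get("data type", 4))])
    if int(fields.get("byte order", 0)) == 1:
        dtype = dtype.newbyteorder(">")

    data_path = hdr_path.with_suffix("")  # foo.hdr -> foo
    if not data_path.exists():
        data_path = hdr_path.with_suffix(".img")
    raw = np.fromfile(data_path, dtype=dtype)
    if raw.size != samples * lines * bands:
        raise ContractError(
            f"binary size {raw.size} does not match header {lines}x{samples}x{bands}"
        )
    if interleave == "bil":
        cube = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        cube = raw.reshape(lines, samples, bands)
    elif interleave == "bsq":
        cube = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    else:
        raise ContractError(f"unknown interleave {interleave!r}")

    if "wavelength" in fields:
        wl = np.array(_parse_list(fields["wavelength"]))
    elif "wavelength start" in fields and "wavelength end" in fields:
        wl = np.linspace(
            float(fields["wavelength start"]), float(fields["wavelength end"]), bands
        )
    else:
        raise ContractError("header carries no wavelength information")
    return Hypercube(cube.astype(float), wl, kind=kind)


def write_envi(
    cube: Hypercube, hdr_path: str | Path, interleave: str = "bil", dtype: str = "f8"
) -> None:
    """Write a :class:`Hypercube` as an ENVI header/binary pair."""
    hdr_path = Path(hdr_path)
    data_path = hdr_path.with_suffix("")
    interleave = interleave.lower()
    arr = cube.data.astype(np.dtype(dtype))
    if interleave == "bil":
        out = arr.transpose(0, 2, 1)
    elif interleave == "bip":
        out = arr
    elif interleave == "bsq":
        out = arr.transpose(2, 0, 1)
    else:
        raise ContractError(f"unknown interleave {interleave!r}")
    out.tofile(data_path)

    rows, cols, bands = cube.shape
    wl_list = ", ".join(f"{w:.4f}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        "description = { hsimoist export }\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[np.dtype(dtype)]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl_list} }}\n"
    )
    hdr_path.write_text(header)
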