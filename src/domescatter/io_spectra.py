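"""Spectrum readers and writers: CSV and JCAMP-DX.

One record type carries any of the package's spectra (refractive index,
extinction, absorbance) as one or two value channels on a wavenumber
grid, plus free-form provenance metadata.

CSV dialect: comma-separated, UTF-8, '#'-prefixed comment lines (parsed
into metadata as ``key: value`` when they contain a colon), header row
``wavenumber_cm-1,value[,value_imag]``.  Floats are written with %.10g so
identical records produce identical bytes.

JCAMP-DX: XYPOINTS ``(XY..XY)`` is written; both XYPOINTS and the common
``XYDATA=(X++(Y..Y))`` AFFN form are read.  Descending-grid files (usual
for dispersive IR instruments) are reversed to ascending on read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

__all__ = ["SpectrumRecord", "read_spectrum", "write_spectrum"]

Kind = Literal["refractive-index", "extinction", "absorbance"]

_FMT = "%.10g"


@dataclass
class SpectrumRecord:
    """A spectrum: wavenumber grid, one or two channels, kind, metadata."""

    grid: np.ndarray
    values: np.ndarray  # shape (n,) or (n, 2)
    kind: Kind = "extinction"
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.ndim != 1:
            raise ValueError("grid must be 1-D")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly monotone increasing")
        if self.values.shape[0] != self.grid.size:
            raise ValueError("channel length must equal grid length")
        if self.values.ndim not in (1, 2) or (self.values.ndim == 2 and self.values.shape[1] != 2):
            raise ValueError("values must have one or two channels")

    @property
    def two_channel(self) -> bool:
        return self.values.ndim == 2


def write_spectrum(rec: SpectrumRecord, path: str | Path, format: str = "csv") -> None:
    """Write a record; byte output is deterministic for identical input."""
    path = Path(path)
    if format == "csv":
        _write_csv(rec, path)
    elif format == "jcamp-dx":
        _write_jcamp(rec, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_spectrum(path: str | Path, format: str | None = None) -> SpectrumRecord:
    """Read a record; the grid is returned ascending regardless of storage order."""
    path = Path(path)
    if format is None:
        format = "jcamp-dx" if path.suffix.lower() in (".jdx", ".dx", ".jcm") else "csv"
    if format == "csv":
        return _read_csv(path)
    if format == "jcamp-dx":
        return _read_jcamp(path)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------


def _write_csv(rec: SpectrumRecord, path: Path) -> None:
    lines = [f"# kind: {rec.kind}"]
    for key in sorted(rec.metadata):
        lines.append(f"# {key}: {rec.metadata[key]}")
    header = "wavenumber_cm-1,value"
    if rec.two_channel:
        header += ",value_imag"
    lines.append(header)
    vals = rec.values if rec.two_channel else rec.values[:, None]
    for nu, row in zip(rec.grid, vals):
        cells = [_FMT % nu] + [_FMT % v for v in row]
        lines.append(",".join(cells))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _read_csv(path: Path) -> SpectrumRecord:
    metadata: dict[str, str] = {}
    kind: Kind = "extinction"
    rows: list[list[float]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    key, val = key.strip(), val.strip()
                    if key == "kind":
                        kind = val  # type: ignore[assignment]
                    else:
                        metadata[key] = val
                else:
                    metadata.setdefault("comments", "")
                    metadata["comments"] = (metadata["comments"] + " " + body).strip()
                continue
            if line.lower().startswith("wavenumber"):
                continue
            try:
                rows.append([float(c) for c in line.split(",")])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric row {line!r}") from exc
    if not rows:
        raise ValueError(f"{path}: no data rows")
    arr = np.asarray(rows, dtype=float)
    grid, values = arr[:, 0], arr[:, 1:]
    if grid[0] > grid[-1]:
        grid, values = grid[::-1], values[::-1]
    values = values[:, 0] if values.shape[1] == 1 else values[:, :2]
    return SpectrumRecord(grid=grid, values=values, kind=kind, metadata=metadata)


# ---------------------------------------------------------------------------
# JCAMP-DX
# ---------------------------------------------------------------------------


def _write_jcamp(rec: SpectrumRecord, path: Path) -> None:
    vals = rec.values if rec.two_channel else rec.values[:, None]
    lines = [
        "##TITLE= domescatter spectrum",
        "##JCAMP-DX= 4.24",
        "##DATA TYPE= INFRARED SPECTRUM",
        f"##XUNITS= 1/CM",
        "##YUNITS= ARBITRARY UNITS",
        f"##$KIND= {rec.kind}",
    ]
    for key in sorted(rec.metadata):
        lines.append(f"##${key.upper()}= {rec.metadata[key]}")
    lines += [
        f"##FIRSTX= {_FMT % rec.grid[0]}",
        f"##LASTX= {_FMT % rec.grid[-1]}",
        f"##NPOINTS= {rec.grid.size}",
    ]
    # two-channel records stored as consecutive blocks (real then imaginary)
    nblocks = vals.shape[1]
    for ch in range(nblocks):
        tag = "##XYPOINTS= (XY..XY)" if ch == 0 else "##$XYPOINTS_IMAG= (XY..XY)"
        lines.append(tag)
        for nu, v in zip(rec.grid, vals[:, ch]):
            lines.append(f"{_FMT % nu}, {_FMT % v}")
    lines.append("##END=")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


_LDR = re.compile(r"^##(\$?[^=]+)=\s*(.*)$")


def _read_jcamp(path: Path) -> SpectrumRecord:
    metadata: dict[str, str] = {}
    kind: Kind = "extinction"
    pts: list[tuple[float, float]] = []
    pts_imag: list[tuple[float, float]] = []
    mode: str | None = None
    xydata_header: dict[str, float] = {}
    ydata: list[float] = []

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("$$"):
                continue
            m = _LDR.match(line)
            if m:
                label = m.group(1).strip().upper()
                value = m.group(2).strip()
                if label == "XYPOINTS":
                    mode = "xy"
                elif label == "$XYPOINTS_IMAG":
                    mode = "xy_imag"
                elif label == "XYDATA":
                    mode = "xppy"
                elif label == "END":
                    mode = None
                elif label == "$KIND":
                    kind = value  # type: ignore[assignment]
                    mode = None
                elif label in ("FIRSTX", "LASTX", "DELTAX", "XFACTOR", "YFACTOR", "NPOINTS"):
                    xydata_header[label] = float(value)
                    mode = None
                else:
                    if label.startswith("$"):
                        metadata[label[1:].lower()] = value
                    else:
                        metadata[label.lower()] = value
                    mode = None
                continue
            if mode in ("xy", "xy_imag"):
                target = pts if mode == "xy" else pts_imag
                for pair in re.split(r";", line):
                    cells = [c for c in re.split(r"[,\s]+", pair.strip()) if c]
                    if len(cells) < 2:
                        continue
                    try:
                        target.append((float(cells[0]), float(cells[1])))
                    except ValueError as exc:
                        raise ValueError(f"{path}:{lineno}: bad XY pair {pair!r}") from exc
            elif mode == "xppy":
                cells = [c for c in re.split(r"[,\s]+", line) if c]
                try:
                    ydata.extend(float(c) for c in cells[1:])  # first cell is X
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad XYDATA line {line!r}") from exc

    if pts:
        arr = np.asarray(pts, dtype=float)
        grid, vals = arr[:, 0], arr[:, 1]
        if pts_imag:
            arr2 = np.asarray(pts_imag, dtype=float)
            vals = np.column_stack([vals, arr2[:, 1]])
    elif ydata:
        first = xydata_header.get("FIRSTX")
        last = xydata_header.get("LASTX")
        if first is None or last is None:
            raise ValueError(f"{path}: XYDATA block without FIRSTX/LASTX")
        yfac = xydata_header.get("YFACTOR", 1.0)
        grid = np.linspace(first, last, len(ydata))
        vals = np.asarray(ydata, dtype=float) * yfac
    else:
        raise ValueError(f"{path}: no XYPOINTS or XYDATA block found")

    if grid[0] > grid[-1]:
        grid = grid[::-1]
        vals = vals[::-1]
    return SpectrumRecord(grid=grid, values=vals, kind=kind, metadata=metadata)
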