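"""Spectrum container and file I/O.

A spectrum is a strictly increasing Raman-shift grid (cm^-1) with paired
intensities (arbitrary units) and a free-form metadata mapping.  On disk a
spectrum is a plain two-column CSV/TSV file (wavenumber, intensity), one
acquisition per file; a minimal JCAMP-DX reader (fixed-point ``XYDATA``
dialect) maps onto the same contract.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np

__all__ = [
    "Spectrum",
    "read_spectrum",
    "write_spectrum",
    "read_jcamp",
    "resample_to_grid",
]


@dataclass
class Spectrum:
    """A single Raman acquisition.

    Parameters
    ----------
    wavenumbers : array-like
        Strictly increasing Raman shifts in cm^-1.
    intensities : array-like
        Intensities in arbitrary units, same length as ``wavenumbers``.
    meta : dict
        Acquisition / patient / group annotations.  Ground truth planted by
        the synthetic generator travels here, never in the data columns.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("wavenumbers and intensities must be 1-D")
        if self.wavenumbers.size != self.intensities.size:
            raise ValueError(
                f"length mismatch: {self.wavenumbers.size} wavenumbers vs "
                f"{self.intensities.size} intensities"
            )
        if self.wavenumbers.size < 2:
            raise ValueError("a spectrum needs at least two points")
        if not np.all(np.diff(self.wavenumbers) > 0):
            raise ValueError("wavenumber grid must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    def crop(self, lo: float, hi: float) -> "Spectrum":
        """Return the sub-spectrum with ``lo <= wavenumber <= hi``."""
        m = (self.wavenumbers >= lo) & (self.wavenumbers <= hi)
        if not np.any(m):
            raise ValueError(f"window ({lo}, {hi}) lies outside the grid")
        return Spectrum(self.wavenumbers[m], self.intensities[m], dict(self.meta))

    def copy_with(self, intensities: np.ndarray, **meta: Any) -> "Spectrum":
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return Spectrum(self.wavenumbers.copy(), np.asarray(intensities, float), new_meta)


def _sniff_delimiter(text: str) -> str:
    first = text.lstrip().splitlines()[0]
    return "\t" if "\t" in first else ","


def read_spectrum(path: str | Path, **meta: Any) -> Spectrum:
    """Read a spectrum from a two-column CSV/TSV or JCAMP-DX file.

    A header row is tolerated (skipped when not numeric).  File extension
    ``.jdx``/``.dx`` selects the JCAMP-DX reader.
    """
    path = Path(path)
    if path.suffix.lower() in {".jdx", ".dx", ".jcm"}:
        return read_jcamp(path, **meta)
    text = path.read_text()
    delim = _sniff_delimiter(text)
    rows: list[tuple[float, float]] = []
    for lineno, rec in enumerate(csv.reader(text.splitlines(), delimiter=delim)):
        if not rec or not rec[0].strip():
            continue
        try:
            rows.append((float(rec[0]), float(rec[1])))
        except (ValueError, IndexError):
            if lineno == 0:
                continue  # header
            raise ValueError(f"{path}: cannot parse line {lineno + 1}: {rec!r}")
    if len(rows) < 2:
        raise ValueError(f"{path}: no spectral data found")
    arr = np.array(rows, dtype=float)
    order = np.argsort(arr[:, 0])
    meta.setdefault("source", str(path))
    return Spectrum(arr[order, 0], arr[order, 1], meta)


def write_spectrum(spectrum: Spectrum, path: str | Path, delimiter: str = ",") -> Path:
    """Write a spectrum as a two-column text file (full precision)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        fh.write(f"wavenumber_cm-1{delimiter}intensity\n")
        for w, y in zip(spectrum.wavenumbers, spectrum.intensities):
            fh.write(f"{w:.6f}{delimiter}{float(y):.12g}\n")
    return path


def read_jcamp(path: str | Path, **meta: Any) -> Spectrum:
    """Minimal JCAMP-DX reader: ``XYDATA=(X++(Y..Y))``, fixed-point values.

    Supports ``XFACTOR``/``YFACTOR`` scaling and ascending or descending
    abscissas.  Compressed (SQZ/DIF/DUP) encodings are out of scope.
    """
    path = Path(path)
    xfactor = yfactor = 1.0
    deltax: float | None = None
    lines: list[tuple[float, list[float]]] = []
    in_data = False
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            value = value.strip()
            if key == "XFACTOR":
                xfactor = float(value)
            elif key == "YFACTOR":
                yfactor = float(value)
            elif key == "DELTAX":
                deltax = float(value)
            elif key == "XYDATA":
                in_data = True
            elif key == "END":
                in_data = False
            elif in_data:
                in_data = False
            continue
        if in_data:
            toks = line.replace(",", " ").split()
            if len(toks) < 2:
                raise ValueError(f"{path}: malformed XYDATA line: {raw!r}")
            lines.append((float(toks[0]) * xfactor, [float(t) * yfactor for t in toks[1:]]))
    if not lines:
        raise ValueError(f"{path}: no XYDATA found")
    # abscissa step: explicit DELTAX, else inferred from consecutive lines
    step = deltax
    if step is None and len(lines) >= 2:
        step = (lines[1][0] - lines[0][0]) / len(lines[0][1])
    if step is None and any(len(yv) > 1 for _, yv in lines):
        raise ValueError(
            f"{path}: multiple ordinates per line but no DELTAX and a single "
            "data line; the abscissa step cannot be inferred"
        )
    xs: list[float] = []
    ys: list[float] = []
    for x0, yvals in lines:
        for i, y in enumerate(yvals):
            xs.append(x0 + i * (step or 0.0))
            ys.append(y)
    if len(xs) < 2:
        raise ValueError(f"{path}: not enough XYDATA points")
    arr = np.column_stack([xs, ys])
    order = np.argsort(arr[:, 0])
    meta.setdefault("source", str(path))
    return Spectrum(arr[order, 0], arr[order, 1], meta)


def resample_to_grid(
    spectrum: Spectrum, grid: np.ndarray, tol: float = 1e-9
) -> Spectrum:
    """Linearly interpolate ``spectrum`` onto ``grid``.

    Returns the input untouched when the grids already agree within ``tol``.
    The target grid must lie inside the source support (no extrapolation).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.shape == spectrum.wavenumbers.shape and np.allclose(
        grid, spectrum.wavenumbers, atol=tol, rtol=0.0
    ):
        return spectrum
    if grid[0] < spectrum.wavenumbers[0] - tol or grid[-1] > spectrum.wavenumbers[-1] + tol:
        raise ValueError("target grid extends beyond the measured range")
    y = np.interp(grid, spectrum.wavenumbers, spectrum.intensities)
    return Spectrum(grid, y, dict(spectrum.meta))


def common_grid(spectra: list[Spectrum], tol: float = 1e-9) -> np.ndarray:
    """Grid shared by ``spectra``; raises when they differ beyond ``tol``."""
    ref = spectra[0].wavenumbers
    for s in spectra[1:]:
        if s.wavenumbers.shape != ref.shape or not np.allclose(
            s.wavenumbers, ref, atol=tol, rtol=0.0
        ):
            raise ValueError("spectra are not on a common grid; resample first")
    return ref
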