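"""Spectral conditioning: baseline, normalization, averaging, difference.

The conditioning chain runs in a fixed order: each acquisition is baseline
corrected with a cubic spline through anchor-window minima, then normalized
to the phenylalanine ring-breathing peak (~1003 cm^-1, the standard serum
internal intensity reference); a patient's replicates are averaged next,
and group averages / the non-treated-minus-treated difference spectrum come
last.  The downstream CH3/CH2 area ratio is a ratio of areas of one
spectrum, so it is invariant to the per-acquisition laser gain that the
phenylalanine normalization cancels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import UnivariateSpline

from .spectra import Spectrum, common_grid

__all__ = [
    "DEFAULT_ANCHOR_WINDOWS",
    "DEFAULT_PHE_WINDOW",
    "GroupSummary",
    "spline_baseline_correct",
    "normalize_to_phe",
    "average_spectra",
    "difference_spectrum",
    "preprocess_spectrum",
]

#: Peak-free wavenumber windows (cm^-1) whose per-window minimum-intensity
#: points anchor the baseline spline: below/between the landmark peaks,
#: sparsely through the quiet 1750-2650 cm^-1 stretch, and above the C-H
#: band.  All windows keep >= 150 cm^-1 clearance from the C-H band edges
#: so that the band's Lorentzian tails barely contaminate the anchors.
DEFAULT_ANCHOR_WINDOWS: tuple[tuple[float, float], ...] = (
    (430.0, 465.0),
    (680.0, 715.0),
    (880.0, 915.0),
    (1085.0, 1120.0),
    (1750.0, 1800.0),
    (1950.0, 2000.0),
    (2150.0, 2200.0),
    (2350.0, 2400.0),
    (2500.0, 2550.0),
    (2600.0, 2650.0),
    (3140.0, 3190.0),
    (3220.0, 3300.0),
)

DEFAULT_PHE_WINDOW: tuple[float, float] = (995.0, 1010.0)


@dataclass
class GroupSummary:
    """Pointwise mean and sample standard deviation of a set of spectra."""

    mean_spectrum: Spectrum
    sd_spectrum: np.ndarray
    n: int


def spline_baseline_correct(
    spectrum: Spectrum,
    anchor_windows: Sequence[tuple[float, float]] = DEFAULT_ANCHOR_WINDOWS,
    smoothing: float = 0.0,
) -> Spectrum:
    """Subtract a cubic smoothing spline through anchor-window minima.

    Within every anchor window the minimum-intensity point is taken as a
    baseline sample; a cubic spline (``smoothing=0`` interpolates, larger
    values smooth) through those samples is evaluated on the full grid and
    subtracted.  At least four usable anchors are required.
    """
    if smoothing < 0:
        raise ValueError("smoothing must be nonnegative")
    w, y = spectrum.wavenumbers, spectrum.intensities
    xs, ys = [], []
    for lo, hi in anchor_windows:
        m = (w >= lo) & (w <= hi)
        if not np.any(m):
            raise ValueError(f"anchor window ({lo}, {hi}) lies outside the grid")
        j = np.argmin(y[m])
        xs.append(w[m][j])
        ys.append(y[m][j])
    if len(xs) < 4:
        raise ValueError("at least 4 anchor windows are required for a cubic spline")
    order = np.argsort(xs)
    xs = np.asarray(xs)[order]
    ys = np.asarray(ys)[order]
    if np.any(np.diff(xs) <= 0):
        raise ValueError("anchor windows must yield distinct, increasing anchor points")
    spline = UnivariateSpline(xs, ys, k=3, s=smoothing)
    baseline = spline(w)
    return spectrum.copy_with(y - baseline, baseline_corrected=True)


def normalize_to_phe(
    spectrum: Spectrum, window: tuple[float, float] = DEFAULT_PHE_WINDOW
) -> Spectrum:
    """Divide all intensities by the maximum inside the phenylalanine window.

    Uses peak height, not area.  A nonpositive window maximum signals a
    failed baseline correction or an absent phenylalanine peak and raises.
    """
    lo, hi = window
    m = (spectrum.wavenumbers >= lo) & (spectrum.wavenumbers <= hi)
    if not np.any(m):
        raise ValueError(f"normalization window ({lo}, {hi}) lies outside the grid")
    peak = float(spectrum.intensities[m].max())
    if peak <= 0:
        raise ValueError(
            "nonpositive intensity maximum in the phenylalanine window; "
            "baseline correction failed or the reference peak is absent"
        )
    return spectrum.copy_with(spectrum.intensities / peak, phe_peak_height=peak)


def average_spectra(group: Sequence[Spectrum], grid_tol: float = 1e-9) -> GroupSummary:
    """Pointwise mean and sample standard deviation over shared-grid spectra."""
    if len(group) == 0:
        raise ValueError("cannot average an empty group")
    grid = common_grid(list(group), tol=grid_tol)
    stack = np.vstack([s.intensities for s in group])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(group) > 1 else np.zeros_like(mean)
    meta = {"n_averaged": len(group)}
    return GroupSummary(Spectrum(grid.copy(), mean, meta), sd, len(group))


def difference_spectrum(treated: GroupSummary, nontreated: GroupSummary) -> Spectrum:
    """Non-treated minus treated group-average spectrum."""
    a, b = treated.mean_spectrum, nontreated.mean_spectrum
    if a.wavenumbers.shape != b.wavenumbers.shape or not np.allclose(
        a.wavenumbers, b.wavenumbers
    ):
        raise ValueError("group averages are not on a common grid")
    return Spectrum(
        a.wavenumbers.copy(),
        b.intensities - a.intensities,
        {"difference": "nontreated - treated"},
    )


def preprocess_spectrum(
    spectrum: Spectrum,
    anchor_windows: Sequence[tuple[float, float]] = DEFAULT_ANCHOR_WINDOWS,
    smoothing: float = 0.0,
    phe_window: tuple[float, float] = DEFAULT_PHE_WINDOW,
) -> Spectrum:
    """Baseline correction followed by phenylalanine normalization."""
    return normalize_to_phe(
        spline_baseline_correct(spectrum, anchor_windows, smoothing), phe_window
    )
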