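"""Synthetic serum Raman spectra with planted ground truth.

Patient spectra behind the serum CH3/CH2 study are not public, so every
downstream stage is exercised against phantoms that emulate the acquisition:
a 400-3300 cm^-1 grid at 2 cm^-1 steps, Gaussian landmark peaks at the
standard serum marker positions (disulfide ~520, tryptophan ~760, tyrosine
doublet ~830/850, phenylalanine ~1003, amide III ~1300, CH2 scissoring
~1450, amide II ~1550, amide I ~1650 cm^-1), a high-wavenumber C-H band
composed of the nine reference Voigt sub-bands with a plantable CH3:CH2
area-sum ratio, smooth polynomial baseline drift, one multiplicative
(log-normal) laser-gain factor per acquisition, and i.i.d. additive Gaussian
noise.

The planted area ratio is the generator's ground truth: it travels in
``Spectrum.meta`` and in a JSON sidecar next to each cohort, never inside
the two-column data files.
"""

from __future__ import annotations

import copy
import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .deconvolution import CH2, CH3, CH_OTHER, VoigtComponent, split_fwhm
from .spectra import Spectrum, write_spectrum

__all__ = [
    "PhantomParams",
    "CohortSpec",
    "Cohort",
    "Patient",
    "default_highwave_template",
    "plant_highwave_band",
    "generate_spectrum",
    "generate_cohort",
    "write_cohort",
    "TREATED",
    "NONTREATED",
]

TREATED = "treated"
NONTREATED = "nontreated"

#: (center cm^-1, height a.u., Gaussian FWHM cm^-1) of the serum landmark
#: peaks outside the quantitatively analyzed region.  Heights are relative
#: to the phenylalanine peak (the normalization anchor, height 1).
DEFAULT_MARKER_PEAKS: list[tuple[float, float, float]] = [
    (520.0, 0.30, 12.0),
    (760.0, 0.25, 10.0),
    (830.0, 0.20, 9.0),
    (850.0, 0.22, 9.0),
    (1003.0, 1.00, 8.0),
    (1300.0, 0.35, 14.0),
    (1450.0, 0.45, 14.0),
    (1550.0, 0.30, 14.0),
    (1650.0, 0.50, 16.0),
]

# Template for the nine C-H stretching sub-bands: (center, class, area,
# total FWHM).  Bandwidths sit around the nominal 10 cm^-1; areas were
# chosen once so that (a) the base CH3:CH2 area-sum ratio is ~3.3, the
# middle of the physiological range, and (b) every sub-band, including the
# closely spaced 2977/2984 pair, produces a resolvable second-derivative
# minimum for planted ratios across 2.5-4.2 (mirroring that all nine
# components are identifiable from curvature analysis of real serum).
_HIGHWAVE_TEMPLATE: list[tuple[float, str, float, float]] = [
    (2858.0, CH2, 2.7, 10.2),
    (2877.0, CH3, 11.8, 11.7),
    (2897.0, CH2, 4.4, 10.8),
    (2912.0, CH_OTHER, 4.4, 11.0),
    (2924.0, CH2, 2.5, 9.0),
    (2940.0, CH3, 11.2, 11.9),
    (2960.0, CH3, 13.6, 11.5),
    (2977.0, CH3, 6.7, 8.2),
    (2984.0, CH2, 3.5, 8.2),
]


def default_highwave_template() -> list[VoigtComponent]:
    """Fresh copies of the nine-sub-band template components."""
    out = []
    for center, cls, area, fwhm in _HIGHWAVE_TEMPLATE:
        sigma, gamma = split_fwhm(fwhm)
        out.append(
            VoigtComponent(center=center, sigma=sigma, gamma=gamma, area=area, vib_class=cls)
        )
    return out


@dataclass
class PhantomParams:
    """Parameters of the synthetic serum phantom.

    ``baseline_coefficients`` are polynomial coefficients (constant first)
    in the normalized coordinate ``(w - start) / (stop - start)``, so the
    drift amplitude is grid-independent.  ``noise_sd`` is the additive noise
    scale and ``intensity_scale_sd`` the log-normal laser-gain spread; both
    default to the high signal-to-noise regime of long-integration,
    multi-accumulation acquisitions.
    """

    marker_peaks: list[tuple[float, float, float]] = field(
        default_factory=lambda: list(DEFAULT_MARKER_PEAKS)
    )
    highwave_components: list[VoigtComponent] = field(
        default_factory=default_highwave_template
    )
    baseline_coefficients: tuple[float, ...] = (0.2, 0.5, -0.3, 0.1)
    noise_sd: float = 5e-4
    intensity_scale_sd: float = 0.05
    grid: tuple[float, float, float] = (400.0, 3300.0, 2.0)

    def __post_init__(self) -> None:
        start, stop, step = self.grid
        if not (stop > start and step > 0):
            raise ValueError("grid must be strictly increasing")
        if self.noise_sd < 0 or self.intensity_scale_sd < 0:
            raise ValueError("noise scales must be nonnegative")
        for center, height, width in self.marker_peaks:
            if width <= 0:
                raise ValueError(f"marker at {center}: width must be positive")
            if height < 0:
                raise ValueError(f"marker at {center}: height must be nonnegative")
        anchors = [c for c, _, _ in self.marker_peaks if 995.0 <= c <= 1010.0]
        if len(anchors) != 1:
            raise ValueError(
                "exactly one marker peak must lie in the 995-1010 cm^-1 "
                "normalization window"
            )

    def wavenumbers(self) -> np.ndarray:
        start, stop, step = self.grid
        return np.arange(start, stop + step / 2, step)


@dataclass
class CohortSpec:
    """Two-group cohort design: sizes, group A_R distributions, replicates."""

    n_treated: int = 8
    n_nontreated: int = 11
    ar_mean_treated: float = 3.17
    ar_mean_nontreated: float = 3.42
    ar_sd: float = 0.086
    replicates_per_patient: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_treated < 1 or self.n_nontreated < 1:
            raise ValueError("group sizes must be >= 1")
        if self.ar_mean_treated <= 0 or self.ar_mean_nontreated <= 0:
            raise ValueError("group A_R means must be positive")
        if self.ar_sd < 0:
            raise ValueError("ar_sd must be nonnegative")
        if self.replicates_per_patient < 1:
            raise ValueError("replicates_per_patient must be >= 1")


@dataclass
class Patient:
    patient_id: str
    group: str
    planted_ar: float
    replicates: list[Spectrum]


@dataclass
class Cohort:
    spec: CohortSpec
    params: PhantomParams
    patients: list[Patient]

    def planted_ar(self) -> dict[str, float]:
        return {p.patient_id: p.planted_ar for p in self.patients}


def plant_highwave_band(
    ar_target: float, template: list[VoigtComponent]
) -> list[VoigtComponent]:
    """Rescale the CH3-class areas jointly so the CH3:CH2 area-sum ratio of
    the returned components equals ``ar_target`` exactly.

    CH2 and other classes keep their areas; centers and widths are
    untouched.  The template must carry class labels and contain at least
    one CH3 and one CH2 component.
    """
    if ar_target <= 0:
        raise ValueError("ar_target must be positive")
    sum_ch3 = sum(c.area for c in template if c.vib_class == CH3)
    sum_ch2 = sum(c.area for c in template if c.vib_class == CH2)
    if sum_ch3 <= 0 or sum_ch2 <= 0:
        raise ValueError("template must contain CH3 and CH2 components with area")
    scale = ar_target * sum_ch2 / sum_ch3
    return [
        replace(c, area=c.area * scale) if c.vib_class == CH3 else copy.copy(c)
        for c in template
    ]


def _clean_intensities(params: PhantomParams, components: list[VoigtComponent]) -> np.ndarray:
    w = params.wavenumbers()
    start, stop, _ = params.grid
    x = (w - start) / (stop - start)
    y = np.polynomial.polynomial.polyval(x, params.baseline_coefficients)
    for center, height, fwhm in params.marker_peaks:
        sd = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        y = y + height * np.exp(-0.5 * ((w - center) / sd) ** 2)
    for comp in components:
        y = y + comp.profile(w)
    return y


def generate_spectrum(
    params: PhantomParams,
    ar_target: float,
    seed: int | np.random.Generator = 0,
) -> Spectrum:
    """One synthetic acquisition with a planted CH3:CH2 area ratio.

    intensities = (baseline + marker peaks + planted C-H band) * gain + noise,
    with one log-normal gain draw per acquisition.  Deterministic for a
    fixed seed; the planted component list and draws are kept in ``meta``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    components = plant_highwave_band(ar_target, params.highwave_components)
    clean = _clean_intensities(params, components)
    gain = (
        float(np.exp(rng.normal(0.0, params.intensity_scale_sd)))
        if params.intensity_scale_sd > 0
        else 1.0
    )
    noise = rng.normal(0.0, params.noise_sd, clean.size) if params.noise_sd > 0 else 0.0
    w = params.wavenumbers()
    meta = {
        "planted_ar": float(ar_target),
        "gain": gain,
        "noise_sd": params.noise_sd,
        "planted_components": [
            {
                "center": c.center,
                "sigma": c.sigma,
                "gamma": c.gamma,
                "area": c.area,
                "vib_class": c.vib_class,
            }
            for c in components
        ],
    }
    return Spectrum(w, clean * gain + noise, meta)


def _truncated_normal_positive(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd == 0:
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > 0:
            return float(x)
    raise RuntimeError("could not draw a positive A_R; check ar_mean/ar_sd")


def generate_cohort(spec: CohortSpec, params: PhantomParams | None = None) -> Cohort:
    """Labeled two-group cohort with per-patient planted A_R ground truth.

    Each patient's A_R is drawn from its group's normal distribution
    (truncated at zero); the patient's replicates share that planted band
    but take independent gain and noise draws.  Fully deterministic given
    ``spec.seed``.
    """
    params = PhantomParams() if params is None else params
    rng = np.random.default_rng(spec.seed)
    patients: list[Patient] = []
    groups = [(TREATED, spec.n_treated, spec.ar_mean_treated), (
        NONTREATED,
        spec.n_nontreated,
        spec.ar_mean_nontreated,
    )]
    for group, n, mean in groups:
        for i in range(n):
            pid = f"{group[:1].upper()}{i + 1:02d}"
            ar = _truncated_normal_positive(rng, mean, spec.ar_sd)
            reps = []
            for r in range(spec.replicates_per_patient):
                s = generate_spectrum(params, ar, rng)
                s.meta.update(patient_id=pid, group=group, replicate=r + 1)
                reps.append(s)
            patients.append(Patient(pid, group, ar, reps))
    return Cohort(spec, params, patients)


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write a cohort to disk in the standard exchange layout.

    One two-column CSV per acquisition under ``spectra/``, a manifest CSV
    (patient_id, group, replicate_path) and a ``ground_truth.json`` sidecar
    carrying the planted per-patient A_R values and the generator settings.
    Returns the manifest path.
    """
    outdir = Path(outdir)
    (outdir / "spectra").mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.csv"
    with manifest.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "group", "replicate_path"])
        for p in cohort.patients:
            for r, s in enumerate(p.replicates, start=1):
                rel = Path("spectra") / f"{p.patient_id}_rep{r}.csv"
                write_spectrum(s, outdir / rel)
                writer.writerow([p.patient_id, p.group, rel.as_posix()])
    truth = {
        "planted_ar": cohort.planted_ar(),
        "groups": {p.patient_id: p.group for p in cohort.patients},
        "cohort_spec": {
            "n_treated": cohort.spec.n_treated,
            "n_nontreated": cohort.spec.n_nontreated,
            "ar_mean_treated": cohort.spec.ar_mean_treated,
            "ar_mean_nontreated": cohort.spec.ar_mean_nontreated,
            "ar_sd": cohort.spec.ar_sd,
            "replicates_per_patient": cohort.spec.replicates_per_patient,
            "seed": cohort.spec.seed,
        },
        "noise_sd": cohort.params.noise_sd,
        "intensity_scale_sd": cohort.params.intensity_scale_sd,
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return manifest
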