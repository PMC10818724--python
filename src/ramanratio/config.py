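"""Run configuration: every tunable of the analysis chain in one record."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import yaml

from .deconvolution import DEFAULT_REGION, REFERENCE_CLASS_TABLE
from .preprocess import DEFAULT_ANCHOR_WINDOWS, DEFAULT_PHE_WINDOW

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Settings of the end-to-end serum Raman area-ratio analysis.

    Defaults reproduce the validated nine-component configuration: the
    2800-3020 cm^-1 fit region, phenylalanine normalization window,
    anchor-window spline baseline, 11-point/order-7 smoothing
    differentiation with a 5% prominence floor, 10 cm^-1 initial
    bandwidths refined within bounds, nearest-center class assignment,
    non-treated as the positive (higher-ratio) class and 95% confidence
    intervals.
    """

    region: tuple[float, float] = DEFAULT_REGION
    phe_window: tuple[float, float] = DEFAULT_PHE_WINDOW
    baseline_anchor_windows: Sequence[tuple[float, float]] = DEFAULT_ANCHOR_WINDOWS
    baseline_smoothing: float = 0.0
    smooth_window: int = 11
    smooth_order: int = 7
    prominence_frac: float = 0.05
    init_fwhm: float = 10.0
    center_bound: float = 5.0
    sigma_bounds: tuple[float, float] = (0.2, 12.7)
    gamma_bounds: tuple[float, float] = (0.0, 15.0)
    cost_tol: float = 1e-10
    local_baseline: str = "constant"
    class_table: dict[float, str] = field(
        default_factory=lambda: dict(REFERENCE_CLASS_TABLE)
    )
    class_max_distance: float = 8.0
    include_other_class: bool = False
    average_replicate_ar: bool = False
    positive_class: str = "nontreated"
    ci_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")
        if self.region[0] >= self.region[1]:
            raise ValueError("region must be an increasing interval")
        if self.phe_window[0] >= self.phe_window[1]:
            raise ValueError("phe_window must be an increasing interval")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["class_table"] = {f"{k:g}": v for k, v in self.class_table.items()}
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        data = dict(data)
        if "class_table" in data:
            data["class_table"] = {float(k): v for k, v in data["class_table"].items()}
        for key in ("region", "phe_window", "sigma_bounds", "gamma_bounds"):
            if key in data:
                data[key] = tuple(data[key])
        if "baseline_anchor_windows" in data:
            data["baseline_anchor_windows"] = tuple(
                tuple(w) for w in data["baseline_anchor_windows"]
            )
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
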