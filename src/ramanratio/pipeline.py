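"""End-to-end runs: cohort manifest in, ratio table and ROC report out.

``run_pipeline`` ties the stages together: read the manifest, condition and
average each patient's replicates, deconvolve the C-H band, compute the
area ratio per patient, then the ROC/Youden report and group summaries.
Results are serialized as diffable CSV tables and a JSON report that echoes
the full configuration; all internal values keep full precision, printed
tables round to three decimals.  One structured log line is emitted per
stage per patient so fit failures are auditable; a failing patient is
excluded and the run continues.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .arstat import ARResult, patient_ar
from .config import RunConfig
from .preprocess import average_spectra, difference_spectrum, preprocess_spectrum
from .rocstats import GroupStats, ROCResult, analyze_scores, group_summary
from .spectra import Spectrum, read_spectrum, write_spectrum
from .synthetic import NONTREATED, TREATED, Cohort, CohortSpec, PhantomParams, generate_cohort, write_cohort

__all__ = ["PipelineResult", "run_pipeline", "simulate", "roc_from_table"]

logger = logging.getLogger("ramanratio")


@dataclass
class PipelineResult:
    ar_table: pd.DataFrame
    roc: ROCResult
    group_stats: dict[str, GroupStats]
    group_means: dict[str, Spectrum]
    difference: Spectrum | None
    excluded: list[tuple[str, str]]
    config: RunConfig


def _read_manifest(manifest_path: str | Path) -> dict[str, tuple[str, list[Path]]]:
    manifest_path = Path(manifest_path)
    patients: dict[str, tuple[str, list[Path]]] = {}
    with manifest_path.open() as fh:
        for row in csv.DictReader(fh):
            pid = row["patient_id"].strip()
            group = row["group"].strip()
            path = Path(row["replicate_path"].strip())
            if not path.is_absolute():
                path = manifest_path.parent / path
            if pid in patients and patients[pid][0] != group:
                raise ValueError(f"patient {pid} listed with conflicting groups")
            patients.setdefault(pid, (group, []))[1].append(path)
    if not patients:
        raise ValueError(f"empty manifest: {manifest_path}")
    return patients


def run_pipeline(
    manifest_path: str | Path,
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis for a cohort manifest.

    Emits (when ``outdir`` is given) the per-patient ratio table
    ``ar_table.csv``, the ROC report ``roc_report.json`` (with the config
    echoed verbatim), per-group mean spectra and the non-treated minus
    treated difference spectrum as two-column CSVs.  Deterministic for a
    fixed manifest and configuration.
    """
    config = RunConfig() if config is None else config
    patients = _read_manifest(manifest_path)

    rows: list[dict] = []
    excluded: list[tuple[str, str]] = []
    results: list[ARResult] = []
    processed_by_group: dict[str, list[Spectrum]] = {}
    for pid, (group, paths) in sorted(patients.items()):
        spectra = []
        for p in paths:
            try:
                spectra.append(read_spectrum(p))
            except (OSError, ValueError) as exc:
                logger.warning("stage=read patient=%s status=skip-file error=%s", pid, exc)
        if not spectra:
            excluded.append((pid, "no readable replicate spectra"))
            logger.error("stage=read patient=%s status=excluded", pid)
            continue
        try:
            res = patient_ar(spectra, config, patient_id=pid, group=group)
        except Exception as exc:  # noqa: BLE001 - per-patient failures must not kill the run
            excluded.append((pid, str(exc)))
            logger.error("stage=fit patient=%s status=excluded error=%s", pid, exc)
            continue
        results.append(res)
        rows.append(
            {
                "patient_id": pid,
                "group": group,
                "ar": res.ar,
                "sum_ch3": res.sum_ch3,
                "sum_ch2": res.sum_ch2,
                "n_components_used": res.n_components_used,
                "n_components_excluded": res.n_components_excluded,
                "residual_rms": res.fit.residual_rms if res.fit else np.nan,
                "converged": res.fit.converged if res.fit else False,
            }
        )
        logger.info(
            "stage=ar patient=%s status=ok ar=%.4f rms=%.3g",
            pid,
            res.ar,
            res.fit.residual_rms if res.fit else np.nan,
        )
        for s in spectra:
            processed_by_group.setdefault(group, []).append(
                preprocess_spectrum(
                    s,
                    anchor_windows=config.baseline_anchor_windows,
                    smoothing=config.baseline_smoothing,
                    phe_window=config.phe_window,
                )
            )

    table = pd.DataFrame(rows)
    groups = sorted(table["group"].unique()) if len(table) else []
    if len(groups) < 2:
        raise ValueError("fewer than 2 groups with usable patients; cannot classify")

    pos_label = config.positive_class
    pos = table.loc[table["group"] == pos_label, "ar"].to_numpy()
    neg = table.loc[table["group"] != pos_label, "ar"].to_numpy()
    roc = analyze_scores(pos, neg, positive_class=pos_label, level=config.ci_level)
    logger.info(
        "stage=roc status=ok auc=%.4f cutoff=%.4f youden=%.4f", roc.auc, roc.cutoff, roc.youden
    )

    stats = {g: group_summary(table.loc[table["group"] == g, "ar"]) for g in groups}
    means = {g: average_spectra(v).mean_spectrum for g, v in processed_by_group.items()}
    diff = None
    if TREATED in means and NONTREATED in means:
        diff = difference_spectrum(
            average_spectra(processed_by_group[TREATED]),
            average_spectra(processed_by_group[NONTREATED]),
        )

    result = PipelineResult(
        ar_table=table,
        roc=roc,
        group_stats=stats,
        group_means=means,
        difference=diff,
        excluded=excluded,
        config=config,
    )
    if outdir is not None:
        _write_bundle(result, Path(outdir))
    return result


def _round3(x: float) -> float:
    return float(np.round(x, 3))


def _write_bundle(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    table = result.ar_table.copy()
    for col in ("ar", "sum_ch3", "sum_ch2", "residual_rms"):
        if col in table.columns:
            table[col] = table[col].map(lambda v: f"{v:.3f}")
    table.to_csv(outdir / "ar_table.csv", index=False)

    roc = result.roc
    report = {
        "auc": _round3(roc.auc),
        "auc_ci": [_round3(roc.auc_ci[0]), _round3(roc.auc_ci[1])],
        "cutoff": _round3(roc.cutoff),
        "youden": _round3(roc.youden),
        "sensitivity": _round3(roc.sens_at_cutoff),
        "sensitivity_ci": [_round3(roc.sens_ci[0]), _round3(roc.sens_ci[1])],
        "specificity": _round3(roc.spec_at_cutoff),
        "specificity_ci": [_round3(roc.spec_ci[0]), _round3(roc.spec_ci[1])],
        "positive_class": roc.positive_class,
        "n_pos": roc.n_pos,
        "n_neg": roc.n_neg,
        "ci_level": roc.level,
        "excluded_patients": [{"patient_id": p, "reason": r} for p, r in result.excluded],
        "group_summaries": {
            g: {
                "n": s.n,
                "median": _round3(s.median),
                "q1": _round3(s.q1),
                "q3": _round3(s.q3),
                "whisker_low": _round3(s.whisker_low),
                "whisker_high": _round3(s.whisker_high),
                "outliers": [_round3(x) for x in s.outliers],
            }
            for g, s in result.group_stats.items()
        },
        "config": result.config.to_dict(),
    }
    (outdir / "roc_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))

    for g, spec in result.group_means.items():
        write_spectrum(spec, outdir / f"mean_{g}.csv")
    if result.difference is not None:
        write_spectrum(result.difference, outdir / "difference_nontreated_minus_treated.csv")


def simulate(
    outdir: str | Path,
    cohort_spec: CohortSpec | None = None,
    params: PhantomParams | None = None,
) -> Path:
    """Generate a synthetic cohort on disk; returns the manifest path."""
    cohort: Cohort = generate_cohort(
        cohort_spec or CohortSpec(), params or PhantomParams()
    )
    manifest = write_cohort(cohort, outdir)
    logger.info(
        "stage=simulate status=ok patients=%d manifest=%s", len(cohort.patients), manifest
    )
    return manifest


def roc_from_table(
    table_path: str | Path,
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
) -> ROCResult:
    """Recompute the ROC report from an existing per-patient ratio table."""
    config = RunConfig() if config is None else config
    table = pd.read_csv(table_path)
    pos = table.loc[table["group"] == config.positive_class, "ar"].to_numpy(float)
    neg = table.loc[table["group"] != config.positive_class, "ar"].to_numpy(float)
    roc = analyze_scores(pos, neg, positive_class=config.positive_class, level=config.ci_level)
    if outdir is not None:
        stats = {
            g: group_summary(table.loc[table["group"] == g, "ar"])
            for g in sorted(table["group"].unique())
        }
        result = PipelineResult(
            ar_table=table,
            roc=roc,
            group_stats=stats,
            group_means={},
            difference=None,
            excluded=[],
            config=config,
        )
        _write_bundle(result, Path(outdir))
    return roc
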