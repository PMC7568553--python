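"""System-suitability metrics, acceptance evaluation, and failure triage.

Six metrics are computed from replicate QC injections: median chromatographic
peak width, MS1 and MS2 data points per peak (derived from the method's
cycle times), mean precursor identifications per injection, protein groups
identified in every injection, and the median inter-injection precursor CV.
Failures are triaged as chromatographic (peak-shape metrics out of band)
versus mass-spectrometric (identification or precision metrics failing with
peak metrics in band).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dia_method import DIAMethod, points_per_peak
from .errors import ConfigError, DegenerateInputError
from .report_io import RunReport, reports_to_frame

__all__ = [
    "QCCriteria",
    "QCMetrics",
    "QCVerdict",
    "compute_qc_metrics",
    "evaluate_qc",
    "qc_timecourse",
    "derive_criteria",
    "CHROMATOGRAPHIC_METRICS",
    "MASS_SPEC_METRICS",
]

CHROMATOGRAPHIC_METRICS = ("median_peak_width", "ms1_points", "ms2_points")
MASS_SPEC_METRICS = ("n_precursors", "n_proteins", "median_precursor_cv")


@dataclass(frozen=True)
class QCCriteria:
    """Acceptance bounds. Bands are inclusive; count minima are strict
    (``>``); the CV bound is inclusive (``<=``)."""

    peak_width_band: tuple[float, float] = (14.0, 20.0)
    ms1_points_band: tuple[int, int] = (8, 11)
    ms2_points_band: tuple[int, int] = (3, 4)
    min_precursors: float = 48000
    min_proteins: float = 5000
    max_median_cv: float = 15.0
    fdr_q: float = 0.01

    def __post_init__(self) -> None:
        for name in ("peak_width_band", "ms1_points_band", "ms2_points_band"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigError(f"{name} is empty: [{lo}, {hi}]")
        if self.min_precursors <= 0 or self.min_proteins <= 0:
            raise ConfigError("count minima must be > 0")
        if self.max_median_cv <= 0:
            raise ConfigError("max_median_cv must be > 0")
        if not (0 < self.fdr_q < 1):
            raise ConfigError("fdr_q must be in (0, 1)")

    @classmethod
    def from_config(cls, cfg: Mapping) -> "QCCriteria":
        block = cfg.get("qc_criteria", cfg)
        return cls(
            peak_width_band=tuple(block["peak_width_band"]),
            ms1_points_band=tuple(block["ms1_points_band"]),
            ms2_points_band=tuple(block["ms2_points_band"]),
            min_precursors=block["min_precursors"],
            min_proteins=block["min_proteins"],
            max_median_cv=block["max_median_cv"],
            fdr_q=block["fdr_q"],
        )


@dataclass(frozen=True)
class QCMetrics:
    """Computed system-suitability metrics; ``None`` marks an unavailable
    metric (e.g. CV with a single injection, peak width without widths)."""

    median_peak_width: float | None
    ms1_points: int | None
    ms2_points: int | None
    n_precursors: float
    n_proteins: int
    median_precursor_cv: float | None
    n_injections: int


@dataclass(frozen=True)
class QCVerdict:
    passed: bool
    failed_metrics: tuple[str, ...]
    triage: str  # ok | chromatographic | mass_spectrometric | mixed

    def __post_init__(self) -> None:
        ok = not self.failed_metrics
        if self.passed != ok or (self.triage == "ok") != ok:
            raise ConfigError("verdict fields are mutually inconsistent")


def compute_qc_metrics(
    qc_runs: Iterable[RunReport],
    criteria: QCCriteria,
    method: DIAMethod,
) -> QCMetrics:
    """Compute the six metrics from replicate QC injections.

    Peak width is the median over q-passing precursors pooled across
    injections; MS1/MS2 points derive from it and the method's cycle times.
    ``n_precursors`` is the mean per-injection count of q-passing records
    with a present quantity. ``n_proteins`` counts protein groups with at
    least one q-passing precursor in every injection. The CV is the median,
    over precursors quantified in >= 2 injections, of 100 * sd / mean
    (sample sd) of quantities across injections.
    """
    runs = list(qc_runs)
    if not runs:
        raise DegenerateInputError("no QC runs supplied")
    df = reports_to_frame(runs)
    passing = df[df["q_value"] <= criteria.fdr_q]
    if passing.empty:
        raise DegenerateInputError(
            f"no q-passing records in QC runs {[r.run_id for r in runs]}"
        )
    n_injections = len(runs)

    widths = passing["peak_width"].dropna()
    if widths.empty:
        median_pw = ms1_pts = ms2_pts = None
    else:
        median_pw = float(widths.median())
        ms1_pts = points_per_peak(median_pw, method.ms1_cycle_time)
        ms2_pts = points_per_peak(median_pw, method.ms2_cycle_time)

    quantified = passing[passing["quantity"].notna()]
    n_precursors = float(
        quantified.groupby("run_id").size().reindex(
            [r.run_id for r in runs], fill_value=0
        ).mean()
    )

    per_protein_runs = passing.groupby("protein_group")["run_id"].nunique()
    n_proteins = int((per_protein_runs == n_injections).sum())

    if n_injections < 2:
        median_cv = None
    else:
        grouped = quantified.groupby("precursor_id")["quantity"]
        stats_df = grouped.agg(["count", "mean", "std"])
        multi = stats_df[stats_df["count"] >= 2]
        if multi.empty:
            median_cv = None
        else:
            median_cv = float((100.0 * multi["std"] / multi["mean"]).median())

    return QCMetrics(
        median_peak_width=median_pw,
        ms1_points=ms1_pts,
        ms2_points=ms2_pts,
        n_precursors=n_precursors,
        n_proteins=n_proteins,
        median_precursor_cv=median_cv,
        n_injections=n_injections,
    )


def _in_band(value, band) -> bool:
    return band[0] <= value <= band[1]


def evaluate_qc(metrics: QCMetrics, criteria: QCCriteria) -> QCVerdict:
    """Compare metrics to bounds; absent metrics fail conservatively."""
    failed = []

    def check(name: str, ok: bool | None) -> None:
        if ok is not True:
            failed.append(name)

    check(
        "median_peak_width",
        None if metrics.median_peak_width is None
        else _in_band(metrics.median_peak_width, criteria.peak_width_band),
    )
    check(
        "ms1_points",
        None if metrics.ms1_points is None
        else _in_band(metrics.ms1_points, criteria.ms1_points_band),
    )
    check(
        "ms2_points",
        None if metrics.ms2_points is None
        else _in_band(metrics.ms2_points, criteria.ms2_points_band),
    )
    check("n_precursors", metrics.n_precursors > criteria.min_precursors)
    check("n_proteins", metrics.n_proteins > criteria.min_proteins)
    check(
        "median_precursor_cv",
        None if metrics.median_precursor_cv is None
        else metrics.median_precursor_cv <= criteria.max_median_cv,
    )

    chrom_fail = any(m in failed for m in CHROMATOGRAPHIC_METRICS)
    ms_fail = any(m in failed for m in MASS_SPEC_METRICS)
    if not failed:
        triage = "ok"
    elif chrom_fail and ms_fail:
        triage = "mixed"
    elif chrom_fail:
        triage = "chromatographic"
    else:
        triage = "mass_spectrometric"
    return QCVerdict(passed=not failed, failed_metrics=tuple(failed), triage=triage)


def qc_timecourse(
    verdicts: Mapping[tuple[str, int], QCVerdict],
) -> dict[str, dict[str, list[int]]]:
    """Per-lab gating schedule: days on which sample analysis proceeds.

    A day proceeds iff its QC verdict passed; a later substitute day (e.g.
    re-qualification after maintenance) appears simply as a passing day.
    """
    out: dict[str, dict[str, list[int]]] = {}
    for (lab, day), verdict in sorted(verdicts.items()):
        entry = out.setdefault(lab, {"proceed": [], "blocked": []})
        entry["proceed" if verdict.passed else "blocked"].append(int(day))
    return out


def derive_criteria(
    baseline: QCMetrics,
    margin: float = 0.95,
    template: QCCriteria | None = None,
) -> QCCriteria:
    """Scale count minima from baseline (reference-laboratory) QC metrics.

    Desk-scale synthetic studies cannot reach the full-scale identification
    minima, so the count criteria are set to ``margin`` times the measured
    baseline; peak-shape bands and the CV bound keep their template values.
    """
    if not (0 < margin < 1):
        raise ConfigError("margin must be in (0, 1)")
    template = template or QCCriteria()
    return replace(
        template,
        min_precursors=math.floor(baseline.n_precursors * margin),
        min_proteins=math.floor(baseline.n_proteins * margin),
    )
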