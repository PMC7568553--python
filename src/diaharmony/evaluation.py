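"""Quantitative-performance scoring.

Given protein-level roll-up results and the study design, computes percent
deviation from theoretical mixture ratios, inter-day CV of protein ratios,
quantification completeness and co-quantification across laboratories, and
cross-site rank correlation / RSD summaries for tissue cohorts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InvalidParameterError
from .report_io import StudyDesign

__all__ = [
    "deviation_from_theoretical",
    "interday_cv",
    "co_quantification",
    "CoQuantSummary",
    "cross_site_correlation",
    "signature_rsd",
    "score_ratio_table",
    "deviation_summary",
    "interday_cv_table",
]


def deviation_from_theoretical(ratio: float, theoretical: float) -> float:
    """Percent deviation ``100 * |ratio - theoretical| / theoretical``."""
    if ratio <= 0 or theoretical <= 0:
        raise InvalidParameterError("ratio and theoretical must be > 0")
    return 100.0 * abs(ratio - theoretical) / theoretical


def interday_cv(ratios: Sequence[float]) -> float | None:
    """CV (percent, sample sd) of per-day ratio estimates; ``None`` when
    fewer than two estimates exist."""
    values = np.asarray([r for r in ratios if r is not None and not np.isnan(r)], float)
    if len(values) < 2:
        return None
    return float(100.0 * values.std(ddof=1) / values.mean())


@dataclass(frozen=True)
class CoQuantSummary:
    """Completeness and co-quantification accounting.

    ``per_lab`` columns: lab, total (union over days), average (mean per-day
    count), complete (intersection over days), completeness
    (complete/total). ``pairwise`` maps each lab combination to its
    intersection size; ``core`` is the protein set quantified by every lab
    on every day.
    """

    per_lab: pd.DataFrame
    pairwise: Mapping[tuple[str, ...], int]
    core: frozenset = field(default_factory=frozenset)


def co_quantification(
    retained_sets: Mapping[tuple[str, int], Iterable],
    max_combination_size: int | None = 2,
) -> CoQuantSummary:
    """Summarize per-lab completeness and cross-lab co-quantification.

    ``retained_sets`` maps (lab, day) to the retained protein identifiers.
    Lab combinations up to ``max_combination_size`` (None = all sizes, plus
    always the full set of labs) get intersection counts.
    """
    if not retained_sets:
        raise DegenerateInputError("no retained sets supplied")
    by_lab: dict[str, dict[int, frozenset]] = {}
    for (lab, day), proteins in retained_sets.items():
        by_lab.setdefault(str(lab), {})[int(day)] = frozenset(proteins)

    rows = []
    lab_totals: dict[str, frozenset] = {}
    lab_completes: dict[str, frozenset] = {}
    for lab, days in sorted(by_lab.items()):
        sets = list(days.values())
        total = frozenset().union(*sets)
        complete = frozenset.intersection(*sets)
        lab_totals[lab] = total
        lab_completes[lab] = complete
        rows.append(
            {
                "lab": lab,
                "n_days": len(sets),
                "total": len(total),
                "average": float(np.mean([len(s) for s in sets])),
                "complete": len(complete),
                "completeness": len(complete) / len(total) if total else np.nan,
            }
        )
    per_lab = pd.DataFrame(rows)

    labs = sorted(by_lab)
    pairwise: dict[tuple[str, ...], int] = {}
    sizes = (
        range(2, len(labs) + 1)
        if max_combination_size is None
        else range(2, min(max_combination_size, len(labs)) + 1)
    )
    for size in sizes:
        for combo in itertools.combinations(labs, size):
            inter = frozenset.intersection(*(lab_totals[lab] for lab in combo))
            pairwise[combo] = len(inter)
    if len(labs) > 1:
        all_combo = tuple(labs)
        pairwise.setdefault(
            all_combo,
            len(frozenset.intersection(*(lab_totals[lab] for lab in labs))),
        )

    core = frozenset.intersection(*(lab_completes[lab] for lab in labs))
    return CoQuantSummary(per_lab=per_lab, pairwise=pairwise, core=core)


def cross_site_correlation(
    abundances: pd.DataFrame,
    min_shared: int = 3,
) -> dict:
    """Spearman rank correlation between every pair of sites.

    ``abundances``: proteins x sites (log2 or raw — rank-based). Each pair
    is evaluated on its co-quantified proteins; pairs with fewer than
    ``min_shared`` shared proteins or a constant vector yield ``None``.
    Returns ``{"pairs": {(s1, s2): rho}, "mean": ..., "sd": ...}``.
    """
    sites = list(abundances.columns)
    if len(sites) < 2:
        raise DegenerateInputError("need at least two sites")
    pair_rho: dict[tuple[str, str], float | None] = {}
    for s1, s2 in itertools.combinations(sites, 2):
        sub = abundances[[s1, s2]].dropna()
        if len(sub) < min_shared:
            pair_rho[(s1, s2)] = None
            continue
        if sub[s1].nunique() < 2 or sub[s2].nunique() < 2:
            pair_rho[(s1, s2)] = None
            continue
        rho = stats.spearmanr(sub[s1], sub[s2]).statistic
        pair_rho[(s1, s2)] = float(rho)
    valid = [r for r in pair_rho.values() if r is not None]
    return {
        "pairs": pair_rho,
        "mean": float(np.mean(valid)) if valid else None,
        "sd": float(np.std(valid, ddof=1)) if len(valid) > 1 else None,
    }


def signature_rsd(abundances: pd.DataFrame) -> dict:
    """Per-(protein, patient) RSD across sites, with mean and standard error.

    ``abundances``: rows indexed by (protein, patient) — or any per-item
    index — columns are sites. RSD = 100 * sample sd / mean across sites;
    rows with fewer than two sites quantified are skipped.
    """
    if abundances.shape[1] < 2:
        raise DegenerateInputError("need at least two sites")
    values = abundances.to_numpy(dtype=float)
    counts = np.sum(~np.isnan(values), axis=1)
    keep = counts >= 2
    sub = abundances[keep]
    rsd = 100.0 * sub.std(axis=1, ddof=1, skipna=True) / sub.mean(axis=1, skipna=True)
    rsd = rsd.dropna()
    n = len(rsd)
    return {
        "rsd": rsd,
        "mean": float(rsd.mean()) if n else None,
        "sem": float(rsd.std(ddof=1) / np.sqrt(n)) if n > 1 else None,
        "n": n,
    }


# ---------------------------------------------------------------------------
# ratio-table scoring (controlled samples)


def score_ratio_table(
    proteins: pd.DataFrame,
    design: StudyDesign,
    restrict_to_core: bool = True,
) -> pd.DataFrame:
    """Attach theoretical ratios and percent deviations to a pairwise
    roll-up table (columns lab, day, protein_group, organism, ratio_ab,
    retained).

    With ``restrict_to_core`` the table is first limited to proteins
    retained in every (lab, day) analysis group present — the
    systematically quantified set the headline deviation figures use.
    """
    df = proteins[proteins["retained"]].copy()
    if restrict_to_core and not df.empty:
        n_groups = df[["lab", "day"]].drop_duplicates().shape[0]
        counts = df.groupby("protein_group")["protein_group"].transform("size")
        df = df[counts == n_groups]
    theoretical = {
        org: design.theoretical_ratio(org)
        for org in df["organism"].unique()
        if org != "other"
    }
    df = df[df["organism"] != "other"].copy()
    df["theoretical"] = df["organism"].map(theoretical)
    df["deviation_pct"] = (
        100.0 * (df["ratio_ab"] - df["theoretical"]).abs() / df["theoretical"]
    )
    return df


def deviation_summary(scored: pd.DataFrame) -> pd.DataFrame:
    """Median percent deviation per (lab, organism)."""
    return (
        scored.groupby(["lab", "organism"])["deviation_pct"]
        .median()
        .rename("median_deviation_pct")
        .reset_index()
    )


def interday_cv_table(scored: pd.DataFrame) -> pd.DataFrame:
    """Per (lab, organism): median CV of per-day protein ratios.

    The CV is computed per protein over its day-level ratio estimates
    within one lab, then the median is taken over proteins.
    """
    def _protein_cv(group: pd.DataFrame) -> float | None:
        return interday_cv(group["ratio_ab"].to_list())

    per_protein = (
        scored.groupby(["lab", "organism", "protein_group"])[["ratio_ab"]]
        .apply(_protein_cv)
        .rename("cv_pct")
        .reset_index()
    )
    per_protein = per_protein.dropna(subset=["cv_pct"])
    return (
        per_protein.groupby(["lab", "organism"])["cv_pct"]
        .median()
        .rename("median_cv_pct")
        .reset_index()
    )
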