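"""Peptide-to-protein quantification.

Two roll-up modes operate on q-filtered, organism-clean peptide matrices:

* **pairwise** (controlled samples): for every retained peptide, all
  inter-sample replicate pairings with quantitative data contribute a
  peptide-level A/B ratio; combination counts are summed per protein and a
  protein is reliably quantifiable only when at least ``threshold`` (default
  8) combinations exist; its ratio is the geometric median of the pairwise
  ratios, which for positive scalars is the exponential of the median
  log-ratio (even-length medians average the two central values).
* **sum** (tissue cohorts): a protein is retained when its peptides supply
  at least ``min_obs`` (default 3) observations across a sample's
  replicates; per-replicate abundance is the summed peptide intensity,
  averaged across replicates.

Upstream filtering shared by both modes: q-value cut at the identification
FDR, removal of peptide sequences observed in more than one organism (plus
all ``organism == "other"`` records, which includes iRT spike-ins and
cross-organism protein groups), and selection of a single charge state per
peptide — the precursor quantified in the most runs of the analysis group,
ties broken by total summed intensity and then lower charge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DiaHarmonyError, InvalidParameterError
from .report_io import RunReport, StudyDesign, reports_to_frame

__all__ = [
    "PeptideMatrix",
    "filter_q",
    "remove_shared_peptides",
    "select_best_charge",
    "count_combinations",
    "peptide_combination_counts",
    "retain_proteins",
    "pairwise_ratio",
    "pairwise_log_ratio_table",
    "rollup_pairwise",
    "sum_rollup",
    "rollup_sum",
    "log2fc_vs_mean",
    "RATIO_ESTIMATORS",
    "DEFAULT_COMBINATION_THRESHOLD",
    "DEFAULT_MIN_OBSERVATIONS",
]

DEFAULT_COMBINATION_THRESHOLD = 8
DEFAULT_MIN_OBSERVATIONS = 3


def _geometric_median(log_ratios: np.ndarray) -> float:
    return float(np.exp(np.median(log_ratios)))


def _geometric_mean(log_ratios: np.ndarray) -> float:
    return float(np.exp(np.mean(log_ratios)))


#: Pluggable central-ratio estimators operating on log-ratios.
RATIO_ESTIMATORS: dict[str, Callable[[np.ndarray], float]] = {
    "geometric_median": _geometric_median,
    "geometric_mean": _geometric_mean,
}


@dataclass(frozen=True)
class PeptideMatrix:
    """Peptide x run quantity matrix after charge selection.

    ``quantities``: float frame indexed by stripped sequence with one column
    per run (NaN = absent). ``meta``: per-peptide protein group, organism,
    and the selected charge state.
    """

    quantities: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.quantities.index.equals(self.meta.index):
            raise DiaHarmonyError("matrix quantity/meta indices disagree")
        values = self.quantities.to_numpy(dtype=float)
        if np.any(values[~np.isnan(values)] <= 0):
            raise DiaHarmonyError("peptide quantities must be > 0 when present")

    def __len__(self) -> int:
        return len(self.quantities)

    @property
    def runs(self) -> list[str]:
        return list(self.quantities.columns)


# ---------------------------------------------------------------------------
# filtering


def filter_q(records: pd.DataFrame, fdr_q: float = 0.01) -> pd.DataFrame:
    """Keep records identified at ``q <= fdr_q`` (inclusive) with a present
    quantity."""
    if not (0 < fdr_q < 1):
        raise InvalidParameterError(f"fdr_q must be in (0, 1), got {fdr_q}")
    mask = (records["q_value"] <= fdr_q) & records["quantity"].notna()
    return records[mask]


def remove_shared_peptides(records: pd.DataFrame) -> pd.DataFrame:
    """Drop sequences seen with more than one organism, and all ``other``
    records (iRT spike-ins, cross-organism protein groups)."""
    records = records[records["organism"] != "other"]
    n_orgs = records.groupby("stripped_sequence")["organism"].transform("nunique")
    return records[n_orgs == 1]


def select_best_charge(
    records: pd.DataFrame,
    runs: Sequence[str] | None = None,
) -> PeptideMatrix:
    """Collapse charge states: keep, per peptide sequence, the precursor
    quantified in the most runs of the analysis group.

    Ties go to the precursor with the larger summed intensity, then to the
    lower charge state.
    """
    df = records if runs is None else records[records["run_id"].isin(runs)]
    if df.empty:
        empty = pd.DataFrame(index=pd.Index([], name="stripped_sequence"))
        return PeptideMatrix(
            quantities=empty.copy(),
            meta=empty.assign(protein_group=[], organism=[], charge=[]),
        )
    run_order = list(runs) if runs is not None else sorted(df["run_id"].unique())

    stats = (
        df.assign(present=df["quantity"].notna())
        .groupby(["stripped_sequence", "charge"], as_index=False)
        .agg(n_present=("present", "sum"), total=("quantity", "sum"))
        .sort_values(
            ["stripped_sequence", "n_present", "total", "charge"],
            ascending=[True, False, False, True],
            kind="mergesort",
        )
    )
    best = stats.drop_duplicates("stripped_sequence")[["stripped_sequence", "charge"]]
    kept = df.merge(best, on=["stripped_sequence", "charge"])

    quantities = (
        kept.pivot(index="stripped_sequence", columns="run_id", values="quantity")
        .reindex(columns=run_order)
    )
    quantities.columns.name = None
    meta = (
        kept.groupby("stripped_sequence")
        .agg(
            protein_group=("protein_group", "first"),
            organism=("organism", "first"),
            charge=("charge", "first"),
        )
        .reindex(quantities.index)
    )
    return PeptideMatrix(quantities=quantities, meta=meta)


# ---------------------------------------------------------------------------
# pairwise mode


def count_combinations(
    peptide_row: Mapping[str, float] | pd.Series,
    runs_a: Sequence[str],
    runs_b: Sequence[str],
) -> int:
    """Available inter-sample pairings for one peptide: the product of the
    numbers of A and B runs with quantitative data."""
    row = pd.Series(peptide_row, dtype=float)
    n_a = int(row.reindex(runs_a).notna().sum())
    n_b = int(row.reindex(runs_b).notna().sum())
    return n_a * n_b


def peptide_combination_counts(
    matrix: PeptideMatrix,
    runs_a: Sequence[str],
    runs_b: Sequence[str],
) -> pd.Series:
    """Vectorized :func:`count_combinations` over the whole matrix."""
    q = matrix.quantities
    return q[list(runs_a)].notna().sum(axis=1) * q[list(runs_b)].notna().sum(axis=1)


def retain_proteins(
    matrix: PeptideMatrix,
    combination_counts: pd.Series,
    threshold: int = DEFAULT_COMBINATION_THRESHOLD,
) -> pd.DataFrame:
    """Sum peptide combination counts per protein group and flag groups with
    at least ``threshold`` combinations as reliably quantifiable."""
    table = matrix.meta.assign(n_combinations=combination_counts)
    out = (
        table.groupby("protein_group")
        .agg(
            organism=("organism", "first"),
            n_peptides=("n_combinations", "size"),
            n_combinations=("n_combinations", "sum"),
        )
        .reset_index()
    )
    out["n_combinations"] = out["n_combinations"].astype(int)
    out["retained"] = out["n_combinations"] >= threshold
    return out


def pairwise_log_ratio_table(
    matrix: PeptideMatrix,
    runs_a: Sequence[str],
    runs_b: Sequence[str],
) -> pd.DataFrame:
    """All peptide-level log(A/B) ratios over available pairings.

    Returns a long frame with columns ``stripped_sequence``,
    ``protein_group``, ``log_ratio`` — one row per (peptide, A-run, B-run)
    pairing with quantities present on both sides.
    """
    log_a = np.log(matrix.quantities[list(runs_a)].to_numpy(dtype=float))
    log_b = np.log(matrix.quantities[list(runs_b)].to_numpy(dtype=float))
    diff = log_a[:, :, None] - log_b[:, None, :]
    flat = diff.reshape(len(matrix), -1)
    rows, cols = np.nonzero(~np.isnan(flat))
    seqs = matrix.quantities.index.to_numpy()[rows]
    return pd.DataFrame(
        {
            "stripped_sequence": seqs,
            "protein_group": matrix.meta["protein_group"].to_numpy()[rows],
            "log_ratio": flat[rows, cols],
        }
    )


def pairwise_ratio(
    matrix: PeptideMatrix,
    protein_group: str,
    runs_a: Sequence[str],
    runs_b: Sequence[str],
    estimator: str = "geometric_median",
) -> float:
    """Central A/B ratio for one protein over all peptide pairings."""
    est = RATIO_ESTIMATORS[estimator]
    peptides = matrix.meta.index[matrix.meta["protein_group"] == protein_group]
    sub = PeptideMatrix(
        quantities=matrix.quantities.loc[peptides],
        meta=matrix.meta.loc[peptides],
    )
    table = pairwise_log_ratio_table(sub, runs_a, runs_b)
    if table.empty:
        raise DiaHarmonyError(
            f"protein {protein_group} has no available inter-sample pairings"
        )
    return est(table["log_ratio"].to_numpy())


def rollup_pairwise(
    reports: Iterable[RunReport] | pd.DataFrame,
    fdr_q: float = 0.01,
    threshold: int = DEFAULT_COMBINATION_THRESHOLD,
    group_by: Sequence[str] = ("lab", "day"),
    estimator: str = "geometric_median",
    sample_a: str = "A",
    sample_b: str = "B",
) -> pd.DataFrame:
    """Full pairwise roll-up, applied independently per analysis group.

    Returns one row per (group, protein group) with columns: the group keys,
    ``protein_group``, ``organism``, ``n_peptides``, ``n_combinations``,
    ``ratio_ab`` (NaN when no pairing exists), and ``retained``.
    """
    if estimator not in RATIO_ESTIMATORS:
        raise InvalidParameterError(f"unknown estimator {estimator!r}")
    df = reports if isinstance(reports, pd.DataFrame) else reports_to_frame(reports)
    df = df[df["sample"].isin((sample_a, sample_b))]
    results = []
    for keys, group in df.groupby(list(group_by)):
        keys = keys if isinstance(keys, tuple) else (keys,)
        filtered = remove_shared_peptides(filter_q(group, fdr_q))
        if filtered.empty:
            continue
        runs_a = sorted(filtered.loc[filtered["sample"] == sample_a, "run_id"].unique())
        runs_b = sorted(filtered.loc[filtered["sample"] == sample_b, "run_id"].unique())
        run_order = runs_a + runs_b
        matrix = select_best_charge(filtered, runs=run_order)
        combos = peptide_combination_counts(matrix, runs_a, runs_b)
        proteins = retain_proteins(matrix, combos, threshold)

        ratios = pairwise_log_ratio_table(matrix, runs_a, runs_b)
        est = RATIO_ESTIMATORS[estimator]
        if ratios.empty:
            ratio_by_protein = pd.Series(dtype=float)
        else:
            ratio_by_protein = ratios.groupby("protein_group")["log_ratio"].agg(
                lambda lr: est(lr.to_numpy())
            )
        proteins["ratio_ab"] = proteins["protein_group"].map(ratio_by_protein)
        if (proteins["retained"] & proteins["ratio_ab"].isna()).any():
            raise DiaHarmonyError("retained protein lacks pairwise ratios")
        for col, value in zip(reversed(list(group_by)), reversed(keys)):
            proteins.insert(0, col, value)
        results.append(proteins)
    if not results:
        return pd.DataFrame(
            columns=[*group_by, "protein_group", "organism", "n_peptides",
                     "n_combinations", "ratio_ab", "retained"]
        )
    return pd.concat(results, ignore_index=True)


# ---------------------------------------------------------------------------
# sum mode


def sum_rollup(
    matrix: PeptideMatrix,
    replicate_groups: Mapping[object, Sequence[str]],
    min_obs: int = DEFAULT_MIN_OBSERVATIONS,
) -> pd.DataFrame:
    """Summed-intensity roll-up over replicate groups.

    For each group (e.g. one patient sample at one site) and protein:
    ``n_obs`` is the number of present peptide observations across the
    group's runs; the protein is retained when ``n_obs >= min_obs``;
    per-replicate abundance is the sum of present peptide intensities and
    the reported abundance is its mean over replicates with data.
    """
    results = []
    protein_of = matrix.meta["protein_group"]
    for key, run_ids in replicate_groups.items():
        run_ids = list(run_ids)
        sub = matrix.quantities[run_ids]
        by_protein = sub.groupby(protein_of)
        n_obs = by_protein.count().sum(axis=1).astype(int)
        per_run_sum = by_protein.sum(min_count=1)
        abundance = per_run_sum.mean(axis=1, skipna=True)
        frame = pd.DataFrame(
            {
                "group": key,
                "protein_group": n_obs.index,
                "n_obs": n_obs.to_numpy(),
                "abundance": abundance.to_numpy(),
                "retained": (n_obs >= min_obs).to_numpy(),
            }
        )
        results.append(frame)
    out = pd.concat(results, ignore_index=True)
    out.loc[~out["retained"], "abundance"] = np.nan
    return out


def rollup_sum(
    reports: Iterable[RunReport] | pd.DataFrame,
    fdr_q: float = 0.01,
    min_obs: int = DEFAULT_MIN_OBSERVATIONS,
    charge_scope: Sequence[str] = ("lab",),
) -> pd.DataFrame:
    """Sum-mode roll-up of a cohort: one replicate group per (lab, sample).

    Charge-state selection is scoped per ``charge_scope`` (default: per
    site), mirroring the per-analysis-series selection of the pairwise mode.
    Returns a frame with ``lab``, ``sample``, ``protein_group``, ``n_obs``,
    ``abundance``, ``retained``.
    """
    df = reports if isinstance(reports, pd.DataFrame) else reports_to_frame(reports)
    results = []
    for keys, group in df.groupby(list(charge_scope)):
        keys = keys if isinstance(keys, tuple) else (keys,)
        filtered = remove_shared_peptides(filter_q(group, fdr_q))
        if filtered.empty:
            continue
        matrix = select_best_charge(filtered)
        groups = {
            sample: sorted(runs["run_id"].unique())
            for sample, runs in filtered.groupby("sample")
        }
        rolled = sum_rollup(matrix, groups, min_obs)
        rolled = rolled.rename(columns={"group": "sample"})
        for col, value in zip(reversed(list(charge_scope)), reversed(keys)):
            rolled.insert(0, col, value)
        results.append(rolled)
    if not results:
        return pd.DataFrame(
            columns=[*charge_scope, "sample", "protein_group", "n_obs",
                     "abundance", "retained"]
        )
    return pd.concat(results, ignore_index=True)


def log2fc_vs_mean(abundance: pd.DataFrame) -> pd.DataFrame:
    """Log2 fold-change of each sample column relative to the per-protein
    mean abundance across all samples (NaN-aware)."""
    mean = abundance.mean(axis=1, skipna=True)
    return np.log2(abundance.div(mean, axis=0))
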