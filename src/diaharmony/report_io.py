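"""Precursor-report, manifest, and study-design I/O.

Reports use the Spectronaut-export TSV dialect: one row per quantified
precursor with the verbatim column names ``EG.PrecursorId``,
``PG.ProteinAccessions``, ``PG.ProteinDescriptions``, ``EG.Qvalue``,
``PEP.Quantity``, ``PG.Quantity``, ``PG.FastaFiles``, ``PG.ProteinGroups``,
plus a configurable per-precursor peak-width column (default
``EG.PeakWidth``, a dialect extension). All writers emit UTF-8 with LF line
endings; the decimal separator is always ``.``.
"""

from __future__ import annotations

import logging
import math
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ManifestError, ReportFormatError

__all__ = [
    "ORGANISMS",
    "PrecursorRecord",
    "RunReport",
    "StudyDesign",
    "parse_precursor_id",
    "strip_modifications",
    "infer_organism",
    "read_report",
    "write_report",
    "read_manifest",
    "write_manifest",
    "build_manifest",
    "default_schedule",
    "reports_to_frame",
    "load_study_reports",
]

logger = logging.getLogger(__name__)

ORGANISMS = ("human", "yeast", "ecoli", "other")

#: Verbatim export column names.
COL_PRECURSOR = "EG.PrecursorId"
COL_ACCESSIONS = "PG.ProteinAccessions"
COL_DESCRIPTIONS = "PG.ProteinDescriptions"
COL_QVALUE = "EG.Qvalue"
COL_QUANTITY = "PEP.Quantity"
COL_PG_QUANTITY = "PG.Quantity"
COL_FASTA = "PG.FastaFiles"
COL_GROUPS = "PG.ProteinGroups"
DEFAULT_PEAK_WIDTH_COL = "EG.PeakWidth"

MANDATORY_COLUMNS = (COL_PRECURSOR, COL_ACCESSIONS, COL_QVALUE, COL_QUANTITY)

#: Cell contents treated as an absent quantity (dialects vary).
MISSING_QUANTITY_TOKENS = {"", "nan", "na", "filtered", "none"}

_DEFAULT_FASTA_PATTERNS: dict[str, list[str]] = {
    "human": ["sapiens", "human"],
    "yeast": ["cerevisiae", "yeast"],
    "ecoli": ["coli"],
}
_DEFAULT_SUFFIXES: dict[str, str] = {
    "human": "_HUMAN",
    "yeast": "_YEAST",
    "ecoli": "_ECOLI",
}

_MOD_RE = re.compile(r"\[[^\]]*\]|\([^)]*\)")


def strip_modifications(sequence: str) -> str:
    """Remove bracketed modification annotations, keeping residue letters."""
    return re.sub(r"[^A-Z]", "", _MOD_RE.sub("", sequence.strip("_")))


def parse_precursor_id(precursor_id: str) -> tuple[str, int]:
    """Split ``MODIFIED_SEQUENCE.CHARGE`` into (stripped_sequence, charge)."""
    seq, sep, charge_str = precursor_id.rpartition(".")
    if not sep or not charge_str.isdigit():
        raise ReportFormatError(
            f"precursor id {precursor_id!r} is not of the form SEQUENCE.CHARGE"
        )
    charge = int(charge_str)
    if charge < 1:
        raise ReportFormatError(f"charge must be >= 1 in {precursor_id!r}")
    return strip_modifications(seq), charge


@dataclass(frozen=True, slots=True)
class PrecursorRecord:
    """One quantified precursor in one run."""

    precursor_id: str
    stripped_sequence: str
    charge: int
    protein_group: str
    organism: str
    q_value: float
    quantity: float | None = None
    peak_width: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.q_value <= 1.0):
            raise ReportFormatError(
                f"q-value {self.q_value} outside [0, 1] for {self.precursor_id}"
            )
        if self.quantity is not None and not self.quantity > 0:
            raise ReportFormatError(
                f"quantity must be > 0 when present, got {self.quantity}"
            )
        if self.organism not in ORGANISMS:
            raise ReportFormatError(f"unknown organism {self.organism!r}")


@dataclass(frozen=True)
class RunReport:
    """All precursor records of one injection plus its run metadata."""

    run_id: str
    lab: str
    day: int
    sample: str
    replicate: int
    records: tuple[PrecursorRecord, ...] = ()

    def __post_init__(self) -> None:
        ids = [r.precursor_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ReportFormatError(f"duplicate precursor ids in run {self.run_id}")

    def __len__(self) -> int:
        return len(self.records)

    def with_records(self, records: Iterable[PrecursorRecord]) -> "RunReport":
        return replace(self, records=tuple(records))


@dataclass(frozen=True)
class StudyDesign:
    """Controlled-sample compositions and the derived theoretical ratios."""

    composition_a: Mapping[str, float]
    composition_b: Mapping[str, float]
    composition_qc: Mapping[str, float] = field(
        default_factory=lambda: {"human": 1.0}
    )
    replicate_schedule: Mapping[int, Mapping[str, int]] | None = None

    def __post_init__(self) -> None:
        for name, comp in (
            ("A", self.composition_a),
            ("B", self.composition_b),
            ("QC", self.composition_qc),
        ):
            total = sum(comp.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(
                    f"composition {name} fractions sum to {total}, expected 1"
                )
            for org, frac in comp.items():
                if org not in ORGANISMS:
                    raise ConfigError(f"unknown organism {org!r} in composition {name}")
                if frac < 0:
                    raise ConfigError(f"negative fraction for {org} in {name}")

    def composition(self, sample: str) -> Mapping[str, float]:
        if sample == "A":
            return self.composition_a
        if sample == "B":
            return self.composition_b
        if sample == "QC":
            return self.composition_qc
        raise ConfigError(f"no composition defined for sample {sample!r}")

    def theoretical_ratio(self, organism: str) -> float:
        """A-over-B abundance ratio implied by the w/w compositions."""
        fa = self.composition_a.get(organism, 0.0)
        fb = self.composition_b.get(organism, 0.0)
        if fa <= 0 or fb <= 0:
            raise ConfigError(f"organism {organism!r} absent from a composition")
        return fa / fb

    def fold_change(self, organism: str) -> float:
        """Higher-over-lower orientation of the theoretical ratio."""
        r = self.theoretical_ratio(organism)
        return max(r, 1.0 / r)

    @classmethod
    def from_config(cls, cfg: Mapping[str, Any]) -> "StudyDesign":
        block = cfg.get("design", cfg)
        return cls(
            composition_a=dict(block["composition_A"]),
            composition_b=dict(block["composition_B"]),
            composition_qc=dict(block.get("composition_QC", {"human": 1.0})),
            replicate_schedule=block.get("replicate_schedule"),
        )


# ---------------------------------------------------------------------------
# organism inference


def infer_organism(
    accessions: str,
    fasta_files: str | None = None,
    fasta_patterns: Mapping[str, Sequence[str]] | None = None,
    accession_suffixes: Mapping[str, str] | None = None,
) -> str:
    """Assign an organism label to a protein group.

    Precedence: substring match on the fasta-file field, then accession
    suffix match; groups matching more than one organism (shared across
    proteomes) and unmatched groups map to ``"other"``.
    """
    fasta_patterns = fasta_patterns or _DEFAULT_FASTA_PATTERNS
    accession_suffixes = accession_suffixes or _DEFAULT_SUFFIXES

    if fasta_files:
        lowered = fasta_files.lower()
        hits = {
            org
            for org, patterns in fasta_patterns.items()
            if any(p.lower() in lowered for p in patterns)
        }
        if len(hits) == 1:
            return hits.pop()
        if len(hits) > 1:
            return "other"

    hits = set()
    matched_all = True
    for acc in str(accessions).split(";"):
        acc = acc.strip()
        if not acc:
            continue
        acc_hit = None
        for org, suffix in accession_suffixes.items():
            if acc.endswith(suffix):
                acc_hit = org
                break
        if acc_hit is None:
            matched_all = False
        else:
            hits.add(acc_hit)
    if len(hits) == 1 and matched_all:
        return hits.pop()
    return "other"


# ---------------------------------------------------------------------------
# report reading / writing


def _parse_quantity(raw: Any) -> float | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    text = str(raw).strip()
    if text.lower() in MISSING_QUANTITY_TOKENS:
        return None
    try:
        value = float(text)
    except ValueError:
        return None
    if math.isnan(value) or value <= 0:
        return None
    return value


def read_report(
    path: str | Path,
    manifest_entry: Mapping[str, Any],
    organism_patterns: Mapping[str, Any] | None = None,
    peak_width_column: str = DEFAULT_PEAK_WIDTH_COL,
) -> RunReport:
    """Read one Spectronaut-dialect TSV report into a :class:`RunReport`.

    No q-value filtering is applied here; duplicate precursor ids collapse
    to the row with the lowest q-value.
    """
    path = Path(path)
    fasta_patterns = None
    suffixes = None
    if organism_patterns:
        fasta_patterns = organism_patterns.get("fasta")
        suffixes = organism_patterns.get("accession_suffix")

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ReportFormatError(
            f"report {path.name} lacks mandatory column(s): {', '.join(missing)}"
        )
    meta = dict(manifest_entry)
    run_id = str(meta.get("run_id") or path.stem)
    if df.empty:
        warnings.warn(f"report {path.name} contains no data rows", stacklevel=2)

    records: dict[str, PrecursorRecord] = {}
    n_dups = 0
    fasta_present = COL_FASTA in df.columns
    pw_present = peak_width_column in df.columns
    for row in df.itertuples(index=False):
        row_d = dict(zip(df.columns, row))
        pid = row_d[COL_PRECURSOR]
        seq, charge = parse_precursor_id(pid)
        q = float(row_d[COL_QVALUE])
        organism = infer_organism(
            row_d[COL_ACCESSIONS],
            row_d.get(COL_FASTA) if fasta_present else None,
            fasta_patterns,
            suffixes,
        )
        record = PrecursorRecord(
            precursor_id=pid,
            stripped_sequence=seq,
            charge=charge,
            protein_group=row_d[COL_ACCESSIONS],
            organism=organism,
            q_value=q,
            quantity=_parse_quantity(row_d[COL_QUANTITY]),
            peak_width=_parse_quantity(row_d[peak_width_column]) if pw_present else None,
        )
        if pid in records:
            n_dups += 1
            if q < records[pid].q_value:
                records[pid] = record
        else:
            records[pid] = record
    if n_dups:
        logger.info("collapsed %d duplicate precursor rows in %s", n_dups, path.name)

    return RunReport(
        run_id=run_id,
        lab=str(meta["lab"]),
        day=int(meta["day"]),
        sample=str(meta["sample"]),
        replicate=int(meta["replicate"]),
        records=tuple(records.values()),
    )


_ORG_FASTA = {
    "human": "uniprot_homo_sapiens.fasta",
    "yeast": "uniprot_saccharomyces_cerevisiae.fasta",
    "ecoli": "uniprot_escherichia_coli.fasta",
    "other": "",
}


def _format_float(value: float | None) -> str:
    return "" if value is None else repr(float(value))


def write_report(
    report: RunReport,
    path: str | Path,
    peak_width_column: str = DEFAULT_PEAK_WIDTH_COL,
) -> None:
    """Write a :class:`RunReport` as a Spectronaut-dialect TSV."""
    path = Path(path)
    columns = [
        COL_PRECURSOR,
        COL_ACCESSIONS,
        COL_DESCRIPTIONS,
        COL_QVALUE,
        COL_QUANTITY,
        COL_PG_QUANTITY,
        COL_FASTA,
        COL_GROUPS,
        peak_width_column,
    ]
    lines = ["\t".join(columns)]
    for r in report.records:
        lines.append(
            "\t".join(
                [
                    r.precursor_id,
                    r.protein_group,
                    "",
                    repr(float(r.q_value)),
                    _format_float(r.quantity),
                    "",
                    _ORG_FASTA.get(r.organism, ""),
                    r.protein_group,
                    _format_float(r.peak_width),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


# ---------------------------------------------------------------------------
# manifests


MANIFEST_COLUMNS = ("run_id", "lab", "day", "sample", "replicate", "file")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate a run manifest (TSV or CSV by extension)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest lacks column(s): {', '.join(missing)}")
    if df.empty:
        return df.assign(day=pd.Series(dtype=int), replicate=pd.Series(dtype=int))
    df = df.copy()
    df["day"] = df["day"].astype(int)
    df["replicate"] = df["replicate"].astype(int)
    keys = list(zip(df["lab"], df["day"], df["sample"], df["replicate"]))
    if len(set(keys)) != len(keys):
        dupes = pd.Series(keys).value_counts()
        dup = dupes[dupes > 1].index[0]
        raise ManifestError(f"duplicate run key (lab, day, sample, replicate): {dup}")
    if df["run_id"].duplicated().any():
        raise ManifestError("duplicate run_id in manifest")
    return df


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    manifest.to_csv(path, sep=sep, index=False, lineterminator="\n")


def default_schedule(days: Sequence[int]) -> dict[int, dict[str, int]]:
    """Acquisition schedule: full triplicate days alternate with single-run
    days bracketed by two QC injections."""
    schedule: dict[int, dict[str, int]] = {}
    for day in days:
        if day % 2 == 1:
            schedule[int(day)] = {"QC": 3, "A": 3, "B": 3}
        else:
            schedule[int(day)] = {"QC": 2, "A": 1, "B": 1}
    return schedule


def build_manifest(
    labs: Sequence[str],
    days: Sequence[int],
    schedule: Mapping[int, Mapping[str, int]] | None = None,
    file_template: str = "{run_id}.tsv",
) -> pd.DataFrame:
    """Expand labs x days x schedule into a validated manifest frame."""
    schedule = schedule or default_schedule(days)
    rows = []
    for lab in labs:
        for day in days:
            for sample, n_reps in schedule[int(day)].items():
                for rep in range(1, int(n_reps) + 1):
                    safe_sample = str(sample).replace(":", "-")
                    run_id = f"{lab}_d{day}_{safe_sample}_r{rep}"
                    rows.append(
                        {
                            "run_id": run_id,
                            "lab": lab,
                            "day": int(day),
                            "sample": sample,
                            "replicate": rep,
                            "file": file_template.format(run_id=run_id),
                        }
                    )
    return pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))


# ---------------------------------------------------------------------------
# frame conversion


def reports_to_frame(reports: Iterable[RunReport]) -> pd.DataFrame:
    """Long-format frame of all records with run metadata attached.

    Absent quantities and peak widths become NaN.
    """
    chunks = []
    for rep in reports:
        n = len(rep.records)
        if n == 0:
            continue
        chunks.append(
            pd.DataFrame(
                {
                    "run_id": np.repeat(rep.run_id, n),
                    "lab": np.repeat(rep.lab, n),
                    "day": np.repeat(rep.day, n),
                    "sample": np.repeat(rep.sample, n),
                    "replicate": np.repeat(rep.replicate, n),
                    "precursor_id": [r.precursor_id for r in rep.records],
                    "stripped_sequence": [r.stripped_sequence for r in rep.records],
                    "charge": [r.charge for r in rep.records],
                    "protein_group": [r.protein_group for r in rep.records],
                    "organism": [r.organism for r in rep.records],
                    "q_value": [r.q_value for r in rep.records],
                    "quantity": [
                        np.nan if r.quantity is None else r.quantity
                        for r in rep.records
                    ],
                    "peak_width": [
                        np.nan if r.peak_width is None else r.peak_width
                        for r in rep.records
                    ],
                }
            )
        )
    if not chunks:
        return pd.DataFrame(
            columns=[
                "run_id", "lab", "day", "sample", "replicate", "precursor_id",
                "stripped_sequence", "charge", "protein_group", "organism",
                "q_value", "quantity", "peak_width",
            ]
        )
    return pd.concat(chunks, ignore_index=True)


def load_study_reports(
    manifest_path: str | Path,
    organism_patterns: Mapping[str, Any] | None = None,
    peak_width_column: str = DEFAULT_PEAK_WIDTH_COL,
) -> list[RunReport]:
    """Read every report referenced by a manifest (paths relative to it)."""
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    reports = []
    for entry in manifest.to_dict("records"):
        file_path = Path(entry["file"])
        if not file_path.is_absolute():
            file_path = manifest_path.parent / file_path
        reports.append(
            read_report(file_path, entry, organism_patterns, peak_width_column)
        )
    return reports
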