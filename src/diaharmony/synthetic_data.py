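"""Synthetic multi-laboratory study generator.

Produces precursor-level run reports with the statistical structure the
downstream analysis assumes: known organism mixture ratios, per-peptide
log-normal base abundances, multiplicative replicate noise, per-lab peptide
biases, intensity-dependent (logistic) plus completely-at-random
missingness, charge-state duplication, a q-value mixture, and per-precursor
chromatographic peak widths. A ground-truth object is returned alongside so
parameter-recovery tests can compare estimates against the design exactly.

All distributional forms are generator choices made for realism and
tractability; the mixture compositions and the peak-width scale are the
study design's. With a fixed seed the output is bit-reproducible.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, InvalidParameterError
from .report_io import (
    PrecursorRecord,
    RunReport,
    StudyDesign,
    build_manifest,
    default_schedule,
)

__all__ = [
    "MissingnessSpec",
    "SimulationConfig",
    "GroundTruth",
    "simulate_study",
    "inject_failure",
    "simulate_tissue_cohort",
    "FAILURE_MODES",
]

#: Biognosys iRT kit sequences — synthetic spike-ins, excluded from roll-up.
IRT_SEQUENCES = (
    "LGGNEQVTR",
    "GAGSSEPVTGLDAK",
    "VEATFGVDESNAK",
    "YILAGVENSK",
    "TPVISGGPYEYR",
    "TPVITGAPYEYR",
    "DGLDAASYYAPVR",
    "ADVTPADFSEWSK",
    "GTFIIDPGGVIR",
    "GTFIIDPAAVIR",
    "LFLQFGAQGSPFLK",
)

FAILURE_MODES = ("chromatographic", "ms_sensitivity")

_AMINO_ACIDS = np.array(list("ACDEFGHILMNPQSTVWY"))


@dataclass(frozen=True)
class MissingnessSpec:
    """Drop probability: logistic in log10 intensity plus a MCAR floor.

    ``p_drop = 1 / (1 + exp(slope * (log10(q) - midpoint)))`` combined with
    ``random_rate`` by inclusion-exclusion; lower intensity means a higher
    drop probability whenever ``slope > 0``.
    """

    midpoint: float = 3.0
    slope: float = 2.0
    random_rate: float = 0.02

    def drop_probability(self, quantity: np.ndarray) -> np.ndarray:
        logq = np.log10(np.asarray(quantity, dtype=float))
        p_int = 1.0 / (1.0 + np.exp(self.slope * (logq - self.midpoint)))
        return p_int + self.random_rate - p_int * self.random_rate


@dataclass(frozen=True)
class SimulationConfig:
    """Desk-scale defaults (~1/10 of observed study magnitudes)."""

    n_proteins: Mapping[str, int] = field(
        default_factory=lambda: {"human": 400, "yeast": 200, "ecoli": 100}
    )
    peptides_per_protein_mean: float = 4.0  # count = 1 + Poisson(mean)
    log10_abundance_mean: float = 5.0
    log10_abundance_sd: float = 0.8
    peptide_log10_sd: float = 0.4  # per-peptide ionization spread
    precursor_log10_sd: float = 0.2  # per-charge-state split
    noise_cv: float = 0.10
    lab_effect_sd: float = 0.05  # sd of per-lab per-peptide log2 bias
    day_effect_sd: float = 0.0  # sd of per-(lab, day) global log2 shift
    missingness: MissingnessSpec | None = field(default_factory=MissingnessSpec)
    charge_dup_prob: float = 0.2
    q_pass_rate: float = 0.99
    fdr_q: float = 0.01
    peak_width_mean: float = 17.0
    peak_width_sd: float = 1.5
    peak_width_min: float = 4.0
    n_irt: int = 11
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("charge_dup_prob", "q_pass_rate"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        if self.n_irt > len(IRT_SEQUENCES):
            raise ConfigError(f"at most {len(IRT_SEQUENCES)} iRT peptides available")

    def scaled(self, factor: float) -> "SimulationConfig":
        """Copy with protein counts multiplied by ``factor`` (full-scale runs)."""
        counts = {k: max(1, int(round(v * factor))) for k, v in self.n_proteins.items()}
        return replace(self, n_proteins=counts)


@dataclass(frozen=True)
class GroundTruth:
    """True abundances underlying a simulated study."""

    proteins: pd.DataFrame  # index protein_group: organism, base, per-sample truth
    peptides: pd.DataFrame  # index stripped_sequence: protein_group, organism, base
    design: StudyDesign | None = None
    signature_proteins: tuple[str, ...] = ()
    histotypes: Mapping[str, str] | None = None  # patient -> group label


# ---------------------------------------------------------------------------
# proteome construction


def _random_sequences(n: int, rng: np.random.Generator) -> list[str]:
    seqs: list[str] = []
    seen: set[str] = set()
    while len(seqs) < n:
        length = int(rng.integers(7, 15))
        body = "".join(rng.choice(_AMINO_ACIDS, size=length))
        seq = body + ("K" if rng.random() < 0.5 else "R")
        if seq not in seen and seq not in IRT_SEQUENCES:
            seen.add(seq)
            seqs.append(seq)
    return seqs


_ACC_SUFFIX = {"human": "_HUMAN", "yeast": "_YEAST", "ecoli": "_ECOLI"}


def _build_proteome(sim: SimulationConfig, rng: np.random.Generator):
    """Draw proteins, peptides, and charge-state precursors.

    Returns (proteins frame, peptides frame, precursors frame). Peptide base
    quantity is the protein's base abundance times a log-normal ionization
    factor, so low-abundance proteins have coherently low peptides.
    """
    prot_rows = []
    for organism, count in sim.n_proteins.items():
        if count < 1:
            raise ConfigError(f"requested {count} proteins for organism {organism}")
        suffix = _ACC_SUFFIX.get(organism, "_OTHER")
        for i in range(count):
            prot_rows.append(
                {
                    "protein_group": f"P{len(prot_rows):05d}{suffix}",
                    "organism": organism,
                }
            )
    proteins = pd.DataFrame(prot_rows)
    n_prot = len(proteins)
    proteins["base_abundance"] = 10.0 ** rng.normal(
        sim.log10_abundance_mean, sim.log10_abundance_sd, size=n_prot
    )

    pep_counts = 1 + rng.poisson(sim.peptides_per_protein_mean, size=n_prot)
    n_pep = int(pep_counts.sum())
    sequences = _random_sequences(n_pep, rng)
    pep_protein_idx = np.repeat(np.arange(n_prot), pep_counts)
    ionization = 10.0 ** rng.normal(0.0, sim.peptide_log10_sd, size=n_pep)
    peptides = pd.DataFrame(
        {
            "stripped_sequence": sequences,
            "protein_group": proteins["protein_group"].to_numpy()[pep_protein_idx],
            "organism": proteins["organism"].to_numpy()[pep_protein_idx],
            "base_quantity": proteins["base_abundance"].to_numpy()[pep_protein_idx]
            * ionization,
        }
    )

    base_charge = np.where(rng.random(n_pep) < 0.7, 2, 3)
    dup = rng.random(n_pep) < sim.charge_dup_prob
    pep_idx = np.concatenate([np.arange(n_pep), np.flatnonzero(dup)])
    charges = np.concatenate([base_charge, np.where(base_charge[dup] == 2, 3, 2)])
    charge_split = 10.0 ** rng.normal(0.0, sim.precursor_log10_sd, size=len(pep_idx))
    precursors = pd.DataFrame(
        {
            "peptide_index": pep_idx,
            "stripped_sequence": peptides["stripped_sequence"].to_numpy()[pep_idx],
            "protein_group": peptides["protein_group"].to_numpy()[pep_idx],
            "organism": peptides["organism"].to_numpy()[pep_idx],
            "charge": charges,
            "base_quantity": peptides["base_quantity"].to_numpy()[pep_idx]
            * charge_split,
        }
    ).sort_values(["stripped_sequence", "charge"], ignore_index=True)
    return proteins, peptides, precursors


def _lognormal_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


def _draw_peak_widths(sim: SimulationConfig, n: int, rng: np.random.Generator):
    a = (sim.peak_width_min - sim.peak_width_mean) / sim.peak_width_sd
    return stats.truncnorm.rvs(
        a, np.inf, loc=sim.peak_width_mean, scale=sim.peak_width_sd,
        size=n, random_state=rng,
    )


def _draw_qvalues(sim: SimulationConfig, n: int, rng: np.random.Generator):
    passing = rng.random(n) < sim.q_pass_rate
    q = np.empty(n)
    q[passing] = rng.uniform(0.0, sim.fdr_q, size=int(passing.sum()))
    q[~passing] = rng.uniform(
        np.nextafter(sim.fdr_q, 1.0), 1.0, size=int((~passing).sum())
    )
    return q


def _emit_run(
    meta: Mapping[str, object],
    expected: np.ndarray,
    precursors: pd.DataFrame,
    sim: SimulationConfig,
    rng: np.random.Generator,
) -> RunReport:
    """Apply noise, missingness, q-values, and peak widths; build the report."""
    present_mask = expected > 0
    idx = np.flatnonzero(present_mask)
    n = len(idx)
    sigma = _lognormal_sigma(sim.noise_cv)
    noise = np.exp(rng.normal(0.0, sigma, size=n)) if sigma > 0 else np.ones(n)
    quantity = expected[idx] * noise

    if sim.missingness is not None:
        dropped = rng.random(n) < sim.missingness.drop_probability(quantity)
    else:
        dropped = np.zeros(n, dtype=bool)
    q_values = _draw_qvalues(sim, n, rng)
    peak_widths = _draw_peak_widths(sim, n, rng)

    seqs = precursors["stripped_sequence"].to_numpy()[idx]
    charges = precursors["charge"].to_numpy()[idx]
    groups = precursors["protein_group"].to_numpy()[idx]
    organisms = precursors["organism"].to_numpy()[idx]

    records = [
        PrecursorRecord(
            precursor_id=f"{seqs[i]}.{charges[i]}",
            stripped_sequence=seqs[i],
            charge=int(charges[i]),
            protein_group=groups[i],
            organism=organisms[i],
            q_value=float(q_values[i]),
            quantity=None if dropped[i] else float(quantity[i]),
            peak_width=float(peak_widths[i]),
        )
        for i in range(n)
    ]

    # iRT spike-ins at a fixed nominal level, flagged "other"
    irt_level = 10.0 ** sim.log10_abundance_mean
    irt_noise = (
        np.exp(rng.normal(0.0, sigma, size=sim.n_irt)) if sigma > 0
        else np.ones(sim.n_irt)
    )
    irt_widths = _draw_peak_widths(sim, sim.n_irt, rng)
    for j in range(sim.n_irt):
        records.append(
            PrecursorRecord(
                precursor_id=f"{IRT_SEQUENCES[j]}.2",
                stripped_sequence=IRT_SEQUENCES[j],
                charge=2,
                protein_group="iRT_KIT",
                organism="other",
                q_value=0.0001,
                quantity=float(irt_level * irt_noise[j]),
                peak_width=float(irt_widths[j]),
            )
        )

    return RunReport(
        run_id=str(meta["run_id"]),
        lab=str(meta["lab"]),
        day=int(meta["day"]),
        sample=str(meta["sample"]),
        replicate=int(meta["replicate"]),
        records=tuple(records),
    )


# ---------------------------------------------------------------------------
# controlled-sample study


def simulate_study(
    design: StudyDesign,
    sim: SimulationConfig,
    labs: Sequence[str],
    days: Sequence[int],
) -> tuple[list[RunReport], GroundTruth]:
    """Simulate one controlled-sample study over ``labs`` x ``days``.

    Run slots follow the design's replicate schedule (default: triplicate
    QC/A/B on odd days, two QC plus one A and one B on even days). A run's
    expected peptide quantity is ``base x composition fraction x per-lab
    peptide bias x per-(lab, day) shift``; multiplicative log-normal noise
    and the missingness model are applied on top.
    """
    if not labs or not days:
        raise ConfigError("labs and days must be non-empty")
    rng = np.random.default_rng(sim.seed)
    proteins, peptides, precursors = _build_proteome(sim, rng)

    schedule = dict(design.replicate_schedule or default_schedule(days))
    manifest = build_manifest(labs, days, schedule)

    frac_by_org = {
        sample: design.composition(sample) for sample in {"QC", "A", "B"}
    }
    org_arr = precursors["organism"].to_numpy()
    base = precursors["base_quantity"].to_numpy()
    n_prec = len(precursors)
    pep_idx = precursors["peptide_index"].to_numpy()
    n_pep = len(peptides)

    lab_bias = {
        lab: (
            2.0 ** rng.normal(0.0, sim.lab_effect_sd, size=n_pep)
            if sim.lab_effect_sd > 0
            else np.ones(n_pep)
        )
        for lab in labs
    }
    day_shift = {
        (lab, int(day)): (
            2.0 ** rng.normal(0.0, sim.day_effect_sd)
            if sim.day_effect_sd > 0
            else 1.0
        )
        for lab in labs
        for day in days
    }

    frac_vectors = {}
    for sample, comp in frac_by_org.items():
        frac = np.zeros(n_prec)
        for org, f in comp.items():
            frac[org_arr == org] = f
        frac_vectors[sample] = frac

    reports = []
    for entry in manifest.to_dict("records"):
        expected = (
            base
            * frac_vectors[str(entry["sample"])]
            * lab_bias[str(entry["lab"])][pep_idx]
            * day_shift[(str(entry["lab"]), int(entry["day"]))]
        )
        reports.append(_emit_run(entry, expected, precursors, sim, rng))

    truth_proteins = proteins.set_index("protein_group").copy()
    truth_peptides = peptides.set_index("stripped_sequence").copy()
    for sample in ("A", "B"):
        comp = design.composition(sample)
        truth_proteins[f"abundance_{sample}"] = truth_proteins[
            "base_abundance"
        ] * truth_proteins["organism"].map(lambda o: comp.get(o, 0.0))
        truth_peptides[f"expected_{sample}"] = truth_peptides[
            "base_quantity"
        ] * truth_peptides["organism"].map(lambda o: comp.get(o, 0.0))
    truth = GroundTruth(proteins=truth_proteins, peptides=truth_peptides, design=design)
    return reports, truth


# ---------------------------------------------------------------------------
# failure injection


def inject_failure(
    reports: Iterable[RunReport],
    mode: str,
    severity: float,
    seed: int = 0,
) -> list[RunReport]:
    """Degrade reports so QC triage can discriminate the failure class.

    ``chromatographic`` inflates every peak width by ``1 + 2 * severity``
    and jitters quantities (broadened peaks integrate noisily) without
    removing records. ``ms_sensitivity`` leaves peak widths untouched but
    deletes the lowest-intensity fraction of records (0.6 * severity of the
    quantified records per run) and attenuates the survivors.
    """
    if mode not in FAILURE_MODES:
        raise InvalidParameterError(
            f"unknown failure mode {mode!r}; expected one of {FAILURE_MODES}"
        )
    if not (0.0 <= severity <= 1.0):
        raise InvalidParameterError(f"severity must be in [0, 1], got {severity}")
    reports = list(reports)
    if not reports:
        raise InvalidParameterError("reports collection is empty")
    if severity == 0:
        return reports

    rng = np.random.default_rng(seed)
    out = []
    for rep in reports:
        if mode == "chromatographic":
            jitter_sigma = _lognormal_sigma(0.05 * severity)
            new_records = tuple(
                PrecursorRecord(
                    precursor_id=r.precursor_id,
                    stripped_sequence=r.stripped_sequence,
                    charge=r.charge,
                    protein_group=r.protein_group,
                    organism=r.organism,
                    q_value=r.q_value,
                    quantity=(
                        None
                        if r.quantity is None
                        else float(r.quantity * np.exp(rng.normal(0, jitter_sigma)))
                    ),
                    peak_width=(
                        None
                        if r.peak_width is None
                        else float(r.peak_width * (1.0 + 2.0 * severity))
                    ),
                )
                for r in rep.records
            )
        else:  # ms_sensitivity
            quantities = np.array(
                [np.nan if r.quantity is None else r.quantity for r in rep.records]
            )
            present = ~np.isnan(quantities)
            threshold = (
                np.quantile(quantities[present], 0.6 * severity)
                if present.any()
                else -np.inf
            )
            attenuation = 1.0 - 0.5 * severity
            new_records = tuple(
                PrecursorRecord(
                    precursor_id=r.precursor_id,
                    stripped_sequence=r.stripped_sequence,
                    charge=r.charge,
                    protein_group=r.protein_group,
                    organism=r.organism,
                    q_value=r.q_value,
                    quantity=(
                        None if r.quantity is None
                        else float(r.quantity * attenuation)
                    ),
                    peak_width=r.peak_width,
                )
                for r, q in zip(rep.records, quantities)
                if np.isnan(q) or q > threshold
            )
        out.append(rep.with_records(new_records))
    return out


# ---------------------------------------------------------------------------
# tissue cohort


def simulate_tissue_cohort(
    n_patients_per_histotype: int,
    n_signature_proteins: int,
    effect_log2fc: float,
    sim: SimulationConfig,
    sites: Sequence[str],
    histotype_labels: tuple[str, str] = ("HGSOC", "OCCC"),
    n_replicates: int = 3,
) -> tuple[list[RunReport], GroundTruth]:
    """Two-histotype tissue cohort, technical triplicates per patient per site.

    A designated subset of proteins carries ``effect_log2fc`` (second
    histotype over first); all other proteins differ only by noise.
    """
    if n_patients_per_histotype < 1:
        raise ConfigError("n_patients_per_histotype must be >= 1")
    rng = np.random.default_rng(sim.seed)
    proteins, peptides, precursors = _build_proteome(sim, rng)
    if n_signature_proteins > len(proteins):
        raise ConfigError(
            f"{n_signature_proteins} signature proteins requested but only "
            f"{len(proteins)} simulated"
        )
    signature = tuple(
        rng.choice(
            proteins["protein_group"].to_numpy(), n_signature_proteins, replace=False
        )
    )
    in_signature = precursors["protein_group"].isin(signature).to_numpy()

    patients = [
        (f"{label}_{i + 1}", label)
        for label in histotype_labels
        for i in range(n_patients_per_histotype)
    ]
    histotypes = dict(patients)

    base = precursors["base_quantity"].to_numpy()
    pep_idx = precursors["peptide_index"].to_numpy()
    n_pep = len(peptides)
    site_bias = {
        site: (
            2.0 ** rng.normal(0.0, sim.lab_effect_sd, size=n_pep)
            if sim.lab_effect_sd > 0
            else np.ones(n_pep)
        )
        for site in sites
    }
    effect = np.where(in_signature, 2.0 ** effect_log2fc, 1.0)

    reports = []
    for site in sites:
        for patient, label in patients:
            expected = base * site_bias[site][pep_idx]
            if label == histotype_labels[1]:
                expected = expected * effect
            for rep_i in range(1, n_replicates + 1):
                meta = {
                    "run_id": f"{site}_{patient}_r{rep_i}",
                    "lab": site,
                    "day": 1,
                    "sample": f"tissue:{patient}",
                    "replicate": rep_i,
                }
                reports.append(_emit_run(meta, expected, precursors, sim, rng))

    truth_proteins = proteins.set_index("protein_group").copy()
    truth_proteins["is_signature"] = truth_proteins.index.isin(signature)
    truth = GroundTruth(
        proteins=truth_proteins,
        peptides=peptides.set_index("stripped_sequence").copy(),
        signature_proteins=signature,
        histotypes=histotypes,
    )
    return reports, truth
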