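import numpy as np
import pytest

from diaharmony.dia_method import build_window_scheme
from diaharmony.report_io import PrecursorRecord, RunReport, StudyDesign
from diaharmony.synthetic_data import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def default_method():
    return build_window_scheme(400, 1210, 15, 18, ms1_cycle_time=1.7, ms2_cycle_time=5.2)


@pytest.fixture(scope="session")
def default_design():
    return StudyDesign(
        composition_a={"human": 0.65, "yeast": 0.15, "ecoli": 0.20},
        composition_b={"human": 0.65, "yeast": 0.30, "ecoli": 0.05},
    )


@pytest.fixture(scope="session")
def zero_noise_sim():
    return SimulationConfig(
        n_proteins={"human": 30, "yeast": 15, "ecoli": 10},
        noise_cv=0.0,
        lab_effect_sd=0.0,
        missingness=None,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_sim():
    return SimulationConfig(
        n_proteins={"human": 60, "yeast": 30, "ecoli": 15},
        seed=7,
    )


@pytest.fixture(scope="session")
def zero_noise_study(default_design, zero_noise_sim):
    return simulate_study(default_design, zero_noise_sim, ["L1"], [1])


@pytest.fixture(scope="session")
def small_study(default_design, small_sim):
    return simulate_study(default_design, small_sim, ["L1"], [1])


def make_record(
    seq="PEPTIDEK",
    charge=2,
    protein="P00001_HUMAN",
    organism="human",
    q=0.001,
    quantity=100.0,
    peak_width=17.0,
):
    return PrecursorRecord(
        precursor_id=f"{seq}.{charge}",
        stripped_sequence=seq,
        charge=charge,
        protein_group=protein,
        organism=organism,
        q_value=q,
        quantity=quantity,
        peak_width=peak_width,
    )


def make_run(run_id, records, lab="L1", day=1, sample="QC", replicate=1):
    return RunReport(
        run_id=run_id,
        lab=lab,
        day=day,
        sample=sample,
        replicate=replicate,
        records=tuple(records),
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def run_factory():
    return make_run


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260905)
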