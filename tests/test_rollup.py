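import itertools
import math

import numpy as np
import pandas as pd
import pytest

from diaharmony.errors import DiaHarmonyError, InvalidParameterError
from diaharmony.report_io import reports_to_frame
from diaharmony.rollup import (
    PeptideMatrix,
    count_combinations,
    filter_q,
    log2fc_vs_mean,
    pairwise_log_ratio_table,
    pairwise_ratio,
    peptide_combination_counts,
    remove_shared_peptides,
    retain_proteins,
    rollup_pairwise,
    select_best_charge,
    sum_rollup,
)

RUNS_A = ["a1", "a2", "a3"]
RUNS_B = ["b1", "b2", "b3"]


def make_records(rows):
    """rows: (run_id, sample, seq, charge, protein, organism, q, quantity)"""
    return pd.DataFrame(
        rows,
        columns=[
            "run_id", "sample", "stripped_sequence", "charge",
            "protein_group", "organism", "q_value", "quantity",
        ],
    ).assign(lab="L1", day=1)


def make_matrix(quantities: dict, protein="P1", organism="human"):
    """quantities: {seq: {run: value}} with NaN for absent."""
    q = pd.DataFrame(quantities).T.reindex(columns=RUNS_A + RUNS_B)
    q.index.name = "stripped_sequence"
    meta = pd.DataFrame(
        {
            "protein_group": protein,
            "organism": organism,
            "charge": 2,
        },
        index=q.index,
    )
    return PeptideMatrix(quantities=q, meta=meta)


class TestFilterQ:
    def test_inclusive_bound(self):
        df = make_records(
            [
                ("a1", "A", "S1", 2, "P1", "human", 0.005, 10.0),
                ("a1", "A", "S2", 2, "P1", "human", 0.01, 10.0),
                ("a1", "A", "S3", 2, "P1", "human", 0.011, 10.0),
            ]
        )
        assert len(filter_q(df, 0.01)) == 2

    def test_empty_input(self):
        df = make_records([])
        assert len(filter_q(df, 0.01)) == 0

    def test_all_passing_identity(self):
        df = make_records(
            [("a1", "A", f"S{i}", 2, "P1", "human", 0.001, 1.0) for i in range(5)]
        )
        assert filter_q(df, 0.01).equals(df)

    def test_absent_quantity_dropped(self):
        df = make_records([("a1", "A", "S1", 2, "P1", "human", 0.001, np.nan)])
        assert len(filter_q(df, 0.01)) == 0

    def test_bad_fdr_rejected(self):
        with pytest.raises(InvalidParameterError):
            filter_q(make_records([]), 0.0)


class TestRemoveShared:
    def test_cross_organism_sequence_dropped(self):
        df = make_records(
            [
                ("a1", "A", "SHARED", 2, "P1", "human", 0.001, 1.0),
                ("b1", "B", "SHARED", 2, "P2", "yeast", 0.001, 1.0),
                ("a1", "A", "UNIQ", 2, "P3", "ecoli", 0.001, 1.0),
            ]
        )
        out = remove_shared_peptides(df)
        assert set(out["stripped_sequence"]) == {"UNIQ"}

    def test_other_records_dropped(self):
        df = make_records(
            [("a1", "A", f"IRT{i}", 2, "iRT_KIT", "other", 0.001, 1.0) for i in range(11)]
        )
        assert len(remove_shared_peptides(df)) == 0

    def test_disjoint_identity(self):
        df = make_records(
            [
                ("a1", "A", "S1", 2, "P1", "human", 0.001, 1.0),
                ("a1", "A", "S2", 2, "P2", "yeast", 0.001, 1.0),
            ]
        )
        assert remove_shared_peptides(df).equals(df)


class TestSelectBestCharge:
    def _df(self, presence2, presence3, q2=10.0, q3=10.0):
        runs = RUNS_A + RUNS_B
        rows = []
        for i, run in enumerate(runs):
            if presence2[i]:
                rows.append((run, "A", "SEQ", 2, "P1", "human", 0.001, q2))
            if presence3[i]:
                rows.append((run, "A", "SEQ", 3, "P1", "human", 0.001, q3))
        return make_records(rows)

    def test_majority_coverage_wins(self):
        df = self._df([1] * 6, [1, 1, 1, 1, 0, 0])
        matrix = select_best_charge(df, RUNS_A + RUNS_B)
        assert matrix.meta.loc["SEQ", "charge"] == 2

    def test_single_charge_kept(self):
        df = self._df([1, 1, 0, 0, 0, 0], [0] * 6)
        matrix = select_best_charge(df, RUNS_A + RUNS_B)
        assert matrix.meta.loc["SEQ", "charge"] == 2

    def test_tie_broken_by_total_intensity(self):
        df = self._df([1, 1, 1, 1, 1, 0], [0, 1, 1, 1, 1, 1], q2=10.0, q3=99.0)
        matrix = select_best_charge(df, RUNS_A + RUNS_B)
        assert matrix.meta.loc["SEQ", "charge"] == 3

    def test_full_tie_prefers_lower_charge(self):
        df = self._df([1, 1, 1, 1, 1, 0], [0, 1, 1, 1, 1, 1], q2=10.0, q3=10.0)
        matrix = select_best_charge(df, RUNS_A + RUNS_B)
        assert matrix.meta.loc["SEQ", "charge"] == 2

    def test_kept_quantities_are_the_selected_precursors(self):
        df = self._df([1] * 6, [1] * 6, q2=7.0, q3=99.0)
        # equal coverage; charge 3 has larger total
        matrix = select_best_charge(df, RUNS_A + RUNS_B)
        assert (matrix.quantities.loc["SEQ"] == 99.0).all()


class TestCountCombinations:
    def test_full_presence(self):
        row = {r: 1.0 for r in RUNS_A + RUNS_B}
        assert count_combinations(row, RUNS_A, RUNS_B) == 9

    def test_partial(self):
        row = {"a1": 1.0, "a2": 1.0, "b1": 1.0}
        assert count_combinations(row, RUNS_A, RUNS_B) == 2

    def test_absent_side(self):
        row = {"b1": 1.0, "b2": 1.0}
        assert count_combinations(row, RUNS_A, RUNS_B) == 0

    def test_vectorized_matches_scalar(self, rng):
        matrix = make_matrix(
            {
                f"S{i}": {
                    r: (rng.uniform(1, 10) if rng.random() < 0.7 else np.nan)
                    for r in RUNS_A + RUNS_B
                }
                for i in range(20)
            }
        )
        vec = peptide_combination_counts(matrix, RUNS_A, RUNS_B)
        for seq in matrix.quantities.index:
            assert vec[seq] == count_combinations(
                matrix.quantities.loc[seq], RUNS_A, RUNS_B
            )


class TestRetainProteins:
    def test_nine_combinations_retained(self):
        matrix = make_matrix({"S1": {r: 1.0 for r in RUNS_A + RUNS_B}})
        combos = peptide_combination_counts(matrix, RUNS_A, RUNS_B)
        out = retain_proteins(matrix, combos)
        assert out.loc[0, "n_combinations"] == 9
        assert bool(out.loc[0, "retained"])

    def test_seven_combinations_dropped(self):
        # peptide 1: 2x2=4, peptide 2: 3x1=3 -> 7 < 8
        matrix = make_matrix(
            {
                "S1": {"a1": 1.0, "a2": 1.0, "b1": 1.0, "b2": 1.0},
                "S2": {"a1": 1.0, "a2": 1.0, "a3": 1.0, "b1": 1.0},
            }
        )
        combos = peptide_combination_counts(matrix, RUNS_A, RUNS_B)
        out = retain_proteins(matrix, combos)
        assert out.loc[0, "n_combinations"] == 7
        assert not bool(out.loc[0, "retained"])

    def test_threshold_monotonicity(self, rng):
        matrix = make_matrix(
            {
                f"S{i}": {
                    r: (rng.uniform(1, 10) if rng.random() < 0.5 else np.nan)
                    for r in RUNS_A + RUNS_B
                }
                for i in range(30)
            },
        )
        combos = peptide_combination_counts(matrix, RUNS_A, RUNS_B)
        sets = {}
        for threshold in (2, 5, 8, 12):
            out = retain_proteins(matrix, combos, threshold)
            sets[threshold] = set(out.loc[out["retained"], "protein_group"])
        assert sets[12] <= sets[8] <= sets[5] <= sets[2]


class TestPairwiseRatio:
    def test_identity_ratio(self):
        matrix = make_matrix({"S1": {r: 5.0 for r in RUNS_A + RUNS_B}})
        assert pairwise_ratio(matrix, "P1", RUNS_A, RUNS_B) == pytest.approx(1.0)

    def test_median_not_mean(self):
        # pairings yield ratios {2, 2, 8}: median-of-logs gives 2, not the
        # geometric mean 2 * cbrt(4) ~ 3.17
        matrix = make_matrix(
            {
                "S1": {"a1": 2.0, "b1": 1.0},
                "S2": {"a2": 2.0, "b2": 1.0},
                "S3": {"a3": 8.0, "b3": 1.0},
            }
        )
        assert pairwise_ratio(matrix, "P1", RUNS_A, RUNS_B) == pytest.approx(2.0)
        geo_mean = pairwise_ratio(
            matrix, "P1", RUNS_A, RUNS_B, estimator="geometric_mean"
        )
        assert geo_mean == pytest.approx((2 * 2 * 8) ** (1 / 3))

    def test_even_count_averages_central_logs(self):
        matrix = make_matrix(
            {
                "S1": {"a1": 2.0, "b1": 1.0},
                "S2": {"a2": 8.0, "b2": 1.0},
            }
        )
        assert pairwise_ratio(matrix, "P1", RUNS_A, RUNS_B) == pytest.approx(4.0)

    def test_no_pairings_raises(self):
        matrix = make_matrix({"S1": {"a1": 1.0}})
        with pytest.raises(DiaHarmonyError):
            pairwise_ratio(matrix, "P1", RUNS_A, RUNS_B)

    def test_scale_equivariance(self, rng):
        values = {
            f"S{i}": {
                r: (rng.uniform(1, 100) if rng.random() < 0.8 else np.nan)
                for r in RUNS_A + RUNS_B
            }
            for i in range(5)
        }
        matrix = make_matrix(values)
        base = pairwise_ratio(matrix, "P1", RUNS_A, RUNS_B)
        c = 3.7
        scaled = {
            seq: {
                r: (v * c if r in RUNS_A else v) for r, v in row.items()
            }
            for seq, row in values.items()
        }
        assert pairwise_ratio(
            make_matrix(scaled), "P1", RUNS_A, RUNS_B
        ) == pytest.approx(c * base, rel=1e-12)

    def test_median_breakdown_robustness(self, rng):
        # corrupting <50% of pairwise ratios leaves the estimate within the
        # span of the uncorrupted ratios
        matrix = make_matrix(
            {f"S{i}": {r: rng.uniform(9, 11) for r in RUNS_A + RUNS_B} for i in range(3)}
        )
        table = pairwise_log_ratio_table(matrix, RUNS_A, RUNS_B)
        clean = np.exp(table["log_ratio"].to_numpy())
        n = len(clean)
        corrupted = clean.copy()
        k = n // 2 - 1  # strictly less than half
        corrupted[:k] *= 1e6
        estimate = np.exp(np.median(np.log(corrupted)))
        assert clean.min() <= estimate <= clean.max()


def brute_force_rollup(matrix, runs_a, runs_b):
    """Independent enumeration oracle for combination counts and ratios."""
    combos_by_protein: dict = {}
    ratios_by_protein: dict = {}
    for seq in matrix.quantities.index:
        protein = matrix.meta.loc[seq, "protein_group"]
        row = matrix.quantities.loc[seq]
        present_a = [r for r in runs_a if not math.isnan(row[r])]
        present_b = [r for r in runs_b if not math.isnan(row[r])]
        combos_by_protein[protein] = combos_by_protein.get(protein, 0) + len(
            present_a
        ) * len(present_b)
        for a, b in itertools.product(present_a, present_b):
            ratios_by_protein.setdefault(protein, []).append(row[a] / row[b])
    medians = {
        p: math.exp(float(np.median(np.log(r)))) for p, r in ratios_by_protein.items()
    }
    return combos_by_protein, medians


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_random_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n_pep = int(rng.integers(1, 6))
        n_rep = int(rng.integers(1, 4))
        runs_a = [f"a{i}" for i in range(n_rep)]
        runs_b = [f"b{i}" for i in range(n_rep)]
        q = pd.DataFrame(
            np.where(rng.random((n_pep, 2 * n_rep)) < 0.7,
                     rng.uniform(1, 100, (n_pep, 2 * n_rep)), np.nan),
            index=pd.Index([f"S{i}" for i in range(n_pep)], name="stripped_sequence"),
            columns=runs_a + runs_b,
        )
        meta = pd.DataFrame(
            {
                "protein_group": [f"P{i % 2}" for i in range(n_pep)],
                "organism": "human",
                "charge": 2,
            },
            index=q.index,
        )
        matrix = PeptideMatrix(quantities=q, meta=meta)

        expected_combos, expected_ratios = brute_force_rollup(matrix, runs_a, runs_b)
        combos = peptide_combination_counts(matrix, runs_a, runs_b)
        by_protein = (
            matrix.meta.assign(c=combos).groupby("protein_group")["c"].sum()
        )
        for protein, count in expected_combos.items():
            assert by_protein[protein] == count
        for protein, expected in expected_ratios.items():
            got = pairwise_ratio(matrix, protein, runs_a, runs_b)
            assert got == pytest.approx(expected, rel=1e-12)


class TestEndToEnd:
    def test_zero_noise_recovery_exact(self, zero_noise_study, default_design):
        reports, _ = zero_noise_study
        table = rollup_pairwise(reports)
        retained = table[table["retained"]]
        assert len(retained) > 0
        for organism in ("human", "yeast", "ecoli"):
            expected = default_design.theoretical_ratio(organism)
            ratios = retained.loc[retained["organism"] == organism, "ratio_ab"]
            assert len(ratios) > 0
            assert np.allclose(ratios, expected, rtol=1e-9)

    def test_irt_never_retained(self, small_study):
        reports, _ = small_study
        table = rollup_pairwise(reports)
        assert "iRT_KIT" not in set(table["protein_group"])

    def test_noisy_recovery_converges(self, small_study, default_design):
        reports, _ = small_study
        table = rollup_pairwise(reports)
        retained = table[table["retained"]]
        for organism in ("human", "yeast", "ecoli"):
            expected = default_design.theoretical_ratio(organism)
            med = retained.loc[retained["organism"] == organism, "ratio_ab"].median()
            assert abs(med - expected) / expected < 0.10


class TestSumRollup:
    def _matrix(self, values):
        return make_matrix(values)

    def test_three_observations_retained(self):
        matrix = self._matrix({"S1": {"a1": 1.0, "a2": 1.0, "a3": 1.0}})
        out = sum_rollup(matrix, {"g": RUNS_A}, min_obs=3)
        assert bool(out.loc[0, "retained"])
        assert out.loc[0, "n_obs"] == 3

    def test_two_observations_dropped(self):
        matrix = self._matrix({"S1": {"a1": 1.0}, "S2": {"a2": 1.0}})
        out = sum_rollup(matrix, {"g": RUNS_A}, min_obs=3)
        assert not bool(out.loc[0, "retained"])
        assert np.isnan(out.loc[0, "abundance"])

    def test_abundance_sums_then_averages(self):
        matrix = self._matrix(
            {
                "S1": {"a1": 10.0, "a2": 20.0, "a3": 30.0},
                "S2": {"a1": 1.0, "a2": 2.0, "a3": 3.0},
            }
        )
        out = sum_rollup(matrix, {"g": RUNS_A}, min_obs=3)
        assert out.loc[0, "abundance"] == pytest.approx((11 + 22 + 33) / 3)

    def test_identical_samples_zero_log2fc(self):
        abund = pd.DataFrame({"s1": [4.0, 8.0], "s2": [4.0, 8.0]}, index=["P1", "P2"])
        fc = log2fc_vs_mean(abund)
        assert np.allclose(fc.to_numpy(), 0.0)
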