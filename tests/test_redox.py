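"""Oxidation ratios, differential testing and the dual redox ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from targetrank.redox import (
    add_oxidation_ratios,
    best_peptide_per_protein,
    complete_case_filter,
    oxidation_ratio,
    peptide_differential_oxidation,
    redox_dual_rank,
    student_t_two_tailed,
)


def redox_rows(records) -> pd.DataFrame:
    """records: (peptide, protein, condition, replicate, label1, label2)."""
    return pd.DataFrame(
        records,
        columns=[
            "peptide_id", "protein_id", "condition", "replicate",
            "label1_abundance", "label2_abundance",
        ],
    )


class TestOxidationRatio:
    def test_basic_fraction(self):
        assert oxidation_ratio(70.0, 30.0) == pytest.approx(0.30)

    def test_fully_oxidized(self):
        assert oxidation_ratio(0.0, 12.0) == 1.0

    def test_fully_reduced(self):
        assert oxidation_ratio(12.0, 0.0) == 0.0

    def test_both_zero_is_missing(self):
        assert np.isnan(oxidation_ratio(0.0, 0.0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            oxidation_ratio(-1.0, 5.0)

    def test_labelling_depth_invariance(self):
        rng = np.random.default_rng(2)
        l1, l2 = rng.uniform(1, 100, 50), rng.uniform(1, 100, 50)
        scale = rng.uniform(0.1, 10, 50)
        np.testing.assert_allclose(
            oxidation_ratio(l1 * scale, l2 * scale), oxidation_ratio(l1, l2)
        )

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(4)
        r = oxidation_ratio(rng.uniform(0, 10, 200), rng.uniform(0, 10, 200))
        valid = r[~np.isnan(r)]
        assert np.all((valid >= 0) & (valid <= 1))


class TestCompleteCaseFilter:
    def test_peptide_missing_one_replicate_dropped(self):
        table = redox_rows(
            [
                ("p1", "A", "vehicle", 1, 70, 30),
                ("p1", "A", "vehicle", 2, 70, 30),
                ("p1", "A", "drug", 1, 50, 50),
                ("p1", "A", "drug", 2, np.nan, np.nan),
                ("p2", "A", "vehicle", 1, 70, 30),
                ("p2", "A", "vehicle", 2, 70, 30),
                ("p2", "A", "drug", 1, 50, 50),
                ("p2", "A", "drug", 2, 50, 50),
            ]
        )
        kept = complete_case_filter(table)
        assert set(kept["peptide_id"]) == {"p2"}

    def test_zero_sum_pair_counts_as_missing(self):
        table = redox_rows(
            [
                ("p1", "A", "vehicle", 1, 0, 0),
                ("p1", "A", "drug", 1, 50, 50),
            ]
        )
        assert complete_case_filter(table).empty

    def test_survivor_count_matches_enumeration(self):
        rng = np.random.default_rng(8)
        samples = [(c, r) for c in ("vehicle", "drug") for r in (1, 2, 3)]
        rows, expected = [], 0
        for i in range(300):
            pep = f"pep{i:03d}"
            observed = rng.random(6) > 0.3
            expected += bool(observed.all())
            for (cond, rep), obs in zip(samples, observed):
                l1, l2 = (70.0, 30.0) if obs else (np.nan, np.nan)
                rows.append((pep, f"P{i:03d}", cond, rep, l1, l2))
        kept = complete_case_filter(redox_rows(rows))
        assert kept["peptide_id"].nunique() == expected


class TestStudentT:
    def test_identical_groups_give_p_one(self):
        assert student_t_two_tailed([0.5, 0.5, 0.5], [0.5, 0.5, 0.5]) == 1.0

    def test_matches_textbook_formula(self):
        g1, g2 = [0.5, 0.6, 0.55], [0.2, 0.25, 0.3]
        n1, n2 = len(g1), len(g2)
        s2 = (np.var(g1, ddof=1) * (n1 - 1) + np.var(g2, ddof=1) * (n2 - 1)) / (
            n1 + n2 - 2
        )
        t = (np.mean(g1) - np.mean(g2)) / np.sqrt(s2 * (1 / n1 + 1 / n2))
        expected = 2 * stats.t.sf(abs(t), n1 + n2 - 2)
        assert student_t_two_tailed(g1, g2) == pytest.approx(expected, abs=1e-10)

    def test_two_tailed_symmetry(self):
        g1, g2 = [0.5, 0.6, 0.55], [0.2, 0.25, 0.3]
        assert student_t_two_tailed(g1, g2) == student_t_two_tailed(g2, g1)

    def test_zero_variance_unequal_means(self):
        assert student_t_two_tailed([1.0, 1.0], [0.0, 0.0]) == 0.0

    def test_group_of_one_rejected(self):
        with pytest.raises(ValueError):
            student_t_two_tailed([1.0], [0.0, 0.1])


class TestPeptideDifferentialOxidation:
    def _table(self, drug_ratios, vehicle_ratios):
        rows = []
        for rep, r in enumerate(vehicle_ratios, start=1):
            rows.append(("p1", "A", "vehicle", rep, 100 * (1 - r), 100 * r))
        for rep, r in enumerate(drug_ratios, start=1):
            rows.append(("p1", "A", "drug", rep, 100 * (1 - r), 100 * r))
        return redox_rows(rows)

    def test_mean_difference(self):
        out = peptide_differential_oxidation(self._table([0.8] * 3, [0.5] * 3))
        assert out.iloc[0]["delta_ox"] == pytest.approx(0.3)

    def test_equal_means_give_zero(self):
        out = peptide_differential_oxidation(
            self._table([0.4, 0.5, 0.6], [0.5, 0.6, 0.4])
        )
        assert out.iloc[0]["delta_ox"] == pytest.approx(0.0)

    def test_delta_bounded(self):
        out = peptide_differential_oxidation(self._table([1.0] * 3, [0.0] * 3))
        assert out.iloc[0]["delta_ox"] == pytest.approx(1.0)

    def test_q_value_column_present(self):
        out = peptide_differential_oxidation(self._table([0.8] * 3, [0.5] * 3))
        assert "q_value" in out.columns


class TestDualRank:
    def _peptides(self, entries) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"peptide_id": pep, "protein_id": prot, "delta_ox": d, "p_value": p}
                for pep, prot, d, p in entries
            ]
        )

    def test_rank_sum_ordering(self):
        ranked = redox_dual_rank(
            self._peptides(
                [("X", "A", 0.5, 0.001), ("Y", "B", 0.4, 0.02), ("Z", "C", 0.1, 0.05)]
            )
        ).set_index("peptide_id")
        assert ranked.loc["X", "rank_sum"] == 2
        assert ranked.loc["Y", "rank_sum"] == 4
        assert list(ranked["final_rank"]) == [1, 2, 3]

    def test_swapped_components_tie_broken_by_id(self):
        ranked = redox_dual_rank(
            self._peptides([("X", "A", 0.5, 0.05), ("Y", "B", 0.1, 0.001)])
        ).set_index("peptide_id")
        assert ranked.loc["X", "rank_sum"] == ranked.loc["Y", "rank_sum"] == 3
        assert ranked.loc["X", "final_rank"] == 1
        assert ranked.loc["Y", "final_rank"] == 2

    def test_sign_flip_inverts_delta_ranking(self):
        rng = np.random.default_rng(6)
        entries = [
            (f"p{i:02d}", f"P{i:02d}", float(rng.normal(0, 0.2)), float(rng.uniform()))
            for i in range(20)
        ]
        ranked = redox_dual_rank(self._peptides(entries)).set_index("peptide_id")
        flipped = redox_dual_rank(
            self._peptides([(a, b, -d, p) for a, b, d, p in entries])
        ).set_index("peptide_id")
        # with distinct deltas, descending ranks invert exactly
        n = len(entries)
        for pep in ranked.index:
            assert flipped.loc[pep, "rank_delta"] == n + 1 - ranked.loc[pep, "rank_delta"]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            n = int(rng.integers(1, 50))
            entries = [
                (f"p{i:02d}", f"P{i:02d}", float(rng.normal()), float(rng.uniform()))
                for i in range(n)
            ]
            ranked = redox_dual_rank(self._peptides(entries)).set_index("peptide_id")
            r1 = {e[0]: r + 1 for r, e in enumerate(sorted(entries, key=lambda e: (-e[2], e[0])))}
            r2 = {e[0]: r + 1 for r, e in enumerate(sorted(entries, key=lambda e: (e[3], e[0])))}
            sums = {pep: r1[pep] + r2[pep] for pep in r1}
            final = {
                pep: r + 1
                for r, pep in enumerate(sorted(sums, key=lambda k: (sums[k], k)))
            }
            assert ranked["final_rank"].to_dict() == final


class TestBestPeptidePerProtein:
    def test_best_peptide_represents_protein(self):
        ranked = pd.DataFrame(
            {
                "peptide_id": ["a1", "a2", "b1"],
                "protein_id": ["A", "A", "B"],
                "final_rank": [40, 5, 12],
            }
        )
        ranking = best_peptide_per_protein(ranked)
        assert ranking.entries.to_dict() == {"A": 1, "B": 2}

    def test_single_peptide_identity_rerank(self):
        ranked = pd.DataFrame(
            {
                "peptide_id": ["a", "b", "c"],
                "protein_id": ["A", "B", "C"],
                "final_rank": [3, 1, 2],
            }
        )
        ranking = best_peptide_per_protein(ranked)
        assert ranking.entries.to_dict() == {"A": 3, "B": 1, "C": 2}

    def test_output_is_permutation(self):
        rng = np.random.default_rng(21)
        n_pep = 60
        ranked = pd.DataFrame(
            {
                "peptide_id": [f"p{i}" for i in range(n_pep)],
                "protein_id": [f"P{rng.integers(0, 20):02d}" for _ in range(n_pep)],
                "final_rank": rng.permutation(n_pep) + 1,
            }
        )
        ranking = best_peptide_per_protein(ranked)
        n = ranking.n_ranked
        assert sorted(ranking.entries.values) == list(range(1, n + 1))


def test_add_oxidation_ratios_column():
    table = redox_rows([("p1", "A", "vehicle", 1, 70, 30)])
    out = add_oxidation_ratios(table)
    assert out.iloc[0]["oxidation_ratio"] == pytest.approx(0.3)
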