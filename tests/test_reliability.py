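"""Pair assembly, percent concordance, and Cohen's kappa."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmaagree import (
    PairSet,
    StudyDataset,
    build_pairs,
    cohen_kappa,
    contingency_table,
    kappa_ci,
    kappa_from_pairs,
    percent_concordance,
)


def kappa_brute_force(counts):
    """Independent oracle: explicit double loops over categories."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    k = counts.shape[0]
    po = sum(counts[i][i] for i in range(k)) / n
    pe = 0.0
    for i in range(k):
        row_i = sum(counts[i][j] for j in range(k)) / n
        col_i = sum(counts[j][i] for j in range(k)) / n
        pe += row_i * col_i
    if pe >= 1.0 - 1e-12:
        return None
    return (po - pe) / (1.0 - pe)


class TestBuildPairs:
    def test_er_pairs_cover_all_cases_with_one_missing_side(self, table1):
        ps = build_pairs(table1, "er")
        assert ps.n_total_cases == 30
        assert ps.n_complete == 29

    def test_her2_reliability_binary_excludes_three_missing_cells(self, table1):
        ps = build_pairs(table1, "her2", coding="reliability-binary")
        assert ps.n_complete == 27
        values = {v for _, a, b in ps.complete_pairs() for v in (a, b)}
        assert values == {"pos", "neg"}

    def test_her2_category_coding_keeps_stain_levels(self, table1):
        ps = build_pairs(table1, "her2")
        case_2_7 = next(p for p in ps.pairs if p[0] == "2-7")
        assert case_2_7[1:] == ("2+", "2+")

    def test_unknown_target_rejected(self, table1):
        with pytest.raises(ValueError, match="unknown target"):
            build_pairs(table1, "ck99")

    def test_empty_dataset_gives_empty_pairset(self):
        ps = build_pairs(StudyDataset(cases=[], panels=[]), "er")
        assert ps.n_total_cases == 0
        with pytest.raises(ValueError):
            percent_concordance(ps)


class TestPercentConcordance:
    def test_fixture_er_is_perfect(self, table1):
        assert percent_concordance(build_pairs(table1, "er")).percent == 100

    def test_fixture_ki67_dichotomized_at_14(self, table1):
        conc = percent_concordance(build_pairs(table1, "ki67"))
        assert conc.percent == 90
        assert conc.n_discordant == 3

    def test_single_discordant_pair_gives_zero(self):
        ps = PairSet(label="x", pairs=(("c1", "pos", "neg"),), policy="")
        assert percent_concordance(ps).percent == 0

    def test_rounding_is_half_up(self):
        pairs = tuple(
            ("c%d" % i, "pos", "pos" if i >= 1 else "neg") for i in range(40)
        )
        # 39/40 = 97.5% -> 98 under half-up
        assert percent_concordance(PairSet("x", pairs, "")).percent == 98

    def test_missing_side_never_discordant(self):
        ps = PairSet("x", (("c1", None, "pos"), ("c2", "pos", "pos")), "")
        conc = percent_concordance(ps)
        assert conc.n_discordant == 0 and conc.percent == 100


class TestCohenKappa:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([[7, 1], [0, 19]], 0.908),   # HER2, 2+/3+ positive, n=27
            ([[1, 2], [1, 25]], 0.346),   # Ki67 >=14% vs <14%, n=29
            ([[10, 0], [0, 5]], 1.0),
        ],
    )
    def test_reference_tables(self, counts, expected):
        result = cohen_kappa(np.array(counts))
        assert result.kappa == pytest.approx(expected, abs=5e-4)

    def test_all_mass_in_one_cell_is_undefined(self):
        result = cohen_kappa(np.array([[12, 0], [0, 0]]))
        assert result.kappa is None and not result.defined

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            cohen_kappa(np.zeros((2, 2)))

    @settings(max_examples=250, deadline=None, derandomize=True)
    @given(
        counts=st.lists(
            st.lists(st.integers(min_value=0, max_value=30), min_size=2, max_size=4),
            min_size=2, max_size=4,
        ).filter(lambda rows: len({len(r) for r in rows} | {len(rows)}) == 1
                 and sum(map(sum, rows)) > 0)
    )
    def test_matches_brute_force_oracle_on_random_tables(self, counts):
        expected = kappa_brute_force(counts)
        result = cohen_kappa(np.array(counts))
        if expected is None:
            assert result.kappa is None
        else:
            assert result.kappa == pytest.approx(expected, abs=1e-12)
            assert result.kappa <= result.p_observed <= 1.0

    def test_permutation_invariance_under_consistent_relabeling(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            k = rng.integers(2, 5)
            counts = rng.integers(0, 20, size=(k, k))
            if counts.sum() == 0:
                continue
            perm = rng.permutation(k)
            permuted = counts[np.ix_(perm, perm)]
            a, b = cohen_kappa(counts), cohen_kappa(permuted)
            if a.kappa is None:
                assert b.kappa is None
            else:
                assert b.kappa == pytest.approx(a.kappa, abs=1e-12)

    def test_kappa_is_one_iff_no_off_diagonal_mass_and_chance_below_one(self):
        assert cohen_kappa(np.array([[5, 0], [0, 7]])).kappa == pytest.approx(1.0)
        near = cohen_kappa(np.array([[5, 1], [0, 7]]))
        assert near.kappa < 1.0

    def test_standard_error_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.inter_rater")
        rng = np.random.default_rng(11)
        for _ in range(25):
            counts = rng.integers(0, 15, size=(3, 3)) + np.eye(3, dtype=int)
            ours = cohen_kappa(counts)
            theirs = sm.cohens_kappa(counts)
            assert ours.kappa == pytest.approx(theirs.kappa, abs=1e-10)
            assert ours.se == pytest.approx(theirs.var_kappa ** 0.5, abs=1e-10)


class TestConfidenceIntervals:
    def test_ki67_asymptotic_interval_straddles_zero(self, table1):
        ps = build_pairs(table1, "ki67")
        result = kappa_ci(ps, method="asymptotic")
        assert result.ci_low < 0.0 < result.kappa < result.ci_high
        # printed for comparison: (-0.225, 0.916)
        assert result.ci_low == pytest.approx(-0.225, abs=5e-4)
        assert result.ci_high == pytest.approx(0.916, abs=5e-4)

    def test_asymptotic_bounds_clipped_to_unit_interval(self, table1):
        result = kappa_ci(build_pairs(table1, "her2", coding="reliability-binary"))
        assert result.ci_high == 1.0
        assert result.ci_low == pytest.approx(0.731, abs=5e-4)

    def test_degenerate_table_has_no_interval(self):
        ps = PairSet("x", (("c1", "pos", "pos"), ("c2", "pos", "pos")), "")
        result = kappa_ci(ps)
        assert result.kappa is None and result.ci_low is None

    def test_bootstrap_is_deterministic_under_fixed_seed(self, table1):
        ps = build_pairs(table1, "ki67")
        a = kappa_ci(ps, method="bootstrap", n_boot=300, seed=5)
        b = kappa_ci(ps, method="bootstrap", n_boot=300, seed=5)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        assert -1.0 <= a.ci_low <= a.ci_high <= 1.0

    def test_bootstrap_requires_enough_replicates(self, table1):
        with pytest.raises(ValueError, match="n_boot"):
            kappa_ci(build_pairs(table1, "er"), method="bootstrap", n_boot=50)

    def test_bootstrap_coverage_close_to_nominal(self):
        """Percentile bootstrap CI covers the generating kappa at roughly
        the nominal rate on simulated 2x2 pair sets."""
        rng = np.random.default_rng(2024)
        cell_p = np.array([0.30, 0.10, 0.10, 0.50])  # true kappa 0.58333
        true_kappa = kappa_brute_force(cell_p.reshape(2, 2) * 100)
        n_pairs, n_sim, hits, defined = 60, 120, 0, 0
        for _ in range(n_sim):
            draws = rng.multinomial(n_pairs, cell_p)
            pairs = []
            labels = [("a", "a"), ("a", "b"), ("b", "a"), ("b", "b")]
            idx = 0
            for (x, y), m in zip(labels, draws):
                for _ in range(m):
                    pairs.append((f"c{idx}", x, y))
                    idx += 1
            ps = PairSet("sim", tuple(pairs), "")
            result = kappa_ci(ps, method="bootstrap", n_boot=199,
                              seed=int(rng.integers(2**31)))
            if result.defined and result.ci_low is not None:
                defined += 1
                hits += result.ci_low <= true_kappa <= result.ci_high
        assert defined > 100
        assert 0.85 <= hits / defined <= 1.0


def test_contingency_counts_match_pairset(table1):
    ps = build_pairs(table1, "ki67")
    categories, counts = contingency_table(ps)
    assert counts.sum() == ps.n_complete == 29
    assert set(categories) == {"high", "low"}
    result = kappa_from_pairs(ps)
    assert result.n_pairs == 29
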