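"""Agreement tables, symmetry tests, precision indices, consensus ages."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.contingency_tables import SquareTable

import seawhip as sw
from seawhip.ageing import AgreementTable

ALL_TESTS = [sw.mcnemar_symmetry, sw.evans_hoenig_symmetry, sw.bowker_symmetry]


def table_from_matrix(n):
    n = np.asarray(n)
    return AgreementTable(ages=np.arange(n.shape[0]), n=n)


class TestAgreementTable:
    def test_small_example(self):
        t = sw.build_agreement_table([(3, 3), (3, 4)])
        assert list(t.ages) == [3, 4]
        assert t.n[0, 0] == 1 and t.n[0, 1] == 1 and t.total == 2

    def test_marginals_reproduce_reader_frequencies(self):
        pairs = [(3, 4), (4, 4), (5, 3), (4, 5), (3, 3)]
        t = sw.build_agreement_table(pairs)
        r1 = np.array([p[0] for p in pairs])
        for k, age in enumerate(t.ages):
            assert t.n[k, :].sum() == (r1 == age).sum()

    def test_fixture_off_diagonal_sums(self, reader_pairs_102):
        t = sw.build_agreement_table(reader_pairs_102)
        assert np.triu(t.n, 1).sum() == 10
        assert np.tril(t.n, -1).sum() == 8
        assert t.total == 102

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            sw.build_agreement_table([])


class TestSymmetryTests:
    @pytest.mark.parametrize("test_fn", ALL_TESTS)
    def test_symmetric_table_gives_zero(self, test_fn):
        n = np.array([[5, 2, 1], [2, 7, 3], [1, 3, 4]])
        res = test_fn(table_from_matrix(n))
        assert res.statistic == 0.0
        assert res.p == pytest.approx(1.0)

    def test_mcnemar_fixture_matches_hand_arithmetic(self, reader_pairs_102):
        res = sw.mcnemar_symmetry(sw.build_agreement_table(reader_pairs_102))
        assert res.statistic == pytest.approx(4 / 18)
        assert res.df == 1
        assert res.p == pytest.approx(0.637, abs=5e-4)

    def test_mcnemar_a3_b1(self):
        n = np.array([[0, 3], [1, 0]])
        res = sw.mcnemar_symmetry(table_from_matrix(n))
        assert res.statistic == pytest.approx(1.0)
        assert res.p == pytest.approx(0.3173, abs=1e-4)

    def test_evans_hoenig_equals_mcnemar_when_all_adjacent(self, reader_pairs_102):
        t = sw.build_agreement_table(reader_pairs_102)
        m, e = sw.mcnemar_symmetry(t), sw.evans_hoenig_symmetry(t)
        assert e.statistic == pytest.approx(m.statistic)
        assert e.df == m.df == 1
        assert e.p == pytest.approx(m.p)

    def test_evans_hoenig_pools_by_distance(self):
        # distance 1: A=2, B=2 -> 0; distance 2: A=1, B=0 -> 1
        n = np.zeros((3, 3), dtype=int)
        n[0, 1] = 2
        n[1, 0] = 2
        n[0, 2] = 1
        res = sw.evans_hoenig_symmetry(table_from_matrix(n))
        assert res.statistic == pytest.approx(1.0)
        assert res.df == 2
        assert res.p == pytest.approx(0.6065, abs=1e-4)

    def test_bowker_single_cell_pair(self):
        n = np.diag([4, 5, 6]).astype(int)
        n[1, 2] = 3
        n[2, 1] = 1
        res = sw.bowker_symmetry(table_from_matrix(n))
        assert res.statistic == pytest.approx(1.0)
        assert res.df == 1
        assert res.p == pytest.approx(0.3173, abs=1e-4)

    def test_bowker_df_counts_discordant_pairs(self):
        # 7 unordered cell pairs carry disagreement -> df = 7
        n = np.zeros((5, 5), dtype=int)
        cells = [(0, 1), (0, 2), (1, 2), (1, 3), (2, 3), (2, 4), (3, 4)]
        for i, j in cells:
            n[i, j] = 2
            n[j, i] = 1
        res = sw.bowker_symmetry(table_from_matrix(n))
        assert res.df == 7

    def test_bowker_agrees_with_statsmodels_oracle(self):
        # strictly positive off-diagonals so no cell pair is dropped and the
        # df conventions of the two implementations coincide
        rng = np.random.default_rng(5)
        n = rng.integers(1, 7, size=(5, 5))
        ours = sw.bowker_symmetry(table_from_matrix(n))
        ref = SquareTable(n.astype(float)).symmetry(method="bowker")
        assert ours.statistic == pytest.approx(float(ref.statistic))
        assert ours.p == pytest.approx(float(ref.pvalue))
        assert ours.df == int(ref.df)

    @pytest.mark.parametrize("test_fn", ALL_TESTS)
    def test_transpose_invariance(self, test_fn):
        """Swapping reader labels (transposing the table) leaves each
        statistic unchanged."""
        rng = np.random.default_rng(11)
        n = rng.integers(0, 7, size=(4, 4))
        a = test_fn(table_from_matrix(n))
        b = test_fn(table_from_matrix(n.T))
        assert a.statistic == pytest.approx(b.statistic)
        assert a.df == b.df

    @pytest.mark.parametrize("test_fn", ALL_TESTS)
    def test_perfect_agreement_undefined(self, test_fn):
        with pytest.raises(ValueError):
            test_fn(table_from_matrix(np.diag([3, 4, 5])))


class TestPrecisionIndices:
    def test_perfect_agreement(self):
        res = sw.precision_indices([(5, 5), (7, 7)])
        assert (res.pa, res.ape, res.acv) == (100.0, 0.0, 0.0)

    def test_single_pair_hand_arithmetic(self):
        res = sw.precision_indices([(9, 10)])
        assert res.ape == pytest.approx(100 * 0.5 / 9.5)
        assert res.acv == pytest.approx(math.sqrt(2) * res.ape)

    def test_fixture_percent_agreement(self, reader_pairs_102):
        res = sw.precision_indices(reader_pairs_102)
        assert res.pa == pytest.approx(100 * 84 / 102)
        assert res.pa == pytest.approx(82.35, abs=0.005)

    @given(
        st.lists(
            st.tuples(st.integers(0, 30), st.integers(0, 30)).filter(
                lambda p: p[0] + p[1] > 0
            ),
            min_size=1,
            max_size=40,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_acv_is_sqrt2_times_ape(self, pairs):
        """Two-reader identity: ACV = sqrt(2) x APE."""
        res = sw.precision_indices(pairs)
        assert res.acv == pytest.approx(math.sqrt(2) * res.ape, rel=1e-9, abs=1e-9)

    def test_zero_mean_pairs_excluded(self):
        with pytest.warns(UserWarning):
            res = sw.precision_indices([(0, 0), (4, 5)])
        assert res.ape == pytest.approx(100 * 0.5 / 4.5)
        with pytest.raises(ValueError):
            sw.precision_indices([(0, 0)])


class TestConsensusAge:
    @pytest.mark.parametrize(
        "pair, rule, expected",
        [
            ((7, 7), "half_even", 7.0),
            ((7, 8), "keep_fraction", 7.5),
            ((7, 8), "half_even", 8.0),
            ((6, 7), "half_even", 6.0),
            ((7, 8), "half_up", 8.0),
            ((7, 8), "half_down", 7.0),
            ((6, 8), "half_even", 7.0),
        ],
    )
    def test_rules(self, pair, rule, expected):
        assert sw.consensus_age(*pair, rule=rule) == expected
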