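import numpy as np
import pytest

from batchmark import CountData, ParameterSet, StudyDesign
from batchmark.histories import enumerate_histories, first_capture, history_prob_vector
from batchmark.matrices import (aggregate_counts, build_A, build_B,
                                build_transform, count_index,
                                enumerate_latent_solutions,
                                forced_zero_reduction, is_feasible,
                                prefilter_histories, stack_T)

from conftest import random_theta

D2 = StudyDesign(K=2, Tks=(1, 1))


class TestCountIndex:
    def test_two_period_minimal(self):
        m_idx, n_idx = count_index(D2)
        assert m_idx == [(1, 1), (2, 1)]
        assert n_idx == [(1, 2, 1)]

    def test_reference_design_length(self):
        d = StudyDesign(K=6, Tks=(2,) * 6)
        m_idx, n_idx = count_index(d)
        assert len(m_idx) == 12
        assert len(n_idx) == 36
        # within-period rows need t >= 2; cross-period rows need k < j
        assert all(t >= 2 for (k, j, t) in n_idx if k == j)
        assert all(k <= j for (k, j, t) in n_idx)

    def test_single_period(self):
        d = StudyDesign(K=1, Tks=(3,))
        m_idx, n_idx = count_index(d)
        assert n_idx == [(1, 1, 2), (1, 1, 3)]
        assert len(m_idx) + len(n_idx) == 5


class TestBuildMatrices:
    def test_A_two_period(self):
        A = build_A(D2).toarray()
        # columns (00, 01, 10, 11)
        np.testing.assert_array_equal(A[0], [0, 0, 1, 1])  # m_11
        np.testing.assert_array_equal(A[1], [0, 1, 0, 0])  # m_21

    def test_B_two_period(self):
        B = build_B(D2).toarray()
        np.testing.assert_array_equal(B[0], [0, 0, 0, 1])  # n_121

    def test_B_within_period(self):
        d = StudyDesign(K=1, Tks=(2,))
        B = build_B(d).toarray()
        # row n_112 over columns (00, 01, 10, 11): only 11 marked at occasion 1
        # and recaptured at occasion 2
        np.testing.assert_array_equal(B[0], [0, 0, 0, 1])

    def test_column_structure(self, small_design):
        tm = build_transform(small_design)
        colsums_A = np.asarray(tm.A.sum(axis=0)).ravel()
        assert set(np.unique(colsums_A)) <= {0.0, 1.0}
        # all-zero history column is entirely zero
        assert tm.T_mat[:, 0].nnz == 0
        J, T = 2 ** small_design.T, small_design.T
        assert tm.A.nnz <= J and tm.B.nnz <= J * T

    def test_stack_requires_matching_columns(self):
        with pytest.raises(ValueError):
            stack_T(build_A(D2), build_B(StudyDesign(K=1, Tks=(3,))))

    def test_worked_aggregate(self):
        data = aggregate_counts(D2, np.array([5, 2, 1, 3]))
        np.testing.assert_array_equal(data.m, [4, 2])
        np.testing.assert_array_equal(data.n, [3])

    def test_linearity_and_zero(self, small_design, rng):
        tm = build_transform(small_design)
        xa = rng.integers(0, 5, size=tm.T_mat.shape[1])
        xb = rng.integers(0, 5, size=tm.T_mat.shape[1])
        ya = tm.T_mat @ xa
        yb = tm.T_mat @ xb
        np.testing.assert_array_equal(tm.T_mat @ (xa + xb), ya + yb)
        assert (tm.T_mat @ np.zeros(tm.T_mat.shape[1]) == 0).all()

    @pytest.mark.parametrize("Tks", [(1, 1), (2, 2), (2, 1, 2)])
    def test_aggregation_matches_individual_tabulation(self, Tks, rng):
        """y = Tx agrees with counting marks/recaptures individual by
        individual from the simulated latent histories."""
        d = StudyDesign(K=len(Tks), Tks=Tks)
        H = enumerate_histories(d)
        th = random_theta(d, rng, N=50)
        pi, _ = history_prob_vector(th, d)
        x = rng.multinomial(50, pi)
        data = aggregate_counts(d, x)

        m_idx, n_idx = count_index(d)
        m_direct = dict.fromkeys(m_idx, 0)
        n_direct = dict.fromkeys(n_idx, 0)
        occ = d.occasions
        for j, count in enumerate(x):
            fc = first_capture(H[j], d)
            if fc is None:
                continue
            m_direct[fc] += count
            k1 = fc[0]
            for pos in np.flatnonzero(H[j]):
                jj, t = occ[pos]
                if (jj, t) == fc:
                    continue  # the marking event itself
                if jj > k1 or (jj == k1 and t > fc[1]):
                    n_direct[(k1, jj, t)] += count
        np.testing.assert_array_equal(data.m, [m_direct[i] for i in m_idx])
        np.testing.assert_array_equal(data.n, [n_direct[i] for i in n_idx])


class TestCoordinateDump:
    def test_round_trips_nonzeros(self, tmp_path):
        from batchmark.matrices import dump_coordinates
        tm = build_transform(D2)
        path = dump_coordinates(tm.T_mat, tmp_path / "T.txt")
        lines = [l.split() for l in open(path) if not l.startswith("#")]
        assert len(lines) == tm.T_mat.nnz
        dense = np.zeros(tm.T_mat.shape)
        for r, c, v in lines:
            dense[int(r), int(c)] = float(v)
        np.testing.assert_array_equal(dense, tm.T_mat.toarray())


class TestForcedZeroReduction:
    def test_zero_row_drops_column(self):
        tm = build_transform(D2)
        y = np.array([4, 0, 3])
        kept, dropped = forced_zero_reduction(tm.T_mat, y)
        assert 1 in dropped  # history 01 first-captured in period 2
        assert 0 in kept     # all-zero history always retained

    def test_positive_data_drops_nothing(self):
        tm = build_transform(D2)
        kept, dropped = forced_zero_reduction(tm.T_mat, np.array([4, 2, 3]))
        assert dropped.size == 0 and kept.size == 4

    @pytest.mark.parametrize("Tks,seed", [((1, 1), 0), ((2, 2), 1), ((2, 1), 4)])
    def test_dropped_columns_truly_impossible(self, Tks, seed):
        """No nonnegative integer solution of Tx = y uses a dropped history."""
        rng = np.random.default_rng(seed)
        d = StudyDesign(K=len(Tks), Tks=Tks)
        th = random_theta(d, rng, N=10)
        pi, _ = history_prob_vector(th, d)
        x = rng.multinomial(10, pi)
        tm = build_transform(d)
        y = np.asarray(tm.T_mat @ x)
        kept, dropped = forced_zero_reduction(tm.T_mat, y)
        sols = enumerate_latent_solutions(tm.T_mat, y, 10)
        assert sols, "simulated y must be feasible"
        for j in dropped:
            assert all(s[j] == 0 for s in sols)


class TestPrefilter:
    def test_fraction_one_keeps_all(self):
        pi = np.linspace(1, 4, 8)
        assert prefilter_histories(pi, fraction=1.0).size == 8

    def test_ceil_count(self):
        pi = np.random.default_rng(0).random(4096)
        kept = prefilter_histories(pi, fraction=0.10)
        assert kept.size == 410  # ceil(409.6)

    def test_top_history_always_kept(self):
        pi = np.random.default_rng(1).random(100)
        kept = prefilter_histories(pi, fraction=0.10)
        assert int(np.argmax(pi)) in kept

    def test_fraction_validation(self):
        with pytest.raises(ValueError):
            prefilter_histories(np.ones(4), fraction=0.0)

    def test_feasibility_readd(self):
        """Prefiltering must never make the observed data infeasible."""
        tm = build_transform(D2)
        y = np.array([4, 2, 3])
        # give the needed histories the LOWEST initial probabilities
        pi = np.array([0.9, 0.05, 0.03, 0.02])
        kept = prefilter_histories(pi, fraction=0.25, always_keep=[0],
                                   T_mat=tm.T_mat, y=y)
        assert is_feasible(tm.T_mat[:, kept], y)
        assert 3 in kept  # history 11 is forced by n_121 = 3
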