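"""DIA decomposition: exactness conditions, invariances, file I/O."""

import math

import numpy as np
import pytest
import scipy.sparse as sp

from diapart.dia import (
    PartitionDecomposition,
    ThermoConditions,
    TwoStateSystem,
    boltzmann_weights,
    dia_global,
    dia_local,
    log_boltzmann_weights,
    mean_cross_interaction,
    mean_indirect,
    partition_bruteforce,
    read_system,
    write_system,
)


def relerr_log(a, b):
    return abs(math.expm1(a - b))


class TestSystemValidation:
    def test_rejects_asymmetric_pairs(self):
        with pytest.raises(ValueError, match="symmetric"):
            TwoStateSystem([0.0, 0.0], [[0.0, 1.0], [2.0, 0.0]])

    def test_rejects_nonzero_diagonal(self):
        with pytest.raises(ValueError, match="diagonal"):
            TwoStateSystem([0.0, 0.0], [[1.0, 0.5], [0.5, 0.0]])

    def test_energy_evaluation(self):
        s = TwoStateSystem([1.0, 2.0, 3.0], np.zeros((3, 3)), energy_offset=0.5)
        assert s.energy([1, 0, 1]) == pytest.approx(4.5)


class TestWeights:
    def test_zero_energies_give_unit_weights(self, cond):
        s = TwoStateSystem(np.zeros(5), np.zeros((5, 5)))
        np.testing.assert_allclose(
            boltzmann_weights(s, 2, cond, include_direct=True), np.ones(4)
        )

    def test_two_particle_direct_factor(self):
        g = 0.8
        s = TwoStateSystem([0.0, 0.0], [[0.0, g], [g, 0.0]])
        cond = ThermoConditions(2.0)
        np.testing.assert_allclose(
            boltzmann_weights(s, 0, cond, include_direct=True), [np.exp(-g / 2.0)]
        )

    def test_direct_flag_shifts_by_pair_energy(self, make_system, cond):
        s = make_system(7, seed=5)
        sel = 3
        lw1 = log_boltzmann_weights(s, sel, cond, include_direct=True)
        lw0 = log_boltzmann_weights(s, sel, cond, include_direct=False)
        others = [i for i in range(7) if i != sel]
        expected = -s.pair_dense()[sel, others] / cond.kt
        np.testing.assert_allclose(lw1 - lw0, expected, rtol=1e-12, atol=1e-14)

    def test_overflow_routes_to_log_form(self):
        s = TwoStateSystem([0.0, -1e6], np.zeros((2, 2)))
        cond = ThermoConditions(1e-3)
        with pytest.raises(OverflowError):
            boltzmann_weights(s, 0, cond, include_direct=False)
        lw = log_boltzmann_weights(s, 0, cond, include_direct=False)
        assert np.isfinite(lw).all()


class TestMeans:
    def test_single_indirect_pair(self):
        G = np.zeros((3, 3))
        G[1, 2] = G[2, 1] = 5.0
        s = TwoStateSystem(np.zeros(3), G)
        assert mean_indirect(s, 0) == pytest.approx(5.0)

    def test_mean_of_three(self):
        G = np.zeros((4, 4))
        for (i, j), v in {(1, 2): 1.0, (1, 3): 2.0, (2, 3): 3.0}.items():
            G[i, j] = G[j, i] = v
        s = TwoStateSystem(np.zeros(4), G)
        assert mean_indirect(s, 0) == pytest.approx(2.0)

    def test_constant_interactions(self, cond):
        n, c = 6, -0.7
        G = np.full((n, n), c) - c * np.eye(n)
        s = TwoStateSystem(np.zeros(n), G)
        for sel in range(n):
            assert mean_indirect(s, sel) == pytest.approx(c)

    def test_no_indirect_pairs_warns_and_returns_zero(self):
        s = TwoStateSystem(np.zeros(2), np.zeros((2, 2)))
        with pytest.warns(UserWarning, match="no indirect pairs"):
            assert mean_indirect(s, 0) == 0.0

    def test_cross_interaction(self):
        G = np.zeros((4, 4))
        G[1, 3] = G[3, 1] = 1.0
        G[2, 3] = G[3, 2] = 3.0
        s = TwoStateSystem(np.zeros(4), G)
        assert mean_cross_interaction(s, [1, 2], [3]) == pytest.approx(2.0)
        assert mean_cross_interaction(s, [1], [3]) == pytest.approx(1.0)

    def test_cross_interaction_rejects_overlap(self):
        s = TwoStateSystem(np.zeros(4), np.zeros((4, 4)))
        with pytest.raises(ValueError, match="disjoint"):
            mean_cross_interaction(s, [1, 2], [2, 3])


class TestBruteforce:
    def test_free_particles_z_is_2_to_n(self, cond):
        s = TwoStateSystem(np.zeros(6), np.zeros((6, 6)))
        dec = partition_bruteforce(s, 0, cond)
        assert dec.z_total == pytest.approx(2**6, rel=1e-12)
        # resolving by the total count of particles in state 1 recovers binomials
        tot = np.zeros(7)
        tot[:6] += dec.z0
        tot[1:] += dec.z1
        want = [math.comb(6, k) for k in range(7)]
        np.testing.assert_allclose(tot, want, rtol=1e-12)

    def test_independent_particles_factorize(self, cond):
        rng = np.random.default_rng(3)
        se = rng.normal(size=5)
        s = TwoStateSystem(se, np.zeros((5, 5)), energy_offset=0.9)
        dec = partition_bruteforce(s, 1, cond)
        want = np.exp(-0.9 / cond.kt) * np.prod(1 + np.exp(-se / cond.kt))
        assert dec.z_total == pytest.approx(want, rel=1e-12)

    def test_hand_summed_four_particle_system(self):
        # 2x2-style toy: ring of 4 particles, printed-by-construction energies
        se = np.array([0.5, -0.25, 1.0, 0.0])
        G = np.zeros((4, 4))
        for (i, j), v in {(0, 1): -1.0, (1, 2): 0.5, (2, 3): -0.5, (0, 3): 0.25}.items():
            G[i, j] = G[j, i] = v
        s = TwoStateSystem(se, G, energy_offset=-0.75)
        t = 0.9
        z = 0.0
        for m in range(16):
            x = [(m >> b) & 1 for b in range(4)]
            e = -0.75 + sum(se[i] * x[i] for i in range(4))
            e += sum(G[i, j] * x[i] * x[j] for i in range(4) for j in range(i + 1, 4))
            z += math.exp(-e / t)
        dec = partition_bruteforce(s, 0, ThermoConditions(t))
        assert dec.z_total == pytest.approx(z, rel=1e-12)

    def test_guard(self, cond):
        s = TwoStateSystem(np.zeros(21), sp.csr_matrix((21, 21)))
        with pytest.raises(ValueError, match="guard"):
            partition_bruteforce(s, 0, cond)


class TestExactnessConditions:
    """The DIA design guarantee: exact when indirect interactions are equal."""

    @pytest.mark.parametrize("variant", [dia_global, dia_local])
    def test_n2_and_n3_exact(self, variant, make_system, cond):
        for n, seed in ((2, 11), (3, 12), (3, 13)):
            s = make_system(n, seed=seed)
            got = variant(s, 0, cond)
            want = partition_bruteforce(s, 0, cond)
            assert relerr_log(got.log_z_total, want.log_z_total) < 1e-10

    @pytest.mark.parametrize("variant", [dia_global, dia_local])
    def test_equal_indirect_exact(self, variant, make_system, cond):
        s = make_system(9, seed=21, heterogeneity=0.0)
        got = variant(s, 0, cond)
        want = partition_bruteforce(s, 0, cond)
        assert relerr_log(got.log_z_total, want.log_z_total) < 1e-10

    @pytest.mark.parametrize("variant", [dia_global, dia_local])
    def test_zero_pair_energies_exact(self, variant, cond):
        rng = np.random.default_rng(8)
        s = TwoStateSystem(rng.normal(size=8), np.zeros((8, 8)), 0.1)
        got = variant(s, 0, cond)
        want = partition_bruteforce(s, 0, cond)
        assert relerr_log(got.log_z_total, want.log_z_total) < 1e-10

    def test_local_exact_when_each_merge_is_homogeneous(self, cond):
        # 8 particles, selected 0; the split-merge tree over {1..7} merges
        # ({1},{2,3}), ({4,5},{6,7}), ({1,2,3},{4,5,6,7}) and the leaves.
        # Within every merge the cross energies are constant, but the
        # constants differ between merges, so only merge-level averaging
        # is exact while the global average is not.
        G = np.zeros((8, 8))

        def setg(pairs, v):
            for i, j in pairs:
                G[i, j] = G[j, i] = v

        setg([(2, 3)], 0.9)
        setg([(1, 2), (1, 3)], -0.6)
        setg([(4, 5)], 0.3)
        setg([(6, 7)], -1.1)
        setg([(4, 6), (4, 7), (5, 6), (5, 7)], 0.45)
        setg([(i, j) for i in (1, 2, 3) for j in (4, 5, 6, 7)], -0.2)
        setg([(0, j) for j in range(1, 8)], 0.7)  # direct: always exact
        rng = np.random.default_rng(5)
        s = TwoStateSystem(rng.normal(size=8), G, 0.0)
        want = partition_bruteforce(s, 0, cond)
        local = dia_local(s, 0, cond)
        assert relerr_log(local.log_z_total, want.log_z_total) < 1e-10
        glob = dia_global(s, 0, cond)
        assert relerr_log(glob.log_z_total, want.log_z_total) > 1e-6

    def test_local_degenerates_to_global_for_equal_indirect(self, make_system, cond):
        s = make_system(11, seed=31, heterogeneity=0.0)
        a = dia_local(s, 0, cond)
        b = dia_global(s, 0, cond)
        np.testing.assert_allclose(a.log_z0, b.log_z0, rtol=0, atol=1e-12)
        np.testing.assert_allclose(a.log_z1, b.log_z1, rtol=0, atol=1e-12)


class TestInvariances:
    def test_global_invariant_under_nonselected_permutation(self, make_system, cond):
        s = make_system(8, seed=41)
        base = dia_global(s, 0, cond)
        rng = np.random.default_rng(0)
        perm = np.concatenate([[0], 1 + rng.permutation(7)])
        P = s.pair_dense()[np.ix_(perm, perm)]
        s2 = TwoStateSystem(s.self_energy[perm], P, s.energy_offset)
        got = dia_global(s2, 0, cond)
        np.testing.assert_allclose(got.log_z0, base.log_z0, rtol=0, atol=1e-10)
        np.testing.assert_allclose(got.log_z1, base.log_z1, rtol=0, atol=1e-10)

    def test_local_invariant_under_branch_swap(self, make_system, cond):
        # swapping the two halves of the non-selected list swaps every
        # top-level branch; convolution commutes and the cross average is
        # symmetric, so the result is unchanged
        s = make_system(9, seed=43)
        base = dia_local(s, 0, cond)
        order = np.array([0, 5, 6, 7, 8, 1, 2, 3, 4])
        P = s.pair_dense()[np.ix_(order, order)]
        s2 = TwoStateSystem(s.self_energy[order], P, s.energy_offset)
        got = dia_local(s2, 0, cond)
        assert got.log_z_total == pytest.approx(base.log_z_total, abs=1e-10)

    def test_deterministic_bitwise(self, make_system, cond):
        s = make_system(12, seed=47)
        a = dia_local(s, 0, cond)
        b = dia_local(s, 0, cond)
        assert np.array_equal(a.log_z0, b.log_z0)
        assert np.array_equal(a.log_z1, b.log_z1)
        assert a.log_z_total == b.log_z_total

    def test_nonnegative_and_consistent_total(self, make_system, cond):
        s = make_system(10, seed=53)
        for dec in (dia_local(s, 0, cond), dia_global(s, 0, cond)):
            assert np.all(dec.z0[:-1] > 0) and np.all(dec.z1[:-1] > 0)
            assert dec.z_total == pytest.approx(
                dec.z0.sum() + dec.z1.sum(), rel=1e-12
            )

    def test_infinite_temperature_limit(self, make_system):
        s = make_system(10, seed=59)
        hot = ThermoConditions(1e12)
        assert dia_local(s, 0, hot).z_total == pytest.approx(2**10, rel=1e-9)

    def test_recorded_error_is_reproducible(self, make_system, cond):
        s = make_system(10, seed=61)
        bf = partition_bruteforce(s, 0, cond)
        err1 = dia_local(s, 0, cond).log_z_total - bf.log_z_total
        err2 = dia_local(s, 0, cond).log_z_total - bf.log_z_total
        assert err1 == err2
        assert err1 != 0.0  # heterogeneous system: approximation is visible


class TestSystemFiles:
    def test_roundtrip(self, tmp_path, make_system, cond):
        s = make_system(7, seed=71)
        path = tmp_path / "sys.tsv"
        write_system(s, path)
        s2 = read_system(path)
        np.testing.assert_array_equal(s2.self_energy, s.self_energy)
        np.testing.assert_array_equal(s2.pair_dense(), s.pair_dense())
        assert s2.energy_offset == s.energy_offset
        a = dia_local(s, 0, cond).log_z_total
        b = dia_local(s2, 0, cond).log_z_total
        assert a == b

    def test_duplicate_pair_is_hard_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("SELF\t0\t1.0\nPAIR\t0\t1\t0.5\nPAIR\t1\t0\t0.5\n")
        with pytest.raises(ValueError, match="duplicate PAIR"):
            read_system(p)

    def test_unmentioned_pairs_default_to_zero(self, tmp_path):
        p = tmp_path / "sparse.tsv"
        p.write_text("# comment\nSELF\t2\t0.25\nPAIR\t0\t2\t-1.5\nOFFSET\t0.1\n")
        s = read_system(p)
        assert s.n == 3
        assert s.pair(0, 1) == 0.0
        assert s.pair(2, 0) == -1.5
        assert s.energy_offset == 0.1
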