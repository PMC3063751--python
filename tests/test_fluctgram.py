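"""Windowing, the fluctuogram and the residue-level variation metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import fluctuogram_from_k
from fluctuogram.fluctgram import (
    conformational_change,
    coupling_series,
    compute_fluctuogram,
    delta_k_consecutive,
    delta_k_two_states,
    make_windows,
    psi,
    residue_coupling,
)
from fluctuogram.fluctmatch import FluctMatchConfig, fluctuation_match, \
    measure_targets
from fluctuogram.errors import RosterMismatchError
from fluctuogram.synth import make_toy_network, sample_from_network


class TestWindows:
    def test_three_windows_of_eight_frames(self):
        scheme = make_windows(8, 4)
        assert scheme.n_windows == 3
        np.testing.assert_array_equal(scheme.starts, [0, 2, 4])

    def test_single_window(self):
        assert make_windows(4, 4).n_windows == 1

    def test_formula(self):
        assert make_windows(100, 4).n_windows == 49

    def test_odd_window_rejected(self):
        with pytest.raises(ValueError, match="even"):
            make_windows(10, 5)

    @settings(max_examples=200, derandomize=True, database=None)
    @given(st.integers(2, 60), st.integers(0, 400))
    def test_window_count_formula_exact(self, half, extra):
        dt = 2 * half
        nframes = dt + extra
        scheme = make_windows(nframes, dt)
        assert scheme.n_windows == (nframes - dt) // (dt // 2) + 1
        # consecutive windows share exactly half a window
        if scheme.n_windows > 1:
            s = scheme.starts
            assert (np.diff(s) == dt // 2).all()


class TestComputeFluctuogram:
    def test_single_window_equals_direct_match(self, rigid_network):
        traj = sample_from_network(rigid_network, 200, seed=31)
        scheme = make_windows(200, 200)
        fluct = compute_fluctuogram(traj, scheme, rigid_network.bond_indices)
        t = measure_targets(traj, rigid_network.bond_indices)
        direct, _ = fluctuation_match(t)
        assert fluct.n_windows == 1
        np.testing.assert_allclose(fluct.networks[0].force_constants,
                                   direct.force_constants, rtol=1e-12)

    def test_stationary_windows_statistically_identical(self, rigid_network):
        traj = sample_from_network(rigid_network, 3000, seed=32)
        scheme = make_windows(3000, 1000)
        fluct = compute_fluctuogram(traj, scheme, rigid_network.bond_indices)
        ks = np.array([n.force_constants for n in fluct.networks])
        rel_spread = ks.std(axis=0) / ks.mean(axis=0)
        # windows of 1000 frames put per-bond sampling noise near sqrt(2/1000)
        assert np.median(rel_spread) < 0.2

    def test_two_state_windows_recover_each_state(self):
        net_a = make_toy_network(12, 24, (2.0, 15.0), seed=41)
        k_b = net_a.force_constants.copy()
        k_b[5] += 12.0
        from fluctuogram.cg import ElasticNetwork

        net_b = ElasticNetwork(net_a.coordinates, net_a.bond_indices,
                               net_a.rest_lengths, k_b,
                               temperature=net_a.temperature)
        from fluctuogram.synth import two_state_trajectory

        traj, change_points = two_state_trajectory(net_a, net_b, 2000, seed=42)
        np.testing.assert_array_equal(change_points, [2000])
        scheme = make_windows(4000, 2000, stride=2000)  # disjoint halves
        fluct = compute_fluctuogram(traj, scheme, net_a.bond_indices)
        rel_a = np.abs(fluct.networks[0].force_constants - net_a.force_constants)
        rel_b = np.abs(fluct.networks[1].force_constants - k_b)
        assert rel_a[5] < 3.0 and rel_b[5] < 3.0
        # window B clearly sees the planted shift on bond 5
        assert (fluct.networks[1].force_constants[5]
                - fluct.networks[0].force_constants[5]) > 6.0


class TestResidueCoupling:
    def test_unconnected_residues_have_zero_coupling(self):
        fluct = fluctuogram_from_k([[1.0]], pool=np.array([[0, 1]]), n_sites=4)
        residues, k_ij, k_i = residue_coupling(fluct.networks[0],
                                               fluct.site_residues())
        assert k_ij[0, 2] == 0.0 and k_ij[2, 3] == 0.0

    def test_sums_bonds_between_residue_sites(self):
        # residues of two sites each: sites 0,1 -> residue 1; 2,3 -> residue 2
        pool = np.array([[0, 2], [0, 3], [1, 2]])
        fluct = fluctuogram_from_k([[1.0, 2.0, 3.0]], pool=pool, n_sites=4)
        residues, k_ij, k_i = residue_coupling(
            fluct.networks[0], np.array([1, 1, 2, 2]))
        assert k_ij[0, 1] == pytest.approx(6.0)
        assert k_i[0] == pytest.approx(6.0)

    def test_intra_residue_bonds_excluded_from_k_i(self):
        pool = np.array([[0, 1], [1, 2]])  # (0,1) intra, (1,2) inter
        fluct = fluctuogram_from_k([[5.0, 2.0]], pool=pool, n_sites=3)
        residues, k_ij, k_i = residue_coupling(
            fluct.networks[0], np.array([1, 1, 2]))
        assert k_ij[0, 0] == pytest.approx(5.0)  # diagonal keeps intra
        assert k_i[0] == pytest.approx(2.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(50)
        n_sites = 14
        site_res = np.sort(rng.integers(1, 7, size=n_sites))
        pairs = [(i, j) for i in range(n_sites) for j in range(i + 1, n_sites)]
        pool = np.array([pairs[p] for p in
                         rng.choice(len(pairs), size=30, replace=False)])
        k = rng.uniform(0, 10, size=30)
        fluct = fluctuogram_from_k([k], pool=pool, n_sites=n_sites)
        residues, k_ij, k_i = residue_coupling(fluct.networks[0], site_res)
        index = {r: n for n, r in enumerate(residues)}
        expected = np.zeros_like(k_ij)
        for (i, j), kk in zip(pool, k):
            a, b = index[site_res[i]], index[site_res[j]]
            expected[a, b] += kk
            if a != b:
                expected[b, a] += kk
        np.testing.assert_allclose(k_ij, expected, rtol=1e-12)
        np.testing.assert_allclose(
            k_i, (expected - np.diag(np.diag(expected))).sum(axis=1), rtol=1e-12)


class TestTwoStateDelta:
    def test_identical_states_all_weak(self):
        fluct = fluctuogram_from_k([[1.0, 2.0], [3.0, 1.0]],
                                   pool=np.array([[0, 1], [1, 2]]))
        s = coupling_series(fluct)
        cmp = delta_k_two_states(s, s)
        assert (cmp.delta_k == 0).all()
        assert (cmp.classes == "weak").all()

    def test_planted_large_residue_classified(self):
        base = np.array([[4.0, 3.0, 2.0]])
        shifted = base + np.array([[25.0, 0.0, 0.0]])
        pool = np.array([[0, 1], [1, 2], [2, 3]])
        sa = coupling_series(fluctuogram_from_k(list(base), pool=pool))
        sb = coupling_series(fluctuogram_from_k(list(shifted), pool=pool))
        cmp = delta_k_two_states(sb, sa)
        # the +25 bond touches residues 1 and 2
        assert cmp.classes[0] == "large" and cmp.classes[1] == "large"
        assert cmp.classes[3] == "weak"

    def test_antisymmetry(self):
        rng = np.random.default_rng(51)
        pool = np.array([(i, i + 1) for i in range(9)])
        ka = [rng.uniform(0, 30, 9) for _ in range(4)]
        kb = [rng.uniform(0, 30, 9) for _ in range(4)]
        sa = coupling_series(fluctuogram_from_k(ka, pool=pool))
        sb = coupling_series(fluctuogram_from_k(kb, pool=pool))
        ab = delta_k_two_states(sa, sb)
        ba = delta_k_two_states(sb, sa)
        np.testing.assert_allclose(ab.delta_k, -ba.delta_k, rtol=1e-12)

    def test_classes_match_brute_force_thresholds(self):
        rng = np.random.default_rng(52)
        pool = np.array([(i, i + 1) for i in range(9)])
        sa = coupling_series(fluctuogram_from_k(
            [rng.uniform(0, 40, 9) for _ in range(5)], pool=pool))
        sb = coupling_series(fluctuogram_from_k(
            [rng.uniform(0, 40, 9) for _ in range(5)], pool=pool))
        cmp = delta_k_two_states(sa, sb)
        for r in range(len(cmp.residues)):
            m = np.abs(sa.k_i[:, r] - sb.k_i[:, r]).mean()
            expected = "large" if m > 20 else ("significant" if m >= 10 else "weak")
            assert cmp.classes[r] == expected

    def test_roster_mismatch_raises(self):
        sa = coupling_series(fluctuogram_from_k([[1.0]], pool=np.array([[0, 1]])))
        sb = coupling_series(fluctuogram_from_k([[1.0], [2.0]],
                                                pool=np.array([[0, 1]])))
        with pytest.raises(RosterMismatchError):
            delta_k_two_states(sa, sb)


class TestConsecutiveMetrics:
    def test_identical_windows_zero_everywhere(self):
        k = [2.0, 0.0, 4.0]
        fluct = fluctuogram_from_k([k, k])
        series = coupling_series(fluct)
        assert (delta_k_consecutive(series) == 0).all()
        _, db = conformational_change(fluct)
        assert (db == 0).all()
        _, ps, _ = psi(fluct)
        live = ~np.isnan(ps)
        assert (ps[live] == 0).all()

    def test_single_window_gives_empty_series(self):
        series = coupling_series(fluctuogram_from_k([[1.0, 2.0]]))
        assert delta_k_consecutive(series).shape == (0, series.k_i.shape[1])

    def test_delta_k_matches_elementwise_oracle(self):
        rng = np.random.default_rng(53)
        ks = [rng.uniform(0, 20, 6) for _ in range(5)]
        series = coupling_series(fluctuogram_from_k(ks))
        dk = delta_k_consecutive(series)
        np.testing.assert_allclose(dk, series.k_i[1:] - series.k_i[:-1],
                                   rtol=1e-12)

    def test_delta_b_counts_only_live_bonds(self):
        """A stretched bond contributes |db| only while k is non-zero somewhere."""
        pool = np.array([[0, 1], [1, 2]])
        fluct = fluctuogram_from_k([[1.0, 0.0], [1.0, 0.0]], pool=pool)
        # stretch bond 0 by 0.3 A in the second window; bond 1 is dead (k=0 twice)
        fluct.networks[1].rest_lengths = fluct.networks[1].rest_lengths.copy()
        fluct.networks[1].rest_lengths[0] += 0.3
        fluct.networks[1].rest_lengths[1] += 9.9  # must not count
        residues, db = conformational_change(fluct)
        assert db[0, 0] == pytest.approx(0.3)
        assert db[0, 1] == pytest.approx(0.3)
        assert db[0, 2] == 0.0

    def test_psi_worked_three_bond_case(self):
        """k(t-1) = (2, 0, 4), k(t) = (4, 1, 2): terms (1/2, 1, -1/2), mean 1/3."""
        fluct = fluctuogram_from_k([[2.0, 0.0, 4.0], [4.0, 1.0, 2.0]])
        residues, ps, n = psi(fluct)
        assert ps[0, 0] == pytest.approx(1.0 / 3.0)
        assert n[0, 0] == 3

    def test_psi_bound_attainment(self):
        appear = fluctuogram_from_k([[0.0, 0.0], [3.0, 7.0]])
        vanish = fluctuogram_from_k([[3.0, 7.0], [0.0, 0.0]])
        assert psi(appear)[1][0, 0] == pytest.approx(1.0)
        assert psi(vanish)[1][0, 0] == pytest.approx(-1.0)

    def test_psi_undefined_residue_is_nan(self):
        fluct = fluctuogram_from_k([[1.0], [2.0]], pool=np.array([[0, 1]]),
                                   n_sites=3)
        _, ps, _ = psi(fluct)
        assert np.isnan(ps[0, 2])

    def test_psi_bounds_on_random_fluctuograms(self):
        """Property: psi in [-1, 1] for every residue and window."""
        rng = np.random.default_rng(54)
        for _ in range(1000):
            n_bonds = int(rng.integers(1, 8))
            n_windows = int(rng.integers(2, 5))
            ks = rng.uniform(0, 10, size=(n_windows, n_bonds))
            ks[rng.random(ks.shape) < 0.3] = 0.0
            if not (np.maximum(ks[:-1], ks[1:]) > 0).any():
                continue
            fluct = fluctuogram_from_k(list(ks))
            _, ps, _ = psi(fluct)
            live = ~np.isnan(ps)
            assert (ps[live] >= -1.0 - 1e-12).all()
            assert (ps[live] <= 1.0 + 1e-12).all()

    def test_change_point_window_has_maximal_psi(self):
        """The transition straddling the planted change carries the peak |psi|.

        The perturbed bond dominates its residues' bond sets: a sparse
        network (few bonds per site) and a large relative force-constant
        change keep the planted signal above the window sampling noise.
        """
        from fluctuogram.cg import ElasticNetwork
        from fluctuogram.synth import two_state_trajectory
        from fluctuogram.fluctgram import compute_fluctuogram

        base = make_toy_network(12, 6, (4.0, 15.0), seed=55)
        bond = int(np.nonzero(np.diff(base.bond_indices, axis=1).ravel() > 1)[0][0])
        k_a = base.force_constants.copy()
        k_a[bond] = 2.0
        k_b = k_a.copy()
        k_b[bond] = 17.0
        net_a = ElasticNetwork(base.coordinates, base.bond_indices,
                               base.rest_lengths, k_a, temperature=300.0)
        net_b = ElasticNetwork(base.coordinates, base.bond_indices,
                               base.rest_lengths, k_b, temperature=300.0)
        traj, _ = two_state_trajectory(net_a, net_b, 1600, seed=56)
        scheme = make_windows(3200, 800)  # change point at frame 1600 = window edge
        fluct = compute_fluctuogram(traj, scheme, net_a.bond_indices)
        residues, ps, _ = psi(fluct)
        i, j = net_a.bond_indices[bond]
        straddle = 3  # windows 2 (800-1600) -> 3 (1200-2000) -> 4 (1600-2400)
        for site in (i, j):
            assert np.nanargmax(np.abs(ps[:, site])) in (straddle - 1, straddle)
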