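"""Exciton Hamiltonian assembly, symmetry averaging, states, observables."""

import math

import numpy as np
import pytest

import lh2exciton as lx
from lh2exciton.exciton_model import (ExcitonStates, ring_permutation,
                                      _default_le_meta)


def bloch_two_band_energies(eps_a, eps_b, v_intra, v_inter, n_units=9):
    """Closed-form eigenvalues of the alternating NN ring (Bloch oracle).

    For each unit-cell momentum theta = 2 pi m / n the 2x2 Bloch block
    [[eps_a, v2 + v1 e^{-i theta}], [c.c., eps_b]] contributes
    mean +- sqrt(delta^2 + |v2 + v1 e^{i theta}|^2).
    """
    mean, delta = 0.5 * (eps_a + eps_b), 0.5 * (eps_a - eps_b)
    out = []
    for m in range(n_units):
        th = 2.0 * math.pi * m / n_units
        off = abs(v_intra + v_inter * np.exp(1j * th))
        gap = math.hypot(delta, off)
        out += [mean - gap, mean + gap]
    return np.sort(out)


def permutation_matrix(sigma):
    P = np.zeros((len(sigma), len(sigma)))
    for i, p in enumerate(sigma):
        P[p, i] = 1.0
    return P


class TestAssembly:
    def test_two_site_hamiltonian(self):
        ham = lx.assemble_hamiltonian(
            [13500.0, 13600.0], {(0, 1): 100.0},
            le_meta=[(0, 0, "alpha"), (1, 0, "beta")], n_units=1)
        assert np.allclose(ham.matrix,
                           [[13500.0, 100.0], [100.0, 13600.0]])

    def test_le_plus_ct_dimensions(self, ring18, nn_records):
        ct = lx.make_ct_manifold(ring18)
        ham = lx.hamiltonian_from_frame(ring18, nn_records, ct)
        assert ham.matrix.shape == (54, 54)
        assert np.allclose(ham.matrix, ham.matrix.T)
        # CT-CT block is zero off-diagonal
        ctb = ham.matrix[18:, 18:]
        assert np.allclose(ctb - np.diag(np.diag(ctb)), 0.0)

    def test_empty_ct_manifold_equals_omitted(self, ring18, nn_records):
        from lh2exciton.synthetic_ring import CTManifold

        empty = CTManifold(ct_labels=[], ct_energies=np.zeros(0),
                           le_ct_couplings={})
        a = lx.hamiltonian_from_frame(ring18, nn_records, empty)
        b = lx.hamiltonian_from_frame(ring18, nn_records)
        assert np.array_equal(a.matrix, b.matrix)

    def test_asymmetric_coupling_input_raises(self):
        with pytest.raises(ValueError, match="asymmetric"):
            lx.assemble_hamiltonian(
                [0.0, 0.0], {(0, 1): 5.0, (1, 0): 6.0},
                le_meta=[(0, 0, "alpha"), (1, 0, "beta")], n_units=1)

    def test_unknown_site_id_raises(self):
        with pytest.raises(ValueError):
            lx.assemble_hamiltonian(
                [0.0, 0.0], {(0, 7): 5.0},
                le_meta=[(0, 0, "alpha"), (1, 0, "beta")], n_units=1)


class TestSymmetryAverage:
    def test_symmetric_frame_is_a_fixed_point(self, ring18, nn_records):
        ham = lx.hamiltonian_from_frame(ring18, nn_records)
        avg = lx.symmetry_average([ham])
        assert np.allclose(avg.matrix, ham.matrix, atol=1e-9)

    def test_average_commutes_with_ring_rotation(self, ideal_ring):
        ens = lx.sample_ensemble(ideal_ring, lx.DisorderModel(seed=9),
                                 n_frames=10)
        hams = [lx.hamiltonian_from_frame(
            f, lx.couple_frame(f, method="point_dipole", cutoff=12.0))
            for f in ens.frames]
        avg = lx.symmetry_average(hams)
        P = permutation_matrix(ring_permutation(avg))
        assert np.max(np.abs(P @ avg.matrix - avg.matrix @ P)) < 1e-9

    def test_recovers_planted_means_and_three_site_classes(self, ideal_ring):
        """50-frame LL ensemble: averaged diagonal within 3 SE of planted."""
        params = lx.COMPLEX_PARAMS["LL"]
        base = lx.build_ideal_ring(site_energy_table=params.site_energies)
        ens = lx.sample_ensemble(
            base, lx.DisorderModel(sigma_by_role=dict(params.site_energy_sd)),
            n_frames=50, seed=13)
        hams = [lx.hamiltonian_from_frame(
            f, lx.couple_frame(f, method="point_dipole", cutoff=12.0))
            for f in ens.frames]
        avg = lx.symmetry_average(hams)
        diag = np.diag(avg.matrix)
        assert np.unique(np.round(diag, 9)).size == 3
        for role, idx in (("alpha", 0), ("beta", 1), ("b800", 18)):
            se = params.site_energy_sd[role] / math.sqrt(9 * 50)
            assert abs(diag[idx] - params.site_energies[role]) < 3 * se

    def test_inconsistent_bases_raise(self, ring18, nn_records, ideal_ring):
        small = lx.hamiltonian_from_frame(ring18, nn_records)
        big = lx.hamiltonian_from_frame(
            ideal_ring, lx.couple_frame(ideal_ring, method="point_dipole",
                                        cutoff=12.0))
        with pytest.raises(ValueError):
            lx.symmetry_average([small, big])


class TestDiagonalize:
    def test_diagonal_hamiltonian_returns_sites(self):
        eps = [13500.0, 13600.0, 13700.0]
        ham = lx.assemble_hamiltonian(
            eps, {}, le_meta=[(0, 0, "alpha"), (1, 0, "beta"), (2, 0, "b800")],
            n_units=1)
        st = lx.diagonalize(ham, np.eye(3))
        assert np.allclose(st.energies, eps)
        assert np.allclose(np.abs(st.coefficients), np.eye(3))

    def test_homodimer_closed_form(self):
        eps, v = 13500.0, 120.0
        ham = lx.assemble_hamiltonian(
            [eps, eps], {(0, 1): v},
            le_meta=[(0, 0, "alpha"), (1, 0, "beta")], n_units=1)
        mu = np.array([[0, 0, 6.3], [0, 0, 6.3]])
        st = lx.diagonalize(ham, mu)
        assert np.allclose(st.energies, [eps - v, eps + v])
        # for positive v the lower state is antisymmetric -> dark here
        assert st.dipole_strengths[0] == pytest.approx(0.0, abs=1e-18)
        assert st.dipole_strengths[1] == pytest.approx(2 * 6.3**2)

    def test_matches_bloch_dispersion_oracle(self):
        """Numeric eigenvalues equal the analytic two-band dispersion."""
        p = lx.COMPLEX_PARAMS["HL"]
        ham = lx.nearest_neighbor_ring_hamiltonian(
            p.site_energies["alpha"], p.site_energies["beta"],
            p.v1_inter, p.v2_intra)
        st = lx.diagonalize(ham)
        oracle = bloch_two_band_energies(
            p.site_energies["alpha"], p.site_energies["beta"],
            -p.v2_intra, -p.v1_inter)
        assert np.max(np.abs(st.energies - oracle)) < 1e-8

    def test_total_dipole_strength_conserved(self, ring18_states, ring18):
        total_site = np.sum(np.linalg.norm(ring18.dipoles, axis=1)**2)
        assert np.sum(ring18_states.dipole_strengths) == pytest.approx(
            total_site, rel=1e-6)

    def test_coefficients_orthonormal(self, ring18_states):
        C = ring18_states.coefficients
        assert np.max(np.abs(C.T @ C - np.eye(C.shape[1]))) < 1e-9

    def test_non_symmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            lx.ExcitonHamiltonian(np.array([[0.0, 1.0], [0.5, 0.0]]),
                                  [(0, 0, "alpha"), (1, 0, "beta")], 1)


class TestAssignK:
    def test_symmetric_ring_bright_states_are_k1_and_k8(self, ring18_states):
        thr = 1e-6 * ring18_states.dipole_strengths.max()
        bright_k = ring18_states.k_labels[ring18_states.dipole_strengths > thr]
        assert sorted(np.abs(bright_k)) == [1, 1, 8, 8]

    def test_lowest_state_is_k0_singlet(self, ring18_states):
        assert ring18_states.k_labels[0] == 0

    def test_localized_states_have_undefined_labels(self):
        eps = np.linspace(13000.0, 14700.0, 18)
        ham = lx.assemble_hamiltonian(eps, {},
                                      le_meta=_default_le_meta(9, False))
        ks = lx.assign_k(lx.diagonalize(ham))
        assert np.all(ks == ExcitonStates.UNDEFINED_K)

    def test_ring_relabeling_preserves_abs_k(self, ring18, nn_records):
        ham = lx.hamiltonian_from_frame(ring18, nn_records)
        P = permutation_matrix(ring_permutation(ham))
        rotated = lx.ExcitonHamiltonian(P @ ham.matrix @ P.T,
                                        list(ham.le_meta), 9)
        a = lx.assign_k(lx.diagonalize(ham))
        b = lx.assign_k(lx.diagonalize(rotated))
        assert np.array_equal(np.abs(a), np.abs(b))


class TestExcitonWidth:
    def test_uniform_ring_closed_form(self):
        """V1 = V2 = V: width = 4 V cos(pi/9)."""
        v = 250.0
        ham = lx.nearest_neighbor_ring_hamiltonian(13500.0, 13500.0, v, v)
        st = lx.diagonalize(ham)
        assert lx.exciton_width(st) == pytest.approx(
            4 * v * math.cos(math.pi / 9), rel=1e-10)

    @pytest.mark.parametrize("name,printed", [("HL", 1098.0), ("LL", 856.0),
                                              ("PucD", 842.0)])
    def test_tabulated_nn_widths_within_ten_percent(self, name, printed):
        """NN-only models land within 10% of the full-coupling widths."""
        st = lx.diagonalize(lx.tabulated_hamiltonian(name))
        assert abs(lx.exciton_width(st) - printed) / printed < 0.10

    def test_width_scales_linearly_with_couplings(self):
        ham = lx.nearest_neighbor_ring_hamiltonian(13500.0, 13500.0,
                                                   266.0, 298.0)
        scaled = lx.nearest_neighbor_ring_hamiltonian(13500.0, 13500.0,
                                                      0.5 * 266.0, 0.5 * 298.0)
        w = lx.exciton_width(lx.diagonalize(ham))
        ws = lx.exciton_width(lx.diagonalize(scaled))
        assert ws == pytest.approx(0.5 * w, rel=1e-10)

    def test_missing_labels_raise(self):
        eps = np.linspace(13000.0, 14700.0, 18)
        ham = lx.assemble_hamiltonian(eps, {},
                                      le_meta=_default_le_meta(9, False))
        with pytest.raises(ValueError):
            lx.exciton_width(lx.diagonalize(ham))

    def test_ll_k1_energy_blue_shifted_from_hl(self):
        def k1(name):
            st = lx.diagonalize(lx.tabulated_hamiltonian(name))
            ks = lx.assign_k(st)
            return float(np.mean(st.energies[np.abs(ks) == 1]))
        assert k1("LL") > k1("HL")


class TestBrightDarkCensus:
    def test_symmetric_ring_census(self, ring18_states):
        census = lx.bright_dark_census(ring18_states)
        assert census["n_dark"] == 14
        assert census["n_bright"] == 4
        assert census["n_degenerate_pairs"] == 8
        assert census["n_singlets"] == 2

    def test_disorder_redistributes_strength_to_dark_states(self, ideal_ring):
        """Static disorder brightens formerly dark ring states."""
        base = ideal_ring.b850_subframe()
        dm = lx.DisorderModel(sigma_by_role={"alpha": 280.0, "beta": 280.0},
                              orient_jitter_deg=8.0, radial_jitter_A=0.3)
        frame = lx.sample_ensemble(base, dm, n_frames=1, seed=21).frames[0]
        recs = lx.couple_frame(frame, method="point_dipole", cutoff=12.0)
        st = lx.diagonalize(lx.hamiltonian_from_frame(frame, recs),
                            frame.dipoles)
        census = lx.bright_dark_census(st)
        assert census["n_bright"] > 4


class TestCTShift:
    def make_pair(self, ring18, nn_records, **ct_kwargs):
        ct = lx.make_ct_manifold(ring18, **ct_kwargs)
        with_ct = lx.hamiltonian_from_frame(ring18, nn_records, ct)
        without = lx.hamiltonian_from_frame(ring18, nn_records)
        return with_ct, without

    def test_zero_ct_coupling_gives_zero_shift(self, ring18, nn_records):
        with_ct, without = self.make_pair(ring18, nn_records,
                                          default_coupling=0.0)
        res = lx.ct_shift(with_ct, without, ring18.dipoles)
        assert np.allclose(res["exact"], 0.0, atol=1e-9)
        assert np.allclose(res["perturbative"], 0.0)

    def test_perturbative_agrees_at_large_gap(self, ring18, nn_records):
        """Gap 10x coupling: exact and 2nd-order shifts agree within 5%."""
        coupling = 150.0
        mean = float(ring18.site_energies.max()) + 10 * coupling \
            + 700.0 - lx.CT_ALIGNMENT_SHIFT
        with_ct, without = self.make_pair(ring18, nn_records,
                                          energy_mean=mean,
                                          default_coupling=coupling)
        res = lx.ct_shift(with_ct, without, ring18.dipoles)
        k = np.argmin(res["exact"])  # largest-magnitude downshift
        assert res["exact"][k] < 0
        assert abs(res["perturbative"][k] - res["exact"][k]) \
            < 0.05 * abs(res["exact"][k])
        assert not res["ambiguous"].any()

    def test_lower_ct_energies_deepen_the_k1_downshift(self, ring18,
                                                       nn_records):
        without = lx.hamiltonian_from_frame(ring18, nn_records)
        st = lx.diagonalize(without, ring18.dipoles)
        ks = lx.assign_k(st)
        k1_states = np.where(np.abs(ks) == 1)[0]
        prev = 0.0
        base_mean = float(ring18.site_energies.max()) - lx.CT_ALIGNMENT_SHIFT
        for extra in (4000.0, 3000.0, 2000.0):
            ct = lx.make_ct_manifold(ring18, energy_mean=base_mean + extra)
            with_ct = lx.hamiltonian_from_frame(ring18, nn_records, ct)
            res = lx.ct_shift(with_ct, without, ring18.dipoles)
            shift = float(np.mean(res["exact"][k1_states]))
            assert shift < prev
            prev = shift
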