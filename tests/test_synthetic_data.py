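"""Generators: toy structures, surrogate ensemble, quadrature, ΔG datasets."""

import numpy as np
import pytest

from chelafix.alchemy import StateSpec
from chelafix.structure_mining import count_transitions, distance_only_c2
from chelafix.synthetic_data import (
    GridSampler,
    SampleArchive,
    SurrogateSpec,
    default_state_chain,
    default_swap_pairs,
    gaussian_pair_matrix,
    generate_configuration_cloud,
    generate_deltaG_dataset,
    generate_toy_complex_pdb,
    quadrature_bin_masses,
    quadrature_free_energies,
    sample_surrogate_ensemble,
    surrogate_potential,
    surrogate_reduced_energy,
)


class TestToyStructures:
    def test_same_seed_byte_identical(self, tmp_path):
        a = generate_toy_complex_pdb("AG", 0.1, seed=11,
                                     path=tmp_path / "a.pdb")
        b = generate_toy_complex_pdb("AG", 0.1, seed=11,
                                     path=tmp_path / "b.pdb")
        assert a.read_bytes() == b.read_bytes()

    def test_different_seed_differs(self, tmp_path):
        a = generate_toy_complex_pdb("AG", 0.1, seed=11,
                                     path=tmp_path / "a.pdb")
        b = generate_toy_complex_pdb("AG", 0.1, seed=12,
                                     path=tmp_path / "b.pdb")
        assert a.read_bytes() != b.read_bytes()

    def test_unknown_mode_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            generate_toy_complex_pdb("XYZ", path=tmp_path / "x.pdb")

    def test_negative_jitter_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            generate_toy_complex_pdb("BG", -0.1, path=tmp_path / "x.pdb")

    def test_cloud_labels_and_determinism(self):
        frames, labels = generate_configuration_cloud(n_per_mode=10, seed=4)
        assert labels.count("C2") == 10 and labels.count("C3") == 10
        frames2, _ = generate_configuration_cloud(n_per_mode=10, seed=4)
        assert np.allclose(frames[3].six_atom_coords,
                           frames2[3].six_atom_coords)


class TestSurrogatePotential:
    def test_barrier_scales_down_with_lambda(self, surrogate_spec):
        s = surrogate_spec
        b0 = surrogate_potential(s, s.r_barrier, 135.0, 0.0) \
            - surrogate_potential(s, s.r_c3, s.theta_c3, 0.0)
        b1 = surrogate_potential(s, s.r_barrier, 135.0, 1.0) \
            - surrogate_potential(s, s.r_c3, s.theta_c3, 1.0)
        assert b1 < b0
        assert b0 > 6.0  # native barrier is high

    def test_invalid_barriers_rejected(self):
        with pytest.raises(ValueError):
            SurrogateSpec(barrier_native=1.0, barrier_reduced=2.0)

    def test_quadrature_matches_scipy_dblquad(self, surrogate_spec):
        from scipy.integrate import dblquad

        spec = surrogate_spec
        state_a = StateSpec(lam=0.0)
        state_b = StateSpec(lam=1.0)
        f = quadrature_free_energies(spec, [state_a, state_b])

        def z(state):
            val, _err = dblquad(
                lambda th, r: np.exp(
                    -surrogate_potential(spec, r, th, state.lam) / spec.kT),
                2.0, 6.2, 20.0, 260.0, epsabs=1e-10, epsrel=1e-10)
            return val

        exact = -(np.log(z(state_b)) - np.log(z(state_a)))
        assert f[1] == pytest.approx(exact, abs=1e-6)

    def test_quadrature_identical_states_zero(self, surrogate_spec):
        f = quadrature_free_energies(surrogate_spec,
                                     [StateSpec(lam=0.3), StateSpec(lam=0.3)])
        assert f[1] == pytest.approx(0.0, abs=1e-12)

    def test_quadrature_grid_translation_invariance(self, surrogate_spec):
        states = [StateSpec(lam=0.0), StateSpec(lam=1.0)]
        f1 = quadrature_free_energies(surrogate_spec, states,
                                      r_range=(2.0, 6.2))
        f2 = quadrature_free_energies(surrogate_spec, states,
                                      r_range=(1.9, 6.3))
        assert np.allclose(f1, f2, atol=1e-6)

    def test_quadrature_richardson_convergence(self, surrogate_spec):
        states = [StateSpec(lam=0.0), StateSpec(lam=1.0)]
        # passes the internal doubling check without raising
        quadrature_free_energies(surrogate_spec, states,
                                 check_convergence=True)

    def test_truncated_support_detected(self, surrogate_spec):
        with pytest.raises(ValueError, match="truncat"):
            quadrature_free_energies(surrogate_spec, [StateSpec(lam=0.0)],
                                     r_range=(3.0, 4.0),
                                     theta_range=(100.0, 160.0))


class TestSampler:
    def test_reduced_charge_state_visits_both_wells(self, surrogate_spec):
        arch = sample_surrogate_ensemble(surrogate_spec,
                                         [StateSpec(lam=1.0)], 1000,
                                         seed=3, thin=5)
        r = arch.coords[0, :, 0]
        frac_c2 = (r > surrogate_spec.r_barrier).mean()
        assert 0.05 <= frac_c2 <= 0.95

    def test_native_state_stalls_behind_the_barrier(self, surrogate_spec):
        arch = sample_surrogate_ensemble(surrogate_spec,
                                         [StateSpec(lam=0.0)], 10000,
                                         seed=3, thin=1, n_equil_sweeps=0)
        labels = np.where(distance_only_c2(arch.coords[0, :, 0]),
                          "C2", "C3")
        assert count_transitions(list(labels)).total == 0

    def test_reduced_state_transitions_freely(self, surrogate_spec):
        arch = sample_surrogate_ensemble(surrogate_spec,
                                         [StateSpec(lam=1.0)], 10000,
                                         seed=3, thin=1, n_equil_sweeps=0)
        labels = np.where(distance_only_c2(arch.coords[0, :, 0]),
                          "C2", "C3")
        assert count_transitions(list(labels)).total > 10

    def test_same_seed_identical_archive(self, surrogate_spec):
        states = default_state_chain(surrogate_spec, n_lambda=5)
        a = sample_surrogate_ensemble(surrogate_spec, states, 150, seed=9,
                                      thin=2, n_equil_sweeps=50)
        b = sample_surrogate_ensemble(surrogate_spec, states, 150, seed=9,
                                      thin=2, n_equil_sweeps=50)
        assert np.array_equal(a.coords, b.coords)
        assert np.array_equal(a.u_kn, b.u_kn)

    def test_u_kn_reproducible_from_coordinates(self, small_archive):
        assert np.max(np.abs(small_archive.u_kn
                             - small_archive.recompute_u_kn())) <= 1e-10

    def test_archive_save_load_roundtrip(self, small_archive, tmp_path):
        small_archive.save(tmp_path / "arch.npz")
        back = SampleArchive.load(tmp_path / "arch.npz")
        assert np.array_equal(back.coords, small_archive.coords)
        assert [s.name for s in back.states] \
            == [s.name for s in small_archive.states]
        assert np.max(np.abs(back.recompute_u_kn() - back.u_kn)) <= 1e-10

    def test_too_few_samples_rejected(self, surrogate_spec):
        with pytest.raises(ValueError):
            sample_surrogate_ensemble(surrogate_spec, [StateSpec(lam=0.0)],
                                      50, seed=0)

    def test_swap_pairs_attach_restrained_states_at_native(self,
                                                           surrogate_spec):
        states = default_state_chain(surrogate_spec, n_lambda=5)
        pairs = default_swap_pairs(states)
        assert (5, 0) in pairs and (6, 0) in pairs
        assert (0, 1) in pairs


class TestGridSampler:
    def test_sample_shapes_and_energy(self, surrogate_spec, rng):
        sampler = GridSampler(surrogate_spec)
        x = sampler.sample(0.5, 200, rng)
        assert x.shape == (200, 3)
        u = sampler.reduced_energy(0.5, x)
        assert np.all(np.isfinite(u))

    def test_reduced_state_samples_both_wells(self, surrogate_spec, rng):
        sampler = GridSampler(surrogate_spec)
        x = sampler.sample(1.0, 2000, rng)
        frac = (x[:, 0] > surrogate_spec.r_barrier).mean()
        assert 0.2 <= frac <= 0.8

    def test_bath_center_tracks_lambda(self, surrogate_spec, rng):
        sampler = GridSampler(surrogate_spec)
        x = sampler.sample(1.0, 4000, rng)
        assert x[:, 2].mean() == pytest.approx(surrogate_spec.bath_shift,
                                               abs=0.1)


class TestBinMassOracle:
    def test_masses_normalized_and_match_quadrature_marginal(
            self, surrogate_spec):
        state = StateSpec(lam=1.0)
        r_edges = np.linspace(2.6, 5.2, 30)
        th_edges = np.linspace(60.0, 220.0, 30)
        mass = quadrature_bin_masses(surrogate_spec, state, r_edges,
                                     th_edges)
        assert mass.sum() == pytest.approx(1.0, abs=1e-6)
        # probability of the C2 side of the barrier, via an independent path
        gs = GridSampler(surrogate_spec)
        p = gs._probs(1.0).reshape(gs._gr.shape)
        frac_exact = p[gs.r > surrogate_spec.r_barrier, :].sum()
        split = r_edges.searchsorted(surrogate_spec.r_barrier)
        assert mass[split:, :].sum() == pytest.approx(frac_exact, abs=0.01)


class TestDeltaGDatasets:
    def test_deterministic_label_count(self):
        records, truth = generate_deltaG_dataset(30, c2_fraction=13 / 30,
                                                 seed=8)
        assert sum(r.observed_mode == "C2" for r in records) == 13
        assert len(records) == 30
        assert (truth["true_bias"] == 6.1).all()

    def test_noise_free_unbiased_dataset_is_perfect_at_zero(self):
        from chelafix.correction import fit_offset, prediction_accuracy

        records, _ = generate_deltaG_dataset(20, true_bias=0.0, noise_sd=0.0,
                                             seed=2)
        assert prediction_accuracy(records, 0.0)[0] == 20
        lo, hi = fit_offset(records).chosen_interval
        assert lo < 0.0 < hi

    def test_same_seed_reproducible(self):
        a, _ = generate_deltaG_dataset(15, seed=3)
        b, _ = generate_deltaG_dataset(15, seed=3)
        assert [(r.delta_g_c3_to_c2, r.observed_mode) for r in a] \
            == [(r.delta_g_c3_to_c2, r.observed_mode) for r in b]

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            generate_deltaG_dataset(1)
        with pytest.raises(ValueError):
            generate_deltaG_dataset(10, c2_fraction=0.0)


class TestGaussianPair:
    def test_exact_value_and_shapes(self):
        mat, exact = gaussian_pair_matrix(500, seed=0)
        assert exact == pytest.approx(-np.log(2.0))
        assert mat.u_kn.shape == (2, 1000)
        assert mat.N_k.tolist() == [500, 500]
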