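"""Tail-frame PCA, density clusters, free-energy surfaces."""

import numpy as np
import pytest

from chelafix.pca_landscape import (
    KT_300K,
    Axis,
    ExtractionError,
    TailFrame,
    build_fes,
    estimate_density_clusters,
    extract_tail_frame,
    fit_pca,
    marginalize_fes,
    phosphate_angle,
    project,
    reproject_angle_fes,
    select_diverse_subset,
    superpose,
)
from chelafix.synthetic_data import (
    generate_configuration_cloud,
    toy_ligand_complex,
    toy_tail_frame,
)


def _rigid(frame, rng):
    from scipy.spatial.transform import Rotation

    q = rng.normal(size=4)
    R = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
    t = rng.uniform(-10, 10, 3)
    return TailFrame(frame.six_atom_coords @ R.T + t,
                     {k: v @ R.T + t
                      for k, v in frame.all_phosphate_oxygens.items()})


class TestExtract:
    def test_roundtrip_matches_template(self):
        cx = toy_ligand_complex("ABG")
        frame = extract_tail_frame(cx)
        assert np.allclose(frame.atom("PA"), cx.atom("PA").position)
        assert np.allclose(frame.atom("MG"), cx.mg.position)
        assert "O1G" in frame.all_phosphate_oxygens

    def test_missing_atom_names_it(self):
        cx = toy_ligand_complex("ABG")
        cx.atp_atoms = [a for a in cx.atp_atoms if a.atom_name != "PG"]
        with pytest.raises(ExtractionError, match="PG"):
            extract_tail_frame(cx)

    def test_no_implicit_centering(self):
        cx = toy_ligand_complex("BG")
        ref = extract_tail_frame(cx).six_atom_coords.copy()
        for a in cx.atp_atoms:
            a.position = a.position + np.array([1.0, 2.0, 3.0])
        cx.mg.position = cx.mg.position + np.array([1.0, 2.0, 3.0])
        assert np.allclose(extract_tail_frame(cx).six_atom_coords,
                           ref + [1.0, 2.0, 3.0])


class TestSuperpose:
    def test_rigid_copy_fits_back_exactly(self, rng):
        f = toy_tail_frame("ABG")
        moved = _rigid(f, rng)
        fitted = superpose([moved], reference=f)[0]
        rmsd = np.sqrt(np.mean((fitted.six_atom_coords
                                - f.six_atom_coords) ** 2))
        assert rmsd < 1e-8

    def test_identical_frames_unchanged(self):
        f = toy_tail_frame("BG")
        out = superpose([f, f, f])
        for o in out:
            assert np.allclose(o.six_atom_coords, f.six_atom_coords,
                               atol=1e-10)

    def test_pairwise_rmsd_preserved_under_random_motions(self, rng):
        base = [toy_tail_frame("BG", 0.2, rng) for _ in range(4)]
        moved = [_rigid(f, rng) for f in base]
        fitted = superpose(moved)
        ref_fit = superpose(base)

        def pair_rmsd(frames, i, j):
            d = frames[i].six_atom_coords - frames[j].six_atom_coords
            return np.sqrt(np.mean(d**2))

        # superposition onto a common mean preserves shape differences
        for i in range(4):
            for j in range(i + 1, 4):
                assert pair_rmsd(fitted, i, j) == pytest.approx(
                    pair_rmsd(ref_fit, i, j), abs=1e-6)

    def test_collinear_reference_rejected(self):
        coords = np.zeros((6, 3))
        coords[:, 0] = np.arange(6)
        with pytest.raises(ValueError, match="collinear"):
            superpose([TailFrame(coords)])


class TestPCA:
    def test_identical_frames_zero_eigenvalues(self):
        f = toy_tail_frame("ABG")
        model = fit_pca([f, f, f])
        assert np.allclose(model.eigenvalues, 0.0, atol=1e-12)

    def test_single_coordinate_variation(self):
        base = toy_tail_frame("BG").six_atom_coords
        shifts = [-0.3, -0.1, 0.2, 0.2]
        frames = []
        for s in shifts:
            c = base.copy()
            c[5, 2] += s  # Mg z only
            frames.append(TailFrame(c))
        model = fit_pca(frames)
        assert np.sum(model.eigenvalues > 1e-12) == 1
        assert model.eigenvalues[0] == pytest.approx(np.var(shifts, ddof=1))

    def test_orthonormality_and_total_variance(self, rng):
        frames = [toy_tail_frame("BG", 0.2, rng) for _ in range(40)]
        frames = superpose(frames)
        model = fit_pca(frames)
        gram = model.eigenvectors.T @ model.eigenvectors
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-10)
        X = np.array([f.flat for f in frames])
        total_var = np.trace(np.cov(X, rowvar=False, ddof=1))
        assert model.eigenvalues.sum() == pytest.approx(total_var, abs=1e-10)

    def test_matches_sklearn_pca(self, rng):
        sklearn_pca = pytest.importorskip("sklearn.decomposition").PCA
        frames = superpose([toy_tail_frame("BG", 0.2, rng)
                            for _ in range(30)])
        model = fit_pca(frames)
        X = np.array([f.flat for f in frames])
        ref = sklearn_pca(n_components=5).fit(X)
        assert np.allclose(model.eigenvalues[:5], ref.explained_variance_,
                           atol=1e-8)

    def test_c2_c3_clouds_linearly_separable(self):
        lda_mod = pytest.importorskip("sklearn.discriminant_analysis")
        frames, labels = generate_configuration_cloud(n_per_mode=150, seed=3)
        frames = superpose(frames)
        model = fit_pca(frames, c2c3_labels=labels)
        proj = project(model, frames)
        clf = lda_mod.LinearDiscriminantAnalysis().fit(proj, labels)
        assert clf.score(proj, labels) >= 0.99
        # orientation convention: C3 mean negative on EV2
        c3 = np.array(labels) == "C3"
        assert proj[c3, 1].mean() < 0

    def test_too_few_frames(self):
        with pytest.raises(ValueError):
            fit_pca([toy_tail_frame("BG")])


class TestProject:
    def test_mean_maps_to_origin_and_ev_units(self, rng):
        frames = superpose([toy_tail_frame("BG", 0.2, rng)
                            for _ in range(20)])
        model = fit_pca(frames)
        mean_frame = TailFrame(model.mean_coords.reshape(6, 3))
        assert np.allclose(project(model, [mean_frame])[0], 0.0, atol=1e-10)
        alpha = 0.7  # Å along EV1
        shifted = TailFrame((model.mean_coords
                             + alpha * model.eigenvectors[:, 0]).reshape(6, 3))
        p = project(model, [shifted])[0]
        assert p[0] == pytest.approx(alpha / 10.0, abs=1e-10)  # nm
        assert p[1] == pytest.approx(0.0, abs=1e-10)

    def test_fitting_set_projections_centered(self, rng):
        frames = superpose([toy_tail_frame("ABG", 0.2, rng)
                            for _ in range(25)])
        model = fit_pca(frames)
        assert np.allclose(project(model, frames).mean(axis=0), 0.0,
                           atol=1e-10)

    def test_dimension_mismatch(self, rng):
        frames = superpose([toy_tail_frame("BG", 0.2, rng)
                            for _ in range(5)])
        model = fit_pca(frames)
        bad = np.delete(model.eigenvectors, 0, axis=0)
        model.eigenvectors = bad / np.linalg.norm(bad, axis=0)
        with pytest.raises(ValueError):
            project(model, frames)


class TestDensityClusters:
    def test_two_separated_clouds_two_clusters(self, rng):
        pts = np.vstack([rng.normal(0, 0.3, (300, 2)),
                         rng.normal(6, 0.3, (300, 2))])
        dm = estimate_density_clusters(pts, level=0.2)
        assert len(dm.cluster_names) == 2
        assert dm.cluster_names[1] == "I"

    def test_single_cloud_one_cluster(self, rng):
        dm = estimate_density_clusters(rng.normal(0, 1, (200, 2)), level=0.2)
        assert len(dm.cluster_names) == 1

    def test_density_normalized(self, rng):
        dm = estimate_density_clusters(rng.normal(0, 1, (100, 2)))
        cell = (np.diff(dm.axes[0].edges)[0] * np.diff(dm.axes[1].edges)[0])
        assert dm.density.sum() * cell == pytest.approx(1.0, abs=1e-6)

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError):
            estimate_density_clusters(np.ones((20, 2)))


class TestBuildFES:
    def test_uniform_two_bins_flat(self):
        pts = np.array([0.25, 0.25, 0.75, 0.75])
        axes = [Axis("x", np.array([0.0, 0.5, 1.0]), "")]
        fes = build_fes(pts, axes=axes)
        assert np.allclose(fes.free_energy, 0.0)

    def test_weight_ratio_gives_delta_f(self):
        kT = 0.6
        pts = np.array([0.25, 0.75])
        w = np.array([1.0, np.exp(-2.0)])
        axes = [Axis("x", np.array([0.0, 0.5, 1.0]), "")]
        fes = build_fes(pts, weights=w, axes=axes, kT=kT)
        assert fes.free_energy[1] - fes.free_energy[0] == pytest.approx(
            2.0 * kT, abs=1e-12)

    def test_equal_weights_reduce_to_log_counts(self, rng):
        pts = rng.normal(0, 1, 300)
        fes = build_fes(pts, kT=KT_300K, n_bins=20)
        counts = fes.bin_weight
        expected = -KT_300K * np.log(counts, where=counts > 0,
                                     out=np.full_like(counts, np.nan))
        expected -= np.nanmin(expected)
        good = counts > 0
        assert np.allclose(fes.free_energy[good], expected[good], atol=1e-10)

    def test_cap_and_empty_bins_flagged(self):
        pts = np.array([0.1] * 1000000 + [0.9])
        axes = [Axis("x", np.linspace(0, 1, 5), "")]
        fes = build_fes(pts, axes=axes, kT=2.0, cap=18.0)
        # ln(1e6) * 2 kcal/mol > 18 → the single-count bin is inaccessible
        assert fes.inaccessible_mask[-1]
        assert fes.inaccessible_mask[1]  # empty bin
        assert not fes.inaccessible_mask[0]

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            build_fes(np.array([1.0, 2.0]), weights=np.zeros(2))


class TestAngle:
    def test_collinear_is_180(self):
        f = toy_tail_frame("BG")
        c = f.six_atom_coords.copy()
        c[0] = [2, 0, 0]   # PA
        c[2] = [0, 0, 0]   # PB
        c[4] = [-3, 0, 0]  # PG
        assert phosphate_angle(TailFrame(c)) == pytest.approx(180.0)

    def test_right_angle(self):
        c = toy_tail_frame("BG").six_atom_coords.copy()
        c[0] = [1, 0, 0]
        c[2] = [0, 0, 0]
        c[4] = [0, 1, 0]
        assert phosphate_angle(TailFrame(c)) == pytest.approx(90.0)

    def test_rigid_invariance(self, rng):
        f = toy_tail_frame("ABG")
        ref = phosphate_angle(f)
        assert phosphate_angle(_rigid(f, rng)) == pytest.approx(ref,
                                                                abs=1e-10)

    def test_coincident_phosphorus_rejected(self):
        c = toy_tail_frame("BG").six_atom_coords.copy()
        c[0] = c[2]
        with pytest.raises(ValueError):
            phosphate_angle(TailFrame(c))


class TestReprojection:
    def test_single_configuration_single_bin(self):
        frames = [toy_tail_frame("BG")] * 5
        fes = reproject_angle_fes(frames, None, np.zeros(5), n_bins=10)
        occupied = fes.bin_weight > 0
        assert occupied.sum() == 1
        assert fes.free_energy[occupied][0] == 0.0

    def test_minimum_in_constructed_region(self, rng):
        # extended (BG-like, angle > 150°) frames carry most weight
        frames = ([toy_tail_frame("BG", 0.1, rng) for _ in range(50)]
                  + [toy_tail_frame("ABG", 0.1, rng) for _ in range(50)])
        w = np.array([10.0] * 50 + [0.1] * 50)
        fes = reproject_angle_fes(frames, w / w.sum(),
                                  np.zeros(100), n_bins=20)
        idx = np.unravel_index(np.nanargmin(
            np.where(fes.bin_weight > 0, fes.free_energy, np.nan)),
            fes.free_energy.shape)
        assert fes.axes[0].centers[idx[0]] > 150.0

    def test_marginalizing_matches_1d_surface(self, rng):
        frames = [toy_tail_frame("BG", 0.2, rng) for _ in range(100)]
        ev2 = rng.normal(0, 0.05, 100)
        w = rng.uniform(0.5, 2.0, 100)
        fes2 = reproject_angle_fes(frames, w, ev2, n_bins=12)
        marg = marginalize_fes(fes2, keep_axis=0)
        angles = np.array([phosphate_angle(f) for f in frames])
        fes1 = build_fes(angles, w, axes=[fes2.axes[0]])
        good = marg.bin_weight > 0
        assert np.allclose(marg.free_energy[good], fes1.free_energy[good],
                           atol=1e-10)


class TestDiverseSubset:
    def test_k_equals_n(self):
        assert select_diverse_subset(np.zeros((4, 2)), 4) == [0, 1, 2, 3]

    def test_unit_square_k2_picks_a_diagonal(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
        idx = select_diverse_subset(pts, 2)
        d = np.linalg.norm(pts[idx[0]] - pts[idx[1]])
        assert d == pytest.approx(np.sqrt(2.0))

    def test_matches_brute_force_optimum(self, rng):
        from itertools import combinations

        pts = rng.uniform(0, 1, (10, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)

        def objective(sub):
            return sum(D[i, j] for i, j in combinations(sub, 2))

        best = max(objective(c) for c in combinations(range(10), 3))
        chosen = select_diverse_subset(pts, 3)
        assert objective(chosen) == pytest.approx(best, abs=1e-12)

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            select_diverse_subset(np.zeros((3, 2)), 4)
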