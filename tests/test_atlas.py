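import numpy as np
import pytest

from lvatlas import (
    CohortDesign,
    align_meshes,
    compute_atlas,
    project_case,
    reconstruct_shape,
    sample_shape_params,
)
from lvatlas.meshfit import LVMesh, mesh_cavity_volume, mesh_from_shape


def tiny_mesh(jitter_rng=None, scale=1.0):
    """Minimal-topology mesh (tens of nodes) for oracle comparisons."""
    m = mesh_from_shape(CohortDesign().baseline, n_circ=3, n_long=2)
    m.nodes = m.nodes * scale
    if jitter_rng is not None:
        m.nodes = m.nodes + jitter_rng.normal(0, 0.02, m.nodes.shape)
    return m


class TestAlignMeshes:
    def test_translation_removed_exactly(self):
        m = tiny_mesh()
        m2 = m.copy()
        m2.nodes = m.nodes + np.array([4.0, -1.0, 2.5])
        a, transforms = align_meshes([m, m2])
        assert np.abs(a[0].nodes - a[1].nodes).max() < 1e-9
        assert np.allclose(transforms[1]["translation"] - transforms[0]["translation"],
                           [4.0, -1.0, 2.5])

    def test_known_rotation_removed(self):
        m = mesh_from_shape(CohortDesign().baseline.with_updates(apex_offset_mm=0.2),
                            n_circ=8, n_long=8)
        ang = np.deg2rad(30)
        R = np.array([[np.cos(ang), -np.sin(ang), 0],
                      [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
        m2 = m.copy()
        m2.nodes = m.nodes @ R.T
        a, _ = align_meshes([m, m2])
        assert np.abs(a[0].nodes - a[1].nodes).max() < 1e-6

    def test_scale_preserved_by_design(self):
        m = tiny_mesh()
        big = tiny_mesh(scale=1.2)
        a, _ = align_meshes([m, big])
        rms = [np.sqrt((x.nodes**2).sum(axis=1).mean()) for x in a]
        assert rms[1] / rms[0] == pytest.approx(1.2, rel=1e-9)

    def test_degenerate_cloud_errors(self):
        m = tiny_mesh()
        flat = m.copy()
        flat.nodes = m.nodes * np.array([1.0, 1.0, 0.0])  # rank-2 cloud
        with pytest.raises(ValueError):
            align_meshes([flat, flat.copy()])


class TestComputeAtlas:
    def test_matches_bruteforce_covariance_eigendecomposition(self, rng):
        """Case-space SVD atlas equals the naive 3N×3N covariance
        eigendecomposition on a small cohort, up to mode sign."""
        meshes = [tiny_mesh(jitter_rng=rng) for _ in range(8)]
        aligned, _ = align_meshes(meshes)
        atlas = compute_atlas(aligned)

        X = np.stack([m.nodes.ravel() for m in aligned])
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / (len(X) - 1)
        evals, evecs = np.linalg.eigh(cov)
        evals, evecs = evals[::-1], evecs[:, ::-1]

        m = atlas.n_modes
        assert np.allclose(atlas.eigenvalues, evals[:m], atol=1e-8)
        for j in range(m):
            dot = abs(np.dot(atlas.modes[:, j], evecs[:, j]))
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_identical_meshes_give_zero_modes(self):
        m = tiny_mesh()
        aligned, _ = align_meshes([m.copy(), m.copy(), m.copy()])
        atlas = compute_atlas(aligned)
        assert atlas.n_modes == 0
        # mean equals the (aligned) mesh itself
        assert np.abs(atlas.mean_shape.reshape(-1, 3) - aligned[0].nodes).max() < 1e-12

    def test_one_parameter_scaling_family_has_one_mode(self):
        meshes = [tiny_mesh(scale=s) for s in (0.9, 0.95, 1.0, 1.05, 1.1)]
        aligned, _ = align_meshes(meshes)
        atlas = compute_atlas(aligned)
        assert atlas.variance_fractions[0] > 0.999

    def test_orthonormal_modes_and_variance_fractions(self, rng):
        meshes = [tiny_mesh(jitter_rng=rng) for _ in range(6)]
        aligned, _ = align_meshes(meshes)
        atlas = compute_atlas(aligned)
        gram = atlas.modes.T @ atlas.modes
        assert np.abs(gram - np.eye(atlas.n_modes)).max() < 1e-8
        assert atlas.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(atlas.eigenvalues) <= 1e-12)
        assert atlas.n_modes <= len(meshes) - 1

    def test_input_order_invariance_bit_identical(self, rng):
        meshes = [tiny_mesh(jitter_rng=rng) for _ in range(6)]
        aligned, _ = align_meshes(meshes)
        a1 = compute_atlas(aligned, case_ids=[str(i) for i in range(6)])
        perm = [3, 1, 5, 0, 4, 2]
        a2 = compute_atlas([aligned[i] for i in perm], case_ids=[str(i) for i in perm])
        assert np.array_equal(a1.mean_shape, a2.mean_shape)
        assert np.allclose(a1.modes, a2.modes, atol=1e-10)
        assert np.allclose(sorted(a1.scores[:, 0]), sorted(a2.scores[:, 0]), atol=1e-10)


class TestProjectReconstruct:
    @pytest.fixture()
    def atlas(self, rng):
        meshes = [tiny_mesh(jitter_rng=rng) for _ in range(8)]
        aligned, _ = align_meshes(meshes)
        self.aligned = aligned
        return compute_atlas(aligned)

    def test_mean_projects_to_zero(self, atlas):
        coeffs = project_case(atlas, atlas.mean_mesh())
        assert np.abs(coeffs).max() < 1e-10

    def test_pure_mode_projects_to_its_coefficient(self, atlas):
        sigma1 = np.sqrt(atlas.eigenvalues[0])
        mesh = reconstruct_shape(atlas, np.array([2 * sigma1]))
        coeffs = project_case(atlas, mesh)
        assert coeffs[0] == pytest.approx(2 * sigma1, abs=1e-9)
        assert np.abs(coeffs[1:]).max() < 1e-9

    def test_training_roundtrip_below_1e6_mm(self, atlas):
        for mesh in self.aligned:
            rec = reconstruct_shape(atlas, project_case(atlas, mesh))
            assert np.abs(rec.nodes - mesh.nodes).max() < 1e-6

    def test_too_many_coefficients_rejected(self, atlas):
        with pytest.raises(ValueError):
            reconstruct_shape(atlas, np.zeros(atlas.n_modes + 1))

    def test_mode1_extremes_straddle_mean_cavity_volume(self):
        """On a size-varying family mode 1 encodes size, so ±3σ shapes
        bracket the mean shape's cavity volume."""
        rng = np.random.default_rng(0)
        meshes = [tiny_mesh(jitter_rng=rng, scale=s)
                  for s in np.linspace(0.85, 1.15, 8)]
        aligned, _ = align_meshes(meshes)
        atlas = compute_atlas(aligned)
        s1 = np.sqrt(atlas.eigenvalues[0])
        v_mean, _ = mesh_cavity_volume(atlas.mean_mesh())
        v_lo, _ = mesh_cavity_volume(reconstruct_shape(atlas, np.array([-3 * s1])))
        v_hi, _ = mesh_cavity_volume(reconstruct_shape(atlas, np.array([+3 * s1])))
        assert min(v_lo, v_hi) < v_mean < max(v_lo, v_hi)

    def test_atlas_roundtrip_through_npz(self, atlas, tmp_path):
        from lvatlas import ShapeAtlas
        p = tmp_path / "atlas.npz"
        atlas.save(p)
        back = ShapeAtlas.load(p)
        assert np.array_equal(back.modes, atlas.modes)
        assert back.case_ids == atlas.case_ids
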