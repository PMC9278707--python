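import dataclasses

import numpy as np
import pytest

from lvatlas import (
    AcquisitionSpec,
    CohortDesign,
    DEFAULT_BASELINE_SHAPE,
    PhysiologyConfig,
    generate_cohort,
    render_volumes,
    sample_shape_params,
    simulate_echo_record,
)
from lvatlas.geometry import shell_volume
from lvatlas.echo import radial_strain

ZERO_SHAPE_NOISE = {k: 0.0 for k in
                    ("length_mm", "endo_radius_mm", "wall_mm", "apex_offset_mm", "truncation_frac")}


class TestSampleShapeParams:
    def test_zero_noise_zero_effects_returns_baseline(self):
        design = CohortDesign(effect_map={}, oxygen_levels=("room_air",),
                              treatment_levels=("CD",), shape_noise_sd=ZERO_SHAPE_NOISE)
        s = sample_shape_params(design, "room_air", "CD", 0)
        assert s == DEFAULT_BASELINE_SHAPE

    def test_seeded_determinism(self):
        design = CohortDesign(master_seed=11)
        a = sample_shape_params(design, "high_O2", "CD_Ang17", 2)
        b = sample_shape_params(design, "high_O2", "CD_Ang17", 2)
        assert a == b

    def test_unknown_level_raises(self):
        design = CohortDesign()
        with pytest.raises(KeyError):
            sample_shape_params(design, "medium_O2", "CD", 0)
        with pytest.raises(IndexError):
            sample_shape_params(design, "room_air", "CD", design.n_per_cell)

    def test_hyperoxia_cell_mean_shift_recovered_by_monte_carlo(self):
        """10k draws from the high-O2 vehicle cell: shorter and more
        globular than baseline, matching the configured effect map."""
        design = CohortDesign(n_per_cell=10_000, master_seed=5)
        base = design.baseline
        draws = [sample_shape_params(design, "high_O2", "CD", i) for i in range(0, 10_000, 10)]
        mean_len = np.mean([d.length_mm for d in draws])
        mean_sph = np.mean([d.sphericity for d in draws])
        assert mean_len < base.length_mm
        assert mean_len == pytest.approx(0.85 * base.length_mm, rel=0.02)
        assert mean_sph > base.sphericity

    def test_unsatisfiable_cell_mean_raises(self):
        from lvatlas import ShapeEffect
        design = CohortDesign(effect_map={
            "high_O2": ShapeEffect(wall_scale=3.0),  # wall >= radius
            "CD_Ang17": ShapeEffect(), "CD_Ala": ShapeEffect(),
        })
        with pytest.raises(ValueError):
            sample_shape_params(design, "high_O2", "CD", 0)


class TestRenderVolumes:
    def test_symmetric_shape_gives_mirror_symmetric_mask(self, noiseless_acq):
        mask, _ = render_volumes(DEFAULT_BASELINE_SHAPE, noiseless_acq, 0)
        assert DEFAULT_BASELINE_SHAPE.apex_offset_mm == 0
        assert np.array_equal(mask.voxels, mask.voxels[::-1])  # x mirror
        assert np.array_equal(mask.voxels, mask.voxels[:, ::-1])  # y mirror

    def test_voxel_count_matches_analytic_shell_volume(self, noiseless_acq):
        shape = DEFAULT_BASELINE_SHAPE.with_updates(apex_offset_mm=0.2)
        mask, _ = render_volumes(shape, noiseless_acq, 0)
        vox = mask.n_foreground * mask.voxel_volume_mm3
        assert vox == pytest.approx(shell_volume(shape), rel=0.05)

    def test_halving_slice_spacing_converges(self, noiseless_acq):
        mask, _ = render_volumes(DEFAULT_BASELINE_SHAPE, noiseless_acq, 0)
        fine = dataclasses.replace(noiseless_acq, n_slices=noiseless_acq.n_slices * 2,
                                   slice_spacing_mm=noiseless_acq.slice_spacing_mm / 2)
        mask2, _ = render_volumes(DEFAULT_BASELINE_SHAPE, fine, 0)
        v1 = mask.n_foreground * mask.voxel_volume_mm3
        v2 = mask2.n_foreground * mask2.voxel_volume_mm3
        assert abs(v2 - v1) / v1 < 0.02

    def test_oversized_shape_errors_with_dimension_name(self):
        tiny = AcquisitionSpec(n_slices=10, slice_spacing_mm=0.1, pixel_mm=0.05,
                               image_size_px=96, speckle_sd=0)
        with pytest.raises(ValueError, match="z"):
            render_volumes(DEFAULT_BASELINE_SHAPE, tiny, 0)


class TestSimulateEchoRecord:
    def test_zero_noise_identities(self):
        physio = PhysiologyConfig(contraction_fraction=0.5,
                                  noise_sd={k: 0.0 for k in
                                            ("lvid", "wall", "velocity", "eprime",
                                             "time", "hr", "weight", "trace")})
        rec = simulate_echo_record(DEFAULT_BASELINE_SHAPE, physio, 0)
        assert rec.lvid_d_mm == pytest.approx(2 * DEFAULT_BASELINE_SHAPE.endo_radius_mm)
        # forced fractional shortening of 50%
        assert (rec.lvid_d_mm - rec.lvid_s_mm) / rec.lvid_d_mm == pytest.approx(0.5)
        strain, _ = radial_strain(rec.endo_radius_trace_mm, rec.frame_interval_ms)
        assert strain == pytest.approx(50.0, abs=0.5)

    def test_trace_extrema_match_mmode_diameters(self):
        rec = simulate_echo_record(DEFAULT_BASELINE_SHAPE, PhysiologyConfig(), 7)
        assert rec.endo_radius_trace_mm.max() == pytest.approx(rec.lvid_d_mm / 2, abs=0.05)
        assert rec.endo_radius_trace_mm.min() == pytest.approx(rec.lvid_s_mm / 2, abs=0.05)

    def test_invalid_contraction_fraction(self):
        with pytest.raises(ValueError):
            PhysiologyConfig(contraction_fraction=1.2)


class TestGenerateCohort:
    def test_default_design_yields_24_animals(self, small_acq, tmp_path):
        design = CohortDesign(master_seed=1)
        bundle = generate_cohort(design, small_acq, out_dir=tmp_path, echo=True)
        assert len(bundle) == 24
        assert len(list(tmp_path.glob("*_mask.nii"))) == 24
        assert len(bundle.manifest) == 24
        assert bundle.manifest["animal_id"].is_unique

    def test_single_animal_manifest(self, small_acq):
        design = CohortDesign(oxygen_levels=("room_air",), treatment_levels=("CD",),
                              effect_map={}, n_per_cell=1)
        bundle = generate_cohort(design, small_acq, render=False, echo=False)
        assert len(bundle.manifest) == 1

    def test_same_seed_is_byte_identical(self, small_acq, tmp_path):
        design = CohortDesign(n_per_cell=1, master_seed=9)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_cohort(design, small_acq, out_dir=d1)
        generate_cohort(design, small_acq, out_dir=d2)
        assert (d1 / "manifest.csv").read_bytes() == (d2 / "manifest.csv").read_bytes()
        for p1 in sorted(d1.glob("*_mask.nii")):
            assert p1.read_bytes() == (d2 / p1.name).read_bytes()

    def test_mean_true_sphericity_higher_under_hyperoxia(self, small_acq):
        design = CohortDesign(master_seed=4)
        bundle = generate_cohort(design, small_acq, render=False, echo=False)
        df = bundle.manifest
        sph = df.groupby("oxygen")["true_sphericity"].mean()
        assert sph["high_O2"] > sph["room_air"]
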