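"""Seeded synthetic LV cohort generation.

Emulates the study design this package targets: a 2 (oxygen exposure) × 3
(treatment) factorial cohort of neonatal-rat left ventricles, imaged as
~100 short-axis slices 0.1 mm apart.  Each animal gets a latent
:class:`~lvatlas.geometry.GroundTruthShape`, a voxelized myocardial mask +
speckled grayscale volume, and a paired echocardiography record.

Hyperoxia is encoded as a smaller, shorter, more globular and
thicker-walled ventricle; active treatments as a slightly shorter
ventricle with the apex shifted toward the septum.  Effect magnitudes are
generator conventions (the directions, not the sizes, are the modelled
biology) and are overridable through :class:`CohortDesign.effect_map`.

Everything is a pure function of the design: per-animal random streams
are derived by hashing (master_seed, oxygen level, treatment level,
animal index), so cohorts are reproducible and insertion-order
independent.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence
from zlib import crc32

import numpy as np
import pandas as pd

from .geometry import DEFAULT_BASELINE_SHAPE, GroundTruthShape
from .imaging import MaskVolume, Volume, save_volume

__all__ = [
    "ShapeEffect",
    "CohortDesign",
    "AcquisitionSpec",
    "PhysiologyConfig",
    "EchoRecord",
    "AnimalRecord",
    "CohortBundle",
    "DEFAULT_EFFECT_MAP",
    "sample_shape_params",
    "render_volumes",
    "simulate_echo_record",
    "generate_cohort",
]

# intensity model for the rendered grayscale volumes
_BACKGROUND_LEVEL = 0.2
_MYOCARDIUM_LEVEL = 0.8


@dataclass(frozen=True)
class ShapeEffect:
    """Shift applied to the baseline shape for one factor level.

    Size fields are scaled multiplicatively; the apex offset and the
    truncation fraction shift additively.
    """

    length_scale: float = 1.0
    endo_radius_scale: float = 1.0
    wall_scale: float = 1.0
    apex_offset_shift_mm: float = 0.0
    truncation_shift: float = 0.0


#: Generator conventions for the factorial effects: hyperoxia shrinks and
#: shortens the ventricle while thickening the wall (net globular,
#: hypertrophied phenotype); treatments shorten slightly and push the apex
#: toward the septum.
DEFAULT_EFFECT_MAP: dict[str, ShapeEffect] = {
    "high_O2": ShapeEffect(length_scale=0.85, endo_radius_scale=0.95, wall_scale=1.15),
    "CD_Ang17": ShapeEffect(length_scale=0.95, apex_offset_shift_mm=0.15),
    "CD_Ala": ShapeEffect(length_scale=0.95, apex_offset_shift_mm=0.15),
}

DEFAULT_SHAPE_NOISE_SD: dict[str, float] = {
    "length_mm": 0.15,
    "endo_radius_mm": 0.05,
    "wall_mm": 0.03,
    "apex_offset_mm": 0.05,
    "truncation_frac": 0.01,
}

DEFAULT_ECHO_NOISE_SD: dict[str, float] = {
    "lvid": 0.05,  # mm
    "wall": 0.03,  # mm
    "velocity": 15.0,  # mm/s, mitral E
    "eprime": 1.5,  # mm/s
    "time": 2.0,  # ms
    "hr": 15.0,  # bpm
    "weight": 1.5,  # g
    "trace": 0.005,  # mm, per-frame radius jitter
}


@dataclass(frozen=True)
class PhysiologyConfig:
    """Functional (non-geometric) simulation parameters.

    Defaults are plausible neonatal-rat values: HR ≈ 400 bpm, fractional
    shortening ≈ 35%, Tei-index timings summing to MPI 0.5, E/E′ ≈ 20.
    """

    contraction_fraction: float = 0.35
    heart_rate_bpm: float = 400.0
    ivct_ms: float = 18.0
    ivrt_ms: float = 22.0
    et_ms: float = 80.0
    mitral_E_mm_s: float = 480.0
    tissue_Eprime_mm_s: float = 24.0
    body_weight_g: float = 22.0
    frame_interval_ms: float = 4.0
    noise_sd: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ECHO_NOISE_SD)
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.contraction_fraction < 1.0:
            raise ValueError("contraction_fraction must lie in (0, 1)")
        if any(v < 0 for v in self.noise_sd.values()):
            raise ValueError("noise SDs must be non-negative")


@dataclass(frozen=True)
class AcquisitionSpec:
    """Short-axis stack acquisition geometry: ~100 slices ~0.1 mm apart."""

    n_slices: int = 100
    slice_spacing_mm: float = 0.1
    pixel_mm: float = 0.05
    image_size_px: int = 96
    speckle_sd: float = 0.08

    def __post_init__(self) -> None:
        if self.n_slices < 3:
            raise ValueError("n_slices must be at least 3")
        if self.slice_spacing_mm <= 0 or self.pixel_mm <= 0:
            raise ValueError("spacings must be positive")
        if self.speckle_sd < 0:
            raise ValueError("speckle_sd must be non-negative")


@dataclass(frozen=True)
class CohortDesign:
    """Factorial cohort layout and generator noise levels.

    The first level of each factor is the reference (no effect applied);
    every other level must have an entry in ``effect_map``.
    """

    oxygen_levels: tuple[str, ...] = ("room_air", "high_O2")
    treatment_levels: tuple[str, ...] = ("CD", "CD_Ang17", "CD_Ala")
    n_per_cell: int = 4
    baseline: GroundTruthShape = DEFAULT_BASELINE_SHAPE
    effect_map: Mapping[str, ShapeEffect] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_MAP)
    )
    shape_noise_sd: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SHAPE_NOISE_SD)
    )
    physiology: PhysiologyConfig = field(default_factory=PhysiologyConfig)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")
        if any(sd < 0 for sd in self.shape_noise_sd.values()):
            raise ValueError("shape noise SDs must be non-negative")
        for lv in list(self.oxygen_levels[1:]) + list(self.treatment_levels[1:]):
            if lv not in self.effect_map:
                raise ValueError(f"effect_map missing entry for level {lv!r}")

    @property
    def n_total(self) -> int:
        return len(self.oxygen_levels) * len(self.treatment_levels) * self.n_per_cell

    def cells(self):
        for ox in self.oxygen_levels:
            for tr in self.treatment_levels:
                yield ox, tr

    def cell_mean_shape(self, oxygen: str, treatment: str) -> GroundTruthShape:
        """Baseline shape with the cell's factor effects applied."""
        self._check_cell(oxygen, treatment)
        effects = [
            self.effect_map[lv]
            for lv in (oxygen, treatment)
            if lv in self.effect_map
        ]
        b = self.baseline
        length = b.length_mm * np.prod([e.length_scale for e in effects] or [1.0])
        radius = b.endo_radius_mm * np.prod([e.endo_radius_scale for e in effects] or [1.0])
        wall = b.wall_mm * np.prod([e.wall_scale for e in effects] or [1.0])
        offset = b.apex_offset_mm + sum(e.apex_offset_shift_mm for e in effects)
        trunc = b.truncation_frac + sum(e.truncation_shift for e in effects)
        return GroundTruthShape(
            length_mm=float(length),
            endo_radius_mm=float(radius),
            wall_mm=float(wall),
            apex_offset_mm=float(offset),
            truncation_frac=float(trunc),
        )

    def _check_cell(self, oxygen: str, treatment: str) -> None:
        if oxygen not in self.oxygen_levels:
            raise KeyError(f"unknown oxygen level {oxygen!r}")
        if treatment not in self.treatment_levels:
            raise KeyError(f"unknown treatment level {treatment!r}")


@dataclass
class EchoRecord:
    """Raw per-animal echocardiography measurements (mm, ms, g)."""

    heart_rate_bpm: float
    lvid_d_mm: float
    lvid_s_mm: float
    lvpw_d_mm: float
    ivs_d_mm: float
    mitral_E_mm_s: float
    tissue_Eprime_mm_s: float
    ivct_ms: float
    ivrt_ms: float
    et_ms: float
    body_weight_g: float
    endo_radius_trace_mm: np.ndarray
    frame_interval_ms: float

    def __post_init__(self) -> None:
        self.endo_radius_trace_mm = np.asarray(self.endo_radius_trace_mm, dtype=float)
        scalars = [
            self.heart_rate_bpm, self.lvid_d_mm, self.lvid_s_mm, self.lvpw_d_mm,
            self.ivs_d_mm, self.mitral_E_mm_s, self.tissue_Eprime_mm_s,
            self.ivct_ms, self.ivrt_ms, self.et_ms, self.body_weight_g,
            self.frame_interval_ms,
        ]
        if any(not np.isfinite(v) or v <= 0 for v in scalars):
            raise ValueError("all echo scalar fields must be positive and finite")
        if self.lvid_s_mm >= self.lvid_d_mm:
            raise ValueError("lvid_s must be smaller than lvid_d")
        if self.endo_radius_trace_mm.size < 3:
            raise ValueError("trace must have at least 3 frames")

    def scalar_dict(self) -> dict[str, float]:
        d = dataclasses.asdict(self)
        d.pop("endo_radius_trace_mm")
        return {k: float(v) for k, v in d.items()}


# ---------------------------------------------------------------------------
# per-animal random streams
# ---------------------------------------------------------------------------


def animal_seed(master_seed: int, oxygen: str, treatment: str, animal_index: int) -> int:
    """Deterministic per-animal seed, independent of generation order."""
    h = crc32(f"{oxygen}|{treatment}|{animal_index}".encode())
    return int((master_seed * 2654435761 + h) % (2**31))


def _animal_streams(design: CohortDesign, oxygen: str, treatment: str, idx: int):
    seed = animal_seed(design.master_seed, oxygen, treatment, idx)
    shape_rng, image_rng, echo_rng = [
        np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(3)
    ]
    return seed, shape_rng, image_rng, echo_rng


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def sample_shape_params(
    design: CohortDesign,
    oxygen: str,
    treatment: str,
    animal_index: int,
    max_redraws: int = 200,
) -> GroundTruthShape:
    """Draw one animal's ground-truth shape for a factorial cell.

    The cell mean (baseline + effects) is perturbed by independent
    Gaussian noise per shape field.  Draws violating the shape invariants
    are rejected and redrawn; after ``max_redraws`` the draw is clipped
    into the feasible region.  A cell mean that itself violates the
    invariants is an error.
    """
    if animal_index >= design.n_per_cell:
        raise IndexError("animal_index exceeds n_per_cell")
    mean = design.cell_mean_shape(oxygen, treatment)  # raises if unsatisfiable
    _, rng, _, _ = _animal_streams(design, oxygen, treatment, animal_index)
    sd = design.shape_noise_sd

    def draw():
        return {
            "length_mm": mean.length_mm + rng.normal(0, sd.get("length_mm", 0)),
            "endo_radius_mm": mean.endo_radius_mm + rng.normal(0, sd.get("endo_radius_mm", 0)),
            "wall_mm": mean.wall_mm + rng.normal(0, sd.get("wall_mm", 0)),
            "apex_offset_mm": mean.apex_offset_mm + rng.normal(0, sd.get("apex_offset_mm", 0)),
            "truncation_frac": mean.truncation_frac + rng.normal(0, sd.get("truncation_frac", 0)),
        }

    fields = draw()
    for _ in range(max_redraws):
        try:
            return GroundTruthShape(**fields)
        except ValueError:
            fields = draw()
    # clip into the feasible region as a last resort
    L = max(fields["length_mm"], 0.2 * mean.length_mm)
    r = max(fields["endo_radius_mm"], 0.2 * mean.endo_radius_mm)
    w = float(np.clip(fields["wall_mm"], 0.05 * r, 0.9 * r))
    f = float(np.clip(fields["truncation_frac"], 0.55, 0.95 * L / (L + w)))
    off = float(np.clip(fields["apex_offset_mm"], -0.9 * r, 0.9 * r))
    return GroundTruthShape(L, r, w, off, f)


def render_volumes(
    shape: GroundTruthShape,
    acq: AcquisitionSpec,
    rng: np.random.Generator | int | None = None,
) -> tuple[MaskVolume, Volume]:
    """Voxelize a shape into a binary myocardial mask and a grayscale stack.

    A voxel is foreground when its centre lies between the endocardial and
    epicardial truncated-ellipsoid surfaces (after undoing the apex-offset
    shear).  The grayscale volume is a two-level intensity image
    (myocardium bright) with additive Gaussian speckle.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    nx = ny = acq.image_size_px
    nz = acq.n_slices
    sx = sy = acq.pixel_mm
    sz = acq.slice_spacing_mm

    half_x = shape.a_epi + abs(shape.apex_offset_mm)
    fov = {
        "x": (2 * half_x, nx * sx),
        "y": (2 * shape.a_epi, ny * sy),
        "z": (shape.length_mm, nz * sz),
    }
    for dim, (need, have) in fov.items():
        if need + 2 * (sx if dim != "z" else sz) > have:
            raise ValueError(
                f"shape extent {need:.2f} mm exceeds the {dim} field of view "
                f"({have:.2f} mm)"
            )

    z_mid = (shape.z_base - shape.c_epi) / 2.0
    origin = (-nx * sx / 2.0, -ny * sy / 2.0, z_mid - nz * sz / 2.0)

    x = origin[0] + (np.arange(nx) + 0.5) * sx
    y = origin[1] + (np.arange(ny) + 0.5) * sy
    z = origin[2] + (np.arange(nz) + 0.5) * sz
    X = x[:, None, None]
    Y = y[None, :, None]
    Z = z[None, None, :]
    Xu = X - shape.apex_offset_mm * shape.shear(Z)  # undo the apex shear
    r2 = Xu**2 + Y**2
    in_epi = (r2 / shape.a_epi**2 + Z**2 / shape.c_epi**2 <= 1.0) & (Z <= shape.z_base)
    in_endo = r2 / shape.endo_radius_mm**2 + Z**2 / shape.c_endo**2 <= 1.0
    mask = in_epi & ~in_endo

    gray = np.where(mask, _MYOCARDIUM_LEVEL, _BACKGROUND_LEVEL)
    if acq.speckle_sd > 0:
        gray = gray + rng.normal(0.0, acq.speckle_sd, size=gray.shape)

    spacing = (sx, sy, sz)
    return MaskVolume(mask, spacing, origin), Volume(gray, spacing, origin)


def simulate_echo_record(
    shape: GroundTruthShape,
    physio: PhysiologyConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> EchoRecord:
    """Simulate one animal's M-mode / Doppler measurement set.

    The diastolic internal diameter is the true endocardial diameter; the
    systolic diameter follows from the configured contraction fraction;
    wall fields come from the true wall thickness; the radius trace is one
    smooth cardiac cycle (raised-sine contraction) consistent with the
    M-mode diameters.  Gaussian measurement noise (SDs from
    ``physio.noise_sd``) is added to every quantity.
    """
    physio = physio or PhysiologyConfig()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    sd = physio.noise_sd
    f = physio.contraction_fraction

    def noisy(mean, key, lo=1e-3):
        return float(max(mean + rng.normal(0, sd.get(key, 0.0)), lo))

    lvid_d = noisy(2.0 * shape.endo_radius_mm, "lvid", lo=0.1)
    lvid_s = float(
        np.clip(
            lvid_d * (1.0 - f) + rng.normal(0, sd.get("lvid", 0.0)),
            0.05 * lvid_d,
            0.98 * lvid_d,
        )
    )
    hr = noisy(physio.heart_rate_bpm, "hr", lo=60.0)
    cycle_ms = 60000.0 / hr
    n_frames = max(int(round(cycle_ms / physio.frame_interval_ms)) + 1, 3)
    t = np.arange(n_frames) * physio.frame_interval_ms
    contraction = np.sin(np.pi * np.minimum(t, cycle_ms) / cycle_ms) ** 2
    trace = lvid_d / 2.0 - (lvid_d - lvid_s) / 2.0 * contraction
    if sd.get("trace", 0.0) > 0:
        trace = trace + rng.normal(0, sd["trace"], size=trace.shape)
        trace[0] = lvid_d / 2.0  # first frame is end-diastole by definition
        trace = np.maximum(trace, 1e-3)

    return EchoRecord(
        heart_rate_bpm=hr,
        lvid_d_mm=lvid_d,
        lvid_s_mm=lvid_s,
        lvpw_d_mm=noisy(shape.wall_mm, "wall", lo=0.05),
        ivs_d_mm=noisy(shape.wall_mm, "wall", lo=0.05),
        mitral_E_mm_s=noisy(physio.mitral_E_mm_s, "velocity", lo=10.0),
        tissue_Eprime_mm_s=noisy(physio.tissue_Eprime_mm_s, "eprime", lo=1.0),
        ivct_ms=noisy(physio.ivct_ms, "time", lo=1.0),
        ivrt_ms=noisy(physio.ivrt_ms, "time", lo=1.0),
        et_ms=noisy(physio.et_ms, "time", lo=5.0),
        body_weight_g=noisy(physio.body_weight_g, "weight", lo=1.0),
        endo_radius_trace_mm=trace,
        frame_interval_ms=physio.frame_interval_ms,
    )


@dataclass
class AnimalRecord:
    """One synthetic animal: latent truth plus simulated observations."""

    animal_id: str
    oxygen: str
    treatment: str
    animal_index: int
    seed: int
    shape: GroundTruthShape
    mask: MaskVolume | None = None
    grayscale: Volume | None = None
    echo: EchoRecord | None = None


@dataclass
class CohortBundle:
    animals: list[AnimalRecord]
    manifest: pd.DataFrame
    design: CohortDesign
    acquisition: AcquisitionSpec

    def __iter__(self):
        return iter(self.animals)

    def __len__(self):
        return len(self.animals)


def generate_cohort(
    design: CohortDesign,
    acq: AcquisitionSpec | None = None,
    out_dir: str | Path | None = None,
    render: bool = True,
    echo: bool = True,
) -> CohortBundle:
    """Generate the full factorial cohort.

    Produces exactly ``Σ n_per_cell`` animals, each fully determined by
    (design, acq): ground-truth shape, optionally rendered volumes and an
    echo record.  When ``out_dir`` is given, masks and grayscale stacks
    are written as NIfTI, echo records and the manifest as CSV.
    """
    acq = acq or AcquisitionSpec()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    animals: list[AnimalRecord] = []
    rows = []
    seen: set[str] = set()
    for ox, tr in design.cells():
        for i in range(design.n_per_cell):
            aid = f"{ox}-{tr}-{i + 1:02d}"
            if aid in seen:
                raise ValueError(f"duplicate animal id {aid}")
            seen.add(aid)
            seed, _, image_rng, echo_rng = _animal_streams(design, ox, tr, i)
            shape = sample_shape_params(design, ox, tr, i)
            rec = AnimalRecord(aid, ox, tr, i, seed, shape)
            row = {
                "animal_id": aid,
                "oxygen": ox,
                "treatment": tr,
                "animal_index": i,
                "seed": seed,
                **{f"true_{k}": v for k, v in dataclasses.asdict(shape).items()},
                "true_sphericity": shape.sphericity,
            }
            if render:
                rec.mask, rec.grayscale = render_volumes(shape, acq, image_rng)
                if out is not None:
                    # paths relative to the manifest, so reruns in different
                    # directories produce identical manifests
                    row["mask_path"] = save_volume(rec.mask, out / f"{aid}_mask.nii").name
                    row["gray_path"] = save_volume(rec.grayscale, out / f"{aid}_gray.nii").name
            if echo:
                rec.echo = simulate_echo_record(shape, design.physiology, echo_rng)
            animals.append(rec)
            rows.append(row)

    manifest = pd.DataFrame(rows)
    if out is not None:
        manifest.to_csv(out / "manifest.csv", index=False)
        if echo:
            echo_df = pd.DataFrame(
                [{"animal_id": a.animal_id, **a.echo.scalar_dict()} for a in animals]
            )
            echo_df.to_csv(out / "echo_records.csv", index=False)
            traces = pd.DataFrame(
                {a.animal_id: pd.Series(a.echo.endo_radius_trace_mm) for a in animals}
            )
            traces.to_csv(out / "echo_traces.csv", index=False)
    return CohortBundle(animals, manifest, design, acq)
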