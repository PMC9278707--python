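# Methods

This note records the models, parameter choices and numerical
conventions behind `lvatlas`, and what the synthetic validation does and
does not establish about real data.

## Geometric model of the left ventricle

The LV myocardium is a shell between two coaxial prolate spheroids
sharing a base truncation plane. Independent parameters (mm):

| parameter | meaning | default |
|---|---|---|
| `length_mm` | base plane → epicardial apex | 4.5 |
| `endo_radius_mm` | endocardial equatorial radius | 1.3 |
| `wall_mm` | equatorial (and apical) wall thickness | 0.6 |
| `apex_offset_mm` | lateral apex displacement toward the septum (+x) | 0.0 |
| `truncation_frac` | fraction of the full ellipsoid height retained | 0.8 |

Sphericity (2·radius/length) is derived, not free. Defaults are
plausible neonatal-rat (P10) dimensions: diastolic internal diameter
≈2.6 mm, wall ≈0.6 mm, long axis ≈4.5 mm. Validity constraints are
enforced at construction; in particular `truncation_frac <
length/(length+wall)` so the cavity stays open at the base. The apex
offset is a lateral shear with weight quadratic in normalized apex-ward
depth — zero at the base ring, one at the apex — so the base is
preserved and volume is unchanged. Truncated-ellipsoid volumes have a
closed form (slice integral), used as the oracle for voxelization and
mesh-volume tests.

## Synthetic cohort generator

The generator emulates the study conditions it is meant to test: a 2
(room air / high O₂) × 3 (vehicle / Angio-(1–7) / alamandine) design
with 4 animals per cell (12 per exposure arm, 24 animals), imaged as
~100 short-axis slices at 0.1 mm spacing. Factor effects act on the
latent shape:

- hyperoxia: length ×0.85, endocardial radius ×0.95, wall ×1.15 —
  net smaller, shorter, more globular, hypertrophied;
- active treatments: length ×0.95, apex offset +0.15 mm — shorter
  with the apex pulled toward the septum.

Only the *directions* of these effects are the modelled biology; the
magnitudes are generator conventions chosen to be comfortably
detectable at n = 12/arm, and are overridable per design. Per-field
Gaussian noise (SD 0.15 mm length, 0.05 mm radius, 0.03 mm wall,
0.05 mm apex offset, 0.01 truncation) creates animal-to-animal
variation; draws violating shape invariants are redrawn, then clipped.

Per-animal random streams are seeded by hashing (master seed, oxygen
level, treatment level, animal index), so any animal can be regenerated
in isolation and cohort generation is independent of iteration order.

Rendering marks a voxel as myocardium when its centre lies between the
two surfaces (centre-of-voxel convention: voxel *i* is centred at
`origin + (i+0.5)·spacing`). Grayscale stacks are two-level images
(background 0.2, myocardium 0.8) plus Gaussian speckle (SD 0.08). This
deliberately ignores real speckle physics, attenuation, anisotropic PSF
and gating artefacts: segmentation performance on these phantoms is an
upper bound, not a claim about clinical ultrasound.

The echo simulator draws M-mode diameters from the true geometry
(LVIDd = 2·endo radius; LVIDs from a configurable contraction fraction,
default 0.35), walls from the true thickness, and Doppler/timing fields
from physiological means (HR 400 bpm; IVCT/IVRT/ET 18/22/80 ms → Tei
index 0.5; E/E′ 20; body weight 22 g), each with measurement noise.
The radius trace is one raised-sine cycle consistent with the M-mode
diameters, so peak radial strain equals 100 × contraction fraction by
construction.

## Segmentation stand-in

Real studies segment semi-automatically with interactive tools; the
package provides a deterministic proxy: intensity threshold (given
percentile, or Otsu when unspecified — robust to the myocardium's
volume fraction varying between acquisitions), then a one-voxel
morphological cleanup *by reconstruction* (closing fills pinholes,
opening removes speckle spurs, and structures that survive are restored
voxel-exactly — a plain opening would also shave single-voxel ridges
off curved voxelized surfaces), then largest 6-connected component with
small components discarded (default < 27 voxels). Ties between equal
largest components break toward the smaller lexicographic minimal voxel
index. On phantoms at default speckle this recovers the true mask with
Dice > 0.99; it is a proxy, not a reproduction of any interactive
tool's behaviour.

## Template mesh and personalization

The template samples both shell surfaces of the default shape into a
fixed topology: an apex node plus `n_long` rings of `n_circ` nodes per
surface (default 32 circumferential × 20 longitudinal → 1282 nodes),
triangulated as an apex fan plus quad strips. The default resolution
puts the inscribed-polyhedron volume bias below 1% of the closed-form
cavity volume; halving it roughly quadruples that bias.

Fitting minimizes, over tricubic B-spline lattice displacements
(default 6³ control points spanning the initialized template's bounding
box with 5% margin):

    mean_i d(node_i)²  +  λ·mean‖L P‖²  +  μ·mean_base (Δz)²

- `d` is the signed distance from a node to its target boundary,
  interpolated from precomputed signed Euclidean distance fields;
  endocardial nodes target the cavity/myocardium interface, epicardial
  nodes the outer boundary. The cavity is recovered by 2D hole-filling
  each short-axis slice (the shell is an annulus in every slice, so
  this works despite the open base). Signed fields put the zero
  crossing at the sub-voxel interface, avoiding the half-voxel bias of
  nearest-boundary-voxel distances.
- `L` is the 6-neighbour lattice Laplacian; λ defaults to 0.1.
- the base term (μ = 10) softly pins the base ring to the top of the
  mask stack, since basal slices are the least reliable part of real
  acquisitions; initialization also aligns the template base there.

Initialization matches centroids, aligns the template long axis to the
mask's principal axis (both axis signs tried, lower initial cost wins,
ties keep the positive sign), and scales isotropically by the extent
ratio along that axis. Displacements are linear in the lattice, so
gradients are exact; L-BFGS-B runs to `max_iter` (200) or a relative
function tolerance derived from `tol` (1e-4 mm). Recorded
per-iteration objectives are non-increasing. A fit whose final RMS
residual exceeds 5 voxels raises rather than returning silently bad
geometry. On noiseless phantoms the self-fit residual is ~0.03 mm
(half an in-plane voxel) and fitted cavity volumes land within ~1% of
closed form; 5% is the contract.

Mesh volumes close each surface with a fan cap over the base ring and
use the divergence-theorem signed sum; 1 mm³ = 1 µL.

## Alignment and atlas

Alignment removes the centre of mass, rotates the principal node axis
to z with the apex marker node at −z, and fixes the roll by rotating
the septal marker node into the +x half-plane. Marker-based sign fixing
is exact under rigid motion and immune to the 180° ambiguity and
near-degenerate equatorial eigenvalues of covariance axes. No scaling
is applied: size differences are part of the phenotype being measured.

PCA runs as a thin SVD of the centred case × 3N matrix (equivalent to
the covariance eigendecomposition, cheap when nodes ≫ cases). Modes
with eigenvalue ≤ `eigenvalue_tol` (default 1e-9) × total variance are
dropped; a cohort whose total variance sits at float rounding noise
returns zero modes with a warning. Mode signs follow a fixed
convention (largest-magnitude entry positive) and cases are processed
in sorted-id order, making the atlas bit-identical under input
permutation. Scores are orthonormal projections, so
project→reconstruct round-trips training shapes to machine precision.

Note the rank subtlety validated by the tests: meshes sampled
*analytically* from the 5-parameter shape family have a spectrum
decaying so fast that trailing eigenvalues fall below the 1e-9
threshold, whereas meshes fitted to rendered masks carry full-rank
per-node variability and retain exactly n − 1 = 23 modes for 24 cases —
as real fitted cohorts do.

## Echo indices

Fractional shortening, cube-formula LV mass (density 1.053 mg/mm³,
mm in → mg out), E/E′ and the Tei MPI are direct transcriptions of
their standard definitions. LV volumes use the Teichholz rule
(`V = 7.0/(2.4+D)·D³`, D in cm) — an M-mode convention adopted because
single-plane diameters are the available measurement; mesh cavity
volumes are exported alongside for cross-checking. Radial endocardial
strain is defined on the radius trace normalized to end-diastole,
`ε(t) = 100·(R₀ − R(t))/R₀`, with strain rate by central differences
(one-sided at the ends, optional moving-average smoothing, off by
default). Speckle-tracking, Simpson volumes and raw Doppler processing
are out of scope; these definitions are documented proxies for
vendor-specific algorithms.

## Statistics

Mode scores are compared with two-sided unpaired t-tests, Welch by
default (robust to unequal variances; pooled Student available by
flag). The factorial ANOVA uses type-III sums of squares — on balanced
layouts computed in closed form (identical to the classical
decomposition there, and fast enough for Monte-Carlo calibration), on
unbalanced layouts via an effect-coded linear model. Post-hoc
comparisons are pairwise t-tests on a configurable cell-pair set
(default: the six figure-style comparisons — each treatment vs its
same-exposure vehicle, plus room-air vs high-O₂ within vehicle and
within the first treatment; "all" gives all 15) with Bonferroni
multiplication by the number of pairs, capped at 1. Growth curves use
a mixed repeated-measures ANOVA (between group × within time, animal
as subject); incomplete panels are an error, never imputed.

Simulation checks: under a null 2×3 design (n = 6/cell) the oxygen
effect rejects at 0.050 ± 0.015 over 2000 replicates, and with the
default effect map the mode-1 t-test separates exposure arms in ≥80%
(empirically ~100%) of 200 seeded cohort replicates.

## Problem sizes and defaults in the distributed checks

Tests and the acceptance script run phantom stacks at 64×64×60–70
voxels (0.075 mm in-plane, 0.1 mm slices) rather than the full
96×96×100 default — the geometry is identical and every contract
(volume recovery, Dice, rank, determinism) is resolution-robust, as
the convergence tests demonstrate. Replicated power studies build
meshes at 8×8 surface resolution, where alignment and PCA behave
identically.

## Known limitations

- The phantom family is a smooth 5-parameter shell: no trabeculae,
  papillary muscles, torsion, right ventricle, or realistic speckle.
  Passing tests validate the *pipeline machinery*, not segmentation or
  fitting performance on clinical images.
- The template is matched to the phantom family; fitting anatomies far
  from a truncated ellipsoid would need a richer template or finer
  lattice.
- Effect magnitudes in the generator are conventions; only directions
  are biologically motivated.
- Two-mode variance fractions depend entirely on the cohort's noise
  structure; the synthetic cohort does not reproduce any particular
  empirical variance split.
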