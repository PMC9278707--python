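"""Template LV mesh construction and fitting to myocardial masks.

A fixed-topology surface mesh of an idealized truncated-ellipsoid LV
(endocardial + epicardial sheets sharing a base opening) is personalized
to each binary myocardial mask in two stages:

1. similarity initialization — centroid, long-axis orientation and
   isotropic scale matched to the mask's voxel cloud;
2. free-form deformation — a regular lattice of control points with
   tricubic B-spline weights is optimized (quasi-Newton) to minimize the
   mean squared distance from endo/epi surface nodes to the corresponding
   mask boundary (signed-distance zero crossings), plus a Laplacian
   smoothness penalty on the lattice displacements and a soft constraint
   keeping the base ring on the base plane.

Node displacements are linear in the lattice displacements, so gradients
are exact and cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.optimize import minimize

from .geometry import DEFAULT_BASELINE_SHAPE, GroundTruthShape
from .imaging import MaskVolume

__all__ = [
    "LVTemplateMesh",
    "LVMesh",
    "FitError",
    "build_template",
    "mesh_from_shape",
    "fit_mesh",
    "mesh_cavity_volume",
]


class FitError(RuntimeError):
    """Mesh fitting failed (non-convergence or degenerate input)."""

    def __init__(self, msg: str, residual: float | None = None):
        super().__init__(msg)
        self.residual = residual


# ---------------------------------------------------------------------------
# template geometry
# ---------------------------------------------------------------------------


def _surface_nodes(a: float, c: float, z_base: float, shape: GroundTruthShape,
                   n_circ: int, n_long: int) -> np.ndarray:
    """Sample one truncated-ellipsoid surface into the fixed node layout.

    Node 0 is the apex (θ=0 at z=−c); rings j=1..n_long at equal θ steps
    up to the base plane.  The apex-offset shear is applied last.
    """
    theta_base = np.arccos(np.clip(-z_base / c, -1.0, 1.0))
    nodes = np.empty((1 + n_long * n_circ, 3))
    nodes[0] = (0.0, 0.0, -c)
    phi = 2.0 * np.pi * np.arange(n_circ) / n_circ
    for j in range(1, n_long + 1):
        th = theta_base * j / n_long
        ring = np.column_stack([
            a * np.sin(th) * np.cos(phi),
            a * np.sin(th) * np.sin(phi),
            np.full(n_circ, -c * np.cos(th)),
        ])
        nodes[1 + (j - 1) * n_circ: 1 + j * n_circ] = ring
    nodes[:, 0] += shape.apex_offset_mm * shape.shear(nodes[:, 2])
    return nodes


def _surface_faces(n_circ: int, n_long: int, offset: int = 0) -> np.ndarray:
    """Triangulation of one surface (apex fan + quad strips), CCW from outside."""
    faces = []
    ring = lambda j, k: offset + 1 + (j - 1) * n_circ + (k % n_circ)
    for k in range(n_circ):
        faces.append((offset, ring(1, k + 1), ring(1, k)))
    for j in range(1, n_long):
        for k in range(n_circ):
            a, b = ring(j, k), ring(j, k + 1)
            c, d = ring(j + 1, k), ring(j + 1, k + 1)
            faces.append((a, b, d))
            faces.append((a, d, c))
    return np.asarray(faces, dtype=int)


@dataclass
class LVTemplateMesh:
    """Idealized LV shell mesh with fixed topology.

    Nodes 0..Ns-1 are the endocardial surface, Ns..2Ns-1 the epicardial
    surface (Ns = 1 + n_long*n_circ each).  Apex at −z, base opening at
    +z, septal direction +x.  ``lattice_resolution`` is the per-axis size
    of the free-form-deformation control grid.
    """

    nodes: np.ndarray
    faces_endo: np.ndarray
    faces_epi: np.ndarray
    n_circ: int
    n_long: int
    lattice_resolution: int
    shape: GroundTruthShape

    @property
    def n_surface_nodes(self) -> int:
        return 1 + self.n_long * self.n_circ

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_surface_nodes

    @property
    def endo_ids(self) -> np.ndarray:
        return np.arange(self.n_surface_nodes)

    @property
    def epi_ids(self) -> np.ndarray:
        return np.arange(self.n_surface_nodes, 2 * self.n_surface_nodes)

    def base_ring_ids(self) -> np.ndarray:
        ns, nc = self.n_surface_nodes, self.n_circ
        last = np.arange(ns - nc, ns)
        return np.concatenate([last, last + ns])

    @property
    def apex_epi_id(self) -> int:
        return self.n_surface_nodes  # first epi node

    @property
    def septal_marker_id(self) -> int:
        """Epicardial base-ring node at φ=0 (+x, septal side)."""
        return 2 * self.n_surface_nodes - self.n_circ


@dataclass
class LVMesh:
    """A fitted (or synthetic) instance of the template topology."""

    nodes: np.ndarray
    template: LVTemplateMesh
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        if self.nodes.shape != (self.template.n_nodes, 3):
            raise ValueError("node array does not match template topology")
        if not np.all(np.isfinite(self.nodes)):
            raise ValueError("mesh nodes must be finite")

    def copy(self) -> "LVMesh":
        return LVMesh(self.nodes.copy(), self.template, dict(self.provenance))


def mesh_from_shape(
    shape: GroundTruthShape,
    n_circ: int = 32,
    n_long: int = 20,
    lattice_resolution: int = 6,
) -> LVMesh:
    """Analytic mesh of a ground-truth shape in the template topology."""
    endo = _surface_nodes(shape.endo_radius_mm, shape.c_endo, shape.z_base,
                          shape, n_circ, n_long)
    epi = _surface_nodes(shape.a_epi, shape.c_epi, shape.z_base,
                         shape, n_circ, n_long)
    tpl = LVTemplateMesh(
        nodes=np.vstack([endo, epi]),
        faces_endo=_surface_faces(n_circ, n_long, 0),
        faces_epi=_surface_faces(n_circ, n_long, 1 + n_long * n_circ),
        n_circ=n_circ,
        n_long=n_long,
        lattice_resolution=lattice_resolution,
        shape=shape,
    )
    return LVMesh(tpl.nodes.copy(), tpl, {"case_id": "template"})


def build_template(
    lattice_resolution: int = 6,
    surface_resolution: tuple[int, int] = (32, 20),
    shape: GroundTruthShape = DEFAULT_BASELINE_SHAPE,
) -> LVTemplateMesh:
    """Build the idealized LV template mesh.

    Parameters
    ----------
    lattice_resolution:
        Control points per axis of the deformation lattice (≥ 4 for
        cubic support).
    surface_resolution:
        (circumferential, longitudinal) sample counts; at least 8 each.
    """
    n_circ, n_long = surface_resolution
    if lattice_resolution < 4:
        raise ValueError("lattice_resolution must be >= 4 for cubic B-splines")
    if n_circ < 8 or n_long < 8:
        raise ValueError("surface_resolution must be at least 8 x 8")
    return mesh_from_shape(shape, n_circ, n_long, lattice_resolution).template


# ---------------------------------------------------------------------------
# mesh volumes (divergence theorem)
# ---------------------------------------------------------------------------


def _closed_surface_volume(nodes: np.ndarray, faces: np.ndarray,
                           base_ring: np.ndarray) -> float:
    """Signed volume of a surface closed by a fan cap over the base ring."""
    centroid = nodes[base_ring].mean(axis=0)
    ring = nodes[base_ring]
    nring = len(ring)
    cap_a = ring
    cap_b = ring[(np.arange(nring) + 1) % nring]
    v = np.einsum("ij,ij->i", nodes[faces[:, 0]],
                  np.cross(nodes[faces[:, 1]], nodes[faces[:, 2]])).sum()
    v += np.einsum("ij,ij->i", cap_a, np.cross(cap_b, np.broadcast_to(centroid, cap_a.shape))).sum()
    return v / 6.0


def mesh_cavity_volume(mesh: LVMesh) -> tuple[float, float]:
    """Cavity (endocardial) and myocardial volumes of a mesh, in µL.

    Each open surface is capped with a triangle fan to the centroid of
    its base ring; volumes are signed divergence-theorem sums (1 mm³ =
    1 µL).  Surface orientation is fixed by sign; a myocardial volume
    that comes out negative indicates inconsistent surface orientation.
    """
    tpl = mesh.template
    ns, nc = tpl.n_surface_nodes, tpl.n_circ
    ring_endo = np.arange(ns - nc, ns)
    ring_epi = ring_endo + ns
    v_endo = abs(_closed_surface_volume(mesh.nodes, tpl.faces_endo, ring_endo))
    v_epi = abs(_closed_surface_volume(mesh.nodes, tpl.faces_epi, ring_epi))
    myo = v_epi - v_endo
    if myo < -1e-9 * max(v_epi, 1.0):
        raise FitError("inconsistent surface orientation: epicardial volume "
                       "smaller than endocardial volume")
    return float(v_endo), float(max(myo, 0.0))


# ---------------------------------------------------------------------------
# free-form deformation lattice
# ---------------------------------------------------------------------------


def _bspline_weights(t: np.ndarray) -> np.ndarray:
    """Uniform cubic B-spline basis values B0..B3 at local coordinate t."""
    t2, t3 = t * t, t * t * t
    return np.stack([
        (1 - t) ** 3 / 6.0,
        (3 * t3 - 6 * t2 + 4) / 6.0,
        (-3 * t3 + 3 * t2 + 3 * t + 1) / 6.0,
        t3 / 6.0,
    ], axis=-1)


def _ffd_weight_matrix(points: np.ndarray, n: int) -> tuple[sparse.csr_matrix, np.ndarray, np.ndarray]:
    """Sparse (N, n³) matrix mapping lattice displacements to point displacements."""
    lo = points.min(axis=0)
    hi = points.max(axis=0)
    extent = np.maximum(hi - lo, 1e-6)
    margin = 0.05 * extent
    x0 = lo - margin
    delta = (extent + 2 * margin) / (n - 3)
    s = (points - x0) / delta  # in [0, n-3]
    i0 = np.clip(np.floor(s).astype(int), 0, n - 4)
    t = s - i0
    w = [_bspline_weights(t[:, d]) for d in range(3)]  # each (N, 4)

    npts = len(points)
    rows = np.repeat(np.arange(npts), 64)
    cols = np.empty(npts * 64, dtype=int)
    vals = np.empty(npts * 64)
    q = 0
    for a in range(4):
        for b in range(4):
            for c in range(4):
                idx = ((i0[:, 0] + a) * n + (i0[:, 1] + b)) * n + (i0[:, 2] + c)
                cols[q::64] = idx
                vals[q::64] = w[0][:, a] * w[1][:, b] * w[2][:, c]
                q += 1
    W = sparse.csr_matrix((vals, (rows, cols)), shape=(npts, n**3))
    return W, x0, delta


def _lattice_laplacian(n: int) -> sparse.csr_matrix:
    """Discrete 6-neighbour Laplacian on the n³ control grid (Neumann edges)."""
    d1 = sparse.diags([np.ones(n - 1), -np.ones(n), np.ones(n - 1)],
                      [-1, 0, 1], format="csr")
    deg = np.zeros(n)
    deg[0] = deg[-1] = 1.0
    d1 = d1 + sparse.diags(deg - 1.0)  # row sums zero, -2 interior, -1 edges
    eye = sparse.identity(n, format="csr")
    lap = (sparse.kron(sparse.kron(d1, eye), eye)
           + sparse.kron(sparse.kron(eye, d1), eye)
           + sparse.kron(sparse.kron(eye, eye), d1))
    return lap.tocsr()


# ---------------------------------------------------------------------------
# mask preprocessing: signed distance fields to the two boundaries
# ---------------------------------------------------------------------------


def _signed_distance(region: np.ndarray, spacing) -> np.ndarray:
    """Signed distance (mm) to the boundary of a voxel region.

    Positive outside, negative inside; the zero crossing sits at the
    interface between voxel centres (sub-voxel accurate target for
    surface fitting).
    """
    inside = ndimage.distance_transform_edt(region, sampling=spacing)
    outside = ndimage.distance_transform_edt(~region, sampling=spacing)
    return outside - inside


def _mask_distance_fields(mask: MaskVolume) -> tuple[np.ndarray, np.ndarray]:
    """Signed distance fields to the endocardial and epicardial boundaries.

    The cavity is recovered by 2D hole-filling each short-axis slice (the
    myocardium is an annulus in every slice below the base), which also
    works for the basally open shell where 3D hole filling would leak.
    """
    vox = mask.voxels
    solid = np.stack(
        [ndimage.binary_fill_holes(vox[:, :, k]) for k in range(vox.shape[2])],
        axis=2,
    )
    cavity = solid & ~vox
    if cavity.sum() == 0:
        raise FitError("degenerate mask: no enclosed cavity found")
    sd_endo = _signed_distance(cavity, mask.spacing_mm)
    sd_epi = _signed_distance(solid, mask.spacing_mm)
    return sd_endo, sd_epi


def _interp(field: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Trilinear interpolation at continuous voxel indices (N, 3)."""
    return ndimage.map_coordinates(field, idx.T, order=1, mode="nearest")


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking unit vector a to unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if c < -1.0 + 1e-12:  # antiparallel: rotate π about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, perp)
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _initialize(template: LVTemplateMesh, mask: MaskVolume,
                sd_endo: np.ndarray, sd_epi: np.ndarray) -> np.ndarray:
    """Similarity (rigid + isotropic scale) placement of the template."""
    pts = mask.foreground_centers()
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] < 1e-6 * max(evals[-1], 1e-12):
        raise FitError("degenerate mask: voxel cloud is planar or linear")
    axis = evecs[:, -1]  # long axis

    tnodes = template.nodes
    tcentroid = tnodes.mean(axis=0)
    t_extent = tnodes[:, 2].max() - tnodes[:, 2].min()

    proj = pts @ axis
    m_extent = proj.max() - proj.min() + mask.spacing_mm[2]
    scale = m_extent / t_extent

    best = None
    ez = np.array([0.0, 0.0, 1.0])
    for sign in (1.0, -1.0):
        rot = _rotation_between(ez, sign * axis)
        nodes = scale * (tnodes - tcentroid) @ rot.T + centroid
        # pin the base ring to the top of the mask stack along the long axis
        ring = template.base_ring_ids()
        base_target = (pts @ (sign * axis)).max() + 0.5 * max(mask.spacing_mm)
        shift = base_target - (nodes[ring] @ (sign * axis)).mean()
        nodes = nodes + shift * sign * axis
        idx = mask.world_to_index(nodes)
        cost = (np.sum(_interp(sd_endo, idx[template.endo_ids]) ** 2)
                + np.sum(_interp(sd_epi, idx[template.epi_ids]) ** 2))
        if best is None or cost < best[0] - 1e-12:
            best = (cost, nodes)
    return best[1]


def fit_mesh(
    template: LVTemplateMesh,
    mask: MaskVolume,
    lam: float = 0.1,
    max_iter: int = 200,
    tol: float = 1e-4,
    base_weight: float = 10.0,
    residual_ceiling_voxels: float = 5.0,
    case_id: str | None = None,
) -> LVMesh:
    """Personalize the template mesh to a myocardial mask.

    Minimizes mean squared node-to-boundary distance (endo nodes against
    the endocardial signed-distance field, epi nodes against the
    epicardial one) + ``lam`` × mean squared lattice-displacement
    Laplacian + a soft base-plane constraint, over tricubic B-spline
    lattice displacements, with L-BFGS-B and exact gradients.

    Raises :class:`FitError` if the mask is degenerate or the final RMS
    residual exceeds ``residual_ceiling_voxels`` × max voxel dimension.
    """
    if mask.n_foreground == 0:
        raise FitError("empty mask")
    sd_endo, sd_epi = _mask_distance_fields(mask)
    spacing = mask.spacing_mm
    grad_endo = np.stack(np.gradient(sd_endo, *spacing), axis=0)
    grad_epi = np.stack(np.gradient(sd_epi, *spacing), axis=0)

    base_nodes = _initialize(template, mask, sd_endo, sd_epi)
    n_lat = template.lattice_resolution
    W, _, _ = _ffd_weight_matrix(base_nodes, n_lat)
    lap = _lattice_laplacian(n_lat)
    lap2 = (lap.T @ lap).tocsr()

    endo_ids, epi_ids = template.endo_ids, template.epi_ids
    ring = template.base_ring_ids()
    base_z = base_nodes[ring, 2].copy()
    n_nodes = template.n_nodes
    n_ctrl = n_lat**3
    origin = np.asarray(mask.origin_mm)
    sp = np.asarray(spacing)

    def unpack(p):
        return p.reshape(n_ctrl, 3)

    def objective(p):
        P = unpack(p)
        disp = W @ P
        nodes = base_nodes + disp
        idx = (nodes - origin) / sp - 0.5
        d = np.empty(n_nodes)
        d[endo_ids] = _interp(sd_endo, idx[endo_ids])
        d[epi_ids] = _interp(sd_epi, idx[epi_ids])
        g_nodes = np.empty((n_nodes, 3))
        for k in range(3):
            g_nodes[endo_ids, k] = _interp(grad_endo[k], idx[endo_ids])
            g_nodes[epi_ids, k] = _interp(grad_epi[k], idx[epi_ids])
        f_data = np.mean(d**2)
        g_data = (2.0 / n_nodes) * d[:, None] * g_nodes

        dz = nodes[ring, 2] - base_z
        f_base = base_weight * np.mean(dz**2)
        g_data[ring, 2] += base_weight * 2.0 / len(ring) * dz

        lp = lap @ P
        f_reg = lam * np.sum(lp**2) / n_ctrl
        g_reg = (2.0 * lam / n_ctrl) * (lap2 @ P)

        grad = W.T @ g_data + g_reg
        return f_data + f_base + f_reg, grad.ravel()

    history: list[float] = []

    def record(pk):
        history.append(float(objective(pk)[0]))

    p0 = np.zeros(n_ctrl * 3)
    res = minimize(
        objective, p0, jac=True, method="L-BFGS-B",
        callback=record,
        options={"maxiter": max_iter, "ftol": tol**2, "gtol": 1e-9, "maxcor": 20},
    )
    nodes = base_nodes + W @ unpack(res.x)

    idx = (nodes - origin) / sp - 0.5
    d = np.empty(n_nodes)
    d[endo_ids] = _interp(sd_endo, idx[endo_ids])
    d[epi_ids] = _interp(sd_epi, idx[epi_ids])
    rms = float(np.sqrt(np.mean(d**2)))
    ceiling = residual_ceiling_voxels * max(spacing)
    if rms > ceiling:
        raise FitError(
            f"fit did not converge: RMS residual {rms:.3f} mm exceeds "
            f"ceiling {ceiling:.3f} mm", residual=rms,
        )
    return LVMesh(
        nodes,
        template,
        provenance={
            "case_id": case_id or "",
            "residual_mm": rms,
            "n_iter": int(res.nit),
            "objective_history": history,
            "converged": bool(res.success or rms <= ceiling),
        },
    )
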