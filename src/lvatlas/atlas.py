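"""Shape-atlas construction: alignment, average anatomy, PCA modes.

Fitted meshes (shared topology) are aligned by centre of mass and
orientation — no scaling, since size differences are part of the biology
being measured — and decomposed by principal component analysis of the
stacked node coordinates.  The atlas holds the mean shape, orthonormal
modes, eigenvalues (mm²), explained-variance fractions and per-case mode
scores, so each ventricle is summarized by a few coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .meshfit import LVMesh, LVTemplateMesh

__all__ = [
    "ShapeAtlas",
    "align_meshes",
    "compute_atlas",
    "project_case",
    "reconstruct_shape",
]


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------


def _alignment_transform(mesh: LVMesh) -> tuple[np.ndarray, np.ndarray]:
    """(rotation, translation) putting a mesh into canonical pose.

    Centre of mass to the origin; long axis (principal eigenvector of the
    node covariance) to the z axis with the apex marker node at −z; roll
    about the long axis fixed by rotating the septal marker node to the
    +x half-plane.  Marker-based sign fixing avoids the 180° ambiguity of
    raw eigenvectors and is exact under rigid motion.
    """
    nodes = mesh.nodes
    com = nodes.mean(axis=0)
    centered = nodes - com
    cov = centered.T @ centered
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] < 1e-9 * max(evals[-1], 1e-12):
        raise ValueError("degenerate node cloud (rank < 3); cannot orient")
    axis = evecs[:, -1]
    apex = centered[mesh.template.apex_epi_id]
    if np.dot(apex, axis) > 0:  # apex must point toward −z
        axis = -axis

    # minimal rotation taking `axis` to ez
    ez = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, ez)
    c = float(np.dot(axis, ez))
    if c < -1.0 + 1e-12:
        r1 = np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        r1 = np.eye(3) + vx + vx @ vx / (1.0 + c)

    # roll: septal marker into the +x half-plane
    marker = r1 @ centered[mesh.template.septal_marker_id]
    ang = np.arctan2(marker[1], marker[0])
    ca, sa = np.cos(-ang), np.sin(-ang)
    r2 = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
    return r2 @ r1, com


def align_meshes(meshes: list[LVMesh]) -> tuple[list[LVMesh], list[dict]]:
    """Align meshes by centre of mass and orientation (no scaling).

    Returns the aligned meshes and, per mesh, the applied transform as
    ``{"rotation": R, "translation": t}`` with
    ``aligned = (nodes − t) @ Rᵀ``.
    """
    if len(meshes) < 2:
        raise ValueError("alignment needs at least 2 meshes")
    n0 = meshes[0].template.n_nodes
    if any(m.template.n_nodes != n0 for m in meshes):
        raise ValueError("meshes must share the template topology")
    aligned, transforms = [], []
    for m in meshes:
        rot, com = _alignment_transform(m)
        out = m.copy()
        out.nodes = (m.nodes - com) @ rot.T
        aligned.append(out)
        transforms.append({"rotation": rot, "translation": com})
    return aligned, transforms


# ---------------------------------------------------------------------------
# PCA atlas
# ---------------------------------------------------------------------------


@dataclass
class ShapeAtlas:
    """Average anatomy plus PCA modes of variation.

    ``modes`` has orthonormal columns in shape space (3N); ``eigenvalues``
    are sample variances (mm²) along each mode, descending;
    ``scores[i, j]`` is case i's coefficient on mode j (mm).
    """

    case_ids: list[str]
    mean_shape: np.ndarray  # (3N,)
    modes: np.ndarray  # (3N, M)
    eigenvalues: np.ndarray  # (M,)
    variance_fractions: np.ndarray  # (M,)
    scores: np.ndarray  # (cases, M)
    template: LVTemplateMesh | None = None

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    def mean_mesh(self) -> LVMesh:
        if self.template is None:
            raise ValueError("atlas carries no template topology")
        return LVMesh(self.mean_shape.reshape(-1, 3), self.template,
                      {"case_id": "atlas-mean"})

    def scores_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.scores,
            index=pd.Index(self.case_ids, name="case_id"),
            columns=[f"mode_{j + 1}" for j in range(self.n_modes)],
        )
        return df

    def save(self, path: str | Path) -> Path:
        """Write the atlas as a single .npz container of named arrays."""
        path = Path(path)
        np.savez(
            path,
            case_ids=np.asarray(self.case_ids),
            mean_shape=self.mean_shape,
            modes=self.modes,
            eigenvalues=self.eigenvalues,
            variance_fractions=self.variance_fractions,
            scores=self.scores,
        )
        return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")

    @classmethod
    def load(cls, path: str | Path, template: LVTemplateMesh | None = None) -> "ShapeAtlas":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                case_ids=[str(c) for c in z["case_ids"]],
                mean_shape=z["mean_shape"],
                modes=z["modes"],
                eigenvalues=z["eigenvalues"],
                variance_fractions=z["variance_fractions"],
                scores=z["scores"],
                template=template,
            )


def compute_atlas(
    aligned_meshes: list[LVMesh],
    eigenvalue_tol: float = 1e-9,
    case_ids: list[str] | None = None,
) -> ShapeAtlas:
    """PCA of aligned meshes about their average anatomy.

    The decomposition runs in case space (thin SVD of the centred
    case × 3N matrix), which is exact and cheap when nodes ≫ cases.
    Modes with eigenvalue ≤ ``eigenvalue_tol`` × total variance are
    dropped; at most cases − 1 modes can survive.  Mode signs follow a
    deterministic convention: the largest-magnitude entry of each mode is
    positive.  All-identical inputs yield a zero-mode atlas (not an
    error).
    """
    if len(aligned_meshes) < 2:
        raise ValueError("atlas needs at least 2 meshes")
    if case_ids is None:
        case_ids = [m.provenance.get("case_id") or f"case_{i:03d}"
                    for i, m in enumerate(aligned_meshes)]
    if len(case_ids) != len(aligned_meshes):
        raise ValueError("case_ids length mismatch")

    # canonical case order (sorted by id): the atlas is then bit-identical
    # regardless of the order meshes were supplied in
    order = sorted(range(len(case_ids)), key=lambda i: (str(case_ids[i]), i))
    case_ids = [case_ids[i] for i in order]
    aligned_meshes = [aligned_meshes[i] for i in order]

    X = np.stack([m.nodes.ravel() for m in aligned_meshes])  # (n, 3N)
    n = X.shape[0]
    mean = X.mean(axis=0)
    Xc = X - mean

    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    total = eigenvalues.sum()
    # variance at the level of float rounding noise means "all identical"
    noise_floor = (1e3 * np.finfo(float).eps * max(np.abs(X).max(), 1.0)) ** 2
    if total <= noise_floor:
        warnings.warn("all input meshes are identical: atlas retains 0 modes",
                      stacklevel=2)
        keep = np.zeros(0, dtype=int)
        total = 0.0
    else:
        keep = np.flatnonzero(eigenvalues > eigenvalue_tol * total)
    modes = Vt[keep].T  # (3N, M), orthonormal, descending eigenvalue
    eigenvalues = eigenvalues[keep]

    # deterministic sign: largest-|entry| component positive
    if modes.size:
        sign_idx = np.argmax(np.abs(modes), axis=0)
        signs = np.sign(modes[sign_idx, np.arange(modes.shape[1])])
        signs[signs == 0] = 1.0
        modes = modes * signs

    scores = Xc @ modes
    fractions = eigenvalues / total if total > 0 else eigenvalues
    return ShapeAtlas(
        case_ids=list(case_ids),
        mean_shape=mean,
        modes=modes,
        eigenvalues=eigenvalues,
        variance_fractions=fractions,
        scores=scores,
        template=aligned_meshes[0].template,
    )


def project_case(atlas: ShapeAtlas, mesh: LVMesh) -> np.ndarray:
    """Mode coefficients of a mesh already in the atlas alignment."""
    vec = mesh.nodes.ravel()
    if vec.shape[0] != atlas.mean_shape.shape[0]:
        raise ValueError("mesh topology does not match the atlas")
    return atlas.modes.T @ (vec - atlas.mean_shape)


def reconstruct_shape(atlas: ShapeAtlas, coefficients: np.ndarray) -> LVMesh:
    """Mean + Σ cᵢ·modeᵢ, reshaped to template node coordinates."""
    coeffs = np.atleast_1d(np.asarray(coefficients, dtype=float))
    if coeffs.shape[0] > atlas.n_modes:
        raise ValueError(
            f"got {coeffs.shape[0]} coefficients but the atlas retains "
            f"{atlas.n_modes} modes"
        )
    vec = atlas.mean_shape + atlas.modes[:, : coeffs.shape[0]] @ coeffs
    if atlas.template is None:
        raise ValueError("atlas carries no template topology")
    return LVMesh(vec.reshape(-1, 3), atlas.template, {"case_id": "reconstruction"})
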