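"""Parametric truncated-ellipsoid left-ventricle geometry.

The LV myocardium is modelled as a shell between two coaxial prolate
spheroids sharing a base truncation plane: an endocardial (inner) surface
with equatorial radius ``endo_radius_mm`` and an epicardial (outer) surface
offset by ``wall_mm`` both equatorially and apically.  The apex points to
-z, the base opening to +z, and the septal direction is +x.  A smooth
base-preserving lateral shear displaces the apex toward the septum by
``apex_offset_mm``.

All lengths are millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "GroundTruthShape",
    "DEFAULT_BASELINE_SHAPE",
    "truncated_ellipsoid_volume",
    "shell_volume",
    "cavity_volume",
]


@dataclass(frozen=True)
class GroundTruthShape:
    """Latent ground-truth LV shape parameters.

    Parameters
    ----------
    length_mm:
        Distance from the base truncation plane to the epicardial apex.
    endo_radius_mm:
        Endocardial equatorial radius.
    wall_mm:
        Equatorial (and apical) wall thickness.
    apex_offset_mm:
        Lateral displacement of the apex toward the septal +x direction,
        applied as a smooth shear that vanishes at the base.
    truncation_frac:
        Fraction of the full epicardial ellipsoid height retained, in
        (0.5, 1): 0.5 truncates at the equator, 1 keeps the full ellipsoid.
    """

    length_mm: float = 4.5
    endo_radius_mm: float = 1.3
    wall_mm: float = 0.6
    apex_offset_mm: float = 0.0
    truncation_frac: float = 0.8

    def __post_init__(self) -> None:
        if self.length_mm <= 0 or self.endo_radius_mm <= 0 or self.wall_mm <= 0:
            raise ValueError("all lengths must be positive")
        if self.wall_mm >= self.endo_radius_mm:
            raise ValueError(
                f"wall_mm ({self.wall_mm}) must be smaller than "
                f"endo_radius_mm ({self.endo_radius_mm})"
            )
        if not (0.5 < self.truncation_frac < 1.0):
            raise ValueError("truncation_frac must lie in (0.5, 1)")
        if abs(self.apex_offset_mm) >= self.endo_radius_mm:
            raise ValueError("|apex_offset_mm| must be below endo_radius_mm")
        # The endocardial surface must reach the base plane (open cavity).
        if self.truncation_frac >= self.length_mm / (self.length_mm + self.wall_mm):
            raise ValueError(
                "truncation_frac too large for this wall thickness: the "
                "endocardial surface would close below the base plane"
            )

    # -- derived quantities -------------------------------------------------

    @property
    def sphericity(self) -> float:
        """Equatorial endocardial diameter over long-axis length."""
        return 2.0 * self.endo_radius_mm / self.length_mm

    @property
    def c_epi(self) -> float:
        """Epicardial long semi-axis."""
        return self.length_mm / (2.0 * self.truncation_frac)

    @property
    def c_endo(self) -> float:
        """Endocardial long semi-axis."""
        return self.c_epi - self.wall_mm

    @property
    def a_epi(self) -> float:
        """Epicardial equatorial radius."""
        return self.endo_radius_mm + self.wall_mm

    @property
    def z_base(self) -> float:
        """z of the base truncation plane (ellipsoid centre at z=0)."""
        return self.length_mm - self.c_epi

    def shear(self, z: np.ndarray | float) -> np.ndarray | float:
        """Apex-ward shear weight: 0 at the base plane, 1 at the apex.

        Quadratic in normalized apex-ward depth, so the base ring is
        exactly preserved and the displacement grows smoothly.
        """
        depth = np.clip((self.z_base - np.asarray(z)) / self.length_mm, 0.0, 1.0)
        return depth**2

    def with_updates(self, **kw) -> "GroundTruthShape":
        return replace(self, **kw)


DEFAULT_BASELINE_SHAPE = GroundTruthShape()


def truncated_ellipsoid_volume(a: float, c: float, z_base: float) -> float:
    """Volume of the ellipsoid x²/a² + y²/a² + z²/c² ≤ 1 below z = z_base.

    Closed form from integrating the circular cross-section
    π a² (1 − z²/c²) over z ∈ [−c, z_base].
    """
    if not -c <= z_base <= c:
        raise ValueError("z_base must lie within [-c, c]")
    return float(np.pi * a**2 * (z_base - z_base**3 / (3 * c**2) + 2 * c / 3))


def cavity_volume(shape: GroundTruthShape) -> float:
    """Analytic endocardial (blood-pool) volume in mm³ (≡ µL)."""
    return truncated_ellipsoid_volume(shape.endo_radius_mm, shape.c_endo, shape.z_base)


def shell_volume(shape: GroundTruthShape) -> float:
    """Analytic myocardial shell volume in mm³ (≡ µL).

    The apex-offset shear is volume preserving, so the sheared shell has
    exactly this volume too.
    """
    outer = truncated_ellipsoid_volume(shape.a_epi, shape.c_epi, shape.z_base)
    return outer - cavity_volume(shape)
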