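"""Conventional echocardiography-derived indices.

Implements the standard M-mode/Doppler index set: fractional shortening,
cube-formula LV mass (myocardial density 1.053 g/cm³), Teichholz LV
volumes, E/E′, the Tei myocardial performance index, and radial
endocardial strain / strain rate from a one-cycle radius trace.

Unit conventions: lengths mm, times ms, weight g in; mass mg, volume µL,
strain %, strain rate 1/s out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import EchoRecord

__all__ = [
    "EchoDerived",
    "lv_mass",
    "fractional_shortening",
    "teichholz_volume",
    "mpi",
    "radial_strain",
    "derive_conventional",
    "derive_table",
]

MYOCARDIAL_DENSITY_MG_PER_MM3 = 1.053


@dataclass(frozen=True)
class EchoDerived:
    """Derived per-animal echocardiographic indices."""

    fs_percent: float
    lv_mass_mg: float
    lv_mass_index_mg_per_g: float
    lv_vol_d_uL: float
    lv_vol_s_uL: float
    stroke_volume_uL: float
    e_over_eprime: float
    mpi: float
    peak_radial_strain_percent: float
    peak_strain_rate_per_s: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fs_percent < 100.0:
            raise ValueError("fractional shortening must lie in [0, 100)")
        if min(self.lv_mass_mg, self.lv_vol_d_uL, self.lv_vol_s_uL) < 0:
            raise ValueError("masses and volumes must be non-negative")
        if self.mpi < 0:
            raise ValueError("MPI must be non-negative")


def lv_mass(lvid_d_mm: float, lvpw_d_mm: float, ivs_d_mm: float) -> float:
    """Cube-formula LV mass in mg.

    mass = 1.053 × ((LVIDd + LVPWd + IVSd)³ − LVIDd³), diameters in mm;
    1.053 mg/mm³ is the myocardial density.
    """
    if min(lvid_d_mm, lvpw_d_mm, ivs_d_mm) <= 0:
        raise ValueError("all diameters and wall thicknesses must be positive")
    outer = (lvid_d_mm + lvpw_d_mm + ivs_d_mm) ** 3
    return MYOCARDIAL_DENSITY_MG_PER_MM3 * (outer - lvid_d_mm**3)


def fractional_shortening(lvid_d_mm: float, lvid_s_mm: float) -> float:
    """FS (%) = 100 · (LVIDd − LVIDs) / LVIDd."""
    if lvid_d_mm <= 0:
        raise ZeroDivisionError("lvid_d_mm must be positive")
    return 100.0 * (lvid_d_mm - lvid_s_mm) / lvid_d_mm


def teichholz_volume(lvid_mm: float) -> float:
    """Teichholz M-mode volume, µL: V(mL) = 7.0/(2.4 + D) · D³ with D in cm."""
    if lvid_mm <= 0:
        raise ValueError("diameter must be positive")
    d_cm = lvid_mm / 10.0
    return 7.0 / (2.4 + d_cm) * d_cm**3 * 1000.0


def mpi(ivct_ms: float, ivrt_ms: float, et_ms: float) -> float:
    """Tei myocardial performance index: (IVCT + IVRT) / ET."""
    if et_ms <= 0:
        raise ZeroDivisionError("et_ms must be positive")
    return (ivct_ms + ivrt_ms) / et_ms


def radial_strain(
    trace_radius_mm: np.ndarray,
    frame_interval_ms: float,
    smooth_window: int = 0,
) -> tuple[float, float]:
    """Peak radial endocardial strain (%) and strain rate (1/s).

    Strain is the inward radial deformation relative to end-diastole
    (first frame, maximal radius): ε(t) = 100·(R0 − R(t))/R0, positive
    during systole.  Strain rate is dε/dt by central differences
    (forward/backward at the ends); the peak strain rate is the extremum
    of largest magnitude, reported with its sign.
    """
    r = np.asarray(trace_radius_mm, dtype=float)
    if r.size < 3:
        raise ValueError("trace must have at least 3 frames")
    if not np.all(np.isfinite(r)):
        raise ValueError("trace contains non-finite values")
    if r[0] <= 0:
        raise ValueError("end-diastolic radius must be positive")
    if frame_interval_ms <= 0:
        raise ValueError("frame interval must be positive")
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        padded = np.pad(r, pad, mode="edge")
        r = np.convolve(padded, kernel, mode="valid")[: r.size]
    strain = 100.0 * (r[0] - r) / r[0]
    rate = np.gradient(strain, frame_interval_ms / 1000.0) / 100.0  # fraction/s
    peak_strain = float(strain.max())
    k = int(np.argmax(np.abs(rate)))
    peak_rate = float(rate[k])
    return peak_strain, peak_rate


def derive_conventional(rec: EchoRecord) -> EchoDerived:
    """All conventional indices for one echo record."""
    fs = fractional_shortening(rec.lvid_d_mm, rec.lvid_s_mm)
    mass = lv_mass(rec.lvid_d_mm, rec.lvpw_d_mm, rec.ivs_d_mm)
    if rec.body_weight_g <= 0:
        raise ZeroDivisionError("body_weight_g must be positive")
    if rec.tissue_Eprime_mm_s <= 0:
        raise ZeroDivisionError("tissue_Eprime_mm_s must be positive")
    vol_d = teichholz_volume(rec.lvid_d_mm)
    vol_s = teichholz_volume(rec.lvid_s_mm)
    strain, rate = radial_strain(rec.endo_radius_trace_mm, rec.frame_interval_ms)
    return EchoDerived(
        fs_percent=fs,
        lv_mass_mg=mass,
        lv_mass_index_mg_per_g=mass / rec.body_weight_g,
        lv_vol_d_uL=vol_d,
        lv_vol_s_uL=vol_s,
        stroke_volume_uL=vol_d - vol_s,
        e_over_eprime=rec.mitral_E_mm_s / rec.tissue_Eprime_mm_s,
        mpi=mpi(rec.ivct_ms, rec.ivrt_ms, rec.et_ms),
        peak_radial_strain_percent=strain,
        peak_strain_rate_per_s=rate,
    )


def derive_table(records: dict[str, EchoRecord]) -> pd.DataFrame:
    """Tidy table of derived indices keyed by animal id."""
    rows = []
    for aid, rec in records.items():
        d = derive_conventional(rec)
        rows.append({"animal_id": aid, **d.__dict__})
    return pd.DataFrame(rows).set_index("animal_id")
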