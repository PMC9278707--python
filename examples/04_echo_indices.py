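"""Simulate an echocardiography record and derive the conventional indices.

Shows the measurement model (M-mode diameters from the true geometry,
Doppler/timing fields from the physiology config) and the derived index
set: fractional shortening, cube-formula LV mass, Teichholz volumes,
E/E', Tei index (MPI) and radial endocardial strain.
"""

from lvatlas import (
    DEFAULT_BASELINE_SHAPE, PhysiologyConfig, derive_conventional,
    simulate_echo_record,
)

physio = PhysiologyConfig()  # HR 400 bpm, contraction fraction 0.35, MPI timing 0.5
rec = simulate_echo_record(DEFAULT_BASELINE_SHAPE, physio, rng=0)
d = derive_conventional(rec)

print(f"LVIDd {rec.lvid_d_mm:.2f} mm, LVIDs {rec.lvid_s_mm:.2f} mm, "
      f"LVPWd {rec.lvpw_d_mm:.2f} mm, IVSd {rec.ivs_d_mm:.2f} mm")
print(f"fractional shortening: {d.fs_percent:.1f} %   (systolic function)")
print(f"LV mass (cube formula): {d.lv_mass_mg:.1f} mg, "
      f"indexed {d.lv_mass_index_mg_per_g:.2f} mg/g")
print(f"Teichholz volumes: diastole {d.lv_vol_d_uL:.1f} uL, "
      f"systole {d.lv_vol_s_uL:.1f} uL, stroke {d.stroke_volume_uL:.1f} uL")
print(f"E/E': {d.e_over_eprime:.1f}   (diastolic filling-pressure surrogate)")
print(f"MPI (Tei index): {d.mpi:.2f}   ((IVCT+IVRT)/ET, global function)")
print(f"peak radial strain: {d.peak_radial_strain_percent:.1f} % "
      f"at {d.peak_strain_rate_per_s:+.1f} 1/s")
print("\nstrain tracks the configured contraction fraction (0.35 -> ~35%),")
print("and FS agrees because both derive from the same radius trace.")
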