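"""Build a PCA shape atlas from a fitted cohort and test the group contrast.

Runs the geometric half of the pipeline on a 24-animal cohort (render →
segment → fit → align → PCA) and prints the retained mode count, the
variance explained by the first two modes, and the unpaired t-test on
mode-1 scores between room-air and hyperoxia animals.
"""

from lvatlas import (
    AcquisitionSpec, CohortDesign, align_meshes, build_template,
    compare_mode_scores, compute_atlas, fit_mesh, generate_cohort,
    segment_myocardium,
)

design = CohortDesign(master_seed=1)
acq = AcquisitionSpec(n_slices=70, pixel_mm=0.075, image_size_px=64)
cohort = generate_cohort(design, acq, echo=False)
template = build_template()

meshes = []
for animal in cohort:
    seg = segment_myocardium(animal.grayscale)
    meshes.append(fit_mesh(template, seg, case_id=animal.animal_id))

aligned, _ = align_meshes(meshes)
atlas = compute_atlas(aligned)
print(f"cases: {len(meshes)}, retained PCA modes: {atlas.n_modes} (= cases - 1)")
print(f"variance explained by modes 1+2: "
      f"{100 * atlas.variance_fractions[:2].sum():.1f}%")

labels = {a.animal_id: a.oxygen for a in cohort}
res = compare_mode_scores(atlas, labels, modes=[1, 2])
for t in res.ttests:
    print(f"{t.label}: t = {t.t_statistic:+.2f}, p = {t.p_value:.2e}")
print("\nmode 1 carries the hyperoxia size/shape contrast, so its scores")
print("separate the exposure arms; mode 2 mixes the treatment phenotype.")
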