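"""End-to-end pipeline orchestration.

Runs simulate → segment → fit → atlas → echo → stats under one config,
persisting every intermediate under a run directory:

```
run_dir/
  cohort/        masks, grayscale stacks (NIfTI), manifest.csv, echo CSVs
  segmented/     segmentation masks
  meshes/        fitted meshes (ASCII PLY + meshes.npz bundle), fit_log.csv
  atlas/         atlas.npz, scores.csv, variance_fractions.csv
  echo/          echo_derived.csv
  stats/         mode_ttests.csv, anova_<endpoint>.csv
  report/        summary.json, mode_scatter.png
```

Each stage writes a parameter-hash stamp; a rerun with the same config
skips stages whose stamp and outputs are present, and a full rerun is
bit-identical for arrays and identical to rounding for floats.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .atlas import ShapeAtlas, align_meshes, compute_atlas
from .echo import derive_table
from .imaging import load_volume, save_volume, segment_myocardium
from .meshfit import LVMesh, LVTemplateMesh, build_template, fit_mesh, mesh_cavity_volume
from .stats import compare_mode_scores, two_way_anova_bonferroni
from .synthetic import AcquisitionSpec, CohortDesign, generate_cohort

__all__ = ["MeshFitParams", "PipelineConfig", "PipelineResult", "run_pipeline",
           "save_mesh_ply", "save_mesh_bundle", "load_mesh_bundle"]


@dataclass(frozen=True)
class MeshFitParams:
    lam: float = 0.1
    lattice_resolution: int = 6
    surface_resolution: tuple[int, int] = (32, 20)
    max_iter: int = 200
    tol: float = 1e-4


@dataclass(frozen=True)
class StatsParams:
    posthoc: str = "default"
    alpha: float = 0.05
    welch: bool = True
    modes: tuple[int, ...] = (1, 2)
    endpoints: tuple[str, ...] = ("fs_percent", "lv_mass_mg", "e_over_eprime", "mpi")


@dataclass(frozen=True)
class PipelineConfig:
    design: CohortDesign = field(default_factory=CohortDesign)
    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    meshfit: MeshFitParams = field(default_factory=MeshFitParams)
    eigenvalue_tol: float = 1e-9
    stats: StatsParams = field(default_factory=StatsParams)
    segmentation_percentile: float | None = None  # None → Otsu

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path, master_seed: int | None = None) -> "PipelineConfig":
        """Build a config from a YAML file of nested sections.

        Unknown keys raise; missing sections fall back to defaults.
        ``master_seed`` overrides the design's seed when given.
        """
        raw = yaml.safe_load(Path(path).read_text()) or {}
        from .geometry import GroundTruthShape
        from .synthetic import PhysiologyConfig, ShapeEffect

        design_kw = dict(raw.get("design", {}))
        if "baseline" in design_kw:
            design_kw["baseline"] = GroundTruthShape(**design_kw["baseline"])
        if "effect_map" in design_kw:
            design_kw["effect_map"] = {
                k: ShapeEffect(**v) for k, v in design_kw["effect_map"].items()
            }
        if "physiology" in design_kw:
            design_kw["physiology"] = PhysiologyConfig(**design_kw["physiology"])
        for key in ("oxygen_levels", "treatment_levels"):
            if key in design_kw:
                design_kw[key] = tuple(design_kw[key])
        if master_seed is not None:
            design_kw["master_seed"] = int(master_seed)
        mf_kw = dict(raw.get("meshfit", {}))
        if "surface_resolution" in mf_kw:
            mf_kw["surface_resolution"] = tuple(mf_kw["surface_resolution"])
        st_kw = dict(raw.get("stats", {}))
        for key in ("modes", "endpoints"):
            if key in st_kw:
                st_kw[key] = tuple(st_kw[key])
        return cls(
            design=CohortDesign(**design_kw),
            acquisition=AcquisitionSpec(**raw.get("acquisition", {})),
            meshfit=MeshFitParams(**mf_kw),
            eigenvalue_tol=raw.get("eigenvalue_tol", 1e-9),
            stats=StatsParams(**st_kw),
            segmentation_percentile=raw.get("segmentation_percentile"),
        )


# ---------------------------------------------------------------------------
# mesh persistence
# ---------------------------------------------------------------------------


def save_mesh_ply(mesh: LVMesh, path: str | Path) -> Path:
    """Write a mesh as ASCII PLY (both surfaces in one element list)."""
    path = Path(path)
    faces = np.vstack([mesh.template.faces_endo, mesh.template.faces_epi])
    lines = [
        "ply", "format ascii 1.0",
        f"element vertex {len(mesh.nodes)}",
        "property float x", "property float y", "property float z",
        f"element face {len(faces)}",
        "property list uchar int vertex_indices", "end_header",
    ]
    lines += [f"{x:.6f} {y:.6f} {z:.6f}" for x, y, z in mesh.nodes]
    lines += [f"3 {a} {b} {c}" for a, b, c in faces]
    path.write_text("\n".join(lines) + "\n")
    return path


def save_mesh_bundle(meshes: list[LVMesh], path: str | Path) -> Path:
    """All fitted meshes + topology parameters in one .npz container."""
    tpl = meshes[0].template
    np.savez(
        path,
        nodes=np.stack([m.nodes for m in meshes]),
        case_ids=np.asarray([m.provenance.get("case_id", "") for m in meshes]),
        residuals=np.asarray([m.provenance.get("residual_mm", np.nan) for m in meshes]),
        n_circ=tpl.n_circ, n_long=tpl.n_long,
        lattice_resolution=tpl.lattice_resolution,
        template_nodes=tpl.nodes,
    )
    return Path(path)


def load_mesh_bundle(path: str | Path) -> list[LVMesh]:
    from .meshfit import mesh_from_shape
    from .geometry import DEFAULT_BASELINE_SHAPE
    with np.load(path, allow_pickle=False) as z:
        tpl = mesh_from_shape(
            DEFAULT_BASELINE_SHAPE, int(z["n_circ"]), int(z["n_long"]),
            int(z["lattice_resolution"]),
        ).template
        tpl.nodes = z["template_nodes"]
        return [
            LVMesh(nodes, tpl, {"case_id": str(cid), "residual_mm": float(res)})
            for nodes, cid, res in zip(z["nodes"], z["case_ids"], z["residuals"])
        ]


# ---------------------------------------------------------------------------
# stage machinery
# ---------------------------------------------------------------------------


def _hash_params(*objs) -> str:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return {"__cls__": type(o).__name__, **dataclasses.asdict(o)}
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, tuple):
            return list(o)
        raise TypeError(str(type(o)))
    payload = json.dumps(objs, default=default, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage_current(stamp: Path, digest: str, outputs: list[Path]) -> bool:
    return (stamp.exists() and stamp.read_text().strip() == digest
            and all(p.exists() for p in outputs))


@dataclass
class PipelineResult:
    run_dir: Path
    n_cases: int
    n_modes_retained: int
    atlas: ShapeAtlas
    manifest: pd.DataFrame
    scores: pd.DataFrame
    echo_derived: pd.DataFrame
    mode_ttests: pd.DataFrame
    anova_tables: dict[str, pd.DataFrame]
    summary: dict


def run_pipeline(config: PipelineConfig, out_dir: str | Path,
                 force: bool = False, log=print) -> PipelineResult:
    """Execute the full pipeline under ``out_dir``.

    Stages are cached by parameter hash: a rerun with an unchanged config
    skips completed stages unless ``force``.  Any stage error aborts with
    the stage name (and case id where applicable) in the message.
    """
    run = Path(out_dir)
    run.mkdir(parents=True, exist_ok=True)
    (run / "report").mkdir(exist_ok=True)

    # -- stage 1: simulate ---------------------------------------------------
    cohort_dir = run / "cohort"
    stamp = run / ".stamp_simulate"
    digest = _hash_params("simulate", config.design, config.acquisition)
    if force or not _stage_current(stamp, digest, [cohort_dir / "manifest.csv"]):
        log("[simulate] generating cohort")
        bundle = generate_cohort(config.design, config.acquisition, out_dir=cohort_dir)
        stamp.write_text(digest)
    else:
        log("[simulate] cached")
        bundle = generate_cohort(config.design, config.acquisition)  # in-memory
    manifest = pd.read_csv(cohort_dir / "manifest.csv")

    # -- stage 2: segment ----------------------------------------------------
    seg_dir = run / "segmented"
    seg_dir.mkdir(exist_ok=True)
    stamp = run / ".stamp_segment"
    digest = _hash_params("segment", config.design, config.acquisition,
                          config.segmentation_percentile)
    seg_paths = {a.animal_id: seg_dir / f"{a.animal_id}_seg.nii" for a in bundle}
    if force or not _stage_current(stamp, digest, list(seg_paths.values())):
        for a in bundle:
            try:
                seg = segment_myocardium(a.grayscale, config.segmentation_percentile)
            except Exception as e:
                raise RuntimeError(f"stage segment failed for case {a.animal_id}: {e}") from e
            save_volume(seg, seg_paths[a.animal_id])
        stamp.write_text(digest)
        log("[segment] done")
    else:
        log("[segment] cached")

    # -- stage 3: fit --------------------------------------------------------
    mesh_dir = run / "meshes"
    mesh_dir.mkdir(exist_ok=True)
    stamp = run / ".stamp_fit"
    digest = _hash_params("fit", config.design, config.acquisition,
                          config.segmentation_percentile, config.meshfit)
    bundle_path = mesh_dir / "meshes.npz"
    if force or not _stage_current(stamp, digest, [bundle_path]):
        template = build_template(
            config.meshfit.lattice_resolution, config.meshfit.surface_resolution,
        )
        meshes, fit_rows = [], []
        for a in bundle:
            seg = load_volume(seg_paths[a.animal_id], as_mask=True)
            try:
                m = fit_mesh(
                    template, seg, lam=config.meshfit.lam,
                    max_iter=config.meshfit.max_iter, tol=config.meshfit.tol,
                    case_id=a.animal_id,
                )
            except Exception as e:
                raise RuntimeError(f"stage fit failed for case {a.animal_id}: {e}") from e
            cav, myo = mesh_cavity_volume(m)
            fit_rows.append({
                "animal_id": a.animal_id,
                "residual_mm": m.provenance["residual_mm"],
                "n_iter": m.provenance["n_iter"],
                "cavity_volume_uL": cav, "myocardial_volume_uL": myo,
            })
            save_mesh_ply(m, mesh_dir / f"{a.animal_id}.ply")
            meshes.append(m)
        save_mesh_bundle(meshes, bundle_path)
        pd.DataFrame(fit_rows).to_csv(mesh_dir / "fit_log.csv", index=False)
        stamp.write_text(digest)
        log(f"[fit] {len(meshes)} meshes, mean residual "
            f"{np.mean([r['residual_mm'] for r in fit_rows]):.3f} mm")
    else:
        log("[fit] cached")
        meshes = load_mesh_bundle(bundle_path)

    # -- stage 4: atlas ------------------------------------------------------
    atlas_dir = run / "atlas"
    atlas_dir.mkdir(exist_ok=True)
    try:
        aligned, _ = align_meshes(meshes)
        atlas = compute_atlas(aligned, eigenvalue_tol=config.eigenvalue_tol)
    except Exception as e:
        raise RuntimeError(f"stage atlas failed: {e}") from e
    atlas.save(atlas_dir / "atlas.npz")
    scores = atlas.scores_frame()
    scores.to_csv(atlas_dir / "scores.csv")
    pd.DataFrame({
        "mode": np.arange(1, atlas.n_modes + 1),
        "eigenvalue_mm2": atlas.eigenvalues,
        "variance_fraction": atlas.variance_fractions,
    }).to_csv(atlas_dir / "variance_fractions.csv", index=False)
    log(f"[atlas] retained {atlas.n_modes} modes")

    # -- stage 5: echo -------------------------------------------------------
    echo_dir = run / "echo"
    echo_dir.mkdir(exist_ok=True)
    records = {a.animal_id: a.echo for a in bundle if a.echo is not None}
    echo_df = derive_table(records)
    echo_df.to_csv(echo_dir / "echo_derived.csv")
    log(f"[echo] derived indices for {len(echo_df)} animals")

    # -- stage 6: stats ------------------------------------------------------
    stats_dir = run / "stats"
    stats_dir.mkdir(exist_ok=True)
    labels = manifest.set_index("animal_id")["oxygen"]
    mode_res = compare_mode_scores(
        atlas, labels, modes=list(config.stats.modes),
        welch=config.stats.welch, alpha=config.stats.alpha,
    )
    mode_ttests = mode_res.to_frame()
    mode_ttests.to_csv(stats_dir / "mode_ttests.csv", index=False)
    meta = manifest.set_index("animal_id")
    anova_tables = {}
    anova_possible = config.design.n_per_cell >= 2
    for endpoint in config.stats.endpoints if anova_possible else ():
        vals = echo_df[endpoint].reindex(meta.index)
        res = two_way_anova_bonferroni(
            vals.to_numpy(), meta["oxygen"].to_numpy(), meta["treatment"].to_numpy(),
            posthoc_pairs=config.stats.posthoc, welch=config.stats.welch,
            alpha=config.stats.alpha,
        )
        tab = res.to_frame()
        tab.to_csv(stats_dir / f"anova_{endpoint}.csv", index=False)
        anova_tables[endpoint] = tab
    log("[stats] done")

    # -- stage 7: report -----------------------------------------------------
    report_dir = run / "report"
    summary = {
        "n_cases": len(manifest),
        "n_modes_retained": int(atlas.n_modes),
        "variance_fraction_mode1": float(atlas.variance_fractions[0]) if atlas.n_modes else 0.0,
        "variance_fraction_two_modes": float(atlas.variance_fractions[:2].sum()) if atlas.n_modes else 0.0,
        "mode_ttest_p": {
            t.label: t.p_value for t in mode_res.ttests
        },
        "anova_oxygen_p": {
            ep: float(tab.loc[tab["name"] == "oxygen", "p"].iloc[0])
            for ep, tab in anova_tables.items()
        },
    }
    (report_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    _scatter_plot(atlas, manifest, report_dir / "mode_scatter.png")

    return PipelineResult(
        run_dir=run, n_cases=len(manifest), n_modes_retained=atlas.n_modes,
        atlas=atlas, manifest=manifest, scores=scores, echo_derived=echo_df,
        mode_ttests=mode_ttests, anova_tables=anova_tables, summary=summary,
    )


def _scatter_plot(atlas: ShapeAtlas, manifest: pd.DataFrame, path: Path) -> None:
    """Mode-1 vs mode-2 score scatter by experimental group."""
    if atlas.n_modes < 2:
        return
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    meta = manifest.set_index("animal_id")
    fig, ax = plt.subplots(figsize=(5, 4))
    groups = meta.groupby(["oxygen", "treatment"]).groups
    for (ox, tr), ids in sorted(groups.items()):
        rows = [atlas.case_ids.index(i) for i in ids if i in atlas.case_ids]
        ax.scatter(atlas.scores[rows, 0], atlas.scores[rows, 1],
                   label=f"{ox}/{tr}", marker="*", s=60)
        ax.scatter(atlas.scores[rows, 0].mean(), atlas.scores[rows, 1].mean(),
                   marker="o", s=120, edgecolor="k", facecolor="none")
    ax.set_xlabel("mode 1 score (mm)")
    ax.set_ylabel("mode 2 score (mm)")
    ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
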