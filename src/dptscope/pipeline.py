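"""End-to-end orchestration on a synthetic or user-supplied cohort.

``run_pipeline`` executes the enabled stages in dependency order
(QC feeds signature scoring; clonal, spatial, trajectory and survival
stages are independent), writes every output under the run directory
and records a manifest of SHA-256 checksums so that reruns with the
same configuration and seed can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clonal, cytof, qc, signatures, spatial, survival, synthetic, trajectory
from .io import write_10x_mtx

__all__ = ["RunConfig", "run_pipeline", "synth_demo"]

STAGES = ("phenotyping", "qc", "signatures", "clonal", "trajectory", "spatial", "survival")


@dataclass
class RunConfig:
    out_dir: str = "dptscope_run"
    seed: int = 0
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})
    # synthetic cohort sizes
    n_patients: int = 4
    cells_per_sample: int = 1500
    n_scrna_cells: int = 1500
    n_tcr_cells: int = 3000
    n_spatial_cells: int = 1500
    n_spatial_cores: int = 2
    n_survival_patients: int = 200
    # analysis parameters
    n_top: int = 20
    min_freq: int = 10
    radii: tuple[float, ...] = (15.0, 45.0)
    spatial_attraction: float = 0.8
    survival_hr: float = 0.35
    trajectory_components: int = 3

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "radii" in raw:
            raw["radii"] = tuple(raw["radii"])
        return cls(**raw)

    def to_yaml(self, path: str | Path, include_out_dir: bool = True) -> None:
        d = asdict(self)
        d["radii"] = list(self.radii)
        if not include_out_dir:
            d.pop("out_dir")  # keep the echo path-independent for rerun comparison
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run all enabled stages on a synthetic cohort; return the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    stage_seed = {s: int(c.generate_state(1)[0] % (2**31)) for s, c in
                  zip(("cohort", *STAGES), ss.spawn(len(STAGES) + 1))}
    manifest: dict = {"seed": config.seed, "stages": {}, "files": {}}
    config.to_yaml(out / "run_config.yaml", include_out_dir=False)

    markers = ann = None
    if config.stages.get("phenotyping") or config.stages.get("trajectory"):
        cohort = synthetic.default_cohort_config(
            n_patients=config.n_patients,
            cells_per_sample=config.cells_per_sample,
            seed=stage_seed["cohort"],
        )
        markers, ann = synthetic.gen_cytof_cohort(cohort)
        pd.concat([markers, ann], axis=1).to_csv(out / "cytof_cells.csv", index=False)

    if config.stages.get("phenotyping"):
        gate = cytof.gate_compartments(markers)
        ann2 = ann.copy()
        ann2["compartment"] = gate.compartment.to_numpy()
        ann2.to_csv(out / "gate_assignments.csv", index=False)
        freq = cytof.cluster_region_frequencies(ann["population"], ann)
        freq.to_csv(out / "cluster_region_frequencies.csv")
        enrich = cytof.assign_region_enrichment(freq)
        enrich.to_csv(out / "region_enrichment.csv")
        dpt_cells = cytof.subset_phenotype(markers, gate, "DPT")
        r, p = cytof.coexpression_matrix(
            markers[["PD1", "CD45RO", "TIM3", "CTLA4", "LAG3", "HLADR", "ICOS", "CD28"]],
            dpt_cells,
        )
        r.to_csv(out / "dpt_coexpression_r.csv")
        p.to_csv(out / "dpt_coexpression_p.csv")
        manifest["stages"]["phenotyping"] = {
            "thresholds": gate.thresholds,
            "n_dpt": int(len(dpt_cells)),
        }

    adata_norm = None
    truth = None
    if config.stages.get("qc") or config.stages.get("signatures"):
        truth = synthetic.make_scrna_truth(seed=stage_seed["qc"])
        adata = synthetic.gen_scrna(truth, config.n_scrna_cells, seed=stage_seed["qc"])
        write_10x_mtx(adata, out / "scrna_counts")
    if config.stages.get("qc"):
        metrics = qc.compute_qc(adata, mito_genes=truth.mito_genes, dissoc_genes=truth.dissoc_genes)
        remove, reasons = qc.flag_low_quality(metrics)
        report = pd.concat([metrics, reasons], axis=1)
        report["removed"] = remove
        report.to_csv(out / "qc_report.tsv", sep="\t")
        kept = adata[~remove.to_numpy()].copy()
        adata_norm = qc.normalize_tpm_like(kept)
        hvg = qc.select_hvg(adata_norm, n_hvg=500, exclude=truth.ribo_genes)
        pd.Series(hvg, name="gene").to_csv(out / "hvg.tsv", sep="\t", index=False)
        pd.Series(kept.obs_names, name="barcode").to_csv(out / "retained_barcodes.tsv", sep="\t", index=False)
        manifest["stages"]["qc"] = {
            "n_input": int(adata.n_obs), "n_removed": int(remove.sum()), "n_hvg": len(hvg),
        }

    if config.stages.get("signatures"):
        if adata_norm is None:
            adata_norm = qc.normalize_tpm_like(adata)
        scores = {}
        members = {}
        for name, anchor in signatures.DEFAULT_ANCHORS.items():
            sig = signatures.build_anchor_signature(adata_norm, anchor, n_top=config.n_top, score_name=name)
            members[name] = sig.members
            scores[name] = signatures.score_cells(adata_norm, sig)
        score_df = pd.DataFrame(scores)
        score_df.to_csv(out / "cell_scores.tsv", sep="\t")
        counts_df = pd.DataFrame(
            adata_norm.layers["counts"] if "counts" in adata_norm.layers else adata_norm.X,
            index=adata_norm.obs_names, columns=adata_norm.var_names,
        )
        summary = signatures.cluster_score_summary(score_df, counts_df, adata_norm.obs["cluster"])
        summary.to_csv(out / "cluster_scores.tsv", sep="\t")
        pd.DataFrame.from_dict(members, orient="index").to_csv(out / "signature_members.tsv", sep="\t")
        manifest["stages"]["signatures"] = {"anchors": signatures.DEFAULT_ANCHORS}

    if config.stages.get("clonal"):
        ctruth = synthetic.default_clonal_truth()
        clusters = list(ctruth.transition_matrix.index)
        rng = np.random.default_rng(stage_seed["clonal"])
        labels = pd.Series(
            rng.choice(clusters, size=config.n_tcr_cells),
            index=[f"tcr_cell_{i:05d}" for i in range(config.n_tcr_cells)],
        )
        table = synthetic.gen_tcr(ctruth, labels, seed=stage_seed["clonal"])
        table.to_csv(out / "clonotypes.csv", index=False)
        expa = clonal.startrac_expa(table)
        tran = clonal.startrac_tran(table)
        expa.join(tran["tran"]).to_csv(out / "clonal_indices.tsv", sep="\t")
        ptran = clonal.pstartrac_tran_matrix(table)
        ptran.to_csv(out / "pairwise_transition.tsv", sep="\t")
        shared = clonal.shared_clone_counts(table)
        shared.to_csv(out / "shared_clones.tsv", sep="\t")
        inc, pairs = clonal.expanded_clone_cooccurrence(table, min_freq=config.min_freq)
        inc.to_csv(out / "expanded_clones.tsv", sep="\t")
        pairs.to_csv(out / "expanded_clone_pairs.tsv", sep="\t")
        json.dump(clonal.venn_regions(table), open(out / "clone_venn.json", "w"), indent=1)
        manifest["stages"]["clonal"] = {"n_clones": int(table["clonotype_id"].nunique())}

    if config.stages.get("trajectory"):
        tcell = ann["population"] != "DNT"
        sub = markers.loc[tcell, ["CD4", "CD8", "PD1", "CD45RO", "CD45RA"]]
        emb = trajectory.diffusion_map(
            sub, n_components=config.trajectory_components,
            max_cells=1500, seed=stage_seed["trajectory"],
        )
        emb.coords.to_csv(out / "diffusion_coords.tsv", sep="\t")
        pd.Series(emb.eigenvalues, name="eigenvalue").to_csv(out / "diffusion_eigenvalues.tsv", sep="\t", index=False)
        prof = trajectory.axis_profile(
            emb.coords["DC2"], markers.loc[emb.coords.index, "PD1"], n_bins=20
        )
        prof.to_csv(out / "dc2_pd1_profile.tsv", sep="\t", index=False)
        manifest["stages"]["trajectory"] = {"epsilon": emb.epsilon, "n_cells": int(len(emb.coords))}

    if config.stages.get("spatial"):
        cores = [
            synthetic.gen_spatial(
                attraction=config.spatial_attraction,
                n_cells=config.n_spatial_cells,
                seed=stage_seed["spatial"] + i,
                core_id=f"core_{i + 1}",
            )
            for i in range(config.n_spatial_cores)
        ]
        cells = pd.concat(cores, ignore_index=True)
        cells.to_csv(out / "spatial_cells.csv", index=False)
        counts = spatial.neighbor_counts(
            cells, "DPT_PD1pos", ("CD4_PD1pos", "CD8_PD1pos"), radii=config.radii
        )
        counts.to_csv(out / "neighbor_counts.tsv", sep="\t")
        cmp = spatial.compare_neighbor_counts(
            counts[[c for c in counts.columns if c.startswith("CD8")]],
            counts[[c for c in counts.columns if c.startswith("CD4")]],
        )
        cmp.to_csv(out / "neighbor_comparison.tsv", sep="\t", index=False)
        dens = pd.DataFrame(
            {
                "dpt": [spatial.cell_density(c, "DPT_PD1pos", area_mm2=1.0) for c in cores],
                "cd8": [spatial.cell_density(c, "CD8_PD1pos", area_mm2=1.0) for c in cores],
            }
        )
        dens.to_csv(out / "densities.tsv", sep="\t", index=False)
        manifest["stages"]["spatial"] = {"n_cores": len(cores)}

    if config.stages.get("survival"):
        rng = np.random.default_rng(stage_seed["survival"])
        density = rng.lognormal(3.0, 0.8, size=config.n_survival_patients)
        base = pd.DataFrame({"dpt_density": density})
        grouped = survival.dichotomize(base, "dpt_density")
        rec = synthetic.gen_survival(
            grouped["group"], hr=config.survival_hr, seed=stage_seed["survival"]
        )
        rec["dpt_density"] = density
        rec.to_csv(out / "survival_records.csv", index=False)
        km = survival.km_logrank(rec)
        cox = survival.cox_univariate(rec)
        stats = {"logrank_chi2": km["chi2"], "logrank_p": km["p"], **{k: v for k, v in cox.items()}}
        json.dump(stats, open(out / "survival_stats.json", "w"), indent=1)
        for g, curve in km["curves"].items():
            curve.to_csv(out / f"km_curve_{g}.tsv", sep="\t")
        manifest["stages"]["survival"] = {"n_patients": int(len(rec))}

    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][str(f.relative_to(out))] = _sha256(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def synth_demo(out_dir: str | Path, seed: int = 0) -> dict:
    """Generate the default synthetic cohort and run every stage."""
    return run_pipeline(RunConfig(out_dir=str(out_dir), seed=seed))
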