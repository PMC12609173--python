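"""End-to-end pipeline driver.

Stage order: group VBM contrast → severity staging → stage-wise contrasts
→ seed selection from the earliest stage's significant atrophy →
seed-based voxel-wise CaSCN (both directions) → ROI graph → degree/hub
metrics → modularity → optional behavioural decoding → mediation of
cognition by global grey-matter volume. Every artifact lands in the
output directory with the config hash and seed embedded in the summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import io
from .cascn import (build_pseudo_timeseries, extract_seed_series,
                    threshold_cascn, voxelwise_cascn)
from .config import AnalysisConfig, GeneratorConfig, config_hash
from .graph import (classify_hubs, degree_metrics, forward_inference_decoding,
                    newman_modularity, roi_gc_matrix)
from .mediation import bootstrap_indirect, inverse_tmt
from .morphometry import cluster_level_fdr
from .simulate import simulate_study
from .staging import assign_stages, fit_stage_thresholds, group_by_fazekas
from .types import ClusterSet, GMVImageSet, Region


@dataclass
class PipelineConfig:
    """Paths, thresholds and generator settings for a full run."""

    out_dir: Union[str, Path] = "cascnet_out"
    phenotype: Optional[str] = None          # CSV; None → simulate
    image_paths: Optional[list] = None
    mask_path: Optional[str] = None
    seed: int = 0
    n_patients: int = 185
    n_controls: int = 40
    stage_method: str = "local_polynomial"   # or "fazekas"
    seed_region: Optional[dict] = None       # {"center": [i,j,k], "radius": r}
    decode_table: Optional[str] = None       # TSV with domain,k,n,p
    n_boot: int = 1000
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig.desk_scale)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    def __post_init__(self) -> None:
        if self.analysis.n_perm < 100:
            raise ValueError("n_perm below the minimum of 100")
        if self.stage_method not in ("local_polynomial", "fazekas"):
            raise ValueError(f"unknown stage method {self.stage_method!r}")


def _covariate_matrix(cohort: pd.DataFrame) -> np.ndarray:
    sex = (cohort["sex"] == "male").astype(float)
    return np.column_stack([cohort["age"], sex, cohort["education_years"],
                            cohort["tiv"]]).astype(float)


def _select_seed_region(clusters: ClusterSet, mask_shape) -> np.ndarray:
    """Largest significant atrophy cluster as a boolean seed mask.

    Contrasts are computed control-positive, so atrophy in patients
    appears as positive-sign clusters.
    """
    sig = [c for c in clusters.significant() if c.sign > 0]
    if not sig:
        sig = [c for c in clusters if c.sign > 0]
    if not sig:
        raise RuntimeError("no atrophy cluster available for seed selection")
    best = max(sig, key=lambda c: c.extent)
    seed_mask = np.zeros(mask_shape, dtype=bool)
    seed_mask[tuple(best.voxels.T)] = True
    return seed_mask


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle; returns the summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    acfg = config.analysis
    summary: dict = {
        "seed": config.seed,
        "config_hash": config_hash(acfg, config.generator),
    }

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:   # annotate failures with the stage name
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return deco

    # ---- inputs -----------------------------------------------------
    if config.phenotype is None:
        cohort, images, truth = simulate_study(
            config.n_patients, config.n_controls, config.generator,
            seed=config.seed)
        io.write_phenotype(cohort, out / "phenotype.csv")
        io.write_ground_truth(truth, out / "ground_truth.json")
    else:
        cohort = io.read_phenotype(config.phenotype)
        images = io.read_image_set(config.image_paths, config.mask_path,
                                   subject_ids=list(cohort["subject_id"]))
        truth = None

    cov = _covariate_matrix(cohort)
    patients = cohort[cohort["group"] == "patient"].reset_index(drop=True)

    # ---- A: overall VBM contrast ------------------------------------
    @stage("vbm")
    def _vbm():
        tmap, clusters = cluster_level_fdr(
            images, cohort["group"], cov, forming_p=acfg.forming_p,
            min_extent=acfg.min_cluster_voxels, n_perm=acfg.n_perm,
            seed=config.seed, positive_level="control")
        io.write_map(tmap.statistic, images.affine, out / "vbm_t.nii.gz")
        io.write_tsv(clusters.to_frame(images.affine), out / "vbm_clusters.tsv")
        return tmap, clusters
    tmap, vbm_clusters = _vbm
    summary["vbm_significant_clusters"] = len(vbm_clusters.significant())

    # ---- B: staging --------------------------------------------------
    @stage("staging")
    def _stage():
        if config.stage_method == "fazekas":
            labels = group_by_fazekas(patients["fazekas"])
            thresholds = None
        else:
            thresholds = fit_stage_thresholds(
                patients["wmh_volume"].to_numpy(),
                patients["global_gmv"].to_numpy())
            labels = assign_stages(patients["wmh_volume"].to_numpy(), thresholds)
        return thresholds, labels
    thresholds, stage_labels = _stage
    staged = patients.copy()
    staged["stage"] = stage_labels
    staged.to_csv(out / "phenotype_staged.csv", index=False)
    summary["stage_thresholds"] = thresholds
    summary["stage_counts"] = pd.Series(stage_labels).value_counts().to_dict()

    # ---- C: earliest-stage contrast and seed selection ---------------
    @stage("seed_selection")
    def _seed():
        if config.seed_region is not None:
            r = Region("seed", tuple(config.seed_region["center"]),
                       int(config.seed_region["radius"]))
            return r.mask(images.mask.shape) & images.mask
        first = min(set(stage_labels))
        sel_ids = set(staged.loc[staged["stage"] == first, "subject_id"]) \
            | set(cohort.loc[cohort["group"] == "control", "subject_id"])
        rows = [i for i, s in enumerate(images.subject_ids) if s in sel_ids]
        sub = GMVImageSet(images.data[rows], images.mask, images.affine,
                          [images.subject_ids[i] for i in rows])
        subgroup = cohort.set_index("subject_id").loc[
            [images.subject_ids[i] for i in rows], "group"]
        subcov = cov[rows]
        _, clusters = cluster_level_fdr(
            sub, subgroup, subcov, forming_p=acfg.forming_p,
            min_extent=acfg.min_cluster_voxels, n_perm=acfg.n_perm,
            seed=config.seed + 1, positive_level="control")
        return _select_seed_region(clusters, images.mask.shape)
    seed_mask = _seed
    summary["seed_voxels"] = int(seed_mask.sum())

    # ---- D/E: pseudo-time series and voxel-wise CaSCN -----------------
    @stage("cascn")
    def _cascn():
        pts = build_pseudo_timeseries(images, cohort)
        ss = extract_seed_series(pts, seed_mask)
        fwd, rev = voxelwise_cascn(pts, ss)
        io.write_map(fwd.gc, images.affine, out / "cascn_gc_fwd.nii.gz")
        io.write_map(fwd.z, images.affine, out / "cascn_z_fwd.nii.gz")
        clusters = threshold_cascn(fwd, pts, seed_mask, acfg,
                                   n_perm=acfg.n_perm, seed=config.seed + 2)
        io.write_tsv(clusters.to_frame(images.affine),
                     out / "cascn_clusters.tsv")
        return pts, ss, fwd, rev, clusters
    pts, seed_series, gc_fwd, gc_rev, cascn_clusters = _cascn
    summary["cascn_clusters"] = len(cascn_clusters.significant(acfg.fdr_alpha))
    summary["cascn_negative_clusters"] = sum(
        1 for c in cascn_clusters.significant(acfg.fdr_alpha) if c.sign < 0)

    # ---- F: ROI graph, degrees, modularity ----------------------------
    @stage("graph")
    def _graph():
        rois = [("seed", seed_mask)]
        for c in cascn_clusters.significant(acfg.fdr_alpha):
            m = np.zeros(images.mask.shape, dtype=bool)
            m[tuple(c.voxels.T)] = True
            rois.append((f"roi{c.id:02d}", m))
        if len(rois) < 2:
            return None
        series = np.column_stack([extract_seed_series(pts, m) for _, m in rois])
        graph = roi_gc_matrix(series, [n for n, _ in rois], acfg)
        deg = degree_metrics(graph)
        deg["role"] = classify_hubs(deg)
        io.write_tsv(graph.edge_frame(), out / "edges.tsv")
        io.write_tsv(deg.reset_index(), out / "degrees.tsv")
        part = None
        if graph.n_edges:
            part = newman_modularity(graph, seed=config.seed)
            io.write_tsv(pd.DataFrame(
                [(n, m) for n, m in part.membership.items()],
                columns=["node", "module"]), out / "modules.tsv")
        return graph, deg, part
    graph_out = _graph
    if graph_out is not None:
        graph, deg, part = graph_out
        summary["n_rois"] = graph.n_nodes
        summary["n_edges"] = graph.n_edges
        summary["top_causal_hub"] = str(deg["out_in_bin"].idxmax())
        summary["modularity_q"] = None if part is None else part.q
        summary["n_modules"] = None if part is None else part.n_modules

    # ---- G: decoding ---------------------------------------------------
    if config.decode_table is not None:
        @stage("decode")
        def _decode():
            table = pd.read_csv(config.decode_table, sep="\t")
            enr = forward_inference_decoding(table, alpha=acfg.fdr_alpha)
            io.write_tsv(enr, out / "decoding.tsv")
            return enr
        summary["enriched_domains"] = int(_decode["enriched"].sum())

    # ---- H: mediation --------------------------------------------------
    @stage("mediation")
    def _mediate():
        res = {}
        x = patients["wmh_volume"].to_numpy()
        m = patients["global_gmv"].to_numpy()
        pcov = _covariate_matrix(patients)
        for name, y in (("dst", patients["dst"].to_numpy()),
                        ("inv_tmt_a", inverse_tmt(patients["tmt_a"].to_numpy()))):
            r = bootstrap_indirect(x, m, y, pcov, n_boot=config.n_boot,
                                   seed=config.seed + 3, outcome=name)
            res[name] = r.to_dict()
        with open(out / "mediation.json", "w") as fh:
            json.dump(res, fh, indent=2)
        return res
    summary["mediation"] = _mediate

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    return summary
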