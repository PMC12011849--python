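"""End-to-end orchestration of the analysis pipeline.

Stages: simulate (optional) -> normalize -> PCA -> cluster -> differential
expression (cytokine contrast and resistant-cell contrast) -> metacells ->
consensus co-expression modules -> tolerance classification and module
down-selection -> signature scoring / AUC on single-cell and multi-source
bulk contrasts -> kME-ranked GSEA -> copy-number inference.  Each stage
writes its artifact with a provenance header, and a run manifest records
checksums and the per-stage seeds derived from the global seed.

The resistant-cell contrast needs a putative resistant set without access
to ground truth: starved (TS) cells are classified against C/T centroids
with the label-transfer classifier, and TS cells assigned "T" (i.e. still
MDSC-like) are treated as resistant — mirroring how the original analysis
identified its resistant cluster by reference enrichment.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cnv_infer, coexpress, diffexpr, gsea, io, preprocess, scoring, synthdata, tolerance
from .config import CnvBlock, PlantedModule, SimConfig, default_config

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "load_pipeline_config", "stage_seed"]

VERSION = "0.1.0"


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministically derive a per-stage seed below 2**31."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "stressmod_run"
    simulate: dict = field(default_factory=dict)    # SimConfig overrides; {} = defaults
    preprocess: dict = field(default_factory=lambda: {
        "n_hvg": None, "n_pcs": 30, "k_neighbors": 15, "resolution": 0.8,
    })
    de: dict = field(default_factory=lambda: {"padj_max": 0.05, "lfc_min": 0.25})
    modules: dict = field(default_factory=lambda: {
        "k_agg": 25, "max_shared": 10, "min_module_size": 25,
        "cut_height": 0.995, "powers": list(range(1, 21)),
        "consensus_quantile": 0.0, "kme_gap": 0.1,
    })
    tolerance: dict = field(default_factory=lambda: {"min_shared": 5})
    gsea: dict = field(default_factory=lambda: {
        "gene_sets": None, "n_perm": 1000, "min_size": 5,
    })
    cnv: dict = field(default_factory=lambda: {"window": 101, "clip": 3.0, "k": 2})
    run_bulk: bool = True
    run_cnv: bool = True
    run_gsea: bool = True

    def sim_config(self) -> SimConfig:
        cfg = default_config(seed=stage_seed(self.seed, "simulate"))
        overrides = dict(self.simulate)
        if "modules" in overrides:
            cfg.modules = [PlantedModule(**m) for m in overrides.pop("modules")]
        if "cnv_blocks" in overrides:
            cfg.cnv_blocks = [CnvBlock(**b) for b in overrides.pop("cnv_blocks")]
        for k, v in overrides.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown simulate parameter {k!r}")
            setattr(cfg, k, v)
        return cfg

    def validate(self) -> None:
        self.sim_config().validate()
        pp = self.preprocess
        if pp["n_pcs"] < 1 or pp["k_neighbors"] < 1 or pp["resolution"] <= 0:
            raise ValueError("invalid preprocess parameters")
        if not (0 < self.de["padj_max"] <= 1) or self.de["lfc_min"] < 0:
            raise ValueError("invalid DE thresholds")
        mo = self.modules
        if mo["k_agg"] < 1 or mo["min_module_size"] < 1 or not (0 < mo["cut_height"] <= 1):
            raise ValueError("invalid module parameters")
        if not (0 <= mo["consensus_quantile"] <= 1):
            raise ValueError("consensus_quantile must lie in [0, 1]")
        if self.tolerance["min_shared"] < 1:
            raise ValueError("min_shared must be >= 1")
        if self.gsea["n_perm"] < 1:
            raise ValueError("n_perm must be >= 1")
        if self.cnv["window"] % 2 == 0 or self.cnv["window"] < 1 or self.cnv["k"] < 2:
            raise ValueError("invalid CNV parameters")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seeds: dict
    files: dict
    stages: list
    started: str = ""
    finished: str = ""

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_table(df: pd.DataFrame, path: Path, stage: str, params: dict, index: bool = True) -> None:
    """TSV with a provenance header line naming the producing stage."""
    kv = " ".join(f"{k}={v}" for k, v in sorted(params.items()))
    with open(path, "w") as fh:
        fh.write(f"# stressmod stage={stage} {kv}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path: str | Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full pipeline on a freshly simulated dataset.

    Any stage failure aborts with the failing stage named; partial outputs
    are retained alongside a FAILED marker file.
    """
    config.validate()  # reject bad parameters before any stage runs
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = {s: stage_seed(config.seed, s) for s in
             ("simulate", "cluster", "metacells", "gsea", "bulk")}
    cfg_dict = config.to_dict()
    cfg_dict.pop("outdir", None)  # hash the scientific config, not the destination
    cfg_json = json.dumps(cfg_dict, sort_keys=True, default=str)
    manifest = RunManifest(
        version=VERSION,
        config_hash=hashlib.sha256(cfg_json.encode()).hexdigest(),
        seeds=seeds,
        files={},
        stages=[],
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    files: dict[str, Path] = {}
    current_stage = "init"

    def record(name: str, path: Path) -> None:
        files[name] = path
        manifest.files[name] = _sha256(path)

    try:
        # ---------------- simulate ----------------------------------
        current_stage = "simulate"
        sim_cfg = config.sim_config()
        ds = synthdata.simulate_sc_experiment(sim_cfg)
        io.write_10x_triplet(ds.counts, outdir / "counts")
        record("matrix.mtx", outdir / "counts" / "matrix.mtx")
        _write_table(ds.cell_meta, outdir / "cell_meta.tsv", "simulate",
                     {"seed": sim_cfg.seed})
        record("cell_meta.tsv", outdir / "cell_meta.tsv")
        io.write_gene_positions(ds.gene_meta, outdir / "gene_positions.tsv")
        record("gene_positions.tsv", outdir / "gene_positions.tsv")
        io.write_json(ds.truth, outdir / "truth.json")
        record("truth.json", outdir / "truth.json")
        truth_gmt = outdir / "planted_modules.gmt"
        io.write_gmt(ds.truth["modules"], truth_gmt, description="planted")
        record("planted_modules.gmt", truth_gmt)
        manifest.stages.append("simulate")

        # ---------------- preprocess --------------------------------
        current_stage = "preprocess"
        norm = preprocess.normalize_log_cp10k(ds.counts)
        z = preprocess.zscore_genes(norm.values, 1)
        z = np.clip(z, -preprocess.ZSCORE_CLIP, preprocess.ZSCORE_CLIP)
        pca = preprocess.compute_pca(z, config.preprocess["n_pcs"],
                                     gene_ids=norm.gene_ids, cell_ids=norm.cell_ids)
        pca_df = pd.DataFrame(
            pca.cell_scores,
            index=pd.Index(norm.cell_ids, name="cell_id"),
            columns=[f"PC{i + 1}" for i in range(pca.cell_scores.shape[1])],
        )
        _write_table(pca_df, outdir / "pca_scores.tsv", "preprocess",
                     {"n_pcs": config.preprocess["n_pcs"]})
        record("pca_scores.tsv", outdir / "pca_scores.tsv")
        manifest.stages.append("preprocess")

        # ---------------- cluster -----------------------------------
        current_stage = "cluster"
        labels = preprocess.cluster_cells(
            pca,
            k_neighbors=config.preprocess["k_neighbors"],
            resolution=config.preprocess["resolution"],
            seed=seeds["cluster"],
        )
        clusters = pd.DataFrame({"cluster": labels},
                                index=pd.Index(norm.cell_ids, name="cell_id"))
        _write_table(clusters, outdir / "clusters.tsv", "cluster",
                     {"resolution": config.preprocess["resolution"],
                      "k_neighbors": config.preprocess["k_neighbors"],
                      "seed": seeds["cluster"]})
        record("clusters.tsv", outdir / "clusters.tsv")
        manifest.stages.append("cluster")

        # ---------------- cytokine contrast --------------------------
        current_stage = "de"
        expr_cells = norm.to_frame()
        group = ds.cell_meta["group"]
        c_cells = list(group.index[group == "C"])
        t_cells = list(group.index[group == "T"])
        ts_cells = group.index[group == "TS"]
        deg_ct = diffexpr.wilcoxon_de(norm, t_cells, c_cells, contrast="T_vs_C")
        _write_table(deg_ct, outdir / "deg_T_vs_C.tsv", "de", config.de, index=False)
        record("deg_T_vs_C.tsv", outdir / "deg_T_vs_C.tsv")

        # ---------------- resistant-set identification --------------
        # starved cells are classified against the control/cytokine
        # reference on the cytokine-responsive gene space; clusters whose
        # TS cells mostly still look cytokine-treated are called resistant
        # (per-cluster majority vote, mirroring the reference-enrichment
        # logic used to pin down the resistant cluster)
        current_stage = "resistant_id"
        mdsc_space = diffexpr.significant_genes(
            deg_ct, config.de["padj_max"], config.de["lfc_min"]
        )["gene"].tolist()
        ref_cells = group.index[group.isin(["C", "T"])]
        clf = scoring.CentroidLabelTransfer().fit(
            expr_cells.loc[mdsc_space, ref_cells], group.loc[ref_cells]
        )
        ts_pred = clf.predict(expr_cells.loc[mdsc_space, ts_cells])
        ts_clusters = clusters.loc[ts_cells, "cluster"]
        t_frac = (ts_pred == "T").groupby(ts_clusters).mean()
        resistant_clusters = set(t_frac.index[t_frac > 0.5])
        is_resistant = ts_clusters.isin(resistant_clusters)
        resistant_pred = ts_cells[is_resistant]
        other_ts = ts_cells[~is_resistant]
        if len(resistant_pred) < 2 or len(other_ts) < 2:
            warnings.warn("cluster vote degenerate; falling back to per-cell votes")
            resistant_pred = ts_cells[(ts_pred == "T").to_numpy()]
            other_ts = ts_cells[(ts_pred != "T").to_numpy()]
            is_resistant = pd.Series(ts_pred == "T", index=ts_cells)
        pred_df = pd.DataFrame(
            {"predicted_resistant": is_resistant, "cell_vote": (ts_pred == "T")},
            index=pd.Index(ts_cells, name="cell_id"),
        )
        _write_table(pred_df, outdir / "resistant_prediction.tsv", "resistant_id",
                     {"n_feature_genes": len(mdsc_space),
                      "resistant_clusters": sorted(resistant_clusters)})
        record("resistant_prediction.tsv", outdir / "resistant_prediction.tsv")
        manifest.stages.append("resistant_id")

        # ---------------- resistant contrast -------------------------
        current_stage = "de"
        deg_r = diffexpr.wilcoxon_de(
            norm, list(resistant_pred), list(other_ts), contrast="resistant_vs_otherTS"
        )
        _write_table(deg_r, outdir / "deg_resistant_vs_otherTS.tsv", "de",
                     config.de, index=False)
        record("deg_resistant_vs_otherTS.tsv", outdir / "deg_resistant_vs_otherTS.tsv")
        manifest.stages.append("de")

        # ---------------- consensus modules -------------------------
        current_stage = "modules"
        mo = config.modules
        metacells = coexpress.make_metacells(
            norm, pca, ds.cell_meta["donor"],
            k_agg=mo["k_agg"], max_shared=mo["max_shared"], seed=seeds["metacells"],
        )
        pick = coexpress.pick_soft_threshold(metacells, mo["powers"])
        toms = []
        for donor in sorted(pd.unique(metacells.donor)):
            sub = metacells.expr[:, metacells.donor == donor]
            adj = coexpress.build_adjacency(sub, pick[donor])
            toms.append(coexpress.compute_tom(adj))
        cons = coexpress.consensus_tom(toms, quantile=mo["consensus_quantile"])
        assignment = coexpress.detect_modules(
            cons, metacells.gene_ids,
            min_module_size=mo["min_module_size"], cut_height=mo["cut_height"],
        )
        eig = coexpress.module_eigengenes(metacells, assignment)
        kme = coexpress.compute_kme(metacells, eig)
        assignment = coexpress.reassign_by_kme(assignment, kme, gap=mo["kme_gap"])
        eig = coexpress.module_eigengenes(metacells, assignment)
        kme = coexpress.compute_kme(metacells, eig)

        cell_flags = pd.DataFrame({
            "Ctrl": group == "C",
            "MDSC": group == "T",
            "MDSC_SF": group == "TS",
            "resistant_pred": pd.Series(group.index.isin(resistant_pred), index=group.index),
        }).astype(float)
        traits = pd.DataFrame(
            [cell_flags.loc[m].mean(axis=0) for m in metacells.membership],
            index=eig.index,
        )
        trait_cor = coexpress.module_trait_correlation(eig, traits)
        moduleset = coexpress.ModuleSet(
            assignment=assignment, eigengenes=eig, kme=kme,
            soft_power=pick, trait_cor=trait_cor,
        )
        _write_table(assignment.to_frame("module"), outdir / "module_assignment.tsv",
                     "modules", {"soft_power": pick, **{k: mo[k] for k in
                                 ("k_agg", "min_module_size", "cut_height")}})
        record("module_assignment.tsv", outdir / "module_assignment.tsv")
        _write_table(kme, outdir / "kme.tsv", "modules", {})
        record("kme.tsv", outdir / "kme.tsv")
        _write_table(eig, outdir / "eigengenes.tsv", "modules", {})
        record("eigengenes.tsv", outdir / "eigengenes.tsv")
        _write_table(trait_cor, outdir / "module_trait_correlation.tsv", "modules",
                     {}, index=False)
        record("module_trait_correlation.tsv", outdir / "module_trait_correlation.tsv")
        manifest.stages.append("modules")

        # ---------------- tolerance classification ------------------
        current_stage = "tolerance"
        tol = tolerance.classify_gene_tolerance(
            deg_ct, deg_r, assignment=assignment,
            padj_max=config.de["padj_max"], lfc_min=config.de["lfc_min"],
        )
        candidates = tolerance.downselect_modules(
            assignment, tol, min_shared=config.tolerance["min_shared"]
        )
        comp = tolerance.module_tolerance_composition(assignment, tol)
        _write_table(tol, outdir / "tolerance_table.tsv", "tolerance",
                     config.de, index=False)
        record("tolerance_table.tsv", outdir / "tolerance_table.tsv")
        _write_table(comp, outdir / "module_tolerance_composition.tsv", "tolerance",
                     {}, index=False)
        record("module_tolerance_composition.tsv", outdir / "module_tolerance_composition.tsv")
        io.write_json({"candidates": candidates}, outdir / "candidates.json")
        record("candidates.json", outdir / "candidates.json")
        manifest.stages.append("tolerance")

        # ---------------- scoring -----------------------------------
        current_stage = "scoring"
        sc_contrasts = {
            "T_vs_C": pd.Series(
                np.where(group.loc[group.isin(["C", "T"])] == "T", 1, 0),
                index=group.index[group.isin(["C", "T"])],
            ),
            "resistant_vs_otherTS": pd.Series(
                [1] * len(resistant_pred) + [0] * len(other_ts),
                index=list(resistant_pred) + list(other_ts),
            ),
        }
        sc_auc = scoring.evaluate_module_separation(assignment, expr_cells, sc_contrasts)
        _write_table(sc_auc, outdir / "module_auc_singlecell.tsv", "scoring",
                     {}, index=False)
        record("module_auc_singlecell.tsv", outdir / "module_auc_singlecell.tsv")
        if config.run_bulk:
            bulk_cfg = dataclasses.replace(sim_cfg, seed=seeds["bulk"])
            bulk = synthdata.simulate_bulk_sources(bulk_cfg)
            bulk_contrast = {"mdsc_vs_control": bulk.sample_meta["is_mdsc"].astype(int)}
            bulk_auc = scoring.evaluate_module_separation(
                assignment, bulk.expr, bulk_contrast
            )
            _write_table(bulk_auc, outdir / "module_auc_bulk.tsv", "scoring",
                         {"seed": seeds["bulk"]}, index=False)
            record("module_auc_bulk.tsv", outdir / "module_auc_bulk.tsv")
        manifest.stages.append("scoring")

        # ---------------- GSEA --------------------------------------
        if config.run_gsea and candidates:
            current_stage = "gsea"
            gmt_path = config.gsea["gene_sets"] or truth_gmt
            sets = io.read_gmt(gmt_path)
            top = candidates[0]
            ranking = kme[top]
            res = gsea.preranked_gsea(
                ranking, sets,
                n_perm=config.gsea["n_perm"], seed=seeds["gsea"],
                min_size=config.gsea["min_size"],
            )
            _write_table(res, outdir / "gsea_kme.tsv", "gsea",
                         {"module": top, "n_perm": config.gsea["n_perm"],
                          "seed": seeds["gsea"]}, index=False)
            record("gsea_kme.tsv", outdir / "gsea_kme.tsv")
            manifest.stages.append("gsea")

        # ---------------- CNV inference -----------------------------
        if config.run_cnv:
            current_stage = "cnv"
            profile = cnv_infer.infer_cnv_profile(
                norm, ds.gene_meta, ref_cells=c_cells,
                window=config.cnv["window"], clip=config.cnv["clip"],
                query_cells=list(group.index[group != "C"]),
            )
            clusters_cnv = cnv_infer.subcluster_cnv(profile, k=config.cnv["k"])
            _write_table(clusters_cnv, outdir / "cnv_clusters.tsv", "cnv",
                         {"window": config.cnv["window"], "clip": config.cnv["clip"]})
            record("cnv_clusters.tsv", outdir / "cnv_clusters.tsv")
            manifest.stages.append("cnv")

    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage={current_stage}\nerror={exc}\n")
        raise RuntimeError(f"pipeline failed at stage {current_stage!r}: {exc}") from exc

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    io.write_json(manifest.to_dict(), outdir / "manifest.json")
    return manifest
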