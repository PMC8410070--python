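"""End-to-end orchestration: one seeded config, one output tree, one manifest.

Stage order follows the analysis: QC → normalize → cluster → annotate →
EC selection → EC subclustering → markers → cross-atlas similarity →
EC-enriched and core-vs-periphery differential genes → BBB modules →
anatomic-region enrichment.  Every file written is recorded in the run
manifest with a content digest; when inputs are synthetic, planted-truth
recovery metrics (ARI, marker precision/recall, module set equality) are
included.  A single global seed fans out to per-stage seeds derived by
hashing the stage name, so any stage can be re-run in isolation.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import anatomic as an
from . import bbb, cross_atlas, markers as mk, preprocess as pp, synthetic as syn
from .core_io import Manifest, write_gene_sets, write_table

logger = logging.getLogger("ecatlas")

__all__ = ["RunConfig", "run_full", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31, derived from the stage name."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class RunConfig:
    seed: int = 1
    out_dir: str = "ecatlas_run"
    simulate: syn.SimConfig | None = None
    input_paths: dict | None = None  # matrix/features/barcodes/meta [+ panels GMT]
    max_mito_fraction: float = 0.10
    min_genes_detected: int = 200
    scale_factor: float = 10_000.0
    n_pcs: int = 20
    k_classes: int = 12  # whole-atlas clusters, finer than the class count
    k_ec: int = 5
    alpha: float = 0.05
    top_k: int = 50
    mds_dims: int = 2
    doublet_quantile: float = 0.99
    min_cpm: float = 100.0
    min_fold: float = 2.0
    min_models: int = 3
    min_cells_detected: int = 1

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.input_paths is None):
            raise ValueError("exactly one of simulate / input_paths must be given")

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None, out_dir: str | None = None):
        d = yaml.safe_load(Path(path).read_text()) or {}
        sim = d.pop("simulate", None)
        if sim is not None:
            sim = syn.SimConfig(**sim)
        cfg = cls(simulate=sim, **d)
        if seed is not None:
            cfg.seed = seed
            if cfg.simulate is not None:
                cfg.simulate.seed = seed
        if out_dir is not None:
            cfg.out_dir = out_dir
        return cfg


@dataclass
class _Run:
    out: Path
    digests: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)

    def record(self, path: Path) -> None:
        rel = str(path.relative_to(self.out))
        self.digests[rel] = hashlib.sha256(path.read_bytes()).hexdigest()


def run_full(config: RunConfig) -> Manifest:
    """Execute every stage in dependency order and return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run = _Run(out=out)
    truth: Manifest | None = None

    def _stage(name):
        logger.info("stage %s", name)
        run.timings[name] = time.perf_counter()

    def _done(name):
        run.timings[name] = round(time.perf_counter() - run.timings[name], 3)

    # ------------------------------------------------------------------ data
    _stage("data")
    if config.simulate is not None:
        simcfg = config.simulate
        cm, truth = syn.simulate_atlas(simcfg)
        from .core_io import write_counts

        for p in write_counts(cm, out / "atlas").values():
            run.record(p)
        run.record(truth.to_json(out / "atlas" / "truth.json"))
        panels = syn.canonical_panel_sets()
    else:
        from .core_io import read_counts, read_gene_sets

        paths = config.input_paths
        for key in ("matrix", "features", "barcodes", "meta", "class_panels"):
            if key not in paths or not Path(paths[key]).exists():
                raise FileNotFoundError(f"input {key!r} missing: {paths.get(key)}")
        cm = read_counts(paths["matrix"], paths["features"], paths["barcodes"], paths["meta"])
        panels = read_gene_sets(paths["class_panels"])
    _done("data")

    # -------------------------------------------------------------------- qc
    _stage("qc")
    thr = pp.QCThresholds(
        max_mito_fraction=config.max_mito_fraction,
        min_genes_detected=config.min_genes_detected,
        scale_factor=config.scale_factor,
    )
    cm_qc, qc_report = pp.qc_filter(cm, thr)
    p = out / "qc_removed.tsv"
    qc_report.removed.to_csv(p, sep="\t")
    run.record(p)
    run.metrics["cells_in"] = qc_report.n_in
    run.metrics["cells_removed_qc"] = qc_report.n_removed
    nm = pp.normalize(cm_qc, thr)
    _done("qc")

    # --------------------------------------------------------------- cluster
    _stage("cluster")
    labels = pp.cluster_cells(
        nm, n_pcs=config.n_pcs, k=config.k_classes, seed=stage_seed(config.seed, "cluster")
    )
    annotation = pp.annotate_clusters(nm, labels, panels)
    run.metrics["n_clusters"] = labels.n_clusters
    run.metrics["cluster_classes"] = {str(k): v for k, v in annotation.cluster_class.items()}
    nm_ec, doublet_report = pp.select_ecs(
        nm, labels, annotation, panels, quantile=config.doublet_quantile
    )
    p = out / "doublets_flagged.tsv"
    doublet_report.flagged.to_csv(p, sep="\t")
    run.record(p)
    run.metrics["ec_cells"] = nm_ec.n_cells
    run.metrics["doublets_flagged"] = len(doublet_report.flagged)

    ec_labels = pp.cluster_cells(
        nm_ec, n_pcs=config.n_pcs, k=config.k_ec, seed=stage_seed(config.seed, "cluster_ec")
    )
    run.metrics["ec_subclusters_found"] = ec_labels.n_clusters
    if truth is not None:
        from sklearn.metrics import adjusted_rand_score

        bc_to_sub = dict(zip(
            [f"CELL{i:05d}" for i in range(len(truth.entries["ec_subcluster"]))],
            truth.entries["ec_subcluster"],
        ))
        true_sub = [bc_to_sub.get(b, "") for b in nm_ec.barcodes]
        usable = [i for i, s in enumerate(true_sub) if s]
        run.metrics["ec_subcluster_ari"] = float(
            adjusted_rand_score(
                [true_sub[i] for i in usable], [ec_labels.labels[i] for i in usable]
            )
        )
    _done("cluster")

    # --------------------------------------------------------------- markers
    _stage("markers")
    table = mk.find_all_markers(nm_ec, ec_labels, alpha=config.alpha)
    p = write_table(table.records, out / "ec_markers.tsv", index_label="row")
    run.record(p)
    top_sets = mk.top_k_markers(table, k=config.top_k, prefix="gbm/EC")
    p = write_gene_sets([m.genes for m in top_sets], out / "ec_top_markers.gmt")
    run.record(p)

    cell_classes = annotation.cell_classes(labels)
    ec_set = mk.ec_enriched_genes(nm, cell_classes, alpha=config.alpha)
    p = write_gene_sets([ec_set], out / "ec_enriched.gmt")
    run.record(p)
    run.metrics["n_ec_enriched"] = len(ec_set)

    split = mk.differential_ec_genes(
        nm_ec, nm_ec.meta_column("region"), ec_set, alpha=config.alpha
    )
    p = write_table(split.table, out / "ec_core_vs_periphery.tsv")
    run.record(p)
    run.metrics["n_up_in_core"] = len(split.up_in_core)
    run.metrics["n_down_in_core"] = len(split.down_in_core)
    _done("markers")

    # ----------------------------------------------------------- cross-atlas
    _stage("cross_atlas")
    sim = cross_atlas.jaccard_matrix([(m.cluster, m.genes) for m in top_sets])
    p = write_table(sim.to_frame(), out / "jaccard.tsv", index_label="cluster")
    run.record(p)
    emb = cross_atlas.classical_mds(sim, dims=config.mds_dims)
    p = write_table(emb.to_frame(), out / "mds.tsv", index_label="cluster")
    run.record(p)
    run.metrics["mds_clamped_mass"] = emb.clamped_mass
    _done("cross_atlas")

    # ------------------------------------------------------------ bbb modules
    _stage("bbb_modules")
    if config.simulate is not None:
        panel, bulk_truth = syn.simulate_bulk_organ_panel(simcfg)
        tbl, dis_truth = syn.simulate_disease_models(simcfg)
        hm, hom_truth = syn.simulate_homolog_map(simcfg)
        core = bbb.build_core_module(
            panel, min_cpm=config.min_cpm, min_fold=config.min_fold, alpha=config.alpha
        )
        dysf = bbb.build_dysfunction_module(tbl, min_models=config.min_models)
        run.metrics["core_module_raw"] = len(core.genes)
        run.metrics["core_module_matches_planted"] = list(core.genes) == list(
            bulk_truth.entries["brain_enriched"]
        )
        core = bbb.map_homologs(core, hm)
        dysf = bbb.map_homologs(dysf, hm)
        run.metrics["core_module_mapped"] = len(core.genes)
        run.metrics["dysfunction_module_mapped"] = len(dysf.genes)
        core = bbb.restrict_to_detected(core, nm_ec, min_cells=config.min_cells_detected)
        dysf = bbb.restrict_to_detected(dysf, nm_ec, min_cells=config.min_cells_detected)
        run.metrics["core_module_detected"] = len(core.genes)
        run.metrics["dysfunction_module_detected"] = len(dysf.genes)
        for mod, fname in ((core, "core_bbb_module.gmt"), (dysf, "bbb_dysfunction_module.gmt")):
            run.record(mod.to_gmt(out / fname))
        coexp = bbb.module_coexpression(nm_ec, core, dysf)
        p = write_table(coexp.correlation.values, out / "module_coexpression.tsv")
        run.record(p)
        run.metrics["coexpression"] = {
            "mean_within_core": coexp.mean_within_core,
            "mean_within_dysfunction": coexp.mean_within_dysfunction,
            "mean_cross": coexp.mean_cross,
        }
    _done("bbb_modules")

    # --------------------------------------------------------------- anatomic
    _stage("anatomic")
    if config.simulate is not None:
        sub_names = list(truth.entries["subcluster_markers"])
        region_for = dict(zip(sub_names, [
            "leading_edge", "microvascular_proliferation", "cellular_tumor",
            "infiltrating_tumor", "pseudopalisading_necrosis",
        ]))
        planted_sets = {s: truth.entries["subcluster_markers"][s][:20] for s in sub_names}
        region_panel, vascular_panel, region_truth = syn.simulate_anatomic_regions(
            simcfg, marker_sets=planted_sets, set_region=region_for
        )
        scores = an.microvascular_score(region_panel, vascular_panel)
        factors = np.array(
            [region_truth.entries["vascular_factor"][s] for s in region_panel.values.columns]
        )
        run.metrics["vascular_score_r"] = float(np.corrcoef(scores.to_numpy(), factors)[0, 1])
        normed = an.normalize_by_score(region_panel, scores)
        profile = an.region_enrichment_profile(normed, top_sets)
        p = write_table(profile.values, out / "region_enrichment.tsv", index_label="marker_set")
        run.record(p)
        # name each discovered set by the planted subcluster it overlaps most
        sub_truth = {s: set(g) for s, g in truth.entries["subcluster_markers"].items()}
        set_to_sub = {
            m.cluster: max(sub_truth, key=lambda s: len(sub_truth[s] & set(m.genes.genes)))
            for m in top_sets
        }
        run.metrics["region_argmax"] = {
            set_to_sub.get(str(i), str(i)): str(profile.values.loc[i].idxmax())
            for i in profile.values.index
        }
    _done("anatomic")

    manifest = Manifest(
        seed=config.seed,
        entries={
            "kind": "run",
            "config": {
                k: v
                for k, v in vars(config).items()
                if k not in ("simulate", "input_paths")
            },
            "digests": run.digests,
            "metrics": run.metrics,
            "wall_time_s": run.timings,
        },
    )
    run_path = manifest.to_json(out / "run_manifest.json")
    logger.info("run manifest written to %s", run_path)
    return manifest
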