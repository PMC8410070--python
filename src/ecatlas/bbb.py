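"""Core blood-brain-barrier and BBB-dysfunction gene modules.

The core module collects genes that behave like brain-EC-specific
transcripts in a multi-organ endothelial bulk panel, under three filters:

(a) abundance — mean brain-EC expression of at least ``min_cpm`` counts
    per million (inclusive at the boundary);
(b) specificity — more than ``min_fold``-fold higher in brain ECs than in
    each of kidney, lung, heart and liver ECs individually (strict), with
    a rank-sum p below ``alpha`` on the replicate values for each organ;
(c) endothelial origin — brain-EC expression no less than whole brain
    vasculature (inclusive), excluding mural-cell contamination.

The dysfunction module collects genes called "up" in at least
``min_models`` of 4 brain-disease models (stroke, multiple sclerosis,
traumatic brain injury, seizure).  Both constructions emit a per-gene
audit covering every gene considered, including rejected ones.  Modules
are then homolog-mapped (mouse → human) and restricted to genes detected
in the single-cell data set, with every drop recorded in a provenance
chain, before co-expression of the two modules is summarised over EC
cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import GeneSet, write_gene_sets
from .stats import CorrelationMatrix, correlation_matrix, rank_sum_test

__all__ = [
    "BulkPanel",
    "DiseaseDiffTable",
    "HomologMap",
    "ModuleDefinition",
    "build_core_module",
    "build_dysfunction_module",
    "map_homologs",
    "restrict_to_detected",
    "CoexpressionSummary",
    "module_coexpression",
]

ORGAN_GROUPS = ("kidney_EC", "lung_EC", "heart_EC", "liver_EC")
REQUIRED_GROUPS = ("brain_EC",) + ORGAN_GROUPS + ("brain_vasculature",)
DISEASE_MODELS = ("stroke", "multiple_sclerosis", "traumatic_brain_injury", "seizure")
CPM_TOTAL = 1_000_000.0


@dataclass
class BulkPanel:
    """Genes × samples CPM table with per-sample group labels."""

    values: pd.DataFrame  # genes × samples
    sample_groups: pd.Series  # sample -> group

    def __post_init__(self) -> None:
        self.sample_groups = self.sample_groups.reindex(self.values.columns)
        if self.sample_groups.isna().any():
            missing = list(self.values.columns[self.sample_groups.isna()])
            raise ValueError(f"samples without group labels: {missing}")
        sums = self.values.sum(axis=0)
        rel = np.abs(sums - CPM_TOTAL) / CPM_TOTAL
        if (rel > 1e-6).any():
            bad = list(sums.index[rel > 1e-6])[:3]
            raise ValueError(f"samples not closed to 1e6 CPM: {bad}")

    def group_samples(self, group: str) -> list[str]:
        return list(self.sample_groups.index[self.sample_groups == group])

    def group_values(self, gene: str, group: str) -> np.ndarray:
        return self.values.loc[gene, self.group_samples(group)].to_numpy(dtype=float)

    @classmethod
    def from_tsv(cls, values_path: str | Path, groups_path: str | Path) -> "BulkPanel":
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        groups = pd.read_csv(groups_path, sep="\t", index_col=0)["group"]
        return cls(values=values, sample_groups=groups)

    def to_tsv(self, values_path: str | Path, groups_path: str | Path) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="gene")
        self.sample_groups.rename("group").to_csv(groups_path, sep="\t", index_label="sample")


@dataclass
class DiseaseDiffTable:
    """Per-(gene, model) direction calls: up / down / ns, exactly 4 models."""

    calls: pd.DataFrame  # genes × DISEASE_MODELS with values in {up, down, ns}

    def __post_init__(self) -> None:
        if tuple(self.calls.columns) != DISEASE_MODELS:
            raise ValueError(f"expected model columns {DISEASE_MODELS}, got {tuple(self.calls.columns)}")
        bad = set(np.unique(self.calls.to_numpy())) - {"up", "down", "ns"}
        if bad:
            raise ValueError(f"invalid direction calls: {sorted(bad)}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DiseaseDiffTable":
        return cls(calls=pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path: str | Path) -> None:
        self.calls.to_csv(path, sep="\t", index_label="gene")


@dataclass
class HomologMap:
    """Source → target symbol map (mouse → human), one target per source.

    One-to-many rows are resolved by keeping the lexicographically
    smallest target; alternatives are retained for audit.
    """

    mapping: dict[str, str]
    alternatives: dict[str, list[str]] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs) -> "HomologMap":
        by_src: dict[str, list[str]] = {}
        for src, tgt in pairs:
            by_src.setdefault(src, []).append(tgt)
        mapping, alternatives = {}, {}
        for src, tgts in by_src.items():
            tgts = sorted(set(tgts))
            mapping[src] = tgts[0]
            if len(tgts) > 1:
                alternatives[src] = tgts[1:]
        return cls(mapping=mapping, alternatives=alternatives)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HomologMap":
        df = pd.read_csv(path, sep="\t")
        return cls.from_pairs(df.itertuples(index=False))

    def to_tsv(self, path: str | Path) -> None:
        rows = [(s, t) for s, t in sorted(self.mapping.items())]
        rows += [(s, a) for s, alts in sorted(self.alternatives.items()) for a in alts]
        pd.DataFrame(rows, columns=["source", "target"]).to_csv(path, sep="\t", index=False)


@dataclass
class ModuleDefinition:
    """Named gene module with a full per-gene audit and provenance chain."""

    name: str
    genes: tuple[str, ...]
    audit: dict[str, dict]  # every gene ever considered, included or not
    provenance: list[dict] = field(default_factory=list)

    def gene_set(self) -> GeneSet:
        return GeneSet(name=self.name, description="; ".join(
            f"{p['stage']}:{p['n_genes']}" for p in self.provenance
        ) or "module", genes=self.genes)

    def to_gmt(self, path: str | Path) -> Path:
        return write_gene_sets([self.gene_set()], path)


def build_core_module(
    panel: BulkPanel,
    min_cpm: float = 100.0,
    min_fold: float = 2.0,
    alpha: float = 0.05,
    name: str = "core_BBB",
) -> ModuleDefinition:
    """Apply the three brain-EC-enrichment criteria to every panel gene."""
    for group in REQUIRED_GROUPS:
        samples = panel.group_samples(group)
        if not samples:
            raise ValueError(f"panel lacks group {group!r}")
        if len(samples) < 2:
            raise ValueError(f"group {group!r} has <2 replicates; criterion (b) untestable")
    brain_cols = panel.group_samples("brain_EC")
    vasc_cols = panel.group_samples("brain_vasculature")
    brain_mean = panel.values[brain_cols].mean(axis=1)
    vasc_mean = panel.values[vasc_cols].mean(axis=1)
    organ_means = {g: panel.values[panel.group_samples(g)].mean(axis=1) for g in ORGAN_GROUPS}

    audit: dict[str, dict] = {}
    included: list[str] = []
    for gene in panel.values.index:
        rec: dict = {"criterion_a": bool(brain_mean[gene] >= min_cpm), "criterion_b": {}}
        b_pass = True
        for organ in ORGAN_GROUPS:
            om = organ_means[organ][gene]
            fold = float(brain_mean[gene] / om) if om > 0 else float("inf")
            res = rank_sum_test(
                panel.values.loc[gene, brain_cols].to_numpy(dtype=float),
                panel.values.loc[gene, panel.group_samples(organ)].to_numpy(dtype=float),
            )
            ok = (fold > min_fold) and (res.p_value < alpha)
            rec["criterion_b"][organ] = {"fold": fold, "p": res.p_value, "passed": ok}
            b_pass = b_pass and ok
        rec["criterion_c"] = bool(brain_mean[gene] >= vasc_mean[gene])
        rec["included"] = rec["criterion_a"] and b_pass and rec["criterion_c"]
        if not rec["included"]:
            failed = []
            if not rec["criterion_a"]:
                failed.append("a")
            failed += sorted(
                f"b:{o}" for o, r in rec["criterion_b"].items() if not r["passed"]
            )
            if not rec["criterion_c"]:
                failed.append("c")
            rec["failed"] = failed
        audit[gene] = rec
        if rec["included"]:
            included.append(gene)
    return ModuleDefinition(
        name=name,
        genes=tuple(included),
        audit=audit,
        provenance=[{"stage": "raw", "n_genes": len(included), "dropped": []}],
    )


def build_dysfunction_module(
    tbl: DiseaseDiffTable, min_models: int = 3, name: str = "BBB_dysfunction"
) -> ModuleDefinition:
    """Genes called up in at least ``min_models`` of the 4 disease models."""
    audit: dict[str, dict] = {}
    included: list[str] = []
    for gene, row in tbl.calls.iterrows():
        voters = [m for m in DISEASE_MODELS if row[m] == "up"]
        ok = len(voters) >= min_models
        audit[gene] = {"up_models": voters, "n_up": len(voters), "included": ok}
        if ok:
            included.append(gene)
    return ModuleDefinition(
        name=name,
        genes=tuple(included),
        audit=audit,
        provenance=[{"stage": "raw", "n_genes": len(included), "dropped": []}],
    )


def map_homologs(m: ModuleDefinition, hm: HomologMap) -> ModuleDefinition:
    """Rename module genes via the homolog map; unmapped genes are dropped
    into provenance, never silently discarded."""
    mapped, dropped = [], []
    for g in m.genes:
        if g in hm.mapping:
            mapped.append(hm.mapping[g])
        else:
            dropped.append(g)
    collisions = sorted({t for t in mapped if mapped.count(t) > 1})
    if collisions:
        raise ValueError(f"homolog map collapses multiple genes onto: {collisions}")
    audit = dict(m.audit)
    for src in m.genes:
        audit[src] = {**audit.get(src, {}), "homolog": hm.mapping.get(src)}
    return ModuleDefinition(
        name=m.name,
        genes=tuple(mapped),
        audit=audit,
        provenance=m.provenance
        + [{"stage": "homolog_mapped", "n_genes": len(mapped), "dropped": dropped}],
    )


def restrict_to_detected(m: ModuleDefinition, nm, min_cells: int = 1) -> ModuleDefinition:
    """Keep genes nonzero in at least ``min_cells`` cells of the data set."""
    gi = {g: i for i, g in enumerate(nm.gene_symbols)}
    values = np.asarray(nm.values)
    kept, dropped = [], []
    for g in m.genes:
        n_nonzero = int((values[gi[g], :] > 0).sum()) if g in gi else 0
        (kept if n_nonzero >= min_cells else dropped).append(g)
    return ModuleDefinition(
        name=m.name,
        genes=tuple(kept),
        audit=m.audit,
        provenance=m.provenance
        + [{"stage": "detected", "n_genes": len(kept), "dropped": dropped}],
    )


@dataclass
class CoexpressionSummary:
    correlation: CorrelationMatrix
    gene_order: list[str]  # average-linkage ordering for block display
    mean_within_core: float
    mean_within_dysfunction: float
    mean_cross: float


def module_coexpression(
    nm_ec, core: ModuleDefinition, dysf: ModuleDefinition, method: str = "pearson"
) -> CoexpressionSummary:
    """Correlation structure of the two modules over EC cells.

    Off-diagonal mean correlations are reported within each module and
    across them; genes are ordered by average-linkage clustering of 1 − r
    so anticorrelated blocks display stably.
    """
    union = list(dict.fromkeys(core.genes + dysf.genes))
    if len(union) < 2:
        raise ValueError("modules provide fewer than 2 distinct genes")
    cm = correlation_matrix(nm_ec, union, method=method)
    usable = set(cm.genes)
    core_genes = [g for g in core.genes if g in usable]
    dysf_genes = [g for g in dysf.genes if g in usable]
    for label, genes in ((core.name, core_genes), (dysf.name, dysf_genes)):
        if len(genes) < 2:
            raise ValueError(f"module {label!r} has fewer than 2 usable genes")
    r = cm.values

    def _mean_within(genes: list[str]) -> float:
        sub = r.loc[genes, genes].to_numpy()
        off = sub[~np.eye(len(genes), dtype=bool)]
        return float(off.mean())

    cross_pairs = r.loc[core_genes, [g for g in dysf_genes if g not in set(core_genes)]]
    mean_cross = (
        float(cross_pairs.to_numpy().mean()) if cross_pairs.size else _mean_within(core_genes)
    )
    order = _linkage_order(r)
    return CoexpressionSummary(
        correlation=cm,
        gene_order=order,
        mean_within_core=_mean_within(core_genes),
        mean_within_dysfunction=_mean_within(dysf_genes),
        mean_cross=mean_cross,
    )


def _linkage_order(r: pd.DataFrame) -> list[str]:
    from scipy.cluster.hierarchy import average, leaves_list
    from scipy.spatial.distance import squareform

    d = 1.0 - r.to_numpy()
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    leaves = leaves_list(average(squareform(d, checks=False)))
    return [r.index[i] for i in leaves]
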