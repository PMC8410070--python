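"""Per-cluster marker discovery and differential analysis of EC genes.

Each gene is tested cluster-vs-rest with the two-sided rank-sum test on
normalized expression, Bonferroni-corrected over the genes tested within
that comparison; markers are up-regulated only (two-sided p kept, a
direction filter applied).  Effect size is the natural-log fold-change of
pseudocounted expm1-means.  "Top k" ranks by ascending raw p, ties broken
by descending fold-change and then lexicographic symbol, so marker sets
are platform-independent and deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import GeneSet
from .preprocess import ClusterLabels, NormalizedMatrix
from .stats import rank_sum_matrix

__all__ = [
    "MarkerTable",
    "MarkerSet",
    "find_all_markers",
    "top_k_markers",
    "ec_enriched_genes",
    "differential_ec_genes",
    "DifferentialSplit",
]

PSEUDOCOUNT = 1.0


@dataclass
class MarkerTable:
    """Significant up-regulated (gene, cluster) records, sorted within cluster."""

    records: pd.DataFrame  # columns: gene, cluster, lfc, p_raw, p_adj, pct_in, pct_out, rank
    alpha: float
    min_lfc: float
    n_genes_tested: int

    def for_cluster(self, cluster) -> pd.DataFrame:
        return self.records[self.records["cluster"] == cluster]


@dataclass
class MarkerSet:
    cluster: str
    genes: GeneSet
    n_available: int  # significant genes the cluster had before truncation


def _group_vs_rest(
    values: np.ndarray, in_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-gene (lfc, p_raw, p_adj, pct_in, pct_out) for one comparison."""
    _, p_raw = rank_sum_matrix(values, in_mask)
    lin = np.expm1(values)
    mean_in = lin[:, in_mask].mean(axis=1)
    mean_out = lin[:, ~in_mask].mean(axis=1)
    lfc = np.log((mean_in + PSEUDOCOUNT) / (mean_out + PSEUDOCOUNT))
    p_adj = np.minimum(1.0, p_raw * values.shape[0])  # Bonferroni within the comparison
    pct_in = (values[:, in_mask] > 0).mean(axis=1)
    pct_out = (values[:, ~in_mask] > 0).mean(axis=1)
    return lfc, p_raw, p_adj, pct_in, pct_out


def _sorted_records(df: pd.DataFrame) -> pd.DataFrame:
    df = df.assign(_neg_lfc=-df["lfc"])
    df = df.sort_values(["cluster", "p_raw", "_neg_lfc", "gene"], kind="mergesort")
    df = df.drop(columns="_neg_lfc").reset_index(drop=True)
    df["rank"] = df.groupby("cluster").cumcount() + 1
    return df


def find_all_markers(
    nm: NormalizedMatrix,
    labels: ClusterLabels,
    alpha: float = 0.05,
    min_lfc: float = 0.0,
) -> MarkerTable:
    """Test every gene in every cluster against all other cells.

    A record is retained when the Bonferroni-adjusted p is below ``alpha``,
    the log fold-change exceeds ``min_lfc``, and the gene is up in the
    cluster.  Singleton clusters are skipped with a warning.
    """
    if labels.n_clusters < 2:
        raise ValueError("marker discovery needs at least 2 clusters")
    frames = []
    for c in range(labels.n_clusters):
        in_mask = labels.labels == c
        if in_mask.sum() < 2:
            warnings.warn(f"cluster {c} has fewer than 2 cells; skipped")
            continue
        lfc, p_raw, p_adj, pct_in, pct_out = _group_vs_rest(nm.values, in_mask)
        keep = (p_adj < alpha) & (lfc > min_lfc) & (lfc > 0)
        frames.append(
            pd.DataFrame(
                {
                    "gene": nm.gene_symbols[keep],
                    "cluster": c,
                    "lfc": lfc[keep],
                    "p_raw": p_raw[keep],
                    "p_adj": p_adj[keep],
                    "pct_in": pct_in[keep],
                    "pct_out": pct_out[keep],
                }
            )
        )
    records = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["gene", "cluster", "lfc", "p_raw", "p_adj", "pct_in", "pct_out"]
    )
    records = _sorted_records(records)
    return MarkerTable(records=records, alpha=alpha, min_lfc=min_lfc, n_genes_tested=nm.n_genes)


def top_k_markers(mt: MarkerTable, k: int = 50, prefix: str = "") -> list[MarkerSet]:
    """Top ``k`` markers per cluster by the table's deterministic ranking."""
    out = []
    for c in sorted(mt.records["cluster"].unique()):
        sub = mt.for_cluster(c)
        genes = tuple(sub["gene"].head(k))
        if not genes:
            continue
        name = f"{prefix}{c}"
        out.append(
            MarkerSet(
                cluster=name,
                genes=GeneSet(name=name, description=f"top {len(genes)} markers", genes=genes),
                n_available=len(sub),
            )
        )
    return out


def ec_enriched_genes(
    nm: NormalizedMatrix,
    cell_classes: np.ndarray,
    ec_class: str = "EC",
    alpha: float = 0.05,
) -> GeneSet:
    """Genes up in EC cells vs all non-EC cells at Bonferroni p < alpha.

    Same machinery as cluster marker discovery, with exactly two groups.
    """
    cell_classes = np.asarray(cell_classes)
    in_mask = cell_classes == ec_class
    if in_mask.sum() == 0:
        raise ValueError(f"no cells of class {ec_class!r}")
    if (~in_mask).sum() == 0:
        raise ValueError("no non-EC cells to compare against")
    lfc, p_raw, p_adj, _, _ = _group_vs_rest(nm.values, in_mask)
    keep = (p_adj < alpha) & (lfc > 0)
    order = np.lexsort((nm.gene_symbols[keep], -lfc[keep], p_raw[keep]))
    genes = tuple(nm.gene_symbols[keep][order])
    if not genes:
        raise ValueError("no EC-enriched genes found")
    return GeneSet(name="EC_enriched", description=f"up in {ec_class}, p_adj<{alpha}", genes=genes)


@dataclass
class DifferentialSplit:
    up_in_core: tuple[str, ...]
    down_in_core: tuple[str, ...]
    table: pd.DataFrame  # tested genes: lfc (core vs periphery), p_raw, p_adj


def differential_ec_genes(
    nm_ec: NormalizedMatrix,
    regions: np.ndarray,
    ec_enriched: GeneSet,
    alpha: float = 0.05,
) -> DifferentialSplit:
    """Core-vs-periphery split of the EC-enriched genes among EC cells.

    Only genes in ``ec_enriched`` are tested; Bonferroni multiplicity is
    the number of genes actually tested.  Significant genes are split by
    the sign of the core-vs-periphery fold-change.
    """
    regions = np.asarray(regions)
    core = regions == "core"
    periph = regions == "periphery"
    if core.sum() == 0 or periph.sum() == 0:
        raise ValueError("both core and periphery must be represented among EC cells")
    gi = nm_ec.gene_index()
    tested = [g for g in ec_enriched.genes if g in gi]
    if not tested:
        raise ValueError("no EC-enriched genes present in the EC matrix")
    sub = nm_ec.values[[gi[g] for g in tested], :][:, core | periph]
    in_mask = core[core | periph]
    _, p_raw = rank_sum_matrix(sub, in_mask)
    lin = np.expm1(sub)
    lfc = np.log(
        (lin[:, in_mask].mean(axis=1) + PSEUDOCOUNT)
        / (lin[:, ~in_mask].mean(axis=1) + PSEUDOCOUNT)
    )
    p_adj = np.minimum(1.0, p_raw * len(tested))
    table = pd.DataFrame(
        {"gene": tested, "lfc": lfc, "p_raw": p_raw, "p_adj": p_adj}
    ).set_index("gene")
    sig = table[table["p_adj"] < alpha].sort_values("p_raw", kind="mergesort")
    up = tuple(sig.index[sig["lfc"] > 0])
    down = tuple(sig.index[sig["lfc"] < 0])
    return DifferentialSplit(up_in_core=up, down_in_core=down, table=table)
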