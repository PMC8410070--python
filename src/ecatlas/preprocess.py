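"""QC filtering, normalization, clustering and cell-class annotation.

The QC rules follow the droplet scRNA-seq convention for CD31-enriched
brain tumour data: a cell is discarded when its mitochondrial count
fraction exceeds 10% or when fewer than 200 genes are detected — both
inequalities strict.  Remaining cells are depth-normalized to a common
scale factor (default 10,000) and natural-log transformed:

    value(g, c) = ln(1 + count(g, c) / total(c) × scale_factor)

Clustering is a pluggable stage with two built-ins (top principal
components followed by k-means, or a kNN-graph Leiden partition); its
contract is recovery of planted structure, not replication of any
particular published pipeline.  Cell classes are assigned per cluster by
mean expression of canonical marker panels (e.g. CLDN5/VWF/CD34 for
endothelial cells), and endothelial cells are selected in silico with an
explicit, reported heterotypic-doublet flagging rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import CountMatrix, GeneSet

__all__ = [
    "QCThresholds",
    "QCReport",
    "qc_filter",
    "NormalizedMatrix",
    "normalize",
    "ClusterLabels",
    "cluster_cells",
    "ClassAnnotation",
    "annotate_clusters",
    "DoubletReport",
    "select_ecs",
]


@dataclass
class QCThresholds:
    max_mito_fraction: float = 0.10
    min_genes_detected: int = 200
    scale_factor: float = 10_000.0

    def __post_init__(self) -> None:
        if not (0.0 < self.max_mito_fraction < 1.0):
            raise ValueError("max_mito_fraction must be in (0, 1)")
        if self.min_genes_detected < 1:
            raise ValueError("min_genes_detected must be ≥ 1")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")


@dataclass
class QCReport:
    removed: pd.DataFrame  # barcode-indexed, columns: reason, mito_fraction, detected_genes
    n_in: int
    n_out: int

    @property
    def n_removed(self) -> int:
        return len(self.removed)


def qc_filter(cm: CountMatrix, thr: QCThresholds | None = None) -> tuple[CountMatrix, QCReport]:
    """Drop cells with mito fraction > threshold or detected genes < minimum.

    Both inequalities are strict, so a cell at exactly 10% mitochondrial
    counts and exactly 200 detected genes is retained.  The gene panel is
    unchanged; removal reasons are reported per barcode.
    """
    thr = thr or QCThresholds()
    mito = cm.mito_fraction()
    detected = cm.detected_genes()
    fail_mito = mito > thr.max_mito_fraction
    fail_genes = detected < thr.min_genes_detected
    fail = fail_mito | fail_genes
    if fail.all():
        raise ValueError("QC removed every cell; thresholds are inappropriate for this data")
    reasons = []
    for fm, fg in zip(fail_mito[fail], fail_genes[fail]):
        reasons.append("+".join([r for r, f in (("mito", fm), ("min_genes", fg)) if f]))
    removed = pd.DataFrame(
        {
            "reason": reasons,
            "mito_fraction": mito[fail],
            "detected_genes": detected[fail],
        },
        index=pd.Index(cm.barcodes[fail], name="barcode"),
    )
    kept = cm.subset_cells(~fail)
    return kept, QCReport(removed=removed, n_in=cm.n_cells, n_out=kept.n_cells)


@dataclass
class NormalizedMatrix:
    """Genes × cells matrix of ln(1 + CP10K) expression values."""

    values: np.ndarray
    gene_symbols: np.ndarray
    barcodes: np.ndarray
    cell_meta: pd.DataFrame
    scale_factor: float = 10_000.0

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def meta_column(self, col: str) -> np.ndarray:
        return self.cell_meta.loc[list(self.barcodes), col].to_numpy()

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_symbols)}

    def subset_cells(self, mask_or_idx: np.ndarray) -> "NormalizedMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        bcs = self.barcodes[idx]
        return NormalizedMatrix(
            values=self.values[:, idx],
            gene_symbols=self.gene_symbols,
            barcodes=bcs,
            cell_meta=self.cell_meta.loc[list(bcs)],
            scale_factor=self.scale_factor,
        )


def normalize(cm: CountMatrix, thr: QCThresholds | None = None) -> NormalizedMatrix:
    """Depth-normalize to ``scale_factor`` counts per cell, then ln(1 + x)."""
    thr = thr or QCThresholds()
    totals = cm.total_counts().astype(float)
    if np.any(totals == 0):
        bad = cm.barcodes[totals == 0][0]
        raise ValueError(f"cell {bad!r} has zero total counts; run qc_filter first")
    dense = np.asarray(cm.values.todense(), dtype=float)
    values = np.log1p(dense / totals[None, :] * thr.scale_factor)
    return NormalizedMatrix(
        values=values,
        gene_symbols=cm.gene_symbols.copy(),
        barcodes=cm.barcodes.copy(),
        cell_meta=cm.cell_meta.loc[list(cm.barcodes)].copy(),
        scale_factor=thr.scale_factor,
    )


@dataclass
class ClusterLabels:
    labels: np.ndarray  # per-cell int, contiguous 0..n_clusters-1
    n_clusters: int
    method: str

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(self.labels)
        if not np.array_equal(uniq, np.arange(self.n_clusters)):
            raise ValueError("labels must be contiguous 0..n_clusters-1 with no empty cluster")


def _pca_scores(nm: NormalizedMatrix, n_pcs: int, seed: int) -> np.ndarray:
    from sklearn.decomposition import PCA

    x = nm.values.T  # cells × genes
    n_pcs = min(n_pcs, min(x.shape) - 1)
    pca = PCA(n_components=n_pcs, svd_solver="randomized", random_state=seed)
    return pca.fit_transform(x - x.mean(axis=0, keepdims=True))


def cluster_cells(
    nm: NormalizedMatrix,
    n_pcs: int = 20,
    k: int | None = None,
    resolution: float | None = None,
    seed: int = 0,
    n_neighbors: int = 15,
) -> ClusterLabels:
    """Cluster cells on top principal components of centered expression.

    Exactly one of ``k`` (k-means) or ``resolution`` (kNN-graph Leiden
    community detection) must be given.  Deterministic for a fixed seed.
    """
    if (k is None) == (resolution is None):
        raise ValueError("give exactly one of k (k-means) or resolution (graph)")
    if n_pcs >= min(nm.n_genes, nm.n_cells):
        raise ValueError("n_pcs must be smaller than both gene and cell counts")
    scores = _pca_scores(nm, n_pcs, seed)
    if k is not None:
        if k > nm.n_cells:
            raise ValueError(f"k={k} exceeds number of cells {nm.n_cells}")
        from sklearn.cluster import KMeans

        raw = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(scores)
        method = f"pca{scores.shape[1]}+kmeans{k}"
    else:
        raw = _leiden_labels(scores, resolution, seed, n_neighbors)
        method = f"pca{scores.shape[1]}+leiden(res={resolution})"
    labels = _relabel_contiguous(raw)
    return ClusterLabels(labels=labels, n_clusters=int(labels.max()) + 1, method=method)


def _leiden_labels(scores: np.ndarray, resolution: float, seed: int, n_neighbors: int) -> np.ndarray:
    import igraph as ig
    import leidenalg
    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=min(n_neighbors + 1, len(scores))).fit(scores)
    _, idx = nn.kneighbors(scores)
    edges = {(min(i, j), max(i, j)) for i, row in enumerate(idx) for j in row[1:]}
    g = ig.Graph(n=len(scores), edges=sorted(edges))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
    )
    return np.array(part.membership)


def _relabel_contiguous(raw: np.ndarray) -> np.ndarray:
    """Relabel clusters 0..K-1 in order of first appearance (drops empty ids)."""
    mapping: dict[int, int] = {}
    out = np.empty(len(raw), dtype=int)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


@dataclass
class ClassAnnotation:
    cluster_class: dict[int, str]
    scores: pd.DataFrame  # clusters × classes, mean panel expression
    ties: list[tuple[int, list[str]]] = field(default_factory=list)

    def cell_classes(self, labels: ClusterLabels) -> np.ndarray:
        return np.array([self.cluster_class[l] for l in labels.labels], dtype=object)


def _panel_cell_scores(nm: NormalizedMatrix, panel: GeneSet) -> np.ndarray:
    """Per-cell mean normalized expression over the panel's present genes."""
    gi = nm.gene_index()
    rows = [gi[g] for g in panel.genes if g in gi]
    missing = [g for g in panel.genes if g not in gi]
    if missing:
        warnings.warn(f"panel {panel.name!r}: {len(missing)} genes absent, skipped: {missing[:5]}")
    if not rows:
        raise ValueError(f"no genes of panel {panel.name!r} are present in the matrix")
    return nm.values[rows, :].mean(axis=0)


def annotate_clusters(
    nm: NormalizedMatrix, labels: ClusterLabels, class_panels: list[GeneSet]
) -> ClassAnnotation:
    """Assign each cluster the class whose marker panel scores highest.

    score(cluster, class) = mean over panel genes of the cluster-mean
    normalized expression.  Ties break by declared panel order and are
    recorded in the annotation.
    """
    per_cell = {p.name: _panel_cell_scores(nm, p) for p in class_panels}
    rows = []
    cluster_class: dict[int, str] = {}
    ties: list[tuple[int, list[str]]] = []
    for c in range(labels.n_clusters):
        mask = labels.labels == c
        row = {name: float(s[mask].mean()) for name, s in per_cell.items()}
        rows.append(row)
        best = max(row.values())
        winners = [p.name for p in class_panels if row[p.name] == best]
        if len(winners) > 1:
            ties.append((c, winners))
        cluster_class[c] = winners[0]
    scores = pd.DataFrame(rows, index=pd.RangeIndex(labels.n_clusters, name="cluster"))
    return ClassAnnotation(cluster_class=cluster_class, scores=scores, ties=ties)


@dataclass
class DoubletReport:
    flagged: pd.DataFrame  # barcode-indexed: offending panel, its score, threshold
    n_ec_cells: int
    quantile: float


def select_ecs(
    nm: NormalizedMatrix,
    labels: ClusterLabels,
    annotation: ClassAnnotation,
    class_panels: list[GeneSet],
    ec_class: str = "EC",
    quantile: float = 0.99,
    min_partner_fraction: float = 0.5,
) -> tuple[NormalizedMatrix, DoubletReport]:
    """Restrict to EC-cluster cells, flagging heterotypic doublets.

    A cell in an EC cluster is flagged when, for some non-EC panel, (i)
    its score exceeds the ``quantile`` of that panel's scores among
    EC-cluster cells, (ii) its EC score still exceeds the median EC score
    of the non-EC background (the cell carries both signatures at once),
    and (iii) the panel score amounts to at least ``min_partner_fraction``
    (default half, what a 50:50 heterotypic doublet carries) of that
    class's mean score in its own cells, which upper-tail noise in a
    singlet EC does not reach.  Flagged cells are removed; the rule
    and all removals are reported.
    """
    ec_clusters = [c for c, cl in annotation.cluster_class.items() if cl == ec_class]
    if not ec_clusters:
        raise ValueError(f"no cluster was annotated as {ec_class!r}")
    ec_mask = np.isin(labels.labels, ec_clusters)
    panels = {p.name: p for p in class_panels}
    if ec_class not in panels:
        raise ValueError(f"class panels lack an {ec_class!r} panel")
    ec_scores = _panel_cell_scores(nm, panels[ec_class])
    non_ec_bg = ec_scores[~ec_mask]
    ec_floor = float(np.median(non_ec_bg)) if non_ec_bg.size else -np.inf

    flagged_by: dict[str, tuple[str, float, float]] = {}
    for name, panel in panels.items():
        if name == ec_class:
            continue
        s = _panel_cell_scores(nm, panel)
        thr_val = float(np.quantile(s[ec_mask], quantile))
        own_clusters = [c for c, cl in annotation.cluster_class.items() if cl == name]
        if own_clusters:
            own_mean = float(s[np.isin(labels.labels, own_clusters)].mean())
            thr_val = max(thr_val, min_partner_fraction * own_mean)
        hit = ec_mask & (s > thr_val) & (ec_scores > ec_floor)
        for bc, sc in zip(nm.barcodes[hit], s[hit]):
            if bc not in flagged_by:
                flagged_by[bc] = (name, float(sc), thr_val)
    flagged = pd.DataFrame(
        [(bc, *info) for bc, info in flagged_by.items()],
        columns=["barcode", "panel", "score", "threshold"],
    ).set_index("barcode")
    keep = ec_mask & ~np.isin(nm.barcodes, list(flagged_by))
    report = DoubletReport(flagged=flagged, n_ec_cells=int(ec_mask.sum()), quantile=quantile)
    return nm.subset_cells(keep), report
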