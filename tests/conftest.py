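"""Shared fixtures: the default planted atlas and its recovery pipeline.

The default-synthetic recovery run (simulate → QC → normalize → cluster →
annotate → EC selection → EC subclustering → markers) is expensive enough
that it is computed once per session and shared by the unit and
acceptance tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from ecatlas import preprocess as pp
from ecatlas import markers as mk
from ecatlas.synthetic import SimConfig, canonical_panel_sets, simulate_atlas


@dataclass
class AtlasRun:
    cfg: SimConfig
    cm: object
    truth: object
    nm: object  # all QC-passed cells, normalized
    labels: object  # whole-atlas clusters
    annotation: object
    cell_classes: np.ndarray
    nm_ec: object  # EC cells after doublet removal
    doublet_report: object
    ec_labels: object  # EC subclusters
    marker_table: object
    top_sets: list

    def truth_percell(self, key: str) -> dict[str, str]:
        vals = self.truth.entries[key]
        return {f"CELL{i:05d}": v for i, v in enumerate(vals)}


def build_atlas_run(seed: int = 1, **overrides) -> AtlasRun:
    cfg = SimConfig(seed=seed, **overrides)
    cm, truth = simulate_atlas(cfg)
    kept, _ = pp.qc_filter(cm)
    nm = pp.normalize(kept)
    panels = canonical_panel_sets()
    labels = pp.cluster_cells(nm, n_pcs=20, k=12, seed=seed + 10)
    annotation = pp.annotate_clusters(nm, labels, panels)
    nm_ec, doublet_report = pp.select_ecs(nm, labels, annotation, panels)
    ec_labels = pp.cluster_cells(nm_ec, n_pcs=20, k=cfg.n_ec_subclusters, seed=seed + 11)
    marker_table = mk.find_all_markers(nm_ec, ec_labels)
    top_sets = mk.top_k_markers(marker_table, k=50, prefix="gbm/EC")
    return AtlasRun(
        cfg=cfg,
        cm=cm,
        truth=truth,
        nm=nm,
        labels=labels,
        annotation=annotation,
        cell_classes=annotation.cell_classes(labels),
        nm_ec=nm_ec,
        doublet_report=doublet_report,
        ec_labels=ec_labels,
        marker_table=marker_table,
        top_sets=top_sets,
    )


@pytest.fixture(scope="session")
def atlas_run() -> AtlasRun:
    """Default study conditions: 3,000 cells × 2,000 genes, seed 1."""
    return build_atlas_run(seed=1)


@pytest.fixture(scope="session")
def match_cluster_to_subcluster(atlas_run):
    """Map each recovered EC subcluster id to its majority planted subcluster."""
    from collections import Counter

    bc2sub = atlas_run.truth_percell("ec_subcluster")
    tsub = np.array([bc2sub.get(b, "") for b in atlas_run.nm_ec.barcodes])

    def _match(cluster_id: int) -> str:
        members = tsub[atlas_run.ec_labels.labels == cluster_id]
        members = members[members != ""]
        return Counter(members).most_common(1)[0][0]

    return _match
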