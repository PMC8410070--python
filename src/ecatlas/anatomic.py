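"""Anatomic-region mapping of EC marker sets in bulk transcriptomes.

Bulk profiles of named tumour anatomic regions (leading edge,
infiltrating tumour, cellular tumour, microvascular proliferation,
pseudopalisading necrosis) differ hugely in vascular abundance, so raw
marker expression mostly measures vessel density.  Each sample is
therefore assigned a microvascular score — the arithmetic mean of its
linear-scale expression over a vascular-enriched gene panel — and all
expression is divided by that score before marker sets are profiled per
region.  The whole pipeline is invariant to rescaling any sample's
column, because the score scales with it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import GeneSet

__all__ = [
    "ANATOMIC_REGIONS",
    "RegionPanel",
    "microvascular_score",
    "normalize_by_score",
    "EnrichmentMatrix",
    "region_enrichment_profile",
]

ANATOMIC_REGIONS = (
    "leading_edge",
    "infiltrating_tumor",
    "cellular_tumor",
    "microvascular_proliferation",
    "pseudopalisading_necrosis",
)


@dataclass
class RegionPanel:
    """Genes × samples nonnegative expression with a region label per sample."""

    values: pd.DataFrame
    sample_regions: pd.Series  # sample -> region

    def __post_init__(self) -> None:
        self.sample_regions = self.sample_regions.reindex(self.values.columns)
        if self.sample_regions.isna().any():
            missing = list(self.values.columns[self.sample_regions.isna()])
            raise ValueError(f"samples without region labels: {missing}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")

    @property
    def regions(self) -> list[str]:
        return list(dict.fromkeys(self.sample_regions))

    def region_samples(self, region: str) -> list[str]:
        return list(self.sample_regions.index[self.sample_regions == region])

    @classmethod
    def from_tsv(cls, values_path, regions_path) -> "RegionPanel":
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        regions = pd.read_csv(regions_path, sep="\t", index_col=0)["region"]
        return cls(values=values, sample_regions=regions)

    def to_tsv(self, values_path, regions_path) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="gene")
        self.sample_regions.rename("region").to_csv(regions_path, sep="\t", index_label="sample")


def microvascular_score(
    panel: RegionPanel,
    vascular_panel: GeneSet,
    input_log2: bool = False,
    mean: str = "arithmetic",
) -> pd.Series:
    """Per-sample vascular-abundance estimate from a vascular gene panel.

    The score is the arithmetic (or geometric) mean of the sample's
    linear-scale expression over the panel genes.  Log-scale input must be
    declared explicitly with ``input_log2``; it is never auto-detected.
    """
    present = [g for g in vascular_panel.genes if g in panel.values.index]
    missing = [g for g in vascular_panel.genes if g not in panel.values.index]
    if missing:
        warnings.warn(f"vascular panel: {len(missing)} genes absent, skipped: {missing[:5]}")
    if not present:
        raise ValueError("no vascular-panel gene is present in the region panel")
    sub = panel.values.loc[present]
    if input_log2:
        sub = np.power(2.0, sub) - 1.0
    if mean == "arithmetic":
        scores = sub.mean(axis=0)
    elif mean == "geometric":
        scores = np.exp(np.log(sub + 1e-12).mean(axis=0))
    else:
        raise ValueError(f"unknown mean {mean!r}")
    zero = scores[scores <= 0]
    if len(zero):
        raise ValueError(f"zero microvascular score for samples: {list(zero.index)}")
    return scores.rename("microvascular_score")


def normalize_by_score(panel: RegionPanel, scores: pd.Series) -> RegionPanel:
    """Divide each sample's column by its microvascular score."""
    if set(scores.index) != set(panel.values.columns):
        raise ValueError("scores are not aligned to the panel's samples")
    scores = scores.reindex(panel.values.columns)
    if (scores <= 0).any():
        raise ValueError("scores must be strictly positive")
    return RegionPanel(
        values=panel.values / scores, sample_regions=panel.sample_regions.copy()
    )


@dataclass
class EnrichmentMatrix:
    """Marker-set × region mean normalized expression."""

    values: pd.DataFrame  # sets × regions
    z_scaled: bool
    constant_rows: list[str]  # rows where z-scaling was undefined (reported as zeros)


def region_enrichment_profile(
    panel_norm: RegionPanel, marker_sets, z_scale: bool = False
) -> EnrichmentMatrix:
    """Mean expression of each marker set in each region.

    cell(set, region) = mean over the set's present genes of the mean
    normalized expression across that region's samples.  Optional per-row
    z-scaling for display; rows constant across regions are reported as
    zeros and flagged.
    """
    regions = panel_norm.regions
    rows, names, constant = [], [], []
    for ms in marker_sets:
        genes = getattr(ms, "genes", ms)
        genes = getattr(genes, "genes", genes)
        name = getattr(ms, "cluster", None) or getattr(ms, "name", None) or str(len(names))
        present = [g for g in genes if g in panel_norm.values.index]
        if not present:
            raise ValueError(f"marker set {name!r} has no genes present in the panel")
        sub = panel_norm.values.loc[present]
        row = [float(sub[panel_norm.region_samples(r)].mean(axis=1).mean()) for r in regions]
        rows.append(row)
        names.append(name)
    df = pd.DataFrame(rows, index=names, columns=regions)
    if z_scale:
        mu = df.mean(axis=1)
        sd = df.std(axis=1, ddof=0)
        constant = list(df.index[sd == 0])
        sd = sd.replace(0.0, 1.0)
        df = df.sub(mu, axis=0).div(sd, axis=0)
        df.loc[constant] = 0.0
    return EnrichmentMatrix(values=df, z_scaled=z_scale, constant_rows=constant)
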