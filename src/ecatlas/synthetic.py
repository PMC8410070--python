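"""Synthetic inputs with planted, manifest-recorded structure.

Every pipeline input can be generated here at desk scale with known
ground truth, emulating a CD31-enriched tumour/periphery single-cell
experiment and its companion bulk resources:

* a droplet-style count matrix (negative-binomial counts, log-normal
  gene base means and library sizes) with planted cell classes, five EC
  subclusters, per-subcluster marker programs, core-vs-periphery
  differential genes, mitochondrial fractions, QC-failing cells and
  heterotypic doublets;
* a multi-organ EC bulk CPM panel whose planted brain-enriched genes
  satisfy the three core-module criteria by construction, plus decoys
  violating exactly one criterion each;
* an up/down differential table over four brain-disease models;
* a region-labelled bulk panel with planted vascular-abundance factors
  confounding the anatomic signal;
* a mouse→human homolog map with a configurable drop set.

Everything is a pure function of (config, seed); the returned manifest
suffices to recompute every planted property.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .anatomic import ANATOMIC_REGIONS, RegionPanel
from .bbb import CPM_TOTAL, DISEASE_MODELS, BulkPanel, DiseaseDiffTable, HomologMap
from .core_io import CountMatrix, GeneSet, Manifest
from .preprocess import NormalizedMatrix

__all__ = [
    "SimConfig",
    "ConfigError",
    "simulate_atlas",
    "simulate_bulk_organ_panel",
    "simulate_disease_models",
    "simulate_anatomic_regions",
    "simulate_homolog_map",
    "simulate_coexpressed_modules",
    "CANONICAL_PANELS",
]


class ConfigError(ValueError):
    """An infeasible or inconsistent simulation configuration."""


# canonical cell-class marker panels; the EC panel genes live inside the
# planted EC program, the others inside their class marker programs
CANONICAL_PANELS: dict[str, tuple[str, ...]] = {
    "EC": ("CLDN5", "VWF", "CD34"),
    "macrophage": ("APOC1", "CD163", "F13A1"),
    "microglia": ("CX3CR1", "P2RY12", "P2RY13"),
    "T_cell": ("CD3D", "CD3E", "GZMK"),
    "mural": ("RGS5", "PDGFRB", "NOTCH3"),
}

MITO_GENES = (
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6", "MT-CO3",
    "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6", "MT-CYB",
)

EC_SUBCLUSTER_NAMES = ("Pe1", "Co1", "Co2", "Pe2", "Co3")
#: probability that a cell of each EC subcluster originates from the tumour core
EC_SUBCLUSTER_CORE_PROB = {"Pe1": 0.1, "Co1": 0.9, "Co2": 0.9, "Pe2": 0.1, "Co3": 0.9}


def _default_proportions() -> dict[str, float]:
    return {"EC": 0.55, "macrophage": 0.15, "microglia": 0.10, "T_cell": 0.10, "mural": 0.10}


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with desk-scale defaults."""

    seed: int = 1
    n_cells: int = 3000
    n_genes: int = 2000
    cell_class_proportions: dict[str, float] = field(default_factory=_default_proportions)
    n_ec_subclusters: int = 5
    markers_per_cluster: int = 50
    marker_lfc: float = 2.0  # natural-log up-shift of a marker in its cluster
    nb_dispersion: float = 0.4  # NB variance = mu + dispersion * mu^2
    library_size_mean: float = 5000.0
    library_size_sigma: float = 0.25  # log-normal sigma of library-size factors
    mito_fraction_range: tuple[float, float] = (0.01, 0.06)
    frac_qc_fail: float = 0.05
    frac_doublets: float = 0.005
    patients: int = 4
    # EC program: genes up in all EC cells (contains the canonical EC panel)
    ec_program_size: int = 150
    ec_program_lfc: float = 1.5
    #: multiplier applied to a class's marker genes in every other class,
    #: making markers class-specific the way canonical markers are in tissue
    offclass_suppression: float = 0.05
    # core-vs-periphery differential genes, planted inside the EC program
    n_core_up: int = 40
    n_core_down: int = 20
    region_lfc: float = 1.0
    patient_shift_sigma: float = 0.05  # mild per-patient per-gene log-normal shift
    # BBB modules planted in the atlas (shared latent "barrier state" factor)
    n_core_module_atlas: int = 147
    n_dysfunction_atlas: int = 128
    coexpression_sigma: float = 0.3
    doublet_library_boost: float = 1.8
    qc_fail_mito_range: tuple[float, float] = (0.20, 0.35)
    qc_fail_library: tuple[int, int] = (50, 150)
    # bulk organ panel
    bulk_replicates: int = 5
    n_core_module_bulk: int = 162
    n_decoys_per_type: int = 5
    n_bulk_background: int = 300
    bulk_noise_sigma: float = 0.05
    # disease models
    n_dysfunction_bulk: int = 136
    n_disease_background: int = 60
    include_pattern_sweep: bool = False
    # homolog map
    homolog_drop_core: int = 7
    homolog_drop_dysfunction: int = 5
    # anatomic region panel
    region_samples_per_region: int = 3
    vascular_panel_size: int = 20
    region_signal_weight: float = 5.0
    region_background_weight: float = 1.0
    vascular_confound_factor: float = 3.0
    region_noise_sigma: float = 0.05

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        tot = sum(self.cell_class_proportions.values())
        if abs(tot - 1.0) > 1e-9:
            raise ConfigError(f"cell_class_proportions sum to {tot}, not 1")
        if self.n_ec_subclusters < 2:
            raise ConfigError("n_ec_subclusters must be ≥ 2")
        if "EC" not in self.cell_class_proportions:
            raise ConfigError("cell_class_proportions must include 'EC'")
        lo, hi = self.mito_fraction_range
        if not (0 <= lo <= hi < 1):
            raise ConfigError("mito_fraction_range must satisfy 0 ≤ lo ≤ hi < 1")
        n_classes = len(self.cell_class_proportions)
        demand = (
            self.ec_program_size
            + self.markers_per_cluster * (n_classes - 1)
            + self.markers_per_cluster * self.n_ec_subclusters
            + self.n_core_module_atlas
            + self.n_dysfunction_atlas
            + len(MITO_GENES)
        )
        if demand > self.n_genes:
            raise ConfigError(
                f"planted structure needs {demand} genes but n_genes={self.n_genes}"
            )
        if self.n_core_up + self.n_core_down > self.ec_program_size:
            raise ConfigError("core-up/core-down demand exceeds the EC program size")
        if not (0 <= self.frac_qc_fail < 1 and 0 <= self.frac_doublets < 1):
            raise ConfigError("fractions must lie in [0, 1)")

    # -- YAML round-trip ----------------------------------------------------
    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        path.write_text(yaml.safe_dump(d, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("mito_fraction_range", "qc_fail_mito_range", "qc_fail_library"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


# ---------------------------------------------------------------------------
# gene universe
# ---------------------------------------------------------------------------

@dataclass
class _GeneRoles:
    symbols: list[str]
    class_markers: dict[str, list[str]]  # class -> marker genes (EC -> program)
    subcluster_markers: dict[str, list[str]]
    core_up: list[str]
    core_down: list[str]
    bbb_core: list[str]
    bbb_dysfunction: list[str]
    mito: list[str]


def _build_gene_universe(cfg: SimConfig) -> _GeneRoles:
    classes = list(cfg.cell_class_proportions)
    symbols: list[str] = []

    def _claim(n: int, stem: str, seeds: tuple[str, ...] = ()) -> list[str]:
        names = list(seeds) + [f"{stem}{i:04d}" for i in range(1, n - len(seeds) + 1)]
        symbols.extend(names)
        return names

    class_markers: dict[str, list[str]] = {}
    for cl in classes:
        seeds = CANONICAL_PANELS.get(cl, ())
        size = cfg.ec_program_size if cl == "EC" else cfg.markers_per_cluster
        class_markers[cl] = _claim(size, f"{cl.upper()[:4]}M", seeds)
    sub_names = list(EC_SUBCLUSTER_NAMES[: cfg.n_ec_subclusters])
    if cfg.n_ec_subclusters > len(EC_SUBCLUSTER_NAMES):
        sub_names += [f"EC{j}" for j in range(len(EC_SUBCLUSTER_NAMES), cfg.n_ec_subclusters)]
    subcluster_markers = {
        s: _claim(cfg.markers_per_cluster, f"{s.upper()}M") for s in sub_names
    }
    bbb_core = _claim(cfg.n_core_module_atlas, "CORE")
    bbb_dysf = _claim(cfg.n_dysfunction_atlas, "DYSF")
    mito = list(MITO_GENES)
    symbols.extend(mito)
    n_background = cfg.n_genes - len(symbols)
    _claim(n_background, "BG")
    ec_prog = class_markers["EC"]
    core_up = ec_prog[3 : 3 + cfg.n_core_up]  # skip the canonical panel genes
    core_down = ec_prog[3 + cfg.n_core_up : 3 + cfg.n_core_up + cfg.n_core_down]
    return _GeneRoles(
        symbols=symbols,
        class_markers=class_markers,
        subcluster_markers=subcluster_markers,
        core_up=core_up,
        core_down=core_down,
        bbb_core=bbb_core,
        bbb_dysfunction=bbb_dysf,
        mito=mito,
    )


# ---------------------------------------------------------------------------
# single-cell atlas
# ---------------------------------------------------------------------------

def _exact_count(frac: float, n: int) -> int:
    return int(round(frac * n))


def simulate_atlas(cfg: SimConfig) -> tuple[CountMatrix, Manifest]:
    """Generate the planted single-cell atlas and its truth manifest.

    Counts are negative binomial around per-cell expected expression:
    log-normal gene base weights, multiplicative class / EC-subcluster /
    region marker effects, mild per-patient shifts, a latent
    barrier-state factor coupling the planted BBB modules (positively
    within, negatively across), per-cell mitochondrial weight tuned to a
    target fraction, and log-normal library sizes.  QC-fail cells get
    either a high mitochondrial target or a tiny library; doublets
    average an EC profile with another class's profile at boosted
    library size.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    roles = _build_gene_universe(cfg)
    g_index = {g: i for i, g in enumerate(roles.symbols)}
    n_genes, n_cells = cfg.n_genes, cfg.n_cells
    classes = list(cfg.cell_class_proportions)
    sub_names = list(roles.subcluster_markers)

    # --- cell composition (exact planting, then shuffled) ---
    counts = {cl: int(np.floor(p * n_cells)) for cl, p in cfg.cell_class_proportions.items()}
    short = n_cells - sum(counts.values())
    for cl in sorted(classes, key=lambda c: -cfg.cell_class_proportions[c])[:short]:
        counts[cl] += 1
    cell_class = np.array(
        [cl for cl in classes for _ in range(counts[cl])], dtype=object
    )
    rng.shuffle(cell_class)
    ec_mask = cell_class == "EC"
    subcluster = np.array([None] * n_cells, dtype=object)
    subcluster[ec_mask] = rng.choice(sub_names, size=int(ec_mask.sum()))
    region = np.empty(n_cells, dtype=object)
    for i in range(n_cells):
        if ec_mask[i]:
            p_core = EC_SUBCLUSTER_CORE_PROB.get(subcluster[i], 0.5)
        else:
            p_core = 0.5
        region[i] = "core" if rng.random() < p_core else "periphery"
    patient = np.array([f"P{rng.integers(1, cfg.patients + 1)}" for _ in range(n_cells)])

    # --- QC failures and doublets (disjoint, exact counts) ---
    n_fail = _exact_count(cfg.frac_qc_fail, n_cells)
    n_doub = _exact_count(cfg.frac_doublets, n_cells)
    special = rng.choice(n_cells, size=n_fail + n_doub, replace=False)
    fail_idx = np.sort(special[:n_fail])
    doub_idx = np.sort(special[n_fail:])
    fail_reason = {
        int(i): ("mito" if k < (n_fail + 1) // 2 else "low_genes")
        for k, i in enumerate(fail_idx)
    }
    non_ec_classes = [c for c in classes if c != "EC"]
    doublet_partner = {
        int(i): (rng.choice(sub_names), rng.choice(non_ec_classes)) for i in doub_idx
    }

    # --- base weights and multiplier programs ---
    base_w = rng.lognormal(mean=0.0, sigma=1.2, size=n_genes)
    mito_rows = np.array([g_index[g] for g in roles.mito])
    base_w[mito_rows] = rng.lognormal(mean=0.0, sigma=0.3, size=len(mito_rows))

    boost = np.exp(cfg.marker_lfc)
    class_mult = {cl: np.ones(n_genes) for cl in classes}
    for cl, genes in roles.class_markers.items():
        rows = [g_index[g] for g in genes]
        lfc = cfg.ec_program_lfc if cl == "EC" else cfg.marker_lfc
        for cl2 in classes:  # markers are class-specific: silenced elsewhere
            class_mult[cl2][rows] = np.exp(lfc) if cl2 == cl else cfg.offclass_suppression
    sub_mult = {s: np.ones(n_genes) for s in sub_names}
    all_sub_rows = [g_index[g] for genes in roles.subcluster_markers.values() for g in genes]
    for cl in classes:  # EC-subcluster markers are endothelial genes
        if cl != "EC":
            class_mult[cl][all_sub_rows] = cfg.offclass_suppression
    for s, genes in roles.subcluster_markers.items():
        sub_mult[s][[g_index[g] for g in genes]] = boost
    core_up_rows = [g_index[g] for g in roles.core_up]
    core_down_rows = [g_index[g] for g in roles.core_down]
    patient_shift = {
        f"P{p}": rng.lognormal(mean=0.0, sigma=cfg.patient_shift_sigma, size=n_genes)
        for p in range(1, cfg.patients + 1)
    }
    core_rows = np.array([g_index[g] for g in roles.bbb_core])
    dysf_rows = np.array([g_index[g] for g in roles.bbb_dysfunction])
    barrier_state = rng.normal(size=n_cells)  # latent factor shared by all cells

    def _profile(cl: str, sub, reg: str, pat: str) -> np.ndarray:
        w = base_w * class_mult[cl] * patient_shift[pat]
        if cl == "EC":
            if sub is not None:
                w = w * sub_mult[sub]
            if reg == "core":
                w = w.copy()
                w[core_up_rows] *= np.exp(cfg.region_lfc)
            else:
                w = w.copy()
                w[core_down_rows] *= np.exp(cfg.region_lfc)
        return w

    weights = np.empty((n_genes, n_cells))
    for i in range(n_cells):
        if int(i) in doublet_partner:
            s, other = doublet_partner[int(i)]
            wa = _profile("EC", s, region[i], patient[i])
            wb = _profile(other, None, region[i], patient[i])
            w = 0.5 * (wa / wa.sum() + wb / wb.sum())
        else:
            w = _profile(cell_class[i], subcluster[i], region[i], patient[i])
        weights[:, i] = w

    # latent barrier-state coupling: core module up, dysfunction down together
    factor = np.exp(cfg.coexpression_sigma * barrier_state)
    weights[core_rows, :] *= factor[None, :]
    weights[dysf_rows, :] /= factor[None, :]

    # per-cell mitochondrial target fraction
    mito_target = rng.uniform(*cfg.mito_fraction_range, size=n_cells)
    for i, reason in fail_reason.items():
        if reason == "mito":
            mito_target[i] = rng.uniform(*cfg.qc_fail_mito_range)
    non_mito_sum = weights.sum(axis=0) - weights[mito_rows, :].sum(axis=0)
    cur_mito = weights[mito_rows, :].sum(axis=0)
    scale = mito_target / (1.0 - mito_target) * non_mito_sum / cur_mito
    weights[mito_rows, :] *= scale[None, :]
    weights /= weights.sum(axis=0, keepdims=True)

    # library sizes
    lib = cfg.library_size_mean * rng.lognormal(
        mean=-cfg.library_size_sigma**2 / 2, sigma=cfg.library_size_sigma, size=n_cells
    )
    for i in doublet_partner:
        lib[i] *= cfg.doublet_library_boost
    for i, reason in fail_reason.items():
        if reason == "low_genes":
            lib[i] = rng.integers(*cfg.qc_fail_library)

    mu = weights * lib[None, :]
    r = 1.0 / cfg.nb_dispersion
    counts_mat = rng.negative_binomial(n=r, p=r / (r + mu))

    barcodes = np.array([f"CELL{i:05d}" for i in range(n_cells)], dtype=object)
    meta = pd.DataFrame(
        {"patient": patient, "region": region.astype(str)},
        index=pd.Index(barcodes, name="barcode"),
    )
    cm = CountMatrix(
        values=sp.csr_matrix(counts_mat),
        gene_symbols=np.array(roles.symbols, dtype=object),
        barcodes=barcodes,
        cell_meta=meta,
    )

    ec_enriched_truth = roles.class_markers["EC"] + [
        g for genes in roles.subcluster_markers.values() for g in genes
    ]
    manifest = Manifest(
        seed=cfg.seed,
        entries={
            "kind": "atlas",
            "cell_class": list(cell_class),
            "ec_subcluster": [s if s is not None else "" for s in subcluster],
            "region": list(map(str, region)),
            "patient": list(patient),
            "qc_fail": {str(barcodes[i]): reason for i, reason in fail_reason.items()},
            "doublets": {
                str(barcodes[i]): {"ec_subcluster": str(s), "partner_class": str(o)}
                for i, (s, o) in doublet_partner.items()
            },
            "canonical_panels": {k: list(v) for k, v in CANONICAL_PANELS.items()},
            "class_markers": roles.class_markers,
            "subcluster_markers": roles.subcluster_markers,
            "ec_program": roles.class_markers["EC"],
            "ec_enriched_truth": ec_enriched_truth,
            "core_up": roles.core_up,
            "core_down": roles.core_down,
            "bbb_core_atlas": roles.bbb_core,
            "bbb_dysfunction_atlas": roles.bbb_dysfunction,
        },
    )
    return cm, manifest


def canonical_panel_sets() -> list[GeneSet]:
    """The canonical cell-class marker panels as GeneSets."""
    return [
        GeneSet(name=cl, description="canonical class markers", genes=genes)
        for cl, genes in CANONICAL_PANELS.items()
    ]


# ---------------------------------------------------------------------------
# bulk organ panel (core-module construction input)
# ---------------------------------------------------------------------------

def _mouse_core_genes(cfg: SimConfig) -> list[str]:
    return [f"Core{i:04d}" for i in range(1, cfg.n_core_module_bulk + 1)]


def _mouse_dysf_genes(cfg: SimConfig) -> list[str]:
    return [f"Dysf{i:04d}" for i in range(1, cfg.n_dysfunction_bulk + 1)]


def simulate_bulk_organ_panel(cfg: SimConfig) -> tuple[BulkPanel, Manifest]:
    """Multi-organ EC CPM panel with planted brain-enriched genes and decoys.

    Planted genes pass all three core-module criteria by construction;
    each decoy family violates exactly one criterion: ``below_cpm`` fails
    the abundance floor, ``subfold`` exceeds 2-fold in only 3 of 4 organs
    (kidney is the failing one), ``vasc_exceeds`` is outexpressed by whole
    brain vasculature.
    """
    if cfg.bulk_replicates < 2:
        raise ConfigError("bulk_replicates must be ≥ 2 (criterion (b) needs replicates)")
    rng = np.random.default_rng(cfg.seed + 101)
    planted = _mouse_core_genes(cfg)
    decoys = {
        "below_cpm": [f"DecoyCpm{i:02d}" for i in range(1, cfg.n_decoys_per_type + 1)],
        "subfold": [f"DecoyFold{i:02d}" for i in range(1, cfg.n_decoys_per_type + 1)],
        "vasc_exceeds": [f"DecoyVasc{i:02d}" for i in range(1, cfg.n_decoys_per_type + 1)],
    }
    background = [f"Bulkbg{i:04d}" for i in range(1, cfg.n_bulk_background + 1)]
    genes = planted + [g for d in decoys.values() for g in d] + background

    groups = list(("brain_EC", "kidney_EC", "lung_EC", "heart_EC", "liver_EC", "brain_vasculature"))
    mean = pd.DataFrame(0.0, index=genes, columns=groups)
    brain_base = rng.uniform(150.0, 1000.0, size=len(planted))
    mean.loc[planted, "brain_EC"] = brain_base
    for organ in ("kidney_EC", "lung_EC", "heart_EC", "liver_EC"):
        mean.loc[planted, organ] = brain_base / 10.0
    mean.loc[planted, "brain_vasculature"] = brain_base * 0.5

    mean.loc[decoys["below_cpm"], :] = 5.0
    mean.loc[decoys["below_cpm"], "brain_EC"] = 50.0  # fails (a): below 100 CPM
    mean.loc[decoys["below_cpm"], "brain_vasculature"] = 25.0

    mean.loc[decoys["subfold"], "brain_EC"] = 400.0
    mean.loc[decoys["subfold"], ["lung_EC", "heart_EC", "liver_EC"]] = 40.0
    mean.loc[decoys["subfold"], "kidney_EC"] = 400.0 / 1.5  # fails (b) in kidney only
    mean.loc[decoys["subfold"], "brain_vasculature"] = 200.0

    mean.loc[decoys["vasc_exceeds"], "brain_EC"] = 400.0
    mean.loc[decoys["vasc_exceeds"], ["kidney_EC", "lung_EC", "heart_EC", "liver_EC"]] = 40.0
    mean.loc[decoys["vasc_exceeds"], "brain_vasculature"] = 800.0  # fails (c)

    # background genes are organ-nonspecific: one level per gene, mild
    # per-group wobble kept well below the 2-fold specificity bar
    bg_level = rng.lognormal(mean=np.log(30.0), sigma=1.0, size=len(background))
    bg_wobble = rng.lognormal(mean=0.0, sigma=0.2, size=(len(background), len(groups)))
    mean.loc[background, :] = bg_level[:, None] * bg_wobble

    # a filler transcript absorbs the remaining mass so each group's design
    # already sums to 1e6 CPM and closure after noise is a ~1.0 no-op;
    # without it closure rescales groups differently and distorts the
    # planted fold-changes
    filler = CPM_TOTAL - mean.sum(axis=0)
    if (filler <= 0).any():
        raise ConfigError("designed panel mass exceeds 1e6 CPM; reduce gene counts")
    mean.loc["Filler"] = filler
    genes = genes + ["Filler"]

    cols, col_groups = [], {}
    data = {}
    for group in groups:
        for rep in range(1, cfg.bulk_replicates + 1):
            sample = f"{group}_r{rep}"
            noise = rng.lognormal(mean=0.0, sigma=cfg.bulk_noise_sigma, size=len(genes))
            col = mean[group].to_numpy() * noise
            col = col / col.sum() * CPM_TOTAL  # re-close to CPM
            data[sample] = col
            cols.append(sample)
            col_groups[sample] = group
    values = pd.DataFrame(data, index=genes)
    panel = BulkPanel(values=values, sample_groups=pd.Series(col_groups))
    manifest = Manifest(
        seed=cfg.seed,
        entries={
            "kind": "bulk_organ_panel",
            "brain_enriched": planted,
            "decoys": decoys,
            "decoy_expected_failure": {
                "below_cpm": "a",
                "subfold": "b:kidney_EC",
                "vasc_exceeds": "c",
            },
        },
    )
    return panel, manifest


# ---------------------------------------------------------------------------
# disease-model differential table (dysfunction-module input)
# ---------------------------------------------------------------------------

def simulate_disease_models(cfg: SimConfig) -> tuple[DiseaseDiffTable, Manifest]:
    """Up/down/ns calls over the four brain-disease models.

    Planted dysfunction genes are up in 3 or 4 models; background genes
    are up in 0–2.  With ``include_pattern_sweep`` one extra gene per
    up/down pattern over the four models is appended (16 genes).
    """
    rng = np.random.default_rng(cfg.seed + 202)
    planted = _mouse_dysf_genes(cfg)
    rows: dict[str, list[str]] = {}
    for g in planted:
        n_up = int(rng.integers(3, 5))
        ups = set(rng.choice(len(DISEASE_MODELS), size=n_up, replace=False))
        rows[g] = [
            "up" if j in ups else rng.choice(["down", "ns"]) for j in range(4)
        ]
    for i in range(1, cfg.n_disease_background + 1):
        g = f"Disbg{i:04d}"
        n_up = int(rng.integers(0, 3))
        ups = set(rng.choice(len(DISEASE_MODELS), size=n_up, replace=False))
        rows[g] = ["up" if j in ups else rng.choice(["down", "ns"]) for j in range(4)]
    if cfg.include_pattern_sweep:
        for bits in range(16):
            pattern = [(bits >> j) & 1 for j in range(4)]
            g = "Pattern" + "".join("U" if b else "D" for b in pattern)
            rows[g] = ["up" if b else "down" for b in pattern]
    calls = pd.DataFrame.from_dict(rows, orient="index", columns=list(DISEASE_MODELS))
    tbl = DiseaseDiffTable(calls=calls)
    manifest = Manifest(
        seed=cfg.seed,
        entries={
            "kind": "disease_models",
            "dysfunction_genes": planted,
            "n_up": {g: int((calls.loc[g] == "up").sum()) for g in calls.index},
        },
    )
    return tbl, manifest


# ---------------------------------------------------------------------------
# homolog map
# ---------------------------------------------------------------------------

def simulate_homolog_map(cfg: SimConfig) -> tuple[HomologMap, Manifest]:
    """Mouse→human map over the planted module genes with planted drops.

    Mapped symbols are the upper-cased mouse symbols; the last
    ``homolog_drop_core`` core genes and ``homolog_drop_dysfunction``
    dysfunction genes have no human homolog (the default drop counts
    mirror a 162→155 and 136→131 attrition).
    """
    core = _mouse_core_genes(cfg)
    dysf = _mouse_dysf_genes(cfg)
    dropped = set(core[len(core) - cfg.homolog_drop_core :]) | set(
        dysf[len(dysf) - cfg.homolog_drop_dysfunction :]
    )
    pairs = [(g, g.upper()) for g in core + dysf if g not in dropped]
    hm = HomologMap.from_pairs(pairs)
    manifest = Manifest(
        seed=cfg.seed,
        entries={"kind": "homolog_map", "dropped": sorted(dropped)},
    )
    return hm, manifest


# ---------------------------------------------------------------------------
# anatomic region panel
# ---------------------------------------------------------------------------

def simulate_anatomic_regions(
    cfg: SimConfig,
    marker_sets: dict[str, list[str]] | None = None,
    set_region: dict[str, str] | None = None,
) -> tuple[RegionPanel, GeneSet, Manifest]:
    """Region-labelled bulk panel with a planted vascular-abundance confound.

    expression(g, s) = (background + region mixture weight) × vascular
    factor × noise.  The vascular factor is boosted
    ``vascular_confound_factor``-fold in microvascular-proliferation
    samples, so raw marker means are dominated by vessel density until
    normalized by the microvascular score.  Returns the panel, the
    vascular-enriched gene panel, and the truth manifest.
    """
    rng = np.random.default_rng(cfg.seed + 303)
    if marker_sets is None:
        marker_sets = {
            "Pe1": [f"PE1A{i:03d}" for i in range(1, 21)],
            "Co1": [f"CO1A{i:03d}" for i in range(1, 21)],
            "Co2": [f"CO2A{i:03d}" for i in range(1, 21)],
        }
    if set_region is None:
        set_region = {
            "Pe1": "leading_edge",
            "Co1": "microvascular_proliferation",
            "Co2": "cellular_tumor",
        }
    unknown = set(set_region.values()) - set(ANATOMIC_REGIONS)
    if unknown:
        raise ConfigError(f"unknown regions in set_region: {sorted(unknown)}")
    vascular = [f"VASC{i:03d}" for i in range(1, cfg.vascular_panel_size + 1)]
    marker_genes = list(dict.fromkeys(g for gs in marker_sets.values() for g in gs))
    background = [f"Regbg{i:04d}" for i in range(1, 201)]
    genes = list(dict.fromkeys(marker_genes + vascular + background))

    base = pd.Series(cfg.region_background_weight, index=genes, dtype=float)
    base[vascular] = 10.0  # vascular genes: constant, scale only with the factor
    weights = {r: base.copy() for r in ANATOMIC_REGIONS}
    for name, gs in marker_sets.items():
        target = set_region[name]
        for r in ANATOMIC_REGIONS:
            w = cfg.region_signal_weight if r == target else cfg.region_background_weight
            present = [g for g in gs if g in weights[r].index]
            weights[r][present] = weights[r][present] + w

    data, regions_map, factors = {}, {}, {}
    for r in ANATOMIC_REGIONS:
        for k in range(1, cfg.region_samples_per_region + 1):
            sample = f"{r}_s{k}"
            vf = float(rng.lognormal(mean=0.0, sigma=0.1))
            if r == "microvascular_proliferation":
                vf *= cfg.vascular_confound_factor
            noise = rng.lognormal(mean=0.0, sigma=cfg.region_noise_sigma, size=len(genes))
            data[sample] = weights[r].to_numpy() * vf * noise
            regions_map[sample] = r
            factors[sample] = vf
    panel = RegionPanel(values=pd.DataFrame(data, index=genes), sample_regions=pd.Series(regions_map))
    vascular_panel = GeneSet(name="vascular", description="vascular-enriched panel", genes=tuple(vascular))
    manifest = Manifest(
        seed=cfg.seed,
        entries={
            "kind": "anatomic_regions",
            "vascular_factor": factors,
            "marker_sets": {k: list(v) for k, v in marker_sets.items()},
            "set_region": dict(set_region),
            "vascular_panel": vascular,
        },
    )
    return panel, vascular_panel, manifest


# ---------------------------------------------------------------------------
# planted co-expression structure (module co-expression oracle input)
# ---------------------------------------------------------------------------

def simulate_coexpressed_modules(
    n_cells: int = 500,
    n_core: int = 10,
    n_dysf: int = 10,
    within_r: float = 0.5,
    seed: int = 0,
) -> tuple[NormalizedMatrix, list[str], list[str]]:
    """Single-factor Gaussian expression with known correlation structure.

    Core genes load +a on a latent factor, dysfunction genes −a, with
    unit noise; a = sqrt(within_r / (1 − within_r)) gives pairwise
    within-module correlation ``within_r`` and cross-module correlation
    ``−within_r``.  Returned as a NormalizedMatrix (shifted positive).
    """
    if not (0 < within_r < 1):
        raise ConfigError("within_r must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    a = np.sqrt(within_r / (1.0 - within_r))
    f = rng.normal(size=n_cells)
    core_names = [f"CORE{i:03d}" for i in range(1, n_core + 1)]
    dysf_names = [f"DYSF{i:03d}" for i in range(1, n_dysf + 1)]
    x_core = a * f[None, :] + rng.normal(size=(n_core, n_cells))
    x_dysf = -a * f[None, :] + rng.normal(size=(n_dysf, n_cells))
    values = np.vstack([x_core, x_dysf]) + 10.0
    barcodes = np.array([f"SIMCELL{i:04d}" for i in range(n_cells)], dtype=object)
    meta = pd.DataFrame(
        {"patient": "P1", "region": "core"}, index=pd.Index(barcodes, name="barcode")
    )
    nm = NormalizedMatrix(
        values=values,
        gene_symbols=np.array(core_names + dysf_names, dtype=object),
        barcodes=barcodes,
        cell_meta=meta,
    )
    return nm, core_names, dysf_names
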