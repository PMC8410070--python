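"""QC boundaries, normalization closed forms, clustering determinism and
planted-class recovery, annotation, and EC selection."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from ecatlas.core_io import CountMatrix, GeneSet
from ecatlas import preprocess as pp


def _cm(values, genes, barcodes):
    meta = pd.DataFrame(
        {"patient": "P1", "region": "core"}, index=pd.Index(barcodes, name="barcode")
    )
    return CountMatrix(
        values=sp.csr_matrix(np.asarray(values)),
        gene_symbols=np.array(genes, dtype=object),
        barcodes=np.array(barcodes, dtype=object),
        cell_meta=meta,
    )


def _qc_fixture():
    """Four cells against a 1-mito + 250-nuclear-gene panel.

    HI_MITO: mito fraction 0.12 (> 0.10, removed); LOW_GENES: 150 detected
    genes (< 200, removed); BOUNDARY: mito fraction exactly 23/230 = 0.10
    and exactly 200 detected genes (retained — inequalities are strict);
    CLEAN: unremarkable.
    """
    genes = ["MT-CO1"] + [f"G{i:03d}" for i in range(250)]
    n_genes = len(genes)

    hi_mito = np.zeros(n_genes)
    hi_mito[0] = 30          # 30 mito / 250 total = 0.12
    hi_mito[1:221] = 1       # 220 nuclear counts -> 221 detected genes

    low_genes = np.zeros(n_genes)
    low_genes[1:151] = 2     # 150 detected genes, no mito

    boundary = np.zeros(n_genes)
    boundary[0] = 23         # 23 mito
    boundary[1:200] = 1      # 199 nuclear genes
    boundary[1] += 8         # 207 nuclear counts; total 230; mito = 23/230 = 0.10
    # detected = 1 mito gene + 199 nuclear genes = 200 exactly

    clean = np.zeros(n_genes)
    clean[1:211] = 3

    names = ["HI_MITO", "LOW_GENES", "BOUNDARY", "CLEAN"]
    mat = np.stack([hi_mito, low_genes, boundary, clean], axis=1)
    return _cm(mat.astype(int), genes, names)


class TestQCFilter:
    def test_boundary_and_failure_reasons(self):
        cm = _qc_fixture()
        mito = dict(zip(cm.barcodes, cm.mito_fraction()))
        det = dict(zip(cm.barcodes, cm.detected_genes()))
        assert mito["HI_MITO"] > 0.10
        assert det["LOW_GENES"] < 200
        assert mito["BOUNDARY"] == pytest.approx(0.10)
        assert det["BOUNDARY"] == 200
        kept, report = pp.qc_filter(cm)
        assert set(kept.barcodes) == {"BOUNDARY", "CLEAN"}  # strict inequalities
        assert report.removed.loc["HI_MITO", "reason"] == "mito"
        assert report.removed.loc["LOW_GENES", "reason"] == "min_genes"

    def test_idempotent(self):
        cm = _qc_fixture()
        kept, _ = pp.qc_filter(cm)
        kept2, report2 = pp.qc_filter(kept)
        assert report2.n_removed == 0
        assert kept2.equals(kept)

    def test_all_cells_removed_is_an_error(self):
        cm = _cm([[5], [1]], ["MT-CO1", "G1"], ["ONLY"])  # 5/6 mito, 2 genes
        with pytest.raises(ValueError, match="every cell"):
            pp.qc_filter(cm)

    def test_gene_panel_unchanged(self):
        cm = _qc_fixture()
        kept, _ = pp.qc_filter(cm)
        assert np.array_equal(kept.gene_symbols, cm.gene_symbols)


class TestNormalize:
    def test_closed_form_value(self):
        # 10 counts in a 10,000-count cell at scale 10,000 -> ln(1 + 10)
        vals = np.zeros((2, 1), dtype=int)
        vals[0, 0] = 10
        vals[1, 0] = 9990
        nm = pp.normalize(_cm(vals, ["A", "B"], ["C1"]))
        assert nm.values[0, 0] == pytest.approx(np.log(11.0))

    def test_zero_count_maps_to_zero(self):
        nm = pp.normalize(_cm([[0, 1], [5, 3]], ["A", "B"], ["C1", "C2"]))
        assert nm.values[0, 0] == 0.0

    def test_depth_invariance_within_cell(self):
        v1 = np.array([[3], [7], [1]])
        nm1 = pp.normalize(_cm(v1, ["A", "B", "C"], ["C1"]))
        nm2 = pp.normalize(_cm(2 * v1, ["A", "B", "C"], ["C1"]))
        assert np.allclose(nm1.values, nm2.values)

    def test_commutes_with_cell_subsetting(self):
        rng = np.random.default_rng(4)
        vals = rng.poisson(2.0, size=(30, 10)) + 1
        cm = _cm(vals, [f"G{i}" for i in range(30)], [f"C{i}" for i in range(10)])
        whole = pp.normalize(cm)
        part = pp.normalize(cm.subset_cells(np.arange(3, 8)))
        assert np.allclose(whole.subset_cells(np.arange(3, 8)).values, part.values)

    def test_zero_total_cell_is_an_error_naming_barcode(self):
        cm = _cm([[0, 1]], ["G1"], ["EMPTY", "OK"])
        with pytest.raises(ValueError, match="EMPTY"):
            pp.normalize(cm)


def _two_class_nm(seed=0, n=60, sep=3.0):
    rng = np.random.default_rng(seed)
    half = n // 2
    x = rng.normal(size=(20, n))
    x[:10, :half] += sep
    x[10:, half:] += sep
    bcs = np.array([f"C{i}" for i in range(n)], dtype=object)
    meta = pd.DataFrame({"patient": "P1", "region": "core"}, index=pd.Index(bcs, name="barcode"))
    nm = pp.NormalizedMatrix(
        values=np.abs(x),
        gene_symbols=np.array([f"G{i}" for i in range(20)], dtype=object),
        barcodes=bcs,
        cell_meta=meta,
    )
    truth = np.array([0] * half + [1] * (n - half))
    return nm, truth


class TestClusterCells:
    def test_two_separated_classes_recovered_exactly(self):
        from sklearn.metrics import adjusted_rand_score

        nm, truth = _two_class_nm()
        labels = pp.cluster_cells(nm, n_pcs=5, k=2, seed=0)
        assert adjusted_rand_score(truth, labels.labels) == 1.0

    def test_deterministic_for_fixed_seed(self):
        nm, _ = _two_class_nm()
        a = pp.cluster_cells(nm, n_pcs=5, k=3, seed=42)
        b = pp.cluster_cells(nm, n_pcs=5, k=3, seed=42)
        assert np.array_equal(a.labels, b.labels)

    def test_leiden_path_deterministic_and_contiguous(self):
        nm, truth = _two_class_nm()
        a = pp.cluster_cells(nm, n_pcs=5, resolution=0.5, seed=3)
        b = pp.cluster_cells(nm, n_pcs=5, resolution=0.5, seed=3)
        assert np.array_equal(a.labels, b.labels)
        assert set(a.labels) == set(range(a.n_clusters))

    def test_k_exceeding_cells_rejected(self):
        nm, _ = _two_class_nm(n=10)
        with pytest.raises(ValueError):
            pp.cluster_cells(nm, n_pcs=5, k=11, seed=0)

    def test_exactly_one_method_must_be_selected(self):
        nm, _ = _two_class_nm()
        with pytest.raises(ValueError):
            pp.cluster_cells(nm, n_pcs=5, seed=0)
        with pytest.raises(ValueError):
            pp.cluster_cells(nm, n_pcs=5, k=2, resolution=1.0, seed=0)


class TestAnnotateAndSelect:
    def test_default_atlas_subcluster_recovery(self, atlas_run, match_cluster_to_subcluster):
        from sklearn.metrics import adjusted_rand_score

        bc2sub = atlas_run.truth_percell("ec_subcluster")
        tsub = np.array([bc2sub.get(b, "") for b in atlas_run.nm_ec.barcodes])
        ok = tsub != ""
        ari = adjusted_rand_score(tsub[ok], atlas_run.ec_labels.labels[ok])
        assert ari >= 0.9

    def test_cluster_level_class_annotation_is_exact(self, atlas_run):
        """Every whole-atlas cluster is assigned its majority planted class."""
        from collections import Counter

        bc2cls = atlas_run.truth_percell("cell_class")
        true_cls = np.array([bc2cls[b] for b in atlas_run.nm.barcodes])
        for c, assigned in atlas_run.annotation.cluster_class.items():
            majority = Counter(true_cls[atlas_run.labels.labels == c]).most_common(1)[0][0]
            assert assigned == majority

    def test_tie_breaks_by_panel_order_and_is_recorded(self):
        bcs = np.array(["C1", "C2", "C3"], dtype=object)
        meta = pd.DataFrame({"patient": "P1", "region": "core"}, index=pd.Index(bcs, name="barcode"))
        nm = pp.NormalizedMatrix(
            values=np.array([[1.0, 1, 1], [1.0, 1, 1]]),
            gene_symbols=np.array(["A", "B"], dtype=object),
            barcodes=bcs,
            cell_meta=meta,
        )
        labels = pp.ClusterLabels(labels=np.zeros(3, int), n_clusters=1, method="t")
        panels = [
            GeneSet(name="first", description="", genes=("A",)),
            GeneSet(name="second", description="", genes=("B",)),
        ]
        ann = pp.annotate_clusters(nm, labels, panels)
        assert ann.cluster_class[0] == "first"
        assert ann.ties == [(0, ["first", "second"])]

    def test_planted_doublets_flagged_with_high_recall(self, atlas_run):
        planted = set(atlas_run.truth.entries["doublets"])
        in_ec_pool = planted & set(atlas_run.nm.barcodes)
        flagged = set(atlas_run.doublet_report.flagged.index)
        assert len(in_ec_pool) > 0
        assert len(flagged & in_ec_pool) / len(in_ec_pool) >= 0.8

    def test_no_doublets_planted_gives_high_specificity(self):
        """With frac_doublets = 0 almost no EC cell may be flagged."""
        from conftest import build_atlas_run

        run = build_atlas_run(seed=3, frac_doublets=0.0)
        false_flags = len(run.doublet_report.flagged)
        assert false_flags / run.doublet_report.n_ec_cells <= 0.01

    def test_missing_ec_cluster_is_an_error(self, atlas_run):
        ann = pp.ClassAnnotation(
            cluster_class={c: "macrophage" for c in range(atlas_run.labels.n_clusters)},
            scores=atlas_run.annotation.scores,
        )
        from ecatlas.synthetic import canonical_panel_sets

        with pytest.raises(ValueError, match="EC"):
            pp.select_ecs(atlas_run.nm, atlas_run.labels, ann, canonical_panel_sets())
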