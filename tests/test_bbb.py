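"""Core-module criteria (boundaries, decoys), dysfunction voting vs brute
force, homolog mapping, detection restriction, module co-expression."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ecatlas.bbb import (
    CPM_TOTAL,
    DISEASE_MODELS,
    BulkPanel,
    DiseaseDiffTable,
    HomologMap,
    ModuleDefinition,
    build_core_module,
    build_dysfunction_module,
    map_homologs,
    module_coexpression,
    restrict_to_detected,
)
from ecatlas.synthetic import (
    SimConfig,
    simulate_bulk_organ_panel,
    simulate_coexpressed_modules,
    simulate_disease_models,
)

GROUPS = ("brain_EC", "kidney_EC", "lung_EC", "heart_EC", "liver_EC", "brain_vasculature")


def _panel_from_means(means: dict[str, dict[str, float]], reps: int = 3) -> BulkPanel:
    """Exact-valued panel: per-group means replicated verbatim, with a
    FILLER gene absorbing the CPM remainder so each column closes to 1e6."""
    genes = list(means)
    data, groups = {}, {}
    for g in GROUPS:
        for r in range(reps):
            sample = f"{g}_r{r}"
            col = np.array([means[gene][g] for gene in genes], dtype=float)
            data[sample] = np.append(col, CPM_TOTAL - col.sum())
            groups[sample] = g
    values = pd.DataFrame(data, index=genes + ["FILLER"])
    return BulkPanel(values=values, sample_groups=pd.Series(groups))


def _uniform(brain, organ, vasc):
    return {
        "brain_EC": brain, "kidney_EC": organ, "lung_EC": organ,
        "heart_EC": organ, "liver_EC": organ, "brain_vasculature": vasc,
    }


class TestCoreModuleBoundaries:
    def test_exactly_100_cpm_is_included(self):
        # 5 fully separated replicates per group: exact rank-sum p = 2/252
        panel = _panel_from_means({"AT100": _uniform(100.0, 10.0, 50.0)}, reps=5)
        mod = build_core_module(panel)
        assert mod.audit["AT100"]["criterion_a"] is True

    def test_exactly_twofold_is_excluded(self):
        panel = _panel_from_means({"FOLD2": _uniform(200.0, 100.0, 50.0)}, reps=5)
        mod = build_core_module(panel)
        rec = mod.audit["FOLD2"]
        assert all(r["fold"] == pytest.approx(2.0) for r in rec["criterion_b"].values())
        assert "FOLD2" not in mod.genes  # "more than 2-fold" is strict

    def test_brain_equal_to_vasculature_is_retained_under_c(self):
        panel = _panel_from_means({"EQVASC": _uniform(400.0, 10.0, 400.0)}, reps=5)
        mod = build_core_module(panel)
        assert mod.audit["EQVASC"]["criterion_c"] is True

    def test_small_replicate_groups_cannot_reach_significance(self):
        """With 3 vs 3 replicates the exact two-sided rank-sum floor is
        2/20 = 0.1, so criterion (b) can never pass at alpha 0.05."""
        panel = _panel_from_means({"STRONG": _uniform(1000.0, 10.0, 100.0)}, reps=3)
        mod = build_core_module(panel)
        assert mod.genes == ()
        assert all(
            r["p"] >= 0.1 for r in mod.audit["STRONG"]["criterion_b"].values()
        )

    def test_missing_group_and_single_replicate_rejected(self):
        panel = _panel_from_means({"G": _uniform(200.0, 10.0, 50.0)}, reps=5)
        dropped = panel.values.drop(columns=[c for c in panel.values.columns if "kidney" in c])
        with pytest.raises(ValueError, match="kidney_EC"):
            build_core_module(
                BulkPanel(values=dropped, sample_groups=panel.sample_groups[dropped.columns])
            )


@pytest.fixture(scope="module")
def built():
    cfg = SimConfig(seed=1)
    panel, truth = simulate_bulk_organ_panel(cfg)
    return build_core_module(panel), truth


class TestCoreModuleOnSyntheticPanel:
    def test_module_equals_planted_set_exactly(self, built):
        mod, truth = built
        assert list(mod.genes) == truth.entries["brain_enriched"]

    def test_each_decoy_fails_exactly_its_planted_criterion(self, built):
        mod, truth = built
        expected = truth.entries["decoy_expected_failure"]
        for family, genes in truth.entries["decoys"].items():
            for g in genes:
                assert g not in mod.genes
                assert mod.audit[g]["failed"] == [expected[family]]

    def test_audit_partitions_every_input_gene(self, built):
        mod, _ = built
        included = {g for g, rec in mod.audit.items() if rec["included"]}
        rejected = {g for g, rec in mod.audit.items() if not rec["included"]}
        assert included == set(mod.genes)
        assert included | rejected == set(mod.audit)
        assert all(mod.audit[g]["failed"] for g in rejected)


class TestDysfunctionModule:
    def test_simple_votes(self):
        calls = pd.DataFrame(
            [["up"] * 4, ["up", "up", "down", "ns"]],
            index=["ALLUP", "TWOUP"], columns=list(DISEASE_MODELS),
        )
        mod = build_dysfunction_module(DiseaseDiffTable(calls=calls))
        assert "ALLUP" in mod.genes and "TWOUP" not in mod.genes

    def test_exhaustive_sixteen_patterns_match_brute_force(self):
        """All 2^4 up/down patterns; included iff ≥3 ups, per literal count."""
        rows = {}
        for bits in itertools.product(["up", "down"], repeat=4):
            rows["_".join(bits)] = list(bits)
        tbl = DiseaseDiffTable(
            calls=pd.DataFrame.from_dict(rows, orient="index", columns=list(DISEASE_MODELS))
        )
        mod = build_dysfunction_module(tbl, min_models=3)
        brute = {g for g, bits in rows.items() if sum(b == "up" for b in bits) >= 3}
        assert set(mod.genes) == brute
        assert len(brute) == 5  # C(4,3) + C(4,4)
        for g, rec in mod.audit.items():
            assert rec["n_up"] == sum(b == "up" for b in rows[g])

    def test_planted_generator_genes_all_pass(self):
        tbl, truth = simulate_disease_models(SimConfig(seed=2))
        mod = build_dysfunction_module(tbl)
        assert set(truth.entries["dysfunction_genes"]) <= set(mod.genes)


def _module(genes, name="m"):
    return ModuleDefinition(name=name, genes=tuple(genes), audit={g: {} for g in genes},
                            provenance=[{"stage": "raw", "n_genes": len(genes), "dropped": []}])


class TestHomologMapping:
    def test_unmapped_gene_moves_to_dropped_provenance(self):
        hm = HomologMap.from_pairs([("Slc2a1", "SLC2A1")])
        mod = map_homologs(_module(["Slc2a1", "Orphan"]), hm)
        assert mod.genes == ("SLC2A1",)
        assert mod.provenance[-1]["dropped"] == ["Orphan"]

    def test_identity_map_preserves_module(self):
        genes = ["A", "B", "C"]
        hm = HomologMap.from_pairs([(g, g) for g in genes])
        assert map_homologs(_module(genes), hm).genes == ("A", "B", "C")

    def test_162_gene_module_with_7_drops_maps_155(self):
        genes = [f"Gene{i:03d}" for i in range(162)]
        hm = HomologMap.from_pairs([(g, g.upper()) for g in genes[:155]])
        mod = map_homologs(_module(genes), hm)
        assert len(mod.genes) == 155
        assert len(mod.provenance[-1]["dropped"]) == 7

    def test_one_to_many_resolved_to_lexicographically_smallest(self):
        hm = HomologMap.from_pairs([("Ambig", "ZZZ"), ("Ambig", "AAA")])
        assert hm.mapping["Ambig"] == "AAA"
        assert hm.alternatives["Ambig"] == ["ZZZ"]

    def test_target_collision_rejected(self):
        hm = HomologMap.from_pairs([("A", "X"), ("B", "X")])
        with pytest.raises(ValueError, match="X"):
            map_homologs(_module(["A", "B"]), hm)

    def test_tsv_round_trip(self, tmp_path):
        hm = HomologMap.from_pairs([("A", "X"), ("B", "Y"), ("B", "Z")])
        p = tmp_path / "hom.tsv"
        hm.to_tsv(p)
        back = HomologMap.from_tsv(p)
        assert back.mapping == hm.mapping and back.alternatives == hm.alternatives


class _NM:
    def __init__(self, values, genes):
        self.values = np.asarray(values, float)
        self.gene_symbols = np.array(genes, dtype=object)


class TestRestrictToDetected:
    def test_detection_boundaries(self):
        nm = _NM([[0] * 10, [1] + [0] * 9, [1] * 9 + [0]], ["ZERO", "ONE", "NINE"])
        assert restrict_to_detected(_module(["ZERO", "ONE", "NINE"]), nm).genes == ("ONE", "NINE")
        assert restrict_to_detected(_module(["NINE"]), nm, min_cells=10).genes == ()
        assert restrict_to_detected(_module(["NINE"]), nm, min_cells=9).genes == ("NINE",)

    def test_provenance_chain_is_monotone(self):
        genes = [f"Gene{i}" for i in range(10)]
        hm = HomologMap.from_pairs([(g, g.upper()) for g in genes[:8]])
        nm = _NM(np.vstack([np.ones((6, 4)), np.zeros((2, 4))]),
                 [g.upper() for g in genes[:8]])
        mod = restrict_to_detected(map_homologs(_module(genes), hm), nm)
        sizes = [p["n_genes"] for p in mod.provenance]
        assert sizes == sorted(sizes, reverse=True)
        assert mod.provenance[0]["stage"] == "raw"
        assert [p["stage"] for p in mod.provenance] == ["raw", "homolog_mapped", "detected"]


class TestModuleCoexpression:
    def test_planted_anticorrelated_modules_detected(self):
        nm, core_names, dysf_names = simulate_coexpressed_modules(n_cells=500, seed=42)
        summary = module_coexpression(nm, _module(core_names, "core"), _module(dysf_names, "dysf"))
        assert summary.mean_cross < -0.2
        assert summary.mean_within_core > 0.2
        assert summary.mean_within_dysfunction > 0.2

    def test_cellwise_shuffle_destroys_structure(self):
        nm, core_names, dysf_names = simulate_coexpressed_modules(n_cells=500, seed=42)
        rng = np.random.default_rng(0)
        shuffled = nm.values.copy()
        for i in range(shuffled.shape[0]):  # break gene–gene coupling per row
            shuffled[i] = shuffled[i, rng.permutation(shuffled.shape[1])]
        nm_null = _NM(shuffled, nm.gene_symbols)
        summary = module_coexpression(nm_null, _module(core_names, "core"), _module(dysf_names, "dysf"))
        assert abs(summary.mean_cross) < 0.1
        assert abs(summary.mean_within_core) < 0.1
        assert abs(summary.mean_within_dysfunction) < 0.1

    def test_module_against_itself_gives_equal_means(self):
        nm, core_names, _ = simulate_coexpressed_modules(n_cells=300, seed=9)
        summary = module_coexpression(nm, _module(core_names, "a"), _module(core_names, "b"))
        assert summary.mean_cross == pytest.approx(summary.mean_within_core)

    def test_constant_module_is_an_error_naming_it(self):
        values = np.vstack([np.random.default_rng(0).normal(size=(3, 50)), np.ones((2, 50))])
        nm = _NM(values, ["A", "B", "C", "FLAT1", "FLAT2"])
        with pytest.raises(ValueError, match="flat"):
            module_coexpression(nm, _module(["A", "B", "C"], "ok"), _module(["FLAT1", "FLAT2"], "flat"))
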