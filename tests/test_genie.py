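"""Variant counting, inventory assembly, category scores and the export."""

import numpy as np
import pytest

from markergenie.calibrate import CutoffPair
from markergenie.errors import ValidationError
from markergenie.genefinder import Orf
from markergenie.genie import (
    SampleInventory,
    SampleMeta,
    InventoryRow,
    build_inventory,
    category_scores,
    count_variants,
    export_fig2_table,
    fig2_table_to_tsv,
)
from markergenie.registry import GeneFamilyRegistry, RegistryEntry
from markergenie.synthdata import FamilySpec, evolve_family

from .oracles import pairwise_identity


def _orf(oid: str, aa: str, contig: str = "c1") -> Orf:
    return Orf(orf_id=oid, contig_id=contig, strand="+", frame=0,
               nt_start=0, nt_end=3 * len(aa), aa_seq=aa)


class TestCountVariants:
    def test_identical_sequences_collapse(self):
        orfs = [_orf(f"o{i}", "MKLV" * 10) for i in range(3)]
        n, clusters = count_variants(orfs)
        assert n == 1
        assert sorted(clusters[0]) == ["o0", "o1", "o2"]

    def test_single_residue_difference_splits_at_exact_threshold(self):
        a = "MKLV" * 10
        b = a[:-1] + "W"
        n, _ = count_variants([_orf("a", a), _orf("b", b)], 1.0)
        assert n == 2

    def test_substring_joins_cluster_at_exact_threshold(self):
        a = "MKLVHGWACD" * 5
        n, _ = count_variants([_orf("a", a), _orf("b", a[5:40])], 1.0)
        assert n == 1

    def test_identity_thresholds_on_simulated_family(self):
        """Five variants with pairwise identity ~0.9: split at 0.97, merge at 0.85."""
        _, members = evolve_family(
            FamilySpec("sdo", root_length=200, n_members=5,
                       substitution_rate=0.05, seed=31)
        )
        idents = [pairwise_identity(a, b)
                  for i, a in enumerate(members) for b in members[i + 1:]]
        assert 0.85 < min(idents) and max(idents) < 0.97  # premise of the example
        orfs = [_orf(f"v{i}", m) for i, m in enumerate(members)]
        assert count_variants(orfs, 0.97)[0] == 5
        assert count_variants(orfs, 0.85)[0] == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            count_variants([])

    def test_deterministic_under_input_order(self):
        rng = np.random.default_rng(8)
        _, members = evolve_family(FamilySpec("f", 60, 6, 0.1, seed=9))
        orfs = [_orf(f"o{i}", m) for i, m in enumerate(members)]
        n1, c1 = count_variants(orfs, 0.9)
        perm = [orfs[i] for i in rng.permutation(len(orfs))]
        n2, c2 = count_variants(perm, 0.9)
        assert n1 == n2
        assert sorted(map(sorted, c1)) == sorted(map(sorted, c2))


def _simple_registry() -> GeneFamilyRegistry:
    reg = GeneFamilyRegistry([
        RegistryEntry("katG", "catalase", target_hmm_names=["katG"],
                      decoy_hmm_names=["dec"]),
        RegistryEntry("sdo", "sulfur_oxidation", target_hmm_names=["sdo"]),
    ])
    reg.attach_cutoffs("katG", CutoffPair(60.0, 10.0, 35.0, True))
    reg.attach_cutoffs("sdo", CutoffPair(60.0, 10.0, 35.0, True))
    return reg


META = SampleMeta("s1", "SITE", 10.0, "present")


class TestBuildInventory:
    def test_no_orf_clears_cutoff_yields_empty_inventory(self):
        orfs = [_orf("o1", "MKLV" * 10)]
        hits = {"o1": {"katG": 5.0, "sdo": 3.0, "dec": 1.0}}
        inv = build_inventory(orfs, hits, _simple_registry(), META)
        assert inv.rows == []

    def test_accepted_orfs_grouped_and_counted(self):
        orfs = [_orf("o1", "MKLV" * 10, "c1"), _orf("o2", "MKLV" * 10, "c2"),
                _orf("o3", "WCDE" * 10, "c3"), _orf("o4", "HGWA" * 10, "c4")]
        hits = {
            "o1": {"katG": 80.0, "sdo": 2.0, "dec": 10.0},
            "o2": {"katG": 70.0, "sdo": 2.0, "dec": 10.0},
            "o3": {"katG": 75.0, "sdo": 2.0, "dec": 10.0},
            "o4": {"katG": 2.0, "sdo": 50.0, "dec": 10.0},  # different gene
        }
        lineages = {"c1": "Chloroflexi", "c2": "Chloroflexi", "c3": "Chloroflexi"}
        inv = build_inventory(orfs, hits, _simple_registry(), META, lineages)
        rows = {(r.lineage, r.gene_symbol): r for r in inv.rows}
        assert rows[("Chloroflexi", "katG")].variant_count == 2  # o1==o2, o3 differs
        assert rows[("unclassified", "sdo")].variant_count == 1
        inv.validate()

    def test_decoy_outcompeted_orf_never_appears(self):
        orfs = [_orf("o1", "MKLV" * 10)]
        hits = {"o1": {"katG": 50.0, "sdo": 1.0, "dec": 55.0}}
        inv = build_inventory(orfs, hits, _simple_registry(), META)
        assert inv.rows == []


class TestCategoryScores:
    def _inventories(self):
        inv1 = SampleInventory(META, rows=[
            InventoryRow("A", "sdo", "sulfur_oxidation", 2, ["a", "b"]),
            InventoryRow("A", "sqr", "sulfur_oxidation", 1, ["c"]),
            InventoryRow("B", "katG", "catalase", 3, ["d", "e", "f"]),
        ])
        inv2 = SampleInventory(SampleMeta("s2", "SITE", 20.0, "depleted"), rows=[])
        return [inv1, inv2]

    def test_scores_sum_variant_counts_per_category(self):
        df = category_scores(self._inventories())
        assert df.loc["s1", "sulfur_oxidation"] == 3
        assert df.loc["s1", "catalase"] == 3
        assert df.loc["s2"].sum() == 0  # all-zero row for an empty sample

    def test_normalized_rows_sum_to_one(self):
        df = category_scores(self._inventories(), normalize=True)
        assert df.loc["s1"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_requires_at_least_one_inventory(self):
        with pytest.raises(ValidationError):
            category_scores([])


class TestExport:
    def test_depth_sorting_and_conservation(self):
        deep = SampleInventory(SampleMeta("d", "SITE", 42.0, "depleted"), rows=[
            InventoryRow("A", "sdo", "sulfur_oxidation", 2, ["a", "b"]),
        ])
        shallow = SampleInventory(SampleMeta("s", "SITE", 12.0, "depleted"), rows=[
            InventoryRow("A", "katG", "catalase", 1, ["c"]),
            InventoryRow("B", "sdo", "sulfur_oxidation", 4, ["d", "e", "f", "g"]),
        ])
        df = export_fig2_table([deep, shallow])
        assert list(df.depth_mbsf) == [12.0, 12.0, 42.0]
        total_inv = deep.total_variants() + shallow.total_variants()
        assert df.transcript_copies.sum() == total_inv

    def test_single_row_export(self):
        inv = SampleInventory(META, rows=[
            InventoryRow("A", "sdo", "sulfur_oxidation", 1, ["a"])])
        tsv = fig2_table_to_tsv(export_fig2_table([inv]))
        lines = tsv.strip().split("\n")
        assert len(lines) == 2
        assert lines[0].startswith("site\tdepth_mbsf")
        assert lines[1] == "SITE\t10\tpresent\tA\tsdo\tsulfur_oxidation\t1"

    def test_zero_count_rows_are_invalid(self):
        inv = SampleInventory(META, rows=[
            InventoryRow("A", "sdo", "sulfur_oxidation", 0, [])])
        with pytest.raises(ValidationError):
            inv.validate()
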