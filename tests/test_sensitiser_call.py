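"""Gene-level calling rule and cross-screen set algebra."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import dropscreen as ds
from dropscreen.errors import DropscreenError


def _rows(fdrs, lfcs, gene="G1", contrast="PDS-t0"):
    return pd.DataFrame(
        {"gene": gene, "contrast": contrast, "fdr": fdrs, "log2fc": lfcs}
    )


class TestCallGene:
    def test_three_of_five_significant_with_strong_median_is_sensitiser(self):
        rows = _rows(
            [0.01, 0.02, 0.04, 0.5, 0.9], [-1.3, -1.5, -1.1, -0.1, 0.2]
        )
        call = ds.call_gene(rows)
        assert call.classification == "sensitiser"
        assert call.n_sig_depleted == 3
        assert call.median_log2fc == pytest.approx(-1.3)

    def test_half_of_four_at_exact_cut_is_sensitiser_inclusive(self):
        rows = _rows([0.01, 0.05, 0.4, 0.6], [-1.0, -1.0, 0.1, 0.0])
        assert ds.call_gene(rows).classification == "sensitiser"

    def test_two_of_six_fails_both_branches(self):
        rows = _rows(
            [0.01, 0.01, 0.5, 0.6, 0.7, 0.8], [-2.0, -2.0, 0, 0, 0, 0]
        )
        assert ds.call_gene(rows).classification == "not_called"

    def test_weak_median_is_depleted_not_sensitiser(self):
        rows = _rows([0.01, 0.01, 0.01, 0.9, 0.9], [-0.5, -0.6, -0.4, 0, 0])
        assert ds.call_gene(rows).classification == "depleted"

    def test_significant_but_enriched_hairpins_do_not_count(self):
        rows = _rows([0.01, 0.01, 0.01], [2.0, 1.5, 1.0])
        call = ds.call_gene(rows)
        assert call.n_sig_depleted == 0
        assert call.classification == "not_called"

    def test_median_over_all_mode(self):
        rows = _rows([0.01, 0.01, 0.9, 0.9, 0.9], [-3, -3, 0, 0, 0])
        assert ds.call_gene(rows).median_log2fc == -3          # over significant
        assert ds.call_gene(rows, median_over="all").median_log2fc == 0

    def test_empty_slice_is_error(self):
        with pytest.raises(DropscreenError, match="empty"):
            ds.call_gene(_rows([], []))

    def test_adding_significant_hairpin_never_removes_a_call(self):
        """Monotonicity: extra significantly depleted evidence can't demote."""
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = rng.integers(2, 8)
            fdrs = rng.uniform(0, 0.3, n)
            lfcs = rng.uniform(-3, 1, n)
            base = ds.call_gene(_rows(fdrs, lfcs))
            if base.classification != "sensitiser":
                continue
            grown = _rows(
                np.append(fdrs, 0.001), np.append(lfcs, base.median_log2fc - 0.5)
            )
            assert ds.call_gene(grown).classification == "sensitiser"


class TestClassifyScreen:
    def test_recovers_planted_classes_end_to_end(self, small_screen):
        calls, truth = small_screen["calls"], small_screen["truth"]
        planted_pds = truth.sensitisers("PDS")
        called_pds = ds.genes_with_class(calls, "PDS-t0")
        assert planted_pds <= called_pds
        # essentials drop out under vehicle too
        essentials = truth.genes_of_class("essential")
        dmso_dep = ds.genes_with_class(calls, "DMSO-t0", ("depleted", "sensitiser"))
        assert len(essentials & dmso_dep) >= len(essentials) - 1
        # neutrals stay uncalled in the vehicle arm
        neutral = truth.genes_of_class("neutral")
        assert len(neutral & dmso_dep) <= max(1, 0.1 * len(neutral))

    def test_single_gene_table_matches_call_gene(self):
        rows = _rows([0.01, 0.01, 0.01, 0.5, 0.5], [-2, -2, -2, 0, 0])
        calls = ds.classify_screen(rows)
        assert len(calls) == 1
        assert calls["class"].iloc[0] == ds.call_gene(rows).classification

    def test_untested_genes_reported(self, small_screen):
        dr = small_screen["dr"]
        sub = dr[dr["gene"] != "GENE00000"]
        calls = ds.classify_screen(sub, lib=small_screen["lib"])
        untested = calls[calls["class"] == "untested"]
        assert set(untested["gene"]) == {"GENE00000"}


class TestSetLogic:
    def test_ligand_specific_subtracts_vehicle(self):
        out = ds.ligand_specific({"PDS": {"A", "B", "C"}}, {"B"})
        assert out["PDS"] == {"A", "C"}
        assert ds.ligand_specific({"PDS": set()}, {"B"})["PDS"] == set()
        assert ds.ligand_specific({"PDS": {"B"}}, {"B", "C"})["PDS"] == set()

    def test_ligand_specific_is_idempotent(self):
        sets = {"PDS": {"A", "B"}, "PhenDC3": {"B", "C"}}
        once = ds.ligand_specific(sets, {"B"})
        twice = ds.ligand_specific(once, {"B"})
        assert once == twice

    @given(
        st.lists(st.sets(st.integers(0, 30)), min_size=2, max_size=3)
    )
    @settings(derandomize=True, max_examples=60)
    def test_venn_regions_partition_the_union(self, sets):
        named = {f"s{i}": s for i, s in enumerate(sets)}
        regions = ds.venn_counts(named)
        assert sum(regions.values()) == len(set().union(*sets))

    def test_two_ligand_venn_worked_example(self):
        """89 PDS-unique + 161 PhenDC3-unique + 40 shared = 290 sensitisers."""
        shared = {f"S{i}" for i in range(40)}
        pds = {f"P{i}" for i in range(89)} | shared
        phen = {f"D{i}" for i in range(161)} | shared
        regions = ds.venn_counts({"PDS": pds, "PhenDC3": phen})
        assert regions[frozenset({"PDS"})] == 89
        assert regions[frozenset({"PhenDC3"})] == 161
        assert regions[frozenset({"PDS", "PhenDC3"})] == 40
        assert len(pds | phen) == 290

    def test_overlap_percent_worked_example(self):
        """308 of a 758-gene reference recovered = 40.6% overlap."""
        reference = {f"G{i}" for i in range(758)}
        query = {f"G{i}" for i in range(308)} | {f"X{i}" for i in range(34)}
        assert ds.overlap_percent(query, reference) == pytest.approx(40.6, abs=0.05)

    def test_key_genes_common_to_all_screens_and_ligands(self):
        screens = {
            "A375_focused": {"PDS": {"BRCA1", "TOP1"}, "PhenDC3": {"BRCA1", "GAR1"}},
            "A375_gw": {"PDS": {"BRCA1", "X"}, "PhenDC3": {"BRCA1"}},
            "HT1080": {"PDS": {"BRCA1"}, "PhenDC3": {"BRCA1", "Y"}},
        }
        summary = ds.combine_and_intersect(screens)
        assert summary["key_genes"] == {"BRCA1"}
        assert summary["per_screen_common"]["A375_focused"] == {"BRCA1"}

    def test_unknown_ligand_name_rejected(self):
        with pytest.raises(DropscreenError, match="unknown ligand"):
            ds.combine_and_intersect({"s": {"CX5461": {"A"}}})
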