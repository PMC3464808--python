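"""Library design, codon edits, and the two-temperature Ts screen."""

import itertools

import pytest

from tsplasmid.datasets import (
    REPB_SITES,
    SCREEN_TABLE_NOTES,
    repb_screen_table,
    synthetic_repb_like_cds,
)
from tsplasmid.library import (
    CodonUsageTable,
    GrowthCall,
    Phenotype,
    build_library,
    classify_ts_phenotype,
    design_substitutions,
    mutate_cds,
    screen_summary,
    translate_cds,
)


class TestDesignSubstitutions:
    def test_kstw_panel_for_met(self):
        assert design_substitutions("M", "kstw") == ["K", "S", "A", "W"]

    def test_kstw_excludes_wild_type(self):
        assert design_substitutions("S", "kstw") == ["K", "A", "W"]

    def test_asp_probe(self):
        assert design_substitutions("W", "asp_probe") == ["D"]

    def test_random_all_deterministic_and_excludes_wild(self):
        a = design_substitutions("I", "random_all", n=4, seed=11)
        b = design_substitutions("I", "random_all", n=4, seed=11)
        assert a == b
        assert "I" not in a
        assert len(set(a)) == 4

    def test_random_all_rejects_oversized_pool(self):
        with pytest.raises(ValueError):
            design_substitutions("I", "random_all", n=20)


class TestMutateCds:
    def test_hand_codon_edit(self, usage):
        # Met-Ile -> Met-Leu, TTA being the most frequent Leu codon
        mutant, spec = mutate_cds("ATGATT", 2, "L", usage)
        assert mutant == "ATGTTA"
        assert spec.name == "I2L"
        assert (spec.codon_old, spec.codon_new) == ("ATT", "TTA")

    def test_silent_substitution_rejected(self, usage):
        with pytest.raises(ValueError, match="silent"):
            mutate_cds("ATGATT", 2, "I", usage)

    def test_edit_confined_to_one_codon(self, usage, rng):
        cds = synthetic_repb_like_cds(seed=5)
        mutant, spec = mutate_cds(cds, 51, "E", usage)
        diffs = [i for i, (a, b) in enumerate(zip(cds, mutant)) if a != b]
        assert len(diffs) <= 3
        assert all(150 <= i < 153 for i in diffs)  # codon 51 is bases 150..152
        # translation differs at exactly the edited residue
        wt, mt = translate_cds(cds), translate_cds(mutant)
        aa_diffs = [i + 1 for i, (a, b) in enumerate(zip(wt, mt)) if a != b]
        assert aa_diffs == [51]

    def test_premature_stop_rejected(self, usage):
        # Met-stop-Ile: editing past the stop is refused
        with pytest.raises(ValueError, match="stop"):
            mutate_cds("ATGTAAATT", 3, "L", usage)

    def test_stop_replacement_rejected(self, usage):
        with pytest.raises(ValueError):
            mutate_cds("ATGATT", 2, "*", usage)

    def test_codon_tie_breaks_alphabetically(self):
        usage = CodonUsageTable(
            organism="tie",
            freq={"TTA": 0.5, "TTG": 0.5, "ATG": 1.0, "ATT": 1.0},
        )
        _, spec = mutate_cds("ATGATT", 2, "L", usage)
        assert spec.codon_new == "TTA"


class TestBuildLibrary:
    def test_printed_site_layout_gives_34_members(self, usage):
        cds = synthetic_repb_like_cds()
        table = repb_screen_table()
        sites = [
            (pos, grp["new_aa"].tolist())
            for pos, grp in table.groupby("position", sort=True)
        ]
        lib = build_library(cds, sites, usage)
        assert len(lib) == 34
        assert sorted({m.spec.position for m in lib.members}) == sorted(REPB_SITES)

    def test_empty_sites_gives_empty_library(self, usage):
        lib = build_library("ATGATT", [], usage)
        assert len(lib) == 0

    def test_product_count(self, usage):
        lib = build_library("ATGATTGTT", [(2, ["L", "K", "W"]), (3, ["A", "R", "T"])], usage)
        assert len(lib) == 6

    def test_members_unique_by_position_and_residue(self, usage):
        with pytest.raises(ValueError, match="duplicate"):
            build_library("ATGATT", [(2, ["L", "L"])], usage)

    def test_error_names_offending_site(self, usage):
        with pytest.raises(ValueError, match="site 2"):
            build_library("ATGATT", [(2, ["I"])], usage)  # silent edit

    def test_round_trip_translation_recovers_specs(self, usage):
        cds = synthetic_repb_like_cds()
        wt = translate_cds(cds)
        table = repb_screen_table()
        sites = [(p, g["new_aa"].tolist()) for p, g in table.groupby("position")]
        lib = build_library(cds, sites, usage)
        for member in lib.members:
            mt = translate_cds(member.cds)
            diffs = [
                (i + 1, a, b) for i, (a, b) in enumerate(zip(wt, mt)) if a != b
            ]
            assert diffs == [
                (member.spec.position, member.spec.old_aa, member.spec.new_aa)
            ]


class TestClassifyTsPhenotype:
    # the full 3x3 grid of growth-call combinations
    GRID = {
        ("+", "+"): Phenotype.ACTIVE,
        ("+", "+/-"): Phenotype.TS,
        ("+", "-"): Phenotype.TS,
        ("+/-", "+"): Phenotype.AMBIGUOUS,
        ("+/-", "+/-"): Phenotype.AMBIGUOUS,
        ("+/-", "-"): Phenotype.AMBIGUOUS,
        ("-", "+"): Phenotype.AMBIGUOUS,
        ("-", "+/-"): Phenotype.AMBIGUOUS,
        ("-", "-"): Phenotype.INACTIVE,
    }

    @pytest.mark.parametrize("g48,g58", list(itertools.product(["+", "+/-", "-"], repeat=2)))
    def test_total_over_call_grid(self, g48, g58):
        got = classify_ts_phenotype(GrowthCall(g48), GrowthCall(g58))
        assert got is self.GRID[(g48, g58)]

    def test_parse_tolerates_unicode_minus(self):
        assert GrowthCall.parse("+/−") is GrowthCall.INTERMEDIATE
        assert GrowthCall.parse("−") is GrowthCall.MINUS

    def test_parse_rejects_garbage(self):
        with pytest.raises(ValueError):
            GrowthCall.parse("++")


class TestScreenSummary:
    def test_printed_screen_has_six_ts(self, screen_records):
        summary = screen_summary(screen_records)
        assert summary["by_phenotype"]["Ts"] == 6
        assert {n.replace("770-", "") for n in summary["ts_names"]} == {
            "I51E", "M166A", "I289W", "I289L", "I289Y", "I320T",
        }

    def test_printed_screen_active_set(self, screen_records):
        # '+/+' rows: I51L, V83A, I320F, I320Y
        summary = screen_summary(screen_records)
        assert summary["by_phenotype"]["active"] == 4

    def test_intermediate_at_48_is_never_ts(self, screen_records):
        f124w = next(r for r in screen_records if r.name == "770-F124W")
        assert f124w.phenotype is Phenotype.AMBIGUOUS

    def test_counts_conserved(self, screen_records):
        summary = screen_summary(screen_records)
        assert sum(summary["by_phenotype"].values()) == summary["n"] == 34
        per_site = sum(
            sum(c.values()) for c in summary["by_site"].values()
        )
        assert per_site == 34

    def test_empty_input(self):
        summary = screen_summary([])
        assert summary["n"] == 0
        assert all(v == 0 for v in summary["by_phenotype"].values())

    def test_printed_inconsistency_is_flagged(self):
        assert "770-I51C" in SCREEN_TABLE_NOTES
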