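"""Haplotype assembly, family classification and census."""

import numpy as np
import pandas as pd
import pytest

from ylineage.haplotypes import (
    Haplotype,
    assign_families,
    build_haplotypes,
    classify_family,
    family_census,
    table_from_dataframe,
)
from ylineage.panel import zebu_panel
from ylineage.synth import FOUNDERS

from conftest import tiny_frame


def make_hap(bands2303=(), umn0307=149, **alleles):
    base = dict(FOUNDERS["Y3_A"][1])
    base["UMN0307"] = umn0307
    base.update(alleles)
    bands = {m: tuple(b) for m, b in FOUNDERS["Y3_A"][0].items()}
    bands["UMN2303"] = tuple(sorted(set(bands["UMN2303"]) - {124} | set(bands2303)))
    return Haplotype("h", bands, base, 1, ("P",))


class TestReadTable:
    def test_identity_read(self, tiny_panel):
        df = tiny_frame(
            [("a", "P1", (10,), 100, 200),
             ("b", "P1", (10, 11), 100, 202),
             ("c", "P2", (), 102, 200)],
            tiny_panel,
        )
        table = table_from_dataframe(df, tiny_panel)
        assert len(table) == 3
        assert not table.flagged.any()
        assert table.populations == ["P1", "P2"]

    def test_non_binary_band_is_fatal_with_address(self, tiny_panel):
        df = tiny_frame([("a", "P1", (10,), 100, 200)], tiny_panel)
        df.loc[0, "IMMX_b11"] = 2
        with pytest.raises(ValueError, match="IMMX_b11"):
            table_from_dataframe(df, tiny_panel)

    def test_unknown_marker_column_is_fatal(self, tiny_panel):
        df = tiny_frame([("a", "P1", (10,), 100, 200)], tiny_panel)
        df["L99"] = 1
        with pytest.raises(ValueError, match="L99"):
            table_from_dataframe(df, tiny_panel)

    def test_missing_calls_flagged_but_retained(self, tiny_panel):
        df = tiny_frame(
            [("a", "P1", (10,), 100, 200), ("b", "P1", (10,), None, 200)],
            tiny_panel,
        )
        table = table_from_dataframe(df, tiny_panel)
        assert len(table) == 2
        assert table.flagged.tolist() == [False, True]
        assert len(table.complete()) == 1

    def test_synthetic_round_trip(self, preset_table, preset_ledger, tmp_path):
        from ylineage.haplotypes import read_genotype_table, write_genotype_table

        path = tmp_path / "table.csv"
        write_genotype_table(preset_table, path)
        again = read_genotype_table(path, preset_table.panel)
        assert len(again) == 248
        assert sorted(again.populations) == sorted(
            preset_ledger.population.unique()
        )
        pd.testing.assert_frame_equal(
            again.data.sort_values("sample_id").reset_index(drop=True),
            preset_table.data.sort_values("sample_id").reset_index(drop=True),
            check_dtype=False,
        )


class TestBuildHaplotypes:
    def test_duplicate_rows_collapse(self, tiny_panel):
        df = tiny_frame(
            [("a", "P1", (10,), 100, 200), ("b", "P2", (10,), 100, 200),
             ("c", "P1", (11,), 100, 200), ("d", "P1", (10,), 102, 200)],
            tiny_panel,
        )
        haps = build_haplotypes(table_from_dataframe(df, tiny_panel))
        assert [h.multiplicity for h in haps] == [2, 1, 1]
        assert haps[0].populations == ("P1", "P2")

    def test_all_identical(self, tiny_panel):
        df = tiny_frame([(f"s{i}", "P1", (10,), 100, 200) for i in range(5)],
                        tiny_panel)
        haps = build_haplotypes(table_from_dataframe(df, tiny_panel))
        assert len(haps) == 1 and haps[0].multiplicity == 5

    def test_multiplicities_conserve_rows(self, preset_table):
        haps = build_haplotypes(preset_table.complete())
        assert sum(h.multiplicity for h in haps) == len(preset_table)

    def test_permutation_invariance(self, tiny_panel, rng):
        rows = [(f"s{i}", f"P{i % 3}", (10,) if i % 2 else (11,),
                 100 + 2 * (i % 4), 200) for i in range(20)]
        df = tiny_frame(rows, tiny_panel)
        haps = build_haplotypes(table_from_dataframe(df, tiny_panel))
        shuffled = df.sample(frac=1, random_state=3).reset_index(drop=True)
        haps2 = build_haplotypes(table_from_dataframe(shuffled, tiny_panel))
        assert [(h.hap_id, h.key, h.multiplicity) for h in haps] == [
            (h.hap_id, h.key, h.multiplicity) for h in haps2
        ]

    def test_flagged_rows_rejected(self, tiny_panel):
        df = tiny_frame([("a", "P1", (10,), None, 200)], tiny_panel)
        with pytest.raises(ValueError, match="missing"):
            build_haplotypes(table_from_dataframe(df, tiny_panel))


class TestClassifyFamily:
    @pytest.mark.parametrize(
        "bands2303,umn0307,expected",
        [
            ((127,), 149, "Y3_B"),       # any of 126/127/128 -> Y3_B
            ((126, 127, 128), 151, "Y3_B"),
            ((), 149, "Y3_A"),           # allele 149, no diagnostic bands
            ((124,), 151, "Y3_C"),       # no 149 plus band 124
            ((124,), 149, "Y3_A"),       # band 124 alone is not enough
            ((124, 126), 151, "Y3_B"),   # rule order: Y3_B wins
            ((), 151, "Y3_A"),
        ],
    )
    def test_band_rules(self, bands2303, umn0307, expected):
        assert classify_family(make_hap(bands2303, umn0307)) == expected

    def test_partition_is_total_and_exclusive(self, preset_table):
        haps = build_haplotypes(preset_table.complete())
        fams = {classify_family(h) for h in haps}
        assert fams <= {"Y3_A", "Y3_B", "Y3_C"}

    def test_override_wins(self, preset_table):
        haps = build_haplotypes(preset_table.complete())
        asg = assign_families(haps, overrides={haps[0].hap_id: "Y3_C"})
        assert asg[haps[0].hap_id] == "Y3_C"
        assert asg.source[haps[0].hap_id] == "override"


class TestFamilyCensus:
    def test_single_family_holds_everything(self, tiny_panel):
        df = tiny_frame([(f"s{i}", "P1", (10,), 100, 200) for i in range(4)],
                        tiny_panel)
        # a haplotype without diagnostic features classifies as Y3_A
        haps = build_haplotypes(table_from_dataframe(df, tiny_panel))
        census = family_census(assign_families(haps), haps)
        assert census.loc["Y3_A", "frac_samples"] == 1.0

    def test_counts_match_brute_force_tally(self, preset_table, preset_ledger):
        haps = build_haplotypes(preset_table.complete())
        asg = assign_families(haps)
        census = family_census(asg, haps)
        truth = preset_ledger.family.value_counts()
        for fam in ("Y3_A", "Y3_B", "Y3_C"):
            assert census.loc[fam, "n_samples"] == truth[fam]
        assert census.n_samples.sum() == 248
        assert census.frac_samples.sum() == pytest.approx(1.0)
        assert census.frac_haplotypes.sum() == pytest.approx(1.0)

    def test_planted_richness(self, preset_table):
        haps = build_haplotypes(preset_table.complete())
        census = family_census(assign_families(haps), haps)
        assert census.n_haplotypes.to_dict() == {
            "Y3_A": 26, "Y3_B": 12, "Y3_C": 9
        }
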