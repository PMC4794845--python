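import math

import numpy as np
import pytest
from scipy import stats as sps

from dpmquant.dpm_quant import (
    ModSiteQuant,
    aa_pair_profile,
    collect_site_quant,
    map_peptide_mods_to_protein,
    pair_matrix,
    proteome_dpm_rate,
    site_anova_table,
    site_group_comparison,
    stoichiometry,
)
from dpmquant.errors import DesignError, MappingError
from dpmquant.psm_io import GroupDesign


class TestSiteMapping:
    def test_offset_arithmetic(self, make_record):
        reference = "G" * 80 + "AQSTL" + "G" * 20
        record = make_record(peptide="AQSTL", mods=[(2, "Q", "Deamidated")])
        assert map_peptide_mods_to_protein(record, reference) == [
            (82, "Q", "Deamidated")
        ]

    def test_repeated_peptide_uses_first_occurrence(self, make_record, caplog):
        reference = "AAAQSTLGGGAQSTLGGG"
        record = make_record(peptide="AQSTL", mods=[(2, "Q", "Deamidated")])
        with caplog.at_level("WARNING"):
            mapped = map_peptide_mods_to_protein(record, reference)
        assert mapped == [(4, "Q", "Deamidated")]
        assert "first occurrence" in caplog.text

    def test_absent_peptide_is_mapping_error(self, make_record):
        record = make_record(peptide="AQSTL")
        with pytest.raises(MappingError):
            map_peptide_mods_to_protein(record, "GGGGGG")


class TestStoichiometry:
    def test_three_of_ten_distinct_peptides(self, make_record):
        records = [
            make_record(peptide=f"PEPTIDE{aa}Q", acc="MBP") for aa in "ACDEFGH"
        ] + [
            make_record(
                peptide=f"PEPTIDE{aa}Q", acc="MBP", mods=[(9, "Q", "Deamidated")]
            )
            for aa in "ILM"
        ]
        result = stoichiometry(records, "Deamidated", protein_acc="MBP")
        assert result.n_total == 10
        assert result.n_modified == 3
        assert result.pct_of_peptides == pytest.approx(30.0)

    def test_no_modified_peptides(self, make_record):
        records = [make_record(peptide="PEPTIDEQ")]
        assert stoichiometry(records, "Deamidated").pct_of_peptides == 0.0

    def test_invariant_to_duplicated_psms(self, make_record):
        base = [
            make_record(peptide="PEPTIDEQ"),
            make_record(peptide="NICEPEQ", mods=[(7, "Q", "Deamidated")]),
        ]
        one = stoichiometry(base, "Deamidated")
        dup = stoichiometry(base + base + base, "Deamidated")
        assert (one.n_modified, one.n_total) == (dup.n_modified, dup.n_total)


def _site(replicate_areas):
    site = ModSiteQuant("MBP", "Q", 82, "Deamidated")
    site.replicate_areas = dict(replicate_areas)
    return site


class TestSiteAnova:
    def test_identical_areas_give_null(self):
        site = _site(
            {(g, f"run{i}"): 10.0 for g in ("control", "female", "male") for i in (1, 2, 3)}
        )
        f, p = site_group_comparison(site)
        assert f == 0.0 and p == 1.0

    def test_hand_computed_f_statistic(self):
        groups = {
            "control": [10.0, 11.0, 9.0],
            "female": [30.0, 29.0, 31.0],
            "male": [10.0, 10.0, 11.0],
        }
        site = _site(
            {(g, f"run{i+1}"): v for g, vals in groups.items() for i, v in enumerate(vals)}
        )
        f, p = site_group_comparison(site)
        # Independent one-way ANOVA oracle from explicit sums of squares.
        all_vals = [v for vals in groups.values() for v in vals]
        grand = sum(all_vals) / len(all_vals)
        ss_between = sum(
            len(v) * (sum(v) / len(v) - grand) ** 2 for v in groups.values()
        )
        ss_within = sum(
            (x - sum(v) / len(v)) ** 2 for v in groups.values() for x in v
        )
        f_oracle = (ss_between / 2) / (ss_within / 6)
        assert f == pytest.approx(f_oracle, rel=1e-9)
        assert p < 0.05 and p * 3 < 0.05  # significant after Bonferroni x3

    def test_single_replicate_groups_excluded(self):
        site = _site({("control", "run1"): 10.0, ("female", "run1"): 30.0})
        f, p = site_group_comparison(site)
        assert math.isnan(f) and math.isnan(p)

    def test_table_applies_bonferroni(self):
        areas = {}
        for i in (1, 2, 3):
            areas[("control", f"run{i}")] = 10.0 + i
            areas[("female", f"run{i}")] = 30.0 + i
            areas[("male", f"run{i}")] = 10.0
        sites = [_site(areas)]
        df = site_anova_table(sites)
        assert (df["p_bonferroni"] >= df["p_raw"] - 1e-15).all()
        assert (df["p_bonferroni"] <= 1.0).all()


class TestProteomeDpmRate:
    def test_equal_rates_give_null_chi_square(self, make_record):
        records = [
            make_record(peptide="PEPTIDEQ", acc=f"P{i}",
                        mods=[(8, "Q", "Deamidated")] if i < 10 else [])
            for i in range(100)
        ]
        result = proteome_dpm_rate(records, GroupDesign(), "Deamidated")
        assert result.pct_by_group == {
            "control": 10.0, "female": 10.0, "male": 10.0
        }
        assert result.chi_square == pytest.approx(0.0, abs=1e-12)

    def test_two_by_two_oracle(self, make_record):
        # Pooled dementia 390 modified / 10000 vs control 352 / 10000.
        design = GroupDesign(channel_map={"114": "control", "116": "female"},
                             replicates=("run1",))
        records = []
        for i in range(10000):
            records.append(
                make_record(
                    peptide="PEPTIDEQ", acc=f"C{i}",
                    areas={"114": 10.0, "116": 0.0},
                    mods=[(8, "Q", "Deamidated")] if i < 352 else [],
                )
            )
            records.append(
                make_record(
                    peptide="PEPTIDEQ", acc=f"F{i}",
                    areas={"114": 0.0, "116": 10.0},
                    mods=[(8, "Q", "Deamidated")] if i < 390 else [],
                )
            )
        result = proteome_dpm_rate(records, design, "Deamidated")
        table = np.array([[390, 9610], [352, 9648]], dtype=float)
        row = table.sum(axis=1, keepdims=True)
        col = table.sum(axis=0, keepdims=True)
        expected = row * col / table.sum()
        chi2_oracle = ((table - expected) ** 2 / expected).sum()
        assert result.pct_by_group["female"] == pytest.approx(3.90)
        assert result.pct_by_group["control"] == pytest.approx(3.52)
        assert result.chi_square == pytest.approx(chi2_oracle, rel=1e-9)

    def test_doubled_dementia_rate_detected(self, make_record):
        design = GroupDesign(channel_map={"114": "control", "116": "female"})
        records = []
        for i in range(3000):
            records.append(
                make_record(peptide="PEPTIDEQ", acc=f"C{i}",
                            areas={"114": 10.0, "116": 0.0},
                            mods=[(8, "Q", "Deamidated")] if i < 90 else []))
            records.append(
                make_record(peptide="PEPTIDEQ", acc=f"F{i}",
                            areas={"114": 0.0, "116": 10.0},
                            mods=[(8, "Q", "Deamidated")] if i < 180 else []))
        result = proteome_dpm_rate(records, design, "Deamidated")
        assert result.p_value < 0.05

    def test_rate_invariant_to_area_scaling(self, make_record):
        records = [
            make_record(peptide="PEPTIDEQ", acc=f"P{i}",
                        mods=[(8, "Q", "Deamidated")] if i % 5 == 0 else [])
            for i in range(50)
        ]
        scaled = [
            make_record(peptide=r.peptide, acc=r.protein_acc, mods=r.mods,
                        areas={ch: a * 1e3 for ch, a in r.reporter_areas.items()})
            for r in records
        ]
        a = proteome_dpm_rate(records, GroupDesign(), "Deamidated")
        b = proteome_dpm_rate(scaled, GroupDesign(), "Deamidated")
        assert a.pct_by_group == b.pct_by_group

    def test_empty_group_is_design_error(self, make_record):
        records = [make_record(areas={"114": 10.0, "116": 0.0, "117": 0.0})]
        with pytest.raises(DesignError):
            proteome_dpm_rate(records, GroupDesign(), "Deamidated")


class TestAaPairProfile:
    def test_c_terminal_neighbor_pair(self, make_record, design):
        record = make_record(peptide="AQDR", mods=[(2, "Q", "Deamidated")])
        profiles = aa_pair_profile([record], design, "Deamidated")
        assert [p.pair for p in profiles] == [("Q", "D")]
        assert profiles[0].group_areas["female"] == pytest.approx(120.0)

    def test_terminal_modification_pairs_with_flank_marker(self, make_record, design):
        record = make_record(
            peptide="AQDR", mods=[(4, "R", "Citrullination")], nxt="-"
        )
        profiles = aa_pair_profile([record], design, "Citrullination")
        assert [p.pair for p in profiles] == [("R", "-")]

    def test_unobserved_pairs_absent(self, make_record, design):
        records = [
            make_record(peptide="ARGL", mods=[(2, "R", "Citrullination")])
            for _ in range(5)
        ]
        matrix = pair_matrix(
            aa_pair_profile(records, design, "Citrullination"), design
        )
        assert list(matrix.index) == ["R-G"]


class TestAreaConservation:
    def test_site_areas_sum_to_contributing_peptide_areas(self, make_record, design):
        reference = "G" * 10 + "AQSTL" + "G" * 10
        records = [
            make_record(peptide="AQSTL", acc="MBP", run=f"run{i}",
                        mods=[(2, "Q", "Deamidated")],
                        areas={"114": 10.0 * i, "116": 20.0 * i, "117": 5.0})
            for i in (1, 2, 3)
        ]
        sites = collect_site_quant(records, reference, design, "MBP")
        site = sites[(12, "Deamidated")]
        assert site.group_areas["control"] == pytest.approx(
            sum(r.area("114") for r in records), abs=1e-9
        )
        assert sum(
            area for (g, _), area in site.replicate_areas.items() if g == "female"
        ) == pytest.approx(site.group_areas["female"], abs=1e-9)
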