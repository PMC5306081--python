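"""Repeat-study grouping, concordance verdicts and summary fractions."""

import pytest

from draize.engine import Category, DriverCode, NoCatSubgroup
from draize.repro import (
    ChemicalGroup,
    ConcordanceLevel,
    StudyOutcome,
    concordance,
    group_repeats,
    summarize_concordance,
    table4_fixture,
    table5_fixture,
)


def _o(sid, chem, cat, driver=None, subgroup=None, assumed=None):
    return StudyOutcome(
        study_id=str(sid), chemical=chem, category=cat,
        main_driver=driver, nocat_subgroup=subgroup, scnm_assumed=assumed,
    )


class TestGrouping:
    def test_concentrations_are_distinct_chemicals(self):
        outcomes = [
            _o(1, "Triton X-100 (5 %)", Category.CAT2A, DriverCode.CO_MEAN_GE_1),
            _o(2, "Triton X-100 (5 %)", Category.CAT2A, DriverCode.CO_MEAN_GE_1),
            _o(3, "Triton X-100 (100 %)", Category.CAT1, DriverCode.CO_MEAN_GE_3),
            _o(4, "Triton X-100 (100 %)", Category.CAT1, DriverCode.CO_MEAN_GE_3),
        ]
        groups = group_repeats(outcomes)
        assert len(groups) == 2

    def test_unique_chemicals_form_no_groups(self):
        outcomes = [_o(i, f"chem{i}", Category.NOCAT) for i in range(5)]
        assert group_repeats(outcomes) == []

    def test_triples_stay_together(self):
        outcomes = [_o(i, "butox", Category.CAT1, DriverCode.CO_PERS_D21) for i in range(3)]
        (g,) = group_repeats(outcomes)
        assert g.n == 3


class TestVerdicts:
    def test_cat1_vs_cat2_discordant(self):
        g = ChemicalGroup("pyridine", [
            _o(13, "pyridine", Category.CAT1, DriverCode.CO_MEAN_GE_3),
            _o(184, "pyridine", Category.CAT2A, DriverCode.CO_MEAN_GE_1),
        ])
        assert concordance(g).level is ConcordanceLevel.DISCORDANT

    def test_same_class_same_driver(self):
        g = ChemicalGroup("dbta", [
            _o(26, "dbta", Category.CAT1, DriverCode.CO_MEAN_GE_3),
            _o(27, "dbta", Category.CAT1, DriverCode.CO_MEAN_GE_3),
        ])
        assert concordance(g).level is ConcordanceLevel.SAME_CLASS_SAME_DRIVER

    def test_2a_vs_2b_depends_on_unified_option(self):
        g = ChemicalGroup("methyl acetate", [
            _o(176, "methyl acetate", Category.CAT2A, DriverCode.CO_MEAN_GE_1),
            _o(225, "methyl acetate", Category.CAT2B, DriverCode.CO_MEAN_GE_1),
        ])
        assert concordance(g, unified_cat2=True).concordant
        assert concordance(g, unified_cat2=False).level is ConcordanceLevel.DISCORDANT

    def test_same_class_different_driver(self):
        g = ChemicalGroup("bcp", [
            _o(19, "bcp", Category.CAT1, DriverCode.CO_MEAN_GE_3),
            _o(84, "bcp", Category.CAT1, DriverCode.CO_PERS_D21),
        ])
        assert concordance(g).level is ConcordanceLevel.SAME_CLASS_DIFF_DRIVER

    def test_scnm_lower_bound_pair_is_uncertain(self):
        g = ChemicalGroup("opd", [
            _o(614, "opd", Category.SCNM, assumed="Cat 2A or higher"),
            _o(615, "opd", Category.SCNM, assumed="Cat 2A or higher"),
        ])
        assert concordance(g).level is ConcordanceLevel.UNCERTAIN

    def test_scnm_without_assumed_class_unusable(self):
        g = ChemicalGroup("x", [
            _o(1, "x", Category.SCNM),
            _o(2, "x", Category.NOCAT, subgroup=NoCatSubgroup.CO_EQ0),
        ])
        assert concordance(g, use_assumed_scnm=True).level is ConcordanceLevel.UNCERTAIN

    def test_lower_bound_vs_nocat_is_decidably_discordant(self):
        g = ChemicalGroup("toluene", [
            _o(321, "toluene", Category.NOCAT, subgroup=NoCatSubgroup.CO_GT0_STAR),
            _o(627, "toluene", Category.SCNM, assumed="at least Cat 2"),
        ])
        assert concordance(g).level is ConcordanceLevel.DISCORDANT

    def test_verdict_invariant_to_member_order(self):
        members = [
            _o(1, "x", Category.CAT1, DriverCode.CO_PERS_D21),
            _o(2, "x", Category.CAT2A, DriverCode.CO_MEAN_GE_1),
        ]
        g1 = ChemicalGroup("x", members)
        g2 = ChemicalGroup("x", list(reversed(members)))
        assert concordance(g1).level is concordance(g2).level

    def test_unified_concordance_at_least_split(self):
        # coarsening Cat 2 can only merge classes, never separate them
        cats = [Category.CAT1, Category.CAT2A, Category.CAT2B, Category.NOCAT]
        for c1 in cats:
            for c2 in cats:
                g = ChemicalGroup("x", [
                    _o(1, "x", c1, DriverCode.CO_PERS_D21,
                       subgroup=NoCatSubgroup.CO_EQ0 if c1 is Category.NOCAT else None),
                    _o(2, "x", c2, DriverCode.CO_PERS_D21,
                       subgroup=NoCatSubgroup.CO_EQ0 if c2 is Category.NOCAT else None),
                ])
                assert (
                    concordance(g, unified_cat2=True).concordant
                    >= concordance(g, unified_cat2=False).concordant
                )


class TestFixtures:
    def test_fixture_sizes(self):
        assert len(table4_fixture()) == 24
        assert len(table5_fixture()) == 18

    def test_uncertain_group_excluded_from_denominators(self):
        summary = summarize_concordance(table4_fixture())
        # 24 groups, one unusable: 16 + 7 enter the denominators
        assert summary["cat1_concordant"].denominator == 16
        assert summary["cat2max_concordant_unified"].denominator == 7

    def test_discordant_triple(self):
        (butox,) = [g for g in table4_fixture() if g.chemical == "Butoxyethanol"]
        assert concordance(butox).level is ConcordanceLevel.DISCORDANT

    def test_all_identical_outcomes_fraction_one(self):
        groups = [
            ChemicalGroup(f"c{i}", [
                _o(2 * i, f"c{i}", Category.CAT1, DriverCode.CO_PERS_D21),
                _o(2 * i + 1, f"c{i}", Category.CAT1, DriverCode.CO_PERS_D21),
            ])
            for i in range(4)
        ]
        summary = summarize_concordance(groups)
        assert summary["cat1_concordant"].pct == 100.0
        assert summary["classified_same_driver"].pct == 100.0

    def test_planted_discordance_rate_recovered(self):
        groups = []
        for i in range(10):
            second = (
                Category.CAT2A if i < 3 else Category.CAT1
            )  # plant 3 discordant of 10
            groups.append(
                ChemicalGroup(f"c{i}", [
                    _o(2 * i, f"c{i}", Category.CAT1, DriverCode.CO_PERS_D21),
                    _o(2 * i + 1, f"c{i}", second, DriverCode.CO_PERS_D21),
                ])
            )
        summary = summarize_concordance(groups)
        m = summary["cat1_concordant"]
        assert (m.numerator, m.denominator) == (7, 10)

    def test_denominators_sum_consistently(self):
        summary = summarize_concordance(table4_fixture() + table5_fixture())
        assert (
            summary["cat1_concordant"].denominator
            + summary["cat2max_concordant_unified"].denominator
            == summary["classified_concordant_unified"].denominator
        )
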