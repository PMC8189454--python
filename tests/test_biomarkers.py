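"""Biomarker rule engine: pattern matches, quorums and purity."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from potlipid import compounds as cmp
from potlipid.biomarkers import (
    detect_aquatic,
    detect_beeswax,
    detect_cereal_markers,
    detect_grape_wax,
    detect_heating,
    detect_pine,
    detect_plant_oil,
    detect_plant_wax,
    detect_ruminant_bacterial,
    detect_sterols,
    detect_taxon_ketones,
    dominance,
    phytanic_srr,
    run_all_rules,
)
from potlipid.types import PeakTable, ValidationError


def table(*peaks):
    return PeakTable(peaks)


class TestDominance:
    def test_strict_maximum_wins(self):
        t = table(cmp.alkane(27, 5), cmp.alkane(29, 10), cmp.alkane(31, 7))
        assert dominance(t, "n_alkane", 29)
        assert not dominance(t, "n_alkane", 31)

    def test_tie_is_not_dominance(self):
        t = table(cmp.alkane(29, 5), cmp.alkane(31, 5))
        assert not dominance(t, "n_alkane", 29)

    def test_empty_class_never_dominates(self):
        assert not dominance(table(), "n_alkane", 29)


class TestPlantWax:
    def test_alkanes_plus_alkanols_positive(self):
        t = table(
            cmp.alkane(27, 3), cmp.alkane(29, 9), cmp.alkane(31, 5),
            cmp.alkanol(26, 2), cmp.alkanol(28, 3),
        )
        res = detect_plant_wax(t)
        assert res.fired and res.strength == "positive"

    def test_alkanes_only_tentative(self):
        t = table(cmp.alkane(27, 3), cmp.alkane(29, 9), cmp.alkane(31, 5))
        res = detect_plant_wax(t)
        assert res.fired and res.strength == "tentative"

    def test_even_chain_alkanes_do_not_fire(self):
        t = table(cmp.alkane(26, 5), cmp.alkane(28, 9))
        assert not detect_plant_wax(t).fired


class TestTaxonKetones:
    def test_brassica_ketone_with_alcohol_positive(self):
        t = table(cmp.ketone(29, 15, 5), cmp.alkanol(29, 2, position=15))
        res = detect_taxon_ketones(t)["brassica"]
        assert res.fired and res.strength == "positive"

    def test_brassica_ketone_alone_tentative(self):
        res = detect_taxon_ketones(table(cmp.ketone(29, 15, 5)))["brassica"]
        assert res.fired and res.strength == "tentative"

    def test_leek_needs_ketone_and_matching_alkane(self):
        both = detect_taxon_ketones(table(cmp.ketone(31, 16, 5), cmp.alkane(31, 9)))
        assert both["leek"].fired
        ketone_only = detect_taxon_ketones(table(cmp.ketone(31, 16, 5)))
        assert not ketone_only["leek"].fired

    def test_fennel_ketone_is_never_more_than_tentative(self):
        res = detect_taxon_ketones(table(cmp.ketone(29, 10, 4)))["fennel_or_sermountain"]
        assert res.fired and res.strength == "tentative"


class TestHeating:
    def test_symmetric_ketone_series_fires(self):
        assert detect_heating(table(*cmp.heating_ketones(2.0))).fired

    def test_apaa_alone_fires(self):
        assert detect_heating(table(cmp.apaa(18, 1.0))).fired

    def test_brassica_ketone_does_not_fire(self):
        assert not detect_heating(table(cmp.ketone(29, 15, 5))).fired

    def test_leek_pair_does_not_fire(self):
        # hentriacontan-16-one doubles as the leek marker, so alone it is
        # never heating evidence
        assert not detect_heating(table(cmp.ketone(31, 16, 5), cmp.alkane(31, 9))).fired


class TestPlantOil:
    def test_high_oleic_ratio_with_linoleic_fires(self):
        t = table(
            cmp.fatty_acid(18, 5.0, unsaturation=1),
            cmp.fatty_acid(18, 2.0),
            cmp.fatty_acid(18, 0.5, unsaturation=2),
        )
        assert detect_plant_oil(t).fired

    def test_ratio_exactly_two_does_not_fire(self):
        t = table(
            cmp.fatty_acid(18, 4.0, unsaturation=1),
            cmp.fatty_acid(18, 2.0),
            cmp.fatty_acid(18, 0.5, unsaturation=2),
        )
        assert not detect_plant_oil(t).fired

    def test_missing_linoleic_blocks_the_call(self):
        t = table(cmp.fatty_acid(18, 6.0, unsaturation=1), cmp.fatty_acid(18, 2.0))
        assert not detect_plant_oil(t).fired

    def test_undefined_ratio_notes_and_abstains(self):
        res = detect_plant_oil(table(cmp.fatty_acid(18, 6.0, unsaturation=1)))
        assert not res.fired and res.notes


class TestBeeswax:
    def _components(self):
        alkanes = [cmp.alkane(25, 2), cmp.alkane(27, 9), cmp.alkane(29, 3)]
        fas = [cmp.fatty_acid(22, 2), cmp.fatty_acid(24, 6), cmp.fatty_acid(26, 2)]
        ols = [cmp.alkanol(26, 2), cmp.alkanol(30, 7), cmp.alkanol(32, 2)]
        wes = [cmp.wax_ester(44, 3), cmp.wax_ester(46, 2)]
        return alkanes, fas, ols, wes

    def test_full_suite_positive(self):
        a, f, o, w = self._components()
        res = detect_beeswax(table(*a, *f, *o, *w))
        assert res.fired and res.strength == "positive"

    def test_two_families_tentative(self):
        a, f, _, _ = self._components()
        res = detect_beeswax(table(*a, *f))
        assert res.fired and res.strength == "tentative"

    def test_single_family_not_fired(self):
        res = detect_beeswax(table(cmp.alkane(27, 9), cmp.alkane(25, 2)))
        assert not res.fired

    def test_c29_dominant_alkanes_do_not_count(self):
        res = detect_beeswax(table(cmp.alkane(27, 3), cmp.alkane(29, 9)))
        assert not res.fired


class TestPine:
    def test_dha_with_oxidation_product_positive(self):
        res = detect_pine(table(cmp.diterpenoid(cmp.DHA, 8), cmp.diterpenoid(cmp.OXO_DHA, 3)))
        assert res["pine_resin"].fired and res["pine_resin"].strength == "positive"
        assert not res["pitch"].fired

    def test_dha_alone_tentative(self):
        res = detect_pine(table(cmp.diterpenoid(cmp.DHA, 8)))
        assert res["pine_resin"].strength == "tentative"

    def test_retene_and_methyl_dha_mark_pitch(self):
        res = detect_pine(
            table(
                cmp.diterpenoid(cmp.DHA, 8),
                cmp.diterpenoid(cmp.RETENE, 4),
                cmp.diterpenoid(cmp.METHYL_DHA, 3),
            )
        )
        assert res["pine_resin"].fired and res["pitch"].fired

    def test_retene_without_resin_base_is_nothing(self):
        res = detect_pine(table(cmp.diterpenoid(cmp.RETENE, 4)))
        assert not res["pine_resin"].fired and not res["pitch"].fired


class TestAquatic:
    def test_long_apaas_with_two_isoprenoids_fire(self):
        t = table(
            cmp.apaa(20, 2),
            cmp.isoprenoid(cmp.PHYTANIC, 3),
            cmp.isoprenoid(cmp.TMTD, 2),
        )
        assert detect_aquatic(t).fired

    def test_isoprenoids_alone_abstain_with_note(self):
        t = table(cmp.isoprenoid(cmp.PHYTANIC, 3), cmp.isoprenoid(cmp.TMTD, 2))
        res = detect_aquatic(t)
        assert not res.fired and res.notes

    def test_short_apaas_do_not_count(self):
        t = table(
            cmp.apaa(18, 2),
            cmp.isoprenoid(cmp.PHYTANIC, 3),
            cmp.isoprenoid(cmp.TMTD, 2),
        )
        assert not detect_aquatic(t).fired

    def test_empty_table_does_not_fire(self):
        assert not detect_aquatic(table()).fired


class TestPhytanicSrr:
    @pytest.mark.parametrize("srr,rrr,pct", [(1, 1, 50.0), (3, 1, 75.0), (0, 2, 0.0)])
    def test_percentage(self, srr, rrr, pct):
        value, _ = phytanic_srr(srr, rrr)
        assert value == pytest.approx(pct)

    def test_overlapping_windows_report_overlap(self):
        _, call = phytanic_srr(3, 2)  # 60% sits in both default windows
        assert call == "overlap"

    def test_both_zero_is_undefined(self):
        with pytest.raises(ValidationError):
            phytanic_srr(0, 0)


class TestSmallRules:
    def test_sterol_calls(self):
        res = detect_sterols(table(cmp.sterol(cmp.CHOLESTEROL, 2)))
        assert res["animal_sterol"].fired and not res["plant_sterol"].fired
        res = detect_sterols(table(cmp.sterol(cmp.B_SITOSTEROL, 2)))
        assert res["plant_sterol"].fired and not res["animal_sterol"].fired

    def test_spinach_sterols_raise_a_note(self):
        res = detect_sterols(table(cmp.sterol(cmp.A_SPINASTEROL, 1)))
        assert any("spinach" in n for n in res["plant_sterol"].notes)

    def test_cereal_and_millet_single_compound_rules(self):
        res = detect_cereal_markers(table(cmp.alkylresorcinol(21, 1)))
        assert res["cereal"].fired and not res["millet"].fired
        res = detect_cereal_markers(table(cmp.miliacin(2)))
        assert res["millet"].fired and not res["cereal"].fired

    def test_ruminant_bacterial_needs_branched_and_linear(self):
        fired = detect_ruminant_bacterial(
            table(cmp.branched_fatty_acid(15, 1), cmp.fatty_acid(17, 1))
        )
        assert fired.fired
        assert not detect_ruminant_bacterial(table(cmp.fatty_acid(15, 1))).fired
        full = detect_ruminant_bacterial(
            table(
                cmp.branched_fatty_acid(15, 1),
                cmp.branched_fatty_acid(17, 1),
                cmp.fatty_acid(15, 1),
                cmp.fatty_acid(17, 1),
            )
        )
        assert len(full.evidence) == 4

    @pytest.mark.parametrize(
        "alkanes,fires",
        [
            ({25: 10, 27: 4, 29: 2}, True),
            ({27: 10, 25: 4}, False),
            ({25: 5, 27: 5}, False),
        ],
    )
    def test_grape_wax_requires_strict_c25_dominance(self, alkanes, fires):
        t = table(*(cmp.alkane(c, a) for c, a in alkanes.items()))
        assert detect_grape_wax(t).fired == fires


# pool of marker peaks for property tests (distinct structural keys)
_marker_pool = [
    cmp.alkane(29, 9.0),
    cmp.alkane(27, 3.0),
    cmp.alkanol(26, 2.0),
    cmp.ketone(29, 15, 5.0),
    cmp.diterpenoid(cmp.DHA, 8.0),
    cmp.diterpenoid(cmp.OXO_DHA, 3.0),
    cmp.isoprenoid(cmp.PHYTANIC, 3.0),
    cmp.apaa(20, 2.0),
    cmp.sterol(cmp.CHOLESTEROL, 2.0),
    cmp.fatty_acid(18, 6.0, unsaturation=1),
    cmp.fatty_acid(18, 2.0),
    cmp.miliacin(2.0),
]

# additions that touch no dominance-scored compound class
_neutral_pool = [
    cmp.sterol(cmp.B_SITOSTEROL, 1.0),
    cmp.alkylresorcinol(21, 1.0),
    cmp.isoprenoid(cmp.TMTD, 2.0),
    cmp.branched_fatty_acid(15, 0.5),
    cmp.wax_ester(44, 1.0),
]


class TestEngineProperties:
    @given(st.sets(st.sampled_from(range(len(_marker_pool))), max_size=8))
    def test_rules_are_pure_and_deterministic(self, idxs):
        t = table(*(_marker_pool[i] for i in sorted(idxs)))
        first = run_all_rules(t)
        second = run_all_rules(t)
        assert {k: (v.fired, v.strength, v.evidence) for k, v in first.items()} == {
            k: (v.fired, v.strength, v.evidence) for k, v in second.items()
        }

    @given(
        st.sets(st.sampled_from(range(len(_marker_pool))), max_size=8),
        st.sets(st.sampled_from(range(len(_neutral_pool))), min_size=1, max_size=4),
    )
    def test_extra_unrelated_peaks_never_unfire_a_rule(self, idxs, extra_idxs):
        base_peaks = [_marker_pool[i] for i in sorted(idxs)]
        extras = [
            _neutral_pool[i]
            for i in sorted(extra_idxs)
            if _neutral_pool[i].key not in {p.key for p in base_peaks}
        ]
        before = run_all_rules(table(*base_peaks))
        after = run_all_rules(table(*base_peaks, *extras))
        for rule_id, res in before.items():
            if res.fired:
                assert after[rule_id].fired, rule_id

    def test_exact_pattern_matching_has_unit_sensitivity_and_specificity(self, specs):
        """Each commodity's marker set fires its own rules and no taxon rule
        of any other commodity, across all injected marker sets."""
        flag_rules = {
            "plant_oil", "beeswax", "aquatic", "cereal", "millet",
            "brassica", "leek", "fennel_or_sermountain", "pine_resin", "pitch",
        }
        for label, spec in specs.items():
            if not spec.markers:
                continue
            results = run_all_rules(PeakTable(spec.markers))
            for rule_id in flag_rules:
                expected = rule_id in spec.expected_flags
                assert results[rule_id].fired == expected, (label, rule_id)
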