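"""The 11-comparison matching table and the response-harmonization rules."""

import itertools
import json
import logging

import pytest

from amstar_robis import (
    DesignMix,
    Response,
    comparison_table,
    coverage_stats,
    harmonize_all,
    unmatched_items,
)
from amstar_robis.harmonization import (
    HarmonizationError,
    Rule,
    harmonize_amstar_default,
    harmonize_one,
    harmonize_robis_default,
    harmonize_rule_b,
    harmonize_rule_c,
    harmonize_rule_e,
    harmonize_rule_f,
    table_from_json,
    table_to_json,
)

from helpers import (
    ROBIS_TOKENS,
    make_assessment,
    oracle_default,
    oracle_rule_b,
    oracle_rule_c,
    oracle_rule_e,
    oracle_rule_f,
)

R = Response
TABLE = comparison_table()


class TestCanonicalTable:
    def test_eleven_comparisons_with_expected_item_sets(self):
        assert len(TABLE) == 11
        amstar = {i for s in TABLE for i in s.amstar_items}
        robis = {i for s in TABLE for i in s.robis_items}
        assert amstar == {"1", "2", "4", "5", "6", "8", "9", "11", "12", "13", "14", "15"}
        assert robis == {"1.1", "1.3", "2.1", "2.2", "2.3", "2.4", "2.5",
                         "3.1", "3.2", "3.4", "4.3", "4.4", "4.5", "4.6"}

    def test_robis_44_serves_two_comparisons(self):
        users = [s.comparison_id for s in TABLE if "4.4" in s.robis_items]
        assert len(users) == 2

    def test_overlap_flags_and_weighting(self):
        assert sum(s.fully_overlapping for s in TABLE) == 10
        partial = [s for s in TABLE if not s.fully_overlapping]
        assert len(partial) == 1 and partial[0].amstar_items == ("15",)
        quadratic = [s for s in TABLE if s.weighting == "QUADRATIC"]
        assert len(quadratic) == 1 and quadratic[0].amstar_items == ("4",)

    def test_domain_layout(self):
        assert [s.domain for s in TABLE] == [1, 1, 2, 2, 3, 3, 3, 4, 4, 4, 4]

    def test_coverage_stats(self):
        stats = coverage_stats(TABLE)
        assert stats.n_comparisons == 11
        assert stats.n_amstar_matched == 12
        assert stats.n_robis_matched == 14
        assert stats.pct_items_matched == 70.3
        assert stats.n_fully_overlapping == 10

    def test_coverage_stats_empty_table(self):
        stats = coverage_stats(())
        assert (stats.n_comparisons, stats.n_amstar_matched, stats.n_robis_matched,
                stats.pct_items_matched, stats.n_fully_overlapping) == (0, 0, 0, 0.0, 0)

    def test_unmatched_items(self):
        amstar_un, robis_un = unmatched_items()
        assert amstar_un == ("3", "7", "10", "16")
        assert robis_un == ("1.2", "1.4", "1.5", "3.3", "3.5", "4.1", "4.2")

    def test_table_json_round_trip(self):
        assert table_from_json(table_to_json()) == TABLE
        payload = json.loads(table_to_json())
        assert [d["comparison_id"] for d in payload] == list(range(1, 12))


class TestDefaultRule:
    @pytest.mark.parametrize("token, expected", [
        (R.Y, "POS"), (R.PY, "POS"), (R.PN, "NEG"), (R.N, "NEG"), (R.NI, "NEG"),
    ])
    def test_robis_side(self, token, expected):
        assert harmonize_robis_default(token) == expected

    def test_na_is_not_a_robis_code(self):
        with pytest.raises(HarmonizationError):
            harmonize_robis_default(R.NA)

    def test_amstar_side(self):
        assert harmonize_amstar_default(R.Y, False) == "POS"
        assert harmonize_amstar_default(R.N, False) == "NEG"
        assert harmonize_amstar_default(R.PY, True) == "POS"
        with pytest.raises(HarmonizationError):
            harmonize_amstar_default(R.PY, False)


class TestRuleB:
    @pytest.mark.parametrize("tokens, expected", [
        ((R.Y, R.Y, R.Y, R.PY), "Y"),
        ((R.N, R.Y, R.Y, R.PY), "PY"),
        ((R.Y, R.Y, R.N, R.Y), "N"),
        ((R.NI, R.PN, R.PY, R.Y), "PY"),
    ])
    def test_examples(self, tokens, expected):
        assert harmonize_rule_b(*tokens) == expected

    def test_exhaustive_625_tuples(self):
        for tokens in itertools.product([R(t) for t in ROBIS_TOKENS], repeat=4):
            assert harmonize_rule_b(*tokens) == oracle_rule_b(
                tuple(t.value for t in tokens))

    def test_missing_subitem_named(self):
        with pytest.raises(HarmonizationError, match="2.3"):
            harmonize_rule_b(R.Y, R.Y, None, R.Y)

    def test_monotone_under_subitem_upgrades(self):
        """Upgrading any sub-item (negative -> PY -> Y) never lowers the
        composite on the order N < PY < Y."""
        order = {"N": 0, "PY": 1, "Y": 2}
        level = {R.Y: 2, R.PY: 1, R.PN: 0, R.N: 0, R.NI: 0}
        upgrades = {R.PN: [R.PY, R.Y], R.N: [R.PY, R.Y], R.NI: [R.PY, R.Y],
                    R.PY: [R.Y], R.Y: []}
        for tokens in itertools.product([R(t) for t in ROBIS_TOKENS], repeat=4):
            base = order[harmonize_rule_b(*tokens)]
            for pos in range(4):
                for up in upgrades[tokens[pos]]:
                    if level[up] <= level[tokens[pos]]:
                        continue
                    new = list(tokens)
                    new[pos] = up
                    assert order[harmonize_rule_b(*new)] >= base


class TestRuleC:
    def test_examples(self):
        both = DesignMix.BOTH
        assert harmonize_rule_c({"RCT": R.Y, "NRSI": R.PY}, R.Y, both) == ("POS", "POS")
        assert harmonize_rule_c({"RCT": R.Y, "NRSI": R.N}, R.PY, both) == ("NEG", "POS")
        assert harmonize_rule_c(R.PY, R.NI, DesignMix.RCT_ONLY) == ("POS", "NEG")

    def test_exhaustive(self):
        tokens9 = [R.Y, R.PY, R.N]
        for design in (DesignMix.RCT_ONLY, DesignMix.NRSI_ONLY):
            for a9, r34 in itertools.product(tokens9, [R(t) for t in ROBIS_TOKENS]):
                assert harmonize_rule_c(a9, r34, design) == oracle_rule_c(
                    a9.value, r34.value, design)
        for rct, nrsi in itertools.product(tokens9, repeat=2):
            for r34 in [R(t) for t in ROBIS_TOKENS]:
                a9 = {"RCT": rct, "NRSI": nrsi}
                expected = oracle_rule_c(
                    {"RCT": rct.value, "NRSI": nrsi.value}, r34.value, DesignMix.BOTH)
                assert harmonize_rule_c(a9, r34, DesignMix.BOTH) == expected

    def test_missing_stratum(self):
        with pytest.raises(HarmonizationError, match="stratum"):
            harmonize_rule_c({"RCT": R.Y}, R.Y, DesignMix.BOTH)

    def test_equals_default_rule_for_single_design(self):
        for a9 in (R.Y, R.PY, R.N):
            for r34 in [R(t) for t in ROBIS_TOKENS]:
                assert harmonize_rule_c(a9, r34, DesignMix.RCT_ONLY) == (
                    harmonize_amstar_default(a9, True),
                    harmonize_robis_default(r34),
                )


class TestRuleE:
    def test_not_considered_without_ma(self):
        assert harmonize_rule_e(R.NA, R.Y, R.Y, False, DesignMix.RCT_ONLY) is None

    def test_examples(self):
        assert harmonize_rule_e(R.Y, R.PY, R.Y, True, DesignMix.RCT_ONLY) == ("POS", "POS")
        assert harmonize_rule_e(R.N, R.Y, R.Y, True, DesignMix.RCT_ONLY) == ("NEG", "POS")

    def test_exhaustive_all_and_any_modes(self):
        robis = [R(t) for t in ROBIS_TOKENS]
        for combine in ("ALL", "ANY"):
            for design in (DesignMix.RCT_ONLY, DesignMix.NRSI_ONLY):
                for a11, r43, r44 in itertools.product([R.Y, R.N], robis, robis):
                    assert harmonize_rule_e(
                        a11, r43, r44, True, design, robis_combine=combine
                    ) == oracle_rule_e(a11.value, r43.value, r44.value, True,
                                       design, combine)
            for rct, nrsi in itertools.product([R.Y, R.N], repeat=2):
                for r43, r44 in itertools.product(robis, repeat=2):
                    a11 = {"RCT": rct, "NRSI": nrsi}
                    expected = oracle_rule_e(
                        {"RCT": rct.value, "NRSI": nrsi.value},
                        r43.value, r44.value, True, DesignMix.BOTH, combine)
                    assert harmonize_rule_e(
                        a11, r43, r44, True, DesignMix.BOTH, robis_combine=combine
                    ) == expected

    def test_single_design_equals_default_on_conjunction(self):
        """With a meta-analysis and one design, the rule is the default rule
        applied to item 11 against (4.3 AND 4.4)."""
        robis = [R(t) for t in ROBIS_TOKENS]
        for a11, r43, r44 in itertools.product([R.Y, R.N], robis, robis):
            got = harmonize_rule_e(a11, r43, r44, True, DesignMix.NRSI_ONLY)
            conj = ("POS" if harmonize_robis_default(r43) == "POS"
                    and harmonize_robis_default(r44) == "POS" else "NEG")
            assert got == (harmonize_amstar_default(a11, False), conj)

    def test_invalid_combine_mode(self):
        with pytest.raises(ValueError):
            harmonize_rule_e(R.Y, R.Y, R.Y, True, DesignMix.RCT_ONLY,
                             robis_combine="SOME")


class TestRuleF:
    def test_examples(self):
        assert harmonize_rule_f(R.NA, R.Y, R.PY, False) == ("POS", "POS")
        assert harmonize_rule_f(R.N, R.Y, R.Y, True) == ("NEG", "POS")
        assert harmonize_rule_f(R.Y, R.Y, R.NI, True) == ("POS", "NEG")

    def test_exhaustive(self):
        robis = [R(t) for t in ROBIS_TOKENS]
        for a12, a13, r46 in itertools.product([R.Y, R.N], [R.Y, R.N], robis):
            assert harmonize_rule_f(a12, a13, r46, True) == oracle_rule_f(
                a12.value, a13.value, r46.value, True)
        for a13, r46 in itertools.product([R.Y, R.N], robis):
            assert harmonize_rule_f(R.NA, a13, r46, False) == oracle_rule_f(
                "NA", a13.value, r46.value, False)

    def test_na_consistency_enforced(self):
        with pytest.raises(HarmonizationError):
            harmonize_rule_f(R.NA, R.Y, R.Y, True)
        with pytest.raises(HarmonizationError):
            harmonize_rule_f(R.Y, R.Y, R.Y, False)


class TestHarmonizeAll:
    def test_no_gating_when_all_reviews_have_ma(self):
        cohort = [make_assessment(review_id=f"r{i}") for i in range(12)]
        result = harmonize_all(cohort)
        assert all(hp.n_applicable == 12 and hp.n_excluded == 0
                   for hp in result.values())

    def test_ma_gated_comparisons_exclude_no_ma_reviews(self):
        cohort = [make_assessment(review_id=f"r{i}", has_ma=i >= 4)
                  for i in range(10)]
        result = harmonize_all(cohort)
        for cid in (8, 11):
            assert result[cid].n_applicable == 6
            assert result[cid].n_excluded == 4
        # item 12 gating folds into the comparison rather than excluding it
        assert result[9].n_applicable == 10
        for hp in result.values():
            assert hp.n_applicable + hp.n_excluded == 10

    def test_all_positive_cohort_is_fully_concordant(self):
        cohort = [make_assessment(review_id=f"r{i}",
                                  design=DesignMix.BOTH if i % 2 else DesignMix.RCT_ONLY)
                  for i in range(6)]
        result = harmonize_all(cohort)
        for hp in result.values():
            assert all(a == b for a, b in hp.pairs)

    def test_invalid_review_dropped_with_warning(self, caplog):
        good = make_assessment(review_id="good")
        bad = make_assessment(review_id="bad", amstar={"1": Response.PY})
        with caplog.at_level(logging.WARNING):
            result = harmonize_all([good, bad, good])
        assert result[1].n_applicable == 2
        assert any("bad" in rec.getMessage() for rec in caplog.records)

    def test_rule_error_carries_review_context(self):
        pa = make_assessment(review_id="rX")
        pa.robis["1.3"] = Response.NA  # bypass validation to hit rule error
        with pytest.raises(HarmonizationError, match="rX"):
            harmonize_all([pa], validate=False)

    def test_pairs_respect_declared_scale(self):
        cohort = [make_assessment(review_id=f"r{i}",
                                  amstar={"4": Response.PY},
                                  robis={"2.1": Response.N})
                  for i in range(3)]
        result = harmonize_all(cohort)
        for spec in TABLE:
            hp = result[spec.comparison_id]
            for a, b in hp.pairs:
                assert a in spec.scale and b in spec.scale


class TestHarmonizeOne:
    def test_rule_dispatch_matches_oracles_on_a_mixed_review(self):
        pa = make_assessment(
            design=DesignMix.BOTH,
            amstar={"4": Response.PY, "13": Response.N,
                    "9": {"RCT": Response.Y, "NRSI": Response.PY},
                    "11": {"RCT": Response.Y, "NRSI": Response.Y}},
            robis={"2.2": Response.PN, "4.6": Response.NI},
        )
        by_id = {s.comparison_id: s for s in TABLE}
        assert harmonize_one(by_id[3], pa) == ("PY", "PY")
        assert harmonize_one(by_id[7], pa) == ("POS", "POS")
        assert harmonize_one(by_id[8], pa) == ("POS", "POS")
        assert harmonize_one(by_id[9], pa) == ("NEG", "NEG")

    def test_rule_a_collapses_py(self):
        pa = make_assessment(amstar={"2": Response.PY}, robis={"1.1": Response.PY})
        by_id = {s.comparison_id: s for s in TABLE}
        assert harmonize_one(by_id[2], pa) == ("POS", "POS")
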