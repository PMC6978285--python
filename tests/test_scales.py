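"""Sum and decision-tree scale scoring: printed ranges, oracles, invariants."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import interrai_mh as m
from interrai_mh.errors import ConfigError
from interrai_mh.scales import TreeNode

from conftest import make_record

PRINTED_MAXIMA = {
    "positive_symptoms": 12,
    "depressive_severity": 15,
    "adl": 16,
    "cage": 4,
    "negative_symptoms": 12,
    "aggressive_behavior": 12,
    "mania": 20,
    "iadl": 30,
    "pain": 4,
}


class TestSumScales:
    def test_all_zero_components_score_zero(self, registry, scale_defs):
        rec = make_record(registry, level="min")
        for name in PRINTED_MAXIMA:
            assert m.score_sum_scale(rec, scale_defs[name]).value == 0

    @pytest.mark.parametrize("name,expected", sorted(PRINTED_MAXIMA.items()))
    def test_max_coded_record_hits_printed_maximum(self, registry, scale_defs, name, expected):
        rec = make_record(registry, level="max")
        score = m.score_sum_scale(rec, scale_defs[name])
        assert score.value == expected == scale_defs[name].out_max

    def test_random_records_match_naive_summation(self, registry, scale_defs, rng):
        recs = m.random_records(registry, "MH", 1000, np.random.default_rng(77))
        for rec in recs:
            for name in PRINTED_MAXIMA:
                sdef = scale_defs[name]
                got = m.score_sum_scale(rec, sdef).value
                expected = 0
                for c in sdef.components:  # independent brute-force loop
                    expected += rec.responses[c]
                assert got == expected

    def test_missing_component_yields_missing_value(self, registry, scale_defs):
        rec = make_record(registry, level="max")
        del rec.responses["hallucinations"]
        score = m.score_sum_scale(rec, scale_defs["positive_symptoms"])
        assert score.value is None
        assert not score.complete
        assert score.n_missing_components == 1

    def test_prorating_scales_up_observed_mean(self, registry, scale_defs):
        rec = make_record(registry, level="min")
        sdef = scale_defs["depressive_severity"]
        for c in sdef.components[:4]:
            rec.responses[c] = 2
        del rec.responses[sdef.components[4]]
        score = m.score_sum_scale(rec, sdef, prorate=True)
        assert score.value == 10  # 8 observed over 4 of 5 items -> 10
        assert score.n_missing_components == 1

    def test_component_cap_variant_range(self, scale_defs):
        assert scale_defs["aggressive_behavior_0_8"].out_max == 8

    @given(st.integers(0, 3), st.integers(0, 3), st.integers(0, 3), st.integers(0, 3))
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariance(self, a, b, c, d):
        reg = m.build_registry()
        defs = m.load_scale_defs(registry=reg)
        sdef = defs["positive_symptoms"]
        values = [a, b, c, d]
        base = make_record(reg)
        scores = set()
        for shift in range(4):
            rotated = values[shift:] + values[:shift]
            base.responses.update(dict(zip(sdef.components, rotated)))
            scores.add(m.score_sum_scale(base, sdef).value)
        assert len(scores) == 1

    def test_unit_monotonicity(self, registry, scale_defs):
        sdef = scale_defs["negative_symptoms"]
        rec = make_record(registry, level="min")
        for c in sdef.components:
            before = m.score_sum_scale(rec, sdef).value
            rec.responses[c] += 1
            after = m.score_sum_scale(rec, sdef).value
            assert after == before + 1


def _enumerate_paths(node, assignment, lookup_range):
    """Exhaustive path oracle: all (constraint-set, leaf) pairs of a tree."""
    if not isinstance(node, TreeNode):
        yield dict(assignment), node
        return
    yield from _enumerate_paths(node.then, {**assignment, (node.var, node.op, node.value): True}, lookup_range)
    yield from _enumerate_paths(node.otherwise, {**assignment, (node.var, node.op, node.value): False}, lookup_range)


class TestTreeScales:
    TREES = ["cognitive_performance", "risk_harm_others", "self_care_index", "self_harm_severity"]

    @pytest.mark.parametrize("name", TREES)
    def test_intact_record_scores_zero(self, registry, scale_defs, name):
        rec = make_record(registry, level="min")
        scores = m.score_all(rec, scale_defs)
        assert scores[name].value == 0

    @pytest.mark.parametrize("name", TREES)
    def test_worst_record_scores_six(self, registry, scale_defs, name):
        rec = make_record(registry, level="max")
        scores = m.score_all(rec, scale_defs)
        assert scores[name].value == 6

    @pytest.mark.parametrize("name", TREES)
    def test_full_severity_range_reachable(self, scale_defs, name):
        leaves = scale_defs[name].tree.leaves()
        assert leaves == set(range(7))

    def test_tree_output_matches_path_walk_oracle(self, registry, scale_defs):
        """1,000 random records: engine leaf equals an independent re-walk."""
        recs = m.random_records(registry, "MH", 1000, np.random.default_rng(123))
        from interrai_mh.scales import _OPS

        for rec in recs:
            scores = m.score_all(rec, scale_defs)
            for name in self.TREES:
                sdef = scale_defs[name]
                node = sdef.tree
                while isinstance(node, TreeNode):  # independent walk
                    kind, _, var = node.var.partition(":")
                    value = rec.responses[var] if kind == "item" else scores[var].value
                    node = node.then if _OPS[node.op](value, node.value) else node.otherwise
                assert scores[name].value == node

    def test_missing_tree_input_yields_missing_score(self, registry, scale_defs):
        rec = make_record(registry, level="max")
        del rec.responses["daily_decision_making"]
        scores = m.score_all(rec, scale_defs)
        assert scores["cognitive_performance"].value is None

    def test_tree_determinism(self, registry, scale_defs):
        recs = m.random_records(registry, "MH", 20, np.random.default_rng(5))
        for rec in recs:
            a = m.score_all(rec, scale_defs)
            b = m.score_all(rec, scale_defs)
            assert {k: v.value for k, v in a.items()} == {k: v.value for k, v in b.items()}

    def test_tree_referencing_undeclared_variable_fails_at_load(self, registry):
        cfg = [
            {
                "name": "bad_tree",
                "kind": "decision_tree",
                "components": ["hallucinations"],
                "instruments": ["MH"],
                "tree": {"var": "item:delusions", "op": ">=", "value": 1, "then": 1, "else": 0},
            }
        ]
        with pytest.raises(ConfigError, match="undeclared"):
            m.load_scale_defs(cfg, registry=registry)


class TestScoreAll:
    def test_mh_record_yields_thirteen_scales(self, registry, scale_defs):
        rec = make_record(registry, level="max")
        assert len(m.score_all(rec, scale_defs)) == 13

    def test_bmhs_record_yields_only_positive_symptoms(self, registry, scale_defs):
        rec = make_record(registry, instrument="BMHS", level="max")
        scores = m.score_all(rec, scale_defs)
        assert set(scores) == {"positive_symptoms"}

    def test_esp_record_omits_uncollected_scales(self, registry, scale_defs):
        rec = make_record(registry, instrument="ESP", level="max")
        scores = m.score_all(rec, scale_defs)
        assert "iadl" not in scores and "cage" not in scores and "pain" not in scores

    def test_empty_responses_all_missing(self, registry, scale_defs):
        rec = m.AssessmentRecord("p", "MH", "admission", dt.date(2017, 1, 1), {})
        scores = m.score_all(rec, scale_defs)
        assert len(scores) == 13
        assert all(s.value is None and not s.complete for s in scores.values())

    def test_range_conformance_on_random_cohort(self, registry, scale_defs):
        recs = m.random_records(registry, "MH", 300, np.random.default_rng(8), response_rate=0.9)
        for rec in recs:
            for name, score in m.score_all(rec, scale_defs).items():
                if score.value is not None:
                    sdef = scale_defs[name]
                    assert sdef.out_min <= score.value <= sdef.out_max
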