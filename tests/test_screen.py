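import pytest
from hypothesis import given, settings, strategies as st

from scamscan.data import synthetic_compound_table_path
from scamscan.metrics import AGGREGATOR, NON_AGGREGATOR
from scamscan.screen import (
    CompoundRecord,
    compare_methods,
    md_calls_from_table,
    read_compound_table,
    success_rate,
    threshold_classify,
)


@pytest.fixture(scope="module")
def fixture_records():
    return read_compound_table(synthetic_compound_table_path())


class TestThresholdClassify:
    def test_logd_2p8_and_1p3_called_non_aggregators(self):
        records = [
            CompoundRecord("31", logd=2.8, label=NON_AGGREGATOR),
            CompoundRecord("32", logd=1.3, label=NON_AGGREGATOR),
        ]
        result = threshold_classify(records, "logd", 3.0)
        assert result.predictions == {"31": NON_AGGREGATOR, "32": NON_AGGREGATOR}
        assert result.success_rate_percent == 100.0

    def test_boundary_value_is_strict(self):
        result = threshold_classify([CompoundRecord("x", logd=3.0)], "logd", 3.0)
        assert result.predictions["x"] == NON_AGGREGATOR
        inclusive = threshold_classify(
            [CompoundRecord("x", logd=3.0)], "logd", 3.0, inclusive=True
        )
        assert inclusive.predictions["x"] == AGGREGATOR

    def test_less_means_aggregator_direction(self):
        records = [CompoundRecord("a", tpsa=30.0), CompoundRecord("b", tpsa=120.0)]
        result = threshold_classify(
            records, "tpsa", 60.0, direction="less_means_aggregator"
        )
        assert result.predictions == {"a": AGGREGATOR, "b": NON_AGGREGATOR}

    def test_missing_descriptor_skipped_and_reported(self):
        records = [CompoundRecord("a", logd=4.0), CompoundRecord("b")]
        result = threshold_classify(records, "logd", 3.0)
        assert result.skipped == ("b",)
        assert "b" not in result.predictions

    def test_unknown_descriptor_lists_columns(self):
        with pytest.raises(KeyError, match="logp"):
            threshold_classify([CompoundRecord("a", logd=1.0)], "molweight", 3.0)

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-5, 10, allow_nan=False), min_size=1, max_size=20))
    def test_extreme_thresholds_label_uniformly(self, values):
        records = [CompoundRecord(str(i), logd=v) for i, v in enumerate(values)]
        below = threshold_classify(records, "logd", min(values) - 1.0)
        above = threshold_classify(records, "logd", max(values) + 1.0)
        assert set(below.predictions.values()) == {AGGREGATOR}
        assert set(above.predictions.values()) == {NON_AGGREGATOR}


class TestSuccessRate:
    def test_31_of_32_reports_96_9(self):
        truth = [AGGREGATOR] * 20 + [NON_AGGREGATOR] * 12
        predicted = list(truth)
        predicted[5] = NON_AGGREGATOR  # one miss
        rate, missed = success_rate(predicted, truth)
        assert rate == 96.9
        assert missed == ("5",)

    def test_all_correct(self):
        rate, missed = success_rate([AGGREGATOR, NON_AGGREGATOR],
                                    [AGGREGATOR, NON_AGGREGATOR])
        assert rate == 100.0
        assert missed == ()

    def test_24_of_32_is_75(self):
        truth = [AGGREGATOR] * 32
        predicted = [AGGREGATOR] * 24 + [NON_AGGREGATOR] * 8
        rate, _ = success_rate(predicted, truth)
        assert rate == 75.0

    def test_symmetric_under_relabelling(self):
        truth = [AGGREGATOR, NON_AGGREGATOR, AGGREGATOR, AGGREGATOR]
        pred = [AGGREGATOR, AGGREGATOR, NON_AGGREGATOR, AGGREGATOR]
        swap = {AGGREGATOR: NON_AGGREGATOR, NON_AGGREGATOR: AGGREGATOR}
        r1, _ = success_rate(pred, truth)
        r2, _ = success_rate([swap[p] for p in pred], [swap[t] for t in truth])
        assert r1 == r2

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            success_rate([AGGREGATOR], [AGGREGATOR, AGGREGATOR])


class TestFixtureTable:
    def test_32_labelled_compounds(self, fixture_records):
        assert len(fixture_records) == 32
        assert all(r.label in (AGGREGATOR, NON_AGGREGATOR) for r in fixture_records)

    def test_logd_rule_misclassifies_exactly_11_21_23(self, fixture_records):
        result = threshold_classify(fixture_records, "logd", 3.0)
        assert set(result.misclassified) == {"11", "21", "23"}
        assert result.success_rate_percent == pytest.approx(90.6)

    def test_md_calls_misclassify_only_21(self):
        calls = md_calls_from_table(synthetic_compound_table_path())
        truth = {
            r.id: r.label
            for r in read_compound_table(synthetic_compound_table_path())
        }
        missed = [cid for cid in truth if calls[cid] != truth[cid]]
        assert missed == ["21"]
        rate, _ = success_rate(
            [calls[c] for c in truth], [truth[c] for c in truth], ids=list(truth)
        )
        assert rate == 96.9

    def test_logp_is_weaker_than_logd_on_fixture(self, fixture_records):
        logd = threshold_classify(fixture_records, "logd", 3.0)
        logp = threshold_classify(fixture_records, "logp", 3.0)
        assert logp.success_rate_percent < logd.success_rate_percent


class TestCompareMethods:
    def test_agreement_table_flags_disjoint_errors(self, fixture_records):
        truth = {r.id: r.label for r in fixture_records}
        table = compare_methods(
            {
                "logd>3": threshold_classify(fixture_records, "logd", 3.0),
                "md": md_calls_from_table(synthetic_compound_table_path()),
            },
            truth,
        )
        assert table.loc["11", "logd>3"] == NON_AGGREGATOR  # logD misses it
        assert table.loc["11", "md"] == AGGREGATOR  # MD catches it
        assert table.loc["__success_rate__", "md"] == "96.9"
        assert table.loc["__success_rate__", "logd>3"] == "90.6"

    def test_missing_compound_marked_not_scored(self):
        truth = {"a": AGGREGATOR, "b": NON_AGGREGATOR}
        table = compare_methods({"m": {"a": AGGREGATOR}}, truth)
        assert table.loc["b", "m"] == "not-scored"

    def test_disjoint_ids_rejected(self):
        with pytest.raises(ValueError, match="shared"):
            compare_methods({"m": {"x": AGGREGATOR}}, {"y": AGGREGATOR})


def test_empty_table_rejected(tmp_path):
    path = tmp_path / "empty.csv"
    path.write_text("id,logp,logd,vsurf_a,tpsa,label\n")
    with pytest.raises(ValueError, match="empty"):
        read_compound_table(path)
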