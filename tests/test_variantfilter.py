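"""Rare-variant filter cascade: rules, trace, cohort summary, fixture."""

import numpy as np
import pandas as pd
import pytest

from smmipkit.variantfilter import (
    DEFAULT_RULE_ORDER,
    FilterConfig,
    VariantTableError,
    apply_filter_cascade,
    load_cohort_fixture,
    load_variant_table,
    normalize_variant_table,
    summarize_cohort,
)


def _row(**kwargs):
    base = dict(
        patient_id="P1",
        cdna_change="c.1A>G",
        protein_change="p.(Met1Val)",
        consequence="missense",
        intron_distance=0,
        af_1000g="0",
        af_exac="0",
        inhouse_count=0,
        cadd="25",
        classification="VUS",
    )
    base.update(kwargs)
    return base


def _table(*rows):
    return pd.DataFrame([_row(**r) for r in rows])


class TestRules:
    def test_synonymous_fails_with_named_rule(self):
        passing, trace = apply_filter_cascade(_table(dict(consequence="synonymous")))
        assert len(passing) == 0
        assert trace.iloc[0].first_failing_rule == "synonymous"

    @pytest.mark.parametrize(
        "row, rule",
        [
            (dict(af_1000g="0.02"), "af_1000g"),
            (dict(af_exac="0.011"), "af_exac"),
            (dict(inhouse_count=50), "inhouse"),
            (dict(consequence="intronic", intron_distance=9), "deep_intronic"),
            (dict(classification="benign"), "benign_classification"),
            (dict(classification="likely_benign"), "benign_classification"),
        ],
    )
    def test_each_rule_excludes(self, row, rule):
        passing, trace = apply_filter_cascade(_table(row))
        assert len(passing) == 0
        assert rule in trace.iloc[0].failing_rules.split(",")

    @pytest.mark.parametrize(
        "row",
        [
            dict(),
            dict(af_1000g="0.009", af_exac="0.0099"),
            dict(inhouse_count=49),
            dict(consequence="intronic", intron_distance=6, cdna_change="c.1066-6T>G"),
            dict(consequence="intronic", intron_distance=8),
            dict(cadd=""),  # missing CADD never excludes
            dict(consequence="inframe_indel"),
        ],
    )
    def test_qualifying_rows_pass(self, row):
        passing, trace = apply_filter_cascade(_table(row))
        assert len(passing) == 1
        assert trace.iloc[0].passed

    def test_thresholds_are_strict(self):
        """AF exactly 1% and in-house exactly 50 fail; just below passes."""
        passing, _ = apply_filter_cascade(_table(dict(af_1000g="0.01")))
        assert len(passing) == 0
        passing, _ = apply_filter_cascade(_table(dict(inhouse_count=50)))
        assert len(passing) == 0

    def test_missing_af_treated_as_zero(self):
        passing, _ = apply_filter_cascade(_table(dict(af_1000g="", af_exac="")))
        assert len(passing) == 1

    def test_malformed_af_reports_row(self):
        df = _table(dict(), dict(af_1000g="one%"))
        with pytest.raises(VariantTableError, match="row 3"):
            apply_filter_cascade(df)

    def test_pass_iff_no_failing_rules(self):
        df = _table(dict(), dict(consequence="synonymous", af_1000g="0.5"))
        _, trace = apply_filter_cascade(df)
        for rec in trace.itertuples():
            assert rec.passed == (rec.failing_rules == "")


def _random_tables(n_rows, seed):
    rng = np.random.default_rng(seed)
    consequences = ["missense", "synonymous", "intronic", "inframe_indel", "splice_region", "other"]
    classes = ["benign", "likely_benign", "VUS", "likely_pathogenic", "pathogenic", "unclassified"]
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n_rows)],
            "cdna_change": [f"c.{i}A>G" for i in range(n_rows)],
            "protein_change": "",
            "consequence": rng.choice(consequences, n_rows),
            "intron_distance": rng.integers(0, 30, n_rows),
            "af_1000g": rng.uniform(0, 0.05, n_rows).round(4).astype(str),
            "af_exac": rng.uniform(0, 0.05, n_rows).round(4).astype(str),
            "inhouse_count": rng.integers(0, 120, n_rows),
            "cadd": rng.uniform(0, 40, n_rows).round(2).astype(str),
            "classification": rng.choice(classes, n_rows),
        }
    )


def test_rule_order_never_changes_passing_set():
    df = _random_tables(300, seed=2)
    rng = np.random.default_rng(3)
    reference, _ = apply_filter_cascade(df)
    for _ in range(5):
        order = list(DEFAULT_RULE_ORDER)
        rng.shuffle(order)
        permuted, _ = apply_filter_cascade(df, rule_order=order)
        assert permuted.equals(reference)


def test_tightening_thresholds_shrinks_passing_set():
    df = _random_tables(300, seed=4)
    base, _ = apply_filter_cascade(df, FilterConfig())
    base_keys = set(zip(base.patient_id, base.cdna_change))
    tighter_configs = [
        FilterConfig(max_pop_af=0.005),
        FilterConfig(max_inhouse=20),
        FilterConfig(intron_cutoff=3),
    ]
    for cfg in tighter_configs:
        tight, _ = apply_filter_cascade(df, cfg)
        assert set(zip(tight.patient_id, tight.cdna_change)) <= base_keys


class TestSummary:
    def test_empty_table_all_zero(self):
        summary = summarize_cohort(_table()[0:0])
        assert summary["distinct_variants"] == 0
        assert summary["carrier_patients"] == 0
        assert summary["biallelic_candidate_pct"] == 0.0

    def test_biallelic_candidate_requires_pathogenic_plus_second(self):
        df = _table(
            dict(patient_id="A", cdna_change="c.1A>G", classification="pathogenic"),
            dict(patient_id="A", cdna_change="c.2A>G"),
            dict(patient_id="B", cdna_change="c.3A>G", classification="pathogenic"),
            dict(patient_id="C", cdna_change="c.4A>G"),
            dict(patient_id="C", cdna_change="c.5A>G"),
        )
        passing, _ = apply_filter_cascade(df)
        summary = summarize_cohort(passing, cohort_size=100)
        assert summary["biallelic_candidate_patients"] == 1  # only A
        assert summary["biallelic_candidate_pct"] == 1.0


class TestFixture:
    def test_fixture_reproduces_published_cadd_and_class(self):
        df = load_cohort_fixture()
        assert len(df) == 24
        by_cdna = df.drop_duplicates("cdna_change").set_index("cdna_change")
        assert by_cdna.loc["c.115A>G", "cadd"] == 14.38
        assert by_cdna.loc["c.8147T>C", "cadd"] == 26.2
        assert by_cdna.loc["c.8147T>C", "classification"] == "pathogenic"
        assert by_cdna.loc["c.8314G>A", "cadd"] == 31
        assert pd.isna(by_cdna.loc["c.1066-6T>G", "cadd"])
        assert (df.loc[df.cdna_change != "c.8147T>C", "classification"] == "VUS").all()

    def test_fixture_round_trips_through_tsv(self, tmp_path):
        df = load_cohort_fixture()
        path = tmp_path / "rt.tsv"
        df.to_csv(path, sep="\t", index=False)
        again = load_variant_table(path)
        pd.testing.assert_frame_equal(df, again)

    def test_fixture_cohort_summary(self):
        """22 carrier patients share 21 distinct variants: 20 VUS, 10 with
        CADD > 20, and one patient carries a pathogenic variant plus a second
        variant (0.3% of the 373-patient cohort)."""
        passing, trace = apply_filter_cascade(load_cohort_fixture())
        assert trace.passed.all()
        summary = summarize_cohort(passing, cohort_size=373)
        assert summary["distinct_variants"] == 21
        assert summary["carrier_patients"] == 22
        assert summary["distinct_vus"] == 20
        assert summary["distinct_cadd_high"] == 10
        assert summary["biallelic_candidate_patients"] == 1
        assert summary["biallelic_candidate_pct"] == 0.3


def test_normalize_rejects_unknown_classification():
    df = _table(dict(classification="weird"))
    with pytest.raises(VariantTableError, match="classification"):
        normalize_variant_table(df)
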