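import datetime

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import expected_detected
from hgcmine import abundance as ab
from hgcmine.io import CountMatrix, SampleMetadata
from hgcmine.loci import LocusCall


def _meta(sid="s", o2_detected=True, o2=3.0, station="ST", depth=10.0,
          filter_um=0.2, prefilter=None, date=datetime.date(2014, 6, 1)):
    return SampleMetadata(
        sample_id=sid, station=station, date=date, depth_m=depth,
        o2_detected=o2_detected, o2_mL_per_L=o2 if o2_detected else None,
        filter_um=filter_um, prefilter_um=prefilter,
    )


def _cm(counts: dict, totals: dict) -> CountMatrix:
    df = pd.DataFrame(counts).T
    return CountMatrix(df, pd.Series(totals).reindex(df.columns))


def _locus(name, *gene_ids):
    a = gene_ids[0]
    b = gene_ids[1] if len(gene_ids) > 1 else None
    return LocusCall(
        locus_name=name,
        category="paired_cluster" if b else "hgcA_only",
        contig_id="c",
        hgcA_gene_id=a,
        hgcB_gene_id=b,
    )


class TestClassifyRedox:
    @pytest.mark.parametrize(
        "o2, expected",
        [(2.0, "normoxic"), (2.01, "normoxic"), (8.0, "normoxic"),
         (1.99, "hypoxic"), (0.5, "hypoxic"), (0.01, "hypoxic"), (0.0, "hypoxic")],
    )
    def test_detected_oxygen_boundary_inclusive_at_2(self, o2, expected):
        assert ab.classify_redox(_meta(o2=o2)) == expected

    def test_undetected_oxygen_is_anoxic_regardless_of_value(self):
        assert ab.classify_redox(_meta(o2_detected=False)) == "anoxic"

    def test_threshold_parameter_moves_boundary(self):
        assert ab.classify_redox(_meta(o2=3.0), threshold_mL_per_L=4.0) == "hypoxic"


class TestComputeAbundance:
    def test_67_reads_per_million_is_6_7_display_units(self):
        cm = _cm({"gA": {"s1": 40}, "gB": {"s1": 27}}, {"s1": 1_000_000})
        rec = ab.compute_abundance(cm, [_locus("L1", "gA", "gB")])[0]
        assert rec.relative_abundance_pct == pytest.approx(6.7e-3)
        assert rec.display_units_1e3 == pytest.approx(6.7)

    def test_zero_reads_zero_percent(self):
        cm = _cm({"gA": {"s1": 0}}, {"s1": 10_000})
        assert ab.compute_abundance(cm, [_locus("L1", "gA")])[0].relative_abundance_pct == 0

    def test_per_locus_records_sum_to_summed_record(self):
        cm = _cm(
            {"gA": {"s1": 10, "s2": 1}, "gB": {"s1": 5, "s2": 2},
             "gC": {"s1": 7, "s2": 0}},
            {"s1": 1000, "s2": 1000},
        )
        loci = [_locus("L1", "gA", "gB"), _locus("L2", "gC")]
        summed = {r.sample_id: r.relative_abundance_pct
                  for r in ab.compute_abundance(cm, loci)}
        per_locus = ab.compute_abundance(cm, loci, per_locus=True)
        for sid in ("s1", "s2"):
            total = sum(r.relative_abundance_pct for r in per_locus
                        if r.sample_id == sid)
            assert total == pytest.approx(summed[sid])

    def test_missing_gene_row_is_hard_error(self):
        cm = _cm({"gA": {"s1": 1}}, {"s1": 100})
        with pytest.raises(ab.AbundanceError, match="missing"):
            ab.compute_abundance(cm, [_locus("L1", "ghost")])

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(min_value=2, max_value=1000))
    def test_invariant_under_joint_count_and_total_scaling(self, factor):
        cm1 = _cm({"gA": {"s1": 13}, "gB": {"s1": 4}}, {"s1": 5000})
        cm2 = _cm({"gA": {"s1": 13 * factor}, "gB": {"s1": 4 * factor}},
                  {"s1": 5000 * factor})
        loci = [_locus("L1", "gA", "gB")]
        r1 = ab.compute_abundance(cm1, loci)[0].relative_abundance_pct
        r2 = ab.compute_abundance(cm2, loci)[0].relative_abundance_pct
        assert r1 == pytest.approx(r2)


class TestZoneSummary:
    def test_two_sample_zone_statistics(self):
        records = [
            ab.AbundanceRecord("s1", ab.SUMMED_KEY, 1.0e-3),
            ab.AbundanceRecord("s2", ab.SUMMED_KEY, 3.2e-3),
        ]
        zones = {"s1": "anoxic", "s2": "anoxic"}
        with pytest.warns(UserWarning):  # empty zones omitted
            rows = ab.summarize_by_zone(records, zones)
        anoxic = next(r for r in rows if r.zone == "anoxic")
        assert anoxic.n_samples == 2
        assert anoxic.mean == pytest.approx(2.1)
        assert anoxic.min == pytest.approx(1.0)
        assert anoxic.max == pytest.approx(3.2)
        assert anoxic.sd == pytest.approx(np.std([1.0, 3.2], ddof=1))
        assert rows[-1].zone == "all"

    def test_single_sample_zone_flagged_degenerate(self):
        records = [ab.AbundanceRecord("s1", ab.SUMMED_KEY, 1e-3)]
        with pytest.warns(UserWarning):
            rows = ab.summarize_by_zone(records, {"s1": "hypoxic"})
        hypoxic = next(r for r in rows if r.zone == "hypoxic")
        assert hypoxic.sd == 0.0 and hypoxic.degenerate_n

    def test_summary_invariant_to_sample_order(self):
        records = [
            ab.AbundanceRecord(f"s{i}", ab.SUMMED_KEY, v * 1e-3)
            for i, v in enumerate([0.5, 2.0, 1.0, 4.0])
        ]
        zones = {f"s{i}": z for i, z in enumerate(
            ["normoxic", "anoxic", "hypoxic", "anoxic"])}
        a = ab.zone_summary_frame(ab.summarize_by_zone(records, zones))
        b = ab.zone_summary_frame(ab.summarize_by_zone(records[::-1], zones))
        pd.testing.assert_frame_equal(a, b)

    def test_unzoned_sample_is_error(self):
        records = [ab.AbundanceRecord("s1", ab.SUMMED_KEY, 1e-3)]
        with pytest.raises(ab.AbundanceError, match="s1"):
            ab.summarize_by_zone(records, {})


class TestFractionEnrichment:
    def _pair_meta(self):
        date = datetime.date(2014, 10, 26)
        return [
            _meta("p3um", station="TF", depth=140.0, filter_um=3.0,
                  prefilter=None, date=date, o2_detected=False),
            _meta("p02um", station="TF", depth=140.0, filter_um=0.2,
                  prefilter=3.0, date=date, o2_detected=False),
        ]

    def test_matched_pair_ratio(self):
        records = [
            ab.AbundanceRecord("p3um", ab.SUMMED_KEY, 6.5e-3),
            ab.AbundanceRecord("p02um", ab.SUMMED_KEY, 1.5e-3),
        ]
        table = ab.fraction_enrichment(records, self._pair_meta())
        assert len(table) == 1
        assert table["ratio"].iloc[0] == pytest.approx(6.5 / 1.5)

    def test_zero_denominator_flagged_undefined_not_infinite(self):
        records = [
            ab.AbundanceRecord("p3um", ab.SUMMED_KEY, 6.5e-3),
            ab.AbundanceRecord("p02um", ab.SUMMED_KEY, 0.0),
        ]
        table = ab.fraction_enrichment(records, self._pair_meta())
        assert not table["defined"].iloc[0]
        assert np.isnan(table["ratio"].iloc[0])

    def test_no_matched_pairs_warns_and_returns_empty(self):
        records = [ab.AbundanceRecord("solo", ab.SUMMED_KEY, 1e-3)]
        with pytest.warns(UserWarning, match="no matched"):
            table = ab.fraction_enrichment(records, [_meta("solo")])
        assert table.empty


class TestRarefaction:
    counts = {"g1": {"s": 1}, "g2": {"s": 3}, "g3": {"s": 5},
              "g4": {"s": 10}, "g5": {"s": 0}}

    def _setup(self, total=60):
        cm = _cm(self.counts, {"s": total})
        loci = [_locus("L1", "g1", "g2"), _locus("L2", "g3", "g4"),
                _locus("L3", "g5")]
        return cm, loci

    def test_full_depth_detects_exactly_nonzero_genes(self):
        cm, loci = self._setup()
        curve = ab.rarefaction(cm, loci, "s", [60], replicates=5, seed=1)
        assert curve["mean_detected"].iloc[0] == 4.0
        assert curve["sd_detected"].iloc[0] == 0.0

    def test_zero_depth_detects_nothing(self):
        cm, loci = self._setup()
        assert ab.rarefaction(cm, loci, "s", [0], seed=1)["mean_detected"].iloc[0] == 0

    def test_depth_beyond_total_is_error(self):
        cm, loci = self._setup()
        with pytest.raises(ab.AbundanceError, match="exceeds total"):
            ab.rarefaction(cm, loci, "s", [61], seed=1)

    def test_mean_detection_matches_hypergeometric_closed_form(self):
        cm, loci = self._setup()
        depths = [5, 15, 30, 45, 60]
        curve = ab.rarefaction(cm, loci, "s", depths, replicates=5000, seed=7)
        exact = ab.rarefaction_expectation(cm, loci, "s", depths)
        ks = [1, 3, 5, 10, 0]
        for i, d in enumerate(depths):
            oracle = expected_detected(ks, 60, d)
            assert exact["expected_detected"].iloc[i] == pytest.approx(oracle, abs=1e-9)
            assert curve["mean_detected"].iloc[i] == pytest.approx(oracle, abs=0.1)
        assert curve["mean_detected"].is_monotonic_increasing

    def test_deterministic_for_fixed_seed(self):
        cm, loci = self._setup()
        a = ab.rarefaction(cm, loci, "s", [10, 20], replicates=20, seed=42)
        b = ab.rarefaction(cm, loci, "s", [10, 20], replicates=20, seed=42)
        pd.testing.assert_frame_equal(a, b)
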