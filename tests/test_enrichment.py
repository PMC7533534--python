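import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lcmproteo import (
    IntensityMatrix,
    SampleMetadata,
    SimConfig,
    analyze_enrichment,
    bh_adjust,
    call_enrichment,
    call_unique,
    compare_to_bulk,
    generate_dataset,
    pair_samples,
    paired_t_test,
    summarize_table1,
)


def bh_oracle(p):
    """Direct min-over-suffix evaluation of the BH step-up q-values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_idx, i in enumerate(order):
        js = np.arange(rank_idx, m)
        q[i] = min(1.0, np.min(p[order[js]] * m / (js + 1)))
    return q


class TestPairSamples:
    def test_all_complete(self, small_matrix, small_metadata):
        paired = pair_samples(small_matrix, small_metadata)
        assert paired.n_pairs == 3
        assert paired.pair_labels == [("K1", "B1"), ("K2", "B1"), ("K3", "B1")]

    def test_kidney_missing_one_compartment(self, small_matrix, small_metadata):
        keep = [s for s in small_matrix.sample_ids if s != "K3_PT"]
        paired = pair_samples(small_matrix.subset_samples(keep), small_metadata)
        assert paired.n_pairs == 2

    def test_empty_matrix(self, small_metadata):
        m = IntensityMatrix(np.empty((0, 6)), np.empty((0, 6), bool), [],
                            small_metadata.sample_ids)
        paired = pair_samples(m, small_metadata)
        assert paired.n_pairs == 3 and paired.first.shape == (0, 3)


class TestPairedTTest:
    def test_closed_form_example(self):
        res = paired_t_test([1.0, 1.2, 0.8, 1.0])
        assert res.df == 3
        sd = np.std([1.0, 1.2, 0.8, 1.0], ddof=1)
        assert sd == pytest.approx(0.1633, abs=2e-4)
        assert res.t_stat == pytest.approx(1.0 / (sd / 2.0), rel=1e-9)  # ~12.25
        assert not res.degenerate

    def test_symmetric_diffs(self):
        res = paired_t_test([1.0, -1.0, 2.0, -2.0])
        assert res.t_stat == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_degenerate_constant_diffs(self):
        res = paired_t_test([0.5, 0.5, 0.5])
        assert res.degenerate and res.p_value == 0.0 and np.isinf(res.t_stat)
        res0 = paired_t_test([0.0, 0.0, 0.0])
        assert res0.degenerate and res0.p_value == 1.0

    def test_min_pairs_enforced(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0, 2.0])


class TestBHAdjust:
    def test_step_up_by_hand(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_tied(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(bh_adjust([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60))
    def test_matches_min_over_suffix_oracle(self, p):
        np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)


class TestCalls:
    def _records(self, q, lfc):
        return pd.DataFrame(
            dict(protein_id=[f"P{i}" for i in range(len(q))],
                 q_value=q, log2_fc=lfc)
        )

    def test_joint_gate(self):
        rec = call_enrichment(self._records([0.05, 0.05, 0.2], [1.5, 1.0, 3.0]))
        assert rec["call"].tolist() == ["enriched_glom", "ns", "ns"]  # fold 2 is strict

    def test_pt_direction(self):
        rec = call_enrichment(self._records([0.05], [-1.5]))
        assert rec["call"].iloc[0] == "enriched_pt"

    def test_untested_without_q(self):
        rec = call_enrichment(self._records([np.nan], [0.5]))
        assert rec["call"].iloc[0] == "untested"

    def test_unique_sets_take_precedence(self):
        rec = call_enrichment(self._records([np.nan], [np.nan]), unique_glom={"P0"})
        assert rec["call"].iloc[0] == "unique_glom"


class TestCallUnique:
    def test_all_glom_no_pt(self, small_matrix, small_metadata):
        ug, up = call_unique(small_matrix, small_metadata)
        assert ug == {"P3"} and up == set()

    def test_one_opposing_observation_disqualifies(self, small_metadata):
        vals = np.array([[25.0, np.nan, 25.3, 24.0, 24.8, np.nan]])  # one PT value
        m = IntensityMatrix(vals, ~np.isfinite(vals), ["P1"], small_metadata.sample_ids)
        ug, up = call_unique(m, small_metadata)
        assert ug == set()

    def test_min_detect_relaxation(self, small_metadata):
        vals = np.array([[25.0, np.nan, 25.3, np.nan, np.nan, np.nan]])  # 2/3 Glom
        m = IntensityMatrix(vals, ~np.isfinite(vals), ["P1"], small_metadata.sample_ids)
        assert call_unique(m, small_metadata)[0] == set()
        assert call_unique(m, small_metadata, min_detect=0.5)[0] == {"P1"}


class TestSummarizeTable1:
    def test_hand_arithmetic(self, small_metadata):
        vals = np.array([[23.0, np.nan, 24.0, np.nan, 25.0, np.nan]])
        m = IntensityMatrix(vals, ~np.isfinite(vals), ["P1"], small_metadata.sample_ids)
        tab = summarize_table1(m, small_metadata, {"P1"}, set())
        row = tab.iloc[0]
        assert row["summary"] == "24.00 ± 1.00"
        assert row["compartment"] == "Glom"

    def test_single_value_sd_na(self, small_metadata):
        vals = np.array([[np.nan, np.nan, np.nan, np.nan, 21.0, np.nan]])
        m = IntensityMatrix(vals, ~np.isfinite(vals), ["P1"], small_metadata.sample_ids)
        tab = summarize_table1(m, small_metadata, {"P1"}, set())
        assert np.isnan(tab.iloc[0]["sd"])
        assert tab.iloc[0]["summary"].endswith("± NA")


class TestAnalyzeEnrichment:
    def test_antisymmetry_under_label_swap(self):
        cfg = SimConfig(n_proteins=300, n_kidneys=6, lod=-np.inf, mcar_rate=0.0, seed=8)
        m, md, _ = generate_dataset(cfg)
        fwd = analyze_enrichment(m, md, compartments=("Glom", "PT"))
        rev = analyze_enrichment(m, md, compartments=("PT", "Glom"))
        np.testing.assert_allclose(fwd["log2_fc"], -rev["log2_fc"], atol=1e-12)
        np.testing.assert_allclose(fwd["q_value"], rev["q_value"], atol=1e-12)
        swap = {"enriched_glom": "enriched_pt", "enriched_pt": "enriched_glom",
                "unique_glom": "unique_pt", "unique_pt": "unique_glom"}
        assert (fwd["call"].map(lambda c: swap.get(c, c)) == rev["call"]).all()

    def test_planted_truth_recovery_without_noise_obstacles(self):
        # delta 1.5 keeps the planted fold clear of the strict >2-fold gate
        cfg = SimConfig(n_proteins=600, n_kidneys=6, sigma_run=0.15, delta=1.5,
                        lod=-np.inf, mcar_rate=0.0, seed=21)
        m, md, truth = generate_dataset(cfg)
        rec = analyze_enrichment(m, md).set_index("protein_id")
        t = truth.set_index("protein_id")
        ug_called = set(rec.index[rec["call"] == "unique_glom"])
        ug_true = set(t.index[t["status"] == "unique_glom"])
        assert ug_called == ug_true
        enr_true = t.index[t["status"] == "enriched_glom"]
        sens = (rec.loc[enr_true, "call"] == "enriched_glom").mean()
        assert sens > 0.8  # sigma_run small: paired test well powered

    def test_complete_case_pair_counts(self, small_matrix, small_metadata):
        rec = analyze_enrichment(small_matrix, small_metadata).set_index("protein_id")
        assert rec.loc["P1", "n_pairs"] == 3
        assert rec.loc["P3", "n_pairs"] == 0  # no complete pairs (PT all missing)
        assert rec.loc["P3", "call"] == "unique_glom"
        assert rec.loc["P4", "call"] == "untested"


class TestCompareToBulk:
    def _with_bulk(self):
        rows, vals = [], []
        for k in (1, 2):
            for comp in ("Glom", "PT", "Bulk"):
                rows.append(dict(sample_id=f"K{k}_{comp}", kidney_id=f"K{k}",
                                 compartment=comp, batch="B1"))
        md = SampleMetadata(pd.DataFrame(rows))
        vals = np.array(
            [
                [23.0, 22.0, 24.0, 23.1, 22.2, 24.2],   # everywhere
                [25.0, np.nan, np.nan, 25.2, np.nan, np.nan],  # Glom only
                [np.nan, np.nan, 22.0, np.nan, np.nan, 22.5],  # bulk only
            ]
        )
        m = IntensityMatrix(vals, ~np.isfinite(vals), ["P1", "P2", "P3"], md.sample_ids)
        return m, md

    def test_flags(self):
        m, md = self._with_bulk()
        flags = compare_to_bulk(m, md).set_index("protein_id")["bulk_flag"]
        assert flags["P1"] == "detected_in_bulk"
        assert flags["P2"] == "sub_compartment_only"
        assert "P3" not in flags.index  # never seen in a sub-compartment

    def test_no_bulk_samples_error(self, small_matrix, small_metadata):
        with pytest.raises(ValueError, match="Bulk"):
            compare_to_bulk(small_matrix, small_metadata)

    def test_low_abundance_glom_proteins_missed_in_bulk(self):
        # PT-dominated bulk + LOD: structurally Glom-restricted proteins are
        # diluted ~5x in bulk and drop below detection more often
        cfg = SimConfig(n_proteins=3000, n_kidneys=6, lod=22.5, tau=0.5,
                        mcar_rate=0.0, seed=33)
        m, md, truth = generate_dataset(cfg)
        flags = compare_to_bulk(m, md).set_index("protein_id")["bulk_flag"]
        t = truth.set_index("protein_id")
        ug = t.index[t["status"] == "unique_glom"].intersection(flags.index)
        ep = t.index[t["status"] == "enriched_pt"].intersection(flags.index)
        rate_ug = (flags[ug] == "sub_compartment_only").mean()
        rate_ep = (flags[ep] == "sub_compartment_only").mean()
        assert rate_ug > rate_ep
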