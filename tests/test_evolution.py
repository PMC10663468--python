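"""Clonality flow, pattern cascade, neoantigen counts, group tests."""

import numpy as np
import pandas as pd
import pytest

from pdxevo.clonality import ClonalityCall, classify_sample, estimate_ccf
from pdxevo.errors import DegenerateDataError, ValidationError
from pdxevo.evolution import (
    ClonalityFlow,
    NeoantigenRecord,
    PatternThresholds,
    Promotion,
    build_flow,
    classify_pattern,
    count_clonal_neoantigens,
    group_compare,
)
from pdxevo.variants import PairedVariantSet

from conftest import make_record


def _call(label):
    return ClonalityCall(per_method={}, consensus=label)


def _flow(cells, promotions=()):
    counts = pd.DataFrame(
        0, index=["clonal", "subclonal", "ambiguous", "absent"],
        columns=["clonal", "subclonal", "ambiguous", "absent"], dtype=int,
    )
    for (row, col), n in cells.items():
        counts.loc[row, col] = n
    return ClonalityFlow(counts=counts, promotions=list(promotions))


class TestBuildFlow:
    def test_all_shared_clonal_lands_on_the_diagonal(self):
        recs = [make_record(pos=p) for p in range(1, 6)]
        pair = PairedVariantSet(pt=recs, pdx=recs)
        calls = {r.key: _call("clonal") for r in recs}
        flow = build_flow(pair, calls, calls)
        assert flow.counts.loc["clonal", "clonal"] == 5
        assert flow.counts.to_numpy().sum() == 5

    def test_disjoint_pair_uses_only_absent_cells(self):
        pt = [make_record(pos=p) for p in range(1, 4)]
        pdx = [make_record(pos=p) for p in range(10, 14)]
        pair = PairedVariantSet(pt=pt, pdx=pdx)
        flow = build_flow(
            pair,
            {r.key: _call("clonal") for r in pt},
            {r.key: _call("clonal") for r in pdx},
        )
        assert flow.n_shared == 0
        assert flow.counts.loc["clonal", "absent"] == 3
        assert flow.counts.loc["absent", "clonal"] == 4

    def test_flow_conserves_the_union(self):
        pt = [make_record(pos=p) for p in range(1, 8)]
        pdx = [make_record(pos=p) for p in range(5, 12)]
        pair = PairedVariantSet(pt=pt, pdx=pdx)
        flow = build_flow(
            pair,
            {r.key: _call("clonal") for r in pt},
            {r.key: _call("subclonal") for r in pdx},
        )
        assert flow.total == len(pair.union)

    def test_present_but_unclassified_mutation_raises(self):
        recs = [make_record(pos=1)]
        pair = PairedVariantSet(pt=recs, pdx=recs)
        with pytest.raises(ValidationError):
            build_flow(pair, {}, {recs[0].key: _call("clonal")})


class TestClassifyPattern:
    def test_branch_seeding_when_pt_clonal_mutations_vanish(self):
        # 41 PT mutations: 2 truncal retained, 39 PT-clonal lost; 32 PDX-private
        flow = _flow({
            ("clonal", "clonal"): 2,
            ("clonal", "absent"): 39,
            ("absent", "clonal"): 32,
        })
        call = classify_pattern(flow)
        assert call.pattern == "branch_seeding" and call.group == "group2"
        assert call.evidence["lost_clonal_fraction"] == pytest.approx(39 / 41)

    def test_sweeping_on_promoted_subclonal_mutation(self):
        flow = _flow(
            {("clonal", "clonal"): 20, ("subclonal", "clonal"): 1},
            promotions=[Promotion(("chr2", 1, "C", "T"), 0.2, 0.98)],
        )
        call = classify_pattern(flow)
        assert call.pattern == "clone_sweeping" and call.group == "group2"

    def test_retention_when_clonal_structure_preserved(self):
        flow = _flow({("clonal", "clonal"): 30, ("subclonal", "subclonal"): 5})
        call = classify_pattern(flow)
        assert call.pattern == "clone_retention" and call.group == "group1"

    def test_no_shared_mutations_is_unclassifiable(self):
        flow = _flow({("clonal", "absent"): 10, ("absent", "clonal"): 10})
        call = classify_pattern(flow)
        assert call.pattern == "unclassifiable" and call.group == "none"

    def test_small_promotion_does_not_trigger_sweeping(self):
        flow = _flow(
            {("clonal", "clonal"): 20, ("subclonal", "clonal"): 1},
            promotions=[Promotion(("chr2", 1, "C", "T"), 0.7, 0.95)],
        )
        assert classify_pattern(flow).pattern == "clone_retention"

    def test_thresholds_are_configurable(self):
        # 60% retained / 40% lost falls between the default cut-offs
        flow = _flow({("clonal", "clonal"): 6, ("clonal", "absent"): 4})
        assert classify_pattern(flow).pattern == "unclassifiable"
        assert classify_pattern(
            flow, PatternThresholds(t_loss=0.3)
        ).pattern == "branch_seeding"
        assert classify_pattern(
            flow, PatternThresholds(t_retain=0.5)
        ).pattern == "clone_retention"


class TestNeoantigens:
    def test_ic50_boundary_inclusive(self):
        key = ("chr1", 1, "C", "T")
        assert count_clonal_neoantigens([NeoantigenRecord(key, 500.0, "clonal")]) == 1
        assert count_clonal_neoantigens([NeoantigenRecord(key, 501.0, "clonal")]) == 0

    def test_subclonal_binders_not_counted(self):
        key = ("chr1", 1, "C", "T")
        assert count_clonal_neoantigens([NeoantigenRecord(key, 10.0, "subclonal")]) == 0

    def test_pt_pdx_asymmetry_like_branch_seeding_case(self):
        # PT-specific mutations encode no clonal neoantigen; 10 of the
        # 32 PDX-specific mutations do
        pt = [
            NeoantigenRecord(("chr1", p, "C", "T"), 100.0, "subclonal")
            for p in range(39)
        ]
        pdx = [
            NeoantigenRecord(("chr2", p, "C", "T"), 100.0, "clonal")
            for p in range(10)
        ] + [
            NeoantigenRecord(("chr2", p, "C", "T"), 900.0, "clonal")
            for p in range(10, 32)
        ]
        assert count_clonal_neoantigens(pt) == 0
        assert count_clonal_neoantigens(pdx) == 10

    def test_nonpositive_ic50_rejected(self):
        with pytest.raises(ValidationError):
            NeoantigenRecord(("chr1", 1, "C", "T"), 0.0, "clonal")


class TestGroupCompare:
    def test_chi_square_matches_closed_form(self):
        # X² = n (ad-bc)² / ((a+b)(c+d)(a+c)(b+d)) = 20*100²/10⁴ = 20
        res = group_compare([10, 0], [0, 10], test="chi_square")
        assert res.statistic == pytest.approx(20.0)

    def test_identical_groups_center_the_rank_sum_statistic(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = group_compare(x, x, test="wilcoxon_rank_sum")
        assert res.statistic == pytest.approx(len(x) ** 2 / 2)
        assert res.pvalue > 0.9

    def test_exact_wilcoxon_for_small_untied_samples(self):
        from scipy import stats

        x, y = [1.0, 5.0, 9.0], [2.0, 4.0, 8.0, 12.0]
        res = group_compare(x, y, test="wilcoxon_rank_sum")
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert res.pvalue == pytest.approx(float(ref.pvalue))

    def test_paired_identical_vectors_signalled(self):
        with pytest.raises(DegenerateDataError):
            group_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], test="paired_t")

    def test_spearman_monotone_is_one(self):
        res = group_compare([1, 2, 3, 4], [10, 20, 40, 80], test="spearman")
        assert res.statistic == pytest.approx(1.0)


def test_simulated_sweeping_pair_fills_promotion_cell():
    from pdxevo.scna import cn_at
    from pdxevo.simulate import ScenarioConfig, simulate_pair
    from pdxevo.variants import consensus_filter

    sim = simulate_pair(ScenarioConfig("sweeping", seed=4))
    pt = consensus_filter(sim.pt_variants)
    pdx = consensus_filter(sim.pdx_variants)
    pair = PairedVariantSet(pt=pt, pdx=pdx)

    def est(records, purity, segs):
        return {
            r.key: estimate_ccf(r, purity, cn_at(segs, r.chrom, r.pos))
            for r in records
        }

    pt_est = est(pt, sim.config.purity_pt, sim.pt_segments)
    pdx_est = est(pdx, sim.config.purity_pdx, sim.pdx_segments)
    flow = build_flow(
        pair,
        classify_sample(pt_est),
        classify_sample(pdx_est),
        pt_est,
        pdx_est,
    )
    assert flow.counts.loc["subclonal", "clonal"] > 0
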