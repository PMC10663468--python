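"""End-to-end per-pair analysis and the cohort driver.

:func:`analyze_pair` runs the whole comparative analysis for one PT/PDX pair
held in memory: consensus + threshold filtering, paired rescue, mutational
similarity, CCF estimation and consensus clonality per sample, the clonality
flow and evolutionary-pattern call, SCNA concordance (GI scores, binned
Pearson correlation, focal matching and rescue), optional signature
refitting and clonal-neoantigen counts.

:func:`run_pipeline` applies it across a sample manifest, isolating per-pair
failures so one bad pair does not abort the cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import io as pio
from .clonality import classify_sample, estimate_ccf
from .errors import DegenerateDataError, PdxEvoError
from .evolution import (
    ClonalityFlow,
    NeoantigenRecord,
    PatternCall,
    PatternThresholds,
    build_flow,
    classify_pattern,
    count_clonal_neoantigens,
)
from .scna import (
    ArmDefinition,
    Segment,
    bin_profile,
    cn_at,
    detect_focal,
    gi_score,
    match_focal,
    profile_correlation,
    rescue_focal,
)
from .signatures import SignatureMatrix, count_contexts, refit
from .variants import (
    PairedVariantSet,
    ThresholdConfig,
    VariantRecord,
    consensus_filter,
    mutational_similarity,
    paired_rescue,
    threshold_filter,
)

log = logging.getLogger("pdxevo")


@dataclass
class PairResult:
    patient_id: str
    similarity: float | None
    heterogeneity_pt: float | None
    heterogeneity_pdx: float | None
    flow: ClonalityFlow | None
    pattern: PatternCall | None
    gi_pt: float | None = None
    gi_pdx: float | None = None
    cn_correlation: float | None = None
    focal_shared_fraction: float | None = None
    n_focal_pt: int = 0
    n_focal_pdx: int = 0
    n_focal_rescued: int = 0
    clonal_neoantigens_pt: int | None = None
    clonal_neoantigens_pdx: int | None = None
    signature_weights: dict | None = None
    counts: dict = field(default_factory=dict)
    mutation_table: pd.DataFrame | None = None


def _estimates_for(
    records: Sequence[VariantRecord],
    purity: float | None,
    segments: Sequence[Segment] | None,
):
    out = {}
    for rec in records:
        cn = cn_at(segments, rec.chrom, rec.pos) if segments else None
        out[rec.key] = estimate_ccf(rec, purity, cn)
    return out


def analyze_pair(
    patient_id: str,
    pt_records: Sequence[VariantRecord],
    pdx_records: Sequence[VariantRecord],
    *,
    purity_pt: float | None,
    purity_pdx: float | None,
    pt_segments: Sequence[Segment] | None = None,
    pdx_segments: Sequence[Segment] | None = None,
    raw_pool_pt: Mapping | None = None,
    raw_pool_pdx: Mapping | None = None,
    arms: Sequence[ArmDefinition] | None = None,
    mask: Sequence[tuple] = (),
    chrom_lengths: dict[str, int] | None = None,
    neoantigens: pd.DataFrame | None = None,
    contexts: Mapping[tuple, str] | None = None,
    signature_matrix: SignatureMatrix | None = None,
    config: pio.PipelineConfig | None = None,
) -> PairResult:
    """Run the full comparative analysis for one PT/PDX pair."""
    cfg = config or pio.PipelineConfig()
    thr = ThresholdConfig(
        min_tumor_depth=cfg.min_tumor_depth,
        min_normal_depth=cfg.min_normal_depth,
        min_tumor_vaf=cfg.min_tumor_vaf,
        max_normal_vaf=cfg.max_normal_vaf,
        min_tumor_alt_reads=cfg.min_tumor_alt_reads,
        max_population_af=cfg.max_population_af,
        max_indel_length=cfg.max_indel_length,
        mode=cfg.variant_mode,
    )
    counts = {"pt_raw": len(pt_records), "pdx_raw": len(pdx_records)}
    pt = threshold_filter(
        consensus_filter(pt_records, mode=cfg.variant_mode), thr
    )
    pdx = threshold_filter(
        consensus_filter(pdx_records, mode=cfg.variant_mode), thr
    )
    counts["pt_filtered"] = len(pt)
    counts["pdx_filtered"] = len(pdx)
    pair = PairedVariantSet(pt=pt, pdx=pdx)
    if raw_pool_pt is not None and raw_pool_pdx is not None:
        pair = paired_rescue(pair, raw_pool_pt, raw_pool_pdx)
    counts["pt_final"] = len(pair.pt)
    counts["pdx_final"] = len(pair.pdx)
    counts["shared"] = len(pair.shared)
    counts["pt_only"] = len(pair.pt_only)
    counts["pdx_only"] = len(pair.pdx_only)
    log.info(
        "%s: filter %d->%d (PT) %d->%d (PDX); shared=%d pt_only=%d pdx_only=%d",
        patient_id, counts["pt_raw"], counts["pt_final"], counts["pdx_raw"],
        counts["pdx_final"], counts["shared"], counts["pt_only"], counts["pdx_only"],
    )

    try:
        similarity = mutational_similarity(pair)
    except DegenerateDataError:
        similarity = None

    pt_est = _estimates_for(pair.pt, purity_pt, pt_segments)
    pdx_est = _estimates_for(pair.pdx, purity_pdx, pdx_segments)
    pt_calls = classify_sample(pt_est, methods=cfg.clonality_methods, seed=cfg.seed)
    pdx_calls = classify_sample(pdx_est, methods=cfg.clonality_methods, seed=cfg.seed)

    def _het(calls):
        from .clonality import genetic_heterogeneity

        try:
            return genetic_heterogeneity(calls.values())
        except DegenerateDataError:
            return None

    flow = build_flow(pair, pt_calls, pdx_calls, pt_est, pdx_est)
    pattern = classify_pattern(
        flow,
        PatternThresholds(t_loss=cfg.t_loss, t_promote=cfg.t_promote,
                          t_retain=cfg.t_retain),
    )

    result = PairResult(
        patient_id=patient_id,
        similarity=similarity,
        heterogeneity_pt=_het(pt_calls),
        heterogeneity_pdx=_het(pdx_calls),
        flow=flow,
        pattern=pattern,
        counts=counts,
    )

    if pt_segments and pdx_segments and arms:
        try:
            _, result.gi_pt = gi_score(pt_segments, arms, cfg.gi_threshold, mask)
            _, result.gi_pdx = gi_score(pdx_segments, arms, cfg.gi_threshold, mask)
        except DegenerateDataError:
            pass
        if chrom_lengths:
            try:
                result.cn_correlation = profile_correlation(
                    bin_profile(pt_segments, chrom_lengths, cfg.bin_size, mask),
                    bin_profile(pdx_segments, chrom_lengths, cfg.bin_size, mask),
                )
            except DegenerateDataError:
                pass
        focal_pt = detect_focal(pt_segments, arms, cfg.focal_ratio,
                                cfg.max_arm_fraction)
        focal_pdx = detect_focal(pdx_segments, arms, cfg.focal_ratio,
                                 cfg.max_arm_fraction)
        matched, un_pt, un_pdx = match_focal(focal_pt, focal_pdx,
                                             cfg.breakpoint_window)
        rescued = rescue_focal(un_pt, pdx_segments, cfg.breakpoint_window,
                               cfg.focal_rescue_ratio)
        rescued += rescue_focal(un_pdx, pt_segments, cfg.breakpoint_window,
                                cfg.focal_rescue_ratio)
        result.n_focal_pt = len(focal_pt)
        result.n_focal_pdx = len(focal_pdx)
        result.n_focal_rescued = len(rescued)
        n_events = len(focal_pt) + len(focal_pdx)
        if n_events:
            result.focal_shared_fraction = (
                2 * len(matched) + len(rescued)
            ) / n_events

    if neoantigens is not None:
        def _neo(calls):
            recs = []
            for row in neoantigens.itertuples(index=False):
                key = (row.chrom, row.pos, row.ref, row.alt)
                call = calls.get(key)
                if call is not None:
                    recs.append(NeoantigenRecord(key, row.best_mt_ic50_nm,
                                                 call.consensus))
            return count_clonal_neoantigens(recs, cfg.ic50_threshold)

        result.clonal_neoantigens_pt = _neo(pt_calls)
        result.clonal_neoantigens_pdx = _neo(pdx_calls)

    if contexts is not None and signature_matrix is not None:
        weights = {}
        for name, records in (("pt", pair.pt), ("pdx", pair.pdx)):
            labels = [contexts[r.key] for r in records
                      if r.indel_length == 0 and r.key in contexts]
            if labels:
                fit = refit(count_contexts(labels), signature_matrix,
                            cfg.min_signature_mutations)
                weights[name] = {"weights": fit.weights,
                                 "eligible": fit.eligible,
                                 "n_mutations": fit.n_mutations}
        result.signature_weights = weights or None

    rows = []
    for key in sorted(pair.union):
        pt_call = pt_calls.get(key)
        pdx_call = pdx_calls.get(key)
        rows.append({
            "chrom": key[0], "pos": key[1], "ref": key[2], "alt": key[3],
            "pt_consensus": pt_call.consensus if pt_call else "absent",
            "pdx_consensus": pdx_call.consensus if pdx_call else "absent",
            "pt_ccf": pt_est[key].ccf_reported
            if pt_est.get(key) is not None else None,
            "pdx_ccf": pdx_est[key].ccf_reported
            if pdx_est.get(key) is not None else None,
        })
    result.mutation_table = pd.DataFrame(rows)
    return result


def _result_row(res: PairResult) -> dict:
    return {
        "patient_id": res.patient_id,
        "similarity": res.similarity,
        "pattern": res.pattern.pattern if res.pattern else None,
        "group": res.pattern.group if res.pattern else None,
        "heterogeneity_pt": res.heterogeneity_pt,
        "heterogeneity_pdx": res.heterogeneity_pdx,
        "gi_pt": res.gi_pt,
        "gi_pdx": res.gi_pdx,
        "cn_correlation": res.cn_correlation,
        "focal_shared_fraction": res.focal_shared_fraction,
        "clonal_neoantigens_pt": res.clonal_neoantigens_pt,
        "clonal_neoantigens_pdx": res.clonal_neoantigens_pdx,
        **{f"n_{k}": v for k, v in res.counts.items()},
    }


def run_pipeline(
    manifest: Sequence[pio.SampleManifestEntry],
    config: pio.PipelineConfig | None = None,
    outdir: str | Path | None = None,
    arms: Sequence[ArmDefinition] | None = None,
    mask: Sequence[tuple] = (),
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Run every PT/PDX pair named in the manifest; returns the cohort
    summary table (one row per pair). Per-pair failures are logged and
    reported as rows with an ``error`` column, not raised."""
    cfg = config or pio.PipelineConfig()
    by_patient: dict[str, dict[str, pio.SampleManifestEntry]] = {}
    for entry in manifest:
        by_patient.setdefault(entry.patient_id, {})[entry.role] = entry
    rows = []
    for patient_id in sorted(by_patient):
        roles = by_patient[patient_id]
        if "PT" not in roles or "PDX" not in roles:
            continue
        pt_entry, pdx_entry = roles["PT"], roles["PDX"]
        try:
            pt_records = pio.read_variants(pt_entry.variants_path)
            pdx_records = pio.read_variants(pdx_entry.variants_path)
            pt_segments = pdx_segments = None
            if pt_entry.segments_path:
                pt_segments = next(iter(pio.read_seg(pt_entry.segments_path).values()))
            if pdx_entry.segments_path:
                pdx_segments = next(iter(pio.read_seg(pdx_entry.segments_path).values()))
            res = analyze_pair(
                patient_id,
                pt_records,
                pdx_records,
                purity_pt=pt_entry.purity,
                purity_pdx=pdx_entry.purity,
                pt_segments=pt_segments,
                pdx_segments=pdx_segments,
                raw_pool_pt={r.key: r for r in pt_records},
                raw_pool_pdx={r.key: r for r in pdx_records},
                arms=arms,
                mask=mask,
                chrom_lengths=chrom_lengths,
                config=cfg,
            )
            row = _result_row(res)
            if outdir is not None and res.mutation_table is not None:
                outdir = Path(outdir)
                outdir.mkdir(parents=True, exist_ok=True)
                res.mutation_table.to_csv(
                    outdir / f"{patient_id}_mutations.tsv", sep="\t", index=False
                )
        except PdxEvoError as exc:
            log.error("pair %s failed: %s", patient_id, exc)
            row = {"patient_id": patient_id, "error": str(exc)}
        rows.append(row)
    summary = pd.DataFrame(rows)
    if outdir is not None and len(summary):
        Path(outdir).mkdir(parents=True, exist_ok=True)
        summary.to_csv(Path(outdir) / "cohort_summary.tsv", sep="\t", index=False)
    return summary
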