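"""Self-contained recovery benchmarks against simulator ground truth.

These drive both the test suite and the reproduction script: simulate paired
cohorts under the default study conditions, run the full analysis, and score
pattern recovery, consensus-clonality accuracy, and CCF confidence-interval
coverage against the generating truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clonality import estimate_ccf
from .io import PipelineConfig
from .pipeline import analyze_pair
from .simulate import ScenarioConfig, expected_vaf, sample_reads, simulate_pair
from .variants import VariantRecord

JOINT_SCENARIOS = ("retention", "sweeping", "branch_seeding")

_PATTERN_FOR = {
    "retention": "clone_retention",
    "sweeping": "clone_sweeping",
    "branch_seeding": "branch_seeding",
}


@dataclass
class RecoveryReport:
    pattern_accuracy: dict[str, float]  # scenario -> fraction recovered
    pattern_accuracy_overall: float
    clonality_accuracy: float
    n_pairs_per_scenario: int
    n_clonality_calls: int
    retention_to_sweeping: int  # retention pairs misread as sweeping


def _score_clonality(pair, result):
    """Compare consensus calls with the simulator's operational truth."""
    correct = total = 0
    for sample, calls_attr in (("pt", "pt_consensus"), ("pdx", "pdx_consensus")):
        truth = pair.truth_clonality(sample)
        table = result.mutation_table
        for row in table.itertuples(index=False):
            key = (row.chrom, row.pos, row.ref, row.alt)
            label = getattr(row, calls_attr)
            if key not in truth or label in ("absent", "unclassified"):
                continue
            total += 1
            if label == truth[key]:  # ambiguous counts as incorrect
                correct += 1
    return correct, total


def pattern_recovery_benchmark(
    n_pairs_per_scenario: int = 100,
    seed: int = 0,
    mean_depth: int = 300,
    config: PipelineConfig | None = None,
) -> RecoveryReport:
    """Simulate pairs under each joint-origin scenario and score the pipeline.

    Per scenario, ``n_pairs_per_scenario`` pairs are generated over a seed
    sweep at the default study conditions (WES-like depth 300); each runs the
    full filter → clonality → flow → pattern cascade.
    """
    cfg = config or PipelineConfig()
    rng = np.random.default_rng(seed)
    accuracy = {}
    correct_clonality = total_clonality = 0
    retention_to_sweeping = 0
    for scenario in JOINT_SCENARIOS:
        hits = 0
        for _ in range(n_pairs_per_scenario):
            pair_seed = int(rng.integers(0, 2**31 - 1))
            sim = simulate_pair(
                ScenarioConfig(scenario=scenario, seed=pair_seed,
                               mean_depth=mean_depth)
            )
            result = analyze_pair(
                f"{scenario}_{pair_seed}",
                sim.pt_variants,
                sim.pdx_variants,
                purity_pt=sim.config.purity_pt,
                purity_pdx=sim.config.purity_pdx,
                pt_segments=sim.pt_segments,
                pdx_segments=sim.pdx_segments,
                raw_pool_pt=sim.raw_pool_pt,
                raw_pool_pdx=sim.raw_pool_pdx,
                config=cfg,
            )
            if result.pattern.pattern == _PATTERN_FOR[scenario]:
                hits += 1
            elif (scenario == "retention"
                  and result.pattern.pattern == "clone_sweeping"):
                retention_to_sweeping += 1
            c, t = _score_clonality(sim, result)
            correct_clonality += c
            total_clonality += t
        accuracy[scenario] = hits / n_pairs_per_scenario
    return RecoveryReport(
        pattern_accuracy=accuracy,
        pattern_accuracy_overall=float(np.mean(list(accuracy.values()))),
        clonality_accuracy=correct_clonality / total_clonality,
        n_pairs_per_scenario=n_pairs_per_scenario,
        n_clonality_calls=total_clonality,
        retention_to_sweeping=retention_to_sweeping,
    )


def ci_coverage_benchmark(
    n_draws: int = 4000,
    seed: int = 0,
    mean_depth: int = 300,
    min_depth: int = 200,
    purity: float = 0.8,
) -> tuple[float, int]:
    """Fraction of 95% CCF intervals containing the true CCF.

    Draws mutations at a spread of true CCFs in a diploid region, samples
    reads at WES-like depth, and checks whether the Wilson-mapped interval
    covers the truth. Only draws with depth >= ``min_depth`` are scored.
    """
    rng = np.random.default_rng(seed)
    true_ccfs = rng.choice([1.0, 0.8, 0.6, 0.4, 0.25], size=n_draws)
    covered = scored = 0
    for ccf in true_ccfs:
        evaf = expected_vaf(ccf, purity, 2, 2, 1)
        depth, alt = sample_reads(evaf, mean_depth, rng)
        if depth < min_depth:
            continue
        rec = VariantRecord(
            chrom="chr1", pos=1, ref="C", alt="T",
            tumor_depth=depth, tumor_alt_reads=alt,
        )
        est = estimate_ccf(rec, purity, 2)
        scored += 1
        if est.ci_low <= ccf <= est.ci_high:
            covered += 1
    return covered / scored, scored
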