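"""PT→PDX clonality flow, evolutionary-pattern classification, and
clonal-neoantigen comparisons.

Each paired sample is summarized by a flow matrix counting mutations by
their (PT state, PDX state) combination, where a state is clonal, subclonal,
ambiguous (including unclassified), or absent. The pattern cascade
formalizes the three engraftment outcomes:

1. **branch seeding** — at least half of the PT clonal mutations are lost in
   the PDX while at least one shared (truncal) mutation is retained;
2. **clone sweeping** — otherwise, some PT-subclonal mutation is clonal in
   the PDX with a CCF increase of at least 0.4;
3. **clone retention** — otherwise, at least 80% of PT clonal mutations are
   clonal in the PDX too;
4. anything else is unclassifiable, as are pairs sharing no mutations.

Retention pairs form group 1; sweeping and branch seeding form group 2
(both mean a PT subclone seeded the PDX).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clonality import CCFEstimate, ClonalityCall
from .errors import ConfigurationError, DegenerateDataError, ValidationError
from .variants import PairedVariantSet, VariantKey

FLOW_STATES = ("clonal", "subclonal", "ambiguous", "absent")


@dataclass(frozen=True)
class Promotion:
    """A PT-subclonal mutation that is clonal in the PDX."""

    key: VariantKey
    ccf_pt: float
    ccf_pdx: float

    @property
    def ccf_increase(self) -> float:
        return self.ccf_pdx - self.ccf_pt


@dataclass
class ClonalityFlow:
    """Counts over (PT state) x (PDX state); the ``absent`` row holds
    PDX-private mutations and the ``absent`` column PT-private ones."""

    counts: pd.DataFrame
    promotions: list[Promotion] = field(default_factory=list)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def n_shared(self) -> int:
        present = list(FLOW_STATES[:3])
        return int(self.counts.loc[present, present].to_numpy().sum())


@dataclass(frozen=True)
class PatternThresholds:
    t_loss: float = 0.5  # min lost-clonal fraction for branch seeding
    t_promote: float = 0.4  # min CCF increase for a sweeping promotion
    t_retain: float = 0.8  # min retained-clonal fraction for retention


@dataclass(frozen=True)
class PatternCall:
    pattern: str  # clone_retention | clone_sweeping | branch_seeding | unclassifiable
    group: str  # group1 | group2 | none
    evidence: dict


@dataclass(frozen=True)
class NeoantigenRecord:
    key: VariantKey
    best_ic50: float  # nM
    clonality: str  # consensus label

    def __post_init__(self):
        if self.best_ic50 <= 0:
            raise ValidationError(f"nonpositive IC50 {self.best_ic50} at {self.key}")


def _state(call: ClonalityCall | None) -> str:
    if call is None:
        return "absent"
    if call.consensus in ("clonal", "subclonal"):
        return call.consensus
    return "ambiguous"  # ambiguous and unclassified are pooled for the flow


def build_flow(
    pair: PairedVariantSet,
    pt_calls: Mapping[VariantKey, ClonalityCall],
    pdx_calls: Mapping[VariantKey, ClonalityCall],
    pt_estimates: Mapping[VariantKey, CCFEstimate | None] | None = None,
    pdx_estimates: Mapping[VariantKey, CCFEstimate | None] | None = None,
) -> ClonalityFlow:
    """Assign every union mutation to exactly one flow cell.

    CCF estimates, when given, let the flow record promotions (PT subclonal →
    PDX clonal) with their CCF increase, which the sweeping rule needs.
    """
    counts = pd.DataFrame(
        0, index=list(FLOW_STATES), columns=list(FLOW_STATES), dtype=int
    )
    promotions = []
    for key in sorted(pair.union):
        in_pt = key in pair.pt_keys
        in_pdx = key in pair.pdx_keys
        if in_pt and key not in pt_calls:
            raise ValidationError(f"mutation {key} present in PT but not classified")
        if in_pdx and key not in pdx_calls:
            raise ValidationError(f"mutation {key} present in PDX but not classified")
        pt_state = _state(pt_calls.get(key)) if in_pt else "absent"
        pdx_state = _state(pdx_calls.get(key)) if in_pdx else "absent"
        counts.loc[pt_state, pdx_state] += 1
        if pt_state == "subclonal" and pdx_state == "clonal":
            ccf_pt = ccf_pdx = float("nan")
            if pt_estimates is not None and pt_estimates.get(key) is not None:
                ccf_pt = pt_estimates[key].ccf_reported
            if pdx_estimates is not None and pdx_estimates.get(key) is not None:
                ccf_pdx = pdx_estimates[key].ccf_reported
            promotions.append(Promotion(key=key, ccf_pt=ccf_pt, ccf_pdx=ccf_pdx))
    return ClonalityFlow(counts=counts, promotions=promotions)


def classify_pattern(
    flow: ClonalityFlow, thresholds: PatternThresholds | None = None
) -> PatternCall:
    """Decision cascade over the clonality flow (see module docstring).

    Branch seeding is tested before sweeping because loss of PT clonal
    mutations is its defining signature. Pairs with no shared mutations are
    unclassifiable (the cohort analysis excludes them).
    """
    th = thresholds or PatternThresholds()
    c = flow.counts
    pt_clonal_total = int(c.loc["clonal"].sum())
    lost_clonal = int(c.loc["clonal", "absent"])
    retained_clonal = int(c.loc["clonal", "clonal"])
    lost_frac = lost_clonal / pt_clonal_total if pt_clonal_total else 0.0
    retained_frac = retained_clonal / pt_clonal_total if pt_clonal_total else 0.0
    promoted = [
        p
        for p in flow.promotions
        if not np.isnan(p.ccf_increase) and p.ccf_increase >= th.t_promote
    ]
    evidence = dict(
        retained_clonal_fraction=retained_frac,
        lost_clonal_fraction=lost_frac,
        promoted_mutation_count=len(promoted),
        n_shared=flow.n_shared,
        n_pt_clonal=pt_clonal_total,
    )

    if flow.n_shared == 0:
        pattern = "unclassifiable"
    elif lost_frac >= th.t_loss and flow.n_shared >= 1:
        pattern = "branch_seeding"
    elif promoted:
        pattern = "clone_sweeping"
    elif retained_frac >= th.t_retain:
        pattern = "clone_retention"
    else:
        pattern = "unclassifiable"

    group = {
        "clone_retention": "group1",
        "clone_sweeping": "group2",
        "branch_seeding": "group2",
        "unclassifiable": "none",
    }[pattern]
    return PatternCall(pattern=pattern, group=group, evidence=evidence)


def count_clonal_neoantigens(
    neoantigens: Sequence[NeoantigenRecord], ic50_threshold: float = 500.0
) -> int:
    """Neoantigens binding MHC at IC50 <= 500 nM (inclusive) on clonal
    mutations."""
    return sum(
        1
        for n in neoantigens
        if n.best_ic50 <= ic50_threshold and n.clonality == "clonal"
    )


@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    test: str


def group_compare(
    x: Sequence[float],
    y: Sequence[float],
    test: str = "wilcoxon_rank_sum",
) -> TestResult:
    """Two-sided group comparisons used in cohort summaries.

    ``wilcoxon_rank_sum`` uses the exact null distribution for n <= 25 per
    group without ties; ``chi_square`` expects a 2x2 table ``(x, y)`` as its
    two rows and applies no continuity correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if test == "wilcoxon_rank_sum":
        if len(x) < 2 or len(y) < 2:
            raise DegenerateDataError("need >= 2 observations per group")
        pooled = np.concatenate([x, y])
        no_ties = len(np.unique(pooled)) == len(pooled)
        method = "exact" if (no_ties and max(len(x), len(y)) <= 25) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        return TestResult(float(res.statistic), float(res.pvalue), test)
    if test == "paired_t":
        if len(x) != len(y) or len(x) < 2:
            raise DegenerateDataError("paired test needs equal-length groups >= 2")
        diffs = x - y
        if np.allclose(diffs.std(ddof=1), 0.0):
            raise DegenerateDataError(
                "paired differences have zero variance; t statistic undefined"
            )
        res = stats.ttest_rel(x, y)
        return TestResult(float(res.statistic), float(res.pvalue), test)
    if test == "spearman":
        if len(x) != len(y) or len(x) < 3:
            raise DegenerateDataError("spearman needs paired vectors of length >= 3")
        rho, p = stats.spearmanr(x, y)
        if np.isnan(rho):
            raise DegenerateDataError("spearman undefined (constant input)")
        return TestResult(float(rho), float(p), test)
    if test == "chi_square":
        table = np.array([x, y], float)
        if table.shape != (2, 2) or (table < 0).any():
            raise DegenerateDataError("chi_square expects a nonnegative 2x2 table")
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            raise DegenerateDataError("chi_square table has an empty margin")
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        return TestResult(float(stat), float(p), test)
    raise ConfigurationError(f"unknown test {test!r}")
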