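"""Synthetic paired PT/PDX cohorts with known clonal structure.

The generator emulates what engraftment does to a tumor's clone composition
under four scenarios:

* ``retention``   — the PDX preserves the PT's clone CCFs;
* ``sweeping``    — a minor PT subclone becomes the PDX major clone and the
  former PT major subclone collapses below it;
* ``branch_seeding`` — the PDX descends from an early branch that shares only
  truncal ancestry with the PT major clone, whose private mutations vanish;
* ``unrelated``   — two disjoint clone trees (mimics pairs whose PT and PDX
  share no mutations at all).

Each mutation's expected allele fraction follows the standard purity /
copy-number dilution, reads are drawn Poisson (depth, truncated at 1) and
binomial (alt reads), trinucleotide contexts are drawn from a signature
mixture, and per-caller support plus injected single-caller artifacts
exercise the consensus filter. Copy-number profiles are integer-CN segment
lists with purity-corrected log2 ratios, identical between PT and PDX except
under ``unrelated``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateDataError
from .scna import Segment
from .signatures import CONTEXTS_96, SignatureMatrix
from .variants import MATCHED_NORMAL_CALLERS, VariantRecord

SCENARIOS = ("retention", "sweeping", "branch_seeding", "unrelated")

#: Toy genome used by the default configurations (name -> length, bp).
DEFAULT_CHROM_LENGTHS = {
    "chr1": 120_000_000,
    "chr2": 100_000_000,
    "chr3": 80_000_000,
    "chr4": 60_000_000,
}

#: Centromere placement on the toy genome (acen bands in the cytoband table).
DEFAULT_CENTROMERES = {
    "chr1": (60_000_000, 63_000_000),
    "chr2": (45_000_000, 48_000_000),
    "chr3": (35_000_000, 38_000_000),
    "chr4": (25_000_000, 28_000_000),
}

# Shared tumor CN events: one arm-level gain, one chromosome loss, one focal
# amplification and one focal deletion, on an otherwise diploid background.
DEFAULT_CN_EVENTS = [
    ("chr1", 63_000_000, 120_000_000, 3),
    ("chr3", 0, 80_000_000, 1),
    ("chr2", 10_000_000, 14_000_000, 5),
    ("chr4", 40_000_000, 42_000_000, 1),
]

# A deliberately different event set for the PDX side of `unrelated` pairs.
UNRELATED_PDX_CN_EVENTS = [
    ("chr2", 48_000_000, 100_000_000, 3),
    ("chr1", 20_000_000, 23_000_000, 5),
    ("chr4", 0, 60_000_000, 1),
]

#: Operational truth label: a clone is "clonal" in a sample iff CCF >= this.
TRUTH_CLONAL_CCF = 0.9

_CALLER_ROSTER = tuple(sorted(MATCHED_NORMAL_CALLERS))
# P(called by exactly k of 4 callers) for true variants, k = 2, 3, 4.
_CALLER_COUNT_PROBS = {2: 0.05, 3: 0.15, 4: 0.80}


def default_cytobands() -> pd.DataFrame:
    """UCSC-style cytoband table for the toy genome (p/q plus acen bands)."""
    rows = []
    for chrom, length in DEFAULT_CHROM_LENGTHS.items():
        c_lo, c_hi = DEFAULT_CENTROMERES[chrom]
        mid = (c_lo + c_hi) // 2
        rows += [
            (chrom, 0, c_lo, "p11", "gneg"),
            (chrom, c_lo, mid, "p11.1", "acen"),
            (chrom, mid, c_hi, "q11.1", "acen"),
            (chrom, c_hi, length, "q11", "gneg"),
        ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "band", "gie_stain"])


def segments_from_events(
    events: Sequence[tuple[str, int, int, int]],
    chrom_lengths: dict[str, int] | None = None,
) -> list[Segment]:
    """Full genome segmentation from a sparse CN event list.

    Gaps between events are filled with diploid (CN 2) segments; log2 ratios
    are purity-corrected, i.e. ``log2(cn / 2)``.
    """
    chrom_lengths = chrom_lengths or DEFAULT_CHROM_LENGTHS
    segments = []
    by_chrom: dict[str, list[tuple[int, int, int]]] = {c: [] for c in chrom_lengths}
    for chrom, start, end, cn in events:
        by_chrom[chrom].append((start, end, cn))
    for chrom, length in chrom_lengths.items():
        cursor = 0
        for start, end, cn in sorted(by_chrom[chrom]):
            if start > cursor:
                segments.append(Segment(chrom, cursor, start, 0.0, total_cn=2))
            segments.append(Segment(chrom, start, end, math.log2(cn / 2), total_cn=cn))
            cursor = end
        if cursor < length:
            segments.append(Segment(chrom, cursor, length, 0.0, total_cn=2))
    return segments


@dataclass(frozen=True)
class Clone:
    """One node of the clone tree with its CCF in each sample.

    Invariants (joint-origin scenarios): children never exceed their parent's
    CCF, and the truncal root sits at CCF 1 in both samples. The
    ``unrelated`` scenario deliberately emits two disjoint trees, each rooted
    at CCF 1 in its own sample and 0 in the other.
    """

    id: str
    parent: str | None
    ccf_pt: float
    ccf_pdx: float
    n_private_mutations: int


@dataclass
class ScenarioConfig:
    scenario: str
    purity_pt: float = 0.7
    purity_pdx: float = 0.9
    mean_depth: int = 300
    n_clones: int | None = None
    mutation_counts: tuple[int, ...] | None = None
    signature_mix: dict[str, float] | None = None
    seed: int = 0
    cn_events: Sequence[tuple[str, int, int, int]] | None = None
    cn_events_pdx: Sequence[tuple[str, int, int, int]] | None = None
    minor_ccf_pt: float | None = None  # CCF of the clone that seeds the PDX
    major_ccf_pt: float | None = None  # CCF of the displaced PT major clone
    subclone_ccfs_pt: tuple[float, ...] | None = None  # retention subclone CCFs
    false_positive_rate: float = 0.1

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ConfigurationError(f"unknown scenario {self.scenario!r}")
        for name in ("purity_pt", "purity_pdx"):
            p = getattr(self, name)
            if not 0 < p <= 1:
                raise ConfigurationError(f"{name}={p} outside (0, 1]")
        if self.signature_mix is not None:
            weights = np.array(list(self.signature_mix.values()), float)
            if (weights < 0).any() or abs(weights.sum() - 1) > 1e-9:
                raise ConfigurationError(
                    "signature_mix weights must be nonnegative and sum to 1"
                )
        if self.n_clones is None:
            self.n_clones = 2 if self.scenario == "unrelated" else 3
        if self.minor_ccf_pt is None:
            self.minor_ccf_pt = 0.05 if self.scenario == "branch_seeding" else 0.2
        if self.major_ccf_pt is None:
            self.major_ccf_pt = 0.95 if self.scenario == "branch_seeding" else 0.6
        if self.mutation_counts is None:
            self.mutation_counts = _default_counts(self.scenario, self.n_clones)
        self.mutation_counts = tuple(self.mutation_counts)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(DEFAULT_CHROM_LENGTHS)

    def pt_profile(self) -> list[Segment]:
        return segments_from_events(
            self.cn_events if self.cn_events is not None else DEFAULT_CN_EVENTS
        )

    def pdx_profile(self) -> list[Segment]:
        if self.cn_events_pdx is not None:
            return segments_from_events(self.cn_events_pdx)
        if self.scenario == "unrelated":
            return segments_from_events(UNRELATED_PDX_CN_EVENTS)
        return self.pt_profile()


def _default_counts(scenario: str, n_clones: int) -> tuple[int, ...]:
    # Mutation burdens per clone, in clone-list order. Branch seeding mirrors
    # the paper's worked case: few truncal mutations, a large doomed PT major
    # clone, and a small seeding branch.
    if scenario == "retention":
        return (30,) + tuple(max(10 - 2 * i, 4) for i in range(n_clones - 1))
    if scenario == "sweeping":
        extras = tuple(6 for _ in range(n_clones - 3))
        return ((25, 10, 8) + extras)[: n_clones]
    if scenario == "branch_seeding":
        extras = tuple(6 for _ in range(n_clones - 3))
        return ((5, 35, 10) + extras)[: n_clones]
    # unrelated: n_clones per tree
    return ((20,) + (8,) * (n_clones - 1)) * 2


def build_clone_tree(config: ScenarioConfig) -> list[Clone]:
    """Construct the clone tree whose CCF geometry defines the scenario."""
    n = config.n_clones
    counts = config.mutation_counts
    scenario = config.scenario
    if scenario == "unrelated":
        if n < 2:
            raise ConfigurationError("unrelated requires n_clones >= 2 per tree")
        expected = 2 * n
    else:
        expected = n
        if n < 2:
            raise ConfigurationError("need n_clones >= 2")
        if scenario == "branch_seeding" and n < 3:
            raise ConfigurationError(
                "branch_seeding needs >= 3 clones (truncal, PT major, seeding branch)"
            )
    if len(counts) != expected:
        raise ConfigurationError(
            f"mutation_counts has {len(counts)} entries; {expected} clones expected"
        )

    clones: list[Clone] = []
    if scenario == "retention":
        if config.subclone_ccfs_pt is not None:
            if len(config.subclone_ccfs_pt) != n - 1:
                raise ConfigurationError(
                    f"subclone_ccfs_pt needs {n - 1} entries for {n} clones"
                )
            ccfs = (1.0,) + tuple(config.subclone_ccfs_pt)
        else:
            ccfs = tuple(1.0 / 2**i for i in range(n))
        parent = None
        for i, ccf in enumerate(ccfs):
            cid = "truncal" if i == 0 else f"sub{i}"
            clones.append(Clone(cid, parent, ccf, ccf, counts[i]))
            parent = cid
    elif scenario == "sweeping":
        if not config.minor_ccf_pt <= 0.3:
            raise ConfigurationError(
                f"sweeping expects a PT minor seeding clone (ccf_pt <= 0.3), "
                f"got {config.minor_ccf_pt}"
            )
        clones.append(Clone("truncal", None, 1.0, 1.0, counts[0]))
        i = 1
        if n >= 3:
            # the PT-major subclone drops below the promoted minor clone
            clones.append(
                Clone("major", "truncal", config.major_ccf_pt, 0.15, counts[i])
            )
            i += 1
        clones.append(Clone("minor", "truncal", config.minor_ccf_pt, 1.0, counts[i]))
        i += 1
        ccf = 0.1
        for j in range(i, n):
            clones.append(Clone(f"sub{j}", "truncal", ccf, ccf / 2, counts[j]))
            ccf /= 2
    elif scenario == "branch_seeding":
        clones.append(Clone("truncal", None, 1.0, 1.0, counts[0]))
        clones.append(Clone("major", "truncal", config.major_ccf_pt, 0.0, counts[1]))
        clones.append(Clone("minor", "truncal", config.minor_ccf_pt, 1.0, counts[2]))
        ccf = config.major_ccf_pt / 2
        for j in range(3, n):
            clones.append(Clone(f"sub{j}", "major", ccf, 0.0, counts[j]))
            ccf /= 2
    else:  # unrelated
        for side, sample in enumerate(("pt", "pdx")):
            ccf = 1.0
            parent = None
            for i in range(n):
                cid = f"{sample}_truncal" if i == 0 else f"{sample}_sub{i}"
                clones.append(
                    Clone(
                        cid,
                        parent,
                        ccf if sample == "pt" else 0.0,
                        ccf if sample == "pdx" else 0.0,
                        counts[side * n + i],
                    )
                )
                parent, ccf = cid, ccf / 2

    _check_monotone(clones)
    return clones


def _check_monotone(clones: list[Clone]) -> None:
    by_id = {c.id: c for c in clones}
    for clone in clones:
        if clone.parent is None:
            continue
        parent = by_id[clone.parent]
        for attr in ("ccf_pt", "ccf_pdx"):
            if getattr(clone, attr) > getattr(parent, attr) + 1e-9:
                raise ConfigurationError(
                    f"clone {clone.id} exceeds parent {parent.id} in {attr}"
                )


def expected_vaf(
    ccf: float,
    purity: float,
    cn_tumor: int,
    cn_normal: int = 2,
    multiplicity: int = 1,
) -> float:
    """Expected variant allele fraction under purity and copy-number dilution:

        purity * multiplicity * ccf / (purity*cn_tumor + (1-purity)*cn_normal)
    """
    if ccf < 0 or cn_tumor < 0 or cn_normal < 0:
        raise ConfigurationError("negative argument to expected_vaf")
    if not 0 < purity <= 1:
        raise ConfigurationError(f"purity {purity} outside (0, 1]")
    if multiplicity < 1:
        raise ConfigurationError("multiplicity must be >= 1")
    denom = purity * cn_tumor + (1 - purity) * cn_normal
    if denom == 0:
        raise DegenerateDataError("zero total copy number at locus")
    return purity * multiplicity * ccf / denom


def sample_reads(
    evaf: float | np.ndarray,
    mean_depth: float,
    rng: int | np.random.Generator,
) -> tuple[np.ndarray, np.ndarray] | tuple[int, int]:
    """Draw (depth, alt_reads): depth ~ Poisson(mean_depth) truncated at >= 1,
    alt_reads ~ Binomial(depth, evaf)."""
    if mean_depth <= 0:
        raise ConfigurationError("mean_depth must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    scalar = np.isscalar(evaf)
    evaf = np.atleast_1d(np.asarray(evaf, float))
    depth = rng.poisson(mean_depth, size=evaf.shape)
    while (zero := depth == 0).any():  # truncation at >= 1
        depth[zero] = rng.poisson(mean_depth, size=int(zero.sum()))
    alt = rng.binomial(depth, evaf)
    if scalar:
        return int(depth[0]), int(alt[0])
    return depth, alt


def assign_contexts(
    n_mutations: int,
    signature_mix: dict[str, float] | None,
    signature_matrix: SignatureMatrix | None,
    rng: int | np.random.Generator,
) -> list[str]:
    """Draw trinucleotide context labels from a signature mixture.

    With no mixture/matrix the 96 contexts are drawn uniformly.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if n_mutations == 0:
        return []
    if signature_mix is None or signature_matrix is None:
        probs = np.full(96, 1 / 96)
    else:
        unknown = set(signature_mix) - set(signature_matrix.signatures)
        if unknown:
            raise ConfigurationError(
                f"signature_mix references unknown signature(s) {sorted(unknown)}"
            )
        probs = np.zeros(96)
        for sig, w in signature_mix.items():
            probs += w * signature_matrix[sig].to_numpy()
        probs /= probs.sum()
    idx = rng.choice(96, size=n_mutations, p=probs)
    return [CONTEXTS_96[i] for i in idx]


_ALT_FOR = {
    "C>A": ("C", "A"), "C>G": ("C", "G"), "C>T": ("C", "T"),
    "T>A": ("T", "A"), "T>C": ("T", "C"), "T>G": ("T", "G"),
}


def _context_alleles(context: str) -> tuple[str, str]:
    return _ALT_FOR[context[2:5]]


@dataclass
class SimulatedPair:
    """Paired PT/PDX tables plus the generating truth."""

    config: ScenarioConfig
    clones: list[Clone]
    pt_variants: list[VariantRecord]
    pdx_variants: list[VariantRecord]
    pt_segments: list[Segment]
    pdx_segments: list[Segment]
    truth: pd.DataFrame

    @property
    def raw_pool_pt(self) -> dict:
        return {r.key: r for r in self.pt_variants}

    @property
    def raw_pool_pdx(self) -> dict:
        return {r.key: r for r in self.pdx_variants}

    def true_keys(self, sample: str) -> set:
        """Keys of non-artifact mutations truly present (CCF > 0) in a sample."""
        t = self.truth
        rows = t[~t.is_artifact & (t[f"ccf_{sample}"] > 0)]
        return set(zip(rows.chrom, rows.pos, rows.ref, rows.alt))

    def truth_clonality(self, sample: str) -> dict:
        """Key -> operational truth label (clonal iff CCF >= 0.9)."""
        t = self.truth[~self.truth.is_artifact]
        out = {}
        for row in t.itertuples():
            ccf = getattr(row, f"ccf_{sample}")
            if ccf > 0:
                out[(row.chrom, row.pos, row.ref, row.alt)] = (
                    "clonal" if ccf >= TRUTH_CLONAL_CCF else "subclonal"
                )
        return out


def _draw_positions(n: int, chrom_lengths: dict[str, int], rng, used: set) -> list:
    chroms = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], float)
    probs = lengths / lengths.sum()
    out = []
    while len(out) < n:
        c = chroms[rng.choice(len(chroms), p=probs)]
        pos = int(rng.integers(1, chrom_lengths[c] + 1))
        if (c, pos) not in used:
            used.add((c, pos))
            out.append((c, pos))
    return out


def _draw_callers(rng) -> frozenset:
    ks = list(_CALLER_COUNT_PROBS)
    k = ks[rng.choice(len(ks), p=list(_CALLER_COUNT_PROBS.values()))]
    idx = rng.choice(len(_CALLER_ROSTER), size=k, replace=False)
    return frozenset(_CALLER_ROSTER[i] for i in idx)


def _cn_lookup(segments: list[Segment], chrom: str, pos: int) -> int:
    for seg in segments:
        if seg.chrom == chrom and seg.start < pos <= seg.end:
            return seg.total_cn
    raise DegenerateDataError(f"position {chrom}:{pos} outside the CN profile")


def simulate_pair(
    config: ScenarioConfig,
    signature_matrix: SignatureMatrix | None = None,
) -> SimulatedPair:
    """Generate one paired PT/PDX dataset with full truth retained.

    Mutations whose sampled alt-read count is zero in a sample are absent
    from that sample's variant table (but stay in the truth). Single-caller
    artifact records are injected per sample at ``false_positive_rate`` of
    the true mutation count to exercise the consensus filter.
    """
    rng = np.random.default_rng(config.seed)
    clones = build_clone_tree(config)
    pt_profile = config.pt_profile()
    pdx_profile = config.pdx_profile()
    chrom_lengths = config.chrom_lengths

    n_true = sum(c.n_private_mutations for c in clones)
    used: set = set()
    positions = _draw_positions(n_true, chrom_lengths, rng, used)
    contexts = assign_contexts(n_true, config.signature_mix, signature_matrix, rng)

    mutations = []  # (clone, chrom, pos, ref, alt, context)
    i = 0
    for clone in clones:
        for _ in range(clone.n_private_mutations):
            chrom, pos = positions[i]
            ref, alt = _context_alleles(contexts[i])
            mutations.append((clone, chrom, pos, ref, alt, contexts[i]))
            i += 1

    tables: dict[str, list[VariantRecord]] = {"pt": [], "pdx": []}
    truth_rows = []
    for clone, chrom, pos, ref, alt, context in mutations:
        for sample, purity, profile in (
            ("pt", config.purity_pt, pt_profile),
            ("pdx", config.purity_pdx, pdx_profile),
        ):
            ccf = clone.ccf_pt if sample == "pt" else clone.ccf_pdx
            cn = _cn_lookup(profile, chrom, pos)
            evaf = expected_vaf(ccf, purity, cn, 2, 1) if ccf > 0 else 0.0
            depth, alt_reads = sample_reads(evaf, config.mean_depth, rng)
            if alt_reads == 0:
                continue
            normal_depth = max(int(rng.poisson(config.mean_depth)), 1)
            tables[sample].append(
                VariantRecord(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    callers=_draw_callers(rng),
                    tumor_depth=depth,
                    tumor_alt_reads=alt_reads,
                    normal_depth=normal_depth,
                    normal_vaf=0.0,
                    population_af=0.0,
                )
            )
        truth_rows.append(
            dict(
                chrom=chrom, pos=pos, ref=ref, alt=alt, clone=clone.id,
                ccf_pt=clone.ccf_pt, ccf_pdx=clone.ccf_pdx, context=context,
                is_artifact=False, artifact_sample="", scenario=config.scenario,
            )
        )

    n_artifacts = int(round(config.false_positive_rate * n_true))
    for sample in ("pt", "pdx"):
        positions = _draw_positions(n_artifacts, chrom_lengths, rng, used)
        art_contexts = assign_contexts(
            n_artifacts, config.signature_mix, signature_matrix, rng
        )
        for (chrom, pos), context in zip(positions, art_contexts):
            ref, alt = _context_alleles(context)
            vaf = float(rng.uniform(0.05, 0.25))
            depth, alt_reads = sample_reads(vaf, config.mean_depth, rng)
            caller = _CALLER_ROSTER[rng.choice(len(_CALLER_ROSTER))]
            tables[sample].append(
                VariantRecord(
                    chrom=chrom, pos=pos, ref=ref, alt=alt,
                    callers=frozenset({caller}),
                    tumor_depth=depth, tumor_alt_reads=max(alt_reads, 1),
                    normal_depth=max(int(rng.poisson(config.mean_depth)), 1),
                    normal_vaf=0.0, population_af=0.0,
                )
            )
            truth_rows.append(
                dict(
                    chrom=chrom, pos=pos, ref=ref, alt=alt, clone="artifact",
                    ccf_pt=0.0, ccf_pdx=0.0, context=context,
                    is_artifact=True, artifact_sample=sample,
                    scenario=config.scenario,
                )
            )

    truth = pd.DataFrame(truth_rows)
    return SimulatedPair(
        config=config,
        clones=clones,
        pt_variants=tables["pt"],
        pdx_variants=tables["pdx"],
        pt_segments=pt_profile,
        pdx_segments=pdx_profile,
        truth=truth,
    )
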