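"""Somatic copy-number concordance between paired samples.

Works on segment tables (log2 ratio of tumor to diploid normal, optionally
with absolute integer copy number). Provides whole-genome-doubling calls,
arm-level genomic-instability (GI) scores, 1-Mb binned profiles with Pearson
correlation, and focal-event detection, breakpoint matching and rescue.

Coordinates are 0-based half-open internally; the SEG reader in
:mod:`pdxevo.io` converts from the 1-based inclusive file convention.
"Copy number ratio" throughout means the log2 ratio, the segmentation tools'
native unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, ValidationError

Interval = tuple[str, int, int]


@dataclass(frozen=True)
class Segment:
    """Half-open genomic interval with a log2 copy ratio."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    log2_ratio: float
    n_markers: int | None = None
    total_cn: int | None = None
    minor_cn: int | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValidationError(
                f"segment {self.chrom}:{self.start}-{self.end} has start >= end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ArmDefinition:
    chrom: str
    arm: str  # "p" or "q"
    start: int
    end: int

    @property
    def name(self) -> str:
        return f"{self.chrom}{self.arm}"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FocalEvent:
    """A sub-arm copy-number event; ``rescued`` events were recovered from the
    paired sample at the relaxed ratio threshold."""

    segment: Segment
    arm: str
    direction: str  # amplification | deletion
    provenance: str = "primary"  # primary | rescued


def validate_segments(segments: Sequence[Segment]) -> None:
    """Segments must be non-overlapping within each chromosome."""
    by_chrom: dict[str, list[Segment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"overlapping segments on {chrom}: "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )


def call_wgd(ploidy: float) -> bool:
    """Whole-genome doubling: ploidy strictly above 2.5."""
    if ploidy <= 0:
        raise ValidationError(f"nonpositive ploidy {ploidy}")
    return ploidy > 2.5


def _masked_overlap(start: int, end: int, lo: int, hi: int, mask: Sequence[Interval], chrom: str) -> int:
    """Length of [start,end) ∩ [lo,hi) minus any masked intervals on chrom."""
    s, e = max(start, lo), min(end, hi)
    if s >= e:
        return 0
    length = e - s
    for mc, ms, me in mask:
        if mc == chrom:
            length -= max(0, min(e, me) - max(s, ms))
    return max(length, 0)


def gi_score(
    segments: Sequence[Segment],
    arms: Sequence[ArmDefinition],
    threshold: float = 0.3,
    mask: Sequence[Interval] = (),
) -> tuple[dict[str, float], float]:
    """Genomic-instability score.

    Per arm: the base-pair fraction of covered (unmasked) arm territory whose
    segment log2 ratio exceeds ``threshold`` in magnitude (strict).  The
    sample score is the unweighted mean over arms with nonzero coverage.

    Returns ``(per_arm, total)``. Arms with no coverage are omitted from
    ``per_arm`` and from the mean.
    """
    per_arm: dict[str, float] = {}
    for arm in arms:
        covered = altered = 0
        for seg in segments:
            if seg.chrom != arm.chrom:
                continue
            ov = _masked_overlap(seg.start, seg.end, arm.start, arm.end, mask, seg.chrom)
            covered += ov
            if abs(seg.log2_ratio) > threshold:
                altered += ov
        if covered > 0:
            per_arm[arm.name] = altered / covered
    if not per_arm:
        raise DegenerateDataError("no arm has covered length; GI undefined")
    return per_arm, float(np.mean(list(per_arm.values())))


def bin_profile(
    segments: Sequence[Segment],
    chrom_lengths: dict[str, int],
    bin_size: int = 1_000_000,
    mask: Sequence[Interval] = (),
) -> pd.Series:
    """Overlap-length-weighted mean log2 ratio in fixed genomic windows.

    Returns a Series indexed by ``(chrom, bin_start)``; bins with no
    (unmasked) coverage are NaN.
    """
    index = []
    for chrom in chrom_lengths:
        for start in range(0, chrom_lengths[chrom], bin_size):
            index.append((chrom, start))
    values = pd.Series(
        np.nan, index=pd.MultiIndex.from_tuples(index, names=["chrom", "bin_start"])
    )
    weight = pd.Series(0.0, index=values.index)
    total = pd.Series(0.0, index=values.index)
    for seg in segments:
        if seg.chrom not in chrom_lengths:
            continue
        first = seg.start // bin_size
        last = (seg.end - 1) // bin_size
        for b in range(first, last + 1):
            lo = b * bin_size
            hi = min(lo + bin_size, chrom_lengths[seg.chrom])
            ov = _masked_overlap(seg.start, seg.end, lo, hi, mask, seg.chrom)
            if ov > 0:
                key = (seg.chrom, lo)
                weight[key] += ov
                total[key] += ov * seg.log2_ratio
    covered = weight > 0
    values[covered] = total[covered] / weight[covered]
    return values


def profile_correlation(vec_a: pd.Series, vec_b: pd.Series) -> float:
    """Pearson correlation over jointly non-missing bins (>= 3 required)."""
    joined = pd.concat([vec_a, vec_b], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise DegenerateDataError(
            f"only {len(joined)} jointly covered bins; need >= 3"
        )
    a = joined.iloc[:, 0].to_numpy(float)
    b = joined.iloc[:, 1].to_numpy(float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateDataError("zero variance in a binned profile")
    return float(np.corrcoef(a, b)[0, 1])


def _assign_arm(seg: Segment, arms: Sequence[ArmDefinition]) -> ArmDefinition | None:
    best, best_ov = None, 0
    for arm in arms:
        if arm.chrom != seg.chrom:
            continue
        ov = min(seg.end, arm.end) - max(seg.start, arm.start)
        if ov > best_ov:
            best, best_ov = arm, ov
    return best


def detect_focal(
    segments: Sequence[Segment],
    arms: Sequence[ArmDefinition],
    ratio_threshold: float = 0.3,
    max_arm_fraction: float = 0.5,
) -> list[FocalEvent]:
    """Focal events: segment shorter than half its chromosome arm with a log2
    ratio strictly beyond ±``ratio_threshold``."""
    events = []
    for seg in segments:
        if abs(seg.log2_ratio) <= ratio_threshold:
            continue
        arm = _assign_arm(seg, arms)
        if arm is None or seg.length >= max_arm_fraction * arm.length:
            continue
        direction = "amplification" if seg.log2_ratio > 0 else "deletion"
        events.append(FocalEvent(segment=seg, arm=arm.name, direction=direction))
    return events


def _breakpoint_distance(a: FocalEvent, b: FocalEvent) -> tuple[int, int]:
    return (abs(a.segment.start - b.segment.start), abs(a.segment.end - b.segment.end))


def match_focal(
    events_a: Sequence[FocalEvent],
    events_b: Sequence[FocalEvent],
    window: int = 10_000,
) -> tuple[list[tuple[FocalEvent, FocalEvent]], list[FocalEvent], list[FocalEvent]]:
    """Greedy 1-to-1 breakpoint matching of focal events between samples.

    A match requires the same chromosome, the same direction, and both
    breakpoints within ±``window`` bp (inclusive). Multi-candidate ties are
    resolved by the smallest summed breakpoint distance. Symmetric in its two
    arguments.
    """
    candidates = []
    for i, ea in enumerate(events_a):
        for j, eb in enumerate(events_b):
            if ea.segment.chrom != eb.segment.chrom or ea.direction != eb.direction:
                continue
            ds, de = _breakpoint_distance(ea, eb)
            if ds <= window and de <= window:
                candidates.append((ds + de, i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched = []
    for _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched.append((events_a[i], events_b[j]))
    unmatched_a = [e for i, e in enumerate(events_a) if i not in used_a]
    unmatched_b = [e for j, e in enumerate(events_b) if j not in used_b]
    return matched, unmatched_a, unmatched_b


def rescue_focal(
    unmatched: Sequence[FocalEvent],
    paired_segments: Sequence[Segment],
    window: int = 10_000,
    rescue_ratio: float = 0.1,
) -> list[tuple[FocalEvent, FocalEvent]]:
    """Recover shared focal events missed by the primary threshold.

    An unmatched event gains a partner when the paired sample's segmentation
    contains a same-chromosome segment with both breakpoints within
    ±``window`` bp and a log2 ratio strictly beyond ``rescue_ratio`` in the
    event's direction. The partner is returned as a ``rescued`` FocalEvent.
    """
    rescued = []
    for event in unmatched:
        best = None
        for seg in paired_segments:
            if seg.chrom != event.segment.chrom:
                continue
            if event.direction == "amplification" and not seg.log2_ratio > rescue_ratio:
                continue
            if event.direction == "deletion" and not seg.log2_ratio < -rescue_ratio:
                continue
            ds = abs(seg.start - event.segment.start)
            de = abs(seg.end - event.segment.end)
            if ds <= window and de <= window:
                if best is None or ds + de < best[0]:
                    best = (ds + de, seg)
        if best is not None:
            partner = FocalEvent(
                segment=best[1],
                arm=event.arm,
                direction=event.direction,
                provenance="rescued",
            )
            rescued.append((event, partner))
    return rescued


def cn_at(segments: Sequence[Segment], chrom: str, pos: int) -> int | None:
    """Integer total copy number at a 1-based position, if annotated."""
    for seg in segments:
        if seg.chrom == chrom and seg.start < pos <= seg.end:
            return seg.total_cn
    return None
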