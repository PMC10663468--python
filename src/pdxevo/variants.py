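"""Somatic-variant consensus filtering and paired-sample statistics.

Implements the multi-caller voting rule (>= 2 of 4 callers with a matched
normal; 3 of 3 in tumor-only mode), the hard threshold cascade on depths,
allele fractions, population frequency, indel length and region class, the
cross-sample rescue of mutations that pass filters in only one member of a
PT/PDX pair, and the pair-level mutational-similarity and mutation-rate
summaries.

Variant identity is ``(chrom, pos, ref, alt)`` with 1-based VCF coordinates;
indels are expected left-normalized upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from .errors import ConfigurationError, DegenerateDataError, ValidationError

MATCHED_NORMAL_CALLERS = frozenset({"MuTect2", "VarScan", "Strelka", "Pindel"})
TUMOR_ONLY_CALLERS = frozenset({"MuTect2", "VarScan", "Strelka"})

REGION_CLASSES = ("exonic_splicing", "intergenic", "intronic", "off_target")

VariantKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class VariantRecord:
    """One somatic SNV/indel call in one sample.

    ``tumor_vaf`` is derived from read counts when not supplied; if both are
    present they must agree to 1e-6.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    callers: frozenset[str] = frozenset()
    tumor_depth: int | None = None
    tumor_alt_reads: int | None = None
    tumor_vaf: float | None = None
    normal_depth: int | None = None
    normal_vaf: float | None = None
    population_af: float | None = None
    indel_length: int = 0
    region_class: str = "exonic_splicing"
    multiallelic_or_mnp: bool = False
    bias_fail: bool = False  # upstream strand/PCR-bias flag, honored if set
    provenance: str = "called"  # called | rescued

    def __post_init__(self):
        if not isinstance(self.callers, frozenset):
            object.__setattr__(self, "callers", frozenset(self.callers))
        if self.tumor_vaf is None and self.tumor_depth:
            object.__setattr__(
                self, "tumor_vaf", self.tumor_alt_reads / self.tumor_depth
            )
        elif (
            self.tumor_vaf is not None
            and self.tumor_depth
            and self.tumor_alt_reads is not None
            and abs(self.tumor_vaf - self.tumor_alt_reads / self.tumor_depth) > 1e-6
        ):
            raise ValidationError(
                f"tumor_vaf {self.tumor_vaf} inconsistent with "
                f"{self.tumor_alt_reads}/{self.tumor_depth} at {self.key}",
                record=self,
            )
        if self.region_class not in REGION_CLASSES:
            raise ValidationError(
                f"unknown region class {self.region_class!r} at {self.key}",
                record=self,
            )

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class PairedVariantSet:
    """PT and PDX variant lists with the induced union partition."""

    pt: list[VariantRecord]
    pdx: list[VariantRecord]

    def __post_init__(self):
        for name, records in (("pt", self.pt), ("pdx", self.pdx)):
            keys = [r.key for r in records]
            if len(keys) != len(set(keys)):
                dupes = {k for k in keys if keys.count(k) > 1}
                raise ValidationError(f"duplicate {name} variant keys: {sorted(dupes)}")

    @property
    def pt_keys(self) -> set[VariantKey]:
        return {r.key for r in self.pt}

    @property
    def pdx_keys(self) -> set[VariantKey]:
        return {r.key for r in self.pdx}

    @property
    def shared(self) -> set[VariantKey]:
        return self.pt_keys & self.pdx_keys

    @property
    def pt_only(self) -> set[VariantKey]:
        return self.pt_keys - self.pdx_keys

    @property
    def pdx_only(self) -> set[VariantKey]:
        return self.pdx_keys - self.pt_keys

    @property
    def union(self) -> set[VariantKey]:
        return self.pt_keys | self.pdx_keys


def consensus_filter(
    records: Iterable[VariantRecord],
    mode: str = "matched_normal",
    roster: frozenset[str] | None = None,
) -> list[VariantRecord]:
    """Keep records supported by enough callers.

    With a matched normal, a record survives when called by at least two of
    the four-caller roster; in tumor-only mode all three callers of the
    reduced roster must agree.
    """
    if mode == "matched_normal":
        roster = roster or MATCHED_NORMAL_CALLERS
        required = 2
        keep = lambda r: len(r.callers) >= required
    elif mode == "tumor_only":
        roster = roster or TUMOR_ONLY_CALLERS
        keep = lambda r: len(r.callers) == len(roster)
    else:
        raise ConfigurationError(f"unknown mode {mode!r}")
    out = []
    for rec in records:
        unknown = rec.callers - roster
        if unknown:
            raise ConfigurationError(
                f"unknown caller(s) {sorted(unknown)} at {rec.key}; roster is "
                f"{sorted(roster)}"
            )
        if keep(rec):
            out.append(rec)
    return out


@dataclass(frozen=True)
class ThresholdConfig:
    min_tumor_depth: int = 14
    min_normal_depth: int = 8
    min_tumor_vaf: float = 0.05
    max_normal_vaf: float = 0.01
    min_tumor_alt_reads: int = 4
    max_population_af: float = 0.001  # strict: keep only < this
    max_indel_length: int = 50  # strict: keep only < this
    mode: str = "matched_normal"


def threshold_filter(
    records: Iterable[VariantRecord], config: ThresholdConfig | None = None
) -> list[VariantRecord]:
    """Apply the hard filter conjunction; boundary values on the five
    depth/VAF inequalities pass, the population-AF and indel-length cuts are
    strict, and only exonic/splicing records in the capture are retained.

    Records missing a field required by the mode raise :class:`ValidationError`
    rather than being dropped silently. A missing ``population_af`` means the
    variant was absent from the population databases and passes that cut.
    """
    cfg = config or ThresholdConfig()
    out = []
    for rec in records:
        required = ["tumor_depth", "tumor_alt_reads", "tumor_vaf"]
        if cfg.mode == "matched_normal":
            required += ["normal_depth", "normal_vaf"]
        missing = [f for f in required if getattr(rec, f) is None]
        if missing:
            raise ValidationError(
                f"record {rec.key} missing required field(s) {missing}", record=rec
            )
        ok = (
            rec.tumor_depth >= cfg.min_tumor_depth
            and rec.tumor_vaf >= cfg.min_tumor_vaf
            and rec.tumor_alt_reads >= cfg.min_tumor_alt_reads
            and (rec.population_af is None or rec.population_af < cfg.max_population_af)
            and abs(rec.indel_length) < cfg.max_indel_length
            and rec.region_class == "exonic_splicing"
            and not rec.multiallelic_or_mnp
            and not rec.bias_fail
        )
        if cfg.mode == "matched_normal":
            ok = (
                ok
                and rec.normal_depth >= cfg.min_normal_depth
                and rec.normal_vaf <= cfg.max_normal_vaf
            )
        if ok:
            out.append(rec)
    return out


def paired_rescue(
    pair: PairedVariantSet,
    raw_pool_pt: Mapping[VariantKey, VariantRecord],
    raw_pool_pdx: Mapping[VariantKey, VariantRecord],
) -> PairedVariantSet:
    """Cross-sample rescue: a mutation that passed all filters in exactly one
    sample is added to the other iff any caller reported it there in the raw
    (pre-filter) outputs.  Rescued records are flagged ``provenance=rescued``.
    Never removes a record; idempotent.
    """
    new_pdx = list(pair.pdx)
    for key in sorted(pair.pt_only):
        if key in raw_pool_pdx:
            new_pdx.append(replace(raw_pool_pdx[key], provenance="rescued"))
    new_pt = list(pair.pt)
    for key in sorted(pair.pdx_only):
        if key in raw_pool_pt:
            new_pt.append(replace(raw_pool_pt[key], provenance="rescued"))
    return PairedVariantSet(pt=new_pt, pdx=new_pdx)


def mutational_similarity(pair: PairedVariantSet) -> float:
    """Fraction of shared mutations over all mutations found in the pair."""
    n_union = len(pair.union)
    if n_union == 0:
        raise DegenerateDataError("mutational similarity undefined on an empty union")
    return len(pair.shared) / n_union


def mutation_rate(n_mutations: int, capture_size_mb: float) -> float:
    """Somatic mutations per megabase of capture."""
    if capture_size_mb <= 0:
        raise DegenerateDataError("capture size must be positive")
    return n_mutations / capture_size_mb
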