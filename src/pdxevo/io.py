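"""Readers and writers for the pipeline's file formats.

Variant tables travel either as a MAF-like TSV with a CALLERS column or as
minimal VCF 4.2 (INFO keys CALLERS, DP, AD plus the auxiliary fields needed
for a lossless round trip). Segments use the SEG convention (1-based
inclusive on disk, converted to the package's 0-based half-open intervals on
read). Cytobands follow the UCSC text layout. Configuration and sample
manifests are YAML.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .errors import ConfigurationError, ValidationError
from .scna import ArmDefinition, Segment
from .signatures import SignatureMatrix
from .variants import VariantRecord

_TSV_COLUMNS = [
    "chrom", "pos", "ref", "alt", "callers", "tumor_depth", "tumor_alt_reads",
    "tumor_vaf", "normal_depth", "normal_vaf", "population_af", "indel_length",
    "region_class", "multiallelic_or_mnp", "bias_fail", "provenance",
]


def write_variants_tsv(records: Iterable[VariantRecord], path) -> None:
    rows = []
    for rec in records:
        row = {c: getattr(rec, c) for c in _TSV_COLUMNS if c != "callers"}
        row["callers"] = ",".join(sorted(rec.callers))
        rows.append(row)
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def _records_from_frame(df: pd.DataFrame) -> list[VariantRecord]:
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        try:
            d = row._asdict()
            callers = d.pop("callers", "")
            callers = frozenset(str(callers).split(",")) if callers else frozenset()
            for key in ("normal_depth", "normal_vaf", "population_af", "tumor_vaf"):
                if key in d and pd.isna(d[key]):
                    d[key] = None
            for key in ("multiallelic_or_mnp", "bias_fail"):
                if key in d:
                    d[key] = bool(d[key])
            records.append(VariantRecord(callers=callers, **d))
        except (TypeError, ValueError, ValidationError) as exc:
            raise ValidationError(f"bad variant row: {exc}", line=i) from exc
    return records


def read_variants(path, dialect: str = "maf_tsv") -> list[VariantRecord]:
    """Load a per-sample variant table from TSV or VCF."""
    if dialect == "maf_tsv":
        df = pd.read_csv(
            path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str},
            keep_default_na=True, na_values=[""], float_precision="round_trip",
        )
        df["callers"] = df["callers"].fillna("")
        return _records_from_frame(df)
    if dialect == "vcf":
        return _read_vcf(path)
    raise ConfigurationError(f"unknown dialect {dialect!r}")


_VCF_INFO_FIELDS = [
    ("CALLERS", "String", "Callers supporting the variant"),
    ("DP", "Integer", "Tumor depth"),
    ("AD", "Integer", "Tumor alt reads"),
    ("NDP", "Integer", "Normal depth"),
    ("NVAF", "Float", "Normal VAF"),
    ("PAF", "Float", "Population allele frequency"),
    ("ILEN", "Integer", "Indel length (0 for SNV)"),
    ("REGION", "String", "Region class"),
    ("PROV", "String", "called or rescued"),
]


def write_vcf(records: Sequence[VariantRecord], path, sample: str = "TUMOR") -> None:
    """Write a minimal VCF 4.2 with all record fields in INFO."""
    contigs = sorted({r.chrom for r in records})
    lines = ["##fileformat=VCFv4.2", f"##source=pdxevo"]
    for c in contigs:
        lines.append(f"##contig=<ID={c}>")
    for key, typ, desc in _VCF_INFO_FIELDS:
        lines.append(
            f'##INFO=<ID={key},Number={"." if key == "CALLERS" else 1},'
            f'Type={typ},Description="{desc}">'
        )
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for rec in sorted(records, key=lambda r: r.key):
        info = [
            "CALLERS=" + ",".join(sorted(rec.callers)),
            f"DP={rec.tumor_depth}",
            f"AD={rec.tumor_alt_reads}",
        ]
        if rec.normal_depth is not None:
            info.append(f"NDP={rec.normal_depth}")
        if rec.normal_vaf is not None:
            info.append(f"NVAF={rec.normal_vaf:g}")
        if rec.population_af is not None:
            info.append(f"PAF={rec.population_af:g}")
        info += [f"ILEN={rec.indel_length}", f"REGION={rec.region_class}",
                 f"PROV={rec.provenance}"]
        lines.append(
            f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\tPASS\t"
            + ";".join(info)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _read_vcf(path) -> list[VariantRecord]:
    import pysam

    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info
            callers = info.get("CALLERS", ())
            if isinstance(callers, str):
                callers = (callers,)
            records.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    callers=frozenset(callers),
                    tumor_depth=info.get("DP"),
                    tumor_alt_reads=info.get("AD"),
                    normal_depth=info.get("NDP"),
                    normal_vaf=_round_float(info.get("NVAF")),
                    population_af=_round_float(info.get("PAF")),
                    indel_length=info.get("ILEN", 0),
                    region_class=info.get("REGION", "exonic_splicing"),
                    provenance=info.get("PROV", "called"),
                )
            )
    return records


def _round_float(x):
    # pysam yields single-precision INFO floats; recover the printed value
    return None if x is None else float(f"{x:.6g}")


def write_seg(segments: Sequence[Segment], path, sample: str = "sample") -> None:
    """SEG output: 1-based inclusive coordinates, seg.mean = log2 ratio."""
    rows = [
        {
            "sample": sample,
            "chrom": s.chrom,
            "start": s.start + 1,
            "end": s.end,
            "num.mark": s.n_markers if s.n_markers is not None else "",
            "seg.mean": s.log2_ratio,
            "total_cn": s.total_cn if s.total_cn is not None else "",
            "minor_cn": s.minor_cn if s.minor_cn is not None else "",
        }
        for s in segments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_seg(path) -> dict[str, list[Segment]]:
    """Read a SEG file; returns segments per sample, 0-based half-open."""
    df = pd.read_csv(
        path, sep="\t", dtype={"chrom": str}, float_precision="round_trip"
    )
    df.columns = [c.replace(".", "_") for c in df.columns]
    out: dict[str, list[Segment]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            seg = Segment(
                chrom=str(d["chrom"]),
                start=int(d["start"]) - 1,
                end=int(d["end"]),
                log2_ratio=float(d["seg_mean"]),
                n_markers=_opt_int(d.get("num_mark")),
                total_cn=_opt_int(d.get("total_cn")),
                minor_cn=_opt_int(d.get("minor_cn")),
            )
        except (KeyError, TypeError, ValueError, ValidationError) as exc:
            raise ValidationError(f"bad SEG row: {exc}", line=i) from exc
        out.setdefault(str(d.get("sample", "sample")), []).append(seg)
    return out


def _opt_int(x):
    if x is None or (isinstance(x, float) and math.isnan(x)) or x == "":
        return None
    return int(x)


def read_cytobands(path) -> pd.DataFrame:
    """UCSC cytoband text: chrom, start, end, band, gieStain (no header)."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "band", "gie_stain"], dtype={"chrom": str},
    )
    return df


def arms_from_cytobands(
    cytobands: pd.DataFrame, telomere_bp: int = 10_000
) -> tuple[list[ArmDefinition], list[tuple[str, int, int]]]:
    """Derive arm extents and an exclusion mask from a cytoband table.

    The mask covers the acen (centromere) bands plus ``telomere_bp`` at each
    chromosome end.
    """
    arms: list[ArmDefinition] = []
    mask: list[tuple[str, int, int]] = []
    for chrom, sub in cytobands.groupby("chrom", sort=False):
        for arm_letter in ("p", "q"):
            bands = sub[sub["band"].str.startswith(arm_letter)]
            if len(bands) == 0:
                continue
            arms.append(
                ArmDefinition(
                    chrom=chrom,
                    arm=arm_letter,
                    start=int(bands["start"].min()),
                    end=int(bands["end"].max()),
                )
            )
        for row in sub[sub["gie_stain"] == "acen"].itertuples():
            mask.append((chrom, int(row.start), int(row.end)))
        if telomere_bp > 0:
            lo, hi = int(sub["start"].min()), int(sub["end"].max())
            mask.append((chrom, lo, lo + telomere_bp))
            mask.append((chrom, hi - telomere_bp, hi))
    for chrom, sub in cytobands.groupby("chrom", sort=False):
        p_end = sub[sub["band"].str.startswith("p")]["end"].max()
        q_start = sub[sub["band"].str.startswith("q")]["start"].min()
        if pd.notna(p_end) and pd.notna(q_start) and p_end > q_start:
            raise ValidationError(f"{chrom}: p arm extends past q arm start")
    return arms, mask


def read_signature_matrix(path) -> SignatureMatrix:
    """TSV with context rows ('A[C>A]A' style) and signature columns."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return SignatureMatrix(df)


def write_signature_matrix(matrix: SignatureMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="context", float_format="%.17g")


def read_neoantigens(path) -> pd.DataFrame:
    """TSV: chrom, pos, ref, alt, peptide, best_mt_ic50_nm."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    required = {"chrom", "pos", "ref", "alt", "best_mt_ic50_nm"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"neoantigen table missing columns {sorted(missing)}")
    return df


@dataclass
class SampleManifestEntry:
    sample_id: str
    patient_id: str
    role: str  # PT | PDX | normal
    purity: float | None = None
    ploidy: float | None = None
    capture_size_mb: float | None = None
    engraftment_weeks: float | None = None
    prior_treatment: bool | None = None
    variants_path: str | None = None
    segments_path: str | None = None

    def __post_init__(self):
        if self.role not in ("PT", "PDX", "normal"):
            raise ValidationError(f"{self.sample_id}: unknown role {self.role!r}")
        if self.purity is not None and not 0 < self.purity <= 1:
            raise ValidationError(f"{self.sample_id}: purity {self.purity} not in (0,1]")


def read_manifest(path) -> list[SampleManifestEntry]:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or []
    entries = [SampleManifestEntry(**item) for item in raw]
    patients_with_pt = {e.patient_id for e in entries if e.role == "PT"}
    for e in entries:
        if e.role == "PDX" and e.patient_id not in patients_with_pt:
            raise ValidationError(
                f"PDX sample {e.sample_id} references patient {e.patient_id} "
                "with no PT entry"
            )
    return entries


def write_manifest(entries: Sequence[SampleManifestEntry], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump([asdict(e) for e in entries], fh, sort_keys=False)


@dataclass
class PipelineConfig:
    """Every tunable threshold in one place; round-trips through YAML."""

    seed: int = 0
    # variant filters
    min_tumor_depth: int = 14
    min_normal_depth: int = 8
    min_tumor_vaf: float = 0.05
    max_normal_vaf: float = 0.01
    min_tumor_alt_reads: int = 4
    max_population_af: float = 0.001
    max_indel_length: int = 50
    variant_mode: str = "matched_normal"
    # clonality
    clonality_methods: tuple = ("ccf_ci", "binomial_mixture", "kmeans_bic")
    high_ccf_cluster: float = 0.9
    # pattern cascade
    t_loss: float = 0.5
    t_promote: float = 0.4
    t_retain: float = 0.8
    # scna
    gi_threshold: float = 0.3
    bin_size: int = 1_000_000
    focal_ratio: float = 0.3
    focal_rescue_ratio: float = 0.1
    breakpoint_window: int = 10_000
    max_arm_fraction: float = 0.5
    telomere_bp: int = 10_000
    # signatures
    min_signature_mutations: int = 20
    signature_display_threshold: float = 0.25
    # neoantigens
    ic50_threshold: float = 500.0

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["clonality_methods"] = list(self.clonality_methods)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "clonality_methods" in d:
            d["clonality_methods"] = tuple(d["clonality_methods"])
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s) {sorted(unknown)}")
        return cls(**d)
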