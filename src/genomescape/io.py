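"""Data model and file I/O.

Every downstream module consumes only the typed records defined here.
Internal coordinates are 0-based half-open everywhere; 1-based formats
(VCF, SAM) are converted at the boundary. TSV dialects (segments, BAF,
sample sheet) are this package's own and are documented per reader.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd
import pysam

from .reference import ReferenceDict

DEFAULT_MIN_PURITY = 0.20

SV_CLASSES = ("DEL", "DUP", "INS", "INV", "BND")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """Well-formed input violating a data-model invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)

    def contains_pos(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def intersection(self, other: "GenomicInterval") -> Optional["GenomicInterval"]:
        if not self.overlaps(other):
            return None
        return GenomicInterval(self.chrom, max(self.start, other.start),
                               min(self.end, other.end))


@dataclass(frozen=True)
class CopyNumberSegment:
    interval: GenomicInterval
    total_cn: float
    major_cn: float
    minor_cn: float
    log2_ratio: float

    def __post_init__(self):
        if not (self.major_cn >= self.minor_cn >= 0):
            raise ValidationError(
                f"segment {self.interval}: need major_cn >= minor_cn >= 0 "
                f"(got {self.major_cn}, {self.minor_cn})")
        if abs(self.total_cn - (self.major_cn + self.minor_cn)) > 0.01:
            raise ValidationError(
                f"segment {self.interval}: total_cn {self.total_cn} != "
                f"major+minor {self.major_cn + self.minor_cn}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class BafSite:
    chrom: str
    pos: int  # 0-based
    baf: float
    depth: int

    def __post_init__(self):
        if not (0.0 <= self.baf <= 1.0):
            raise ValidationError(f"BAF {self.baf} outside [0,1] at {self.chrom}:{self.pos}")
        if self.depth < 1:
            raise ValidationError(f"depth {self.depth} < 1 at {self.chrom}:{self.pos}")

    @property
    def folded_baf(self) -> float:
        """max(baf, 1-baf): major-allele fraction, phase-free."""
        return max(self.baf, 1.0 - self.baf)


@dataclass(frozen=True)
class Breakend:
    chrom: str
    pos: int  # 0-based
    orientation: str  # '+' or '-' (BEDPE strand convention)

    def __post_init__(self):
        if self.orientation not in ("+", "-"):
            raise ValidationError(f"orientation {self.orientation!r} not in {{+,-}}")


@dataclass(frozen=True)
class StructuralVariant:
    sv_id: str
    bend_a: Breakend
    bend_b: Breakend
    svclass: str
    inserted_seq: Optional[str] = None

    def __post_init__(self):
        if self.svclass not in SV_CLASSES:
            raise ValidationError(f"unknown svclass {self.svclass!r}")
        inter = self.bend_a.chrom != self.bend_b.chrom
        if inter != (self.svclass == "BND"):
            raise ValidationError(
                f"{self.sv_id}: svclass BND iff breakends on different chromosomes")
        if not inter and self.bend_a.pos > self.bend_b.pos:
            raise ValidationError(
                f"{self.sv_id}: intrachromosomal SV must have bend_a.pos <= bend_b.pos")

    @property
    def is_intrachromosomal(self) -> bool:
        return self.bend_a.chrom == self.bend_b.chrom

    def breakends(self) -> tuple[Breakend, Breakend]:
        return (self.bend_a, self.bend_b)


def infer_svclass(chrom_a: str, orient_a: str, chrom_b: str, orient_b: str) -> str:
    """Orientation-pair convention: +/- DEL, -/+ DUP, ++/-- INV, cross-chrom BND."""
    if chrom_a != chrom_b:
        return "BND"
    pair = (orient_a, orient_b)
    if pair == ("+", "-"):
        return "DEL"
    if pair == ("-", "+"):
        return "DUP"
    return "INV"


@dataclass(frozen=True)
class SmallVariant:
    chrom: str
    pos: int  # 0-based
    ref_allele: str
    alt_allele: str
    vaf: float
    gene: Optional[str] = None
    effect: Optional[str] = None

    def __post_init__(self):
        if not (0.0 <= self.vaf <= 1.0):
            raise ValidationError(f"VAF {self.vaf} outside [0,1]")
        if self.ref_allele == self.alt_allele:
            raise ValidationError("ref_allele == alt_allele")

    @property
    def is_indel(self) -> bool:
        return len(self.ref_allele) != len(self.alt_allele)


@dataclass(frozen=True)
class SamplePurityPloidy:
    purity: float
    ploidy: float

    def __post_init__(self):
        if not (0.0 < self.purity <= 1.0):
            raise ValidationError(f"purity {self.purity} outside (0,1]")
        if self.ploidy <= 0:
            raise ValidationError(f"ploidy {self.ploidy} <= 0")


@dataclass(frozen=True)
class Read:
    """A minimal aligned (or unmapped) read; the SAM boundary object."""

    name: str
    seq: str
    chrom: Optional[str] = None  # None -> unmapped
    pos: int = 0                 # 0-based leftmost reference position
    cigar: Optional[str] = None
    mapq: int = 60

    @property
    def is_unmapped(self) -> bool:
        return self.chrom is None

    def cigar_ops(self) -> list[tuple[str, int]]:
        if not self.cigar or self.cigar == "*":
            return []
        return [(m.group(2), int(m.group(1)))
                for m in re.finditer(r"(\d+)([MIDNSHP=X])", self.cigar)]

    def clipped_length(self) -> int:
        return sum(n for op, n in self.cigar_ops() if op in "SH")

    def leading_softclip(self) -> int:
        ops = self.cigar_ops()
        return ops[0][1] if ops and ops[0][0] == "S" else 0

    def trailing_softclip(self) -> int:
        ops = self.cigar_ops()
        return ops[-1][1] if ops and ops[-1][0] == "S" else 0

    def reference_length(self) -> int:
        return sum(n for op, n in self.cigar_ops() if op in "MDN=X")

    def reference_end(self) -> int:
        return self.pos + self.reference_length()

    def gc_fraction(self) -> float:
        if not self.seq:
            return 0.0
        gc = sum(1 for b in self.seq if b in "GCgc")
        return gc / len(self.seq)


@dataclass
class SampleProfile:
    """One tumor/normal pair's full somatic evidence."""

    sample_id: str
    cohort_label: str = "other"
    segments: list[CopyNumberSegment] = field(default_factory=list)
    baf_sites: list[BafSite] = field(default_factory=list)
    svs: list[StructuralVariant] = field(default_factory=list)
    small_variants: list[SmallVariant] = field(default_factory=list)
    purity_ploidy: SamplePurityPloidy = field(
        default_factory=lambda: SamplePurityPloidy(1.0, 2.0))
    tumor_reads_path: Optional[str] = None
    normal_reads_path: Optional[str] = None
    # in-memory read sets (populated by the simulator or loaders)
    tumor_reads: Optional[list[Read]] = None
    normal_reads: Optional[list[Read]] = None

    @property
    def purity(self) -> float:
        return self.purity_ploidy.purity

    def segments_on(self, chrom: str) -> list[CopyNumberSegment]:
        return [s for s in self.segments if s.chrom == chrom]

    def svs_on(self, chrom: str) -> list[StructuralVariant]:
        return [v for v in self.svs
                if v.bend_a.chrom == chrom or v.bend_b.chrom == chrom]

    def reads(self, tissue: str) -> list[Read]:
        """Reads for 'tumor' or 'normal', from memory or from the SAM path."""
        if tissue not in ("tumor", "normal"):
            raise ValueError(f"tissue must be tumor/normal, got {tissue!r}")
        in_mem = self.tumor_reads if tissue == "tumor" else self.normal_reads
        if in_mem is not None:
            return in_mem
        path = self.tumor_reads_path if tissue == "tumor" else self.normal_reads_path
        if path is None:
            return []
        return list(read_sam(path))

    def validate(self, reference: ReferenceDict) -> None:
        validate_segments(self.segments, reference)
        for s in self.baf_sites:
            _check_pos(reference, s.chrom, s.pos, "BAF site")
        for v in self.svs:
            for b in v.breakends():
                _check_pos(reference, b.chrom, b.pos, f"SV {v.sv_id} breakend")
        for m in self.small_variants:
            _check_pos(reference, m.chrom, m.pos, "small variant")


def _check_pos(reference: ReferenceDict, chrom: str, pos: int, what: str) -> None:
    if chrom not in reference:
        raise ValidationError(f"{what}: chromosome {chrom!r} not in reference")
    if not (0 <= pos < reference.length(chrom)):
        raise ValidationError(f"{what}: position {chrom}:{pos} outside chromosome")


def validate_segments(segments: Iterable[CopyNumberSegment],
                      reference: Optional[ReferenceDict] = None) -> None:
    """Enforce per-chromosome sortedness and non-overlap."""
    by_chrom: dict[str, list[CopyNumberSegment]] = {}
    for seg in segments:
        if reference is not None:
            _check_pos(reference, seg.chrom, seg.interval.start, "segment")
            if seg.interval.end > reference.length(seg.chrom):
                raise ValidationError(f"segment {seg.interval} runs off chromosome")
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.interval.start)
        for a, b in zip(segs, segs[1:]):
            if a.interval.end > b.interval.start:
                raise ValidationError(
                    f"overlapping segments on {chrom}: "
                    f"{a.interval.start}-{a.interval.end} and "
                    f"{b.interval.start}-{b.interval.end}")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> list[SmallVariant]:
    """Read small variants from a VCF 4.x file.

    VAF is taken from INFO/AF (per ALT) or, failing that, from the first
    sample's AD pair. Multiallelic records are split; coordinates are
    converted to 0-based.
    """
    out: list[SmallVariant] = []
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: malformed VCF header ({exc})") from exc
    with vf:
        for rec in vf:
            alts = rec.alts or ()
            afs = _record_afs(rec, len(alts))
            if afs is None:
                raise FormatError(
                    f"{path}: record {rec.chrom}:{rec.pos} {rec.ref}>"
                    f"{','.join(alts) or '.'} has neither AF nor AD")
            gene = _info_field(rec, "GENE")
            effect = _info_field(rec, "EFFECT")
            for alt, af in zip(alts, afs):
                out.append(SmallVariant(
                    chrom=rec.chrom, pos=rec.start, ref_allele=rec.ref,
                    alt_allele=alt, vaf=float(af), gene=gene, effect=effect))
    return out


def _info_field(rec, key: str):
    try:
        val = rec.info.get(key)
    except (KeyError, ValueError):  # tag absent from the header
        return None
    return val[0] if isinstance(val, tuple) else val


def _record_afs(rec, n_alts: int):
    if "AF" in rec.info:
        af = rec.info["AF"]
        if not isinstance(af, tuple):
            af = (af,)
        return tuple(float(x) for x in af)
    for sample in rec.samples.values():
        ad = sample.get("AD")
        if ad is not None and len(ad) >= 2 and ad[0] is not None:
            total = sum(int(x) for x in ad if x is not None)
            if total > 0:
                return tuple(int(ad[i + 1]) / total for i in range(n_alts))
    return None


def write_vcf(variants: Iterable[SmallVariant], path: str | Path,
              reference: ReferenceDict) -> None:
    header = pysam.VariantHeader()
    for chrom, length in reference.lengths.items():
        header.contigs.add(chrom, length=length)
    header.info.add("AF", "A", "Float", "Variant allele fraction")
    header.info.add("GENE", "1", "String", "Gene symbol")
    header.info.add("EFFECT", "1", "String", "Consequence label")
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            rec = vf.new_record(contig=v.chrom, start=v.pos,
                                alleles=(v.ref_allele, v.alt_allele))
            rec.info["AF"] = (v.vaf,)
            if v.gene:
                rec.info["GENE"] = v.gene
            if v.effect:
                rec.info["EFFECT"] = v.effect
            vf.write(rec)


# ---------------------------------------------------------------------------
# BEDPE
# ---------------------------------------------------------------------------

_BEDPE_COLS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2",
               "name", "score", "strand1", "strand2", "svclass", "inserted_seq"]


def read_bedpe(path: str | Path) -> list[StructuralVariant]:
    """Read SVs from BEDPE (0-based half-open; strand columns required).

    svclass is taken from column 11 when present, otherwise inferred from
    the orientation pair (+/- DEL, -/+ DUP, ++/-- INV, cross-chrom BND).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 10:
        raise FormatError(f"{path}: BEDPE needs >= 10 columns, found {df.shape[1]}")
    df.columns = _BEDPE_COLS[: df.shape[1]]
    out = []
    for row in df.itertuples(index=False):
        for strand in (row.strand1, row.strand2):
            if strand not in ("+", "-"):
                raise FormatError(f"{path}: strand field {strand!r} outside {{+,-}}")
        svclass = getattr(row, "svclass", None)
        if svclass is None or pd.isna(svclass) or svclass == ".":
            svclass = infer_svclass(row.chrom1, row.strand1, row.chrom2, row.strand2)
        ins = getattr(row, "inserted_seq", None)
        if ins is not None and (pd.isna(ins) or ins == "."):
            ins = None
        a = Breakend(row.chrom1, int(row.start1), row.strand1)
        b = Breakend(row.chrom2, int(row.start2), row.strand2)
        if a.chrom == b.chrom and a.pos > b.pos:
            a, b = b, a
        out.append(StructuralVariant(sv_id=row.name, bend_a=a, bend_b=b,
                                     svclass=svclass, inserted_seq=ins))
    return out


def write_bedpe(svs: Iterable[StructuralVariant], path: str | Path) -> None:
    rows = []
    for v in svs:
        rows.append([v.bend_a.chrom, v.bend_a.pos, v.bend_a.pos + 1,
                     v.bend_b.chrom, v.bend_b.pos, v.bend_b.pos + 1,
                     v.sv_id, ".", v.bend_a.orientation, v.bend_b.orientation,
                     v.svclass, v.inserted_seq or "."])
    pd.DataFrame(rows, columns=_BEDPE_COLS).to_csv(path, sep="\t", header=False,
                                                   index=False)


# ---------------------------------------------------------------------------
# SEG / BAF TSVs
# ---------------------------------------------------------------------------

def read_segments(path: str | Path) -> list[CopyNumberSegment]:
    """SEG-like TSV: chrom, start, end, total_cn, major_cn, minor_cn, log2_ratio."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "total_cn", "major_cn", "minor_cn",
                "log2_ratio"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {required - set(df.columns)}")
    segs = [CopyNumberSegment(
        interval=GenomicInterval(r.chrom, int(r.start), int(r.end)),
        total_cn=float(r.total_cn), major_cn=float(r.major_cn),
        minor_cn=float(r.minor_cn), log2_ratio=float(r.log2_ratio))
        for r in df.itertuples(index=False)]
    validate_segments(segs)
    return sorted(segs, key=lambda s: (s.chrom, s.interval.start))


def write_segments(segments: Iterable[CopyNumberSegment], path: str | Path) -> None:
    rows = [(s.chrom, s.interval.start, s.interval.end, s.total_cn,
             s.major_cn, s.minor_cn, s.log2_ratio) for s in segments]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "total_cn", "major_cn",
                                "minor_cn", "log2_ratio"]
                 ).to_csv(path, sep="\t", index=False)


def read_baf(path: str | Path) -> list[BafSite]:
    """BAF TSV: chrom, pos (0-based), baf, depth."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "baf", "depth"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {required - set(df.columns)}")
    return [BafSite(r.chrom, int(r.pos), float(r.baf), int(r.depth))
            for r in df.itertuples(index=False)]


def write_baf(sites: Iterable[BafSite], path: str | Path) -> None:
    rows = [(s.chrom, s.pos, s.baf, s.depth) for s in sites]
    pd.DataFrame(rows, columns=["chrom", "pos", "baf", "depth"]
                 ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def read_sam(path: str | Path) -> Iterator[Read]:
    """Stream reads from a SAM/BAM file (text SAM is the minimum contract)."""
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for rec in af.fetch(until_eof=True):
            yield Read(
                name=rec.query_name,
                seq=rec.query_sequence or "",
                chrom=None if rec.is_unmapped else rec.reference_name,
                pos=0 if rec.is_unmapped else rec.reference_start,
                cigar=rec.cigarstring,
                mapq=rec.mapping_quality,
            )


def write_sam(reads: Iterable[Read], path: str | Path,
              reference: ReferenceDict) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": n} for c, n in reference.lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as af:
        for r in reads:
            a = pysam.AlignedSegment(af.header)
            a.query_name = r.name
            a.query_sequence = r.seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(r.seq))
            if r.is_unmapped:
                a.is_unmapped = True
            else:
                a.reference_name = r.chrom
                a.reference_start = r.pos
                a.cigarstring = r.cigar or f"{len(r.seq)}M"
                a.mapping_quality = r.mapq
            af.write(a)


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

_SHEET_COLS = ["sample_id", "cohort_label", "purity", "ploidy", "segments",
               "baf", "svs", "small_variants", "tumor_reads", "normal_reads"]


def read_sample_sheet(path: str | Path, *,
                      min_purity: float = DEFAULT_MIN_PURITY,
                      load_files: bool = True) -> list[SampleProfile]:
    """Sample sheet TSV; per-sample file paths are resolved relative to the
    sheet's directory. Samples below the purity floor are rejected."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = set(_SHEET_COLS[:4]) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: sample sheet missing columns {missing}")
    base = path.parent
    profiles = []
    for r in df.itertuples(index=False):
        purity = float(r.purity)
        if purity < min_purity:
            raise ValidationError(
                f"sample {r.sample_id}: purity {purity} below the "
                f"{min_purity} inclusion floor")

        def _resolve(field_name):
            val = getattr(r, field_name, None)
            if val is None or (isinstance(val, float) and math.isnan(val)) or val == ".":
                return None
            return str(base / str(val))

        seg_p, baf_p = _resolve("segments"), _resolve("baf")
        sv_p, vcf_p = _resolve("svs"), _resolve("small_variants")
        profiles.append(SampleProfile(
            sample_id=str(r.sample_id),
            cohort_label=str(r.cohort_label),
            segments=read_segments(seg_p) if load_files and seg_p else [],
            baf_sites=read_baf(baf_p) if load_files and baf_p else [],
            svs=read_bedpe(sv_p) if load_files and sv_p else [],
            small_variants=read_vcf(vcf_p) if load_files and vcf_p else [],
            purity_ploidy=SamplePurityPloidy(purity, float(r.ploidy)),
            tumor_reads_path=_resolve("tumor_reads"),
            normal_reads_path=_resolve("normal_reads"),
        ))
    return profiles


def write_sample_sheet(rows: list[dict], path: str | Path) -> None:
    pd.DataFrame(rows, columns=_SHEET_COLS).to_csv(path, sep="\t", index=False)


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path,
              names: Optional[list[str]] = None) -> None:
    rows = []
    for i, iv in enumerate(intervals):
        name = names[i] if names else f"region_{i}"
        rows.append((iv.chrom, iv.start, iv.end, name))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
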