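"""TP53 (or any gene locus) allele-status classification.

Resolves a locus as wild-type / monoallelic / multi-hit from four evidence
channels — SNV/indel calls, allele-specific copy loss, copy-neutral LOH
(detected from the BAF track at neutral log2 ratio), and SV disruption —
and, for multi-hit calls, decides whether the hits are demonstrably
biallelic. Folded BAF (max(baf, 1-baf)) is used throughout so phasing is
never required.

Biallelic resolution for a two-SNV locus uses a documented cancer-cell-
fraction proxy: CCF = vaf * (rho*CN + 2*(1-rho)) / (rho * mult) at
multiplicity mult=1; two variants whose CCFs sum to more than 1 + tau_ccf
must coexist in some tumor cells and are taken as affecting both alleles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .io import BafSite, CopyNumberSegment, GenomicInterval, SampleProfile, SmallVariant

MECHANISMS = ("SNV", "INDEL", "CN_LOSS", "CN_LOH", "SV_DISRUPTION")
CATEGORIES = ("WILD_TYPE", "MONOALLELIC", "MULTI_HIT")
_CATEGORY_RANK = {c: i for i, c in enumerate(CATEGORIES)}


@dataclass(frozen=True)
class CnLohRegion:
    interval: GenomicInterval
    mean_major_baf: float
    mean_log2: float
    n_sites: int


@dataclass(frozen=True)
class StatusThresholds:
    """Detection thresholds; defaults are insensitive at purity >= 0.4."""

    tau_baf: float = 0.05   # folded-BAF slack below the 0.5 + rho/2 target
    tau_cn: float = 0.2     # |mean log2 ratio| bound for copy neutrality
    n_min_sites: int = 20   # minimum BAF sites per CN-LOH region
    tau_ccf: float = 0.1    # slack on the two-SNV CCF-sum rule


@dataclass(frozen=True)
class AlleleStatusCall:
    sample_id: str
    gene: str
    locus: GenomicInterval
    snv_hits: tuple[SmallVariant, ...]
    mechanisms: frozenset[str]
    category: str
    biallelic: str  # BIALLELIC / UNRESOLVED / NOT_APPLICABLE
    evidence_notes: str = ""


def detect_cnloh(segments: Sequence[CopyNumberSegment],
                 baf_sites: Sequence[BafSite], purity: float, *,
                 thresholds: StatusThresholds = StatusThresholds(),
                 ) -> list[CnLohRegion]:
    """Maximal copy-neutral LOH regions.

    Works over the CN caller's segments (the natural units of allelic
    state): a segment qualifies when |log2 ratio| <= tau_cn and the folded
    BAF of its covered het sites averages at least the purity-scaled
    target 0.5 + rho/2 - tau_baf. Adjacent qualifying segments merge into
    maximal regions, reported when they span >= n_min sites and still meet
    the folded-BAF target overall. Chromosomes without BAF sites are
    skipped.
    """
    th = thresholds
    target = 0.5 + purity / 2.0 - th.tau_baf
    by_chrom: dict[str, list[CopyNumberSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    sites_by_chrom: dict[str, list[BafSite]] = {}
    for s in baf_sites:
        sites_by_chrom.setdefault(s.chrom, []).append(s)

    regions: list[CnLohRegion] = []
    for chrom, segs in by_chrom.items():
        sites = sorted(sites_by_chrom.get(chrom, ()), key=lambda s: s.pos)
        if not sites:
            continue
        segs = sorted(segs, key=lambda s: s.interval.start)
        pos = np.array([s.pos for s in sites])
        folded = np.array([s.folded_baf for s in sites])

        def qualifies(seg: CopyNumberSegment) -> bool:
            if abs(seg.log2_ratio) > th.tau_cn:
                return False
            mask = (pos >= seg.interval.start) & (pos < seg.interval.end)
            return bool(mask.any()) and float(folded[mask].mean()) >= target

        run: list[CopyNumberSegment] = []
        for seg in segs + [None]:
            if seg is not None and qualifies(seg):
                run.append(seg)
                continue
            if run:
                start, end = run[0].interval.start, run[-1].interval.end
                mask = (pos >= start) & (pos < end)
                n = int(mask.sum())
                mean_f = float(folded[mask].mean())
                if n >= th.n_min_sites and mean_f >= target:
                    mean_l2 = float(np.mean([r.log2_ratio for r in run]))
                    regions.append(CnLohRegion(
                        interval=GenomicInterval(chrom, start, end),
                        mean_major_baf=mean_f, mean_log2=mean_l2,
                        n_sites=n))
            run = []
    return regions


def cancer_cell_fraction(vaf: float, purity: float, cn_total: float,
                         multiplicity: float = 1.0) -> float:
    """CCF = vaf * (rho*CN + 2*(1-rho)) / (rho * mult)."""
    if purity <= 0:
        raise ValueError("purity must be positive")
    return vaf * (purity * cn_total + 2.0 * (1.0 - purity)) / (purity * multiplicity)


def classify_locus(locus: GenomicInterval, profile: SampleProfile,
                   cnloh: Sequence[CnLohRegion], *, gene: str = "TP53",
                   thresholds: StatusThresholds = StatusThresholds(),
                   ) -> AlleleStatusCall:
    """Assemble hit mechanisms at ``locus`` and classify.

    CN_LOSS requires an overlapping segment with minor_cn = 0 AND
    total_cn < 2 (allele-specific loss of the wild-type allele; a merely
    subclonal dip does not count). SV_DISRUPTION requires a breakend
    strictly inside the locus.
    """
    snv_hits = tuple(v for v in profile.small_variants
                     if locus.contains_pos(v.chrom, v.pos))
    mechanisms: set[str] = set()
    notes: list[str] = []
    for v in snv_hits:
        mechanisms.add("INDEL" if v.is_indel else "SNV")
    for seg in profile.segments:
        if seg.interval.overlaps(locus) and seg.minor_cn == 0 and seg.total_cn < 2:
            mechanisms.add("CN_LOSS")
            notes.append(f"copy loss {seg.interval.start}-{seg.interval.end}")
    for region in cnloh:
        if region.interval.overlaps(locus):
            mechanisms.add("CN_LOH")
            notes.append(f"CN-LOH folded-BAF {region.mean_major_baf:.3f}")
    for sv in profile.svs:
        if any(locus.contains_pos(b.chrom, b.pos) for b in sv.breakends()):
            mechanisms.add("SV_DISRUPTION")
            notes.append(f"SV {sv.sv_id} breakend in locus")

    n_small = len(snv_hits)
    disruptive = mechanisms & {"CN_LOSS", "CN_LOH", "SV_DISRUPTION"}
    if n_small >= 2 or (n_small >= 1 and disruptive) or (
            {"CN_LOSS", "SV_DISRUPTION"} <= mechanisms):
        category = "MULTI_HIT"
    elif n_small >= 1:
        category = "MONOALLELIC"
    else:
        category = "WILD_TYPE"

    call = AlleleStatusCall(
        sample_id=profile.sample_id, gene=gene, locus=locus,
        snv_hits=snv_hits, mechanisms=frozenset(mechanisms),
        category=category,
        biallelic="NOT_APPLICABLE",
        evidence_notes="; ".join(notes))
    if category == "MULTI_HIT":
        call = resolve_biallelic(call, profile, thresholds=thresholds)
    return call


def resolve_biallelic(call: AlleleStatusCall, profile: SampleProfile, *,
                      thresholds: StatusThresholds = StatusThresholds(),
                      ) -> AlleleStatusCall:
    """Fill the biallelic field of a MULTI_HIT call.

    BIALLELIC when a small variant co-occurs with physical loss/disruption
    of the other allele (CN_LOSS, CN_LOH or SV_DISRUPTION), or when two
    small variants' CCFs (multiplicity 1) sum above 1 + tau_ccf so they
    must coexist in some tumor cells; otherwise UNRESOLVED.
    """
    if call.category != "MULTI_HIT":
        raise ValueError("resolve_biallelic requires a MULTI_HIT call")
    disruptive = call.mechanisms & {"CN_LOSS", "CN_LOH", "SV_DISRUPTION"}
    has_small = bool(call.mechanisms & {"SNV", "INDEL"})
    if (has_small and disruptive) or {"CN_LOSS", "SV_DISRUPTION"} <= call.mechanisms:
        return replace(call, biallelic="BIALLELIC")
    if len(call.snv_hits) >= 2:
        rho = profile.purity
        cn = _locus_total_cn(profile, call.locus)
        ccfs = sorted((cancer_cell_fraction(v.vaf, rho, cn, 1.0)
                       for v in call.snv_hits), reverse=True)
        if ccfs[0] + ccfs[1] > 1.0 + thresholds.tau_ccf:
            return replace(call, biallelic="BIALLELIC")
    return replace(call, biallelic="UNRESOLVED")


def _locus_total_cn(profile: SampleProfile, locus: GenomicInterval) -> float:
    """Length-weighted mean total CN over the locus (2.0 when uncovered)."""
    num = den = 0.0
    for seg in profile.segments:
        inter = seg.interval.intersection(locus)
        if inter:
            num += seg.total_cn * len(inter)
            den += len(inter)
    return num / den if den else 2.0


def classify_cohort(profiles: Sequence[SampleProfile],
                    locus: GenomicInterval, *, gene: str = "TP53",
                    thresholds: StatusThresholds = StatusThresholds(),
                    ) -> list[AlleleStatusCall]:
    calls = []
    for p in profiles:
        cnloh = detect_cnloh(p.segments, p.baf_sites, p.purity,
                             thresholds=thresholds)
        calls.append(classify_locus(locus, p, cnloh, gene=gene,
                                    thresholds=thresholds))
    return calls
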