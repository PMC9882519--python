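"""Telomere content, variant-repeat profiling and interstitial insertions.

Telomere content is reported as TRPM — telomeric reads per GC-content-
matched million reads: the denominator counts only reads whose GC fraction
falls in a window matching telomeric sequence composition (default
0.48-0.52), which controls for per-sample GC bias. A read is telomeric
when a greedy hexamer scan (both strand orientations) finds at least
ceil(6*L/100) accepted hexamers: the canonical t-type TTAGGG plus a panel
of telomere variant repeats (TVRs).

A TVR occurrence is a *singleton* when flanked by >= 3 contiguous t-type
hexamers on each side within the same read — the context in which TTTGGG
enrichment distinguishes TP53-mutated myeloid malignancies.

Interstitial telomere insertions are detected from soft-clipped reads
whose clipped tail is telomeric, clustered by locus, and subtracted
against the matched normal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .chromothripsis import ChromothripsisCall
from .io import Read, StructuralVariant
from .reference import ReferenceDict

T_TYPE = "TTAGGG"
# standard TVR panel; the composition beyond TTTGGG follows common usage
DEFAULT_TVR_SET = ("TCAGGG", "TGAGGG", "TTGGGG", "TTCGGG", "TTTGGG",
                   "ATAGGG", "CATGGG", "CTAGGG", "GTAGGG", "TAAGGG")

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class HexamerUnit:
    hexamer: str  # normalized to the G-rich strand
    offset: int   # index within the decomposition's scan


@dataclass(frozen=True)
class TelomereMetrics:
    sample_id: str
    tissue: str
    n_gc_matched_reads: int
    n_telomeric_reads: int
    trpm: float
    singleton_tvr_counts: dict
    singleton_tvr_norm: dict  # per million GC-matched reads


@dataclass(frozen=True)
class InterstitialTelomereInsertion:
    chrom: str
    pos: int
    n_support_tumor: int
    n_support_normal: int
    clipped_telomeric_fraction: float
    nearest_sv_distance_bp: Optional[int]
    within_chromothripsis_10kb: bool
    normal_subtracted: bool = True


@dataclass(frozen=True)
class InsertionParams:
    min_clip: int = 12
    min_telomeric_fraction: float = 0.8
    min_support: int = 3
    cluster_bp: int = 50
    termini_mask_bp: int = 500_000
    sv_proximity_bp: int = 10_000


def hexamer_decomposition(seq: str, tvr_set: Sequence[str] = DEFAULT_TVR_SET,
                          ) -> tuple[list[HexamerUnit], str]:
    """Greedy non-overlapping hexamer scan of both orientations.

    Returns the richer orientation's decomposition, normalized to G-rich
    hexamers in 5'->3' telomere order, and the orientation used
    ('G' or 'C').
    """
    seq = seq.upper()
    accepted_g = {T_TYPE, *tvr_set}
    accepted_c = {_revcomp(h) for h in accepted_g}

    def scan(accepted):
        units, i, slot = [], 0, 0
        while i + 6 <= len(seq):
            hexamer = seq[i:i + 6]
            if hexamer in accepted:
                units.append((hexamer, slot))
                i += 6
            else:
                i += 1
            slot += 1
        return units

    g_units = scan(accepted_g)
    c_units = scan(accepted_c)
    if len(c_units) > len(g_units):
        # flip to the G strand: reverse order, complement each hexamer;
        # negated offsets keep sequence-contiguity (slot diff 1) intact
        flipped = [HexamerUnit(_revcomp(h), -o) for h, o in reversed(c_units)]
        return flipped, "C"
    return [HexamerUnit(h, o) for h, o in g_units], "G"


def classify_telomeric_read(seq: str, *,
                            tvr_set: Sequence[str] = DEFAULT_TVR_SET,
                            ) -> tuple[bool, list[HexamerUnit]]:
    """A read of length L is telomeric iff its decomposition contains at
    least ceil(6*L/100) accepted hexamers."""
    if len(seq) < 6:
        raise ValueError("read shorter than one hexamer")
    if any(b not in "ACGTacgt" for b in seq):
        return False, []
    units, _ = hexamer_decomposition(seq, tvr_set)
    threshold = math.ceil(6 * len(seq) / 100)
    return len(units) >= threshold, units


def singleton_tvr_profile(decompositions: Iterable[Sequence[HexamerUnit]], *,
                          min_flank: int = 3) -> dict:
    """Count TVR occurrences flanked by >= ``min_flank`` contiguous t-type
    hexamers immediately on each side (within one read)."""
    counts: dict[str, int] = {}
    for units in decompositions:
        hexes = [u.hexamer for u in units]
        offsets = [u.offset for u in units]
        n = len(hexes)
        for i, h in enumerate(hexes):
            if h == T_TYPE:
                continue
            if i < min_flank or i + min_flank >= n:
                continue
            ok = True
            for j in range(i - min_flank, i + min_flank + 1):
                if j != i and hexes[j] != T_TYPE:
                    ok = False
                    break
                # contiguous in the read (greedy slots advance by 6 -> +1)
                if j > i - min_flank and offsets[j] != offsets[j - 1] + 1:
                    ok = False
                    break
            if ok:
                counts[h] = counts.get(h, 0) + 1
    return counts


def telomere_content(reads: Iterable[Read], *, gc_low: float = 0.48,
                     gc_high: float = 0.52, sample_id: str = "",
                     tissue: str = "tumor",
                     tvr_set: Sequence[str] = DEFAULT_TVR_SET,
                     ) -> TelomereMetrics:
    """TRPM and singleton-TVR profile for one read set.

    The GC-matched denominator counts reads with GC in [gc_low, gc_high];
    telomeric reads are counted regardless of their own GC.
    """
    if not (0.0 <= gc_low < gc_high <= 1.0):
        raise ValueError("invalid GC window")
    n_gc = n_tel = 0
    decomps = []
    for r in reads:
        if gc_low <= r.gc_fraction() <= gc_high:
            n_gc += 1
        try:
            is_tel, units = classify_telomeric_read(r.seq, tvr_set=tvr_set)
        except ValueError:
            continue
        if is_tel:
            n_tel += 1
            decomps.append(units)
    if n_gc == 0:
        raise ValueError("zero GC-matched reads; TRPM undefined")
    singles = singleton_tvr_profile(decomps)
    norm = {h: c / n_gc * 1e6 for h, c in singles.items()}
    return TelomereMetrics(sample_id=sample_id, tissue=tissue,
                           n_gc_matched_reads=n_gc, n_telomeric_reads=n_tel,
                           trpm=n_tel / n_gc * 1e6,
                           singleton_tvr_counts=singles,
                           singleton_tvr_norm=norm)


@dataclass(frozen=True)
class TumorNormalComparison:
    ratio: Optional[float]  # None when normal TRPM is 0
    difference: float


def tumor_normal_ratio(metrics_t: TelomereMetrics,
                       metrics_n: TelomereMetrics) -> TumorNormalComparison:
    diff = metrics_t.trpm - metrics_n.trpm
    ratio = metrics_t.trpm / metrics_n.trpm if metrics_n.trpm > 0 else None
    return TumorNormalComparison(ratio=ratio, difference=diff)


# ---------------------------------------------------------------------------
# interstitial telomere insertions
# ---------------------------------------------------------------------------

def _clip_candidates(reads: Iterable[Read], params: InsertionParams,
                     reference: ReferenceDict,
                     tvr_set: Sequence[str]) -> list[tuple[str, int, float]]:
    """(chrom, locus, telomeric fraction) per qualifying clipped read."""
    out = []
    for r in reads:
        if r.is_unmapped or not r.cigar:
            continue
        for side in ("left", "right"):
            clip = (r.leading_softclip() if side == "left"
                    else r.trailing_softclip())
            if clip < params.min_clip:
                continue
            clip_seq = r.seq[:clip] if side == "left" else r.seq[-clip:]
            units, _ = hexamer_decomposition(clip_seq, tvr_set)
            frac = len(units) * 6 / len(clip_seq)
            if frac < params.min_telomeric_fraction:
                continue
            locus = r.pos if side == "left" else r.reference_end()
            length = reference.length(r.chrom)
            if locus < params.termini_mask_bp or locus > length - params.termini_mask_bp:
                continue  # chromosome termini are real telomere
            out.append((r.chrom, locus, frac))
    return out


def detect_interstitial_insertions(
        tumor_reads: Iterable[Read], normal_reads: Optional[Iterable[Read]],
        svs: Sequence[StructuralVariant],
        chromothripsis_calls: Sequence[ChromothripsisCall], *,
        reference: ReferenceDict,
        params: InsertionParams = InsertionParams(),
        tvr_set: Sequence[str] = DEFAULT_TVR_SET,
        ) -> list[InterstitialTelomereInsertion]:
    """Somatic interstitial telomere-insertion calls.

    A candidate locus needs >= ``min_support`` tumor reads whose soft clip
    (>= min_clip bases) is >= 80% telomeric hexamer sequence, clustered
    within ``cluster_bp``; it is somatic only if the matched normal has no
    qualifying clipped read at the locus. Calls are annotated with the
    distance to the nearest SV breakend and a 10-kb chromothripsis
    proximity flag. With ``normal_reads=None`` calls are emitted flagged
    as un-subtracted.
    """
    tumor_cands = _clip_candidates(tumor_reads, params, reference, tvr_set)
    have_normal = normal_reads is not None
    normal_cands = (_clip_candidates(normal_reads, params, reference, tvr_set)
                    if have_normal else [])

    # cluster tumor candidates per chromosome within cluster_bp
    by_chrom: dict[str, list[tuple[int, float]]] = {}
    for chrom, pos, frac in tumor_cands:
        by_chrom.setdefault(chrom, []).append((pos, frac))
    ct_regions = [(c.chrom, c.region) for c in chromothripsis_calls
                  if c.confidence == "HIGH"]
    bend_pos: dict[str, list[int]] = {}
    for v in svs:
        for b in v.breakends():
            bend_pos.setdefault(b.chrom, []).append(b.pos)

    calls = []
    for chrom, items in sorted(by_chrom.items()):
        items.sort()
        cluster: list[tuple[int, float]] = []
        for item in items + [(None, None)]:
            if item[0] is not None and (
                    not cluster or item[0] - cluster[-1][0] <= params.cluster_bp):
                cluster.append(item)
                continue
            if len(cluster) >= params.min_support:
                pos = int(round(sum(p for p, _ in cluster) / len(cluster)))
                n_norm = sum(1 for c, p, _ in normal_cands
                             if c == chrom and abs(p - pos) <= params.cluster_bp)
                if n_norm == 0:
                    dists = [abs(pos - b) for b in bend_pos.get(chrom, [])]
                    near_sv = min(dists) if dists else None
                    in_ct = any(
                        c == chrom and (r.start - params.sv_proximity_bp
                                        <= pos
                                        <= r.end + params.sv_proximity_bp)
                        for c, r in ct_regions)
                    calls.append(InterstitialTelomereInsertion(
                        chrom=chrom, pos=pos, n_support_tumor=len(cluster),
                        n_support_normal=0,
                        clipped_telomeric_fraction=(
                            sum(f for _, f in cluster) / len(cluster)),
                        nearest_sv_distance_bp=near_sv,
                        within_chromothripsis_10kb=in_ct,
                        normal_subtracted=have_normal))
            cluster = [item] if item[0] is not None else []
    return calls
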