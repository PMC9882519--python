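"""Synthetic tumor/normal cohort generator with known ground truth.

Emulates, on a small toy genome, every statistical structure the analysis
pipeline assumes: recurrent arm-level aneuploidy, chromothripsis-like
clustered breakpoints with oscillating copy number, 17p copy-neutral LOH,
TP53 hits at purity-consistent VAF, telomeric reads built from t-type
TTAGGG hexamers plus variant repeats, and interstitial telomere insertions
as soft-clipped reads near SV breakpoints.

The generator observes a strict determinism contract: one global integer
seed, with per-(sample, stage) substreams derived by stable CRC hashing so
adding a sample never perturbs the others. Distributions are stand-ins
chosen to mirror the cohort frequencies reported for TP53-mutated AML/MDS;
they carry no sequence-level realism (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as gio
from .io import (BafSite, Breakend, CopyNumberSegment, GenomicInterval, Read,
                 SamplePurityPloidy, SampleProfile, SmallVariant,
                 StructuralVariant, infer_svclass)
from .reference import ReferenceDict, TOY_GENES, toy_genome

T_TYPE = "TTAGGG"
_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def rng_for(seed: int, *keys) -> np.random.Generator:
    """Substream generator: stable hash of (seed, *keys)."""
    entropy = [int(seed)] + [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng(entropy)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class ChromothripsisSpec:
    probability: float = 0.60            # fraction of samples with an event
    n_breakpoints: tuple[int, int] = (15, 40)
    # (chrom, arm) -> weight; arms chosen to avoid the TP53 and 12p loci
    arm_weights: dict = field(default_factory=lambda: {
        ("chr5", "p"): 0.10, ("chr5", "q"): 0.30, ("chr7", "p"): 0.10,
        ("chr7", "q"): 0.15, ("chr12", "q"): 0.15, ("chr17", "q"): 0.20})
    region_fraction: tuple[float, float] = (0.35, 0.6)  # of the arm length
    n_cn_states: int = 2
    # token floor keeping cut positions distinct; cuts stay effectively
    # uniform so inter-breakpoint gaps remain exponential-like
    min_segment_bp: int = 100


@dataclass
class CnLohSpec:
    probability: float = 0.26            # 11/42 in the reference cohort
    target_arm: tuple[str, str] = ("chr17", "p")


@dataclass
class Tp53Spec:
    # hit-mechanism mix (fractions; mirror the 42-case cohort composition)
    mechanism_mix: dict = field(default_factory=lambda: {
        "SNV+CN_LOSS": 22 / 42, "SNV+CN_LOH": 11 / 42, "TWO_SNV": 3 / 42,
        "SNV+SV": 5 / 42, "MONOALLELIC": 1 / 42, "WILD_TYPE": 0.0})
    vaf_depth: int = 60                  # binomial depth for observed VAF
    indel_fraction: float = 0.25


@dataclass
class TelomereSpec:
    content_mean: float = 3000.0         # TRPM, per-sample normal tissue
    content_sd: float = 400.0
    tumor_shift_mean: float = 0.0        # tumor minus normal, TRPM
    tumor_shift_sd: float = 100.0
    read_length: int = 102               # 17 hexamers
    background_reads: int = 3000         # per tissue; GC-matched denominator
    background_gc_mean: float = 0.45
    background_gc_sd: float = 0.07
    # iid per-hexamer substitution fractions (remainder is t-type)
    tvr_composition: dict = field(default_factory=lambda: {
        "TCAGGG": 0.01, "TGAGGG": 0.01})
    # per-read probability of planting one singleton TVR (>=3 t-type flanks)
    singleton_rate_tumor: dict = field(default_factory=lambda: {"TTTGGG": 0.40})
    singleton_rate_normal: dict = field(default_factory=lambda: {"TTTGGG": 0.20})


@dataclass
class InsertionSpec:
    probability: float = 13 / 42         # samples with >=1 insertion
    extra_insertion_probability: float = 4 / 13  # second locus given one
    support_range: tuple[int, int] = (4, 8)      # clipped tumor reads
    sv_proximal_probability: float = 0.68        # within 10 kb of an SV breakend
    max_sv_offset_bp: int = 8_000
    # anchor long relative to the clip so support reads stay below the
    # telomeric-read hexamer threshold (clip 30 bp = 5 hexamers < ceil(6L/100))
    clip_len: int = 30
    anchor_len: int = 90
    termini_mask_bp: int = 500_000


@dataclass
class MdrSpec:
    chrom: str = "chr12"
    arm: str = "p"
    core: tuple[int, int] = (10_000_000, 12_750_000)  # 2.75 Mb, contains ETV6
    flank_max_bp: int = 3_000_000


@dataclass
class SimulationConfig:
    seed: int = 0
    n_samples: int = 42
    cohort_label: str = "TP53_AML"
    purity_range: tuple[float, float] = (0.4, 0.9)
    # (chrom, arm, kind) -> probability; kind in {loss, gain}
    aneuploidy_spec: dict = field(default_factory=lambda: {
        ("chr5", "q", "loss"): 0.80, ("chr7", "q", "loss"): 0.56,
        ("chr12", "p", "loss"): 0.45, ("chr5", "p", "gain"): 0.10})
    chromothripsis_spec: ChromothripsisSpec = field(default_factory=ChromothripsisSpec)
    cnloh_spec: CnLohSpec = field(default_factory=CnLohSpec)
    tp53_spec: Tp53Spec = field(default_factory=Tp53Spec)
    telomere_spec: TelomereSpec = field(default_factory=TelomereSpec)
    insertion_spec: InsertionSpec = field(default_factory=InsertionSpec)
    mdr_spec: MdrSpec = field(default_factory=MdrSpec)
    baf_site_spacing: int = 100_000
    baf_depth: int = 40
    log2_noise_sd: float = 0.02
    background_sv_range: tuple[int, int] = (2, 8)
    toy_genome: Optional[ReferenceDict] = None

    def reference(self) -> ReferenceDict:
        return self.toy_genome if self.toy_genome is not None else toy_genome()

    def validate(self) -> None:
        for probs in (self.chromothripsis_spec.probability,
                      self.cnloh_spec.probability,
                      self.insertion_spec.probability):
            if not (0.0 <= probs <= 1.0):
                raise ConfigError(f"probability {probs} outside [0,1]")
        if sum(self.telomere_spec.tvr_composition.values()) > 1.0:
            raise ConfigError("TVR composition fractions sum to > 1")
        if self.telomere_spec.read_length < 6:
            raise ConfigError("telomere read length must be >= 6")
        ref = self.reference()
        cs = self.chromothripsis_spec
        for (chrom, arm), w in cs.arm_weights.items():
            start, end = ref.arm(chrom, arm)
            min_region = (end - start) * cs.region_fraction[0]
            if min_region < cs.n_breakpoints[1] * cs.min_segment_bp:
                raise ConfigError(
                    f"toy genome arm {chrom}{arm} too small for "
                    f"{cs.n_breakpoints[1]} breakpoints at "
                    f"{cs.min_segment_bp} bp minimum segment size")


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class SampleTruth:
    sample_id: str
    purity: float
    tp53_category: str                      # WILD_TYPE / MONOALLELIC / MULTI_HIT
    tp53_mechanisms: list[str]
    tp53_biallelic: bool
    cnloh_regions: list[tuple[str, int, int]]
    arm_events: list[tuple[str, str, str]]  # (chrom, arm, loss|gain)
    loss_intervals: list[tuple[str, int, int]]
    chromothripsis_regions: list[tuple[str, int, int]]
    cluster_sizes: list[int]                # planted complex-cluster sizes
    background_sv_count: int
    sv_class_counts: dict
    telomere_content_tumor: float
    telomere_content_normal: float
    insertion_loci: list[tuple[str, int]]


@dataclass
class GroundTruth:
    samples: list[SampleTruth]
    mdr: Optional[tuple[str, int, int]]     # intersection of planted losses

    def to_json(self, path: str | Path) -> None:
        payload = {
            "samples": [dataclasses.asdict(s) for s in self.samples],
            "mdr": self.mdr,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        samples = []
        for s in payload["samples"]:
            s = dict(s)
            for key in ("cnloh_regions", "arm_events", "loss_intervals",
                        "chromothripsis_regions", "insertion_loci"):
                s[key] = [tuple(x) for x in s[key]]
            samples.append(SampleTruth(**s))
        mdr = payload["mdr"]
        return cls(samples=samples, mdr=tuple(mdr) if mdr else None)


# ---------------------------------------------------------------------------
# segment helpers
# ---------------------------------------------------------------------------

def _seg(chrom, start, end, major, minor, purity, rng=None, noise_sd=0.0):
    total = major + minor
    observed = (purity * total + 2 * (1 - purity)) / 2.0
    log2 = float(np.log2(max(observed, 1e-6)))
    if rng is not None and noise_sd > 0:
        log2 += float(rng.normal(0.0, noise_sd))
    return CopyNumberSegment(GenomicInterval(chrom, start, end),
                             total_cn=float(total), major_cn=float(major),
                             minor_cn=float(minor), log2_ratio=log2)


def overlay_segments(base: list[CopyNumberSegment],
                     patch: list[CopyNumberSegment]) -> list[CopyNumberSegment]:
    """Replace the regions covered by ``patch`` inside ``base`` (same chrom)."""
    if not patch:
        return sorted(base, key=lambda s: s.interval.start)
    patch = sorted(patch, key=lambda s: s.interval.start)
    out: list[CopyNumberSegment] = []
    for seg in sorted(base, key=lambda s: s.interval.start):
        pieces = [(seg.interval.start, seg.interval.end)]
        for p in patch:
            nxt = []
            for s0, e0 in pieces:
                if p.interval.end <= s0 or p.interval.start >= e0:
                    nxt.append((s0, e0))
                    continue
                if s0 < p.interval.start:
                    nxt.append((s0, p.interval.start))
                if p.interval.end < e0:
                    nxt.append((p.interval.end, e0))
            pieces = nxt
        for s0, e0 in pieces:
            if e0 > s0:
                out.append(dataclasses.replace(
                    seg, interval=GenomicInterval(seg.chrom, s0, e0)))
    out.extend(patch)
    return sorted(out, key=lambda s: s.interval.start)


# ---------------------------------------------------------------------------
# event simulators
# ---------------------------------------------------------------------------

def simulate_chromothripsis_event(
        chrom: str, n_breakpoints: int, rng: np.random.Generator, *,
        region: GenomicInterval, purity: float = 1.0, n_cn_states: int = 2,
        min_segment_bp: int = 5_000, sv_prefix: str = "ct",
        log2_noise_sd: float = 0.0,
) -> tuple[list[CopyNumberSegment], list[StructuralVariant]]:
    """Plant a shattered region: ``n_breakpoints`` uniform cuts whose
    segments oscillate between two (or three) copy-number states, joined by
    SVs in uniformly random orientation and order."""
    if n_breakpoints < 6:
        raise ConfigError("chromothripsis needs >= 6 breakpoints")
    if len(region) < n_breakpoints * min_segment_bp:
        raise ConfigError(
            f"region {region.chrom}:{region.start}-{region.end} shorter than "
            f"{n_breakpoints} x {min_segment_bp} bp")
    # rejection-free spaced uniform draw
    while True:
        cuts = np.sort(rng.integers(region.start + 1, region.end, n_breakpoints))
        bounds = np.concatenate([[region.start], cuts, [region.end]])
        if np.diff(bounds).min() >= min_segment_bp:
            break
    states = [2, 1] if n_cn_states == 2 else [2, 1, 3]
    cn_seq = []
    cur = 0
    for i in range(len(bounds) - 1):
        cn_seq.append(states[cur])
        if n_cn_states == 2:
            cur = 1 - cur
        else:
            cur = (cur + int(rng.integers(1, len(states)))) % len(states)
    segments = []
    for (s0, e0), cn in zip(zip(bounds[:-1], bounds[1:]), cn_seq):
        major, minor = (1, 1) if cn == 2 else ((1, 0) if cn == 1 else (2, 1))
        segments.append(_seg(chrom, int(s0), int(e0), major, minor, purity,
                             rng, log2_noise_sd))
    # joins: random breakpoint pairs, orientation uniform over 4 classes
    svs = []
    orient_classes = [("+", "-"), ("-", "+"), ("+", "+"), ("-", "-")]
    for i in range(n_breakpoints):
        a, b = rng.choice(n_breakpoints, size=2, replace=False)
        pa, pb = int(cuts[min(a, b)]), int(cuts[max(a, b)])
        if pa == pb:
            continue
        oa, ob = orient_classes[int(rng.integers(4))]
        svs.append(StructuralVariant(
            sv_id=f"{sv_prefix}_{i}",
            bend_a=Breakend(chrom, pa, oa), bend_b=Breakend(chrom, pb, ob),
            svclass=infer_svclass(chrom, oa, chrom, ob)))
    return segments, svs


def simulate_cnloh(chrom_arm: tuple[str, str], purity: float, *,
                   reference: ReferenceDict, rng: np.random.Generator,
                   depth: int = 40, site_spacing: int = 100_000,
                   log2_noise_sd: float = 0.0,
                   ) -> tuple[list[CopyNumberSegment], list[BafSite]]:
    """Copy-neutral LOH over an arm: total CN 2 with minor CN 0; het-site
    BAF drawn binomially around (1+purity)/2 (major side random per site)."""
    chrom, arm = chrom_arm
    start, end = reference.arm(chrom, arm)
    seg = _seg(chrom, start, end, 2, 0, purity, rng, log2_noise_sd)
    p_major = (1.0 + purity) / 2.0
    positions = np.arange(start + site_spacing // 2, end, site_spacing)
    sides = rng.random(len(positions)) < 0.5
    p = np.where(sides, p_major, 1.0 - p_major)
    bafs = rng.binomial(depth, p) / depth
    sites = [BafSite(chrom, int(pos), float(b), depth)
             for pos, b in zip(positions, bafs)]
    return [seg], sites


def baf_sites_for_segments(segments: list[CopyNumberSegment], purity: float,
                           rng: np.random.Generator, *, depth: int = 40,
                           site_spacing: int = 100_000) -> list[BafSite]:
    """Heterozygous-site BAF track consistent with allele-specific CN."""
    sites = []
    for seg in sorted(segments, key=lambda s: (s.chrom, s.interval.start)):
        tumor_total = seg.major_cn + seg.minor_cn
        denom = purity * tumor_total + 2 * (1 - purity)
        p_major = (purity * seg.major_cn + (1 - purity)) / denom
        start = seg.interval.start + site_spacing // 2
        positions = np.arange(start, seg.interval.end, site_spacing)
        if len(positions) == 0:
            continue
        sides = rng.random(len(positions)) < 0.5
        p = np.where(sides, p_major, 1.0 - p_major)
        bafs = rng.binomial(depth, p) / depth
        sites.extend(BafSite(seg.chrom, int(pos), float(b), depth)
                     for pos, b in zip(positions, bafs))
    return sites


# ---------------------------------------------------------------------------
# telomere reads
# ---------------------------------------------------------------------------

def _background_reads(n: int, read_length: int, spec: TelomereSpec,
                      rng: np.random.Generator, reference: ReferenceDict,
                      prefix: str) -> list[Read]:
    if n == 0:
        return []
    gc = np.clip(rng.normal(spec.background_gc_mean, spec.background_gc_sd, n),
                 0.05, 0.95)
    u = rng.random((n, read_length))
    is_gc = u < gc[:, None]
    pick = rng.random((n, read_length)) < 0.5
    bases = np.where(is_gc, np.where(pick, "G", "C"), np.where(pick, "A", "T"))
    chroms = list(reference.lengths)
    chrom_idx = rng.integers(0, len(chroms), n)
    out = []
    for i in range(n):
        chrom = chroms[chrom_idx[i]]
        pos = int(rng.integers(0, reference.length(chrom) - read_length))
        out.append(Read(name=f"{prefix}_bg{i}", seq="".join(bases[i]),
                        chrom=chrom, pos=pos, cigar=f"{read_length}M"))
    return out


def _telomeric_read_seq(spec: TelomereSpec, singleton_rate: dict,
                        rng: np.random.Generator) -> str:
    n_hex = spec.read_length // 6
    tvrs = list(spec.tvr_composition)
    probs = [spec.tvr_composition[h] for h in tvrs]
    p_t = 1.0 - sum(probs)
    hexes = list(rng.choice(tvrs + [T_TYPE], size=n_hex, p=probs + [p_t]))
    # plant at most one singleton TVR with >= 3 t-type hexamers each side
    for hexamer, rate in singleton_rate.items():
        if n_hex >= 7 and rng.random() < rate:
            pos = int(rng.integers(3, n_hex - 3))
            for j in range(pos - 3, pos + 4):
                hexes[j] = T_TYPE
            hexes[pos] = hexamer
            break
    seq = "".join(hexes)
    pad = spec.read_length - 6 * n_hex
    seq += T_TYPE[:pad]
    if rng.random() < 0.5:  # half the reads on the C-rich strand
        seq = revcomp(seq)
    return seq


def simulate_telomere_reads(spec: TelomereSpec, content_trpm: float,
                            rng: np.random.Generator, *,
                            reference: ReferenceDict, tissue: str,
                            prefix: str) -> list[Read]:
    """Background reads (GC per spec) plus telomeric reads at a planted
    content, in telomeric reads per GC-matched million."""
    if spec.read_length < 6:
        raise ConfigError("read length must be >= 6")
    reads = _background_reads(spec.background_reads, spec.read_length, spec,
                              rng, reference, prefix)
    gc_matched = sum(1 for r in reads if 0.48 <= r.gc_fraction() <= 0.52)
    n_tel = int(rng.poisson(content_trpm * gc_matched / 1e6)) if gc_matched else 0
    singleton = (spec.singleton_rate_tumor if tissue == "tumor"
                 else spec.singleton_rate_normal)
    for i in range(n_tel):
        reads.append(Read(name=f"{prefix}_tel{i}",
                          seq=_telomeric_read_seq(spec, singleton, rng)))
    return reads


def plant_insertion_reads(chrom: str, pos: int, n_support: int, *,
                          spec: InsertionSpec, rng: np.random.Generator,
                          prefix: str) -> list[Read]:
    """Soft-clipped reads whose clipped tail is pure t-type sequence,
    anchored so the clip boundary falls exactly at ``pos``."""
    tail = (T_TYPE * (spec.clip_len // 6 + 1))[: spec.clip_len]
    reads = []
    for i in range(n_support):
        anchor = "".join(rng.choice(list("ACGT"), size=spec.anchor_len))
        if rng.random() < 0.5:  # clip on the right: [anchor][tel>
            reads.append(Read(
                name=f"{prefix}_ins{i}", seq=anchor + tail, chrom=chrom,
                pos=pos - spec.anchor_len,
                cigar=f"{spec.anchor_len}M{spec.clip_len}S"))
        else:                   # clip on the left: <tel][anchor]
            reads.append(Read(
                name=f"{prefix}_ins{i}", seq=tail + anchor, chrom=chrom,
                pos=pos, cigar=f"{spec.clip_len}S{spec.anchor_len}M"))
    return reads


# ---------------------------------------------------------------------------
# whole-sample and whole-cohort simulation
# ---------------------------------------------------------------------------

def _weighted_choice(rng, mapping: dict):
    keys = list(mapping)
    w = np.asarray([mapping[k] for k in keys], dtype=float)
    w = w / w.sum()
    return keys[int(rng.choice(len(keys), p=w))]


def _random_snv(locus: GenomicInterval, vaf: float, rng, spec: Tp53Spec,
                gene: str) -> SmallVariant:
    pos = int(rng.integers(locus.start, locus.end))
    vaf_obs = float(rng.binomial(spec.vaf_depth, min(vaf, 1.0)) / spec.vaf_depth)
    bases = "ACGT"
    ref = bases[int(rng.integers(4))]
    if rng.random() < spec.indel_fraction:
        ref2 = ref + bases[int(rng.integers(4))]
        return SmallVariant(locus.chrom, pos, ref2, ref, vaf_obs, gene=gene,
                            effect="frameshift")
    alt = bases[(bases.index(ref) + 1 + int(rng.integers(3))) % 4]
    return SmallVariant(locus.chrom, pos, ref, alt, vaf_obs, gene=gene,
                        effect="missense")


def simulate_sample(cfg: SimulationConfig, index: int,
                    ) -> tuple[SampleProfile, SampleTruth]:
    ref = cfg.reference()
    sid = f"S{index:03d}"
    tp53 = GenomicInterval(*TOY_GENES["TP53"])
    rng = rng_for(cfg.seed, sid, "events")
    purity = float(rng.uniform(*cfg.purity_range))

    arm_events: list[tuple[str, str, str]] = []
    loss_intervals: list[tuple[str, int, int]] = []
    patches: dict[str, list[CopyNumberSegment]] = {c: [] for c in ref.lengths}

    # --- arm-level aneuploidy -------------------------------------------
    for (chrom, arm, kind), prob in cfg.aneuploidy_spec.items():
        if rng.random() >= prob:
            continue
        arm_events.append((chrom, arm, kind))
        a0, a1 = ref.arm(chrom, arm)
        if (kind == "loss" and chrom == cfg.mdr_spec.chrom
                and arm == cfg.mdr_spec.arm):
            # focal loss containing the shared deleted core
            c0, c1 = cfg.mdr_spec.core
            s0 = max(a0, c0 - int(rng.integers(0, cfg.mdr_spec.flank_max_bp)))
            s1 = min(a1, c1 + int(rng.integers(0, cfg.mdr_spec.flank_max_bp)))
            patches[chrom].append(_seg(chrom, s0, s1, 1, 0, purity, rng,
                                       cfg.log2_noise_sd))
            loss_intervals.append((chrom, s0, s1))
        elif kind == "loss":
            patches[chrom].append(_seg(chrom, a0, a1, 1, 0, purity, rng,
                                       cfg.log2_noise_sd))
            loss_intervals.append((chrom, a0, a1))
        else:
            patches[chrom].append(_seg(chrom, a0, a1, 2, 1, purity, rng,
                                       cfg.log2_noise_sd))

    # --- TP53 mechanism --------------------------------------------------
    mech = _weighted_choice(rng, cfg.tp53_spec.mechanism_mix)
    mechanisms: list[str] = []
    cnloh_regions: list[tuple[str, int, int]] = []
    small_variants: list[SmallVariant] = []
    svs: list[StructuralVariant] = []
    tp_chrom, tp_arm = tp53.chrom, ref.arm_of(tp53.chrom, tp53.start)

    def _tp53_arm_loss():
        a0, a1 = ref.arm(tp_chrom, tp_arm)
        patches[tp_chrom].append(_seg(tp_chrom, a0, a1, 1, 0, purity, rng,
                                      cfg.log2_noise_sd))
        arm_events.append((tp_chrom, tp_arm, "loss"))
        loss_intervals.append((tp_chrom, a0, a1))

    if mech == "SNV+CN_LOSS":
        _tp53_arm_loss()
        vaf = purity / (2.0 - purity)  # one mutant copy on a one-copy locus
        small_variants.append(_random_snv(tp53, vaf, rng, cfg.tp53_spec, "TP53"))
        mechanisms = ["SNV", "CN_LOSS"]
    elif mech == "SNV+CN_LOH":
        a0, a1 = ref.arm(tp_chrom, tp_arm)
        patches[tp_chrom].append(_seg(tp_chrom, a0, a1, 2, 0, purity, rng,
                                      cfg.log2_noise_sd))
        cnloh_regions.append((tp_chrom, a0, a1))
        # mutation duplicated with the retained allele: multiplicity 2
        small_variants.append(_random_snv(tp53, purity, rng, cfg.tp53_spec,
                                          "TP53"))
        mechanisms = ["SNV", "CN_LOH"]
    elif mech == "TWO_SNV":
        for _ in range(2):
            small_variants.append(_random_snv(tp53, purity / 2.0, rng,
                                              cfg.tp53_spec, "TP53"))
        mechanisms = ["SNV", "SNV"]
    elif mech == "SNV+SV":
        small_variants.append(_random_snv(tp53, purity / 2.0, rng,
                                          cfg.tp53_spec, "TP53"))
        bp = int(rng.integers(tp53.start, tp53.end))
        other = int(rng.integers(ref.arm(tp_chrom, "q")[0] + 1_000_000,
                                 ref.length(tp_chrom) - 1))
        svs.append(StructuralVariant(
            sv_id=f"{sid}_tp53sv", bend_a=Breakend(tp_chrom, bp, "+"),
            bend_b=Breakend(tp_chrom, other, "+"), svclass="INV"))
        mechanisms = ["SNV", "SV_DISRUPTION"]
    elif mech == "MONOALLELIC":
        small_variants.append(_random_snv(tp53, purity / 2.0, rng,
                                          cfg.tp53_spec, "TP53"))
        mechanisms = ["SNV"]
    category = ("MULTI_HIT" if len(mechanisms) >= 2
                else "MONOALLELIC" if mechanisms else "WILD_TYPE")
    biallelic = category == "MULTI_HIT"

    # --- chromothripsis --------------------------------------------------
    cs = cfg.chromothripsis_spec
    ct_regions: list[tuple[str, int, int]] = []
    cluster_sizes: list[int] = []
    if rng.random() < cs.probability:
        chrom, arm = _weighted_choice(rng, cs.arm_weights)
        a0, a1 = ref.arm(chrom, arm)
        frac = float(rng.uniform(*cs.region_fraction))
        span = int((a1 - a0) * frac)
        start = int(rng.integers(a0, a1 - span))
        region = GenomicInterval(chrom, start, start + span)
        n_bp = int(rng.integers(cs.n_breakpoints[0], cs.n_breakpoints[1] + 1))
        ct_segs, ct_svs = simulate_chromothripsis_event(
            chrom, n_bp, rng, region=region, purity=purity,
            n_cn_states=cs.n_cn_states, min_segment_bp=cs.min_segment_bp,
            sv_prefix=f"{sid}_ct", log2_noise_sd=cfg.log2_noise_sd)
        patches[chrom] = _merge_patches(patches[chrom], ct_segs)
        svs.extend(ct_svs)
        ct_regions.append((chrom, region.start, region.end))
        cluster_sizes.append(len(ct_svs))
        # the shattered region overwrites any arm-level loss there; keep
        # the recorded loss footprint consistent with the emitted segments
        loss_intervals = _subtract_region(loss_intervals, region)

    # --- background isolated SVs ----------------------------------------
    n_bg = int(rng.integers(*cfg.background_sv_range))
    placed: list[tuple[str, int]] = [(b.chrom, b.pos)
                                     for v in svs for b in v.breakends()]
    guard = 2_000_000
    bg_count = 0
    for i in range(n_bg):
        for _ in range(50):  # rejection sampling away from planted events
            chrom = list(ref.lengths)[int(rng.integers(len(ref.lengths)))]
            length = int(rng.integers(20_000, 1_000_000))
            pos = int(rng.integers(1, ref.length(chrom) - length - 1))
            span = (pos - guard, pos + length + guard)
            if tp53.chrom == chrom and not (
                    span[1] < tp53.start - 100_000 or span[0] > tp53.end + 100_000):
                continue
            if any(c == chrom and span[0] <= p <= span[1] for c, p in placed):
                continue
            oa, ob = [("+", "-"), ("-", "+"), ("+", "+"), ("-", "-")][
                int(rng.integers(4))]
            svs.append(StructuralVariant(
                sv_id=f"{sid}_bg{i}", bend_a=Breakend(chrom, pos, oa),
                bend_b=Breakend(chrom, pos + length, ob),
                svclass=infer_svclass(chrom, oa, chrom, ob)))
            placed.extend([(chrom, pos), (chrom, pos + length)])
            bg_count += 1
            break

    # --- final segment set and BAF track --------------------------------
    segments: list[CopyNumberSegment] = []
    for chrom in ref.lengths:
        base = [_seg(chrom, 0, ref.length(chrom), 1, 1, purity, rng,
                     cfg.log2_noise_sd)]
        segments.extend(overlay_segments(base, patches[chrom]))
    baf_rng = rng_for(cfg.seed, sid, "baf")
    baf_sites = baf_sites_for_segments(segments, purity, baf_rng,
                                       depth=cfg.baf_depth,
                                       site_spacing=cfg.baf_site_spacing)

    # --- telomere reads and interstitial insertions ---------------------
    tel_rng = rng_for(cfg.seed, sid, "telomere")
    tspec = cfg.telomere_spec
    content_n = float(tel_rng.normal(tspec.content_mean, tspec.content_sd))
    content_t = content_n + float(tel_rng.normal(tspec.tumor_shift_mean,
                                                 tspec.tumor_shift_sd))
    content_n, content_t = max(content_n, 0.0), max(content_t, 0.0)
    tumor_reads = simulate_telomere_reads(tspec, content_t, tel_rng,
                                          reference=ref, tissue="tumor",
                                          prefix=f"{sid}_t")
    normal_reads = simulate_telomere_reads(tspec, content_n, tel_rng,
                                           reference=ref, tissue="normal",
                                           prefix=f"{sid}_n")

    ins_rng = rng_for(cfg.seed, sid, "insertion")
    ispec = cfg.insertion_spec
    insertion_loci: list[tuple[str, int]] = []
    if ins_rng.random() < ispec.probability:
        n_ins = 1
        if ins_rng.random() < ispec.extra_insertion_probability:
            n_ins += 1
        breakends = [b for v in svs for b in v.breakends()]
        for j in range(n_ins):
            if breakends and ins_rng.random() < ispec.sv_proximal_probability:
                b = breakends[int(ins_rng.integers(len(breakends)))]
                off = int(ins_rng.integers(500, ispec.max_sv_offset_bp))
                off *= -1 if ins_rng.random() < 0.5 else 1
                chrom, pos = b.chrom, b.pos + off
            else:
                chrom = list(ref.lengths)[int(ins_rng.integers(len(ref.lengths)))]
                pos = int(ins_rng.integers(ispec.termini_mask_bp + 100_000,
                                           ref.length(chrom)
                                           - ispec.termini_mask_bp - 100_000))
            lo = ispec.termini_mask_bp + ispec.anchor_len + 1
            pos = int(np.clip(pos, lo,
                              ref.length(chrom) - lo))
            n_support = int(ins_rng.integers(*ispec.support_range))
            tumor_reads.extend(plant_insertion_reads(
                chrom, pos, n_support, spec=ispec, rng=ins_rng,
                prefix=f"{sid}_L{j}"))
            insertion_loci.append((chrom, pos))

    profile = SampleProfile(
        sample_id=sid, cohort_label=cfg.cohort_label, segments=segments,
        baf_sites=baf_sites, svs=svs, small_variants=small_variants,
        purity_ploidy=SamplePurityPloidy(purity, 2.0),
        tumor_reads=tumor_reads, normal_reads=normal_reads)
    profile.validate(ref)

    class_counts = {c: 0 for c in gio.SV_CLASSES}
    for v in svs:
        class_counts[v.svclass] += 1
    truth = SampleTruth(
        sample_id=sid, purity=purity, tp53_category=category,
        tp53_mechanisms=sorted(set(mechanisms)), tp53_biallelic=biallelic,
        cnloh_regions=cnloh_regions, arm_events=arm_events,
        loss_intervals=loss_intervals, chromothripsis_regions=ct_regions,
        cluster_sizes=cluster_sizes, background_sv_count=bg_count,
        sv_class_counts=class_counts,
        telomere_content_tumor=content_t, telomere_content_normal=content_n,
        insertion_loci=insertion_loci)
    return profile, truth


def _subtract_region(intervals: list[tuple[str, int, int]],
                     region: GenomicInterval) -> list[tuple[str, int, int]]:
    out = []
    for chrom, s0, s1 in intervals:
        if chrom != region.chrom or s1 <= region.start or s0 >= region.end:
            out.append((chrom, s0, s1))
            continue
        if s0 < region.start:
            out.append((chrom, s0, region.start))
        if region.end < s1:
            out.append((chrom, region.end, s1))
    return out


def _merge_patches(existing: list[CopyNumberSegment],
                   new: list[CopyNumberSegment]) -> list[CopyNumberSegment]:
    """New patches take precedence over earlier arm-level ones."""
    return overlay_segments(existing, new) if existing else list(new)


def simulate_cohort(cfg: SimulationConfig,
                    ) -> tuple[list[SampleProfile], GroundTruth]:
    """Generate ``cfg.n_samples`` tumor/normal pairs with ground truth.

    Fully reproducible given ``cfg.seed``; per-sample substreams are
    independent, so changing ``n_samples`` never perturbs earlier samples.
    """
    cfg.validate()
    profiles, truths = [], []
    for i in range(cfg.n_samples):
        profile, truth = simulate_sample(cfg, i)
        profiles.append(profile)
        truths.append(truth)
    mdr = _planted_mdr(truths, cfg)
    return profiles, GroundTruth(samples=truths, mdr=mdr)


def _planted_mdr(truths: list[SampleTruth], cfg: SimulationConfig,
                 ) -> Optional[tuple[str, int, int]]:
    """Intersection of the planted focal losses on the MDR arm (independent
    bookkeeping at plant time, not a call of the analysis code)."""
    chrom = cfg.mdr_spec.chrom
    a0, a1 = cfg.reference().arm(chrom, cfg.mdr_spec.arm)
    lo, hi = 0, 10 ** 18
    n = 0
    for t in truths:
        for (c, s0, s1) in t.loss_intervals:
            if c == chrom and s0 < a1 and s1 > a0:
                lo, hi = max(lo, s0), min(hi, s1)
                n += 1
    if n == 0 or hi <= lo:
        return None
    return (chrom, lo, hi)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_cohort(profiles: list[SampleProfile], truth: GroundTruth,
                 outdir: str | Path, *, reference: Optional[ReferenceDict] = None,
                 ) -> Path:
    """Write the full per-sample file set, sample sheet and truth.json;
    returns the sample-sheet path. Emitted files pass core_io validation."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = reference if reference is not None else toy_genome()
    rows = []
    for p in profiles:
        sid = p.sample_id
        gio.write_segments(p.segments, outdir / f"{sid}.seg.tsv")
        gio.write_baf(p.baf_sites, outdir / f"{sid}.baf.tsv")
        gio.write_bedpe(p.svs, outdir / f"{sid}.bedpe")
        gio.write_vcf(p.small_variants, outdir / f"{sid}.vcf", ref)
        gio.write_sam(p.tumor_reads or [], outdir / f"{sid}.tumor.sam", ref)
        gio.write_sam(p.normal_reads or [], outdir / f"{sid}.normal.sam", ref)
        rows.append({
            "sample_id": sid, "cohort_label": p.cohort_label,
            "purity": p.purity_ploidy.purity, "ploidy": p.purity_ploidy.ploidy,
            "segments": f"{sid}.seg.tsv", "baf": f"{sid}.baf.tsv",
            "svs": f"{sid}.bedpe", "small_variants": f"{sid}.vcf",
            "tumor_reads": f"{sid}.tumor.sam", "normal_reads": f"{sid}.normal.sam",
        })
    sheet = outdir / "sample_sheet.tsv"
    gio.write_sample_sheet(rows, sheet)
    truth.to_json(outdir / "truth.json")
    return sheet
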