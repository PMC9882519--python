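"""Per-chromosome chromothripsis calling from SVs + copy-number segments.

Operationalizes the three qualitative hallmarks of chromothripsis —
(1) clustered breakpoints with interleaving stretches of normal sequence,
(2) oscillation between two or three copy-number states, and (3) fragment
joins in random orientation and order — with explicit statistical tests,
following the high-confidence scheme popularized by ShatterSeek. All
numeric thresholds are exposed on :class:`CallerThresholds`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .io import CopyNumberSegment, GenomicInterval, SampleProfile, StructuralVariant

ORIENT_CLASSES = ("DEL-like", "DUP-like", "h2hINV", "t2tINV")
_ORIENT_OF = {("+", "-"): "DEL-like", ("-", "+"): "DUP-like",
              ("+", "+"): "h2hINV", ("-", "-"): "t2tINV"}


@dataclass(frozen=True)
class CallerThresholds:
    min_interleaved: int = 6
    min_oscillation_2state: int = 7
    min_oscillation_3state: int = 4
    alpha_orientation: float = 0.05
    alpha_spacing: float = 0.05
    exact_multinomial_max_n: int = 20
    # LOW-confidence margins: one criterion may fail but only this far
    margin_interleaved: int = 2
    margin_oscillation: int = 2
    margin_p_factor: float = 0.1


@dataclass(frozen=True)
class ChromothripsisCall:
    sample_id: str
    chrom: str
    region: GenomicInterval
    n_interleaved_sv: int
    n_oscillating_segments: int
    n_cn_states: int
    orientation_counts: dict
    orientation_p: Optional[float]
    spacing_p: Optional[float]
    confidence: str  # HIGH / LOW / NONE


# ---------------------------------------------------------------------------
# criterion 1: breakpoint clustering / interleaving
# ---------------------------------------------------------------------------

def _interleaves(a: StructuralVariant, b: StructuralVariant) -> bool:
    """Strict crossing of breakend intervals: neither nested nor disjoint."""
    a1, a2 = a.bend_a.pos, a.bend_b.pos
    b1, b2 = b.bend_a.pos, b.bend_b.pos
    return (a1 < b1 < a2 < b2) or (b1 < a1 < b2 < a2)


def interleaved_sv_count(svs_on_chrom: Sequence[StructuralVariant],
                         ) -> tuple[int, Optional[GenomicInterval]]:
    """Size and span of the largest connected set of mutually interleaving
    intrachromosomal SVs (an SV contained entirely within another does not
    interleave with it)."""
    svs = [v for v in svs_on_chrom if v.is_intrachromosomal]
    if not svs:
        return 0, None
    n = len(svs)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    any_edge = [False] * n
    for i, j in combinations(range(n), 2):
        if _interleaves(svs[i], svs[j]):
            any_edge[i] = any_edge[j] = True
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri
    comps: dict[int, list[int]] = {}
    for i in range(n):
        if any_edge[i]:
            comps.setdefault(find(i), []).append(i)
    if not comps:
        return 0, None
    best = max(comps.values(), key=len)
    lo = min(svs[i].bend_a.pos for i in best)
    hi = max(svs[i].bend_b.pos for i in best)
    chrom = svs[best[0]].bend_a.chrom
    return len(best), GenomicInterval(chrom, lo, hi + 1)


# ---------------------------------------------------------------------------
# criterion 2: copy-number oscillation
# ---------------------------------------------------------------------------

def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def oscillation_run(segments_in_region: Sequence[CopyNumberSegment],
                    ) -> tuple[int, int]:
    """Longest run of adjacent segments oscillating within a 2-state
    alphabet, with the 3-state run as fallback.

    Returns ``(run_length, n_states)``: the 2-state run when it is at
    least as informative, otherwise the 3-state run.
    """
    cns = [round_half_up(s.total_cn) for s in
           sorted(segments_in_region, key=lambda s: s.interval.start)]
    run2 = longest_oscillation(cns, 2)
    run3 = longest_oscillation(cns, 3)
    if run3 > run2:
        return run3, 3
    return run2, 2


def longest_oscillation(cns: Sequence[int], n_states: int) -> int:
    """Longest contiguous run where adjacent values differ and the run's
    alphabet has at most ``n_states`` distinct values."""
    if not cns:
        return 0
    best = 1
    for i in range(len(cns)):
        seen = {cns[i]}
        for j in range(i + 1, len(cns)):
            if cns[j] == cns[j - 1]:
                break
            seen.add(cns[j])
            if len(seen) > n_states:
                break
            best = max(best, j - i + 1)
    return best


# ---------------------------------------------------------------------------
# criterion 3: orientation randomness; breakpoint spacing
# ---------------------------------------------------------------------------

def orientation_counts(svs: Sequence[StructuralVariant]) -> dict:
    counts = {c: 0 for c in ORIENT_CLASSES}
    for v in svs:
        if v.is_intrachromosomal:
            cls = _ORIENT_OF[(v.bend_a.orientation, v.bend_b.orientation)]
            counts[cls] += 1
    return counts


def orientation_randomness(counts: dict, *,
                           exact_max_n: int = 20) -> Optional[float]:
    """Goodness-of-fit p-value of the four join-orientation counts against
    the uniform (1/4 each) null: exact multinomial for small n, chi-square
    otherwise. Returns None for zero joins (no test)."""
    obs = [counts.get(c, 0) for c in ORIENT_CLASSES]
    n = sum(obs)
    if n == 0:
        return None
    if n <= exact_max_n:
        return _exact_multinomial_gof(obs)
    chi2 = stats.chisquare(obs)
    return float(chi2.pvalue)


def _exact_multinomial_gof(obs: list[int]) -> float:
    """Sum of multinomial(n; 1/4,1/4,1/4,1/4) probabilities of all outcome
    tables no more probable than the observed one."""
    n = sum(obs)
    from scipy.special import gammaln
    log_quarter = math.log(0.25)

    def logp(t):
        return (gammaln(n + 1) - sum(gammaln(x + 1) for x in t)
                + n * log_quarter)

    lp_obs = logp(obs)
    total = 0.0
    for a in range(n + 1):
        for b in range(n - a + 1):
            for c in range(n - a - b + 1):
                t = (a, b, c, n - a - b - c)
                lp = logp(t)
                if lp <= lp_obs + 1e-9:
                    total += math.exp(lp)
    return min(1.0, total)


def spacing_randomness(positions: Sequence[int],
                       region: GenomicInterval) -> Optional[float]:
    """Kolmogorov-Smirnov p-value of inter-breakpoint gaps against an
    exponential with rate n/span (clustering with interleaving normal
    sequence looks Poisson within the shattered region)."""
    pos = sorted(set(positions))
    if len(pos) < 3:
        return None
    gaps = np.diff(pos)
    scale = len(region) / len(pos)
    res = stats.kstest(gaps, "expon", args=(0, scale))
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# the caller
# ---------------------------------------------------------------------------

def call_chromothripsis(profile: SampleProfile, *,
                        thresholds: CallerThresholds = CallerThresholds(),
                        ) -> list[ChromothripsisCall]:
    """Evaluate every chromosome carrying intrachromosomal SVs; returns a
    call (HIGH / LOW / NONE) per evaluated chromosome. Calls on one
    chromosome are unaffected by SVs on any other."""
    th = thresholds
    calls = []
    chroms = sorted({v.bend_a.chrom for v in profile.svs
                     if v.is_intrachromosomal})
    for chrom in chroms:
        svs = [v for v in profile.svs
               if v.is_intrachromosomal and v.bend_a.chrom == chrom]
        n_inter, region = interleaved_sv_count(svs)
        if region is None:
            lo = min(v.bend_a.pos for v in svs)
            hi = max(v.bend_b.pos for v in svs)
            region = GenomicInterval(chrom, lo, hi + 1)
        cluster_svs = [v for v in svs
                       if region.start <= v.bend_a.pos <= region.end
                       and region.start <= v.bend_b.pos <= region.end]
        segs = [s for s in profile.segments_on(chrom)
                if s.interval.overlaps(region)]
        run, n_states = oscillation_run(segs)
        ocounts = orientation_counts(cluster_svs)
        o_p = orientation_randomness(ocounts,
                                     exact_max_n=th.exact_multinomial_max_n)
        positions = sorted({b.pos for v in cluster_svs for b in v.breakends()})
        s_p = spacing_randomness(positions, region)
        has_interchrom = any(
            not v.is_intrachromosomal and any(
                region.contains_pos(b.chrom, b.pos) for b in v.breakends())
            for v in profile.svs)
        confidence = _confidence(n_inter, run, n_states, has_interchrom,
                                 o_p, s_p, th)
        calls.append(ChromothripsisCall(
            sample_id=profile.sample_id, chrom=chrom, region=region,
            n_interleaved_sv=n_inter, n_oscillating_segments=run,
            n_cn_states=n_states, orientation_counts=ocounts,
            orientation_p=o_p, spacing_p=s_p, confidence=confidence))
    return calls


def _confidence(n_inter, run, n_states, has_interchrom, o_p, s_p,
                th: CallerThresholds) -> str:
    def osc_ok(r, ns, slack=0):
        if ns == 2:
            return r >= th.min_oscillation_2state - slack
        return r >= th.min_oscillation_3state - slack and has_interchrom

    checks = [
        # (passes, marginally_fails)
        (n_inter >= th.min_interleaved,
         n_inter >= th.min_interleaved - th.margin_interleaved),
        (osc_ok(run, n_states),
         osc_ok(run, n_states, th.margin_oscillation)),
        (o_p is not None and o_p >= th.alpha_orientation,
         o_p is not None and o_p >= th.alpha_orientation * th.margin_p_factor),
        (s_p is not None and s_p >= th.alpha_spacing,
         s_p is not None and s_p >= th.alpha_spacing * th.margin_p_factor),
    ]
    n_fail = sum(1 for ok, _ in checks if not ok)
    if n_fail == 0:
        return "HIGH"
    if n_fail == 1 and all(marginal for ok, marginal in checks if not ok):
        return "LOW"
    return "NONE"


def high_confidence_calls(profile: SampleProfile, *,
                          thresholds: CallerThresholds = CallerThresholds(),
                          ) -> list[ChromothripsisCall]:
    return [c for c in call_chromothripsis(profile, thresholds=thresholds)
            if c.confidence == "HIGH"]


def cohort_summary(cohort: Sequence[SampleProfile], *,
                   thresholds: CallerThresholds = CallerThresholds(),
                   ) -> dict:
    """Cohort prevalence and per-chromosome fraction of samples with a
    high-confidence call."""
    n = len(cohort)
    per_chrom: dict[str, int] = {}
    n_pos = 0
    for p in cohort:
        highs = high_confidence_calls(p, thresholds=thresholds)
        if highs:
            n_pos += 1
        for chrom in {c.chrom for c in highs}:
            per_chrom[chrom] = per_chrom.get(chrom, 0) + 1
    return {
        "n_samples": n,
        "fraction_with_call": n_pos / n if n else float("nan"),
        "per_chromosome_fraction": {c: k / n for c, k in sorted(per_chrom.items())},
    }
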