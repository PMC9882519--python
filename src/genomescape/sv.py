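"""Structural-variant landscape: class counts, complex-event clustering and
genome-wide breakpoint frequency in fixed windows.

Clustering is the transitive closure of breakend proximity: two SVs link
when any breakend of one lies within ``proximity_bp`` of any breakend of
the other on the same chromosome. Both breakends of an SV always
co-cluster, so a single cross-chromosome junction merges chains. Windowed
frequencies count breakends (both ends of one SV can hit two windows),
with each sample contributing at most once per window.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .io import GenomicInterval, SampleProfile, StructuralVariant, SV_CLASSES

DEFAULT_PROXIMITY_BP = 1_000_000
DEFAULT_WINDOW_BP = 100_000


@dataclass(frozen=True)
class ComplexSVCluster:
    cluster_id: str
    member_sv_ids: frozenset[str]
    footprint: tuple[GenomicInterval, ...]

    @property
    def size(self) -> int:
        return len(self.member_sv_ids)


@dataclass(frozen=True)
class WindowFrequency:
    window: GenomicInterval
    n_samples_hit: int
    fraction: float


def count_sv_classes(profile: SampleProfile | Sequence[StructuralVariant],
                     ) -> dict[str, int]:
    svs = profile.svs if isinstance(profile, SampleProfile) else profile
    counts = {c: 0 for c in SV_CLASSES}
    counts.update(Counter(v.svclass for v in svs))
    return counts


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def cluster_complex(svs: Sequence[StructuralVariant],
                    proximity_bp: int = DEFAULT_PROXIMITY_BP,
                    ) -> list[ComplexSVCluster]:
    """Partition ``svs`` into complex clusters by breakend proximity."""
    if proximity_bp <= 0:
        raise ValueError("proximity_bp must be > 0")
    svs = list(svs)
    uf = _UnionFind(len(svs))
    # sort breakends per chromosome; adjacent-pair linkage realises the
    # full transitive closure of the 1-D proximity relation
    bends: list[tuple[str, int, int]] = []
    for i, v in enumerate(svs):
        for b in v.breakends():
            bends.append((b.chrom, b.pos, i))
    bends.sort()
    for (c1, p1, i1), (c2, p2, i2) in zip(bends, bends[1:]):
        if c1 == c2 and p2 - p1 <= proximity_bp:
            uf.union(i1, i2)
    groups: dict[int, list[int]] = {}
    for i in range(len(svs)):
        groups.setdefault(uf.find(i), []).append(i)
    clusters = []
    for k, members in enumerate(sorted(groups.values(), key=lambda m: m[0])):
        ids = frozenset(svs[i].sv_id for i in members)
        span: dict[str, list[int]] = {}
        for i in members:
            for b in svs[i].breakends():
                span.setdefault(b.chrom, []).append(b.pos)
        footprint = tuple(GenomicInterval(c, min(ps), max(ps) + 1)
                          for c, ps in sorted(span.items()))
        clusters.append(ComplexSVCluster(cluster_id=f"cluster_{k}",
                                         member_sv_ids=ids,
                                         footprint=footprint))
    return clusters


def window_breakpoint_frequency(cohort: Sequence[SampleProfile],
                                window_bp: int = DEFAULT_WINDOW_BP,
                                ) -> list[WindowFrequency]:
    """Fraction of samples with >= 1 SV breakend per fixed window.

    Only windows hit by at least one sample are reported (the rest have
    fraction 0 by definition).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    n = len(cohort)
    hits: Counter[tuple[str, int]] = Counter()
    for profile in cohort:
        seen = {(b.chrom, b.pos // window_bp)
                for v in profile.svs for b in v.breakends()}
        hits.update(seen)
    out = []
    for (chrom, w), k in sorted(hits.items()):
        out.append(WindowFrequency(
            window=GenomicInterval(chrom, w * window_bp, (w + 1) * window_bp),
            n_samples_hit=k, fraction=k / n))
    return out


@dataclass(frozen=True)
class ClusterSizeSummary:
    per_sample_sizes: dict[str, list[int]]
    n_samples_gt20: int    # samples with any cluster of > 20 members
    n_samples_gt100: int   # ... > 100 members


def cluster_size_summary(cohort: Sequence[SampleProfile],
                         proximity_bp: int = DEFAULT_PROXIMITY_BP,
                         ) -> ClusterSizeSummary:
    """Per-sample complex-cluster size histogram; the >20 / >100 member
    buckets use strict inequalities."""
    sizes: dict[str, list[int]] = {}
    for p in cohort:
        clusters = cluster_complex(p.svs, proximity_bp)
        sizes[p.sample_id] = sorted((c.size for c in clusters), reverse=True)
    gt20 = sum(1 for s in sizes.values() if s and s[0] > 20)
    gt100 = sum(1 for s in sizes.values() if s and s[0] > 100)
    return ClusterSizeSummary(per_sample_sizes=sizes, n_samples_gt20=gt20,
                              n_samples_gt100=gt100)
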