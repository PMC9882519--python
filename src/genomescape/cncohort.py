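"""Cohort-level copy-number landscapes.

Sample filtering ('mostly diploid': no whole-genome doubling and >= 50% of
covered autosomal bases copy-neutral), per-unit gain/loss frequencies,
cross-cohort comparison with exact tests, and minimally-deleted regions.

Conventions: 'copy neutral' means rounded total CN = 2 on autosomes; sex
chromosomes are excluded throughout; a unit's state is assigned by
majority overlap (> 50% of its bases), ties broken toward neutral.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .chromothripsis import round_half_up
from .io import GenomicInterval, SampleProfile
from .reference import ReferenceDict, SEX_CHROMS
from .stats import bh_adjust, fisher_exact_2x2

WGD_MAJOR_CN_FRACTION = 0.5
DIPLOID_FRACTION = 0.5


@dataclass(frozen=True)
class CohortCNProfile:
    cohort_label: str
    units: tuple[GenomicInterval, ...]
    unit_names: tuple[str, ...]
    gain_fraction: tuple[float, ...]
    loss_fraction: tuple[float, ...]
    n_samples_included: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "unit": self.unit_names,
            "chrom": [u.chrom for u in self.units],
            "start": [u.start for u in self.units],
            "end": [u.end for u in self.units],
            "gain_fraction": self.gain_fraction,
            "loss_fraction": self.loss_fraction,
        })


@dataclass(frozen=True)
class MinimalDeletedRegion:
    interval: GenomicInterval
    n_supporting_samples: int
    gene_symbols_contained: frozenset[str]
    universal: bool  # True when every loss-bearing sample supports it


def _autosomal_segments(profile: SampleProfile):
    return [s for s in profile.segments if s.chrom not in SEX_CHROMS]


def detect_wgd(profile: SampleProfile) -> bool:
    """Whole-genome doubling: major CN >= 2 over more than half of the
    covered autosomal bases (PURPLE-style base-weighted rule)."""
    total = doubled = 0
    for seg in _autosomal_segments(profile):
        n = len(seg.interval)
        total += n
        if seg.major_cn >= 2:
            doubled += n
    return total > 0 and doubled / total > WGD_MAJOR_CN_FRACTION


def is_mostly_diploid(profile: SampleProfile) -> bool:
    """True iff >= 50% of covered autosomal bases have rounded total CN 2
    and there is no evidence of whole-genome doubling."""
    total = neutral = 0
    for seg in _autosomal_segments(profile):
        n = len(seg.interval)
        total += n
        if round_half_up(seg.total_cn) == 2:
            neutral += n
    if total == 0:
        raise ValueError(f"sample {profile.sample_id}: no autosomal coverage")
    return neutral / total >= DIPLOID_FRACTION and not detect_wgd(profile)


def filter_mostly_diploid(cohort: Sequence[SampleProfile]) -> list[SampleProfile]:
    return [p for p in cohort if is_mostly_diploid(p)]


def _unit_state(profile: SampleProfile, unit: GenomicInterval) -> str:
    """'gain' / 'loss' / 'neutral' by majority (> 50%) of the unit's bases;
    ties break toward neutral."""
    gain = loss = 0
    for seg in profile.segments:
        inter = seg.interval.intersection(unit)
        if inter is None:
            continue
        cn = round_half_up(seg.total_cn)
        if cn > 2:
            gain += len(inter)
        elif cn < 2:
            loss += len(inter)
    half = len(unit) / 2.0
    if gain > half and gain >= loss:
        return "gain"
    if loss > half:
        return "loss"
    return "neutral"


def cn_frequency_landscape(cohort: Sequence[SampleProfile],
                           units: Sequence[GenomicInterval], *,
                           unit_names: Optional[Sequence[str]] = None,
                           cohort_label: str = "cohort",
                           prefiltered: bool = False) -> CohortCNProfile:
    """Per-unit gain/loss fractions over the mostly-diploid subset."""
    included = list(cohort) if prefiltered else filter_mostly_diploid(cohort)
    if not included:
        raise ValueError("no samples pass the mostly-diploid filter")
    names = (tuple(unit_names) if unit_names is not None
             else tuple(f"{u.chrom}:{u.start}-{u.end}" for u in units))
    gains, losses = [], []
    for unit in units:
        states = [_unit_state(p, unit) for p in included]
        gains.append(sum(s == "gain" for s in states) / len(included))
        losses.append(sum(s == "loss" for s in states) / len(included))
    return CohortCNProfile(cohort_label=cohort_label, units=tuple(units),
                           unit_names=names, gain_fraction=tuple(gains),
                           loss_fraction=tuple(losses),
                           n_samples_included=len(included))


def fixed_bins(reference: ReferenceDict, bin_bp: int) -> list[GenomicInterval]:
    units = []
    for chrom in reference.autosomes():
        length = reference.length(chrom)
        for start in range(0, length, bin_bp):
            units.append(GenomicInterval(chrom, start, min(start + bin_bp, length)))
    return units


# ---------------------------------------------------------------------------
# minimally deleted region
# ---------------------------------------------------------------------------

def _sample_loss_intervals(profile: SampleProfile, arm: GenomicInterval,
                           ) -> list[GenomicInterval]:
    out = []
    for seg in profile.segments:
        if round_half_up(seg.total_cn) < 2:
            inter = seg.interval.intersection(arm)
            if inter is not None:
                out.append(inter)
    return out


def minimal_deleted_region(cohort: Sequence[SampleProfile],
                           arm: GenomicInterval, *,
                           gene_annotation: Optional[dict] = None,
                           ) -> MinimalDeletedRegion:
    """Largest interval contained in every loss-bearing sample's deletion
    footprint on the arm, built by iterative intersection (start from the
    arm; per sample keep the loss piece overlapping the candidate).

    When the per-sample losses share no common interval, falls back to the
    largest interval supported by the maximum number of samples (reported
    with ``universal=False``).
    """
    per_sample = []
    for p in cohort:
        losses = _sample_loss_intervals(p, arm)
        if losses:
            per_sample.append(losses)
    if not per_sample:
        raise ValueError(f"no sample has a loss on {arm.chrom}:{arm.start}-{arm.end}")

    candidate: Optional[GenomicInterval] = arm
    for losses in per_sample:
        pieces = [candidate.intersection(l) for l in losses]
        pieces = [x for x in pieces if x is not None]
        if not pieces:
            candidate = None
            break
        candidate = max(pieces, key=len)
    if candidate is not None:
        support = sum(1 for losses in per_sample
                      if any(l.overlaps(candidate)
                             and l.start <= candidate.start
                             and l.end >= candidate.end for l in losses))
        return MinimalDeletedRegion(
            interval=candidate, n_supporting_samples=support,
            gene_symbols_contained=_genes_in(candidate, gene_annotation),
            universal=support == len(per_sample))

    # sweep for the deepest (then widest) interval
    events = []
    for losses in per_sample:
        for l in losses:
            events.append((l.start, 1))
            events.append((l.end, -1))
    events.sort()
    depth = best_depth = 0
    best: Optional[tuple[int, int]] = None
    for (pos, delta), nxt in zip(events, events[1:] + [(arm.end, 0)]):
        depth += delta
        if depth > best_depth or (depth == best_depth and best is not None
                                  and nxt[0] - pos > best[1] - best[0]):
            if nxt[0] > pos:
                best_depth, best = depth, (pos, nxt[0])
    interval = GenomicInterval(arm.chrom, *best)
    return MinimalDeletedRegion(
        interval=interval, n_supporting_samples=best_depth,
        gene_symbols_contained=_genes_in(interval, gene_annotation),
        universal=False)


def _genes_in(interval: GenomicInterval, annotation: Optional[dict],
              ) -> frozenset[str]:
    """Genes whose bodies are fully contained in the interval.

    ``annotation`` maps symbol -> (chrom, start, end).
    """
    if not annotation:
        return frozenset()
    return frozenset(
        sym for sym, (c, s, e) in annotation.items()
        if c == interval.chrom and s >= interval.start and e <= interval.end)


# ---------------------------------------------------------------------------
# cross-cohort comparison
# ---------------------------------------------------------------------------

def compare_landscapes(profile_a: CohortCNProfile,
                       profile_b: CohortCNProfile, *,
                       state: str = "loss") -> pd.DataFrame:
    """Per-unit fraction differences with two-sided exact tests and
    Benjamini-Hochberg adjustment, sorted by |delta|."""
    if profile_a.unit_names != profile_b.unit_names:
        raise ValueError("cohort landscapes computed over different units")
    frac_a = (profile_a.loss_fraction if state == "loss"
              else profile_a.gain_fraction)
    frac_b = (profile_b.loss_fraction if state == "loss"
              else profile_b.gain_fraction)
    na, nb = profile_a.n_samples_included, profile_b.n_samples_included
    rows = []
    for name, fa, fb in zip(profile_a.unit_names, frac_a, frac_b):
        ka, kb = round(fa * na), round(fb * nb)
        res = fisher_exact_2x2(ka, na - ka, kb, nb - kb)
        rows.append((name, fa, fb, fa - fb, res.or_mle, res.p_two_sided))
    df = pd.DataFrame(rows, columns=["unit", f"{state}_fraction_a",
                                     f"{state}_fraction_b", "delta",
                                     "odds_ratio", "p_value"])
    df["q_value"] = bh_adjust(df["p_value"].to_numpy())
    return df.reindex(df["delta"].abs().sort_values(ascending=False).index
                      ).reset_index(drop=True)
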