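"""Chromothripsis caller: interleaving, oscillation, randomness tests and
truth recovery."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from genomescape.chromothripsis import (CallerThresholds, call_chromothripsis,
                                        high_confidence_calls,
                                        interleaved_sv_count,
                                        longest_oscillation,
                                        orientation_randomness,
                                        oscillation_run, spacing_randomness)
from genomescape.io import (Breakend, CopyNumberSegment, GenomicInterval,
                            SampleProfile, StructuralVariant, infer_svclass)


def _sv(i, chrom, p1, p2, o1="+", o2="-"):
    return StructuralVariant(f"sv{i}", Breakend(chrom, p1, o1),
                             Breakend(chrom, p2, o2),
                             infer_svclass(chrom, o1, chrom, o2))


def _seg(chrom, start, end, total):
    major = total - total // 2
    return CopyNumberSegment(GenomicInterval(chrom, start, end),
                             float(total), float(major),
                             float(total // 2), 0.0)


class TestInterleaving:
    def test_nested_pair_not_interleaved(self):
        svs = [_sv(0, "chr5", 10, 100), _sv(1, "chr5", 30, 60)]
        count, _ = interleaved_sv_count(svs)
        assert count == 0

    def test_crossing_pair_interleaved(self):
        svs = [_sv(0, "chr5", 10, 30), _sv(1, "chr5", 20, 40)]
        count, region = interleaved_sv_count(svs)
        assert count == 2
        assert region.start == 10 and region.end == 41

    def test_matches_pairwise_brute_force(self):
        """Maximal interleaving component equals an independent
        graph construction from the O(n^2) pairwise test."""
        import networkx as nx
        rng = np.random.default_rng(8)
        for rep in range(15):
            svs = []
            for i in range(50):
                p1 = int(rng.integers(0, 10 ** 6))
                p2 = p1 + int(rng.integers(1, 3 * 10 ** 5))
                svs.append(_sv(i, "chr5", p1, p2))
            count, _ = interleaved_sv_count(svs)
            g = nx.Graph()
            for a, b in itertools.combinations(svs, 2):
                a1, a2 = a.bend_a.pos, a.bend_b.pos
                b1, b2 = b.bend_a.pos, b.bend_b.pos
                if a1 < b1 < a2 < b2 or b1 < a1 < b2 < a2:
                    g.add_edge(a.sv_id, b.sv_id)
            expected = (max((len(c) for c in nx.connected_components(g)),
                            default=0))
            assert count == expected


class TestOscillation:
    def test_alternating_two_state_run(self):
        segs = [_seg("chr5", i * 100, (i + 1) * 100, cn)
                for i, cn in enumerate([2, 1, 2, 1, 2, 1, 2])]
        run, states = oscillation_run(segs)
        assert (run, states) == (7, 2)

    def test_constant_sequence_has_run_one(self):
        segs = [_seg("chr5", i * 100, (i + 1) * 100, 2) for i in range(3)]
        run, _ = oscillation_run(segs)
        assert run == 1

    def test_matches_exhaustive_oracle(self):
        """longest_oscillation equals brute-force enumeration of all
        substrings for random CN strings."""
        rng = np.random.default_rng(9)

        def oracle(seq, k):
            best = 1 if seq else 0
            for i in range(len(seq)):
                for j in range(i + 1, len(seq) + 1):
                    sub = seq[i:j]
                    if all(a != b for a, b in zip(sub, sub[1:])) \
                            and len(set(sub)) <= k:
                        best = max(best, len(sub))
            return best

        for rep in range(40):
            seq = [int(x) for x in rng.integers(0, 4, rng.integers(1, 20))]
            for k in (2, 3):
                assert longest_oscillation(seq, k) == oracle(seq, k), (seq, k)

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(st.lists(st.integers(min_value=0, max_value=5), min_size=1,
                    max_size=14),
           st.sampled_from([2, 3]))
    def test_oscillation_oracle_property(self, seq, k):
        best = 1
        for i in range(len(seq)):
            for j in range(i + 1, len(seq) + 1):
                sub = seq[i:j]
                if (all(a != b for a, b in zip(sub, sub[1:]))
                        and len(set(sub)) <= k):
                    best = max(best, len(sub))
        assert longest_oscillation(seq, k) == best


class TestOrientationRandomness:
    def test_perfectly_uniform_counts(self):
        p = orientation_randomness({"DEL-like": 5, "DUP-like": 5,
                                    "h2hINV": 5, "t2tINV": 5})
        assert p == pytest.approx(1.0)

    def test_concentrated_counts_reject(self):
        p = orientation_randomness({"DEL-like": 20, "DUP-like": 0,
                                    "h2hINV": 0, "t2tINV": 0})
        assert p < 0.001

    def test_zero_joins_returns_no_test(self):
        assert orientation_randomness(
            {"DEL-like": 0, "DUP-like": 0, "h2hINV": 0, "t2tINV": 0}) is None

    def test_exact_path_matches_enumeration_oracle(self):
        """Exact multinomial tail equals direct enumeration via
        scipy's multinomial pmf."""
        rng = np.random.default_rng(10)
        for rep in range(10):
            counts = rng.multinomial(int(rng.integers(4, 16)),
                                     [0.25] * 4)
            n = counts.sum()
            dist = stats.multinomial(n, [0.25] * 4)
            p_obs = dist.pmf(counts)
            total = 0.0
            for t in itertools.product(range(n + 1), repeat=3):
                if sum(t) > n:
                    continue
                table = [*t, n - sum(t)]
                p = dist.pmf(table)
                if p <= p_obs * (1 + 1e-9):
                    total += p
            got = orientation_randomness(dict(zip(
                ("DEL-like", "DUP-like", "h2hINV", "t2tINV"),
                (int(x) for x in counts))))
            assert got == pytest.approx(min(1.0, total), rel=1e-6)


class TestCalling:
    def test_planted_event_called_high(self, recovery_cohort):
        _, profiles, truth = recovery_cohort
        # the first sample with a planted region is called HIGH there
        for p, t in zip(profiles, truth.samples):
            if t.chromothripsis_regions:
                chroms = {c for c, _, _ in t.chromothripsis_regions}
                high = {c.chrom for c in high_confidence_calls(p)}
                assert high & chroms
                break

    def test_isolated_deletions_none(self):
        svs = [_sv(0, "chr5", 1_000_000, 1_100_000),
               _sv(1, "chr5", 10_000_000, 10_050_000),
               _sv(2, "chr5", 30_000_000, 30_200_000)]
        segs = [_seg("chr5", 0, 50_000_000, 2)]
        profile = SampleProfile(sample_id="S", svs=svs, segments=segs)
        assert all(c.confidence == "NONE"
                   for c in call_chromothripsis(profile))

    def test_whole_arm_loss_none(self):
        segs = [_seg("chr5", 0, 25_000_000, 2),
                _seg("chr5", 25_000_000, 50_000_000, 1)]
        profile = SampleProfile(sample_id="S", segments=segs, svs=[
            _sv(0, "chr5", 24_900_000, 25_000_000)])
        assert all(c.confidence == "NONE"
                   for c in call_chromothripsis(profile))

    def test_locality(self, recovery_cohort):
        """Adding SVs on other chromosomes never changes a chromosome's
        call."""
        _, profiles, truth = recovery_cohort
        p = next(p for p, t in zip(profiles, truth.samples)
                 if t.chromothripsis_regions)
        chrom = t0 = truth.samples[profiles.index(p)].chromothripsis_regions[0][0]
        before = [c for c in call_chromothripsis(p) if c.chrom == chrom]
        other = "chr7" if chrom != "chr7" else "chr5"
        extra = [_sv(900 + i, other, 1_000_000 + i * 10_000,
                     1_005_000 + i * 10_000) for i in range(10)]
        p2 = SampleProfile(sample_id=p.sample_id, segments=p.segments,
                           svs=p.svs + extra, baf_sites=p.baf_sites,
                           purity_ploidy=p.purity_ploidy)
        after = [c for c in call_chromothripsis(p2) if c.chrom == chrom]
        assert [(c.confidence, c.n_interleaved_sv) for c in before] == \
            [(c.confidence, c.n_interleaved_sv) for c in after]

    def test_removing_svs_never_increases_interleaving(self, recovery_cohort):
        """Monotone destruction: along a chain of SV removals the
        interleaved-SV count never increases (the interleave graph of a
        subset is a subgraph), so a destroyed region cannot regain the
        clustering criterion."""
        _, profiles, truth = recovery_cohort
        p, t = next((p, t) for p, t in zip(profiles, truth.samples)
                    if t.chromothripsis_regions)
        chrom = t.chromothripsis_regions[0][0]
        rng = np.random.default_rng(0)
        keep = [v for v in p.svs
                if v.bend_a.chrom == chrom and v.is_intrachromosomal]
        prev, _ = interleaved_sv_count(keep)
        while len(keep) > 2:
            keep.pop(int(rng.integers(len(keep))))
            count, _ = interleaved_sv_count(keep)
            assert count <= prev
            prev = count

    def test_recovery_sensitivity_specificity(self, recovery_cohort):
        """>= 0.9 sensitivity and specificity at defaults on the seeded
        40-sample cohort with 60% planted prevalence."""
        _, profiles, truth = recovery_cohort
        tp = fp = fn = tn = 0
        for p, t in zip(profiles, truth.samples):
            tc = {c for c, _, _ in t.chromothripsis_regions}
            cc = {c.chrom for c in high_confidence_calls(p)}
            if tc:
                tp, fn = tp + bool(tc & cc), fn + (not tc & cc)
            else:
                fp, tn = fp + bool(cc), tn + (not cc)
        assert tp / (tp + fn) >= 0.9
        assert tn / (tn + fp) >= 0.9


class TestSpacing:
    def test_uniform_breakpoints_not_rejected(self):
        rng = np.random.default_rng(11)
        region = GenomicInterval("chr5", 0, 10 ** 7)
        pvals = [spacing_randomness(
            sorted(rng.integers(0, 10 ** 7, 30)), region)
            for _ in range(20)]
        assert np.median(pvals) > 0.05

    def test_regular_grid_rejected(self):
        region = GenomicInterval("chr5", 0, 10 ** 6)
        pos = list(range(0, 10 ** 6, 25_000))
        assert spacing_randomness(pos, region) < 0.01
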