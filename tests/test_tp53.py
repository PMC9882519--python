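"""Allele-status classification: CN-LOH detection, mechanism assembly,
biallelic resolution and truth recovery."""

import numpy as np
import pytest

from genomescape.io import (BafSite, CopyNumberSegment, GenomicInterval,
                            SamplePurityPloidy, SampleProfile, SmallVariant,
                            StructuralVariant, Breakend)
from genomescape.reference import TOY_GENES
from genomescape.tp53 import (AlleleStatusCall, StatusThresholds,
                              cancer_cell_fraction, classify_cohort,
                              classify_locus, detect_cnloh, resolve_biallelic)

LOCUS = GenomicInterval(*TOY_GENES["TP53"])


def _seg(chrom, start, end, major, minor, log2):
    return CopyNumberSegment(GenomicInterval(chrom, start, end),
                             float(major + minor), float(major), float(minor),
                             log2)


def _sites(chrom, start, end, baf, n, depth=40):
    pos = np.linspace(start, end - 1, n).astype(int)
    return [BafSite(chrom, int(p), baf, depth) for p in pos]


def _profile(segments=(), baf=(), svs=(), variants=(), purity=0.8):
    return SampleProfile(sample_id="T", segments=list(segments),
                         baf_sites=list(baf), svs=list(svs),
                         small_variants=list(variants),
                         purity_ploidy=SamplePurityPloidy(purity, 2.0))


class TestDetectCnloh:
    def test_pure_tumor_loh_detected_over_arm(self):
        segs = [_seg("chr17", 0, 8_000_000, 2, 0, 0.0),
                _seg("chr17", 8_000_000, 20_000_000, 1, 1, 0.0)]
        sites = (_sites("chr17", 0, 8_000_000, 0.99, 40)
                 + _sites("chr17", 8_000_000, 20_000_000, 0.5, 40))
        (region,) = detect_cnloh(segs, sites, purity=1.0)
        assert region.interval == GenomicInterval("chr17", 0, 8_000_000)
        assert region.n_sites == 40
        assert region.mean_major_baf >= 0.95

    def test_balanced_heterozygosity_yields_nothing(self):
        segs = [_seg("chr17", 0, 20_000_000, 1, 1, 0.0)]
        sites = _sites("chr17", 0, 20_000_000, 0.5, 100)
        assert detect_cnloh(segs, sites, purity=1.0) == []

    def test_threshold_formula_boundary(self):
        """At purity 0.5 the folded-BAF target is 0.75 - tau; 0.75 passes,
        0.70 fails with tau=0.03."""
        segs = [_seg("chr17", 0, 8_000_000, 2, 0, 0.0)]
        th = StatusThresholds(tau_baf=0.03)
        hit = detect_cnloh(segs, _sites("chr17", 0, 8_000_000, 0.75, 30),
                           purity=0.5, thresholds=th)
        miss = detect_cnloh(segs, _sites("chr17", 0, 8_000_000, 0.70, 30),
                            purity=0.5, thresholds=th)
        assert len(hit) == 1 and miss == []

    def test_matches_brute_force_scan(self):
        """Agreement with an exhaustive scan over every maximal run of
        qualifying segments, on randomized toy inputs."""
        rng = np.random.default_rng(42)
        th = StatusThresholds(n_min_sites=5)
        for rep in range(25):
            purity = float(rng.uniform(0.4, 1.0))
            n_seg = int(rng.integers(2, 8))
            bounds = np.sort(rng.choice(
                np.arange(1, 100), size=n_seg - 1, replace=False)) * 10 ** 5
            bounds = [0, *bounds.tolist(), 10 ** 7]
            segs, sites = [], []
            for s0, s1 in zip(bounds[:-1], bounds[1:]):
                kind = rng.choice(["loh", "balanced", "loss"])
                if kind == "loh":
                    segs.append(_seg("chr1", s0, s1, 2, 0, float(rng.normal(0, 0.05))))
                    baf = 0.5 + purity / 2
                elif kind == "balanced":
                    segs.append(_seg("chr1", s0, s1, 1, 1, float(rng.normal(0, 0.05))))
                    baf = 0.5
                else:
                    segs.append(_seg("chr1", s0, s1, 1, 0, -0.6))
                    baf = 0.5 + purity / 4
                n = int(rng.integers(2, 12))
                sites.extend(_sites("chr1", s0, s1, min(baf + float(
                    rng.normal(0, 0.01)), 1.0), n))
            got = detect_cnloh(segs, sites, purity, thresholds=th)
            expected = _brute_force_cnloh(segs, sites, purity, th)
            assert [(r.interval.start, r.interval.end) for r in got] == expected

    def test_chromosome_without_sites_skipped(self):
        segs = [_seg("chr17", 0, 8_000_000, 2, 0, 0.0)]
        assert detect_cnloh(segs, [], purity=1.0) == []


def _brute_force_cnloh(segs, sites, purity, th):
    """Independent enumeration: maximal contiguous runs of segments that
    individually pass CN-neutrality + folded-BAF, then region-level checks."""
    target = 0.5 + purity / 2 - th.tau_baf
    segs = sorted(segs, key=lambda s: s.interval.start)

    def seg_ok(seg):
        inside = [s for s in sites
                  if seg.interval.start <= s.pos < seg.interval.end]
        if abs(seg.log2_ratio) > th.tau_cn or not inside:
            return False
        return np.mean([s.folded_baf for s in inside]) >= target

    flags = [seg_ok(s) for s in segs]
    out, i = [], 0
    while i < len(segs):
        if not flags[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(segs) and flags[j + 1]:
            j += 1
        start, end = segs[i].interval.start, segs[j].interval.end
        inside = [s for s in sites if start <= s.pos < end]
        if (len(inside) >= th.n_min_sites
                and np.mean([s.folded_baf for s in inside]) >= target):
            out.append((start, end))
        i = j + 1
    return out


class TestClassifyLocus:
    def test_snv_plus_cnloh_is_multi_hit(self):
        """The WGS-reclassification scenario: VAF ~49% SNV plus 17p CN-LOH."""
        var = SmallVariant("chr17", 5_010_000, "C", "T", 0.489, gene="TP53")
        segs = [_seg("chr17", 0, 8_000_000, 2, 0, 0.0)]
        sites = _sites("chr17", 0, 8_000_000, 0.74, 50)
        profile = _profile(segments=segs, baf=sites, variants=[var], purity=0.5)
        cnloh = detect_cnloh(segs, sites, 0.5)
        call = classify_locus(LOCUS, profile, cnloh)
        assert call.category == "MULTI_HIT"
        assert {"SNV", "CN_LOH"} <= call.mechanisms
        assert call.biallelic == "BIALLELIC"

    def test_single_snv_diploid_is_monoallelic(self):
        var = SmallVariant("chr17", 5_010_000, "C", "T", 0.25, gene="TP53")
        profile = _profile(segments=[_seg("chr17", 0, 20_000_000, 1, 1, 0.0)],
                           variants=[var], purity=0.5)
        call = classify_locus(LOCUS, profile, [])
        assert call.category == "MONOALLELIC"
        assert call.biallelic == "NOT_APPLICABLE"

    def test_no_hits_is_wild_type(self):
        profile = _profile(segments=[_seg("chr17", 0, 20_000_000, 1, 1, 0.0)])
        call = classify_locus(LOCUS, profile, [])
        assert call.category == "WILD_TYPE"
        assert call.biallelic == "NOT_APPLICABLE"

    def test_subclonal_dip_does_not_count_as_loss(self):
        """CN_LOSS needs minor_cn = 0, not merely total < 2."""
        seg = CopyNumberSegment(GenomicInterval("chr17", 0, 20_000_000),
                                1.6, 0.9, 0.7, -0.2)
        var = SmallVariant("chr17", 5_010_000, "C", "T", 0.3, gene="TP53")
        call = classify_locus(LOCUS, _profile(segments=[seg], variants=[var]), [])
        assert call.category == "MONOALLELIC"

    def test_sv_breakend_in_locus(self):
        sv = StructuralVariant("sv1", Breakend("chr17", 5_005_000, "+"),
                               Breakend("chr17", 15_000_000, "+"), "INV")
        var = SmallVariant("chr17", 5_010_000, "C", "T", 0.3, gene="TP53")
        call = classify_locus(LOCUS, _profile(svs=[sv], variants=[var]), [])
        assert call.category == "MULTI_HIT"
        assert "SV_DISRUPTION" in call.mechanisms

    def test_monotonic_in_added_mechanisms(self):
        """Adding evidence never demotes the category."""
        rank = {"WILD_TYPE": 0, "MONOALLELIC": 1, "MULTI_HIT": 2}
        var = SmallVariant("chr17", 5_010_000, "C", "T", 0.45, gene="TP53")
        loss = _seg("chr17", 0, 8_000_000, 1, 0, -0.6)
        sv = StructuralVariant("sv1", Breakend("chr17", 5_001_000, "-"),
                               Breakend("chr17", 9_000_000, "-"), "INV")
        prev = -1
        for extras in ([], [var], [var, loss], [var, loss, sv]):
            profile = _profile(
                segments=[s for s in extras if isinstance(s, CopyNumberSegment)],
                svs=[s for s in extras if isinstance(s, StructuralVariant)],
                variants=[s for s in extras if isinstance(s, SmallVariant)])
            cat = rank[classify_locus(LOCUS, profile, []).category]
            assert cat >= prev
            prev = cat


class TestResolveBiallelic:
    def test_ccf_formula(self):
        # clonal het SNV in a diploid locus at purity 0.6: CCF = 1
        assert cancer_cell_fraction(0.30, 0.6, 2.0) == pytest.approx(1.0)
        assert cancer_cell_fraction(0.25, 0.6, 2.0) == pytest.approx(0.8333, abs=1e-3)

    def test_two_clonal_snvs_resolve_biallelic(self):
        variants = [SmallVariant("chr17", 5_001_000, "C", "T", 0.30, gene="TP53"),
                    SmallVariant("chr17", 5_002_000, "G", "A", 0.25, gene="TP53")]
        profile = _profile(segments=[_seg("chr17", 0, 20_000_000, 1, 1, 0.0)],
                           variants=variants, purity=0.6)
        call = classify_locus(LOCUS, profile, [])
        # CCFs 1.0 + 0.83 exceed 1 + tau: the variants must share cells
        assert call.category == "MULTI_HIT" and call.biallelic == "BIALLELIC"

    def test_high_purity_high_vaf_pair_biallelic(self):
        variants = [SmallVariant("chr17", 5_001_000, "C", "T", 0.48, gene="TP53"),
                    SmallVariant("chr17", 5_002_000, "G", "A", 0.45, gene="TP53")]
        profile = _profile(segments=[_seg("chr17", 0, 20_000_000, 1, 1, 0.0)],
                           variants=variants, purity=0.9)
        call = classify_locus(LOCUS, profile, [])
        assert call.biallelic == "BIALLELIC"

    def test_subclonal_pair_unresolved(self):
        # CCFs 0.40 + 0.33 cannot prove co-occurrence
        variants = [SmallVariant("chr17", 5_001_000, "C", "T", 0.12, gene="TP53"),
                    SmallVariant("chr17", 5_002_000, "G", "A", 0.10, gene="TP53")]
        profile = _profile(segments=[_seg("chr17", 0, 20_000_000, 1, 1, 0.0)],
                           variants=variants, purity=0.6)
        call = classify_locus(LOCUS, profile, [])
        assert call.category == "MULTI_HIT" and call.biallelic == "UNRESOLVED"

    def test_contract_error_on_non_multi_hit(self):
        profile = _profile()
        call = classify_locus(LOCUS, profile, [])
        with pytest.raises(ValueError, match="MULTI_HIT"):
            resolve_biallelic(call, profile)


class TestRecovery:
    def test_category_recovery_on_simulated_cohort(self, recovery_cohort):
        """Classified category matches planted truth for >= 99% of samples."""
        _, profiles, truth = recovery_cohort
        calls = classify_cohort(profiles, LOCUS)
        ok = sum(c.category == t.tp53_category
                 for c, t in zip(calls, truth.samples))
        assert ok / len(calls) >= 0.99
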