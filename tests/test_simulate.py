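"""Synthetic-cohort generator: determinism, planted-event contracts and
distributional fidelity."""

import dataclasses
import hashlib
from pathlib import Path

import numpy as np
import pytest
from scipy import stats

from genomescape.io import GenomicInterval, read_baf, read_bedpe, read_segments, read_vcf
from genomescape.reference import toy_genome
from genomescape.simulate import (ChromothripsisSpec, ConfigError,
                                  SimulationConfig, TelomereSpec,
                                  plant_insertion_reads, rng_for,
                                  simulate_chromothripsis_event,
                                  simulate_cnloh, simulate_cohort,
                                  simulate_telomere_reads, write_cohort)
from genomescape.telomere import classify_telomeric_read, singleton_tvr_profile


def _dir_hashes(d):
    return {f.name: hashlib.md5(f.read_bytes()).hexdigest()
            for f in sorted(Path(d).iterdir())}


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = SimulationConfig(seed=5, n_samples=2)
        for sub in ("a", "b"):
            profiles, truth = simulate_cohort(
                SimulationConfig(seed=5, n_samples=2))
            write_cohort(profiles, truth, tmp_path / sub)
        assert _dir_hashes(tmp_path / "a") == _dir_hashes(tmp_path / "b")

    def test_adding_a_sample_preserves_earlier_ones(self):
        p2, _ = simulate_cohort(SimulationConfig(seed=9, n_samples=2))
        p3, _ = simulate_cohort(SimulationConfig(seed=9, n_samples=3))
        assert p2[0].svs == p3[0].svs
        assert p2[1].small_variants == p3[1].small_variants

    def test_empty_cohort(self):
        profiles, truth = simulate_cohort(SimulationConfig(seed=1, n_samples=0))
        assert profiles == [] and truth.samples == []


class TestChromothripsisEvent:
    def test_k_cuts_make_k_plus_one_segments(self):
        region = GenomicInterval("chr5", 10 ** 6, 11 * 10 ** 6)
        segs, svs = simulate_chromothripsis_event(
            "chr5", 10, rng_for(0, "x"), region=region)
        assert len(segs) == 11
        # adjacent segments alternate between exactly two CN states
        cns = [round(s.total_cn) for s in segs]
        assert set(cns) == {1, 2}
        assert all(a != b for a, b in zip(cns, cns[1:]))

    def test_region_too_short_rejected(self):
        region = GenomicInterval("chr5", 0, 1000)
        with pytest.raises(ConfigError, match="shorter"):
            simulate_chromothripsis_event("chr5", 20, rng_for(0, "x"),
                                          region=region)

    def test_orientation_classes_uniform(self):
        """Over many joins the four orientation classes are ~ uniform."""
        region = GenomicInterval("chr5", 0, 20 * 10 ** 6)
        counts = {("+", "-"): 0, ("-", "+"): 0, ("+", "+"): 0, ("-", "-"): 0}
        rng = rng_for(2, "orient")
        n = 0
        for rep in range(400):
            _, svs = simulate_chromothripsis_event("chr5", 25, rng,
                                                   region=region)
            for v in svs:
                counts[(v.bend_a.orientation, v.bend_b.orientation)] += 1
                n += 1
        assert n >= 9000
        res = stats.chisquare(list(counts.values()))
        assert res.pvalue > 0.001


class TestCnLoh:
    @pytest.mark.parametrize("purity,expected", [(1.0, 1.0), (0.5, 0.75)])
    def test_major_baf_matches_mixture_formula(self, toy_ref, purity, expected):
        segs, sites = simulate_cnloh(("chr17", "p"), purity,
                                     reference=toy_ref,
                                     rng=rng_for(3, "cnloh"), depth=400)
        (seg,) = segs
        assert seg.total_cn == 2 and seg.minor_cn == 0
        assert abs(seg.log2_ratio) < 0.05
        folded = np.array([max(s.baf, 1 - s.baf) for s in sites])
        assert folded.mean() == pytest.approx(expected, abs=0.01)

    def test_zero_purity_limit_is_balanced(self, toy_ref):
        _, sites = simulate_cnloh(("chr17", "p"), 1e-9, reference=toy_ref,
                                  rng=rng_for(4, "cnloh"), depth=400)
        folded = np.array([max(s.baf, 1 - s.baf) for s in sites])
        # folded BAF of a balanced site at depth 400 sits at
        # 0.5 + sigma*sqrt(2/pi) ~ 0.52 (half-normal mean of the noise)
        assert folded.mean() == pytest.approx(0.52, abs=0.01)


class TestTelomereReads:
    def test_all_zero_composition_is_pure_t_type(self, toy_ref):
        spec = TelomereSpec(tvr_composition={}, singleton_rate_tumor={},
                            singleton_rate_normal={}, background_reads=0)
        rng = rng_for(5, "tel")
        reads = simulate_telomere_reads(spec, 0, rng, reference=toy_ref,
                                        tissue="tumor", prefix="t")
        # content path needs GC-matched reads; build telomeric reads directly
        from genomescape.simulate import _telomeric_read_seq, revcomp
        for _ in range(20):
            seq = _telomeric_read_seq(spec, {}, rng)
            if seq.startswith("CC") or seq.endswith("TAA"):
                seq = revcomp(seq)
            assert set(seq[i:i + 6] for i in range(0, 102, 6)) == {"TTAGGG"}

    def test_planted_insertion_read_counts(self):
        from genomescape.simulate import InsertionSpec
        reads = plant_insertion_reads("chr5", 2_000_000, 5,
                                      spec=InsertionSpec(),
                                      rng=rng_for(6, "ins"), prefix="p")
        assert len(reads) == 5
        for r in reads:
            clip = max(r.leading_softclip(), r.trailing_softclip())
            assert clip == 30
            locus = r.pos if r.leading_softclip() else r.reference_end()
            assert locus == 2_000_000

    def test_requested_singleton_fraction_recovered(self, toy_ref):
        f = 0.3
        spec = TelomereSpec(tvr_composition={},
                            singleton_rate_tumor={"TTTGGG": f},
                            background_reads=0)
        rng = rng_for(7, "tvr")
        from genomescape.simulate import _telomeric_read_seq
        n = 800
        hits = 0
        for _ in range(n):
            seq = _telomeric_read_seq(spec, spec.singleton_rate_tumor, rng)
            _, units = classify_telomeric_read(seq)
            if singleton_tvr_profile([units]).get("TTTGGG", 0):
                hits += 1
        lo, hi = stats.binom.interval(0.999, n, f)
        assert lo <= hits <= hi

    def test_short_read_length_rejected(self, toy_ref):
        with pytest.raises(ConfigError):
            simulate_telomere_reads(TelomereSpec(read_length=5), 100,
                                    rng_for(0, "x"), reference=toy_ref,
                                    tissue="tumor", prefix="t")


class TestCohortContracts:
    def test_chromothripsis_probability_one(self):
        cs = ChromothripsisSpec(probability=1.0)
        cfg = SimulationConfig(seed=8, n_samples=10, chromothripsis_spec=cs,
                               telomere_spec=TelomereSpec(background_reads=0))
        _, truth = simulate_cohort(cfg)
        assert all(len(t.chromothripsis_regions) >= 1 for t in truth.samples)

    def test_truth_events_present_in_emitted_files(self, tmp_path,
                                                   small_cohort):
        """Every planted event appears in the written files (direct scan,
        not via the callers under test)."""
        cfg, profiles, truth = small_cohort
        write_cohort(profiles, truth, tmp_path, reference=cfg.reference())
        for t in truth.samples:
            segs = read_segments(tmp_path / f"{t.sample_id}.seg.tsv")
            svs = read_bedpe(tmp_path / f"{t.sample_id}.bedpe")
            variants = read_vcf(tmp_path / f"{t.sample_id}.vcf")
            if "SNV" in t.tp53_mechanisms:
                assert any(v.gene == "TP53" for v in variants)
            for (chrom, s0, s1) in t.cnloh_regions:
                assert any(s.chrom == chrom and s.interval.start <= s0
                           and s.interval.end >= s1 - 1 and s.minor_cn == 0
                           and s.total_cn == 2 for s in segs)
            for (chrom, s0, s1) in t.loss_intervals:
                covered = sum(
                    min(s.interval.end, s1) - max(s.interval.start, s0)
                    for s in segs
                    if s.chrom == chrom and s.total_cn < 2
                    and s.interval.start < s1 and s.interval.end > s0)
                assert covered >= 0.95 * (s1 - s0)
            for (chrom, s0, s1) in t.chromothripsis_regions:
                inside = [v for v in svs
                          if v.bend_a.chrom == chrom
                          and s0 <= v.bend_a.pos <= s1]
                assert len(inside) >= 6

    def test_arm_loss_frequencies_match_spec(self):
        """Arm-loss rates over a large cohort stay within 3 binomial SE of
        the configured probabilities."""
        spec = {("chr5", "q", "loss"): 0.8, ("chr7", "q", "loss"): 0.56,
                ("chr12", "p", "loss"): 0.45}
        n = 400
        cfg = SimulationConfig(
            seed=13, n_samples=n, aneuploidy_spec=dict(spec),
            chromothripsis_spec=ChromothripsisSpec(probability=0.0),
            telomere_spec=TelomereSpec(background_reads=0),
            baf_site_spacing=2_000_000)
        _, truth = simulate_cohort(cfg)
        for (chrom, arm, kind), p in spec.items():
            k = sum((chrom, arm, kind) in t.arm_events for t in truth.samples)
            se = np.sqrt(p * (1 - p) / n)
            assert abs(k / n - p) <= 3 * se, (chrom, arm, k / n, p)

    def test_emitted_files_pass_validation(self, small_cohort):
        cfg, profiles, _ = small_cohort
        ref = cfg.reference()
        for p in profiles:
            p.validate(ref)
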