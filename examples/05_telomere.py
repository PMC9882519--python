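"""Telomere content (TRPM), singleton TVRs and interstitial insertions.

TRPM = telomeric reads per GC-matched million reads. A singleton TVR is a
variant hexamer (e.g. TTTGGG) flanked by >= 3 t-type TTAGGG hexamers on
each side. Interstitial insertions are somatic loci where soft-clipped
tumor reads carry telomeric tails away from the chromosome ends.
"""

from genomescape.chromothripsis import call_chromothripsis
from genomescape.reference import toy_genome
from genomescape.simulate import SimulationConfig, TelomereSpec, simulate_cohort
from genomescape.telomere import (detect_interstitial_insertions,
                                  telomere_content, tumor_normal_ratio)

ref = toy_genome()
cfg = SimulationConfig(seed=7, n_samples=6,
                       telomere_spec=TelomereSpec(background_reads=10_000))
profiles, truth = simulate_cohort(cfg)

print(f"{'sample':8} {'TRPM tumor':>11} {'TRPM normal':>12} {'ratio':>6}  "
      "planted(t)")
for p, t in zip(profiles, truth.samples):
    m_t = telomere_content(p.reads("tumor"), sample_id=p.sample_id)
    m_n = telomere_content(p.reads("normal"), sample_id=p.sample_id,
                           tissue="normal")
    cmp_ = tumor_normal_ratio(m_t, m_n)
    print(f"{p.sample_id:8} {m_t.trpm:11.0f} {m_n.trpm:12.0f} "
          f"{cmp_.ratio:6.2f}  {t.telomere_content_tumor:8.0f}")
    calls = detect_interstitial_insertions(
        p.reads("tumor"), p.reads("normal"), p.svs,
        call_chromothripsis(p), reference=ref)
    for c in calls:
        print(f"         insertion {c.chrom}:{c.pos:,} "
              f"({c.n_support_tumor} clipped tumor reads, 0 normal; "
              f"nearest SV {c.nearest_sv_distance_bp} bp)")
# TRPM estimates scatter around the planted content with Poisson noise
# set by the telomeric read count; insertions are recovered at the exact
# planted locus and vanish when the normal carries the same clips.
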