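"""End-to-end pipeline driver and cohort report assembly.

Stages run in dependency order (TP53 status -> SV landscape ->
chromothripsis -> copy number -> telomere); a failing stage is isolated
per sample and recorded in that sample's row rather than aborting the
cohort. Every cohort aggregate is recomputable from the per-sample rows
it summarizes, and that consistency is asserted inside the pipeline.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .chromothripsis import CallerThresholds, call_chromothripsis
from .cncohort import is_mostly_diploid
from .io import GenomicInterval, SampleProfile, SV_CLASSES
from .reference import ReferenceDict, TOY_GENES, toy_genome
from .sv import cluster_complex, count_sv_classes
from .telomere import (InsertionParams, detect_interstitial_insertions,
                       telomere_content, tumor_normal_ratio)
from .tp53 import StatusThresholds, classify_locus, detect_cnloh

logger = logging.getLogger("genomescape")

ONCOPRINT_STATES = ("none", "SNV", "indel", "CN_loss", "CN_gain", "SV", "multi")


@dataclass
class PipelineConfig:
    tp53_locus: tuple[str, int, int] = TOY_GENES["TP53"]
    status_thresholds: StatusThresholds = field(default_factory=StatusThresholds)
    caller_thresholds: CallerThresholds = field(default_factory=CallerThresholds)
    insertion_params: InsertionParams = field(default_factory=InsertionParams)
    proximity_bp: int = 1_000_000
    window_bp: int = 100_000
    seed: Optional[int] = None


@dataclass
class CohortReport:
    per_sample: pd.DataFrame
    aggregates: dict
    provenance: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.per_sample.to_csv(outdir / "per_sample.tsv", sep="\t", index=False)
        payload = {"aggregates": self.aggregates, "provenance": self.provenance}
        (outdir / "cohort_report.json").write_text(
            json.dumps(payload, indent=1, sort_keys=True, default=str))


def _config_hash(config: PipelineConfig) -> str:
    text = repr(config).encode()
    return hashlib.sha256(text).hexdigest()[:16]


def _sample_row(profile: SampleProfile, config: PipelineConfig,
                reference: ReferenceDict) -> dict:
    row: dict = {"sample_id": profile.sample_id,
                 "cohort_label": profile.cohort_label,
                 "purity": profile.purity}
    locus = GenomicInterval(*config.tp53_locus)

    cnloh = detect_cnloh(profile.segments, profile.baf_sites, profile.purity,
                         thresholds=config.status_thresholds)
    call = classify_locus(locus, profile, cnloh,
                          thresholds=config.status_thresholds)
    row["tp53_category"] = call.category
    row["tp53_biallelic"] = call.biallelic
    row["tp53_mechanisms"] = ",".join(sorted(call.mechanisms))

    counts = count_sv_classes(profile)
    for cls in SV_CLASSES:
        row[f"sv_{cls.lower()}"] = counts[cls]
    row["sv_total"] = sum(counts.values())
    clusters = cluster_complex(profile.svs, config.proximity_bp)
    row["largest_cluster"] = max((c.size for c in clusters), default=0)

    ct_calls = call_chromothripsis(profile,
                                   thresholds=config.caller_thresholds)
    high = sorted({c.chrom for c in ct_calls if c.confidence == "HIGH"})
    row["chromothripsis_chroms"] = ",".join(high)
    row["n_chromothripsis_chroms"] = len(high)

    row["mostly_diploid"] = is_mostly_diploid(profile)

    t_reads = profile.reads("tumor")
    n_reads = profile.reads("normal")
    if t_reads:
        m_t = telomere_content(t_reads, sample_id=profile.sample_id)
        row["trpm_tumor"] = m_t.trpm
        if n_reads:
            m_n = telomere_content(n_reads, sample_id=profile.sample_id,
                                   tissue="normal")
            cmp_ = tumor_normal_ratio(m_t, m_n)
            row["trpm_normal"] = m_n.trpm
            row["trpm_ratio"] = cmp_.ratio
            row["trpm_difference"] = cmp_.difference
        insertions = detect_interstitial_insertions(
            t_reads, n_reads or None, profile.svs, ct_calls,
            reference=reference, params=config.insertion_params)
        row["n_insertions"] = len(insertions)
    return row


def run_pipeline(cohort: Sequence[SampleProfile],
                 config: Optional[PipelineConfig] = None, *,
                 reference: Optional[ReferenceDict] = None) -> CohortReport:
    """Run all stages over the cohort and assemble the report."""
    if not cohort:
        raise ValueError("empty cohort")
    config = config or PipelineConfig()
    reference = reference or toy_genome()
    rows = []
    for profile in cohort:
        try:
            rows.append(_sample_row(profile, config, reference))
            logger.info("sample %s: ok", profile.sample_id)
        except Exception as exc:  # isolate per-sample failures
            logger.error("sample %s: %s", profile.sample_id, exc)
            rows.append({"sample_id": profile.sample_id, "error": str(exc)})
    df = pd.DataFrame(rows)
    aggregates = _aggregate(df)
    _assert_consistent(df, aggregates)
    provenance = {"version": __version__, "config_hash": _config_hash(config),
                  "seed": config.seed, "n_samples": len(cohort)}
    return CohortReport(per_sample=df, aggregates=aggregates,
                        provenance=provenance)


def _aggregate(df: pd.DataFrame) -> dict:
    ok = df[~df.get("error", pd.Series(index=df.index, dtype=object)).notna()] \
        if "error" in df.columns else df
    n = len(ok)
    agg: dict = {"n_samples": n, "n_failed": len(df) - n}
    if n == 0:
        return agg
    agg["tp53_category_counts"] = ok["tp53_category"].value_counts().to_dict()
    agg["fraction_multi_hit"] = float((ok["tp53_category"] == "MULTI_HIT").mean())
    multi = ok[ok["tp53_category"] == "MULTI_HIT"]
    agg["fraction_biallelic_of_multi_hit"] = (
        float((multi["tp53_biallelic"] == "BIALLELIC").mean())
        if len(multi) else float("nan"))
    agg["sv_count_median"] = float(ok["sv_total"].median())
    agg["n_samples_cluster_gt20"] = int((ok["largest_cluster"] > 20).sum())
    agg["n_samples_cluster_gt100"] = int((ok["largest_cluster"] > 100).sum())
    agg["fraction_chromothripsis"] = float(
        (ok["n_chromothripsis_chroms"] > 0).mean())
    chrom_counts: dict[str, int] = {}
    for entry in ok["chromothripsis_chroms"].fillna(""):
        for chrom in filter(None, entry.split(",")):
            chrom_counts[chrom] = chrom_counts.get(chrom, 0) + 1
    agg["chromothripsis_per_chrom_fraction"] = {
        c: k / n for c, k in sorted(chrom_counts.items())}
    if "n_insertions" in ok.columns:
        agg["fraction_with_insertion"] = float((ok["n_insertions"] > 0).mean())
    if "trpm_difference" in ok.columns:
        agg["mean_trpm_difference"] = float(ok["trpm_difference"].mean())
    return agg


def _assert_consistent(df: pd.DataFrame, agg: dict) -> None:
    ok = df[df["error"].isna()] if "error" in df.columns else df
    if len(ok):
        assert agg["fraction_multi_hit"] == float(
            (ok["tp53_category"] == "MULTI_HIT").mean())
        assert agg["n_samples_cluster_gt20"] == int(
            (ok["largest_cluster"] > 20).sum())


# ---------------------------------------------------------------------------
# oncoprint-style matrix
# ---------------------------------------------------------------------------

def oncoprint_matrix(cohort: Sequence[SampleProfile],
                     gene_list: Sequence[str], *,
                     gene_annotation: Optional[dict] = None) -> pd.DataFrame:
    """gene x sample matrix of mutation classes.

    Cell values: none / SNV / indel / CN_loss / CN_gain / SV / multi;
    'multi' marks >= 2 SNV/indel hits in the gene. Unknown genes produce a
    warning and an empty row.
    """
    from .chromothripsis import round_half_up

    annotation = gene_annotation if gene_annotation is not None else TOY_GENES
    matrix = {}
    for gene in gene_list:
        if gene not in annotation:
            logger.warning("gene %s not in annotation; emitting empty row", gene)
            matrix[gene] = {p.sample_id: "" for p in cohort}
            continue
        locus = GenomicInterval(*annotation[gene])
        row = {}
        for p in cohort:
            hits = [v for v in p.small_variants
                    if locus.contains_pos(v.chrom, v.pos)]
            if len(hits) >= 2:
                val = "multi"
            elif len(hits) == 1:
                val = "indel" if hits[0].is_indel else "SNV"
            elif any(locus.contains_pos(b.chrom, b.pos)
                     for v in p.svs for b in v.breakends()):
                val = "SV"
            else:
                # majority-overlap CN state
                gain = loss = 0
                for seg in p.segments:
                    inter = seg.interval.intersection(locus)
                    if inter is None:
                        continue
                    cn = round_half_up(seg.total_cn)
                    if cn > 2:
                        gain += len(inter)
                    elif cn < 2:
                        loss += len(inter)
                half = len(locus) / 2
                if loss > half:
                    val = "CN_loss"
                elif gain > half:
                    val = "CN_gain"
                else:
                    val = "none"
            row[p.sample_id] = val
        matrix[gene] = row
    return pd.DataFrame(matrix).T
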