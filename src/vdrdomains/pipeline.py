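"""End-to-end orchestration: domains -> responses -> hits -> calls -> enrichment."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .chromatin_response import FaireResponse, compute_responses, write_response_table
from .domain_builder import (
    AnchorSet,
    ChromatinDomain,
    SizeSummary,
    anchors_from_interactions,
    build_domains,
    size_summary,
    write_domain_bed,
    write_domain_table,
)
from .dr3_scanner import Dr3Hit, default_dr3_pwm, scan_peaks, write_hit_table
from .io_formats import GeneRecord, Interaction, PWM, Peak, SignalTable
from .master_classifier import (
    MasterCall,
    Thresholds,
    VennCounts,
    classify,
    masters_per_domain,
    venn,
    write_calls_table,
)
from .target_enrichment import (
    EnrichmentReport,
    assign_genes,
    enrichment,
    report_to_table,
    write_assignment_table,
)

__all__ = ["PipelineResult", "run_pipeline", "write_results"]


@dataclass
class PipelineResult:
    anchors: AnchorSet
    domains: list[ChromatinDomain]
    peak_to_domain: dict[str, str]
    sizes: SizeSummary
    responses: dict[str, FaireResponse]
    hits: dict[str, Dr3Hit]
    calls: list[MasterCall]
    venn: VennCounts
    domain_master_counts: pd.DataFrame
    assignments: pd.DataFrame | None
    report: EnrichmentReport | None

    @property
    def n_masters(self) -> int:
        return sum(c.is_master for c in self.calls)


def run_pipeline(
    peaks: Sequence[Peak],
    interactions: Sequence[Interaction],
    chrom_sizes: Mapping[str, int],
    genome,
    signals: SignalTable | None,
    genes: Sequence[GeneRecord] | None = None,
    target_ids: Sequence[str] | None = None,
    thresholds: Thresholds | None = None,
    pwm: PWM | None = None,
    level: int = 1,
    merge_gap: int = 0,
    pseudocount: float = 0.5,
    test_method: str = "ttest",
) -> PipelineResult:
    """Run every stage on in-memory inputs.

    ``genome`` is a :class:`pyfaidx.Fasta` or a chrom -> sequence mapping.
    When ``genes`` is None the gene assignment and enrichment stages are
    skipped.  ``target_ids``, when given, overrides the primary-target
    flags carried by the gene records.
    """
    th = thresholds or Thresholds()
    pwm = pwm or default_dr3_pwm(threshold=th.dr3_min)
    anchorset = anchors_from_interactions(interactions, merge_gap=merge_gap)
    domains, peak_to_domain = build_domains(peaks, anchorset, chrom_sizes, level=level)
    responses = (
        compute_responses(signals, pseudocount=pseudocount, method=test_method)
        if signals is not None
        else {}
    )
    hits = scan_peaks(pwm, genome, peaks, halfwidth=th.window_halfwidth, threshold=th.dr3_min)
    calls = classify(peaks, responses, hits, th)
    for c in calls:
        c.domain_id = peak_to_domain[c.peak_id]
    counts = masters_per_domain(calls, peak_to_domain)
    assignments = None
    report = None
    if genes is not None:
        if target_ids is not None:
            targets = set(target_ids)
            genes = [
                GeneRecord(g.gene_id, g.chrom, g.tss, g.strand, g.gene_id in targets)
                for g in genes
            ]
        assignments = assign_genes(genes, domains, calls, peak_to_domain)
        report = enrichment(assignments, calls)
    return PipelineResult(
        anchors=anchorset,
        domains=domains,
        peak_to_domain=peak_to_domain,
        sizes=size_summary(domains),
        responses=responses,
        hits=hits,
        calls=calls,
        venn=venn(calls),
        domain_master_counts=counts,
        assignments=assignments,
        report=report,
    )


def write_results(result: PipelineResult, outdir: str | Path) -> None:
    """Write every pipeline output as a tab-separated table (plus domain BED)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_domain_table(result.domains, out / "domains.tsv")
    write_domain_bed(result.domains, out / "domains.bed")
    write_response_table(result.responses, out / "faire_responses.tsv")
    write_hit_table(result.hits, out / "dr3_hits.tsv")
    write_calls_table(result.calls, out / "master_calls.tsv")
    venn_rows = [{"region": k, "count": v} for k, v in sorted(result.venn.regions.items())]
    pd.DataFrame(venn_rows).to_csv(out / "venn_counts.tsv", sep="\t", index=False)
    result.domain_master_counts.to_csv(out / "domain_master_counts.tsv", sep="\t", index=False)
    if result.assignments is not None:
        write_assignment_table(result.assignments, out / "gene_assignments.tsv")
    if result.report is not None:
        report_to_table(result.report).to_csv(out / "enrichment.tsv", sep="\t", index=False)
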