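"""Gene-to-domain assignment and the master-domain target-gene enrichment fold.

A gene belongs to a chromatin domain when its TSS lies inside the
domain's [left, right) interval (a configurable ``tss_slop`` widens the
TSS to a symmetric window for the looser "TSS region" reading; default
0).  For every gene the distance to the nearest peak-containing domain
and to the nearest master-containing domain is reported: 0 when inside,
otherwise the number of bases from the TSS to the nearest base contained
in any such domain on that chromosome, and missing when the chromosome
carries none.

The enrichment fold L deliberately mixes two levels, exactly as the
headline statistic is defined: the fraction of target-gene-containing
domains that enclose a master site, divided by the fraction of *peaks*
that are masters.  Both fractions are reported separately as well, so
alternative normalizations can be formed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .domain_builder import ChromatinDomain
from .io_formats import GeneRecord
from .master_classifier import MasterCall

logger = logging.getLogger(__name__)

__all__ = [
    "GeneRecord",
    "EnrichmentReport",
    "assign_genes",
    "enrichment",
    "enrichment_from_counts",
    "write_assignment_table",
    "report_to_table",
]


@dataclass
class EnrichmentReport:
    """Counts and fractions behind the master-domain enrichment fold.

    ``fold_likelihood`` = (n_target_domains_with_master / n_target_domains)
    / (n_master_peaks / n_peaks); None when any denominator is zero.
    """

    n_peaks: int
    n_master_peaks: int
    n_targets: int
    n_targets_in_domain: int
    n_target_domains: int
    n_target_domains_with_master: int

    @property
    def master_peak_fraction(self) -> float | None:
        return self.n_master_peaks / self.n_peaks if self.n_peaks else None

    @property
    def in_domain_fraction(self) -> float | None:
        return self.n_targets_in_domain / self.n_targets if self.n_targets else None

    @property
    def master_domain_fraction(self) -> float | None:
        if not self.n_target_domains:
            return None
        return self.n_target_domains_with_master / self.n_target_domains

    @property
    def fold_likelihood(self) -> float | None:
        num = self.master_domain_fraction
        den = self.master_peak_fraction
        if num is None or den is None or den == 0:
            return None
        return num / den


def _master_domain_ids(
    calls: Sequence[MasterCall], peak_to_domain: Mapping[str, str]
) -> set[str]:
    out = set()
    for c in calls:
        if c.is_master:
            dom = peak_to_domain.get(c.peak_id)
            if dom is None:
                raise ValueError(f"master peak {c.peak_id} has no domain assignment")
            out.add(dom)
    return out


def assign_genes(
    genes: Sequence[GeneRecord],
    domains: Sequence[ChromatinDomain],
    calls: Sequence[MasterCall],
    peak_to_domain: Mapping[str, str],
    tss_slop: int = 0,
) -> pd.DataFrame:
    """Per-gene domain assignment and distances.

    Columns: gene_id, chrom, tss, strand, is_primary_target, domain_id
    (empty when outside every domain), in_domain, in_master_domain,
    dist_to_domain, dist_to_master_domain (NaN when the chromosome has no
    domain of that kind).  With overlapping domains (expansion level > 1)
    a TSS inside several is assigned to the smallest.
    """
    master_ids = _master_domain_ids(calls, peak_to_domain)
    by_chrom: dict[str, list[ChromatinDomain]] = {}
    for d in domains:
        by_chrom.setdefault(d.chrom, []).append(d)
    arrays: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    for chrom, ds in by_chrom.items():
        ds.sort(key=lambda d: (d.left, d.right))
        arrays[chrom] = (
            np.array([d.left for d in ds], dtype=np.int64),
            np.array([d.right for d in ds], dtype=np.int64),
            [d.id for d in ds],
        )
    rows = []
    n_missing = 0
    for g in genes:
        rec = {
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "tss": g.tss,
            "strand": g.strand,
            "is_primary_target": g.is_primary_target,
            "domain_id": "",
            "in_domain": False,
            "in_master_domain": False,
            "dist_to_domain": math.nan,
            "dist_to_master_domain": math.nan,
        }
        entry = arrays.get(g.chrom)
        if entry is None:
            n_missing += 1
            rows.append(rec)
            continue
        lefts, rights, ids = entry
        # distance from the (possibly slopped) TSS to the nearest base of
        # each domain; 0 means overlap/containment
        lo, hi = g.tss - tss_slop, g.tss + tss_slop
        dist = np.maximum(np.maximum(lefts - hi, lo - (rights - 1)), 0)
        inside = np.flatnonzero(dist == 0)
        if inside.size:
            k = inside[np.argmin(rights[inside] - lefts[inside])]
            rec["domain_id"] = ids[k]
            rec["in_domain"] = True
        rec["dist_to_domain"] = float(dist.min())
        is_master = np.array([i in master_ids for i in ids], dtype=bool)
        if is_master.any():
            rec["dist_to_master_domain"] = float(dist[is_master].min())
            rec["in_master_domain"] = bool((dist[is_master] == 0).any())
        rows.append(rec)
    if n_missing:
        logger.info("%d gene(s) on chromosomes without any domain", n_missing)
    return pd.DataFrame(rows)


def enrichment(assignments: pd.DataFrame, calls: Sequence[MasterCall]) -> EnrichmentReport:
    """Enrichment of primary target genes in master-site domains.

    A domain counts once toward ``n_target_domains`` no matter how many
    primary target TSSs it contains.
    """
    targets = assignments[assignments["is_primary_target"]]
    in_dom = targets[targets["in_domain"]]
    target_domains = in_dom["domain_id"].unique()
    with_master = in_dom[in_dom["in_master_domain"]]["domain_id"].unique()
    return EnrichmentReport(
        n_peaks=len(calls),
        n_master_peaks=sum(c.is_master for c in calls),
        n_targets=len(targets),
        n_targets_in_domain=len(in_dom),
        n_target_domains=len(target_domains),
        n_target_domains_with_master=len(with_master),
    )


def enrichment_from_counts(
    n_peaks: int,
    n_master_peaks: int,
    n_target_domains: int,
    n_target_domains_with_master: int,
    n_targets: int = 0,
    n_targets_in_domain: int = 0,
) -> EnrichmentReport:
    """Build a report directly from published-style summary counts."""
    return EnrichmentReport(
        n_peaks=n_peaks,
        n_master_peaks=n_master_peaks,
        n_targets=n_targets,
        n_targets_in_domain=n_targets_in_domain,
        n_target_domains=n_target_domains,
        n_target_domains_with_master=n_target_domains_with_master,
    )


def report_to_table(report: EnrichmentReport) -> pd.DataFrame:
    def _f(x: float | None) -> float:
        return x if x is not None else math.nan

    return pd.DataFrame(
        [
            {
                "n_peaks": report.n_peaks,
                "n_master_peaks": report.n_master_peaks,
                "master_peak_fraction": _f(report.master_peak_fraction),
                "n_targets": report.n_targets,
                "n_targets_in_domain": report.n_targets_in_domain,
                "in_domain_fraction": _f(report.in_domain_fraction),
                "n_target_domains": report.n_target_domains,
                "n_target_domains_with_master": report.n_target_domains_with_master,
                "master_domain_fraction": _f(report.master_domain_fraction),
                "fold_likelihood": _f(report.fold_likelihood),
            }
        ]
    )


def write_assignment_table(assignments: pd.DataFrame, path: str | Path) -> None:
    assignments.to_csv(path, sep="\t", index=False)
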