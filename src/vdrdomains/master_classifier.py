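"""Master-site classification: the three-criterion conjunction per peak.

A master VDR locus is a peak that simultaneously shows (i) high ChIP
fold enrichment, (ii) a ligand-induced increase of chromatin
accessibility, and (iii) a DR3-type sequence under its summit.  Default
cutoffs are 9, 1.1-fold and a PWM score of 7, compared inclusively (>=);
``strict=True`` flips all three comparisons to > for the exclusive
reading of the cutoffs.

A peak absent from the signal table fails the accessibility criterion and
a peak without a DR3 hit fails the motif criterion (logged, never an
error): the motif column of real supplementary tables is sparse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .chromatin_response import FaireResponse
from .dr3_scanner import Dr3Hit
from .io_formats import Peak

logger = logging.getLogger(__name__)

__all__ = [
    "Thresholds",
    "MasterCall",
    "VennCounts",
    "classify",
    "venn",
    "masters_per_domain",
    "calls_to_table",
    "write_calls_table",
]


@dataclass
class Thresholds:
    """Cutoffs for the three master criteria.

    fe_min: ChIP fold-enrichment cutoff (default 9).
    faire_min: accessibility fold-change cutoff (default 1.1).
    dr3_min: PWM log-odds cutoff (default 7).
    window_halfwidth: summit window half-width in bp (default 100).
    strict: use exclusive (>) instead of inclusive (>=) comparisons.
    """

    fe_min: float = 9.0
    faire_min: float = 1.1
    dr3_min: float = 7.0
    window_halfwidth: int = 100
    strict: bool = False

    def __post_init__(self) -> None:
        if self.window_halfwidth < 7:
            raise ValueError("window_halfwidth must be >= 7 to fit a 15-mer")

    def passes(self, value: float, cutoff: float) -> bool:
        return value > cutoff if self.strict else value >= cutoff


@dataclass
class MasterCall:
    peak_id: str
    pass_fe: bool
    pass_faire: bool
    pass_dr3: bool
    domain_id: str | None = None

    @property
    def is_master(self) -> bool:
        return self.pass_fe and self.pass_faire and self.pass_dr3


@dataclass
class VennCounts:
    """Counts of the 7 regions of the 3-set Venn (fe, faire, dr3 order).

    Region keys are 3-character strings of 0/1 flags, e.g. ``"110"`` =
    fe and faire but not dr3.  ``total_*`` are the per-criterion totals.
    """

    regions: dict[str, int] = field(default_factory=dict)

    @property
    def total_fe(self) -> int:
        return sum(v for k, v in self.regions.items() if k[0] == "1")

    @property
    def total_faire(self) -> int:
        return sum(v for k, v in self.regions.items() if k[1] == "1")

    @property
    def total_dr3(self) -> int:
        return sum(v for k, v in self.regions.items() if k[2] == "1")

    @property
    def center(self) -> int:
        return self.regions.get("111", 0)


def classify(
    peaks: Sequence[Peak],
    responses: Mapping[str, FaireResponse],
    hits: Mapping[str, Dr3Hit],
    thresholds: Thresholds | None = None,
) -> list[MasterCall]:
    """Apply the three criteria to every peak; one call per peak."""
    th = thresholds or Thresholds()
    ids = [p.id for p in peaks]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate peak ids")
    calls: list[MasterCall] = []
    n_no_resp = n_no_hit = 0
    for p in peaks:
        pass_fe = th.passes(p.fold_enrichment, th.fe_min)
        r = responses.get(p.id)
        if r is None:
            n_no_resp += 1
            pass_faire = False
        else:
            pass_faire = th.passes(r.fold, th.faire_min)
        h = hits.get(p.id)
        if h is None:
            n_no_hit += 1
            pass_dr3 = False
        else:
            pass_dr3 = th.passes(h.score, th.dr3_min)
        calls.append(MasterCall(p.id, pass_fe, pass_faire, pass_dr3))
    if n_no_resp:
        logger.info("%d peak(s) without accessibility data fail that criterion", n_no_resp)
    if n_no_hit:
        logger.info("%d peak(s) without a DR3 hit fail that criterion", n_no_hit)
    return calls


def venn(calls: Sequence[MasterCall]) -> VennCounts:
    """Exact 7-region partition of peaks passing at least one criterion."""
    regions = {f"{a}{b}{c}": 0 for a in "01" for b in "01" for c in "01"}
    for call in calls:
        key = f"{int(call.pass_fe)}{int(call.pass_faire)}{int(call.pass_dr3)}"
        regions[key] += 1
    del regions["000"]
    return VennCounts(regions=regions)


def masters_per_domain(
    calls: Sequence[MasterCall],
    peak_to_domain: Mapping[str, str],
) -> pd.DataFrame:
    """Master count per domain (reported, never enforced, to be <= 1).

    Returns one row per domain with its master count; the isolation
    property observed in real data ("one master per loop") can be read
    off as ``(counts > 1).sum() == 0``.
    """
    counts: dict[str, int] = {}
    for call in calls:
        try:
            dom = peak_to_domain[call.peak_id]
        except KeyError:
            raise ValueError(f"peak {call.peak_id} has no domain assignment") from None
        counts.setdefault(dom, 0)
        if call.is_master:
            counts[dom] += 1
    df = pd.DataFrame(
        {"domain_id": sorted(counts), "n_masters": [counts[d] for d in sorted(counts)]}
    )
    return df


def calls_to_table(calls: Sequence[MasterCall]) -> pd.DataFrame:
    rows = sorted(calls, key=lambda c: c.peak_id)
    return pd.DataFrame(
        {
            "peak_id": [c.peak_id for c in rows],
            "pass_fe": [c.pass_fe for c in rows],
            "pass_faire": [c.pass_faire for c in rows],
            "pass_dr3": [c.pass_dr3 for c in rows],
            "is_master": [c.is_master for c in rows],
            "domain_id": [c.domain_id if c.domain_id else "" for c in rows],
        }
    )


def write_calls_table(calls: Sequence[MasterCall], path: str | Path) -> None:
    calls_to_table(calls).to_csv(path, sep="\t", index=False)
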