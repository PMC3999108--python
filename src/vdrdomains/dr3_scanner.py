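"""Log-odds scanning for DR3-type nuclear-receptor elements under peak summits.

A DR3 element is a direct repeat of two hexameric half-sites (consensus
RGKTCA) separated by a 3-bp spacer, the preferred VDR-RXR binding element.
Scores are natural-log odds against a flat 0.25 background, the HOMER
scoring convention, so genuine HOMER matrices loaded via the ``.motif``
reader give comparable scores.  ``N`` (and any non-ACGT character) scores
0 at every position, so masked genome stretches cannot produce hits above
roughly zero.

The scan window is the peak summit +/-100 bp (201 bp) by default and only
the single best hit per peak is retained, mirroring the one sequence /
position per peak bookkeeping of the supplementary-table layout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import PWM, Peak, extract_window

logger = logging.getLogger(__name__)

__all__ = [
    "Dr3Hit",
    "default_dr3_pwm",
    "score_window",
    "scan_window",
    "scan_peak",
    "scan_peaks",
    "hits_to_table",
    "write_hit_table",
]

DEFAULT_HALFWIDTH = 100
DEFAULT_THRESHOLD = 7.0

# sequence encoding: A=0 C=1 G=2 T=3, anything else = 4 (scores 0)
_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i
_COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


@dataclass
class Dr3Hit:
    """Best-scoring DR3 match in a summit window.

    ``offset`` is the start of the 15-mer relative to the summit (may be
    negative); ``sequence`` is the matched 15-mer in forward-strand
    coordinates regardless of strand.
    """

    peak_id: str
    offset: int
    strand: str
    score: float
    sequence: str


def default_dr3_pwm(threshold: float = DEFAULT_THRESHOLD) -> PWM:
    """The built-in 15-position DR3 matrix: RGKTCA-nnn-RGKTCA.

    Single-consensus positions put probability 0.85 on the consensus base
    (0.05 elsewhere); the two-fold degenerate positions R (A/G) and K
    (G/T) put 0.425 on each allowed base (0.075 elsewhere); the 3-bp
    spacer is uniform and therefore contributes exactly 0 to every score.
    The maximum attainable score is
    2*(4*ln(0.85/0.25) + 2*ln(0.425/0.25)) ~= 11.913.
    """
    strong = {"A": 0, "C": 1, "G": 2, "T": 3}
    rows = []

    def consensus_row(base: str) -> list[float]:
        row = [0.05] * 4
        row[strong[base]] = 0.85
        return row

    def degenerate_row(b1: str, b2: str) -> list[float]:
        row = [0.075] * 4
        row[strong[b1]] = 0.425
        row[strong[b2]] = 0.425
        return row

    half = [
        degenerate_row("A", "G"),  # R
        consensus_row("G"),
        degenerate_row("G", "T"),  # K
        consensus_row("T"),
        consensus_row("C"),
        consensus_row("A"),
    ]
    rows.extend(half)
    rows.extend([[0.25] * 4] * 3)  # spacer
    rows.extend(half)
    return PWM(name="DR3", probs=np.array(rows), threshold=threshold)


def encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def score_window(pwm: PWM, fifteen_mer: str) -> float:
    """Score one sequence of exactly ``pwm.length`` bases.

    score = sum_i ln(p_i(base_i) / background(base_i)); N contributes 0.
    """
    if len(fifteen_mer) != pwm.length:
        raise ValueError(
            f"sequence length {len(fifteen_mer)} != PWM length {pwm.length}"
        )
    # same sequential accumulation as the sliding scan, so that scores of
    # tied candidates are bit-identical between the two code paths
    return float(_sliding_scores(pwm.log_odds(), encode(fifteen_mer))[0])


def _sliding_scores(log_odds: np.ndarray, enc: np.ndarray) -> np.ndarray:
    """Scores of every length-L substring of ``enc`` (vectorized)."""
    L = log_odds.shape[0]
    n = enc.size - L + 1
    if n <= 0:
        return np.empty(0)
    out = np.zeros(n)
    for i in range(L):
        out += log_odds[i, enc[i : i + n]]
    return out


def scan_window(
    pwm: PWM,
    window_sequence: str,
    window_start_offset: int,
    threshold: float | None = None,
    peak_id: str = "",
) -> Dr3Hit | None:
    """Scan every 15-mer on both strands; return the best hit above threshold.

    ``window_start_offset`` is the offset of the window's first base
    relative to the summit (-100 for an unclamped default window).  Ties
    on score are broken by smaller ``|offset|``, then + strand, then
    smaller offset.  Windows shorter than the PWM yield no hit (logged).
    """
    if threshold is None:
        threshold = pwm.threshold
    L = pwm.length
    W = len(window_sequence)
    if W < L:
        logger.info("peak %s: window of %d bp shorter than PWM (%d bp)", peak_id, W, L)
        return None
    lo = pwm.log_odds()
    enc = encode(window_sequence)
    fwd = _sliding_scores(lo, enc)
    rc = _COMP_CODE[enc][::-1]
    rev = _sliding_scores(lo, rc)
    best: tuple[float, int, bool, int] | None = None
    best_hit: tuple[int, str] | None = None
    n = W - L + 1
    for i in range(n):
        for score, start, strand in (
            (fwd[i], i, "+"),
            (rev[i], W - L - i, "-"),
        ):
            off = window_start_offset + start
            key = (score, -abs(off), strand == "+", -off)
            if best is None or key > best:
                best = key
                best_hit = (start, strand)
    assert best is not None and best_hit is not None
    score = best[0]
    if score < threshold:
        return None
    start, strand = best_hit
    return Dr3Hit(
        peak_id=peak_id,
        offset=window_start_offset + start,
        strand=strand,
        score=float(score),
        sequence=window_sequence[start : start + L].upper(),
    )


def scan_peak(
    pwm: PWM,
    genome,
    peak: Peak,
    halfwidth: int = DEFAULT_HALFWIDTH,
    threshold: float | None = None,
) -> Dr3Hit | None:
    """Scan the summit +/-halfwidth window of one peak (clamped at ends)."""
    window = extract_window(genome, peak.chrom, peak.summit, halfwidth)
    wstart = max(0, peak.summit - halfwidth)
    return scan_window(pwm, window, wstart - peak.summit, threshold, peak_id=peak.id)


def scan_peaks(
    pwm: PWM,
    genome,
    peaks: Sequence[Peak],
    halfwidth: int = DEFAULT_HALFWIDTH,
    threshold: float | None = None,
) -> dict[str, Dr3Hit]:
    """Best above-threshold hit per peak; peaks without a hit are absent."""
    hits: dict[str, Dr3Hit] = {}
    for p in peaks:
        h = scan_peak(pwm, genome, p, halfwidth=halfwidth, threshold=threshold)
        if h is not None:
            hits[p.id] = h
    return hits


def hits_to_table(hits: Mapping[str, Dr3Hit]) -> pd.DataFrame:
    rows = sorted(hits.values(), key=lambda h: h.peak_id)
    return pd.DataFrame(
        {
            "peak_id": [h.peak_id for h in rows],
            "offset": [h.offset for h in rows],
            "strand": [h.strand for h in rows],
            "score": [h.score for h in rows],
            "sequence": [h.sequence for h in rows],
        }
    )


def write_hit_table(hits: Mapping[str, Dr3Hit], path: str | Path) -> None:
    hits_to_table(hits).to_csv(path, sep="\t", index=False, float_format="%.6f")
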