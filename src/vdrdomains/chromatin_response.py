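"""Ligand-induced chromatin-opening fold change and its significance.

Accessibility (FAIRE) signals arrive pre-summarized per peak as matched
control and ligand-treated vectors over the same time points.  The fold
change is the ratio of the two *averages* (not the average of per-time
ratios), with a pseudocount guarding against zero signals; significance
is a two-tailed paired test on log-transformed signals, defaulting to the
paired t-test (a Wilcoxon signed-rank alternative is provided, as the
underlying test is a modeling choice).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import SignalTable

__all__ = [
    "FaireResponse",
    "faire_fold",
    "faire_significance",
    "compute_response",
    "compute_responses",
    "responses_to_table",
    "write_response_table",
]

DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class FaireResponse:
    """Per-peak ligand response: signal means, their ratio, and a p-value.

    ``pvalue`` is None when fewer than 2 matched time points are
    available (never fabricated).
    """

    peak_id: str
    mean_control: float
    mean_treated: float
    fold: float
    pvalue: float | None

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError(f"peak {self.peak_id}: fold must be > 0")
        if self.pvalue is not None and not (0.0 <= self.pvalue <= 1.0):
            raise ValueError(f"peak {self.peak_id}: p-value outside [0, 1]")


def faire_fold(
    control: Sequence[float],
    treated: Sequence[float],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """Fold change of the averages: (mean(treated)+eps) / (mean(control)+eps)."""
    c = np.asarray(control, dtype=float)
    t = np.asarray(treated, dtype=float)
    if c.size == 0 or c.size != t.size:
        raise ValueError("control and treated must be equal-length, n >= 1")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    denom = c.mean() + pseudocount
    if denom <= 0:
        raise ValueError("zero control mean with zero pseudocount")
    return float((t.mean() + pseudocount) / denom)


def faire_significance(
    control: Sequence[float],
    treated: Sequence[float],
    method: str = "ttest",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float | None:
    """Two-tailed significance of the ligand effect on log signals.

    Paired over the matched time points.  Returns None (missing) with
    fewer than 2 points.  Identical vectors (all-zero differences) give
    p = 1.0 by convention; zero-variance nonzero differences give 0.0.
    """
    c = np.asarray(control, dtype=float)
    t = np.asarray(treated, dtype=float)
    if c.size != t.size:
        raise ValueError("control and treated must be equal length")
    if c.size < 2:
        return None
    d = np.log(t + pseudocount) - np.log(c + pseudocount)
    if np.allclose(d, 0.0):
        return 1.0
    if method == "ttest":
        if np.allclose(d, d[0]):  # zero variance, nonzero shift
            return 0.0
        res = stats.ttest_rel(np.log(t + pseudocount), np.log(c + pseudocount))
        return float(res.pvalue)
    if method == "wilcoxon":
        res = stats.wilcoxon(d, zero_method="wilcox")
        return float(res.pvalue)
    raise ValueError(f"unknown method {method!r}")


def compute_response(
    peak_id: str,
    control: Sequence[float],
    treated: Sequence[float],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    method: str = "ttest",
) -> FaireResponse:
    c = np.asarray(control, dtype=float)
    t = np.asarray(treated, dtype=float)
    return FaireResponse(
        peak_id=peak_id,
        mean_control=float(c.mean()),
        mean_treated=float(t.mean()),
        fold=faire_fold(c, t, pseudocount),
        pvalue=faire_significance(c, t, method=method, pseudocount=pseudocount),
    )


def compute_responses(
    table: SignalTable,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    method: str = "ttest",
) -> dict[str, FaireResponse]:
    return {
        pid: compute_response(
            pid, table.control[i], table.treated[i], pseudocount, method
        )
        for i, pid in enumerate(table.peak_ids)
    }


def responses_to_table(responses: Mapping[str, FaireResponse]) -> pd.DataFrame:
    rows = sorted(responses.values(), key=lambda r: r.peak_id)
    return pd.DataFrame(
        {
            "peak_id": [r.peak_id for r in rows],
            "mean_control": [r.mean_control for r in rows],
            "mean_treated": [r.mean_treated for r in rows],
            "fold": [r.fold for r in rows],
            "pvalue": [r.pvalue if r.pvalue is not None else math.nan for r in rows],
        }
    )


def write_response_table(responses: Mapping[str, FaireResponse], path: str | Path) -> None:
    responses_to_table(responses).to_csv(path, sep="\t", index=False, float_format="%.6g")
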