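"""Readers and writers for every on-disk format the pipeline touches.

Coordinate conventions
----------------------
All internal coordinates are 0-based, half-open (BED convention).  A peak
*summit* is an absolute 0-based position.  The single exception is GTF
ingestion (1-based, closed), converted once at read time in
:func:`read_genes`.

Supported formats: BED5 / narrowPeak (TF ChIP-seq peaks), BEDPE and BED12
block-pair (ChIA-PET interactions), FASTA (+ ``.fai`` via :mod:`pyfaidx`),
HOMER ``.motif`` (position weight matrices), tab-separated signal tables
(per-peak accessibility signals), BED/GTF gene annotation, one-id-per-line
gene lists, and two-column chromosome-size files.

Malformed records are rejected with a logged error rather than aborting
the whole file; see the individual readers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Peak",
    "Interaction",
    "PWM",
    "SignalTable",
    "GeneRecord",
    "read_peaks",
    "write_peaks",
    "read_interactions",
    "write_interactions",
    "read_motif",
    "write_motif",
    "read_signal_table",
    "write_signal_table",
    "read_genes",
    "write_genes",
    "read_gene_list",
    "write_gene_list",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "extract_window",
    "reverse_complement",
    "open_genome",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Peak:
    """A TF ChIP-seq peak: interval, summit and fold-enrichment score.

    ``fold_enrichment`` is the dimensionless ChIP-vs-background ratio the
    peak caller reported (narrowPeak ``signalValue``), not the capped UCSC
    display score.
    """

    id: str
    chrom: str
    start: int
    end: int
    summit: int
    fold_enrichment: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"peak {self.id}: start {self.start} >= end {self.end}")
        if not (self.start <= self.summit < self.end):
            raise ValueError(
                f"peak {self.id}: summit {self.summit} outside [{self.start}, {self.end})"
            )
        if self.fold_enrichment < 0:
            raise ValueError(f"peak {self.id}: negative fold enrichment")


@dataclass
class Interaction:
    """One intra-chromosomal ChIA-PET interaction: two anchor intervals.

    Anchors are normalized so ``anchor_a.start <= anchor_b.start``.
    """

    chrom: str
    anchor_a: tuple[int, int]
    anchor_b: tuple[int, int]
    support: int | None = None

    def __post_init__(self) -> None:
        if self.anchor_a[0] > self.anchor_b[0]:
            self.anchor_a, self.anchor_b = self.anchor_b, self.anchor_a
        for s, e in (self.anchor_a, self.anchor_b):
            if s >= e:
                raise ValueError(f"interaction anchor [{s}, {e}) is empty")


@dataclass
class PWM:
    """A position weight matrix with log-odds scoring over a flat background.

    ``probs`` is a ``(length, 4)`` array of per-position probabilities in
    A, C, G, T order; each row sums to 1.  ``threshold`` is the default
    log-odds cutoff applied by the scanner.
    """

    name: str
    probs: np.ndarray
    threshold: float = 0.0
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM probs must have shape (length, 4)")
        sums = self.probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("PWM rows must sum to 1 within 1e-6")
        if np.any(self.probs <= 0):
            raise ValueError("PWM probabilities must be > 0 after regularization")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def log_odds(self) -> np.ndarray:
        """Per-position log-odds terms, shape ``(length, 5)``.

        Column 4 is the score of an ``N`` (or any non-ACGT character): 0,
        i.e. background-equivalent.
        """
        lo = np.zeros((self.length, 5))
        lo[:, :4] = np.log(self.probs / self.background)
        return lo

    def max_score(self) -> float:
        return float(np.log(self.probs / self.background).max(axis=1).sum())


@dataclass
class SignalTable:
    """Per-peak accessibility signals for control and ligand-treated series.

    Rows are peaks, columns are matched time points (arbitrary units).
    """

    peak_ids: list[str]
    control: np.ndarray  # (n_peaks, n_timepoints)
    treated: np.ndarray  # (n_peaks, n_timepoints)
    control_labels: list[str]
    treated_labels: list[str]

    def __post_init__(self) -> None:
        self.control = np.asarray(self.control, dtype=float)
        self.treated = np.asarray(self.treated, dtype=float)
        if self.control.shape != self.treated.shape:
            raise ValueError("control/treated matrices must have equal shape")
        if self.control.shape[0] != len(self.peak_ids):
            raise ValueError("signal rows do not match peak ids")
        if len(set(self.peak_ids)) != len(self.peak_ids):
            raise ValueError("duplicate peak ids in signal table")

    def __len__(self) -> int:
        return len(self.peak_ids)

    def for_peak(self, peak_id: str) -> tuple[np.ndarray, np.ndarray]:
        i = self.peak_ids.index(peak_id)
        return self.control[i], self.treated[i]

    def as_dict(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        return {
            pid: (self.control[i], self.treated[i])
            for i, pid in enumerate(self.peak_ids)
        }


@dataclass
class GeneRecord:
    """A gene reduced to its TSS, plus the externally supplied target flag."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    is_primary_target: bool = False

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id}: negative TSS")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")


# ---------------------------------------------------------------------------
# Peaks
# ---------------------------------------------------------------------------


def read_peaks(path: str | Path, dialect: str = "narrowPeak") -> list[Peak]:
    """Read peak calls from BED5 or narrowPeak.

    ``bed5``: column 5 is the fold enrichment; the summit is the interval
    midpoint.  ``narrowPeak``: column 7 (signalValue) is the fold
    enrichment and column 10 the summit offset from ``start`` (offset -1
    falls back to the midpoint).

    Records violating ``start < end`` are rejected with a logged error.
    Peaks are returned sorted by (chrom, start); missing/duplicate names
    are auto-suffixed so ids are unique.
    """
    if dialect not in ("bed5", "narrowPeak"):
        raise ValueError(f"unknown peak dialect {dialect!r}")
    peaks: list[Peak] = []
    raw: list[tuple[str, int, int, str, float, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                name = f[3] if len(f) > 3 and f[3] not in ("", ".") else ""
                if start >= end:
                    raise ValueError(f"start {start} >= end {end}")
                if dialect == "bed5":
                    fe = float(f[4]) if len(f) > 4 else 0.0
                    summit = (start + end) // 2
                else:
                    fe = float(f[6]) if len(f) > 6 else float(f[4])
                    offset = int(f[9]) if len(f) > 9 else -1
                    summit = start + offset if offset >= 0 else (start + end) // 2
                if fe < 0:
                    raise ValueError("negative fold enrichment")
                if not (start <= summit < end):
                    raise ValueError(f"summit {summit} outside interval")
            except (ValueError, IndexError) as exc:
                logger.error("%s line %d: rejected peak record (%s)", path, lineno, exc)
                continue
            raw.append((chrom, start, end, name, fe, summit))
    # assign unique ids in file order, then sort
    seen: dict[str, int] = {}
    for i, (chrom, start, end, name, fe, summit) in enumerate(raw):
        if not name:
            name = f"peak_{i + 1:05d}"
        if name in seen:
            seen[name] += 1
            name = f"{name}_{seen[name]}"
        seen.setdefault(name, 1)
        peaks.append(Peak(name, chrom, start, end, summit, fe))
    peaks.sort(key=lambda p: (p.chrom, p.start, p.end, p.id))
    return peaks


def write_peaks(peaks: Iterable[Peak], path: str | Path, dialect: str = "narrowPeak") -> None:
    """Write peaks; narrowPeak preserves all fields and round-trips exactly."""
    with open(path, "w") as fh:
        for p in peaks:
            if dialect == "bed5":
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.id}\t{p.fold_enrichment:.10g}\n")
            elif dialect == "narrowPeak":
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{p.id}\t0\t.\t"
                    f"{p.fold_enrichment:.10g}\t-1\t-1\t{p.summit - p.start}\n"
                )
            else:
                raise ValueError(f"unknown peak dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Interactions
# ---------------------------------------------------------------------------


def read_interactions(path: str | Path, dialect: str = "bedpe") -> list[Interaction]:
    """Read ChIA-PET interactions from BEDPE or BED12 block-pair rows.

    Inter-chromosomal pairs are dropped (their count is logged).  In the
    block-pair dialect each row is BED12-like and its two blocks are the
    anchors; rows whose block count differs from 2 are rejected.
    """
    if dialect not in ("bedpe", "block-pair"):
        raise ValueError(f"unknown interaction dialect {dialect!r}")
    out: list[Interaction] = []
    n_inter = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            try:
                if dialect == "bedpe":
                    c1, s1, e1, c2, s2, e2 = f[0], int(f[1]), int(f[2]), f[3], int(f[4]), int(f[5])
                    support = int(f[7]) if len(f) > 7 and f[7] not in (".", "") else None
                    if c1 != c2:
                        n_inter += 1
                        continue
                    out.append(Interaction(c1, (s1, e1), (s2, e2), support))
                else:
                    chrom, start = f[0], int(f[1])
                    n_blocks = int(f[9])
                    if n_blocks != 2:
                        raise ValueError(f"block count {n_blocks} != 2")
                    sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                    starts = [int(x) for x in f[11].rstrip(",").split(",")]
                    if len(sizes) != 2 or len(starts) != 2:
                        raise ValueError("blockSizes/blockStarts do not list 2 blocks")
                    a = (start + starts[0], start + starts[0] + sizes[0])
                    b = (start + starts[1], start + starts[1] + sizes[1])
                    support = int(f[4]) if len(f) > 4 and f[4] not in (".", "") else None
                    out.append(Interaction(chrom, a, b, support))
            except (ValueError, IndexError) as exc:
                logger.error("%s line %d: rejected interaction record (%s)", path, lineno, exc)
    if n_inter:
        logger.info("%s: dropped %d inter-chromosomal pair(s)", path, n_inter)
    return out


def write_interactions(interactions: Iterable[Interaction], path: str | Path) -> None:
    """Write interactions as 10-column BEDPE."""
    with open(path, "w") as fh:
        for i, x in enumerate(interactions):
            support = x.support if x.support is not None else "."
            fh.write(
                f"{x.chrom}\t{x.anchor_a[0]}\t{x.anchor_a[1]}\t"
                f"{x.chrom}\t{x.anchor_b[0]}\t{x.anchor_b[1]}\t"
                f"int_{i + 1:05d}\t{support}\t.\t.\n"
            )


# ---------------------------------------------------------------------------
# HOMER .motif
# ---------------------------------------------------------------------------


def read_motif(path: str | Path) -> PWM:
    """Read the first motif from a HOMER-style ``.motif`` file.

    The header is ``>CONSENSUS name threshold [...]``; each subsequent row
    holds the A C G T probabilities of one position.  Rows are renormalized
    when their sum is within 1e-3 of 1 (logged); larger deviations raise an
    error naming the row.  Zero probabilities are floored at 1e-3 and the
    row renormalized.
    """
    name = ""
    threshold = 0.0
    rows: list[list[float]] = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines or not lines[0].startswith(">"):
        raise ValueError(f"{path}: missing HOMER motif header")
    header = lines[0][1:].split()
    if len(header) > 1:
        name = header[1]
    if len(header) > 2:
        threshold = float(header[2])
    for i, ln in enumerate(lines[1:], 1):
        if ln.startswith(">"):
            break  # only the first motif
        vals = [float(x) for x in ln.split()]
        if len(vals) != 4:
            raise ValueError(f"{path}: position row {i} does not have 4 probabilities")
        total = sum(vals)
        if abs(total - 1.0) > 1e-3:
            raise ValueError(f"{path}: position row {i} sums to {total:.6f}, not 1")
        if abs(total - 1.0) > 1e-9:
            logger.info("%s: renormalized position row %d (sum %.6f)", path, i, total)
        vals = [v / total for v in vals]
        if min(vals) < 1e-3:
            vals = [max(v, 1e-3) for v in vals]
            t = sum(vals)
            vals = [v / t for v in vals]
        rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: motif has no position rows")
    return PWM(name=name or "motif", probs=np.array(rows), threshold=threshold)


def write_motif(pwm: PWM, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{pwm.consensus}\t{pwm.name}\t{pwm.threshold:g}\n")
        for row in pwm.probs:
            fh.write("\t".join(f"{v:.9f}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# Signal tables
# ---------------------------------------------------------------------------


def read_signal_table(path: str | Path) -> SignalTable:
    """Read a tab-separated per-peak signal table.

    The header declares the column manifest: a ``peak_id`` column followed
    by columns prefixed ``control_`` and ``treated_`` (one per time point,
    equal counts, any interleaving).
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if "peak_id" not in df.columns:
        raise ValueError(f"{path}: signal table must have a 'peak_id' column")
    control_cols = [c for c in df.columns if c.startswith("control_")]
    treated_cols = [c for c in df.columns if c.startswith("treated_")]
    if not control_cols or len(control_cols) != len(treated_cols):
        raise ValueError(
            f"{path}: need equal, nonzero numbers of control_*/treated_* columns"
        )
    return SignalTable(
        peak_ids=df["peak_id"].astype(str).tolist(),
        control=df[control_cols].to_numpy(float),
        treated=df[treated_cols].to_numpy(float),
        control_labels=control_cols,
        treated_labels=treated_cols,
    )


def write_signal_table(table: SignalTable, path: str | Path) -> None:
    import pandas as pd

    df = pd.DataFrame({"peak_id": table.peak_ids})
    for j, c in enumerate(table.control_labels):
        df[c] = table.control[:, j]
    for j, c in enumerate(table.treated_labels):
        df[c] = table.treated[:, j]
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genes and gene lists
# ---------------------------------------------------------------------------


def read_genes(
    path: str | Path,
    fmt: str = "bed",
    primary_targets: Iterable[str] | None = None,
) -> list[GeneRecord]:
    """Read gene annotation and reduce each gene to its TSS.

    ``bed``: BED6; the TSS is ``start`` on + and ``end - 1`` on -.
    ``gtf``: rows with feature ``gene`` (or ``transcript`` when no gene
    rows exist); GTF is 1-based closed, so ``start - 1`` is the 0-based
    TSS on + and ``end - 1`` on -.  ``primary_targets`` flags the
    externally supplied up-regulated gene list.
    """
    targets = set(primary_targets) if primary_targets is not None else set()
    genes: list[GeneRecord] = []
    if fmt == "bed":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t") if "\t" in line else line.split()
                try:
                    chrom, start, end = f[0], int(f[1]), int(f[2])
                    name = f[3]
                    strand = f[5] if len(f) > 5 else "+"
                    if start >= end:
                        raise ValueError("start >= end")
                    tss = start if strand == "+" else end - 1
                    genes.append(GeneRecord(name, chrom, tss, strand, name in targets))
                except (ValueError, IndexError) as exc:
                    logger.error("%s line %d: rejected gene record (%s)", path, lineno, exc)
    elif fmt == "gtf":
        rows = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9:
                    continue
                rows.append(f)
        features = {"gene"} if any(r[2] == "gene" for r in rows) else {"transcript"}
        for f in rows:
            if f[2] not in features:
                continue
            chrom, start, end, strand, attrs = f[0], int(f[3]), int(f[4]), f[6], f[8]
            gene_id = _gtf_attr(attrs, "gene_id") or _gtf_attr(attrs, "gene_name")
            if gene_id is None:
                logger.error("%s: gene row without gene_id attribute", path)
                continue
            # GTF is 1-based closed: 0-based TSS is start-1 (+) / end-1 (-)
            tss = start - 1 if strand == "+" else end - 1
            genes.append(GeneRecord(gene_id, chrom, tss, strand, gene_id in targets))
    else:
        raise ValueError(f"unknown gene format {fmt!r}")
    genes.sort(key=lambda g: (g.chrom, g.tss, g.gene_id))
    return genes


def _gtf_attr(attrs: str, key: str) -> str | None:
    for chunk in attrs.split(";"):
        chunk = chunk.strip()
        if chunk.startswith(key + " "):
            return chunk.split(" ", 1)[1].strip().strip('"')
    return None


def write_genes(genes: Iterable[GeneRecord], path: str | Path) -> None:
    """Write genes as BED6 rows of the single TSS base."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.tss}\t{g.tss + 1}\t{g.gene_id}\t0\t{g.strand}\n")


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]


def write_gene_list(ids: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for x in ids:
            fh.write(f"{x}\n")


# ---------------------------------------------------------------------------
# Chromosome sizes, genome access
# ---------------------------------------------------------------------------


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            f = line.split("\t") if "\t" in line else line.split()
            sizes[f[0]] = int(f[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def open_genome(path: str | Path):
    """Open an indexed FASTA (index built on first access)."""
    from pyfaidx import Fasta

    return Fasta(str(path), sequence_always_upper=True)


def _chrom_seq_len(genome, chrom: str) -> int:
    rec = genome[chrom]
    return len(rec)


def extract_window(genome, chrom: str, center: int, halfwidth: int) -> str:
    """Extract the uppercase sequence of ``[center-hw, center+hw+1)``.

    ``genome`` is either a :class:`pyfaidx.Fasta` or any mapping of
    chromosome name to sequence string.  The window is clamped to
    ``[0, chromosome length)``; the result has ``2*halfwidth + 1`` bases
    unless clamped.  An unknown chromosome raises ``ValueError``.
    """
    if halfwidth < 0:
        raise ValueError("halfwidth must be >= 0")
    try:
        rec = genome[chrom]
    except KeyError:
        raise ValueError(f"unknown chromosome {chrom!r}") from None
    length = len(rec)
    start = max(0, center - halfwidth)
    end = min(length, center + halfwidth + 1)
    if start >= end:
        return ""
    seq = rec[start:end]
    if not isinstance(seq, str):  # pyfaidx Sequence
        seq = str(seq)
    return seq.upper()


def reverse_complement(seq: str) -> str:
    """A<->T, C<->G; any other character maps to N."""
    return "".join(_COMPLEMENT.get(b, "N") for b in reversed(seq.upper()))
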