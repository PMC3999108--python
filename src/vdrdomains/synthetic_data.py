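"""Synthetic genome-track bundles with planted ground truth.

The generator emulates the statistical structure the pipeline consumes:
CTCF anchors with exponential spacing paired into adjacent-loop
interactions, ChIP-seq peaks placed inside loops with log-normal fold
enrichments, accessibility signal vectors with a multiplicative ligand
induction at master sites, DR3 elements embedded under master summits in
an otherwise i.i.d. uniform ACGT genome, and primary target genes
preferentially placed inside master-site loops at a configurable rate.

Placement model (chosen for an exact closed-form companion):

* anchor gaps are ``min_spacing + Exponential(mean_spacing - min_spacing)``;
* the K master loci live in K *distinct* loops drawn uniformly among all
  loops (one master per loop, the isolation property of the real data),
  with the summit uniform inside its loop;
* non-master peaks are uniform over the genome;
* each primary target TSS is placed, with probability
  ``target_master_placement_prob``, uniformly inside a uniformly chosen
  master loop, and otherwise uniformly on the genome; all other genes are
  uniform.

Under this model :func:`expected_enrichment` evaluates the expectation of
the enrichment fold L with two one-dimensional integrals over the
gap-length distribution -- no size-biased inclusion approximations.

Every file in a bundle is reproducible byte-for-byte from the seed; each
record type draws from its own child of the seed sequence, so adding a
new file type never perturbs earlier outputs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import integrate

from .dr3_scanner import default_dr3_pwm
from .io_formats import (
    GeneRecord,
    Interaction,
    Peak,
    PWM,
    SignalTable,
    write_chrom_sizes,
    write_gene_list,
    write_genes,
    write_interactions,
    write_motif,
    write_peaks,
    write_signal_table,
)

__all__ = [
    "SynthConfig",
    "SynthTruth",
    "SynthBundle",
    "generate",
    "write_bundle",
    "expected_enrichment",
    "truth_enrichment",
]

_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: margin keeping peak intervals and motif windows inside the chromosome
_EDGE_MARGIN = 160


@dataclass
class SynthConfig:
    """Study conditions of the synthetic genome.

    Defaults: 3 chromosomes of 5 Mb; mean anchor spacing 50 kb (floored at
    1 kb so ChIA-PET anchor blocks never overlap); 500 peaks of which 7%
    are masters (echoing the 6.8% observed genome-wide); master ChIP fold
    enrichments log-normal around 25 vs 4 for other peaks, straddling the
    cutoff of 9; a true 1.5-fold ligand induction of accessibility at
    masters vs 1.0 elsewhere over 6 matched time points; above-threshold
    DR3 elements embedded only under master summits; 300 genes of which
    20% are primary targets, placed into a master loop with probability
    0.25.
    """

    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000, "chr3": 5_000_000}
    )
    anchor_mean_spacing: float = 50_000.0
    anchor_min_spacing: float = 1_000.0
    anchor_halfwidth: int = 200
    n_peaks: int = 500
    peak_halfwidth: int = 150
    master_fraction: float = 0.07
    fe_master_logmean: float = math.log(25.0)
    fe_master_logsd: float = 0.4
    fe_other_logmean: float = math.log(4.0)
    fe_other_logsd: float = 0.6
    faire_fold_master: float = 1.5
    faire_fold_other: float = 1.0
    signal_mean: float = 100.0
    signal_shape: float = 20.0
    noise_shape: float = 50.0
    n_timepoints: int = 6
    motif_halfwidth: int = 100
    dr3_threshold: float = 7.0
    n_genes: int = 300
    target_fraction: float = 0.2
    target_master_placement_prob: float = 0.25

    def __post_init__(self) -> None:
        for name in ("master_fraction", "target_fraction", "target_master_placement_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if min(self.chrom_sizes.values()) <= 0:
            raise ValueError("chromosome sizes must be positive")
        if not self.anchor_min_spacing < self.anchor_mean_spacing:
            raise ValueError("anchor_min_spacing must be < anchor_mean_spacing")
        if self.n_peaks <= 0 or self.n_genes < 0 or self.n_timepoints < 1:
            raise ValueError("counts must be positive")

    @property
    def n_masters(self) -> int:
        return round(self.n_peaks * self.master_fraction)

    @property
    def n_targets(self) -> int:
        return round(self.n_genes * self.target_fraction)


@dataclass
class SynthTruth:
    """Planted ground truth, consistent with the emitted files by construction."""

    peaks: pd.DataFrame  # one row per peak, keyed by peak_id
    genes: pd.DataFrame  # one row per gene, keyed by gene_id
    anchors: dict[str, np.ndarray]  # planted anchor summits per chromosome


@dataclass
class SynthBundle:
    config: SynthConfig
    chrom_sizes: dict[str, int]
    genome: dict[str, str] | None
    peaks: list[Peak]
    interactions: list[Interaction]
    signals: SignalTable | None
    genes: list[GeneRecord]
    target_ids: list[str]
    pwm: PWM
    truth: SynthTruth


def _planted_domain(boundaries: np.ndarray, summit: int) -> tuple[int, int]:
    """Loop [left, right) containing a summit; anchor == summit counts left."""
    j = int(np.searchsorted(boundaries, summit, side="right")) - 1
    return int(boundaries[j]), int(boundaries[j + 1])


def _sample_motif(rng: np.random.Generator, pwm: PWM, threshold: float,
                  max_tries: int = 1000) -> tuple[str, float]:
    """Sample a 15-mer from the PWM conditioned on scoring >= threshold."""
    lo = pwm.log_odds()
    idx_range = np.arange(pwm.length)
    for _ in range(max_tries):
        idx = np.array([rng.choice(4, p=row) for row in pwm.probs])
        score = float(lo[idx_range, idx].sum())
        if score >= threshold:
            return "".join("ACGT"[i] for i in idx), score
    raise RuntimeError(f"could not sample a motif scoring >= {threshold}")


def _revcomp_str(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[b] for b in reversed(seq))


def generate(
    config: SynthConfig | None = None,
    seed: int = 0,
    with_sequence: bool = True,
    with_signals: bool = True,
) -> SynthBundle:
    """Generate one coherent bundle plus its truth tables.

    ``with_sequence=False`` / ``with_signals=False`` skip the genome and
    signal matrices (the structural tracks and truth are unchanged),
    which is what placement-recovery experiments need.
    """
    cfg = config or SynthConfig()
    streams = np.random.SeedSequence(seed).spawn(6)
    rng_anchor = np.random.default_rng(streams[0])
    rng_peaks = np.random.default_rng(streams[1])
    rng_motif = np.random.default_rng(streams[2])
    rng_seq = np.random.default_rng(streams[3])
    rng_signal = np.random.default_rng(streams[4])
    rng_genes = np.random.default_rng(streams[5])

    chroms = list(cfg.chrom_sizes)
    d = cfg.anchor_min_spacing
    s = cfg.anchor_mean_spacing - d
    ahw = cfg.anchor_halfwidth

    # --- anchors and loops -------------------------------------------------
    anchors: dict[str, np.ndarray] = {}
    for chrom in chroms:
        L = cfg.chrom_sizes[chrom]
        pos: list[int] = []
        t = 0.0
        while True:
            t += d + rng_anchor.exponential(s)
            if t > L - ahw:
                break
            pos.append(int(t))
        anchors[chrom] = np.array(pos, dtype=np.int64)

    interactions: list[Interaction] = []
    for chrom in chroms:
        a = anchors[chrom]
        for i in range(len(a) - 1):
            interactions.append(
                Interaction(
                    chrom,
                    (int(a[i]) - ahw, int(a[i]) + ahw),
                    (int(a[i + 1]) - ahw, int(a[i + 1]) + ahw),
                )
            )

    # loops (= inter-anchor segments incl. chromosome-end segments)
    segments: list[tuple[str, int, int]] = []
    boundaries: dict[str, np.ndarray] = {}
    for chrom in chroms:
        L = cfg.chrom_sizes[chrom]
        b = np.concatenate(([0], anchors[chrom], [L]))
        boundaries[chrom] = b
        segments.extend((chrom, int(b[j]), int(b[j + 1])) for j in range(len(b) - 1))

    # --- peaks -------------------------------------------------------------
    K = cfg.n_masters
    if K > len(segments):
        raise ValueError("more masters requested than loops available")
    master_seg_idx = np.sort(rng_peaks.choice(len(segments), size=K, replace=False))
    master_pos: list[tuple[str, int]] = []
    for j in master_seg_idx:
        chrom, lo, hi = segments[j]
        L = cfg.chrom_sizes[chrom]
        lo2 = max(lo + 1, _EDGE_MARGIN)
        hi2 = min(hi, L - _EDGE_MARGIN)
        master_pos.append((chrom, int(rng_peaks.integers(lo2, hi2))))

    n_np = cfg.n_peaks - K
    weights = np.array([cfg.chrom_sizes[c] - 2 * _EDGE_MARGIN for c in chroms], dtype=np.int64)
    offsets = np.concatenate(([0], np.cumsum(weights)))
    flat = rng_peaks.integers(0, offsets[-1], size=n_np)
    other_pos: list[tuple[str, int]] = []
    for v in flat:
        c = int(np.searchsorted(offsets, v, side="right")) - 1
        other_pos.append((chroms[c], int(v - offsets[c]) + _EDGE_MARGIN))

    fe_master = np.round(
        rng_peaks.lognormal(cfg.fe_master_logmean, cfg.fe_master_logsd, K), 3
    )
    fe_other = np.round(
        rng_peaks.lognormal(cfg.fe_other_logmean, cfg.fe_other_logsd, n_np), 3
    )

    recs = [
        (chrom, pos, True, float(fe_master[i]))
        for i, (chrom, pos) in enumerate(master_pos)
    ] + [
        (chrom, pos, False, float(fe_other[i]))
        for i, (chrom, pos) in enumerate(other_pos)
    ]
    recs.sort(key=lambda r: (r[0], r[1], not r[2]))

    peaks: list[Peak] = []
    truth_rows = []
    phw = cfg.peak_halfwidth
    for i, (chrom, summit, is_master, fe) in enumerate(recs, 1):
        pid = f"peak_{i:05d}"
        peaks.append(Peak(pid, chrom, summit - phw, summit + phw + 1, summit, fe))
        left, right = _planted_domain(boundaries[chrom], summit)
        truth_rows.append(
            {
                "peak_id": pid,
                "chrom": chrom,
                "summit": summit,
                "is_master": is_master,
                "fold_enrichment": fe,
                "faire_fold": cfg.faire_fold_master if is_master else cfg.faire_fold_other,
                "motif_offset": pd.NA,
                "motif_strand": "",
                "motif_score": math.nan,
                "domain_left": left,
                "domain_right": right,
            }
        )
    truth_peaks = pd.DataFrame(truth_rows).astype({"motif_offset": "Int64"})

    # --- genome with embedded motifs ----------------------------------------
    pwm = default_dr3_pwm(threshold=cfg.dr3_threshold)
    genome: dict[str, str] | None = None
    if with_sequence:
        arrays = {
            chrom: rng_seq.integers(0, 4, size=cfg.chrom_sizes[chrom]).astype(np.uint8)
            for chrom in chroms
        }
        mhw = cfg.motif_halfwidth
        master_mask = truth_peaks["is_master"].to_numpy()
        for row_i in np.flatnonzero(master_mask):
            offset = int(rng_motif.integers(-mhw, mhw - pwm.length + 2))
            strand = "+" if rng_motif.random() < 0.5 else "-"
            seq, score = _sample_motif(rng_motif, pwm, cfg.dr3_threshold)
            embedded = seq if strand == "+" else _revcomp_str(seq)
            chrom = truth_peaks.at[row_i, "chrom"]
            start = int(truth_peaks.at[row_i, "summit"]) + offset
            codes = np.frombuffer(embedded.encode("ascii"), dtype=np.uint8)
            arrays[chrom][start : start + pwm.length] = np.array(
                ["ACGT".index(chr(c)) for c in codes], dtype=np.uint8
            )
            truth_peaks.at[row_i, "motif_offset"] = offset
            truth_peaks.at[row_i, "motif_strand"] = strand
            truth_peaks.at[row_i, "motif_score"] = score
        genome = {
            chrom: _CODES[arr].tobytes().decode("ascii") for chrom, arr in arrays.items()
        }

    # --- accessibility signals ----------------------------------------------
    signals: SignalTable | None = None
    if with_signals:
        n, T = cfg.n_peaks, cfg.n_timepoints
        fold = truth_peaks["faire_fold"].to_numpy(float)
        control = rng_signal.gamma(cfg.signal_shape, cfg.signal_mean / cfg.signal_shape, (n, T))
        noise = rng_signal.gamma(cfg.noise_shape, 1.0 / cfg.noise_shape, (n, T))
        treated = control * fold[:, None] * noise
        signals = SignalTable(
            peak_ids=list(truth_peaks["peak_id"]),
            control=np.round(control, 4),
            treated=np.round(treated, 4),
            control_labels=[f"control_t{j + 1}" for j in range(T)],
            treated_labels=[f"treated_t{j + 1}" for j in range(T)],
        )

    # --- genes ---------------------------------------------------------------
    n_t = cfg.n_targets
    gene_recs: list[tuple[str, int, bool, bool]] = []  # chrom, tss, is_target, in_master
    for _ in range(n_t):
        if K > 0 and rng_genes.random() < cfg.target_master_placement_prob:
            j = int(master_seg_idx[rng_genes.integers(0, K)])
            chrom, lo, hi = segments[j]
            gene_recs.append((chrom, int(rng_genes.integers(lo + 1, hi)), True, True))
        else:
            v = int(rng_genes.integers(0, sum(cfg.chrom_sizes.values())))
            c, tss = _locate(v, chroms, cfg.chrom_sizes)
            gene_recs.append((c, tss, True, False))
    for _ in range(cfg.n_genes - n_t):
        v = int(rng_genes.integers(0, sum(cfg.chrom_sizes.values())))
        c, tss = _locate(v, chroms, cfg.chrom_sizes)
        gene_recs.append((c, tss, False, False))
    strands = np.where(rng_genes.random(len(gene_recs)) < 0.5, "+", "-")
    order = sorted(range(len(gene_recs)), key=lambda i: (gene_recs[i][0], gene_recs[i][1], i))

    genes: list[GeneRecord] = []
    gene_truth_rows = []
    for n_out, i in enumerate(order, 1):
        chrom, tss, is_target, in_master = gene_recs[i]
        gid = f"gene_{n_out:04d}"
        genes.append(GeneRecord(gid, chrom, tss, str(strands[i]), is_target))
        left, right = _planted_domain(boundaries[chrom], tss)
        gene_truth_rows.append(
            {
                "gene_id": gid,
                "chrom": chrom,
                "tss": tss,
                "is_primary_target": is_target,
                "placed_in_master_domain": in_master,
                "domain_left": left,
                "domain_right": right,
            }
        )
    truth_genes = pd.DataFrame(gene_truth_rows)
    target_ids = [g.gene_id for g in genes if g.is_primary_target]

    return SynthBundle(
        config=cfg,
        chrom_sizes=dict(cfg.chrom_sizes),
        genome=genome,
        peaks=peaks,
        interactions=interactions,
        signals=signals,
        genes=genes,
        target_ids=target_ids,
        pwm=pwm,
        truth=SynthTruth(peaks=truth_peaks, genes=truth_genes, anchors=anchors),
    )


def _locate(v: int, chroms: list[str], sizes: Mapping[str, int]) -> tuple[str, int]:
    for c in chroms:
        if v < sizes[c]:
            return c, v
        v -= sizes[c]
    raise AssertionError("position outside genome")


def write_bundle(bundle: SynthBundle, outdir: str | Path) -> dict[str, Path]:
    """Write every track of a bundle (plus truth tables) to a directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if bundle.genome is not None:
        paths["genome"] = out / "genome.fa"
        with open(paths["genome"], "w") as fh:
            for chrom, seq in bundle.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
    paths["chrom_sizes"] = out / "genome.chrom.sizes"
    write_chrom_sizes(bundle.chrom_sizes, paths["chrom_sizes"])
    paths["peaks"] = out / "peaks.narrowPeak"
    write_peaks(bundle.peaks, paths["peaks"], dialect="narrowPeak")
    paths["interactions"] = out / "interactions.bedpe"
    write_interactions(bundle.interactions, paths["interactions"])
    if bundle.signals is not None:
        paths["signals"] = out / "faire_signals.tsv"
        write_signal_table(bundle.signals, paths["signals"])
    paths["genes"] = out / "genes.bed"
    write_genes(bundle.genes, paths["genes"])
    paths["targets"] = out / "primary_targets.txt"
    write_gene_list(bundle.target_ids, paths["targets"])
    paths["motif"] = out / "dr3.motif"
    write_motif(bundle.pwm, paths["motif"])
    paths["truth_peaks"] = out / "truth_peaks.tsv"
    bundle.truth.peaks.to_csv(paths["truth_peaks"], sep="\t", index=False)
    paths["truth_genes"] = out / "truth_genes.tsv"
    bundle.truth.genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    paths["config"] = out / "config.json"
    with open(paths["config"], "w") as fh:
        json.dump(dataclasses.asdict(bundle.config), fh, indent=1)
    return paths


# ---------------------------------------------------------------------------
# Closed-form companion
# ---------------------------------------------------------------------------


def expected_enrichment(config: SynthConfig | None = None) -> float | None:
    """Expectation of the enrichment fold L under the generator.

    Loop lengths are i.i.d. ``min + Exp(mean - min)``; the K master loops
    are a uniform sample of loops, so their lengths follow the same
    (unbiased) distribution, and a target TSS hits a given master loop of
    length x with probability ``p/K + (1-p) x/G``.  A non-master loop of
    length x is a peak-containing domain with probability
    ``1 - (1-x/G)^n_nonmaster`` and receives a given target with
    probability ``(1-p) x/G``.  Then

        E[D_master] = K * E_x[1 - (1 - p/K - (1-p)x/G)^n_targets]
        E[D_other]  = (N_loops - K)
                      * E_x[(1-(1-x/G)^n_np) (1 - (1-(1-p)x/G)^n_targets)]
        E[L] ~ (E[D_master] / (E[D_master] + E[D_other])) / (K / n_peaks)

    (the final step replaces the expectation of the ratio by the ratio of
    expectations, accurate to well under a percent at the default sizes).
    Returns None for degenerate configurations (no masters or no targets).
    """
    cfg = config or SynthConfig()
    K = cfg.n_masters
    n_t = cfg.n_targets
    if K == 0 or n_t == 0:
        return None
    G = float(sum(cfg.chrom_sizes.values()))
    a, d = cfg.anchor_mean_spacing, cfg.anchor_min_spacing
    s = a - d
    n_np = cfg.n_peaks - K
    p = cfg.target_master_placement_prob
    n_loops = sum(
        (L - 2 * cfg.anchor_halfwidth) / a + 1.0 for L in cfg.chrom_sizes.values()
    )

    def pdf(y: float) -> float:
        return math.exp(-y / s) / s

    def g_master(y: float) -> float:
        x = d + y
        t = min(1.0, p / K + (1.0 - p) * x / G)
        return (1.0 - (1.0 - t) ** n_t) * pdf(y)

    def g_other(y: float) -> float:
        x = d + y
        occ = 1.0 - max(0.0, 1.0 - x / G) ** n_np
        t = min(1.0, (1.0 - p) * x / G)
        return occ * (1.0 - (1.0 - t) ** n_t) * pdf(y)

    # the Exp(s) tail beyond 50 s carries ~2e-22 mass; a finite range keeps
    # the quadrature well conditioned
    e_master = K * integrate.quad(g_master, 0, 50 * s, limit=200)[0]
    e_other = (n_loops - K) * integrate.quad(g_other, 0, 50 * s, limit=200)[0]
    if e_master + e_other == 0:
        return None
    master_domain_fraction = e_master / (e_master + e_other)
    return master_domain_fraction / (K / cfg.n_peaks)


def truth_enrichment(config: SynthConfig | None = None, seed: int = 0) -> float | None:
    """Realized enrichment fold L of one bundle, using planted master labels.

    Runs the real domain builder and gene-assignment machinery on a
    structure-only bundle; master status is taken from the truth table so
    the result isolates the placement model from classifier error.
    """
    from .domain_builder import anchors_from_interactions, build_domains
    from .master_classifier import MasterCall
    from .target_enrichment import assign_genes, enrichment

    bundle = generate(config, seed, with_sequence=False, with_signals=False)
    anchorset = anchors_from_interactions(bundle.interactions)
    domains, p2d = build_domains(bundle.peaks, anchorset, bundle.chrom_sizes)
    truth = bundle.truth.peaks.set_index("peak_id")["is_master"]
    calls = [
        MasterCall(p.id, bool(truth[p.id]), bool(truth[p.id]), bool(truth[p.id]))
        for p in bundle.peaks
    ]
    assignments = assign_genes(bundle.genes, domains, calls, p2d)
    return enrichment(assignments, calls).fold_likelihood
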