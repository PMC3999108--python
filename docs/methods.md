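# Methods

## Chromatin domains from ChIA-PET anchors

A chromatin domain (core loop) of a ChIP-seq peak is the interval between
the summit of the nearest CTCF anchor at or left of the peak summit and
the summit of the nearest anchor strictly right of it; its size is the
number of bases between the two summits.  When fewer than `level` anchors
exist on a side, the chromosome start/end stands in as the natural limit
and the corresponding end flag is set on the domain.  Conventions:

* **Anchor summits.** ChIA-PET anchors are intervals without summits.
  All anchor intervals are pooled per chromosome, merged when they
  overlap (or lie within `merge_gap` bp, default 0 — the merge choice is
  deliberately exposed), and each merged interval contributes its integer
  midpoint as the anchor summit.  The midpoint is the only deterministic
  summit-free choice.
* **Tie-break.** An anchor summit exactly equal to a peak summit counts
  as a *left* anchor, which guarantees every domain has positive size.
* **Level-k expansion.** `level = k` uses the k-th nearest anchors on each
  side, generalizing "larger loops defined by more distant CTCF sites";
  a level-k domain always contains the level-(k-1) domain.  Level-1
  domains are non-overlapping by construction; with `level > 1` a TSS may
  fall into several domains and is assigned to the smallest.
* **Size summaries.** Quartiles are formed by rank on the size-sorted
  domain list (4 contiguous groups, remainder to the earliest groups),
  and the arithmetic mean size of each group is reported.  The histogram
  uses 14 log10-spaced bins between 1 kb and 21 Mb plus an underflow bin
  (< 1 kb); only the bin count and range are fixed by convention, the
  edges are a package choice.  Sizes above 21 Mb are counted in the top
  bin.

## DR3 scanning

The built-in DR3 model is a 15-position PWM: two RGKTCA half-sites
(positions 1–6 and 10–15) around a uniform 3-bp spacer.  Single-consensus
positions carry probability 0.85 on the consensus base (0.05 elsewhere);
the degenerate positions R = A/G and K = G/T carry 0.425 on each allowed
base (0.075 elsewhere).  Scoring is natural-log odds against a flat 0.25
background — the HOMER convention, so user-supplied HOMER `.motif`
matrices give comparable scores.  The maximum attainable score is

    2 * (4 ln(0.85/0.25) + 2 ln(0.425/0.25)) ≈ 11.9127,

and the spacer contributes exactly 0.  `N` and any other non-ACGT
character score 0 (background-equivalent), so repeat-masked stretches
cannot rise much above 0.  The exact matrix used in the original HOMER
analyses is not public; absolute scores from this matrix are therefore
comparable only qualitatively with published per-site scores, and the
default cutoff of 7 is the published operating point.

The scanner evaluates every 15-mer on both strands of the summit ±100 bp
window (clamped at chromosome ends) and keeps the single best hit if its
score reaches the threshold.  Score ties are broken by smaller |offset|,
then + strand, then smaller offset; the single-best-hit scan and the
15-mer scorer share one accumulation code path so that mathematically
tied candidates are bit-identical and the tie-break is well defined.

## Accessibility response

Per-peak FAIRE signals arrive pre-summarized as matched control and
ligand-treated vectors over the same time points (which time points enter
is left to the caller's column manifest).  The fold change is the ratio
of averages, `(mean(treated)+ε)/(mean(control)+ε)`, not the average of
per-time-point ratios; the pseudocount ε (default 0.5, configurable)
guards against zero signals.  Significance of the ligand effect is a
two-tailed paired t-test on log(signal + ε) — the underlying test is not
prescribed by the domain, so a Wilcoxon signed-rank alternative is
provided behind the same interface.  Conventions: identical vectors give
p = 1; fewer than two time points give a missing p-value (never a
fabricated one).  The paired t-test on logs is close to nominal for
gamma-like accessibility noise (differences of log-gamma variates are
symmetric), which the calibration test verifies directly.

## Master classification

A peak is a master locus when it passes all three criteria: FE ≥ 9,
FAIRE fold ≥ 1.1, DR3 score ≥ 7.  Whether the cutoffs themselves count
as passing is ambiguous in common usage; comparisons are inclusive (≥)
by default and a `strict` flag flips all three to `>` — neither mode is
asserted to be the original operating convention.  A peak absent from the signal table, or
without a DR3 hit, fails that criterion rather than raising: sparse motif
and signal columns are the norm in real supplementary tables.  Outputs
are per-peak boolean calls, the 7-region Venn partition with
per-criterion totals, and a per-domain master count (the empirical
one-master-per-loop property is reported, never enforced).

## Target-gene enrichment

A gene belongs to a domain when its TSS lies inside `[left, right)`; the
"TSS region" reading is available as a symmetric `tss_slop` (default 0).
Each gene also gets its distance to the nearest peak-containing domain
and the nearest master-containing domain: 0 if inside, otherwise base
pairs from the TSS to the nearest contained base (a definition symmetric
under coordinate reflection), missing if the chromosome has no such
domain.  The enrichment fold

    L = (D*/D) / (M/N)

deliberately mixes a domain-level numerator (fraction of
target-gene-containing domains that enclose a master site, each domain
counted once regardless of how many targets it holds) with a peak-level
denominator (fraction of peaks that are masters) — that is how the
headline statistic is defined, and both fractions are reported separately
so users can form alternative normalizations.  L is reported missing
whenever a denominator is zero.

## Synthetic data

The generator emulates the statistical structure of the real inputs, not
their biology:

| parameter | default | rationale |
| --- | --- | --- |
| chromosomes | 3 × 5 Mb | enough loops for stable counts at desk scale |
| anchor spacing | 1 kb + Exp(49 kb), mean 50 kb | CTCF-loop scale; the 1 kb floor keeps anchor blocks disjoint so merged midpoints equal planted summits |
| peaks | 500, summit ±150 bp intervals | desk-scale stand-in for a genome-wide peak list |
| master fraction | 0.07 | echoes the ~6.8% master share of real peak lists |
| FE, masters | log-normal(ln 25, 0.4) | comfortably above the cutoff of 9, with a realistic tail below it |
| FE, others | log-normal(ln 4, 0.6) | bulk below 9 with a passing tail (~9%) |
| FAIRE truth fold | 1.5 (masters) / 1.0 (others) | a clear but modest ligand induction |
| signals | control ~ Gamma(20, 5) (mean 100); treated = control × fold × Gamma(50, 1/50) noise; 6 time points | multiplicative accessibility noise, CV ≈ 0.22 per point |
| DR3 embedding | PWM-sampled 15-mer conditioned on score ≥ 7, random strand, uniform offset in [−100, 86] | master sites by definition carry an above-threshold element; conditioning (rejection sampling) models that |
| genes | 300, 20% primary targets | a few dozen targets, as in short-induction expression lists |
| target placement | p = 0.25 into a uniformly chosen master loop, else uniform | sets the planted enrichment; see below |

Placement model: the K = 35 master loci occupy K *distinct* loops chosen
uniformly among all loops (one master per loop — the isolation property
observed in real data), with the summit uniform inside the loop;
non-master peaks and non-target genes are uniform over the genome.  The
genome background is i.i.d. uniform ACGT with no repeat structure —
sufficient to calibrate scanner false positives at the default threshold,
but *not* a model of real sequence composition; likewise the generator
has no peak-width variation, no signal-level correlation between
neighboring peaks, and no gene clustering, so passing recovery tests
demonstrate correctness of the pipeline's logic under the stated noise
model, not performance on real data.

Uniform-among-loops master placement makes the closed form exact: master
loops have the *unbiased* loop-length distribution, a target hits a given
master loop of length x with probability `p/K + (1−p)x/G`, and a
non-master loop of length x is a domain with probability
`1 − (1−x/G)^465`, giving

    E[D*] = K · E_x[1 − (1 − p/K − (1−p)x/G)^60]
    E[D−D*] = (N_loops − K) · E_x[(1 − (1−x/G)^465)(1 − (1 − (1−p)x/G)^60)]
    E[L] ≈ (E[D*] / (E[D*] + E[D−D*])) / (K/500)

evaluated by 1-D quadrature over the shifted-exponential loop-length
density.  The final step replaces E[ratio] by ratio of expectations; at
the default sizes the induced bias is well under 1% (verified against a
300-run simulation during development of the formula, mean 4.93 ± 0.05
vs 4.90 analytic).  Note a structural property of the statistic itself:
because L divides a domain-level fraction by a peak-level fraction, even
placement-neutral targets (p = 0) give L ≈ 3 under this geometry — L = 1
is *not* the no-enrichment baseline.  The recovery experiment therefore
compares the realized L against this closed form, using planted master
labels (classifier error is measured separately by the precision/recall
experiment).

Reproducibility: one seed drives a `SeedSequence` whose children feed
anchors, peaks, motifs, sequence, signals and genes separately, so the
same seed yields byte-identical bundles and adding a new output type
cannot perturb existing ones.

## Problem sizes used by the test and acceptance suites

Domain-builder oracle equivalence runs 1,000 random instances (3
chromosomes, ≤200 anchors, ≤50 peaks); the scanner oracle 500 random
201-bp windows; classifier recovery 20 default bundles (pooled precision
and recall); type-I calibration 10,000 null replicates at n = 6;
enrichment recovery 200 structure-only bundles.  These sizes give
comfortably stable statistics for each check while keeping the default
suite quick to run.

## Known limitations

* Anchor summits are merged-interval midpoints, not signal summits; with
  real ChIA-PET releases that carry peak summits, domains can shift by up
  to half an anchor width.
* `expected_enrichment` describes the generator's placement model only;
  it is not an estimator for real data.
* The significance column of the accessibility response is descriptive;
  no multiple-testing control is applied anywhere (none is part of the
  procedure being implemented).
* BAM/bigWig quantification is out of scope: per-peak signals must
  arrive pre-summarized.
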