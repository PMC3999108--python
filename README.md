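# vdrdomains

Nuclear receptors such as the vitamin D receptor (VDR) bind thousands of
genomic sites, yet only hundreds of genes respond to the ligand
(1α,25-dihydroxyvitamin D3) — which binding sites matter, and for which
genes?  `vdrdomains` implements a chromatin-domain answer for
epigenomicists working with ChIP-seq, FAIRE-seq and ChIA-PET data:

1. **Domains.** Every VDR ChIP-seq peak is framed by the summits of the
   nearest CTCF ChIA-PET anchor on each side; the interval between the two
   summits is the peak's chromatin loop (domain), with the chromosome ends
   as natural limits when no anchor exists on one side.  Peaks sharing the
   same flanking anchors share one domain, and `level = k` generalizes the
   frame to the k-th nearest anchors.
2. **Master sites.** A peak is a *master* VDR locus when it passes all
   three criteria: ChIP fold enrichment FE ≥ 9, ligand-induced chromatin
   opening (FAIRE fold change ≥ 1.1 between treated and control signal
   averages), and a DR3-type element (RGKTCA-nnn-RGKTCA) under its summit
   (±100 bp) with log-odds score ≥ 7 against a flat background.
3. **Target-gene enrichment.** Genes are assigned to domains by TSS
   containment.  With M/N the master fraction of peaks and D\*/D the
   fraction of primary-target-gene domains that contain a master site, the
   enrichment fold is

       L = (D*/D) / (M/N)

   — the increased likelihood of finding a primary ligand target gene
   inside a master-site domain rather than near an arbitrary binding site.

A first-class synthetic-data module generates a complete input bundle
(FASTA genome with embedded DR3 elements, ChIA-PET BEDPE, narrowPeak
peaks, FAIRE signal tables, gene BED + target list) with planted ground
truth, so the whole pipeline is testable offline, and ships an exact
closed form for the expected enrichment fold under its placement model.

## Worked example

```bash
vdrdomains synth --out bundle/ --seed 1
vdrdomains run --bundle bundle/ --out results/
```

prints

```
195 domains, 35 master sites
37 target-gene domains, 9 with a master site (enrichment fold 3.47)
```

i.e. the 500 synthetic peaks collapse into 195 CTCF-framed domains; the 35
planted master sites are recovered by the three-criterion conjunction; and
9 of the 37 domains holding a primary target-gene TSS contain a master
site, so L = (9/37)/(35/500) ≈ 3.5 for this seed (the placement model's
expectation is ≈ 4.9; single runs scatter around it).  All tables
(domains, responses, DR3 hits, calls, Venn regions, per-gene assignments,
enrichment report) land in `results/`.

The same statistic applied to published-style summary counts — 52 of 179
target-gene domains with a master site versus 160 of 2,340 peaks being
masters — gives L = (52/179)/(160/2340) ≈ 4.25, a more than 4-fold
increased likelihood:

```python
from vdrdomains import enrichment_from_counts
enrichment_from_counts(2340, 160, 179, 52).fold_likelihood  # 4.2487...
```

## Library layout

| module | contents |
| --- | --- |
| `io_formats` | BED5/narrowPeak, BEDPE/block-pair, HOMER `.motif`, FASTA windows, signal tables, genes, chrom sizes |
| `domain_builder` | anchor merging, nearest-anchor domains, size quartiles/histogram |
| `dr3_scanner` | default DR3 PWM, log-odds scoring, best-hit summit-window scan |
| `chromatin_response` | FAIRE fold change + paired-test significance |
| `master_classifier` | three-criterion calls, Venn regions, masters per domain |
| `target_enrichment` | TSS-to-domain assignment, distances, enrichment fold |
| `synthetic_data` | bundle generator, planted truth, closed-form expected fold |
| `pipeline`, `cli` | orchestration and the `vdrdomains` command |

Coordinates are 0-based half-open throughout (GTF input converted at
ingestion).  See `docs/methods.md` for the model, parameter defaults and
numerical conventions.
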