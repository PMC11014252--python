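# circtdmd

Tools for asking whether circular RNAs (circRNAs) shape the stability of
the microRNAs they pair with — in particular, whether circRNA binding
sites have the architecture of **target-directed miRNA degradation
(TDMD)** sites, and whether the extent of circRNA pairing a miRNA
experiences tracks with post-transcriptional changes in its abundance
across a two-condition experiment (e.g. stem-cell to neuron
differentiation).

## Who this is for

Computational biologists working with circRNA–miRNA interaction
networks: CLIP-supported interaction tables (ENCORI/starBase style),
backspliced circRNA sequences (circBase style), and matched
miRNA / pri-miRNA / circRNA / mRNA expression across two conditions.

## What it computes

**Site architecture.** A seed-match scanner classifies every
miRNA binding site on a target RNA by its pairing geometry:

- *canonical* — a seed match (6mer/7mer-A1/7mer-m8/8mer by m8 pairing
  and t1 adenosine) without extensive 3′ pairing; the ordinary
  silencing configuration.
- *TDMD-like* — seed pairing (≥7mer) **plus** extensive 3′-end
  complementarity: a central target-side bulge of 1–5 nt opposite miRNA
  positions 9–12, ≥6 of positions 13–22 paired with a contiguous run of
  ≥4, and at most 3 mismatches in addition to the central bulge. This
  is the geometry that triggers degradation of the *miRNA* rather than
  the target.
- *slicing* — contiguous perfect complementarity over the full miRNA,
  enabling AGO2-catalyzed target cleavage.

Circular targets are scanned across the backsplice junction (the
sequence is extended by one maximal site footprint and offsets reported
modulo the circle length), so junction-spanning sites are found exactly
once — a site that only exists on the covalently closed form is
detected as such.

**Pairing statistics.** From a filtered interaction table
(clipExpNum ≥ 1, programNum ≥ 2) joined to circRNA genomic spans:

- *effective sites* per miRNA = Σ over circRNAs of
  (site count × mean backsplice-junction reads across the two
  conditions);
- *pairing coefficient* = effective sites / miRNA mean abundance,
  with miRNAs stratified into quartiles from "− paired" to
  "+++ paired";
- *pairing load index* per circRNA = Σ over miRNAs of
  (site count × miRNA mean abundance).

**Differential statistics.** Per-quartile Spearman correlation of
mature vs pri-miRNA log2 fold changes (a weakened correlation in the
top quartile is the signature of a post-transcriptional effect acting
in parallel to transcription), circRNA fold changes across load
quartiles (GLM contrasts vs the least-loaded quartile), and Wilcoxon
rank-sum tests with Hochberg correction.

**Enrichment.** Per-quartile proportions of miRNAs with ≥1 predicted
TDMD-like site on expressed circRNAs (or on linear RNAs, with a
3′-UTR-only sensitivity variant), with one-sided Fisher's exact tests
of each quartile against the least-paired quartile.

**Synthetic cohorts.** A generator emulates every input — miRNA
sequences with unique seeds, lognormal abundances, negative-binomial
junction reads, backspliced sequences with planted sites of controlled
architecture (including junction-spanning and seed-mutant controls),
ENCORI-like interaction records with sub-threshold decoys — and records
a truth table, so the full pipeline is testable end to end with no
downloads.

## Worked example

```bash
circtdmd run-all --seed 17 --out demo
```

writes a synthetic cohort to `demo/data/`, then runs every stage:
`demo/scan/sites.tsv` (one row per site with seed class, 3′ pairing,
bulge and architecture), `demo/pair/mirna_pairing.tsv` (effective
sites, coefficients, quartiles), `demo/diff/` (quartile correlations
and load contrasts) and `demo/enrich/enrichment.tsv`.

On this cohort (236 miRNAs, 120 circRNAs, default stabilization
coefficient β = 0.6) the circRNA rows of `demo/enrich/enrichment.tsv`
read:

```
quartile  target_class  n_with_tdmd  n_total  proportion  odds_ratio  p_value
1         circRNA        0           59       0.000       1.0         1.0
2         circRNA       12           59       0.203       inf         1.3e-04
3         circRNA       16           59       0.271       inf         4.7e-06
4         circRNA       27           59       0.458       inf         1.5e-10
```

i.e. the proportion of miRNAs with at least one TDMD-like circRNA site
rises from 0% in the least-paired quartile to ~46% in the most highly
paired quartile, and the Fisher test against quartile 1 is significant
for every upper quartile (the odds ratio is infinite here because the
reference quartile happens to have no hits at all) — the planted
enrichment is recovered. `demo/diff/correlation_attenuation.tsv` shows
the matching fold-change signature: the mature~pri Spearman correlation
is 0.948 in quartile 1 but 0.783 in quartile 4
(one-sided p = 5.4e-05), the planted post-transcriptional decoupling.

The same stages run individually (`simulate`, `scan`, `pair`, `diff`,
`enrich`) on any data laid out in the same formats; coordinates are
0-based half-open internally, with 1-based-inclusive (ENCORI-style)
interaction tables converted on read via `--dialect`-style flags in the
library API.

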