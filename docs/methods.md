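# Methods

## The question and the quantities

TDMD (target-directed miRNA degradation) inverts the usual logic of
silencing: a target with seed pairing *plus* extensive 3′-end
complementarity — at most 3 mismatches in addition to a central bulge —
triggers degradation of the miRNA itself. Because circRNAs are
covalently closed and exonuclease-resistant, they are plausible TDMD
agents (or, conversely, protectors that stabilize miRNAs). This package
implements the desk half of that investigation: classify the
architecture of circRNA–miRNA binding sites, quantify how much circRNA
pairing each miRNA experiences, and test whether that pairing tracks
with post-transcriptional behavior across a two-condition experiment.

Definitions used throughout, for a miRNA of length N (positions
numbered 5′→3′; the target position opposite position 1 is the site's
*offset*):

- **Seed classes.** Positions 2–7 must pair by strict Watson–Crick
  complementarity (G:U never counts in the seed); m8 pairing and a
  target adenosine at t1 upgrade the class to 7mer-m8 / 7mer-A1 / 8mer.
- **3′ geometry.** Target-side central loops of length 0–5 are
  enumerated at every insertion point opposite positions 9–12; the
  geometry maximizing the number of paired nucleotides among positions
  13..N is kept (ties: fewer mismatches, then smaller bulge, then the
  5′-most loop placement — a deterministic order). Positions that fall
  off the end of a linear target count as unpaired. G:U counts as a
  mismatch in the 3′ region by default (`gu_wobble` flips this).
- **Architectures.** *slicing*: full seed (≥7mer-m8), no bulge, no 3′
  mismatch, every 3′ position paired. *TDMD-like*: seed ≥7mer, bulge
  1–5 nt, ≥6 of positions 13–22 paired including a contiguous run ≥4,
  and ≤3 mismatches. *canonical*: everything else. The thresholds are
  `RunConfig` fields; the defaults encode the TDMD definition above
  plus the canonical-literature requirement of substantive contiguous
  3′ pairing.

**Circular topology.** A circular target of length L is scanned through
`circularize_sequence`: the sequence is extended by (window − 1)
nucleotides, window = miRNA length + maximal bulge, so every
junction-spanning site appears contiguously. Offsets are reported
modulo L and wrapped duplicates collapsed, keeping the representative
with full upstream context. Circles shorter than one footprint are
extended to at most their own length; a site wrapping onto itself more
than once is out of scope.

**Pairing statistics.** With validated interactions filtered at
clipExpNum ≥ 1 and programNum ≥ 2 and assigned to circRNAs by full
containment on the same chromosome and strand:

- effective sites(m) = Σ_c sites(m, c) · (junction reads pre + post)/2,
- pairing coefficient(m) = effective sites(m) / mean miRNA abundance,
- pairing load(c) = Σ_m sites(m, c) · mean abundance(m).

"Average before and after differentiation" is read as the arithmetic
mean of the two condition values. The load index multiplies each
miRNA's own site count by that miRNA's abundance and sums (the
alternative reading — pooled counts times a single abundance — is
recovered when one miRNA dominates). Site-to-circRNA assignment
requires full containment because a binding site must lie within the
transcript to be bound. miRNAs with zero mean abundance are excluded
from coefficients (undefined) and logged.

**Quartiles.** Breaks at the empirical 25/50/75 percentiles of the
coefficient; ties at a break go to the lower quartile (so a cohort of
identical values is all "− paired" rather than arbitrarily split).
Quartile 4 is "+++ paired".

## Statistical procedures

- Per-quartile mature~pri fold-change correlation: Spearman by default
  (heavy-tailed fold changes; Pearson by config). Quartiles with < 3
  matched pairs are reported missing. Multi-locus miRNAs sum their
  pri-transcript counts before the fold change, since total precursor
  supply is the transcription proxy.
- Attenuation comparison (quartile 4 vs quartile 1): one-sided
  Fisher-z test for two independent correlations, with the Spearman
  variance factor 1.06/(n−3).
- Group comparisons: pairwise two-sided Wilcoxon rank-sum against a
  reference group with Hochberg adjustment, or one linear model with
  treatment contrasts against the reference (both raw and adjusted p
  reported).
- Enrichment: per-quartile proportion of miRNAs with ≥1 TDMD-like site
  on the requested target class, Fisher's exact test vs quartile 1,
  one-sided (greater) by default because the hypothesis is enrichment;
  two-sided by config. Zero-margin tables give p = 1 with an undefined
  odds ratio. Sites on circRNAs are first restricted to expressed
  circRNAs (≥1 junction read in either condition).
- Fold changes: log2((post + pc)/(pre + pc)), pseudocount 1.0 by
  default on count-scale tables.

### Stratifying fold-change tests on the pre-condition coefficient

One subtlety discovered while validating the null behavior of the
attenuation test: the pairing coefficient's denominator is the *mean*
abundance across conditions, which contains the post-condition value —
i.e. the outcome whose fold change the test examines. Conditioning the
quartile-4-vs-quartile-1 correlation comparison on mean-based quartiles
therefore selects, at the quartile boundaries, miRNAs by their own
mature fold change, and this selection measurably depresses the
quartile-4 correlation even when no post-transcriptional effect exists
(a ~12% false-signature rate at α = 0.05 in null simulations, stable
under changes of abundance scale and coefficient spread). The reported
pairing tables keep the mean-based definition, but the attenuation
*test* stratifies on the pre-condition coefficient
(`summarize_mirna_pairing(..., condition="pre")`), which is outcome-free;
its measured false-signature rate is ≈8% (400 null replicates), of
which most is the Fisher-z approximation at high rho, and its detection
rate for the planted effect is ≈97%. Analysts applying this package to
real data should be aware that mean-based stratification carries this
circularity.

## The synthetic cohort

`SimulationModel` defaults describe one study-scale cohort:

| parameter | default | meaning |
|---|---|---|
| n_mirnas / n_circrnas / n_mrnas | 236 / 120 / 100 | cohort sizes (236 = analyzed miRNA count at study scale) |
| mirna_abundance | ln-N(5.0, 1.2) | mature reads; median ≈ 150 |
| pri_abundance | ln-N(3.5, 1.0) | precursor proxy counts |
| junction reads | NB(mean 8, size 2) | overdispersed circRNA counts; ~4% zeros exercise the expressed filter |
| circ length | ln-N(6.3, 0.35), ≥150 nt | backspliced exon lengths |
| propensity | ln-N(0.69, 1.0) | per-miRNA expected canonical circRNA sites — continuous and heavy-tailed like CLIP network degree distributions |
| tiers | bottom 25% / middle 50% / top 25% of propensity | targets of the architecture-planting plan |
| TDMD-like plan | 0.08 / 0.3 / 1.2 per tier | planted TDMD relative risk ≈9 between top and bottom tiers |
| slicing / seed-mutant plan | 0.02–0.1 / 0.1 | controls |
| beta | 0.6 | added mature log2FC per SD of pairing coefficient |
| transcription_fc | N(0, 1.0) | shared pri/mature transcription law |
| noise_sd | 0.25 | mature-specific measurement noise |
| circ_fc_sd | 0.5 | circRNA fold changes, independent of load (the null) |

Outcome model: pri log2FC ~ transcription law; mature log2FC = pri
log2FC + β·z + noise, where z is the standardized pre-condition pairing
coefficient; post-abundances are pre × 2^FC. circRNA fold changes are
drawn independently of load, so the load-quartile contrast is a true
null under the defaults.

Planting writes, at a chosen position, the reverse complement of the
miRNA with architecture-specific edits (TDMD: a 1–5-nt random loop
between the nucleotides opposite positions 9 and 8 plus ≤3
substitutions opposite positions 13–15, which preserves a contiguous
paired run; seed mutant: three disrupting substitutions in the seed
complement). Sites never overlap: each planting reserves the worst-case
alignment window (footprint + unused bulge allowance) so later
plantings cannot change an earlier site's verified geometry. Every
planting is locally verified through the alignment and classification
path at generation time and redrawn if its flank context makes the
geometry ambiguous. For every planted non-mutant circRNA site an
ENCORI-like interaction record is emitted with coordinates inside the
circRNA span and evidence counts at/above threshold; sub-threshold
decoy records are always added so the interaction filter does real
work.

Random background occasionally contains a chance TDMD-like geometry for
some other miRNA. So that the truth table is the complete inventory of
high-architecture sites, a post-planting screen breaks such chance
sites with a single seed-core substitution outside every reserved
window; the rare site whose core lies wholly inside reserved windows is
instead recorded in the truth inventory flagged `planted=False`
(recovery statistics use planted records only; inventory-equality
checks use all).

What the generator does *not* emulate: real genomic coordinates or
miRNA families, isoform structure (each linear target carries a single
region label rather than a 5′UTR/CDS/3′UTR partition of one
transcript), CLIP read pileups, sequence composition biases, and any
dependence of circRNA fold changes on miRNA load. Passing tests
therefore demonstrate the pipeline's internal correctness and its
behavior under a controlled generative model — not that real data obey
that model.

## Numerical and engineering choices

- Coordinates are 0-based half-open internally; ENCORI-style 1-based
  inclusive input is converted once at the boundary.
- All randomness flows from integer seeds through
  `numpy.random.default_rng`; identical model + seed reproduces every
  output byte for byte (no timestamps, no set-iteration order in any
  output path).
- The scanner finds seed cores by exact substring search of the
  reverse-complemented positions 2–7 (C-speed), then scores only those
  candidates; a cohort-scale scan (236 miRNAs × ~65 kb of targets) runs
  in ~1.5 s.
- Effective-site conservation (aggregating per miRNA vs directly over
  the count table) holds to < 1e-9 and is asserted in tests.
- Problem sizes in the validation suite — 500 scanner-oracle cases,
  100-replicate recovery/null suites (study-scale cohorts for the
  fold-change statistics; 120 miRNAs / 60 circRNAs for the
  sequence-level enrichment replicates), 1000 calibration replicates,
  Fisher tables with margins ≤ 30 — were chosen so the whole suite
  completes in a few minutes on one CPU while keeping every measured
  rate's binomial error well inside its asserted band.

## Known limitations

- No thermodynamic folding/accessibility scoring and no AGO structural
  modeling; the classifier is purely geometric, so its calls need not
  coincide with tools that weigh pairing energetically.
- Seed pairing is strict Watson–Crick; the G:U switch affects only the
  3′ region.
- miRNAs longer than 22 nt apply the "positions 13–22" thresholds to
  positions 13..N.
- The load-index and quartile-membership definitions follow one
  reading of ambiguous prose (see above); both are config-surfaced
  where alternatives exist.
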