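# Methods

## The analysis

`circheterosis` implements a circRNA-centred heterosis analysis for a
two-parent / multi-F1 trial: a female parent (FP) with high growth
potential, a male parent (MP) with low growth potential, three
high-growth and two low-growth F1 hybrids, three biological replicates
each (21 samples). The pipeline stages are:

1. **Catalog integration.** Two back-splice callers' per-sample call tables
   are merged: calls on the same chromosome and strand whose start *and* end
   coordinates agree within 10 nt (inclusive, configurable) form one group.
   Grouping is single-link; chains are collapsed to one entry whose
   coordinates come from the best-supported call (ties: caller A, then the
   smaller start). Per-sample counts average the two callers where both
   report; a single caller's count passes through un-averaged, so
   caller-specific sensitivity is not penalised. Coordinates are 1-based
   inclusive throughout.
2. **Origin classification.** Against a gene annotation: *exonic* — both
   back-splice ends in exons of one gene and the span inside that gene
   (sequence taken as the spliced exon concatenation); *intronic* — span
   entirely inside a single intron; *exon_intron* — gene-overlapping but
   neither purely exonic nor purely intronic (including spans extending past
   the gene); *intergenic* — no gene overlap. Overlap is tested on the
   matching strand first, then rescued strand-agnostically and flagged, so
   antisense-derived circRNAs are not misfiled as intergenic.
3. **Quantification.** RPM = back-spliced reads × 10⁶ / mapped reads.
   Expression bins: low < 100 RPM, moderate 100–500 RPM (boundaries
   inclusive), high > 500 RPM. Presence defaults to any-replicate > 0.
4. **Differential expression.** Replicates are pooled per group and compared
   with an exact conditional binomial test: given the total count, the
   group-A count is Binomial(total, n_A/(n_A+n_B)) under equal rates; the
   two-sided p doubles the smaller tail (capped at 1). Benjamini–Hochberg
   q-values; DEC thresholds |log2FC| ≥ 1 and q ≤ 0.05, both inclusive.
   log2FC uses a pseudo-rate ε = 0.5/min(n_A, n_B) on both sides. Counts are
   rounded to integers for the binomial only (dual-caller averaging yields
   half-integers); fold changes use the raw rates.
5. **Heterosis taxonomy.** The mid-parent value (MPV) is (mean FP + mean
   MP)/2 on RPM; the MPV *test* group pools both parents' counts and library
   sizes. Features expressed in the F1 or with MPV > 0 are classified
   additive (no significant F1-vs-MPV difference) or non-additive;
   non-additive features get a Stupar subtype — up vs MPV: AHP if the F1
   exceeds the high parent else HP; down: BLP if below the low parent else
   LP. The high/low parent is fixed by growth potential (FP high, MP low);
   `by_expression=True` restores the higher-expressing-parent convention.
   Presence/absence in the parents independently yields SPE-F (female only),
   SPE-M (male only), CoPE (both) and the SFE flag (F1 only).
6. **Function.** miRNA sites are scored gap-free with the Allen plant
   penalty scheme (0 per Watson–Crick pair, 0.5 per G:U wobble, 1 per
   mismatch, doubled at miRNA positions 2–13), cutoff 4.0; scanning is
   circular (sequence extended by its first L−1 nt) so junction-spanning
   sites are found. ORFs are detected in all three frames of the sequence
   concatenated four times, start offsets restricted to the first copy;
   minimum length 63 nt counted ATG through stop inclusive; a frame with an
   ATG and no stop across the wraps is reported *rolling* with length
   4·L truncated to a codon multiple. Coding potential = ORF AND IRES when
   an IRES annotation is supplied (IRES prediction itself is an external
   trained model and is consumed as a boolean column), otherwise ORF-only
   mode.
7. **Correlation.** Pearson r and two-sided p between each circRNA's RPM and
   its parent gene's FPKM across all samples; significance at unadjusted
   p ≤ 0.05 (a BH option exists, off by default). Zero-variance pairs are NA
   and excluded from summaries; r = 0 ties count as positive (measure-zero).
   Multi-parent circRNAs produce one record per gene.
8. **Co-expression.** Unsigned adjacency |cor|ᵝ; β chosen as the smallest
   power whose scale-free fit R² ≥ 0.8 (fallback 6). TOM_ij =
   (Σ_u a_iu a_uj + a_ij)/(min(k_i, k_j) + 1 − a_ij). Modules: average-
   linkage clustering of 1 − TOM with a static cut at height 0.99 (a
   deliberate simplification of dynamic tree cutting — deterministic and
   sufficient for planted-block recovery); clusters below the minimum size
   become grey. Eigengene = first principal component of the standardized
   module submatrix, unit-norm, sign-oriented so the mean feature
   correlation is positive (ties: largest-magnitude loading made positive).
   Module–trait correlation uses per-genotype (or per-role) binary
   indicators. Hubs are the top-k features by intramodular connectivity
   kWithin. Term enrichment is the upper-tail hypergeometric probability.

## The synthetic world

The generator emulates the trial at toy scale and plants every label the
pipeline must recover:

- **Annotation/genome:** non-overlapping genes (1–4 exons of 80–300 nt,
  introns 60–200 nt, intergenic gaps 250–800 nt) on random chromosomes.
- **circRNAs:** placed per origin class (default mix 57.2% intergenic,
  40.2% exonic, 1.0% intronic, 1.6% exon_intron; lengths mainly
  100–700 nt); same-chromosome placements keep start or end separated by
  > 25 nt so jittered caller calls can never cross-merge.
- **Expression:** per-genotype RPM means with negative-binomial
  (Gamma–Poisson) counts; `dispersion` (default 0.1, a typical bulk-RNA
  replicate overdispersion) of 0 degrades to Poisson. SPE/SFE absences are
  *exact structural zeros*, matching the presence/absence definition of
  single-parent expression. The default parental-pattern mix mirrors the
  emulated catalog (SPE-F 0.164, SPE-M 0.142, CoPE 0.105, SFE 0.589); the
  default class mix keeps additive expression dominant (92%) with HP rare
  (0.5%). SFE circRNAs are definitionally non-additive (MPV = 0), so the
  class mix applies to parent-expressed circRNAs and SFE ones are recorded
  AHP.
- **HP is a boundary class.** Under fold-change ≥ 2 vs MPV, an F1
  significantly above MPV yet not above the female parent forces the male
  parent's expression to ~0; planted HP circRNAs therefore have mu_MP = 0
  and sit exactly at 2×MPV. HP recovery is boundary-limited by
  construction — a property of the thresholds, not of the implementation.
  LP planting skews the parents 2·fold : 1 so the F1 can sit a full effect
  fold below MPV while staying at or above the male parent.
- **Sequencing depth:** mapped-read totals are uniform 4–6 million per
  sample. The emulated study's depths vary by only a few percent; keeping
  them near-equal makes the pooled mid-parent pseudo-library an unbiased
  stand-in for the mean-RPM MPV (a 10× depth spread would bias pooled rates
  by over one log2 unit for single-parent circRNAs even without noise).
- **Callers:** per-caller coordinate jitter truncated to ±5 nt per end
  (so planted pairs always stay within the 10-nt window), per-caller
  dropout, and relative count noise around a common support value.
- **miRNAs:** planted target miRNAs are the exact reverse complement of a
  circular window of a chosen circRNA — derived *from* the sequence rather
  than edited into it, so the sequence-equals-genome invariant holds by
  construction. Planted ORFs (ATG + non-stop codons + stop, spanning the
  junction) *are* written into the genome, but only inside intergenic
  circRNAs placed without mutual overlap, before sequences are extracted.
- **Parent-gene FPKM:** parent genes co-vary with their circRNA's RPM —
  negatively for SPE-M circRNAs, positively otherwise; other genes are
  independent noise.

What the generator does **not** emulate: read-level artefacts, alignment
ambiguity, alternative back-splicing isoforms, GC or length biases,
realistic miRNA families, real GO/KEGG ontologies, or replicate-level
batch effects. A green recovery test therefore establishes that the
pipeline's logic is faithful to its definitions — not that the statistics
are robust to unmodelled real-data structure.

## Numerical choices and degenerate inputs

- The pooled binomial test ignores replicate variance (the two-library
  paradigm); with overdispersed replicates its p-values are anti-
  conservative, which is why DEC calling is gated by the fold-change
  threshold as well. A replicate-aware NB GLM is out of scope.
- Features with zero counts in both groups are excluded (p undefined, NA).
- BH correction passes NAs through untouched.
- Constant features are dropped with a warning before network construction;
  zero-variance correlation pairs are NA.
- Merge tie-breaks: total read support, then caller A, then smaller start.
- ±10 inclusive is used for the merge window (the alternative reading of a
  10-wide window is flag-tunable via `tolerance`).
- All generators and stages are deterministic given a seed; the pipeline
  derives per-stage seeds from one master seed via `SeedSequence.spawn`.

## Known limitations

- Toy-scale catalogs (hundreds of circRNAs) only; no attempt to reproduce
  genome-scale catalog counts, which depend on unavailable sequencing data.
- The single re-implemented target scorer stands in for the union/
  intersection behaviour of two external tools whose merge rule is unknown.
- Static-height module cutting can split or lump modules that dynamic tree
  cutting would resolve; module *labels* (colour names) are ordered by size
  and are not comparable across runs.
- Gapped target alignment is available but off by default; thermodynamic
  scoring is out of scope.
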