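# Methods

This note documents the statistical model behind each pipeline stage, the
synthetic-data generator's assumptions, and the numerical and design
choices that were genuinely open.

## Study design assumed by the pipeline

Four ordered developmental stages of bone-marrow B cells (pro-B, pre-B,
immature, mature), each profiled as a single pooled library per omics
layer: circRNA (RPM), miRNA (TPM), mRNA (FPKM). There is no within-stage
replication — pooling several animals into one library is part of the
design — which dictates the replicate-free count test below. All three
matrices share the stage axis; transcript sets are independent per layer.

## Expressed calls and stage specificity

A transcript is expressed in a stage when its normalized value ≥ threshold
(threshold > 0), or > 0 at the default threshold of 0. The default makes
"expressed" mean "any nonzero signal", the only rule that needs no tuning;
the threshold is exposed because any fixed cutoff in normalized units is a
judgment call. The Venn class is the exact expressed-stage subset (15
non-empty subsets plus `not_expressed`); a transcript is stage-specific
iff its subset is a singleton. The per-stage specific fraction divides
specific-to-*s* by expressed-in-*s* and is undefined (None, never 0) when
nothing is expressed in *s*.

Stage correlation is Pearson's r between stage columns over all
transcripts, computed on the normalized values without log transform (the
statistic is defined on total expression levels; a `log1p` variant would
change r and is not the default). Zero-variance stages yield NaN entries,
flagged rather than zeroed.

## Differential expression: Audic–Claverie conditional test

For counts x, y at library sizes N₁, N₂, the conditional distribution of y
given x under equal underlying rates is

    P(y | x) = (N₂/N₁)^y · (x+y)! / (x!·y!) · (1 + N₂/N₁)^−(x+y+1),

a negative binomial with r = x+1 and success probability N₁/(N₁+N₂)
(implemented via `scipy.stats.nbinom`; the test suite re-derives it by
direct lgamma-based tail summation). The two-sided p doubles the smaller
of the two inclusive tails at the observed count, capped at 1.

**Canonical orientation.** On a discrete distribution, tail-doubling
depends on which sample is conditioned on: the naive rule can differ by up
to ~0.37 between orientations at small counts. Since the test must not
care which stage is listed first, the pair is put in a canonical
orientation before testing — condition on the sample with the smaller
normalized rate x/N₁ (ties broken by count, then library size). This makes
p(x,N₁; y,N₂) exactly symmetric under swapping, keeps p = 1 when the two
rates are equal, and preserves monotonicity in |x−y| at fixed totals.

**DE rule.** is_DE ⟺ p < 0.05 (strict) and |log₂FC| ≥ 1 (inclusive), with
log₂FC computed on per-million-normalized values with pseudocount 1.0
(log₂((a+1)/(b+1))); significance always uses raw counts. No multiplicity
correction enters the call — with one test per transcript per comparison
the raw-p rule is the convention this pipeline follows — but BH-adjusted
p-values are reported in every record for readers who want FDR control.
The FPKM layer's fold changes equal its count-ratio fold changes (the
per-transcript length factor cancels), so DE is computed uniformly on
counts for all three layers.

## Temporal patterns

Each profile is normalized to the pro-B stage, (vᵢ+pc)/(v₀+pc) with
pseudocount 1.0, then each of the three transitions is labelled `up` when
the ratio exceeds 1+δ, `down` below 1/(1+δ), else `flat` (δ = 0.2 default,
chosen as a band comfortably wider than Poisson ratio noise at the
simulated depths while still separating two-fold steps). Ratio (not
difference) thresholds make labels scale-invariant, consistent with
fold-change semantics elsewhere. The 27 sign words replace model-profile
clustering with permutation significance (the STEM approach): for the
purpose of binning trajectories into named up/down patterns, the sign word
is the bin, and it is deterministic and directly checkable against planted
truth.

## Seed matching

Site definitions on the target read 5'→3' (the target is never
reverse-complemented; only the miRNA seed is complemented):
8mer = revcomp(miRNA[2..8])+"A"; 7mer-m8 = revcomp(miRNA[2..8]);
7mer-A1 = revcomp(miRNA[2..7])+"A"; 6mer = revcomp(miRNA[2..7]).
Coordinates are 0-based half-open. At each target start position only the
strongest matching type is reported (8mer > 7mer-m8 > 7mer-A1 > 6mer),
which prevents double-counting nested sites at one position; nested sites
at *different* start positions (an 8mer always contains a 7mer-A1 one base
downstream) are distinct sites by definition. The model is exact canonical
seeds only — no G:U wobble, no 3'-supplementary pairing, no context or
conservation scores — so that a brute-force sliding-window comparison is a
complete oracle. Where fidelity to dedicated prediction tools matters,
their exports are loaded as interaction tables and merged by union with
provenance retained (union, not intersection, because the merge must not
silently drop a curated edge; filtering is the caller's decision).

## ceRNA assembly

A transcript belongs to a transition group iff it is DE in exactly that
adjacent-stage comparison — exclusivity is evaluated per transcript within
its own layer. A triplet requires: all three members in the same group;
interactions miRNA→circRNA and miRNA→mRNA present in the merged table; and
direction consistency sign(circ) = sign(mRNA) = −sign(miRNA), i.e. one of
the two schemes decreased-circ/increased-miR/decreased-mRNA or its mirror.
No minimum site count and no expression-correlation filter is applied by
default (none is part of the model); both can be imposed upstream by
filtering the interaction table. Output is complete (every qualifying
triplet) and lexicographically sorted, making network files byte-stable.

## Enrichment and qPCR

Over-representation uses the upper-tail hypergeometric p = Σ_{i≥k}
C(K,i)C(N−K,n−i)/C(N,n) via `scipy.stats.hypergeom.sf`, BH-corrected
across tested terms (`statsmodels` step-up behind the
`benjamini_hochberg` surface). The background defaults to all genes with
at least one annotation in the supplied GMT — the clusterProfiler
convention — and query genes outside it are dropped with a warning. Terms
with no background gene are skipped. GeneRatio is the literal string
"k/n". The qPCR side computes 2^−ΔΔCt from the four cycle thresholds
(target and reference gene, condition and control).

## The synthetic generator

The generator emulates the study regime, not any particular dataset:

- **Layer sizes** default to 1005 circRNAs, 1600 miRNAs, 9758 mRNAs (the
  scale of a sorted-population tri-omics experiment).
- **Stage specificity.** `frac_stage_specific_*` is the *per-stage*
  specific fraction p (specific-to-s over expressed-in-s). Planting S
  specific transcripts per stage and expressing everything else in all
  four stages gives p = S/(n−3S), so S = n·p/(3p+1). Defaults: 0.6 for
  circRNAs (the stage-restricted layer), 0.08 for miRNAs and mRNAs.
- **Expression levels.** Per-transcript base expression is log-normal
  (median ≈ e^(ln 100 − 0.5) in normalized units, σ = 1, mean 100),
  constant across the transcript's expressed stages; zero elsewhere.
- **DE planting** uses step profiles: level A up to the earlier stage of
  the planted comparison, level B = A×fold (default fold 4) from the later
  stage on, so exactly one adjacent comparison sees a fold change.
  Planted-DE transcripts sit at base 100 so their counts are deep enough
  for near-certain detection. `de_truth` records *planted* effects only;
  stage-specific transcripts also change between stages by construction
  (on/off), so null-rate measurements use the flat `background_ids`.
- **Patterns** are planted for circRNAs as multiplicative walks with step
  2.0 per `up`/`down` transition, for six characteristic sign words by
  default.
- **Sponge triplets** (default 5 per transition group) get step-profile DE
  with scheme-consistent directions (alternating the two schemes) plus
  sequences: 21-nt miRNAs and 200-nt targets with one exact 8mer site per
  planted pair written at a recorded offset. Target backgrounds are
  rejection-sampled (≤1000 attempts, then error) until no *non-planted*
  pair has a 6mer-or-better site anywhere, so seed-match prediction on
  these sequences returns exactly the planted edges. miRNA draws reject
  seed collisions in which one miRNA's 6mer site string embeds in
  another's 8mer site, a configuration that would make target rejection
  sampling unsatisfiable.
- **Counts.** Mean count = normalized mean × depth/10⁶ (× length/10³ for
  the FPKM layer, with effective lengths uniform in [500, 5000] nt;
  FPKM = count/(library/10⁶ × length/10³)). Noise is Poisson by default or
  gamma-Poisson (negative binomial, var = μ + φμ²) with user dispersion φ;
  the pooled design provides no replicates from which to estimate φ, hence
  the simple default. `replicates_per_stage` pools r independent libraries
  into one column (library size r × depth), matching a pooled design.
  **Hard planting** writes the mean values directly into the normalized
  matrices and rounds them into counts, so exact-recovery tests are
  deterministic.

What the generator does *not* emulate: read-level artifacts (mapping,
back-splice junction detection), isoform structure, between-stage library
composition effects, correlated transcript modules, and biological miRNA
sequence composition. Passing tests therefore demonstrate that the
pipeline's logic recovers the structure it is designed to detect under its
own model assumptions — not that the upstream quantification of any real
dataset is reproduced.

## Degenerate inputs and tie-breaks

Empty layers, empty networks and empty tables are valid and produce empty
outputs; an undefined specificity fraction is None; zero-variance
correlation entries are NaN; equal counts give p = 1; all-zero profiles
normalize to flat via the pseudocount. Writers order everything
lexicographically so identical content is byte-identical on disk.

## Problem sizes used in tests and the acceptance script

Seed-matcher oracle: 500 random pairs, targets ≤ 200 nt. Triplet oracle:
50 instances, ≤ 20 ids per layer. End-to-end recovery: default-size
hard-planted study, 5 triplets per group. Specificity: 1000 circRNAs hard;
20 Poisson seeds for the realized-fraction band. DE: 2000 null and 1000
four-fold transcripts at mean count 100. Count test vs summation: all
x, y ≤ 30 at two depth ratios (tolerance 1e-10). Hypergeometric vs
enumeration: universes N ≤ 30 (literal draw enumeration at N ≤ 12).

## Known limitations

- The count test assumes Poisson sampling within each pooled library;
  overdispersed data (the generator's negative-binomial mode) will inflate
  its false-positive rate, which is inherent to replicate-free designs.
- The seed matcher is deliberately less sensitive than thermodynamic or
  context-scoring predictors; it is a clean stand-in, and curated
  interaction tables should be merged in when available.
- Exclusive-group assignment reads "DE in exactly one comparison" per
  transcript within its layer; a joint-across-layers reading is not
  implemented.
- Pattern labels carry no significance measure; a flat transition is
  whatever falls inside the δ band.
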