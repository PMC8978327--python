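# bcellcerna

Analysis pipeline for circRNA–miRNA–mRNA (ceRNA) regulatory networks across
the four developmental stages of bone-marrow B cells — pro-B, pre-B,
immature and mature — built for transcriptomics researchers who profile
circRNAs (RPM), miRNAs (TPM) and mRNAs (FPKM) in sorted cell populations
and want a tested, reproducible route from expression matrices to
direction-consistent sponge networks.

## What it computes

- **Stage-specificity (Venn) classes.** A transcript is *expressed* in a
  stage when its normalized value clears a threshold (default: any nonzero
  value); its class is the exact subset of stages in which it is expressed.
  The per-stage specific fraction — specific-to-*s* over expressed-in-*s* —
  is the statistic that separates highly stage-restricted circRNAs from
  broadly shared miRNAs/mRNAs. Inter-stage Pearson correlation is computed
  on total expression levels.
- **Adjacent-stage differential expression.** With one pooled library per
  stage there are no replicates, so DE is tested per transcript with the
  Audic–Claverie conditional count test: given count *x* at library size
  *N₁*, the count *y* at size *N₂* follows
  P(y|x) = (N₂/N₁)^y (x+y)! / (x! y!) (1+N₂/N₁)^−(x+y+1)
  under equal rates; the two-sided p doubles the smaller inclusive tail.
  A transcript is DE when p < 0.05 and |log₂FC| ≥ 1.
- **Temporal patterns.** Profiles normalized to pro-B are binned into one
  of 27 sign words over the three transitions (e.g. `down-up-down`,
  `up-up-up` = continuously increased) with a relative threshold δ = 0.2.
- **miRNA target prediction.** Canonical seed matching on target sequences:
  8mer, 7mer-m8, 7mer-A1 and 6mer sites (seed = miRNA nucleotides 2–7/2–8),
  exact Watson–Crick only. Exports from external databases (e.g.
  Starbase/miRTarBase-style tables) can be loaded and merged with recorded
  provenance.
- **ceRNA assembly.** Transcripts DE in exactly one adjacent-stage
  comparison form that transition's exclusive group; a triplet
  (circRNA, miRNA, mRNA) enters the group's network when the shared miRNA
  has a site on both partners and directions satisfy
  sign(circ) = sign(mRNA) = −sign(miRNA) (decreased circRNA / increased
  miRNA / decreased mRNA, or the mirror scheme). Networks export to SIF or
  GraphML for Cytoscape.
- **Enrichment and qPCR arithmetic.** Upper-tail hypergeometric
  over-representation against GMT gene sets with Benjamini–Hochberg
  correction (significant: adjusted p < 0.05, GeneRatio `k/n`), and
  relative quantification by the comparative cycle threshold (2^−ΔΔCt)
  method.

A synthetic tri-omics generator (`bcellcerna.synthetic_data`) reproduces
this data regime with planted, machine-checkable ground truth — stage
specificity, step-profile DE, trajectory patterns, and sponge triplets
whose sequences carry real seed sites — so every stage of the pipeline is
tested against known answers.

## Worked example

```
$ bcellcerna simulate --outdir sim --seed 5
wrote dataset and ground truth to sim

$ bcellcerna profiles --matrix sim/circ_expression.tsv --unit RPM --out calls.tsv
pro-B: specific fraction 0.597
pre-B: specific fraction 0.597
immature: specific fraction 0.597
mature: specific fraction 0.597
```

About 60 % of the circRNAs expressed in each stage are expressed in that
stage only — the planted stage-restricted regime. Calling DE per layer and
comparison, merging seed-match predictions, and assembling the pro-B→pre-B
network:

```
$ bcellcerna de --counts sim/circ_counts.tsv --libsizes sim/library_sizes.tsv \
      --layer circ --comparison PreVsPro --out de_circ_PreVsPro.tsv
PreVsPro: 228 up, 226 down

$ bcellcerna cerna --de-circ de_circ_all.tsv --de-mir de_mirna_all.tsv \
      --de-mrna de_mrna_all.tsv --interactions merged.tsv \
      --group PrePro_only --out net.sif
{"n_circ": 5, "n_mirna": 5, "n_mrna": 5, "n_edges": 10}
```

The DE counts are dominated by stage-specific circRNAs switching on or off
between stages; the assembled network recovers exactly the five sponge
triplets planted in the pro-B→pre-B transition group (each triplet
contributes one `sponges` and one `targets` edge). `de_*_all.tsv` files are
the per-comparison DE tables concatenated; `merged.tsv` comes from
`bcellcerna targets` run on the dataset's miRNA/circRNA/mRNA sequences.

The same flow is available as a library — `generate_dataset`,
`call_expressed` / `classify_specificity`, `de_all_comparisons`,
`predict_interactions`, `build_triplets` — see `bcellcerna.pipeline` for
the end-to-end convenience wrapper.

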