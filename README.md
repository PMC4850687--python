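# nipiscreen

Analysis pipeline for quantitative, genome-wide RNAi screens read out with a
large-particle flow sorter (COPAS Biosort), built around the *C. elegans*
antifungal-immunity screen design: an epidermal antimicrobial-peptide
reporter (*nlp-29p::gfp*) induced by *Drechmeria coniospora* infection, a
constitutive control reporter (*col-12p::dsRed*) on the same array, and
per-worm measurements of size (TOF) and fluorescence for every well of a
21,000-clone RNAi library.

The package is for people analyzing (or planning) such screens: it turns raw
per-worm sorter events into per-clone phenotype calls and downstream
gene-level analyses, and ships a synthetic-data generator with known ground
truth so every stage can be exercised and validated without any raw-data
download.

## What it computes

1. **Normalization.** Per worm, fluorescence is divided by size
   (GFP/TOF, dsRed/TOF); per well, worm ratios are averaged; per plate,
   well means are divided by the plate's truncated mean (discarding the
   25 % lowest and 25 % highest well values), giving plate-comparable
   normalized values *n*GFP, *n*Red, *n*TOF. Normalization is exactly
   invariant to constant plate factors and robust to the few real hits per
   plate.
2. **Phenotype calling.**
   - *Nipi* (no induction of peptide after infection): normalized GFP
     reduced ≥ 20 % in both round-1 duplicates, control reporter and
     worm-size guards clean, confirmed in ≥ 3 of 4 round-2 replicates.
   - *enhancers → Peni / Hipi*: mean GFP up ≥ 30 % in round 1; in
     quadruplicate retest with and without infection, constitutive
     expression (Peni) is separated from infection-only hyper-induction
     (Hipi) at a cut-off anchored midway between positive and negative
     control clones.
   - *developmental* exclusion from round-2 quantitative data (median
     normalized size or red reporter below cut).
   - *G/O/I epistasis flags* (abrogates constitutive GPA-12\*-driven
     expression / blocks osmotic induction / induces the intestinal *irg-1*
     reporter), tri-state when an assay is missing.
   - spore-adhesion scoring (categories and adhesion index
     `(mouth + vulva) / (2 × worms)`).
3. **Target mapping and accounting**: clone→gene maps with multi-target
   families (*his*, *msp*) filtered as a block, screen-efficiency and
   library-assembly arithmetic, DIOPT-style ortholog selection by score gap.
4. **Enrichment**: one-sided Fisher exact (hypergeometric upper tail) with
   Bonferroni correction, optional EASE-penalized mode, foundling-gene
   detection (hits in no significant class), 1 − Pearson biclustering,
   protein-complex coverage (size ≥ 3, strictly > half recovered).
5. **Phylogenetic profiling**: best-hit bit-score matrices from tabular
   alignment files, self-normalized rows (C<sub>ij</sub>/C<sub>ii</sub>),
   within-taxon-group species clustering, and orphan / clade-restricted /
   broadly-conserved classification.

## Worked example

```sh
nipiscreen --config configs/default.yaml --seed 3 --out-dir demo_out run
```

simulates a 384-clone screen with 8 planted Nipi, 3 Peni, 3 Hipi and 3
developmental clones, then runs the adaptive two-round analysis (round-2
wells are generated for the actual round-1 positives). It prints:

```
INFO nipiscreen: run: library                         384
INFO nipiscreen: run: round1_nipi_candidates           11
INFO nipiscreen: run: round1_enhancer_candidates        6
INFO nipiscreen: run: round2_nipi                      11
INFO nipiscreen: run: pronounced_developmental          3
INFO nipiscreen: run: retained_nipi                     8
INFO nipiscreen: run: peni                              3
INFO nipiscreen: run: hipi                              3
```

Reading the accounting: 11 round-1 Nipi candidates are the 8 planted Nipi
clones plus the 3 developmental clones (which also damp the reporter); all
confirm in round 2, the developmental filter then removes exactly the 3
planted sick clones, leaving the 8 true Nipi hits; the 6 enhancer
candidates resolve into 3 Peni and 3 Hipi at the control-anchored cut-off.
`demo_out/` contains the clone library, ground truth, per-clone call table
(`calls.tsv`) and the per-step report. The stages can equally be run one at
a time (`simulate`, `normalize`, `call`, `map`, `enrich`, `profile`,
`report`) over the TSV artifacts.

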