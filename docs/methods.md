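# Methods

## Measurement model

The unit of raw data is one worm passing the sorter: size (TOF), extension,
and green/red fluorescence in arbitrary units. Fluorescence scales with worm
size, so all decisions are made on size-corrected ratios GFP/TOF and
dsRed/TOF. The unit of decision is the well (one RNAi clone, ~100 worms);
the unit of nuisance variation is the plate.

Two nuisances dominate such data and both are multiplicative: heavy-tailed
worm-to-worm variation in reporter expression, and plate-to-plate variation
in culture, infection and detector conditions. Normalization removes the
plate component in three steps: per-worm ratios, per-well arithmetic means
of the ratios, and division of every well mean by the plate's truncated mean
of that quantity over wells (trim fraction 0.25 per tail, count-based:
`floor(0.25 n)` values discarded per end, so the trim degrades gracefully to
the plain mean for small plates). The truncated mean is the right normalizer
here because any plate carries a handful of genuine hits in either tail;
trimming one quarter per side tolerates up to 25 % of wells being real
effects without moving the reference. Two exact properties follow and are
tested: multiplying every event on a plate by a constant leaves all
normalized values unchanged (the formal content of "across-plate
comparison"), and inflating the plate maximum arbitrarily leaves the
normalizer untouched whenever at least one value is trimmed per tail.

Low-yield wells (fewer than `min_worms = 80` events, the typical yield of
the assay) are flagged rather than dropped — dropping them silently would
bias calls against slow-growing (often developmental) clones — and are
excluded from the plate normalizer so that sparse, noisy means do not
perturb it. Whether the original analysis excluded such wells from the
normalizer is not documented; excluding them is the conservative choice and
is configurable in effect via the flag.

## Synthetic screens

The generator emulates the statistical structure of the sorter data rather
than its biology:

* Worm-level noise is independent multiplicative lognormal (unit mean,
  coefficient of variation `worm_cv`, default 0.2) on TOF and on each
  fluorescence ratio. Lognormal because the channels are strictly positive
  with a heavy right tail. The true inter-individual variance of reporter
  expression is not published; 20 % is a plausible order for an integrated
  multi-copy reporter and is a parameter, not a fitted value.
* The plate effect is one lognormal factor per plate (log-SD
  `plate_effect_sd`, default 0.3) multiplying TOF and both per-worm ratios,
  so all three normalized channels carry it and the truncated-mean
  normalization removes it exactly. (Applying the factor to raw TOF and raw
  fluorescence alone would cancel out of the ratios and make the
  normalization step vacuous; the generator is built so the nuisance it
  plants is precisely the one the analysis removes.)
* Wild-type infection induces GFP `wt_induction_fold`-fold (default 10 — a
  strongly induced reporter), scaled by a Hill dose response in the spore
  dose (EC50 and Hill coefficient configurable; infected wells use 10× EC50,
  near saturation). Induction is 0 at dose 0 and saturates at 1.
* Planted effects are per-clone multipliers: on the induced GFP level
  (Nipi < 1, Hipi > 1), on the uninfected baseline (Peni > 1), on the red
  control reporter and on size. Epistasis classes apply their induced-GFP
  multiplier to their own assay condition (GPA-12*, osmotic, irg-1).
  Default planted strengths (Nipi 0.4, Hipi 2.0, Peni 3.0, developmental
  red 0.5) are chosen as clear-but-not-extreme phenotypes, several noise
  SDs from null at the well level.
* Every plate carries the control block used by the callers: two null
  negative controls, a small-size signaling control (TOF multiplier 0.8)
  anchoring the size guard and the developmental cut, a strong positive
  knock-down control, and — on retest plates — two constitutive-expression
  positive controls anchoring the Peni cut-off.
* Retest and epistasis plates are padded to full plates with null filler
  wells (at most 8 retested clones per 96-well plate). This mirrors the fact
  that the plate normalizer is only meaningful when most wells are
  unremarkable; without padding, a retest plate consisting mostly of strong
  hits would drag its own truncated mean toward the hits and erase them.

What the generator does **not** model: within-plate spatial gradients,
fungal growth dynamics, developmental stage progression, worm-yield
differences between clones, and clone identity errors. Passing tests
therefore demonstrate that the decision rules recover effects of the planted
kind under multiplicative plate/worm noise — not that they are robust to
spatially structured artifacts or mislabeled clones, which in real screens
must be handled upstream.

All randomness flows from one integer seed through three deterministic
substreams (round 1, round 2, epistasis); identical seeds give byte-identical
event tables.

## Decision rules

All thresholds live in one `Thresholds` record (and one flat YAML file for
the CLI) because most of them are screen-design conventions rather than
statistically derived quantities; every default is stated here.

* **Round-1 Nipi** (duplicates, infected): normalized GFP ≤ 0.80 in *both*
  replicates; mean normalized red < 1.30; mean normalized size not below the
  small-size control's. The red guard is deliberately one-sided (increases
  only): a clone that *reduces* the control reporter signals a sick or
  delayed population, and that is the job of the round-2 developmental
  filter, which sees the quadruplicate data. A symmetric round-1 band at
  30 % would be self-defeating: any clone sick enough to be flagged
  developmental later (red < 0.7) would already have been discarded in
  round 1, making the developmental category unreachable.
* **Round-1 enhancer**: mean normalized GFP ≥ 1.30 with neither red nor size
  increased by ≥ 30 % (the one-sided form here is the stated rule).
  Whether the 30 % refers to the mean of the duplicates or to each
  replicate is not specified in the source protocol; the mean is used.
* **Round-2 Nipi** (quadruplicates, infected): at least 3 of 4 replicates at
  ≤ 0.80 *and* median ≤ 0.80, guards re-applied on medians. The exact
  historical round-2 criteria are not published in the main protocol; this
  reproducibility-weighted rule (count + median) is the package's explicit,
  configurable stand-in.
* **Developmental exclusion** (round-2 quadruplicates): median normalized
  size below the small-size control's level (fallback 0.7), or median
  normalized red below 0.7. The historical criteria table is unavailable;
  these two cuts are the documented convention here.
* **Peni/Hipi**: the Peni cut-off is anchored midway between the highest
  negative and lowest positive control value (error when the controls
  overlap — that is an assay failure, and the CLI exits nonzero on it).
  Peni requires the uninfected normalized GFP above the cut-off in ≥ 3 of 4
  replicates; Hipi requires not-Peni plus infected GFP ≥ 1.3 (the "simple
  cut-off", configurable) in ≥ 3 of 4. Peni therefore takes precedence and
  the two flags are mutually exclusive by construction.
* **G/O/I epistasis**: the clone/control ratio of mean normalized GFP in the
  corresponding assay, at ≤ 0.5 (G), ≤ 0.5 (O) and ≥ 2.0 (I). Normalized
  expression is used as the induction proxy — with a shared baseline the
  ratio of normalized levels equals the ratio of inductions. Flags are
  tri-state: a missing assay leaves the flag absent, never false.
* **Adhesion**: spore counts bin at 10 and 25 spores/worm with boundaries
  assigned to the lower bin (the printed intervals share endpoints, so a
  convention is required); the adhesion index is
  (worms with > 1 spore at mouth + at vulva) / (2 × worms); selection
  requires index below every control and > 50 % reporter reduction in both
  duplicates.

## Target mapping, enrichment, profiling

Family filtering removes a clone only when *all* its predicted targets are
in the flagged families (histone/major-sperm-protein), otherwise it keeps
the clone and drops the family genes; the operation is idempotent and
family membership is an input gene list, never inferred from nomenclature.
Sequence-ambiguous clones (no predicted target) stay in clone-level counts
and out of gene-level ones. Ortholog selection keeps the best-scoring
candidate when it beats the runner-up by ≥ 2 score points (strict mode) or
keeps the top two when the gap is ≤ 2 (complex-mapping mode); ties break by
gene id.

Enrichment is the one-sided hypergeometric upper tail (over-representation
only, since that is what the analysis reports), Bonferroni-corrected by the
number of classes actually tested (those with at least one universe gene) —
the only defensible multiplicity count when classes can be empty in a given
universe. The universe defaults to the union of all class genes plus the
query, with an explicit override, because the original annotation database
behind the published p-values is not recoverable; for the same reason those
p-values are validated structurally (enumeration agreement, planted-class
ranking) rather than numerically. Both plain Fisher and the EASE-penalized
variant (k − 1 in place of k, floored at zero) are provided because the
source is ambiguous about which was used. Clustering uses 1 − Pearson
distance with average linkage; the distance was named by the original
analysis but the linkage was not, so average linkage (the usual default of
the tool cited) is fixed here explicitly for reproducibility. Zero-variance
rows, where the correlation is undefined, sit at distance 1 from everything
by convention.

Phylogenetic profiles never execute an aligner: standard 12-column tabular
best-hit files are inputs, and the test fixture writes synthetic ones with a
designed truth. Rows are normalized by the query's self-alignment score, so
the query's own species sits at exactly 1.0. A homolog is called present at
a normalized score ≥ 0.25 — no numeric cut-off is published for "homolog
present", and the relative color scale of the original display implies one;
0.25 of self-similarity is a deliberately permissive, documented default
(roughly the level of clear but distant homology) and a single parameter.
Species are clustered only within their taxon group, groups kept in a fixed
order, so orderings never mix groups. Classification (orphan /
clade-restricted / broadly conserved) is monotone in the threshold: raising
it never moves a gene toward broader conservation.

## Numerical and degenerate-input conventions

Truncated means trim `floor(f·n)` per tail (weakest trim consistent with the
stated fractions); a truncated mean of zero marks a degenerate plate and is
an error rather than a NaN. Reported percentages round half-up to the
printed precision (`decimal`-based, not banker's rounding). The anchored
cut-off errors on overlapping controls instead of guessing. Empty wells,
empty gene lists, duplicate clone ids, nonpositive TOF, and missing self
scores are all hard validation errors at the I/O boundary so the analysis
core never sees them.

## Problem sizes

The bundled demo screen is 384 clones; the planted-recovery study runs
2,000 clones (5 % Nipi at a 60 % reduction, 10 Peni, 10 Hipi) with 100
worms per well, two round-1 replicates and adaptive quadruplicate retests
— about 700,000 simulated worms, a few seconds of compute. These sizes are
the package's validation conditions: large enough for the 2 % false-call
bound on ~1,900 null clones to be meaningful, small enough to run routinely.

## Known limitations

Recovery statistics are conditional on the generator's noise model
(independent lognormal worm noise, plate-constant multiplicative effects);
real sorter data additionally shows within-plate gradients, clumped debris
events and occasional empty wells, which this pipeline does not detect. The
round-2 and developmental criteria are explicit reconstructions, not the
unpublished originals, so clone-list-level agreement with the historical
screen is out of scope by design. Gene-level statistics inherit whatever
errors the upstream clone-to-target prediction table contains.
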