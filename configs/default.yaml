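# Default run configuration: every tunable parameter of the pipeline in one
# flat key-value file.  Unknown keys are rejected by name.

# --- synthetic library composition -----------------------------------------
n_clones: 384                # library size of the simulated screen
planted_nipi: 8              # clones that abolish infection-induced GFP
planted_peni: 3              # constitutive reporter expression, no infection
planted_hipi: 3              # exaggerated induction upon infection only
planted_developmental: 3     # pronounced size / control-reporter phenotype
nipi_strength: 0.4           # induced-GFP multiplier of planted Nipi clones
with_epistasis: false        # also run the GPA-12*/osmotic/irg-1 assays

# --- generator --------------------------------------------------------------
seed: 0
n_worms_per_well: 100        # sorter events per well
worm_cv: 0.2                 # lognormal worm-to-worm coefficient of variation
plate_effect_sd: 0.3         # log-scale SD of the multiplicative plate factor
wt_induction_fold: 10.0      # infection-induced GFP fold-change, wild type
dose_ec50: 1.0               # spore dose giving half-maximal induction
dose_hill: 2.0               # Hill coefficient of the dose response
spore_dose: 10.0             # dose used for infected wells (10x EC50)
base_tof: 100.0              # wild-type worm size, arbitrary sorter units
base_gfp_ratio: 1.0          # uninfected GFP/TOF baseline
base_red_ratio: 2.0          # constitutive dsRed/TOF baseline
osmotic_fold: 5.0            # osmotic-stress GFP induction fold
gpa12_fold: 8.0              # constitutive fold in the GPA-12* strain
irg1_baseline: 0.3           # basal level of the intestinal irg-1 reporter
wells_per_plate: 96
retest_clones_per_plate: 8   # round-2 plates are padded with null wells
epistasis_clones_per_plate: 8

# --- normalization ----------------------------------------------------------
trim_fraction: 0.25          # discard the 25 % lowest and highest well values
min_worms: 80                # wells below this worm count are QC-flagged

# --- phenotype calling ------------------------------------------------------
nipi_reduction: 0.20         # required GFP reduction, both round-1 duplicates
enhancer_increase: 0.30      # required mean GFP increase for enhancer clones
guard_increase: 0.30         # tolerated increase of red reporter / worm size
round2_min_hits: 3           # replicates (of 4) that must pass in round 2
g_abrogation: 0.50           # GPA-12* expression reduction for a G-clone
o_block: 0.50                # osmotic-induction reduction for an O-clone
i_fold: 2.0                  # irg-1 reporter fold-increase for an I-clone
dev_ntof: null               # developmental size cut; null = anchor to rack-1
dev_nred: 0.7                # developmental control-reporter cut
hipi_cutoff: 1.3             # infected normalized GFP cut-off for Hipi

# --- enrichment / profiling -------------------------------------------------
alpha: 0.001                 # corrected-p significance level
enrichment_mode: fisher      # fisher | ease (penalized overlap)
presence_threshold: 0.25     # normalized bit score calling a homolog present
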