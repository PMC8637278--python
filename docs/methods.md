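# Methods

This note documents the models, conventions and numerical choices behind
`stepscore`, what the synthetic-data generator does and does not emulate,
and the design decisions taken where more than one reading was defensible.

## Scoring model

**Epitope unit.** A T-cell epitope is a pair (9-mer core, presenting DRB1
allele). Cores are all sliding 9-residue windows (stride 1) of a target
HLA's mature-chain protein; a core is *non-self* if it occurs as a substring
of no HLA protein of the recipient at the considered loci (A, B, C, DRB1,
DRB3/4/5, DQA1/DQB1, DPA1/DPB1, as present in the reference). Only
HLA-DRB1 acts as the presenting (restriction) locus. Duplicate (core,
presenter) pairs arising within one genotype configuration — the same core
at two sequence positions, or from both alleles of a locus — count once: an
epitope is a peptide–MHC pair, not an occurrence.

**Presentation predictor.** Presentation of a core by a DRB1 allele is
delegated to a pluggable deterministic predictor. The default,
`PwmPredictor`, draws an independent 9 × 20 standard-normal position-weight
matrix per DRB1 allele from a seed; a core's score is the mean matrix entry
over its residues and the per-allele threshold is calibrated on random
cores so a fraction `p_present` (default 0.30) of peptide space is
presented. It is a deterministic surrogate with the right *interface* and
allele-specificity, not a trained binding model; an adapter implementing
`presented(core, drb1)` can substitute a NetMHCIIpan-class tool. The STEP
construction itself — non-self filtering, weighting, merging, intersection —
is independent of which predictor is plugged in.

**Imputation.** A serological typing constrains, per locus group, the *set*
of antigen labels of the genotype (homozygosity is encoded as a single
label; untyped C/DQ/DP groups are unconstrained and marginalized over).
Candidate genotypes are all unordered reference-haplotype pairs whose
serological projection matches; the prior is Hardy–Weinberg, `f1*f2` for a
homozygous pair and `2*f1*f2` otherwise, renormalized over the candidates.
The "normalized frequency" convention in the source literature does not
state the combinatorial factor; HWE is the standard convention of
haplotype-frequency imputation and is used throughout.

**DRB1 extrapolation and gate.** For each serological DR antigen, compatible
DRB1 alleles are ranked by their probability of being present in the
genotype; each candidate genotype's weight is then attributed to its
highest-ranked present compatible allele, giving an *exclusive* marginal
distribution that sums to 1. (This reproduces the worked two-haplotype
example — exclusive weights 8/9 and 1/9 — which a naive equal-split rule
does not.) The top allele replaces the serological label iff its weight is
at least the threshold (default 0.65). An exact tie in presence probability
between the two best alleles is never broken by chance: the label is
excluded, because a coin flip would silently pick a wrong presenter half the
time. A recipient is excluded when any DR label fails the gate, since both
presenting molecules enter the overlap comparison.

**Weighted epitope sets.** For a list of targets (two-field allele names, or
serological labels that resolve to frequency-weighted allele candidates),
each joint configuration (recipient genotype candidate × target candidate)
contributes its probability mass to every (core, presenter) pair it
produces, with the recipient's extrapolated DRB1 alleles fixed in every
configuration's self-proteome. A pair's weight is the summed mass, capped
at 1 — whether a production system lets such weights exceed 1 when summed
over many configurations is not documented; the cap keeps a weight
interpretable as "probability this epitope exists". Donor ("recall")
targets are the donor's serological antigens absent from the recipient at
each locus group typed on both sides; matched antigens contribute nothing.
For DQ/DP alpha/beta dimer beads both chains enter the immunizer target
list; chains the recipient carries are neutralized by the non-self filter.

**Overlap and STEP.** Recall-set duplicates per (core, presenter) are merged
with weights summed. A recall epitope survives iff the same (core,
presenter) occurs in the immunizer set; it keeps its recall weight
(immunizer-side weights only decide membership — the recall weight is a
property of the donor-side peptide, so the cross-bead dedupe cannot depend
on bead order). For DRB1-homozygous recipients the comparison runs once on
the single distinct allele. The overlap score is the sum of surviving
recall weights; `STEP = ln(overlap + 1)`.

**Bead normalization and selection.** Raw MFI is divided by the minimum MFI
of the bead's locus group (A, B, C, DR1/3/4/5, DQA1/DQB1, DPA1/DPB1) for
that recipient; a non-positive minimum is an error, never epsilon-patched.
Approach A selects ratio strictly above 5 ("above"/"higher than" read as
strict — flagged as a convention, since an inclusive reading is also
possible); B selects the panel-wide highest positive *raw* MFI with ties
all included (A/C/D operate on ratios, B on raw MFI — the literal reading
of the four descriptions); C and D use
`cutoff = min + (max − min)·(1 − q)` with q = 0.05 and 0.01 over the
recipient's full ratio set, boundary inclusive. A's absolute threshold may
select nothing (the recipient then contributes overlap 0); DSA-carrying
beads are assumed excluded upstream (the intended cohort has no
pre-transplant DSA), so no DSA filtering happens here.

## Statistical layer

* **Cox models** are fitted by lifelines (`CoxPHFitter`) with Efron tie
  handling (lifelines supports no other; the Breslow option was therefore
  not exposed). Records with missing values in the selected variables are
  dropped listwise. `repeat_tx` (reference: first transplant) and
  `donation_dbd` (reference: DCD) are 0/1 indicators; all other covariates
  are continuous.
* **Time-dependent covariates** `x·f(t)` (default `f = ln(1+t)`) are
  realized by episode-splitting at the event times and fitting
  `CoxTimeVaryingFitter` — the standard `tt()` construction.
* **PH diagnostics** use the scaled-Schoenfeld score test against
  transformed time (Kaplan–Meier transform by default); variables with
  p < 0.05 are refitted with a time interaction in the pipeline.
* **Stepwise selection** alternates forward entry (best likelihood-ratio p
  below SLE = 0.15) and backward elimination (worst LR p above SLS = 0.15),
  on a complete-case table fixed up front so every nested test compares the
  same rows. LR tests were chosen over Wald as better behaved at small
  event counts. Deterministic: ties break by smallest p, then candidate
  order; an oscillation guard stops label cycling. The null partial
  log-likelihood has the closed Efron form at beta = 0.
* **Kaplan–Meier** is a direct numpy product-limit implementation (the ABS
  permutation loops need ~1e5 fits); it is cross-checked against lifelines'
  estimator in the tests.
* **ABS permutation test**: statistic `∫|S1 − S2| dt` on the merged
  event-time grid up to the smaller of the two groups' last observed times;
  group labels are permuted (default 1000 permutations, mandatory seed) and
  p follows the add-one rule `(1 + #{perm ≥ obs})/(1 + n_perm)`. The
  unweighted integrand is used; a variance-weighted variant would be a
  different statistic.
* **Cut-point**: Gaussian-kernel-smoothed CDFs of the score in the
  non-event (F0) and event (F1) groups, Silverman bandwidth per group,
  cutoff maximizing J(c) = F0(c) − F1(c) on a 512-point grid spanning the
  data ± 3 bandwidths.
* **HR curves**: *virtual endpoints* administratively censor all follow-up
  at t and refit; *landmarks* keep only records event-free past t **without
  resetting the clock** — "setting survival to 100 % at t" is read as
  conditioning, and since every retained subject is at risk from t onward
  the partial likelihood equals the left-truncated one. Grid points with
  fewer than 5 events (configurable) are skipped with a reason. By
  construction the virtual endpoint at the follow-up cap and the landmark
  at 0 reproduce the full-model fit bit for bit.
* **Baseline comparisons**: two-sided tie-corrected Mann–Whitney U for
  continuous variables, Pearson chi-square without continuity correction
  for categorical ones, missing values dropped per variable.

## Synthetic world

The generator emulates the *reference data* a real analysis consumes, not
their biology:

* **Alleles**: per locus, a shared random base sequence (default 60
  residues) with a small set of polymorphic positions whose residues encode
  the allele index in base 20 — so any two alleles of a locus, in particular
  serology siblings, differ in at least one residue and non-self 9-mers are
  guaranteed to exist between any allele pair. Default universe:
  4/4/4/6/4 alleles at A/B/C/DRB1/DQB1, two alleles per serology.
* **Haplotypes**: 12 distinct random allele combinations with symmetric
  Dirichlet frequencies — deliberately no linkage disequilibrium or
  population structure.
* **Eplets**: one identifier per (locus, polymorphic position, residue), so
  alleles sharing a residue share the eplet — a table-driven stand-in, not
  a curated registry.
* **Bead panels**: one bead per allele (alpha/beta dimers where both chains
  of a DQ/DP group exist), uniform background MFI in [50, 500] and the
  planted immunizer at 5000, making the plant the panel-wide argmax — so
  approach B recovers it with probability 1 by construction. No MFI
  physics (saturation, prozone, cross-reactive backgrounds).
* **Cohorts**: covariates drawn from plausible transplant ranges (donor age
  N(50, 15²) clipped, cold ischemia N(22, 8²) hours with 3 % missing,
  transplant years 1995–2005, ~20 % repeat transplants, ~60 % DBD, hPRA
  from a right-skewed Beta). Failure times are exponential with hazard
  `λ0·exp(Σ βk·xk)` (λ0 = 0.02/year), death with functioning graft is an
  independent exponential censoring process (0.015/year — both chosen to
  give a realistic ~17 % ten-year death-censored failure fraction), and
  administrative censoring at 10 years. The exponential model satisfies
  proportional hazards exactly, which is what the estimators are validated
  against. The STEP covariate is **computed through the real scoring
  pipeline** for each generated recipient (typings → DRB1 gate → bead panel
  → epitope sets → overlap), never sampled from a distribution; recipients
  whose typing fails the DRB1 gate are resampled, so generated cohorts are
  fully analyzable and pipeline exclusions can only come from user data.

Consequently, passing tests demonstrate the *algorithmic* properties —
exact set arithmetic, correct weighting and normalization, calibrated
tests, recoverable planted effects — on data whose generative assumptions
(no LD, uniform backgrounds, exponential hazards, surrogate presentation)
are idealized. They say nothing about clinical effect sizes, about
real-world imputation accuracy (which depends on population-specific
haplotype tables), or about the fidelity of any particular binding
predictor.

## Determinism and problem sizes

Every generator and every stochastic procedure is a pure function of an
integer seed; rerunning the pipeline with an identical configuration
produces byte-identical outputs (verified by hashing). Caches
(`ScoringEngine`) only memoize pure functions and cannot change results.
The verification script uses 1000 random overlap instances, 500 bead
panels, 100 cohorts of n = 2000 for effect-recovery coverage, and 500 null
runs × 200 permutations for ABS calibration — sizes at which the Monte
Carlo error of each check is well inside its acceptance band.

## Known limitations

* The presentation surrogate shares no parameters with real MHC-II binding;
  absolute STEP magnitudes are not comparable to scores from production
  epitope services.
* Serological label matching requires genotype labels to equal the typed
  label set exactly; typings with reporting idiosyncrasies (broad/split
  mixtures, CREG groups) are out of scope.
* Landmark fits condition on survival, they do not re-time; if a clock
  reset is wanted it must be done upstream.
* Competing-risks modelling (death as a competing event rather than
  censoring) and multiple imputation of missing cold-ischemia times are
  deliberately out of scope.
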