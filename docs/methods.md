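# Methods

`opsinpred` studies how well regression on aligned amino-acid sequences can
predict the spectral phenotype of opsin visual pigments — λ_max, the
wavelength of maximal absorbance in nm — and how that compares with, and
complements, phylogenetic trait imputation. This note records the models,
the choices behind them, and what the synthetic validation does and does not
demonstrate.

## The prediction model

Sequences enter as rows of a multiple sequence alignment (the package
consumes aligned FASTA; alignment itself is delegated to external tools such
as MAFFT or MUSCLE). Each alignment column becomes a block of indicator
features, one per residue observed at that column in the training data:

* **Zero-entropy columns are dropped.** An invariant column cannot explain
  phenotype variation, so it contributes no features.
* **Unseen residues are all-zero.** At prediction time, a residue that never
  occurred at that column in training — and a gap — encodes as an all-zero
  block. The model therefore cannot distinguish one novel residue from
  another; it degrades gracefully instead of failing. Treating the gap as a
  21st state is available behind a flag in `one_hot` callers via the
  vocabulary argument, but the all-zero convention is the default because it
  keeps the unseen-residue contract uniform.

A registry of seven regressors is trained on these features: ridge and
Bayesian ridge (linear, closed-form shrinkage), random forest, gradient
boosting (scikit-learn GBR, LightGBM, XGBoost) and AdaBoost stumps. All
hyperparameters are the libraries' defaults except ensemble sizes fixed at
100 and seeds threaded from one explicit integer. Models are compared by
k-fold cross-validation (default k = 10) on folds shared across estimators,
scored with R², MAE, MAPE, MSE and RMSE, and ranked by mean R² with ties
broken by lower MAE, then name.

**Position importance.** For the top models (default 3), per-feature
importances — impurity importance for the forest/boosting family, split
counts for LightGBM, gain for XGBoost, |coefficient|·feature-SD for the
linear family — are summed within each column block, scaled per model so the
maximum is 1, and averaged. The report joins each column to bovine-rhodopsin
reference numbering (with `pos+k` insertion codes where the reference is
gapped) and its transmembrane-domain label. TMD boundaries are configuration
data, not constants.

**New sequences.** Unaligned queries are projected onto training columns by
global pairwise alignment to the training reference row (match 2, mismatch
−1, gap open −10, extend −0.5), then encoded with the training vocabulary.
Query residues inserted relative to the reference have no column and are
dropped.

## Mutants, chimeras and epistasis

Mutation notation (`D83N_A292S`) is parsed into ordered, position-disjoint
edits; positions are 1-based indices into the ungapped native parent unless
flagged as reference-frame, in which case a PositionMap translates them.
Applying an edit validates the stated wild-type residue — a mismatch almost
always means a coordinate-frame error and is a hard error, not a warning.
Chimeras replace whole TMDs of a parent with a donor's, in alignment column
space.

For a multimutant whose wild type and every component single mutant are
measured in the same background, the **epistasis-free additive mutation
value** is

    EAMV = λ_wt + Σ_i (λ_single_i − λ_wt),

and the multimutant is called epistatic when |λ_obs − EAMV| > 1 nm (strict
inequality, raw values). The leave-epistatic-out experiment removes all
epistatic multimutants from training (retaining their singles) and compares
three predictors of the removed records: the trained model, a wild-type-only
model, and the EAMV baseline. Squared errors are paired per multimutant and
compared with a Wilcoxon signed-rank test: zero differences dropped,
midranks for ties, exact two-sided p by enumeration of sign assignments
(computed by dynamic programming, identical to brute force) up to n = 25,
normal approximation with tie-corrected variance and continuity correction
beyond; Bonferroni correction for the three pairwise comparisons. XGBoost is
the default estimator for this experiment: in our validation the deeper
trees recover planted interactions that shallow GBR captures only
marginally.

## Phylogenetic imputation

Under Brownian motion with rate σ² on a rooted tree, tip traits are jointly
normal with covariance σ²·C, C[i][j] the shared root-to-tip path length.
Missing tips are imputed by the conditional normal given observed tips, with
the root state estimated by GLS and σ² by maximum likelihood (REML is not
used; the conditional means do not depend on σ², only the reported
conditional variances do). A singular observed block — duplicate zero-length
tips — receives a diagonal ridge of 10⁻⁸ × tree height, with a warning,
rather than failing. The comparison harness withholds the same random tips
from both the regression route and the imputation route and pairs their
residuals.

## The synthetic study

Real opsin data cannot be bundled, so every experiment runs on generated
studies with known truth. The generator emulates the structure the analyses
assume: a Yule tree scaled to height 1; sequences evolved without indels
(root uniform over 20 residues, Poisson(rate·t) substitution events per
site, each uniform over the other 19); phenotypes

    λ(tip) = 500 + Σ additive site effects + Σ pairwise interactions
             + BM(σ²_phylo) + N(0, σ_e²),

clamped to the empirical 350–611 nm range (the clamp never fires at default
scales and warns if it does); and laboratory-style mutants spawned from
wild-type parents with notation written by diffing, phenotypes computed
noiselessly from the truth function on the parent's Brownian background
(mutagenesis does not re-draw phylogenetic history).

Default scales, chosen once to echo the magnitudes typical of opsin work:
200 tips, length 300, rate 0.5 events/site/unit height, five tuning sites
with |δ| ~ U[5, 25] nm, two interacting pairs with |γ| ~ U[5, 20] nm,
σ²_phylo = 25 nm²/unit (≈5 nm background SD), σ_e = 3 nm.

**Identifiability guards.** A planted signal must be recoverable in
principle for recovery tests to mean anything, and three structural
properties of the study guarantee that:

1. *Tuning sites are convergent, not clade markers.* A site whose minor
   allele arose once is statistically confounded with the Brownian
   background of that clade and with every other substitution on the same
   branch. Real spectral tuning substitutions recur across lineages, and the
   generator enforces the analogue: a planted site's carrier pattern must
   have ≥10% minor-allele frequency and Pearson |r| ≤ 0.7 with every other
   column's carrier pattern.
2. *Interactions are expressed in the population.* The two residues of an
   interacting pair must co-occur in enough wild-type tips (the same floor)
   — an interaction never realised in training data is unlearnable by any
   method.
3. *Multimutants without characterised singles exist.* Besides full
   wild-type/single/single/double quartets (which the epistasis discovery
   finds and the experiment removes), the study includes double mutants
   carrying an interacting pair whose singles were never measured. These are
   the records that keep interaction information in a training set purged of
   identifiable epistatic mutants — the situation the leave-epistatic-out
   experiment probes. Without this record class the model provably predicts
   additively and the experiment reduces to a tie with the EAMV baseline.

**What passing tests show, and what they do not.** The synthetic study has
no indels (so alignment is exact and downstream logic is isolated from
aligner behaviour), a uniform substitution model rather than an empirical
amino-acid matrix, phyla assigned by a root split, and noise-free mutant
phenotypes. Success on it demonstrates that the pipeline's machinery —
encoding, model ranking, hold-out bookkeeping, EAMV arithmetic, conditional-
normal imputation, importance aggregation — is correct and that the planted
signal classes are recovered under realistic magnitudes. It does not
demonstrate performance on real opsins, where alignment error, chromophore
and expression-system effects, taxonomic sampling bias and literature
curation noise all intrude.

## Numerical choices and edge cases

* AIC for least-squares trend fits is n·ln(RSS/n) + 2k with constant terms
  dropped; RSS is floored at n·(10⁻⁹·scale)² so numerically exact fits tie
  and the tie-break prefers fewer parameters, then name. Nonlinear
  candidates (exponential rise, saturating, power) use multi-start
  `curve_fit`; a model that fails to converge is flagged and ranked last
  rather than aborting the comparison.
* The learning-curve driver scores each training size by k-fold CV (the
  spec point of comparison is relative, not absolute, so the cheaper k = 3
  is used in the acceptance driver; k = 5 elsewhere). Analysis problem
  sizes — 200-tip studies, hold-out groups of 25, 30-record curve steps —
  were chosen as the smallest sizes at which the studied effects are
  clearly resolved.
* Hold-out residuals use the strict rule: an absolute residual of exactly
  10 nm is not an outlier.
* Duplicate sequences with λ_max spread ≤ 3 nm (configurable) merge to the
  mean; a wider spread raises a curation error rather than silently
  averaging incompatible measurements.
* A training alignment with no variable columns yields a mean predictor
  with a warning instead of a crash (it arises in tiny hold-out folds).
* Relative Shannon entropy is per-column entropy (bits, gaps excluded from
  frequencies) divided by the alignment's maximum column entropy; all-gap
  columns are flagged and excluded from the scaling.

## Known limitations

* The gap-fraction trimmer removes heavily gapped columns only; it is not a
  Gblocks reimplementation and applies no flank or conservation criteria.
* Pairwise projection of unaligned queries ignores insertions relative to
  the reference; a query with long insertions loses those residues.
* Importance scores inherit each library's importance semantics; they are
  comparable within a model after max-scaling but not calibrated across
  model families beyond the [0, 1] normalisation.
* Imputation assumes strict Brownian motion; no Ornstein–Uhlenbeck or
  multi-rate variants are provided.
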