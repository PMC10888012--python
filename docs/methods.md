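# Methods

## Scope and model

`stabpath` treats missense pathogenicity as a thermodynamic question: does a
substitution destabilize the folded protein (ΔΔG = ΔG_wt − ΔG_mut < 0,
kcal/mol), and does it sit in the buried core (low relative solvent
accessibility, RSA ∈ [0, 1])?  Three kinds of statements are produced:

* descriptive — stabilizing/destabilizing censuses and benign/pathogenic
  counts per chemical-property substitution category;
* single-score discrimination — ROC/AUC and MCC-optimal cutoffs for ΔΔG
  scores and RSA used as threshold classifiers;
* a combined classifier — logistic regression on (ΔΔG, RSA).

The package never computes ΔΔG or RSA from sequence or structure; they are
inputs (predictor columns in the variant table, or an oracle table for the
saturation profiler).  Predictors that emit the opposite sign convention
(positive = destabilizing) are declared as such and flipped at ingestion, so
everything downstream assumes negative = destabilizing.

## Curation

Filters run in a fixed order: label resolution → frequency → conflict →
gene balance.  The order matters only for attribution of drops to filters
and for the gene-balance denominator, which is deliberately computed on the
records surviving the earlier stages.  Choices worth noting:

* Frequency rules use strict inequalities (benign dropped when
  frequency < 0.01, pathogenic when > 0.01); a frequency of exactly 0.01
  survives both.  Records with no frequency are retained — real clinical
  tables frequently lack one, and dropping them would gut the cohort.
* Gene balance requires **both** class fractions to strictly exceed the
  threshold (default 10%): a gene with 9 pathogenic + 1 benign (benign
  fraction exactly 0.10) is dropped.
* The two label policies mirror the two common benchmark conventions:
  strict (drop `likely_*`) and inclusive (fold `likely_*` into the parent
  class).

Curation is idempotent and its report reconciles exactly (every input
record is either kept or counted in exactly one drop bucket); both are
tested properties.

## Substitution categories

The four axes follow the standard chemical grouping: hydrophobic
{A,C,G,I,L,M,F,P,W,V} vs polar; small {A,C,G,S,N,D,P,T,V} vs large;
aromatic {H,F,W,Y} vs aliphatic {A,I,K,L,M,P,V}; positive {H,K,R} vs
negative {D,E}.  Lys appears in the aliphatic group — chemically debatable
(its side chain is an aminoalkyl chain) but kept as the scheme defines it.
A substitution belongs simultaneously to one directed category per axis on
which both residues are grouped; ring/charge pairs involving an ungrouped
residue are silently skipped, not errors.  Non-canonical residues (B, Z, X,
U) are rejected at parse time rather than remapped.  Category tables are
reported only where a category has more than 100 records, so rates are not
driven by tiny denominators.

## Evaluation

Scores are oriented so that lower = more pathogenic; a record is called
pathogenic when score ≤ cutoff (direction-reversed scores such as |ΔΔG| use
≥).  MCC uses the standard binary formula with the MCC = 0 convention when a
denominator factor vanishes.

The ROC sweep visits each distinct score once (ties collapse into a single
step), which makes the trapezoid area mathematically identical to the
concordance (Mann–Whitney) AUC with ties scored ½; the suite checks the two
routes against each other to 1e−9 and against scikit-learn.  MCC scans use
a fixed grid, −5…+5 step 0.1 kcal/mol for ΔΔG and 0…1 step 0.01 for RSA,
matching the one-decimal resolution at which such cutoffs are usually
quoted; ties on MCC break toward the cutoff of smallest magnitude.

Balanced resampling draws N = ⌊min(n_benign, n_pathogenic)/2⌋ records per
class without replacement, 100 times, and reports mean ± sd (ddof = 1) of
TPR/FPR/FNR/accuracy at a fixed cutoff.  When several methods are compared,
all are evaluated on the same drawn sample in each repetition (paired
draws), so between-method contrasts are not inflated by sampling noise.

## Logistic classifier

P(pathogenic) = σ(β₀ + x·β) on features standardized to zero mean / unit sd
on the training split (standardization makes the regularization strength
comparable across features; the stored means/scales travel with the model).
The fit maximizes the penalized log-likelihood with penalty ‖β‖²/(2c),
intercept unpenalized — the same objective as scikit-learn's C-parameterized
logistic regression, which serves as an independent cross-check in the
tests.  Because the problem is 3-parameter and strictly concave, a damped
Newton iteration converges to an infinity-norm gradient below 1e−10 in a
handful of steps and is bit-deterministic; a finite-difference gradient
check at the optimum is part of the acceptance suite.

Protocol: downsample the majority class to the minority count, split 80/20
stratified, select c ∈ {10⁻³ … 10³} by 100 repetitions of stratified 5-fold
cross-validation on held-out AUC (ties → smaller c, i.e. stronger
regularization), refit on the whole training split, report AUC and MCC at
probability cutoff 0.5 on both splits.  With only two well-scaled features
the held-out AUC is nearly flat in c, so the tie-break typically selects the
strongest regularization; coefficients on standardized features are small
in magnitude but their signs (both negative: more destabilizing and more
buried ⇒ more pathogenic) and the model's discrimination are unaffected.
Balancing precedes the split so both splits are balanced.

## Saturation profiling

All 19·L substitutions of a protein are enumerated (position-major, mutant
residue alphabetical); positions with non-canonical wild-type residues are
skipped and recorded.  A substitution is called potentially pathogenic when
its ΔΔG ≤ −1.1 kcal/mol — the boundary counts as pathogenic; entries
without a ΔΔG are flagged uncalled and excluded from the called totals.
The cutoff default matches the MCC-optimal operating point commonly found
for sequence-based ΔΔG predictors on curated benchmarks.

## Synthetic cohort generator

The generator produces the study conditions rather than any real dataset:

* **Latent ΔΔG** per variant from a class-conditional two-sided mixture: a
  destabilizing truncated normal (below 0) and a stabilizing one (above 0),
  with destabilizing mass 0.70 for pathogenic (mean −2.8, sd 1.6) and 0.55
  for benign (mean −0.4, sd 0.4) — pathogenic variants are both more often
  and more strongly destabilizing, while the classes overlap substantially.
* **Predictors** = latent + independent Gaussian noise (sd 0.8 and 1.0 for
  the two informative read-outs, 2.5 for the deliberately weak one, which
  also uses the flipped sign convention to exercise normalization).  The
  shared latent value reproduces inter-predictor correlation and makes the
  two-predictor average beat the weak predictor, without modelling any real
  tool.
* **RSA** from class-conditional Beta laws — pathogenic Beta(2, 4) (mode
  0.25, buried-skewed), benign Beta(2.6, 2.4) (mode 0.53) — coupled to the
  latent ΔΔG through a class-conditional Gaussian copula with correlation
  +0.1 (destabilizing ↔ buried).  The configured coupling is the
  within-class correlation; pooled over classes the two signals also share
  the benign/pathogenic mean shift, which is exactly the "two weakly
  related, individually informative signals" regime the analyses assume.
* **Planted violations** at per-record rates (10% `likely_*` labels, 5%
  frequency contradictions, 5% conflicts, 5% one-sided-gene records), with
  clean records rotated across genes so every kept gene stays two-sided.
  A sidecar records each record's latent ΔΔG, fate, and expected survival
  under both label policies; curation tests assert exact-set agreement.
* **Saturation oracle**: each substitution falls at or below the cutoff
  with exactly the configured probability (exponential tails hanging off
  the cutoff), so the planted pathogenic mass (default 0.37) is exact by
  construction.

What passing tests on this cohort do **not** show: real predictors have
sequence-dependent, non-Gaussian, mutually correlated errors; real RSA and
ΔΔG are linked through structure, not a copula; real gene effects are far
more heterogeneous.  The generator validates the pipeline's logic and its
statistical behaviour under known truth, not the empirical performance of
any particular predictor.

## Problem sizes and determinism

Default analyses use 3,000 records per class (≈4,500 after curation), 100
cross-validation repetitions, 100 resampling repetitions, and L = 1,000 for
the profiler recovery check — large enough that binomial/Monte-Carlo error
bands are tight (accuracy sd < 0.01 at N = 702 per class), small enough
that the whole pipeline runs in seconds.  Every stochastic step takes an
explicit integer seed; identical seeds give byte-identical outputs.

## Known limitations

* ΔΔG/RSA are consumed as point predictions; predictor uncertainty is not
  propagated.
* The logistic model is intentionally minimal (two features, no
  interaction, no calibration step); it is a baseline, not a competitor to
  evolutionary-information-based pathogenicity predictors.
* Binary labels only; uncertain/conflicting clinical significance is
  handled by exclusion, not modelling.
* The gene-balance filter assumes gene identifiers are consistent across
  records; no isoform logic is included.
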