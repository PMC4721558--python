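# Methods

## Study model

The package models a test–retest reliability design for archival breast-tumor
immunostains. A case is a tumor specimen with a diagnosis year in one of six
strata (1947–1959, then calendar decades through 2000–2009). Each case is
represented on two independently reviewed tissue microarrays (TMA1, TMA2),
each holding three 0.6-mm cores of the specimen per stain. The reviewed stains
are a broad-spectrum cytokeratin (CK) cocktail used as an antigen-preservation
control, ER, PR, HER2, CK 5/6, EGFR, and Ki67.

## Aggregation: cores → TMA call

* Binary stains: positive if ≥1 core positive; negative if ≥1 core bears
  tissue and none is positive; missing if no core bears tissue.
* HER2: maximum ordinal score (negative < 1+ < 2+ < 3+) over tissue-bearing
  cores. The any-positive rule for binary stains generalizes to an ordinal
  stain as a maximum, and the reference table prints a single score per TMA;
  how discordant cores were actually summarized there is not stated, so the
  maximum is this package's convention.
* Ki67: arithmetic mean of percent-positive over tissue-bearing cores only —
  a panel that lost two cores is the mean of the survivor, not a division
  by three.
* Antigen integrity is a case-level verdict: not preserved only when at least
  one CK-cocktail call is evaluable and every evaluable call across both TMAs
  is negative. A single positive call on either TMA certifies the case.

All aggregation is permutation-invariant in core order and monotone (an added
positive core can never demote a call); both properties are tested.

## Phenotype classification

The classifier implements the standard IHC surrogate-subtype algorithm with
two explicit conventions:

* **HER2 positivity = {3+} only** (default). 2+ without reflex in-situ
  hybridization counts negative; the reference calls require this (2+ cases
  are printed basal-like, which demands HER2−). The positive-level set is
  configurable but must be upward-closed on the ordinal scale.
* **Ki67 cutoff 14%, boundary high.** A panel at exactly 14.0% is Ki67-high;
  the reference Ki67 discordance count fixes the boundary side.

Missing markers are resolved by *completion enumeration*, not imputation:
classify the panel under every completion of the missing values; if all
completions agree the call is definite. A panel with both hormone receptors
missing is always Unknown. When completions disagree, the call is an
explicit **ambiguous candidate set** (e.g. {Luminal A, Luminal B} for
ER+/PR+ with HER2 missing and Ki67 low) — *unless* the observed
hormone-receptor pair is itself equivocal (ER and PR both definite but
discordant), in which case the phenotype is reported as **Unknown**. The
rationale: a discordant ER/PR pair is a borderline hormone-receptor result,
and with a classification-critical marker missing as well, a candidate set
would overstate what the panel supports. This distinction is exactly the
behavior the reference calls exhibit on the two panels with a missing HER2
cell, and it is required to reproduce the printed per-panel labels and the
phenotype concordance; a uniform ambiguous-set rule would merge the two
and yield 87% instead of 90%.

Fully-missing panels (no evaluable marker at all) receive no phenotype entry;
grade and histology are never classifier inputs.

## Agreement statistics

* **Percent concordance** uses all cases as denominator; a pair is discordant
  only when both calls are definite and differ. HER2 is compared on reported
  stain categories (2+ vs negative differs); Ki67 on the high/low dichotomy;
  phenotype with Unknown as missing and an ambiguous set as a definite
  category of its own, differing from any non-identical call. Display
  rounding is half-up to integer percent; the raw proportion is retained.
  This is the unique simple convention that reproduces every printed
  concordance in the reference table.
* **Cohen's kappa** is computed on complete pairs only (both sides definite):
  κ = (p_o − p_e)/(1 − p_e), with p_e from the product of the two margins.
  When all mass sits in one cell, p_e = 1 and κ is undefined and flagged —
  never coerced to a number. HER2 kappa uses the {2+, 3+} = positive
  dichotomy, which is the coding that reproduces the published 0.908; the
  phenotype-classification coding ({3+}) and the reliability coding are both
  explicit and documented wherever used.
* **Standard error**: the large-sample form of Fleiss, Cohen & Everitt (1969),
  cross-checked in the tests against an independent implementation
  (statsmodels) to 1e-10.
* **Confidence intervals**: default asymptotic κ ± z·SE clipped to [−1, 1] —
  this reproduces every kappa CI the reference table prints, including the
  asymmetric-looking ones, which are simply clipped at 1. A case-resampled
  percentile bootstrap (seeded, ≥100 replicates; undefined-κ resamples
  dropped) is available for small-sample checks; its coverage is verified
  ≈ nominal on simulated pair sets.

### Known non-reproducible published values

Two printed kappas do not follow from the printed panel data under any
pairing convention enumerated here: PR (printed 0.926; the printed PR columns
give 0.858 on 29 complete pairs) and phenotype (printed 0.724; the documented
policy gives 0.830 on 28 pairs). The package prints its recomputed values
with the convention attached and does not force agreement. Likewise the
published narrative count of concordant basal-like classifications (3)
exceeds what the printed table supports (2); the table is taken as
authoritative.

## Synthetic study generator

The generator emulates the full data-producing process so that every pipeline
stage is testable end-to-end, and so the kappa–prevalence phenomenon can be
demonstrated rather than asserted.

* **Sampling and retrieval.** 10 cases per stratum are sampled (default);
  pathology reports are located with probability 55/60 and blocks, given a
  report, with probability 50/55 — the realized rates of the reference study —
  then 5 cases per stratum are subsampled without replacement among retrieved
  cases. A stratum that cannot fill its quota raises an explicit shortfall
  flag, never a silent under-fill.
* **Latent states.** Each case has one latent state driving both TMAs:
  Bernoulli positivity per binary marker (defaults set to the positivity the
  reference study reports: ER 0.80, PR 0.60, HER2 0.30, CK 5/6 0.13, EGFR
  0.07, CK-cocktail preservation 28/30), a latent HER2-amplified indicator,
  and a log-normal Ki67 mean (median 5%, log-sd 0.80, truncated to [0, 100]),
  calibrated so ~10% of cases are at or above the 14% cutoff, matching the
  reported 86–90% low-Ki67 fraction.
* **Core noise.** Per core: tissue dropout (default 0.05); binary stains via
  sensitivity 0.95 / specificity 0.97 given the latent state; HER2 drawn from
  per-level confusion distributions given the latent indicator; Ki67 as the
  latent mean times log-normal dispersion (log-sd 0.25), truncated. The noise
  mechanism is invented — the reference study describes none — and the
  defaults are chosen as plausible for well-controlled clinical IHC; the
  generator recovers them empirically at large n (tested at tolerance 0.02).
* **Seeding.** One root seed expands via `numpy.random.SeedSequence` into
  per-stage child generators (truth, retrieval, cores), so every stage and
  every sweep cell is individually reproducible.

What the generator does *not* model: fixation-age-dependent antigen decay
(the reference finding is precisely that decade did not matter), intratumor
spatial correlation between cores beyond the shared latent state, the
node-positive restriction of the sampling frame (prevalences are free
parameters instead), and reviewer-level error. Passing tests on synthetic
data therefore show pipeline correctness under this noise model, not
biological realism of any particular marker's heterogeneity.

### Kappa–prevalence sweep

`kappa_prevalence_sweep` varies one binary stain's latent prevalence with all
noise parameters held fixed, simulating full studies per prevalence and
averaging concordance and kappa over replicates (kappa-undefined replicates
are excluded and counted). With the default noise, prevalence 0.05 vs 0.5
shows kappa falling sharply while concordance moves by a few points — the
mechanism behind the reference study's high-concordance/low-kappa Ki67 row.

## Problem sizes and numerics

The fixture computations are instantaneous (30 cases). Test-suite simulation
sizes — 120 cases/stratum for parameter recovery, 25/stratum × 15 replicates
for the sweep — keep the whole suite under a minute while holding Monte-Carlo
error well inside the asserted tolerances. Tolerances: published kappas are
asserted to 3 decimals (5e-4); oracle equivalence to 1e-12; SE vs the
independent implementation to 1e-10. Ties: the Ki67 boundary is high by
definition; bootstrap quantiles use numpy's default (linear) interpolation;
CI bounds are clipped, never re-normalized.
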