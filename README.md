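# tmaagree

Test–retest reliability of immunohistochemistry (IHC) biomarker panels scored on
duplicate tissue microarrays (TMAs), with surrogate molecular-phenotype
classification for breast cancer.

## The problem

Archival formalin-fixed paraffin-embedded (FFPE) tumor blocks are the only route
to long-term trends in tumor biology, but before trusting stains on decades-old
tissue one must ask: if the same specimen is arrayed and stained twice,
independently, how often do the calls agree? This package implements the full
computational chain of such a feasibility design:

1. **Core aggregation** — each specimen contributes 3 × 0.6-mm cores per TMA.
   A binary stain (CK cocktail, ER, PR, CK 5/6, EGFR) is positive at the TMA
   level if ≥1 core is positive; HER2 takes the maximum ordinal score
   (0/1+/2+/3+) over tissue-bearing cores; Ki67 averages percent-positive cells
   over tissue-bearing cores; no evaluable core ⇒ missing.
2. **Antigen integrity** — a case whose every evaluable CK-cocktail call is
   negative is flagged as antigen-degraded.
3. **Surrogate phenotype** — the standard IHC subtype algorithm:
   Luminal A (ER+ and/or PR+, HER2−, Ki67 < 14%), Luminal B (ER+ and/or PR+
   with HER2+, or HER2− with Ki67 ≥ 14%), HER2-enriched (ER−, PR−, HER2+),
   basal-like (ER−, PR−, HER2−, CK 5/6+ and/or EGFR+), else unclassifiable.
   HER2+ for classification means 3+ only. Missing markers are resolved by
   enumerating every completion of the missing values.
4. **Agreement** — per-case (TMA1, TMA2) pairs give percent concordance
   (denominator = all cases; discordance requires two definite, differing
   calls) and unweighted Cohen's kappa on complete pairs,
   κ = (p_o − p_e)/(1 − p_e), with the large-sample (Fleiss–Cohen–Everitt)
   standard error; confidence intervals are asymptotic (clipped to [−1, 1])
   or case-resampled bootstrap.
5. **Synthetic studies** — a seeded generator emulating the whole design
   (stratified sampling per decade, two-stage report/block retrieval, latent
   marker states shared by both TMAs, per-core sensitivity/specificity,
   ordinal HER2 confusion, Ki67 dispersion, tissue dropout), used for
   end-to-end property tests and for demonstrating the kappa–prevalence
   paradox: a rare category keeps raw concordance high while κ collapses,
   because chance agreement p_e is already near 1.

The package ships a fixture (`table1`) transcribing a published 30-case
reference study (5 cases per decade, 1947–2009, duplicate TMAs) whose printed
statistics everything reproduces.

## Worked example

```python
from tmaagree import load_table1, build_pairs, percent_concordance, kappa_ci

ds = load_table1()
ps = build_pairs(ds, "ki67")           # dichotomized at 14%, boundary high
print(percent_concordance(ps).percent) # -> 90
r = kappa_ci(ps)                       # asymptotic 95% CI
print(round(r.kappa, 3), round(r.ci_low, 3), round(r.ci_high, 3))
# -> 0.346 -0.225 0.916
```

Ki67 is the textbook kappa–prevalence case in this dataset: 26 of 29 complete
pairs agree (90% concordance), but only 3–4 cases per TMA are Ki67-high, so
chance agreement is 0.84 and κ is merely fair at 0.346 — the interval straddles
zero. From the shell, the whole report:

```sh
tmaagree reproduce            # recompute and check every published statistic
tmaagree agree table1 --csv   # concordance/kappa/CI table as CSV
tmaagree classify table1      # per-panel phenotype calls with match flags
tmaagree simulate --seed 1 --out scratch/sim   # synthetic study
tmaagree sweep --n-reps 20 --seed 1            # kappa vs prevalence
```

`tmaagree reproduce` prints, per target, the recomputed concordance and kappa
next to the published value, e.g. `her2: concordance 97% (published 97%) [ok];
kappa 0.908 (published 0.908) [ok]`, and exits non-zero on any mismatch.

Two published values are knowingly not recomputable from the printed panel
data under any documented pairing convention (PR kappa 0.926, recomputed
0.858; phenotype kappa 0.724, recomputed 0.830); the report prints the
recomputed values with their conventions. See `docs/methods.md`.

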