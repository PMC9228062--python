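# Methods

## Model

Each endpoint model is an aggregated inductive conformal classifier (ICP)
over random forests. The training data is first split, stratified by
class, into a working training set (80%) and a validation set (20%). Each
of the `n_models = 50` members draws its own stratified 70/30 split of the
working set into a proper training part and a calibration part, fits a
300-tree random forest on the former (all other forest hyperparameters at
scikit-learn defaults), and records the nonconformity score of every
calibration compound under its *true* class,

    alpha_c(x) = 1 - P_hat(c | x),

in that class's calibration list. This class-conditional (Mondrian)
calibration is essential here: it gives a separate coverage guarantee per
class, so a 3%-active endpoint cannot satisfy its error budget purely on
the majority class. The p-value of a test compound for class `c` is the
(+1-corrected) fraction of class-`c` calibration scores at least as large
as the compound's own score; ties count as "at least" and p-values are
non-smoothed, so all outputs are deterministic. Member p-values are
combined by the median (mean of the central pair for an even member
count), and at significance level `sl` the prediction set is
`{c : p_c > sl}` — strict inequality, so a compound can receive the
`empty` region when both p-values are small, which operates as an
applicability-domain flag. The decidability score `p_active - p_inactive`
ranks compounds by how confidently they separate the classes.

Assumptions: exchangeability of calibration and test compounds within a
class. A single Mondrian ICP then guarantees a per-class error rate of at
most `sl`; the median aggregation does not inherit the exact finite-sample
guarantee but is empirically conservative, which is why validity is also
verified empirically (see below) rather than taken on faith.

## Parameters that matter

| parameter | default | why |
|---|---|---|
| `n_models` | 50 | variance reduction of p-values; beyond ~50 the median stabilizes |
| `n_estimators` | 300 | forest size; probabilities stable enough for ranking nonconformity |
| validation fraction | 0.20 | held out once, never resampled per member |
| calibration fraction | 0.30 | of the working set, per member |
| `significance_level` | 0.1 | screening default: favors high active-region hit rate (TDR.A) and low FPR over raw efficiency |
| validity tolerance | 0.01 | a shortfall of validity below `1 - sl` strictly smaller than 0.01 is treated as negligible |
| prioritization threshold | 9 | minimum thyroid-specific active calls for the compounds-of-concern list |
| member seed ladder | `base_seed + i` | reproducibility with member independence; recorded in every bundle |

All randomness descends from one base seed; two runs with the same
configuration produce byte-identical curated tables, bundle metadata and
predictions.

## Curation and featurization choices

Standardization: parse, remove explicit hydrogens, strip salt/solvent
fragments from a fixed versioned list, reject records with no organic
fragment (`inorganic`) or more than one (`mixture` — the larger fragment
is deliberately *not* kept), neutralize charges, canonicalize the
tautomer with RDKit's canonical tautomer enumerator, and key the result
by InChIKey. If stripping would delete every fragment, the largest
stripped organic fragment is restored so that simple salts of small
organic acids (sodium acetate) standardize to their parent acid rather
than vanishing. "Inorganic" means: no carbon, or carbon only in
conventionally inorganic species (carbonate, cyanide, carbon oxides).
Stereoisomers that standardize to the same key are treated as duplicates;
duplicate handling is by label concordance (merge if concordant, omit all
if conflicting). Agreement with any proprietary standardizer is
functional, not bit-for-bit; tautomer conventions in particular differ
between toolkits.

Descriptors: a pinned manifest (`rdkit2d-119-v1`) of 119 RDKit 2-D
physicochemical descriptors. The identity of "the" RDKit descriptor set
drifts across releases, so the list is frozen in code, its tag is stored
in every model bundle, and a bundle refuses matrices computed under a
different manifest. Recently added composite scores (drug-likeness,
fingerprint densities) are excluded. Sanitization: columns non-finite for
more than 5% of training compounds are dropped at fit time; remaining
non-finite entries are imputed with training-set medians, which are
stored and re-applied at prediction time. No scaling — forests are
scale-invariant. The descriptorizer is fitted on the working training
partition only, so validation and screening compounds are featurized
exactly like future unknowns.

## Synthetic data: what it emulates and what it does not

`gen_gaussian` draws two identity-covariance Gaussians whose means are a
chosen distance apart (default 2.0 common standard deviations,
dimension 10) with an exactly stratified class split. It is exchangeable
by construction and isolates the conformal mathematics: validity,
nestedness and p-value calibration results on it say nothing about
chemistry. Active fractions used in tests span the imbalance regimes of
real thyroid bioactivity panels — 0.7% (receptor-antagonist-like), 3%
(high-throughput-screen-like), 30% (enzyme-inhibition-literature-like),
40% (small-binding-panel-like).

`gen_molecules` enumerates substituted benzenes (1-3 substituents from a
fixed menu) and labels them with a deterministic structural rule —
default: active iff both a halogen and a hydroxyl group are present,
echoing the halogenated/hydroxylated chemotypes associated with
thyroid-axis binding — plus an independent label-flip noise (default
0.05 in pipeline tests). Structures are unique and standardize cleanly,
so clean generations round-trip curation with zero removals. What it does
*not* emulate: the chemical diversity, assay noise structure, activity
cliffs or scaffold clustering of real screening data. A passing pipeline
test demonstrates that the machinery recovers a recoverable signal under
controlled imbalance and noise; it does not certify predictive accuracy
on any real endpoint, which depends entirely on the training data
supplied.

## Numerical and design choices

- Nonconformity from predicted class probability (`1 - P_hat`) — the
  standard choice for probabilistic underlying learners.
- Non-smoothed p-values with ties counted as `>=`: conservative and
  deterministic; smoothed (tie-randomized) p-values would trade exactness
  of determinism for exact uniformity.
- One fixed validation partition for all members (members resample only
  the proper-training/calibration split).
- Validity acceptance uses a strict shortfall rule (`(1 - sl) - validity
  < 0.01`), compared after rounding to 9 decimals so the boundary is
  exact at printed precision; a shortfall of exactly 0.01 fails.
- TPR/FPR numerators count single-label predictions only; denominators
  are full true-class sizes, so compounds in `both`/`empty` depress TPR
  rather than being excluded from it. Zero-denominator rates propagate as
  NA, never 0.
- Members whose calibration part loses a class are refused; if more than
  10% of members are refused the fit aborts rather than silently training
  a thinner ensemble.
- `empty` predictions count in validity denominators and are always
  errors; they are not single-label predictions for efficiency.
- Screening "known" status is keyed on standardized structure identity
  (not identifiers), covers both training and validation membership, and
  overrides model predictions. Prioritization ranks by active-call count,
  then summed decidability, then compound id for stable ties.
- Test and acceptance problem sizes (n = 3000 Gaussian fixtures, n = 800
  molecule pipeline, 50-member aggregates with 300 trees) were chosen as
  the smallest sizes at which the binomial margins on per-class error
  rates are informative for the imbalance regimes studied.

## Known limitations

- The coverage guarantee is exact for a single ICP member; the median
  aggregate is validated empirically, not proven.
- The descriptor manifest approximates a version-dependent descriptor
  set; models are only comparable under the same manifest tag.
- Tautomer and charge normalization follow RDKit conventions and will
  not match every vendor standardizer.
- The synthetic molecule space (substituted benzenes) is tiny compared to
  real inventories; generator saturation reduces the achievable active
  fraction for large n.
- No regression conformal prediction, cross-conformal/jackknife variants,
  or probability calibration of the underlying forest.
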