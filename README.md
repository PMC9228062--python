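# thyscreen

Conformal-prediction QSAR models for flagging potential thyroid hormone
system disruptors in chemical inventories.

Bioactivity screening data for thyroid-related molecular initiating events
(MIEs) — thyroperoxidase inhibition, transthyretin binding, sodium/iodide
symporter inhibition, deiodinase inhibition, receptor ag/antagonism — are
scarce and heavily imbalanced: many endpoints have well under 5% active
compounds. Plain classifiers give point predictions with no error control,
which is a poor basis for deciding which of thousands of inventory
chemicals to send for in vitro confirmation. `thyscreen` wraps random
forests in the **inductive conformal prediction** (ICP) framework so that
the user chooses the acceptable error rate up front, and builds a battery
of per-endpoint models whose active calls are counted to prioritize
compounds of concern. It is intended for computational toxicologists and
cheminformaticians doing first-tier hazard screening.

## The method

For one endpoint with binary labels (active/inactive):

1. A stratified 20% **validation** partition is set aside.
2. 50 ICP members are built, each on its own stratified split of the
   working training set into 70% proper training (a 300-tree random
   forest) and 30% **calibration**.
3. The nonconformity score of a compound *x* for class *c* is
   α<sub>c</sub>(x) = 1 − P̂(c | x). Calibration scores are kept **per
   class** (Mondrian / class-conditional calibration), and the p-value of
   a new compound for class *c* is

   p<sub>c</sub>(x) = (#{α<sup>cal</sup><sub>c</sub> ≥ α<sub>c</sub>(x)} + 1) / (n<sup>cal</sup><sub>c</sub> + 1)

4. Member p-values are aggregated by the **median**; at significance level
   *sl* the prediction set is {c : p<sub>c</sub> > sl}, reported as one of
   four regions: **active**, **inactive**, **both** (uncertain) or
   **empty** (outside the applicability domain). Under exchangeability the
   per-class error rate — true label missing from the prediction set — is
   controlled at *sl*, separately for each class, which is what makes the
   approach workable on heavily imbalanced data.

Models are evaluated across a significance-level sweep with per-class
validity and efficiency plus classical rates (TPR = TP/nA, FPR = FP/nIA,
NPV = TN/nIAp, TDR.A = TP/nAp, TDR.B = TP.B/nBp, where nAp/nIAp/nBp/nEp
count compounds predicted in each region). Screening an inventory counts,
per compound, how many thyroid-specific models call it active (known
experimental labels override predictions); compounds active in many
models are ranked up for follow-up testing.

Structures are standardized before modeling (hydrogen normalization,
salt/solvent stripping, aromatization, charge neutralization, tautomer
canonicalization), mixtures and inorganics are rejected, duplicates are
merged or dropped by label concordance, and molecules are featurized with
a pinned manifest of 119 RDKit 2-D physicochemical descriptors.

## Worked example

Train an aggregated conformal model on a synthetic two-Gaussian dataset
(30% actives, class means two standard deviations apart) and sweep three
significance levels:

```python
from thyscreen import GaussianSpec, SplitPlan, fit_aggregated, gen_gaussian
from thyscreen.evaluation import report_to_markdown, sweep

X, y = gen_gaussian(GaussianSpec(n=600, active_fraction=0.3,
                                 class_separation=2.0, seed=11))
model, X_val, y_val = fit_aggregated(X, y, SplitPlan(base_seed=5),
                                     n_models=10, n_estimators=100)
report = sweep(model, X_val, y_val, [0.01, 0.1, 0.25])
print(report_to_markdown(report))
```

which prints:

| sl | validity_active | validity_inactive | efficiency_active | efficiency_inactive | nAp | TDR.A | nIAp | NPV | nBp | TDR.B | nEp | TPR | FPR |
|---|---|---|---|---|---|---|---|---|---|---|---|---|---|
| 0.01 | 1.00 | 1.00 | 0.22 | 0.00 | 8 | 1.00 | 0 | NA | 112 | 0.25 | 0 | 0.22 | 0.00 |
| 0.1 | 0.89 | 0.96 | 0.72 | 0.56 | 25 | 0.88 | 48 | 0.92 | 47 | 0.21 | 0 | 0.61 | 0.04 |
| 0.25 | 0.78 | 0.83 | 0.97 | 0.98 | 40 | 0.70 | 77 | 0.91 | 0 | NA | 3 | 0.78 | 0.14 |

Read it like this: at the strictest level (sl = 0.01) almost everything
lands in the uncertain *both* region (nBp = 112) — validity is perfect but
efficiency is useless. At sl = 0.1 both classes are still valid within the
0.01 tolerance (0.89 ≥ 0.90 − 0.01, 0.96 ≥ 0.89), 25 compounds are
predicted active and 88% of them are truly active (TDR.A). At sl = 0.25
nearly every prediction is a single label, but the active-region hit rate
has dropped to 0.70 and the false positive rate has risen — the standard
conformal trade-off. `NA` marks rates whose region is empty
(zero denominator).

The same workflow is available from the shell:

```bash
thyscreen simulate --kind molecules -o sim --n 300 --label-noise 0.05 --seed 7
thyscreen curate sim/simulated_molecules.csv -o curated
thyscreen train curated/curated.csv -o bundle --name TPO --seed 7
thyscreen evaluate bundle -o report
thyscreen screen inventory.csv --bundle bundle -o screened --sl 0.1
```

Every command writes a `run_config.json`; re-running with the same config
reproduces the outputs bit for bit.

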