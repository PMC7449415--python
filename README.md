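# lithicnet

Neural-network ensemble classification of eastern African Stone Age lithic
assemblages, with input-inversion extraction of significant typological
indicators.

## The problem

The transition from the Middle Stone Age (MSA) to the Later Stone Age (LSA)
in eastern Africa is protracted, asynchronous, and not marked by any single
diagnostic artefact type. A productive way to put the question on a
quantitative footing is to describe each assemblage by the presence or
absence of 16 broad technology categories (backed pieces, bipolar
reduction, blade technology, Levallois methods, points, scrapers, …) with a
class label — LSA, MIS3&4 MSA, or MIS5 MSA — and ask (a) whether the
classes are separable at all, and (b) which technologies carry the
separation. `lithicnet` is a tested, reusable implementation of that
pipeline for archaeologists and quantitative-methods researchers.

## The method

- **Classifier.** A 16→10→K multilayer perceptron: ±1-rescaled inputs, tanh
  hidden layer, softmax head (K = 3) or a single sigmoid read as P(LSA)
  (K = 1). Trained by Levenberg–Marquardt on the sum of squared errors
  between output probabilities and one-hot targets, with Bayesian
  regularization: F = β·E_D + α·E_W, where α, β are re-estimated each epoch
  from the evidence framework via the effective parameter count
  γ = Σ λᵢ/(λᵢ+α). The built-in shrinkage replaces a held-out validation
  set — essential with only 92 observations.
- **Ensemble.** Many networks (1,000 at reference scale), each with its own
  stratified 85/15 partition (exactly 26/26/25 + 5/5/5 three-way,
  26/52 + 5/9 two-way) and random initialization. Each network is scored on
  all assemblages and its overall accuracy becomes its weight; the
  performance-weighted mean probability vector classifies each assemblage.
- **Indicators.** For one technology at a time, its column is inverted
  (presence ↔ absence) and the table re-scored: the delta is the change in
  class probability. Per network, the median delta over the applicable
  assemblages (removal where originally present, addition where absent) is
  one bootstrap replicate; the 2.5/50/97.5 percentiles over networks give
  the effect and its 95% CI. A technology is a significant indicator of a
  class only if addition raises and removal lowers that class's
  probability, neither CI covers zero, and both conditions have n ≥ 10.

The empirical presence/absence table is supplementary data of the original
study and is not redistributed; the package ships a clearly-labelled
synthetic surrogate (`synthetic_reference_matrix()`) that reproduces every
published marginal count exactly (class sizes, per-class prevalences,
presence totals) with invented within-class joint structure — see
`docs/methods.md` for exactly what that does and does not support. The
canonical CSV of the real table can be dropped in without code changes.

## Worked example

```python
import lithicnet as ln
from lithicnet.indicators import (compute_delta_records,
                                  extract_indicator_calls, indicator_summary)

matrix = ln.synthetic_reference_matrix()          # 92 x 16 surrogate table
scheme = ln.scheme_from_name("3way")
ens = ln.train_ensemble(matrix, scheme, 100, seed=42)
print(ln.confusion_metrics(ens.predicted, ens.truth, scheme).to_frame())

records = compute_delta_records(ens, matrix)
calls = extract_indicator_calls(records, matrix, scheme)
print(indicator_summary(calls, scheme))
```

Output (100 networks, seed 42):

```
                     LSA MIS3&4 MSA MIS5 MSA Specificity (TN%)
Output Class
LSA                   31          0        0             100.0
MIS3&4 MSA             0         31        0             100.0
MIS5 MSA               0          0       30             100.0
Sensitivity (TP%)  100.0      100.0    100.0

                         LSA MIS3&4 MSA MIS5 MSA
Lithic component
Backed Pieces                             CONTRA
Bipolar Tech             IND              CONTRA
Core Tool             CONTRA                 IND
Levallois Flake Tech  CONTRA                    
Point Tech            CONTRA        IND
```

Reading it: the ensemble separates the three classes of the surrogate table
perfectly (the real table, which contains identical assemblages in
different classes, caps near 94.6%), and the inversion analysis flags five
technologies. Core tools indicate MIS5 MSA and contra-indicate LSA; point
technology indicates MIS3&4 MSA; bipolar reduction indicates LSA — the
direction of every call matches the published prevalence gradients (e.g.
core tools decline from 57% of MIS5 MSA assemblages to 3% of LSA ones). A
single delta record shows the underlying numbers: adding a core tool to the
69 assemblages lacking one raises their MIS5 MSA probability by a median of
0.042 in this run, with a 95% CI of [0.000, 0.901] across networks.

The same pipeline runs from the shell:

```sh
lithicnet simulate --profile synthetic-table --out table.csv
lithicnet ensemble --scheme 3way --n-networks 1000 --seed 1 \
    --data table.csv --out run3/
lithicnet recover --profile reference --n-networks 100 --n-replicates 10
```

`run3/` then contains the confusion table, per-assemblage weighted
probabilities, per-class indicator tables (lower/median/upper/n per
condition), the indicator summary, overlap statistics and a JSON manifest
that reproduces the run bit-for-bit.

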