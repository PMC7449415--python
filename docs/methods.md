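# Methods

## The problem

Eastern African lithic assemblages spanning Marine Isotope Stages 5–2 are
conventionally assigned to the Middle Stone Age (MSA) or the Later Stone Age
(LSA), but no single artefact form separates the two complexes. `lithicnet`
treats the question as a supervised classification problem on binary data:
each assemblage is a 16-dimensional presence/absence vector over broad
technology categories (Backed Pieces, Bipolar, Blade, … Scraper), labelled
LSA, MIS3&4 MSA or MIS5 MSA (or, collapsed, LSA vs MSA). An ensemble of
small neural networks learns the mapping, and a perturbation procedure then
asks, technology by technology, how flipping one presence bit moves the
class probabilities — turning the fitted black box into a table of
indicator and contra-indicator technologies with confidence intervals.

## Classifier

One network is a three-layer perceptron: 16 inputs (presence/absence
rescaled to ±1 so presence and absence pull symmetrically on the tanh
units), a hidden layer of 10 tanh nodes, and an output head of 3 softmax
nodes (three-way; outputs sum to one and read as class probabilities) or a
single sigmoid node (two-way; the output reads as P(LSA)). Exact `tanh` is
used throughout. Weights flatten in a fixed order (W1 row-major, b1, W2
row-major, b2; 203 parameters for 16→10→3) so Jacobians, penalties and
serialized networks are reproducible. Initialization is Nguyen–Widrow-style:
hidden rows renormalized to magnitude 0.7·H^(1/I) with biases spread across
the same range, output weights uniform(−0.5, 0.5); this places the tanh
active regions across the input cube and conditions the optimizer well.
Argmax ties break to the lowest class index in declared order.

## Training: Levenberg–Marquardt with Bayesian regularization

The loss is the sum of squared errors between output probabilities and
one-hot targets (not cross-entropy: squared error on the probabilities is
the quantity the ensemble statistics are built on), plus a quadratic weight
penalty:

    F = β·E_D + α·E_W,   E_D = Σ r²,   E_W = Σ θ²  (biases included by default).

Steps solve the damped, regularized normal equations
(β·JᵀJ + α·I + μ·I)δ = −(β·Jᵀr + α·θ), accepted only if F strictly
decreases; μ shrinks by 0.1 on acceptance and grows by 10 on rejection
(start 5·10⁻³, ceiling 10¹⁰). The Jacobian is analytic (chain rule through
the softmax/sigmoid head), verified against central finite differences.

After each accepted step the evidence framework re-estimates the
regularization: the effective number of parameters is

    γ = Σᵢ λᵢ/(λᵢ + α)   over the eigenvalues λᵢ of β·JᵀJ,

and the point targets are α* = γ/(2·E_W), β* = (N_resid − γ)/(2·E_D). The
eigenvalue form is used deliberately: when the network holds more
parameters than training residuals (always true for the two-way head: 203
parameters, 78 residuals), γ tends to rank(J) rather than the parameter
count as α → 0, which keeps β* non-negative. Even so, the two point
estimates have no stable joint fixed point away from degeneracy in that
regime, and replacing (α, β) outright makes them oscillate between
all-penalty and all-data settings (the network collapses onto the exact
zero-weight stationary point). The loop therefore relaxes the
hyperparameters halfway toward their targets each epoch
(`evidence_damping = 0.5`); this settles an interior balance (typical
converged γ ≈ 70 of 203 three-way, ≈ 45 two-way) and is the one numerical
choice that materially matters. Stopping: gradient below 10⁻⁷, relative
objective decrease below 10⁻⁵, damping ceiling, or 1000 epochs (typical
convergence: 60–160 epochs). Because the penalty strength is estimated from
the data, no validation set is held out.

The zero-weight configuration is an exact stationary point of F, and on
very small problems individual runs can still land on it; this is the
ordinary local-minimum failure of network training, and it is precisely
what ensembling over random restarts averages away.

## Ensemble

Each of N networks (1,000 in the reference analyses; reduced modes of
100–200 behave equivalently for every statistic reported here) draws its
own stratified partition — per-class test quota = 15% rounded half-up,
giving exactly 26/26/25 train + 5/5/5 test (three-way) and 26/52 + 5/9
(two-way) on class sizes 31/31/30 — and its own initial weights, from child
streams of one master seed (`SeedSequence(master).spawn(N)`, child *i* →
network *i*, so any single network is re-runnable). Every trained network
is evaluated on all assemblages; its overall proportion correct is its
ensemble weight. Weighted-mean class probabilities (weights normalized to
sum to one, which leaves the argmax unchanged) give the ensemble
classification, summarized in a confusion table with sensitivity (TP%,
column-wise) and a row-wise diagonal share that classical reports label
"specificity (TN%)" but is in fact a predictive value; the API names it
`row_predictive_value` and report output keeps the conventional label.

## Indicator extraction by input inversion

For each technology, its column is inverted (0 ↔ 1) across all assemblages
and the table re-scored by every network; the delta is
P_inverted − P_original per assemblage per class. Assemblages originally
carrying the technology form the *removal* condition ("False Absence"),
the rest the *addition* condition ("False Presence"); the two condition
sizes always partition the table, and removal-n equals the technology's
presence count. Each network contributes one summary per
technology × class × condition — the median delta over applicable
assemblages — and the per-network medians are treated as a bootstrap
sampling distribution of the median: its median is the reported effect and
its 2.5th/97.5th percentiles (linear interpolation between order
statistics) the 95% CI. Alternative aggregations (pooled
assemblage × network deltas; accuracy-weighted medians) are available
behind flags for sensitivity analysis; defaults are per-network medians,
unweighted.

A technology is called IND for a class only if the addition median is
positive, the removal median negative, neither CI covers zero, and both
conditions hold at least 10 applicable assemblages; CONTRA is the mirrored
sign pattern; anything else is NS, with the failing rule components
recorded. Significance is assessed separately per technology per class; no
multiple-testing correction is applied beyond this dual-inversion rule. In
the two-way scheme the two class probabilities are complementary, so a
CONTRA for LSA is reported as an MSA indicator.

## Synthetic data and the reconstructed reference table

The generator draws each cell as an independent Bernoulli with a
class-conditional probability. `reference_profile()` encodes the study
conditions: class sizes 31/31/30 and the published per-class prevalences
for the seven individually discussed technologies (e.g. Backed Pieces
0.77/0.71/0.23, Core Tool 0.03/0.16/0.57); the other nine technologies sit
at a neutral 0.5 in every class — declared filler, not empirical values. A
correlated mode adds a latent per-assemblage "richness" factor on the logit
scale (assemblages genuinely differ in technological diversity), inducing
positive within-row correlation while roughly preserving marginals.

The empirical table itself is supplementary data not redistributed here, so
`synthetic_reference_matrix()` builds a fixed synthetic surrogate from the
published summary counts: exact per-class presence counts (the published
percentages round to counts whose sums reproduce the published presence
totals for all six cross-checkable technologies), membership assigned
independently at random within class under one fixed internal seed. Every
marginal statistic of the surrogate is exact by construction; its
within-class joint structure is invented. Consequences worth stating
plainly: the surrogate contains none of the real table's cross-class
duplicate rows, so ensembles classify it essentially perfectly rather than
at the published ~94.6%; and co-occurrence statistics (the
indicators-of-multiple-classes percentages) come out higher than published,
because the real assemblages anti-correlate LSA-block and MSA-block
technologies in a way marginal counts cannot pin down. Passing pipeline
tests on the surrogate therefore demonstrates correct mechanics and
marginal fidelity, not joint-structure replication.

One published inconsistency is preserved, not resolved: the indicator
tables give Bipolar Tech presence n = 62 while the per-class prevalences
imply 57; the surrogate follows the per-class figures and
`bipolar_presence_discrepancy()` reports both.

## Parameter recovery: what it shows

Under the reference profile, technologies with an unambiguous class
association are recovered reliably (Core Tool and Point Tech flagged for
their classes in ≳85% of replicates at 100 networks). Technologies whose
prevalence differs only mildly between the top two classes (Backed 77 vs
71%, Blade 94 vs 84%) are flagged against MIS5 consistently but their IND
attribution splits between LSA and MIS3&4 across replicates — under
independent cells that attribution is intrinsically ambiguous, and the
published clean attribution to LSA evidently rests on correlations the
marginals do not determine. Neutral fillers are occasionally flagged
(~10–15% of technology-class cells): Bernoulli sampling at n ≈ 31 per class
produces real in-sample prevalence contrasts, which every network in the
ensemble sees identically; the network-bootstrap CI quantifies training
stochasticity, not sampling noise of the table itself. Under an
exchangeable profile the cell-level NS rate is ≈ 91%.

## Problem sizes used in the shipped tests and acceptance script

Reduced modes keep the full pipeline intact and shrink only the ensemble
and replicate counts, chosen as the smallest sizes at which the reported
statistics are stable: 200-network ensembles for replication runs and the
acceptance script, 100 networks × 6–8 replicates for recovery experiments,
16 networks for shared test fixtures. The reference 1,000-network analysis
is available unchanged via the CLI (`lithicnet ensemble --n-networks 1000`).

## Known limitations

- The evidence-framework update has no stable fixed point when parameters
  outnumber residuals; damping is a pragmatic (and documented) remedy, not
  a derived one.
- Indicator CIs do not propagate table-level sampling uncertainty (by
  design: they mirror the network-bootstrap construction).
- The surrogate reference table supports marginal checks only; conclusions
  about joint structure require the original supplementary data, which can
  be dropped in as a canonical CSV without code changes.
- No multiple-testing control across the 16 × K significance calls beyond
  the dual-inversion rule itself.
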