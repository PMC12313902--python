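# Methods

## Molecular graphs and descriptors

Molecules are hydrogen-suppressed simple graphs: one vertex per heavy
atom, one edge per bond, bond order and atom identity ignored. This is
the convention under which degree-based indices are defined — the degree
range 1–4 in the reference data reflects organic heavy-atom valence. All
ten indices are edge sums of a term t(d_u, d_v), so they are computed
from the edge partition (count of edges per unordered degree pair), which
is exact and O(edges). Disconnected inputs are accepted (every index is
additive over components) but logged, since real drug molecules are
connected.

Two naming caveats are deliberate:

* **SS** is evaluated as √(d_u·d_v/(d_u+d_v)) per edge. Some sources
  attach the label "symmetric division degree" to this column, but the
  conventional SDD is Σ (d_u²+d_v²)/(d_u·d_v); the formula used here is
  the one our reference descriptor table was actually computed with, and
  fidelity to that arithmetic wins over nomenclature.
* **ABC** on a (1,1) edge is 0 (the numerator d_u+d_v−2 vanishes); no
  special-casing is needed because degrees ≥ 1 rule out division by zero.

The identity HZ = F + 2·M2 — exact because (a+b)² = a² + b² + 2ab edge by
edge — doubles as the integrity check on the packaged 17-drug descriptor
table (`validate_descriptor_table`). One cell of that table (Axitinib's
F) is absent from the printed source and is reconstructed through the
identity as 704 − 2·171 = 362; it is the only cell flagged
`reconstructed`. Property units are not stated by the source and the
pipeline is unit-agnostic.

A consequence of the identity worth knowing: the 17×10 descriptor matrix
can never have rank 10. Any model consuming all ten columns (the network,
the Shapley attribution) operates on collinear features; the regression
stage is immune because it is single-descriptor by design.

## Polynomial regression

One property on one descriptor, degree 1 or 3, ordinary least squares on
the raw monomial design solved by QR (`numpy.linalg.lstsq`). Raw
monomials — not orthogonal polynomials — keep the printed coefficients
directly comparable with conventional QSPR tables; the price is an
ill-conditioned design for wide-ranged descriptors (the cubic column of
HZ spans ~1e10), which QR handles and which is logged via the condition
number at DEBUG level.

Statistics panel: R² = 1 − RSS/TSS; R is reported as +√R² (a magnitude,
as is conventional in these tables, even where the slope is negative);
S_E = √(RSS/(n−k−1)) is the residual standard error; F is the usual
overall-regression statistic with (k, n−k−1) degrees of freedom and p its
upper-tail probability. Degenerate inputs raise a dedicated error:
constant regressor or fewer than k+1 distinct x values (rank), constant
response (TSS = 0, R² undefined), or n ≤ k+1. The rank test uses a
relative 1e-10 singular-value cutoff applied to the design built from
x/max|x|, which is invariant to the regressor's scale and therefore does
not misclassify legitimately wide-ranged descriptors as degenerate.

All fits are in-sample on all 17 records; there is no cross-validation —
with n = 17 the tables are descriptive fits, not validated predictors.

## Feedforward network

Architecture 10 → 32 → 32 → 1, ReLU hidden activations, linear output,
MSE loss. Choices the architecture leaves open were fixed as follows:

* **Optimizer**: full-batch Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8),
  learning rate 1e-3, at most 20 000 epochs, early stop when the
  running-best loss fails to improve by 1e-10 for 500 consecutive
  epochs. Full-batch removes minibatch randomness, so the seed alone
  (initialization) determines the trajectory bit-for-bit.
* **Initialization**: uniform U(−√(6/fan_in), +√(6/fan_in)) weights from
  a seeded generator, zero biases.
* **Standardization**: inputs and target are z-scored (descriptor scales
  differ by orders of magnitude); predictions are mapped back.
* **Returned weights**: the parameters at the best observed training
  loss, not the last epoch.

Gradients are hand-derived reverse-mode and verified against central
finite differences in the tests. One subtlety: the MSE surface is
non-differentiable where a pre-activation is exactly zero (e.g. zero
biases plus a fully inactive layer make a second-layer pre-activation
identically 0), so the finite-difference oracle is only applied at
parameter points with a verified margin from those ReLU kinks.

Reported metrics (MSE, MAE, RMSE = √MSE, R²) are **in-sample**: the
reference analysis lists fitted values for all 17 drugs and no split, so
the package fits on all samples and says so. Capability statements
("reaches R² ≥ 0.99 for polarizability") quantify over the documented
seed set {0..9}. Per-drug predicted values from any particular training
run are seed-dependent and not a reproduction surface; only metric-level
and capability-level checks are.

## Shapley attribution

Exact enumeration of all 2^d coalitions (d = 10 → 1024 model calls per
sample), with the value function v(S) = f(x with features outside S set
to the background per-feature mean). A single mean-imputed background —
rather than averaging v over all background rows — keeps the computation
deterministic and 17× cheaper; it is a documented approximation of
interventional SHAP and coincides with it exactly for linear models.
Efficiency (base value + Σφ = prediction) holds by construction and is
asserted per sample. The background is the full 17-drug descriptor
table. Global importance is mean |φ| per feature, ties broken by feature
order; rankings, not φ magnitudes, are the stable comparison surface. An
independent permutation-sampling estimator is included purely as a
cross-check oracle.

## Synthetic data

`random_molecular_graph` builds a uniform random-attachment spanning tree
(respecting the degree cap) and then adds each remaining compatible
vertex pair with probability `extra_edge_prob` — connectivity holds by
construction, degrees stay in [1, max_degree]. The default cap of 4
mirrors heavy-atom valence. `simulate_property` draws
y = β₀ + β₁x + β₂x² + β₃x³ + N(0, σ²) with homoscedastic Gaussian noise,
matching the OLS error model; a single descriptor drives the response,
as in the single-descriptor regression stage. `make_dataset` defaults to
17 molecules of 20 heavy atoms with a linear M1 response and σ = 5 —
the reference study's scale with a moderate noise level.

What the generator does *not* emulate: real ring statistics, heteroatom
labels, the correlation structure of a congeneric drug series, or
measurement error in tabulated properties. Passing recovery tests
therefore demonstrate correctness of the estimators under their assumed
model, not predictive validity on laboratory data.

Because of the HZ identity (above), generated descriptor matrices are
full rank only modulo that identity: rank 9 after dropping HZ is the
attainable maximum, and that is what is asserted.

## Numerical conventions

* Descriptor values are carried at full float precision; comparisons to
  4-decimal reference tables round to 4 d.p. first.
* Output CSVs default to 4 decimal places; p-values display as 0.000
  when below, full precision kept internally.
* R² = 1 exactly maps the F statistic to +inf and p to 0 rather than
  overflowing.
* All randomness flows through `numpy.random.default_rng` seeds; every
  generator accepts either an integer seed or a live `Generator` so
  composite pipelines can share one stream.

## Known limitations

* n = 17 throughout the packaged analysis: every fit statistic is
  descriptive, and the network trivially has capacity to interpolate.
* The printed S_E column of some reference regression tables is
  internally inconsistent (cubic S_E far exceeding linear S_E despite
  higher R²); this package reports the standard residual standard error
  and does not attempt to match those cells.
* Shapley values use mean imputation, so attributions on strongly
  correlated descriptors (which these are, by construction) spread credit
  in ways a conditional-expectation value function would not.
* SMILES input requires rdkit and ignores stereochemistry, charges,
  isotopes and bond order by design.
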