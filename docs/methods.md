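# Methods

This note documents the models implemented in `invqsar`, the defaults they
ship with, the numerical choices that matter, and what the synthetic
benchmarks do and do not demonstrate.

## The constrained optimization problem

Coordinate optimization for inverse QSAR is posed as

minimize f(**x**) subject to g_j(**x**) ≤ 0 (j = 1..q), h_j(**x**) = 0
(j = q+1..m), l_i ≤ x_i ≤ u_i,

with f(**x**) = −ŷ(**x**) (the negated ν-SVR prediction, since the goal is
maximal predicted activity), g₁(**x**) = −o(**x**) (the negated OCSVM
output, so feasibility means being inside the applicability domain), and
one additional inequality x_lesser − x_greater ≤ 0 per
descriptor-consistency rule. Equality constraints are supported by the
optimizer but unused by the built-in pipelines. The search runs in
range-scaled descriptor space: every feature is mapped affinely so its
training minimum/maximum land on −1/+1, and the box bounds are exactly
[−1, 1]^d — optimized coordinates therefore always lie inside the training
range. Descriptor rules are evaluated in unscaled units (counts), so the
pipeline un-scales, evaluates, and re-scales internally.

## ε-constrained differential evolution

Each generation applies, per individual i:

1. **Mutation** (DE/rand/1): **v** = **x**_r1 + F(**x**_r2 − **x**_r3)
   with r1, r2, r3 mutually distinct and different from i, drawn uniformly.
2. **Reflection**: a component below its bound is reflected about it,
   v_i < l_i → min(u_i, 2l_i − v_i), and symmetrically above; output is
   always in the box.
3. **Discrete rounding**: dimensions flagged discrete are rounded
   half-away-from-zero — in unscaled units when a scaler is attached, then
   mapped back and clipped to the box (the round trip can overshoot a bound
   by a few ulps).
4. **Exponential crossover**: a uniform start position, then donor
   components are copied circularly while successive uniform draws stay
   below CR; at least one donor component is always copied.
5. **ε-level selection**: the trial replaces its parent iff
   (f_t, Φ_t) <_ε (f_p, Φ_p), where the order compares objectives when both
   violations are within ε(t) (or exactly equal) and violations otherwise.
   Ties keep the parent.

Φ(**x**) = Σ_j max(0, g_j)^p + Σ_j |h_j|^p with p = 1 by default; ε(0) is
the violation of the individual at ascending-Φ rank ⌈θN⌉ (θ = 0.2), decays
as ε(0)(1 − t/Tc)^cp, and is zero from generation Tc on. With the default
Tc = 1 the tolerance applies only to the first offspring round — the
standard setting for this application, which makes θ and cp (default 5)
nearly irrelevant; both remain configurable. Generation t = 0 is the first
offspring round, so ε(0) is used exactly once.

Defaults follow the standard protocol for this method: F = 0.5, CR = 0.9,
p = 1, Tc = 1; 1,000 generations for the 2-D simulation benchmark and
10,000 for descriptor-space compound runs; the initial population is the
(scaled) training matrix itself rather than a random cloud, which seeds the
search inside the feasible region.

Implementation notes:

- The population is updated synchronously: all donors come from the
  generation-start population, and all trial vectors are evaluated in one
  batch, so SVR/OCSVM predictions run once per generation.
- Mutation indices are drawn by vectorized rejection sampling and crossover
  masks from one uniform block per generation; both are distributionally
  identical to the per-individual operations and deterministic given the
  seed. Without constraints the algorithm is canonical DE/rand/1/exp
  (verified against an independent seed-matched implementation).
- The reported best is tracked over every vector ever evaluated under the
  ε = 0 comparison (for Φ ≥ 0 this is lexicographic in (Φ, f)), so the
  result is feasible whenever any feasible point was visited; an
  all-infeasible run is flagged, not raised.
- Convergence is reported as the final population having collapsed to one
  point (max per-dimension spread < 1e-6); the full generation budget is
  always executed.

## Regression and applicability domain

- **ν-SVR** with RBF kernel k(x, x') = exp(−γ‖x − x'‖²). Hyperparameters
  {C, ν, γ} are selected by exhaustive grid search maximizing the pooled
  cross-validated Q² = 1 − PRESS/TSS (10 folds for the simulation
  benchmark, 5 for compound-scale data; folds are a seeded shuffle shared
  across the grid; ties keep the earliest grid point). Default grid:
  C ∈ 2^−5..2^5, ν ∈ {0.0625, 0.125, 0.25, 0.5}, γ ∈ 2^−4..2^4.
- **OCSVM applicability domain** at ν = 0.01 (ν bounds the training
  fraction allowed outside). γ is chosen from 2^−10..2^10 to maximize the
  elementwise variance of the training Gram matrix (diagonal included;
  ties toward the smallest γ) — a heuristic that avoids both the all-ones
  (γ→0) and identity-like (γ→∞) degenerate kernels. On the scaled 2-D
  simulation trials this heuristic selects γ = 1.
- A point is inside the AD iff the signed OCSVM output is ≥ 0. Boundary
  support vectors lie exactly on the zero level set; the solver leaves
  them numerically a hair below it, so the model fits with tol = 1e-8 and
  snaps decision values within 1e-6 of zero to exactly 0. Without this,
  membership counts on high-dimensional data are spuriously low.
- Constant features carry no range information; the scaler maps them to 0
  with a warning rather than failing, since correlation filtering can
  leave near-constant columns on small fixtures.

## Simulation benchmark

Ground truth is Mishra's bird function
sin(x₁)e^{(1−cos x₂)²} + cos(x₂)e^{(1−sin x₁)²} + (x₁−x₂)²
over x₁ ∈ [−2, 3], x₂ ∈ [−1, 4]; its in-domain maximum on a 0.005 lattice
is 56.18 near (−1.59, 0.06). Each trial samples 50 training and 20 test
points uniformly (inputs uniform over the rectangle; "random" sampling is
not otherwise specified, so uniform is the documented choice) and adds
Gaussian noise parameterized by variance (not SD), default variance 1.

The lattice oracle starts at the lower bound of each axis with the given
spacing; when the span is not an exact multiple of the resolution the last
point is the largest l + k·res ≤ u. Ties break toward the first point in
row-major order. The oracle used to validate optimization runs maximizes
the SVR surface over the optimizer's own feasible box (training min/max per
dimension) restricted to the AD — exactly the feasible set εDE searches —
so the oracle gap isolates optimizer error from model error.

## Compound curation and descriptors

Multiple Ki measurements (nM) merge by geometric mean when they agree
within one order of magnitude (max/min < 10, strict), otherwise the
compound is discarded; potency is reported as pKi = 9 − log₁₀ Ki[nM] (the
molar conversion). Structures are standardized to the parent fragment
(salt/solvent stripping) before matching against the RDKit PAINS and Brenk
reactive-substructure catalogs. The default descriptor registry holds 44
RDKit descriptors (constitutional counts, Chi/Kappa topological indices,
Gasteiger partial-charge extrema); count descriptors are flagged discrete
and any user-supplied name list is accepted for exact replication of an
external descriptor set. Correlation filtering is a greedy scan in column
order dropping any column whose |Pearson r| with an already-retained column
exceeds 0.9; zero-variance columns are retained with a warning. Train/test
splitting is a seeded half split with the odd element going to training.

## The synthetic compound fixture

`generate_compound_fixture` emulates the statistical shape of a curated
compound table without any chemistry: n = 600 rows, d = 15 descriptors by
default. Five integer count columns carry built-in consistency relations
(#HBA ≤ #heavy atoms, #HBD ≤ #HBA, #aromatic rings ≤ #rings) satisfied at
every row by construction; continuous columns include a molecular-weight
surrogate correlated with the heavy-atom count and a TPSA surrogate driven
by the H-bond counts; remaining columns are uninformative uniform noise.
The planted activity is a smooth unimodal surface over three descriptors,

pKi = 6 + 3·exp(−((logP−2)/2.5)²) + 2.25·exp(−((TPSA−60)/40)²)
      + 1.5·exp(−((heavy−25)/12)²) + N(0, 0.3²),

peaking at drug-like values with σ = 0.3 pKi units of noise (log-normal in
Ki). Amplitudes and length scales were chosen once, at generator-design
time, so that an RBF regression can recover the surface through the
irrelevant descriptors at this noise level.

What passing fixture tests show: the full pipeline (scaling, CV selection,
AD, constrained εDE with discrete rounding) finds feasible coordinates
that beat every training prediction and respect all count constraints, and
distance to those coordinates anti-correlates with predicted potency. What
they do not show: behavior on real descriptor distributions (heavy-tailed,
strongly inter-correlated, cluster-structured), assay heterogeneity, or
activity cliffs — conclusions about real compound sets require real data.

## Screening analyses

Rankings are computed after an AD pre-filter (both distance- and
potency-based rankings use it): distance mode sorts ascending by Euclidean
distance in scaled space, potency mode descending by predicted pKi, ties
stable in input order. ROC AUC uses the trapezoidal rule, equal to the
Mann–Whitney pairwise statistic with half credit for ties. PCA maps are
fitted on scaled training data only; query points are projected into that
basis. MMPs use single-cut fragmentation at acyclic single bonds with a
canonical shared core, requiring core heavy atoms ≥ 2× the substituent's
and substituent ≤ 13 heavy atoms; each compound-id pair is counted once.
The consistency ratio is the fraction of pairs with |ΔpKi| ≥ 1 in which
the member nearer the optimized coordinates is the more potent (distance
ties count as inconsistent; zero qualifying pairs yield an undefined
ratio, reported as None, never 0).

## Reproducibility and numeric output

A single run seed fans out to per-subsystem seeds through
`numpy.random.SeedSequence([seed, stream])`, so data generation, CV fold
assignment and the optimizer are independently reproducible. CSV/JSON
outputs are formatted at six significant digits; all test comparisons use
explicit tolerances, never string equality.

## Problem sizes used in the checks

The shipped checks run three full simulation trials (50/20 points, 1,000
generations, 0.005-resolution oracle grids), ten 2-D toy problems with
closed-form optima (population 40, 300 generations), one fixture pipeline
(n = 600, d = 15, 10,000 generations) and 100 random AUC instances of up
to 200 scores. These sizes keep a complete run within a few minutes on a
single CPU while exercising every component at the protocol's own
settings.

## Known limitations

- The benchmark's original random draws are unrecoverable, so trial-level
  numbers are reproduced only in protocol and distribution, not value by
  value; quantities independent of the draws (the 56.18 lattice maximum,
  the OCSVM γ = 1 selection) reproduce exactly.
- Equality constraints and multi-solution (niching/per-subset) protocols
  are supported or sketched but not exercised by any built-in study.
- No adaptive F/CR, archive-based variants, or kernels beyond RBF.
- The MMP definition is single-cut with a fixed size rule; double cuts and
  fuzzy cores are out of scope.
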