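# invqsar

Descriptor-coordinate optimization for two-stage inverse QSAR, built on
ε-constrained differential evolution (εDE).

## The problem

Forward QSAR fits a regression f(**x**) from molecular descriptors **x** to
activity (e.g. pKi). Inverse QSAR runs the other way: find descriptor values
that correspond to *higher* predicted activity than any known compound, as
the starting point for generating new structures. This package implements
the first stage of that process — the coordinate search — as a constrained
optimization problem (COP):

```
minimize   f(x) = −ŷ(x)                      (ŷ: ν-SVR prediction)
s.t.       g₁(x) = −o(x) ≤ 0                 (o: OCSVM output; o ≥ 0 ⇔ inside the AD)
           g_k(x) = x_lesser − x_greater ≤ 0  (descriptor consistency, e.g. #HBA ≤ #heavy atoms)
           −1 ≤ x_i ≤ +1                      (range-scaled training bounds)
```

The applicability-domain (AD) constraint keeps the optimum where the model
is trustworthy; consistency constraints keep count descriptors physically
possible. Chemical graph construction from the optimized coordinates
(stage two) is out of scope.

## Method

- **εDE optimizer** (`invqsar.optimize`): DE/rand/1 mutation
  **v** = **x**_r1 + F(**x**_r2 − **x**_r3), reflection into bounds,
  rounding of discrete dimensions, exponential crossover (probability CR),
  and one-to-one ε-level selection on (f, Φ) pairs, where
  Φ(x) = Σ max(0, g_j)^p + Σ |h_j|^p is the aggregate constraint violation
  and the tolerance ε(t) decays from Φ of the top-θ initial individual to 0
  at generation Tc. Defaults: F=0.5, CR=0.9, p=1, Tc=1.
- **Model layer** (`invqsar.models`): scikit-learn-style estimators —
  `RangeScaler` ([-1,1] per-feature training range), `ActivityRegressor`
  (RBF ν-SVR; {C, ν, γ} selected by maximizing cross-validated
  Q² = 1 − PRESS/TSS), `ApplicabilityDomain` (OCSVM at ν=0.01, γ chosen to
  maximize the Gram-matrix variance).
- **Simulation benchmark** (`invqsar.simdata`): Mishra's bird function over
  [-2,3]×[-1,4] with unit-variance Gaussian noise, 50 training / 20 test
  points per trial, and a brute-force lattice oracle (resolution 0.005) for
  validating optimization results.
- **Compound tools** (`invqsar.compounds`): Ki curation (geometric mean
  within one order of magnitude, pKi = 9 − log₁₀ Ki[nM]), PAINS/reactive
  structure filtering, a 44-descriptor RDKit registry, greedy |r| > 0.9
  correlation filtering, consistency-constraint construction, and a
  synthetic planted-activity fixture generator.
- **Screening analyses** (`invqsar.screening`): distance- and potency-based
  virtual-screening rankings with ROC AUC and top-k true-positive ratios,
  PCA maps, distance–activity profiles, and single-cut matched-molecular-pair
  (MMP) consistency ratios.

## Worked example

Fit the simulation benchmark and optimize coordinates:

```python
from invqsar import SimulationConfig, generate_simulation_data, bird_function
from invqsar.models import CVConfig
from invqsar.pipeline import fit_qsar_models, optimize_coordinates
from invqsar.optimize import DEParams

config = SimulationConfig(seed=1)          # 50 train / 20 test points
train, test = generate_simulation_data(config)

models = fit_qsar_models(train.X, train.y_observed, cv=CVConfig(n_folds=10, seed=1))
print(f"selected SVR params: C={models.svr_params.C:g}, "
      f"nu={models.svr_params.nu:g}, gamma={models.svr_params.gamma:g}")
print(f"OCSVM gamma (Gram-variance heuristic): {models.ad.gamma_:g}")

opt = optimize_coordinates(models, train.X,
                           de_params=DEParams(n_generations=1000, seed=1))
x1, x2 = opt.x_unscaled
print(f"optimized coordinates: ({x1:.3f}, {x2:.3f})")
print(f"predicted y: {opt.predicted_activity:.2f}   AD score: {opt.ad_score:.4f}")
print(f"true y at optimum: {bird_function(x1, x2):.2f}")
print(f"largest training prediction: "
      f"{models.regressor.predict(models.scaler.transform(train.X)).max():.2f}")
```

Output:

```
selected SVR params: C=32, nu=0.5, gamma=8
OCSVM gamma (Gram-variance heuristic): 1
optimized coordinates: (1.473, 3.137)
predicted y: 54.92   AD score: 0.0123
true y at optimum: 56.10
largest training prediction: 51.39
```

The optimizer found a point whose predicted activity (54.92) exceeds every
training prediction (max 51.39) while staying inside the applicability
domain (AD score ≥ 0); its true bird-function value (56.10) sits near the
in-domain maximum of 56.18.

The same workflow is available from the shell:

```bash
invqsar simulate --seed 3 --out out/            # write benchmark trials
invqsar optimize --config config.yaml --out out # fit + εDE, JSON/CSV results
invqsar analyze  --config config.yaml --out out # rankings, AUC, PCA, profiles
```

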