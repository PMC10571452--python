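# jointvitals

Joint modelling of two longitudinal vital signs — pulse rate (PR, beats/min)
and body temperature (BT, °C) — together with time to recovery for
hospitalised pneumonia patients under treatment.  The package provides the
full analysis chain for a 6-hourly vital-sign follow-up design (visits at
6, 12, …, 102 h, at most 17 per outcome): exploratory survival statistics,
a bivariate linear mixed sub-model, a Cox proportional-hazards sub-model,
and a shared-random-effects joint model, plus a synthetic cohort generator
with known truth for parameter-recovery studies.

## The model

Longitudinal sub-model, for outcome *k* ∈ {PR, BT} of subject *i*:

```
y_ik(t) = x_i'β_k + b_ik0 + b_ik1·t + ε_ik(t),     ε_ik ~ N(0, σ_k²)
```

with the four random effects b_i = (b_i10, b_i11, b_i20, b_i21) ~ N(0, D)
correlated across the two outcomes.  Survival sub-model:

```
h_i(t) = h₀(t) · exp( γ'w_i + association term )
```

where h₀ is piecewise-constant, w_i are baseline covariates, and the
association term is one of

* **current value**: Σ_k α_k m_ik(t), with m_ik(t) the noise-free biomarker;
* **current value and slope**: adds α-terms on the subject slopes m′_ik;
* **shared random effects**: Σ_k α_k b_ik1 (random slopes in the hazard).

The joint likelihood integrates the shared random effects out with adaptive
Gauss–Hermite quadrature (nodes centred at each subject's Gaussian
posterior); because the true trajectories are affine in time, the
cumulative hazard is closed-form for every quadrature node.  Hazard ratios
are `exp(coefficient)` throughout.

## Worked example

```python
import numpy as np
from jointvitals import (SimulationConfig, simulate_cohort,
                         JointSpec, fit_joint, association_summary)
from jointvitals.design import Covariate, CovariateDesign
from jointvitals.hazard import PiecewiseConstantHazard

cfg = SimulationConfig(
    n_subjects=120,
    design=CovariateDesign(covariates=(Covariate("grp", ("a", "b")),)),
    covariate_probs={"grp": (0.5, 0.5)},
    beta={"PR": np.array([110.0, 2.0, -0.4]),
          "BT": np.array([38.0, 0.3, -0.012])},
    D=np.array([[25.0, 0.5, 3.0, 0.0],
                [0.5, 0.09, 0.0, 0.01],
                [3.0, 0.0, 1.0, 0.0],
                [0.0, 0.01, 0.0, 0.04]]),
    sigma=(3.0, 0.5),
    hazard=PiecewiseConstantHazard((48.0,), (0.012, 0.015)),
    gamma=np.array([0.3]),
    alpha=(-0.05, -0.5), assoc_center=(110.0, 38.0),
    association="current_value", seed=7)

cohort, truth = simulate_cohort(cfg)
fit = fit_joint(JointSpec(association="current_value",
                          n_pieces=2, n_nodes=5), cohort)
print(association_summary(fit)[["parameter", "estimate", "se", "hr"]])
```

prints

```
        parameter  estimate       se       hr
0  assoc_value_PR   -0.0486   0.0150   0.9526
1  assoc_value_BT   -0.5348   0.0599   0.5858
```

i.e. the fit recovers the generating association α = (−0.05, −0.5): each
extra beat/min of true pulse rate multiplies the recovery hazard by ≈0.95,
each extra °C by ≈0.59, with Wald standard errors from the observed
information.

A YAML-driven command line covers the same flow end to end:

```
jointvitals run --config config.yaml --out results/ --seed 1
```

with subcommands `simulate`, `explore`, `fit-lmm`, `fit-cox`, `fit-joint`,
`report`.  Every run writes a `manifest.json` with SHA-256 checksums of all
artifacts; identical config + seed reproduces identical checksums.

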