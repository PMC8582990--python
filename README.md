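# asriskmap

Spatial mapping of groundwater arsenic concentrations and the associated
human-health risk, for hydrogeologists and environmental-health analysts
working with scattered household-well surveys.

Shallow-aquifer arsenic measurements are strongly right-skewed,
approximately log-normal, spatially correlated over kilometers, and
left-censored at the laboratory detection limit (non-detects below
0.9 µg/L are recorded at 0.45 µg/L).  `asriskmap` interpolates such point
data over a regular grid by two independent routes and compares them
honestly before mapping risk:

* **Ordinary kriging (OK).**  The empirical semivariogram
  γ̂(h) = (1/2N(h)) Σ [Z(xᵢ+h) − Z(xᵢ)]² of the log₁₀ concentrations is
  fitted with a spherical, exponential or Gaussian model (nugget c₀,
  partial sill c, range a), and the best linear unbiased estimate
  Z\*(x₀) = Σ λᵢ Z(xᵢ) is obtained from the augmented kriging system with
  the constraint Σ λᵢ = 1.
* **Back-propagation neural network (BPNN).**  A from-scratch feed-forward
  network mapping planar coordinates to log₁₀ concentration
  (netⱼ = Σᵢ XᵢWⱼᵢ − bⱼ, tanh hidden layers, linear output), trained by
  full-batch Levenberg–Marquardt: (JᵀJ + λI)δ = −Jᵀr with adaptive damping,
  stopping at training mse ≤ 10⁻².

The two are compared by three-fold cross-validation on a
**concentration-ordered split** (wells sorted by concentration and dealt
round-robin to sets A/B/C, so every fold spans the full range), scoring
R² = 1 − SSE/SStot and RMSE on the log₁₀ scale.  The winning surface is
converted into USEPA risk layers:

* daily intake DI = C·IR/BW,
* hazard quotient HQ = DI/RfD (HQ > 1 ⇒ possible non-carcinogenic effects),
* target risk TR = DI·(EF·ED/AT)·CSF·10⁻³ (lifetime cancer risk; the
  1e-6–1e-4 band is conventionally acceptable),
* irrigation/aquaculture suitability (unsuitable above 50 µg/L) and the
  <5 / 5–10 / 10–50 / ≥50 µg/L concentration classes.

A Gaussian-random-field simulator (`asriskmap.synthetic`) generates censored
log-normal well datasets with exactly this statistical structure, so the
whole pipeline is testable end-to-end without access to any proprietary
monitoring records.

## Worked example

```python
import numpy as np
from asriskmap import (FieldSpec, VariogramModel, generate_wells, ordered_split,
                       cross_validate, KrigingModel, make_grid)
from asriskmap.bpnn import NetworkSpec, TrainConfig
from asriskmap.risk import risk_layers

vm = VariogramModel("exponential", nugget=0.005, partial_sill=0.06, range_=15000)
spec = FieldSpec(vm, log_mean=0.5, extent=(0, 0, 30000, 20000), seed=42)
wells = generate_wells(spec, n_wells=600)

split = ordered_split(wells, k=3)
report = cross_validate(wells, split, "exponential", NetworkSpec((2, 10, 10, 1)),
                        TrainConfig(seed=42), restarts=3)
print(report.summary())
```

prints

```
Cross-validation (log10 scale)
method fold       R2     RMSE
    OK    A 0.706106 0.132832
  BPNN    A 0.662727 0.142298
    OK    B 0.723831 0.126976
  BPNN    B 0.671584 0.138468
    OK    C 0.618107 0.148676
  BPNN    C 0.650200 0.142292

Averages:
              R2      RMSE
method                    
OK      0.682681  0.136161
BPNN    0.661504  0.141019
```

Each row is one held-out fold: both interpolators were rebuilt on the other
two folds and scored on it.  Here both methods explain ~65–70% of the
log-concentration variance; on this simulated Gaussian field kriging has a
slight edge (it is the optimal linear predictor for exactly this data-
generating process), while on real aquifers the network's flexibility can
reverse the ordering.  Fitting the variogram and mapping risk:

```python
res = KrigingModel(wells).fit()
print(res.summary())
grid = res.predict_grid(make_grid(wells, cell_size=1000, padding=1000))
layers = risk_layers(grid["conc_ugL"])
print(f"cells at unacceptable cancer risk: {(layers['tr_level'] == 3).sum()}")
```

```
Ordinary Kriging Results
=======================================
Model:               ordinary kriging (exponential variogram)
No. wells:           600
Nugget c0:           0.018045 (log10 ug/L)^2
Partial sill c:      0.0481178 (log10 ug/L)^2
Sill c0+c:           0.0661628 (log10 ug/L)^2
Range a:             16827.3 m
Weighted SSE:        0.000198632
Lag bins used:       15
Range identifiable:  True
cells at unacceptable cancer risk: 2
```

The fitted sill 0.066 and range 16.8 km recover the simulation truth
(0.065, 15 km) well; on the 704-cell 1-km grid two cells exceed the
TR = 10⁻⁴ unacceptable-risk threshold.

The same workflow is available from the shell:

```sh
asriskmap simulate --n-wells 600 --seed 42 --out wells.csv
asriskmap crossval --wells wells.csv --structure 2,10,10,1 --seed 42
asriskmap run --seed 42 --out results/
```

`asriskmap run` writes the wells table, split, CV report, concentration and
risk grids (ESRI ASCII + CSV) and GeoJSON zone polygons, all stamped with
the config hash and seed in `manifest.json`.

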