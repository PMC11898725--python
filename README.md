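# napacool

Postharvest cold-storage modelling for Chinese cabbage (*Brassica rapa*
ssp. *pekinensis*), for postharvest engineers and cold-chain modellers.
The package covers the full desk-scale chain:

1. **Morphology classification** — K-means on (length circumference, width
   circumference, weight) with silhouette-based selection of the cluster
   count, yielding size classes 1..k by ascending weight, and heat-balanced
   basket allocation (one head per class per basket).
2. **Respiration** — molar CO2 production from sealed-basket traces via the
   ideal gas law, `R_CO2 = P·V·(dx/dt)/(M·R·T)`, and metabolic heat from
   the ASHRAE power law `Q(T) = 10.7 f/3600 · (9T/5 + 32)^g` (W/kg), with
   conversion to a volumetric source `q̇ = Q·m/V`.
3. **Porous-sphere cooling** — transient radial finite-volume solution of
   the local-thermal-equilibrium energy equation
   `(ρc)_eff ∂T/∂t = (1/r²) ∂/∂r (r² k_eff ∂T/∂r) + q̇(T)`
   with a Robin surface condition `−k_eff ∂T/∂r = h (T_s − T∞)`, verified
   against the convective-sphere eigenfunction series.
4. **Calibration** — the surface coefficient h estimated by RMSE grid scan
   of simulated against observed cooling curves.
5. **Zonal storage scenarios** — a lumped compartment model comparing
   fully packed, 50:50 batch-filled, and repositioned-cooler loading of a
   cold room by temperature-gradient and equilibrium times.

A synthetic-data module generates every input (morphology tables,
sealed-chamber traces, cooling experiments, environment logs) with the
statistical structure of the original measurements, so the whole pipeline
is testable without any external data. See `docs/methods.md` for models,
assumptions and defaults.

## Worked example

```python
import napacool as nc

# 162 synthetic heads (54 per class), cluster and summarize
df, truth = nc.gen_morphology(54, seed=1)
sel = nc.select_k(df, k_range=(2, 3, 4, 5), seed=1)
print("selected k =", sel.k_opt)
res = nc.MorphologyClassifier(df).fit(k=sel.k_opt, seed=1)
print(res.summary())
```

```
selected k = 3
Morphology K-means classification
---------------------------------
records:         162
clusters (k):    3
SSE:             31.208
mean silhouette: 0.718

per-class trait means (ascending weight):
  class 1 (n=54): length 73.64 cm, width 46.19 cm, weight 1514.03 g
  class 2 (n=54): length 82.51 cm, width 51.21 cm, weight 2115.24 g
  class 3 (n=54): length 88.83 cm, width 58.25 cm, weight 2835.26 g
```

Three size classes emerge with mean weights within a standard error of the
generating values (1503 / 2132 / 2826 g); the mean silhouette 0.72 says the
classes are well separated in standardized trait space.

Cooling and calibration:

```python
# synthetic cooling experiment at h = 270 W/m2K, 0.2 degC sensor noise
exp = nc.gen_cooling_experiment(h_true=270.0, noise_sd=0.2, duration=20.0, seed=0)
fit = nc.HeatTransferCalibration(exp).fit()
print(fit.summary())
```

```
Heat-transfer coefficient calibration
-------------------------------------
positions:        top, middle, bottom
h grid:           150..400 W/m2K (step 10)
optimal h:        340 W/m2K
RMSE at optimum:  0.2015 degC
```

The RMSE at the optimum recovers the injected noise level. Note the wide
scatter of the recovered h itself: at Biot ≈ 1200 the head's cooling is
conduction-limited and the volume-average curve is nearly insensitive to h,
so single-experiment estimates spread far beyond one grid step even though
they are unbiased (see `docs/methods.md`).

Loading scenarios:

```python
states = {ly: nc.simulate_storage(nc.build_scenario(ly), t_end=30.0)
          for ly in ("fully_packed", "batch_50_50", "repositioned_batch")}
print(nc.compare_scenarios(states).to_string(index=False))
```

```
          scenario  gradient_time_h  gradient_time_second_set_h  equilibrium_time_h
repositioned_batch         3.573807                   11.269480           12.451514
       batch_50_50         8.757323                   12.385468           13.924710
      fully_packed        11.985576                    7.385468           16.639883
```

Repositioned coolers with batch filling equilibrate first, fully packed
last — the ranking the storage-design comparison is after (the clock times
are desk-scale, not room-scale).

A `napacool` CLI exposes the same steps (`synth`, `classify`,
`respiration`, `props`, `cool`, `fit-h`, `scenario`); try
`napacool --help`.

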