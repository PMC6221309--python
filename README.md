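# osteotex

Quantitative 3D surface texture analysis of bone use-wear.

Use-wear analysts study the microscopic traces that manufacture (grinding,
scraping) and use (rubbing against skin, leather, bark) leave on bone tools,
to reconstruct how such tools were made and used.  Traditional assessments
are qualitative; `osteotex` implements the quantitative alternative: scans of
the bone surface are treated as height maps, reduced to a small vector of
areal texture parameters, and analysed with a hierarchical Bayesian model
that separates experimental effects from specimen- and acquisition-level
noise.

The package provides, end to end:

* **Surface metrology** — the ISO 25178 preprocessing chain (acceptance QC at
  95 % measured area, least-squares leveling, y/z mirroring of mold scans,
  robust outlier removal, fill-in of holes < 225 points, Gaussian S-filter,
  degree-2 form removal) and from-scratch implementations of four areal
  texture parameters, one per ISO family:
  - `Sa` (µm) — arithmetic mean height: E|z − z̄| over measured cells;
  - `Sal` (µm) — autocorrelation length: the shortest lag at which the
    normalised areal ACF decays to 0.2;
  - `Spc` (1/µm) — arithmetic mean peak curvature, −½(z_xx + z_yy) averaged
    over watershed peaks surviving Wolf pruning at 5 % of Sz;
  - `Smr1` (%) — upper material ratio from the equivalent-line construction
    on the areal Abbott–Firestone curve.
* **Synthetic experiments** — a registry replicating a wear experiment's
  design (37 bone specimens in 5 lots, 3 manufacturing states × 3 worked
  materials, incremental molds at 0/30/60/90 then 90-minute steps: 239
  samples, 5 crosswise scan locations each), a mechanistic simulator of bone
  microtopography and material wear, and a fast parametric generator that
  draws observation tables from the statistical model itself.
* **The statistical model** — for Y the n×4 matrix of log texture parameters,

      Y = XB + ZU + E

  with fixed experimental/control effects XB (a nested ladder M0–M3 up to
  state × material × log-time interactions), crossed Gaussian random
  intercepts U for specimen and lot (Z is the 0/1 incidence matrix, 42
  columns on the default design), and rows of E multivariate Student-t with
  scale Σ = DΩD.  Priors: N(0, 5²) on B, half-Cauchy(2.5) on D, LKJ(1.5) on
  Ω, Gamma(2, 0.1) truncated at 2 on the degrees of freedom.  Inference is a
  blocked Gibbs sampler on the Student-t scale-mixture representation
  (2 chains × 500 warmup + 500 draws by default), with WAIC model
  comparison, intraclass correlations per grouping factor, posterior mean
  trajectories/ellipses, and a Mahalanobis-distance QQ check against
  F(p, ν) quantiles.

See `docs/methods.md` for the modelling details and numerical choices.

## Worked example

```python
from osteotex import (simulate_base_surface, apply_wear, preprocess_pipeline,
                      PreprocessConfig, compute_all_params)

# a scraped-with-flint bone surface, worn 180 min on fresh skin
hm = simulate_base_surface("SF", seed=0, shape=(256, 256))
worn = apply_wear(hm, "FS", 180, seed=1)
clean = preprocess_pipeline(worn, PreprocessConfig())
tp = compute_all_params(clean)
print(f"Sa={tp.sa:.3f} um  Sal={tp.sal:.3f} um  "
      f"Spc={tp.spc:.4f} 1/um  Smr1={tp.smr1:.2f} %")
```

prints

```
Sa=1.163 um  Sal=32.812 um  Spc=0.0314 1/um  Smr1=4.92 %
```

— a rough (high Sa), long-wavelength (high Sal) furrowed surface, as
expected for flint scraping; 180 minutes of fresh-skin polish has already
rounded its peaks (Spc well below the unworn ~0.04).

Fitting the model ladder to a simulated observation table:

```python
from osteotex import build_registry, simulate_observation_table, TextureMixedModel

table = simulate_observation_table(build_registry(), seed=0)   # 1255 scans
sub = table.sample(n=300, random_state=0).reset_index(drop=True)
m1 = TextureMixedModel(model_id="M1", chains=2, warmup=300, draws=300, seed=0).fit(sub)
m3 = TextureMixedModel(model_id="M3", chains=2, warmup=300, draws=300, seed=0).fit(sub)
print(f"dWAIC(M1 vs M3) = {m1.waic_['waic'] - m3.waic_['waic']:.1f}")
print(m3.icc_[m3.icc_.factor == 'specimen'].head(2))
```

```
dWAIC(M1 vs M3) = 30.6
   factor parameter  icc_mean  icc_lo  icc_hi
 specimen    log_Sa     0.105   0.020   0.239
 specimen   log_Sal     0.237   0.092   0.391
```

The interaction model M3 is preferred (lower WAIC: the generator contains
state × material × time structure that M1 cannot express), and roughly
10–25 % of the unstructured variance per parameter is attributable to the
individual bone specimen.  `TextureMixedModel` is a scikit-learn style
estimator: constructor parameters via `get_params`/`set_params`, fitted
state in trailing-underscore attributes (`draws_`, `waic_`, `icc_`,
`rhat_max_`, `converged_`).

A command-line interface mirrors the pipeline stages:

```sh
osteotex simulate --mode table --seed 1 --out runs/d
osteotex fit --table runs/d/observations.csv --model M3 --seed 1 --out runs/d/M3
osteotex waic runs/d/M0 runs/d/M1 runs/d/M2 runs/d/M3
osteotex run --config demo.yaml          # full pipeline with manifest
```

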