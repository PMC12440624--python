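# hetflow

Heterogeneous nanoparticle–cell association kinetics from flow cytometry.

In vitro particle–cell association experiments incubate cells with
nano-engineered particles and read out, by flow cytometry, thousands of
single-cell fluorescence values per time point. Classical analyses collapse
each time point to a median intensity and fit a homogeneous two-parameter
uptake model, discarding the cell-to-cell variability that the data actually
contain. `hetflow` is for researchers who want to *use* that variability: it
models each cell j with its own association rate r_j [m s⁻¹] and carrying
capacity K_j [particles cell⁻¹],

    r ~ LogNormal(mean m_r, SD s_r),      K ~ LogNormal(mean m_K, SD s_K),
    P_j(t) = K_j (1 − exp(−C S r_j/K_j ∫₀ᵗ ū)),

where ū(t) is a mean-field media concentration built from the analytic
homogeneous solution

    P(t) = Vu0 (1 − (Vu0 − K)/(Vu0 − K e^(−rCS(Vu0−K)t/(KV)))),

and generates synthetic flow-cytometry measurements by resampling measured
cell-only and particle-only control distributions (additive autofluorescence
noise, multiplicative per-particle noise). The four hyperparameters
θ = (m_r, s_r, m_K, s_K) are inferred with ABC-SMC under summed per-time
two-sample Anderson–Darling distances (Cramér–von Mises and
Kolmogorov–Smirnov variants included), summarised with highest-posterior-
density intervals, and propagated into predictions: fluorescence histogram
bands, inferred r and K distributions, particles-per-cell P(t) bands, and
the fraction of cells above β·K. The package also ranks all C(14,6) = 3003
choices of six measurement time points by the mean inverse determinant of
the rejection-ABC posterior covariance (a precision utility), identifying
optimal experimental designs per association-rate scenario and overall.
Median-transform + least-squares and per-cell-transform baselines are
included for comparison.

Everything runs on synthetic data generated by the package itself;
calibrated experimental CSV exports (one `fluorescence` column for
controls, `time_h`/`fluorescence` long format for time courses) drop into
the same pipeline.

## Worked example

Infer the hyperparameters of an intermediate-rate scenario from a synthetic
dataset of 2000 cells per time point at t = 1, 2, 4, 8, 16, 24 h:

```python
import numpy as np
import hetflow as hf

consts = hf.presets.DEFAULT_CONSTANTS
rng = np.random.default_rng(0)
controls = hf.generate_control_fixtures(hf.presets.DEFAULT_CONTROL_SPEC, rng)
truth = hf.presets.SCENARIO_HYPERPARAMS["intermediate"]
obs = hf.simulate_dataset(truth, consts, hf.presets.STANDARD_TIMES, controls, 2000, rng)

cfg = hf.SMCConfig(n_particles=100, n_cells=1000, n_prior_predictive=300,
                   max_generations=30, target_noise_multiple=2.0)
post = hf.abc_smc(obs, hf.UniformPriorBox(), controls, consts, cfg, seed=1)
med = post.median()
for i, name in enumerate(hf.PARAM_NAMES):
    h = post.hpd(name, 0.95)
    print(f"{name:4s} true {truth.theta()[i]:9.3g}  posterior median {med[i]:9.3g}"
          f"  95% HPD ({h.lower:.3g}, {h.upper:.3g})")

fit = hf.least_squares_fit(hf.median_transform(obs, controls), consts)
print(f"least-squares baseline: r = {fit.r:.3g} m/s, K = {fit.K:.3g}")
```

Output (about 90 s on one CPU):

```
m_r  true  3.86e-07  posterior median  4.64e-07  95% HPD (3.21e-07, 7.35e-07)
s_r  true  4.57e-07  posterior median  7.33e-07  95% HPD (1.76e-07, 1.64e-06)
m_K  true        10  posterior median      10.1  95% HPD (8.8, 11.1)
s_K  true         2  posterior median      1.92  95% HPD (0.153, 3.67)
least-squares baseline: r = 4.06e-07 m/s, K = 11.4
```

Every generating value lies inside its 95% HPD interval: the ABC pipeline
recovers both the typical kinetics and the spread of the population, while
the baseline returns a single (r, K) pair — of the right order, but blind to
heterogeneity and, on right-skewed controls, biased upward relative to the
true median particles per cell.

The same stages are available from the shell:

```
hetflow simulate --scenario intermediate --seed 1 --out runs/sim
hetflow fit      --obs runs/sim/timecourse.csv --cells runs/sim/cells_control.csv \
                 --particles runs/sim/particles_control.csv --seed 1 --out runs/fit
hetflow predict  --posterior runs/fit/posterior.csv --cells runs/sim/cells_control.csv \
                 --particles runs/sim/particles_control.csv --out runs/pred
hetflow baseline --obs runs/sim/timecourse.csv --cells runs/sim/cells_control.csv \
                 --particles runs/sim/particles_control.csv --out runs/bl
hetflow design   --scenario low --seed 1 --out runs/design
```

Each command writes CSV/JSON artifacts plus `run_metadata.json` (resolved
configuration, seed, config hash); every artifact is reproducible from that
metadata.

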