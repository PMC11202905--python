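# dsbdyn

Stochastic simulation of the motion and repair of radiation-induced DNA
double-strand-break (DSB) ends during canonical non-homologous end joining
(c-NHEJ), for radiation biophysicists studying repair kinetics and
chromosome-aberration dosimetry.

After ionizing radiation severs both DNA strands, the two free chromosome
ends wander through the nucleoplasm until repair machinery ligates them.
Single-particle tracking shows this motion is *subdiffusive* —
MSD ∼ t^α with α ≈ 0.3–0.5 — interrupted by rare, roughly
constant-velocity directed excursions.  `dsbdyn` implements this
heterogeneous anomalous mobility model and couples it to a proximity-driven
repair scheme:

- **Passive motion** is 3D fractional Brownian motion (FBM) driven by
  fractional Gaussian noise with Hurst exponent H = α/2 and generalized
  diffusion coefficient K_α, normalized so the ensemble MSD is
  ⟨r²(t)⟩ = 6 K_α t^α.  Noise series are sampled *exactly* by circulant
  embedding (Davies–Harte) in a single FFT pass per trajectory.
- **Active runs**: a two-state Markov indicator I(t) ∈ {0, 1} with rates
  μ0 (on) and μ1 (off) adds a velocity term I(t)·v·d̂, with a fresh random
  unit direction each active phase.  Defaults (μ0 = 0.001 s⁻¹,
  μ1 = 0.016 s⁻¹, v = 16 nm/s) give ≈ 62 s runs covering ≈ 1 µm, active
  ≈ 6 % of the time.
- **Repair** is a diffusion–annihilation reaction A + A → 0: ends climb a
  kinetic ladder (naked → Ku70/80-bound → DNA-PKcs-bound) and, once
  synapsis-competent, ligate irreversibly on contact within a capture
  radius (25 nm default).  A join between non-partner ends is a misrepair;
  if both fragments carry a centromere it forms a **dicentric** chromosome.
- **Observables**: the survival function S(t) = residual DSBs / initial
  DSBs, its power-law decay exponent, and the dicentric dose–response
  (mean dicentrics per cell after 24 h vs dose in Gy).

Initial damage comes from a built-in synthetic generator (Poisson DSB
counts at a configurable yield per Gy, uniform or track-clustered
placement in a spherical nucleus, per-chromosome centromere bookkeeping)
or from a minimal dialect of the Standard DNA Damage (SDD) format.

## Worked example

```python
import numpy as np
from dsbdyn import (MotionParams, SimulationConfig, ensemble_msd,
                    fit_powerlaw, generate_fbm_3d, run_repeats,
                    survival_curve)

# 1. Verify the passive-motion scaling: 1000 FBM trajectories, H = 0.25
p = MotionParams(hurst=0.25, k_alpha=20.0, dt=1.0, n_steps=1024)
trajs = [generate_fbm_3d(p, seed=1, end_id=i) for i in range(1000)]
lags, msd = ensemble_msd(trajs)
fit = fit_powerlaw(lags, msd, window=(10, 500))
print(f"MSD exponent {fit.exponent:.3f}, prefactor {fit.prefactor:.1f}")
# -> MSD exponent 0.493, prefactor 126.2

# 2. Repair of 1 Gy of damage by the heterogeneous model, 24 h, 10 cells
cfg = SimulationConfig(dose_gy=1.0)   # HFBM defaults, 24 h, dt = 1 s
results = run_repeats(cfg, 10, seed=42)
curve = survival_curve(results)
print(f"S(24 h) = {curve.mean[-1]:.2f}, "
      f"dicentrics/cell = {np.mean([r.dicentrics() for r in results]):.2f}")
# -> S(24 h) = 0.63, dicentrics/cell = 0.00
```

The MSD exponent ≈ 0.5 and prefactor ≈ 6 K_α = 120 nm²/s^0.5 confirm the
subdiffusive normalization; the repair run shows about a third of
the DSBs rejoined quickly while ends separated by directed runs remain
open at 24 h; dicentrics are rare at 1 Gy with spatially uniform damage
and appear at higher doses (and vanish entirely when the directed-run
channel is switched off, `motion.mu0 = 0`).

A command-line interface mirrors the library:

```sh
dsbdyn simulate --config config.yaml --seed 1 --out-prefix run1
dsbdyn dose-response --config config.yaml --doses 1,2,4,6 --seed 1 --out dr.tsv
dsbdyn msd --n 1000 --seed 1 --out msd.tsv
dsbdyn fit msd.tsv --xcol lag_s --ycol msd_nm2 --window 10,500
```

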