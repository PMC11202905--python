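# Methods

## Model

Each free DSB end is an independent overdamped Langevin particle in a
spherical nucleus:

    r(t + dt) = reflect( r(t) + ξ_fGn(t) + I(t) · v · d̂(t) · dt )

**Fractional Gaussian noise.**  The passive term ξ_fGn is a stationary
Gaussian increment process with per-dimension autocovariance

    γ(k) = K_α dt^α ( |k+1|^α − 2|k|^α + |k−1|^α ),

the increment process of fractional Brownian motion with Hurst exponent
H = α/2.  For α < 1 increments are anti-persistent and the motion is
subdiffusive.  The single normalization convention used everywhere is the
3D ensemble MSD ⟨r²(t)⟩ = 6 K_α t^α (so γ(0) = 2 K_α dt^α per dimension);
the generalized diffusion coefficient D quoted with the default parameters
is identified with K_α in this convention.  Anti-persistence makes the
exploration *compact* (walk dimension 2/H = 8 > 3 at H = 0.25), which is
why nearby partner ends reliably re-find each other.

**Sampling.**  fGn series are drawn exactly by circulant embedding
(Davies–Harte): the covariance of the padded series (next power of two) is
embedded in a symmetric circulant whose eigenvalues come from one real
FFT; a Hermitian complex Gaussian spectrum is shaped by √λ and transformed
back in a single inverse real FFT.  The embedding is checked for
non-negative definiteness and the generator fails loudly (rather than
clipping) if it is violated.  Full-length one-pass generation matters:
chunked generation would sever the long-range anticorrelation.  Each end
and each Cartesian component has its own counter-derived substream
(`SeedSequence([master, end_id, stream, dim])`), so ensembles are
reproducible and independent of iteration order.

**Switching.**  The indicator I(t) is a continuous-time two-state Markov
chain simulated event-driven (exact exponential dwells, no discretization
error in phase boundaries); a step of the integrator is "active" when its
midpoint falls in an active phase, unbiased for dt ≪ 1/μ1.  Every active
phase draws a fresh unit direction, by default uniform on the sphere
(`isotropic3d`); a planar `azimuthal` mode (uniform angle in (0, 2π),
z-component 0) is retained for comparison with strictly two-dimensional
direction sampling, since the dynamics themselves are three-dimensional.
All ends start passive — activity is rare (stationary active fraction
μ0/(μ0+μ1) ≈ 6 %) so the initial condition washes out within ~1/μ1.

**Boundary.**  The nuclear envelope reflects radially: a point at R + δ
(δ < R) maps to R − δ on the same ray; pathological overshoots beyond one
radius are clamped to the surface with a logged warning.  Reflection
modifies the position only, never the stored noise stream, preserving the
noise correlation structure.

**Damage.**  DSB counts per cell are Poisson with mean dose × yield.
Positions are uniform in the nucleus by default; a track-like placer
(DSBs scattered along random chords) is available as a plug-in for
sensitivity studies.  Genomic bookkeeping uses a normalized karyotype
(unit chromosome length, one centromere), because dicentric scoring only
needs centromere containment: the breaks on a chromosome partition it
into fragments, and exactly one fragment per broken chromosome carries
the centromere.

**Repair.**  Ends advance through naked → Ku-bound → DNA-PKcs-bound with
per-step probability 1 − exp(−rate·dt) and are then joinable; two joinable
ends within the capture radius ligate irreversibly (greedy
ascending-distance pairing with an end-index tie-break — near-optimal in
total distance at the simulated densities, and deterministic).  The bulk
driver pre-samples each end's eligibility step as the sum of two geometric
variates with the same per-step probabilities — identical in distribution
to stepping the state machine, and vectorizable — and runs the motion/
contact loop in a compiled kernel with a per-step cell list for neighbor
search.  Survival is recorded on a 32-points-per-decade logarithmic grid
as S(t) = (unligated ends / 2) / initial DSBs.

**Scoring.**  A join between original partners is correct; same-chromosome
non-partners are intra-chromosomal misrepair, anything else
inter-chromosomal.  A misjoin of two centromere-carrying fragments counts
as one dicentric; "dicentrics per cell" counts such events per realization
(no karyotype-graph reconstruction — a documented extension hook).

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| α (= 2H) | 0.5 | — | anomalous MSD exponent of passive motion |
| K_α | 20 | nm²/s^α | generalized diffusion coefficient (MSD = 6 K_α t^α) |
| v | 16 | nm/s | active-run speed (mean run ≈ v/μ1 ≈ 1 µm) |
| μ0 | 0.001 | s⁻¹ | passive → active rate |
| μ1 | 0.016 | s⁻¹ | active → passive rate (mean active dwell 62.5 s) |
| dt | 1 | s | integration step (resolves runs and Ku-scale kinetics) |
| nucleus radius | 4600 | nm | typical fibroblast nucleus scale, reflecting |
| DSB yield | 35 | Gy⁻¹ cell⁻¹ | representative proton-irradiation value |
| end offset | 10 | nm | initial partner-end separation (avoids zero-distance artifacts) |
| naked→Ku rate | 0.02 | s⁻¹ | calibration parameter (recruitment kinetics) |
| Ku→PKcs rate | 0.005 | s⁻¹ | calibration parameter (mean total lag ≈ 250 s) |
| capture radius | 25 | nm | synaptic-complex length scale |
| repeats | 200 | — | default cells per condition (50 in the fast suites) |

The two recruitment rates and the capture radius are calibration
parameters: the motion physics is fully specified, the recruitment
kinetics is not, and observables in the 10²–10³ s range depend on them.
A `minimal` kinetics mode (all ends immediately joinable) exposes the pure
diffusion–annihilation reaction for benchmark runs.

## What the synthetic damage generator does and does not emulate

The generator reproduces dose-proportional Poisson DSB counts, spatial
confinement to the nucleus, and per-chromosome centromere bookkeeping.  It
does **not** reproduce the microdosimetric structure of real charged-
particle tracks: clustered lesions in sub-100-nm track cores, correlated
damage complexity, or LET dependence.  This matters for density-driven
observables.  With spatially uniform (or chord-clustered) damage at
35 DSB/Gy, the end density is ~10⁻¹⁰ nm⁻³ and the well-mixed annihilation
rate k·n (k ≈ 2 f_act π σ² v ≈ 4·10³ nm³/s with σ = 25 nm) is of order
10⁻⁶ s⁻¹: inter-end joins are rare and the survival function at desk scale
is dominated by partner rejoining.  Consequently:

- Pure subdiffusion shows a slow power-law survival tail (fitted magnitude
  ≈ 0.4 over 1–10 h) from the compact first-passage return of partner
  ends, and essentially zero dicentrics — directed transport is required
  for inter-chromosomal misrepair, which the dicentric dose–response
  contrast demonstrates.
- The full heterogeneous model *plateaus* in the 1–10 h window
  (|slope| ≈ 0.02): a ~1 µm run separates a pair far beyond the 25 nm
  capture radius, and re-encounters are density-limited.  An inverse-
  power-law (t⁻¹-like) survival decay over hours therefore is **not**
  reproduced under these synthetic-damage conditions; reaching the t⁻¹
  annihilation regime needs k·n·t ≫ 1 inside the window, i.e. orders of
  magnitude higher local end density (realistic track cores) and/or
  recruitment kinetics with slow hour-scale processing states.  The
  corresponding acceptance test records this as an expected failure of
  the study conditions, not of the integrator: the same engine in the
  Brownian benchmark (below) reproduces its t⁻¹ law cleanly.

Passing tests therefore validate the motion statistics, the switching
process, the reaction bookkeeping and the benchmark kinetics — not the
absolute repair half-times of any real cell line.

## Numerical choices and problem sizes

- FFT lengths are padded to the next power of two; padding is discarded.
- The eligibility pre-sampling (geometric sums) replaces per-step state
  updates in the bulk driver; the public `step_repair_states` implements
  the per-step form and the two are equivalent in distribution.
- Neighbor search uses a per-step counting-sort cell list with
  ~cbrt(5m) cells per axis (never narrower than the capture radius);
  candidate pairs are sorted by (distance, id, id) and joined greedily.
- The Brownian annihilation benchmark uses 2000 ends in a reflecting
  R = 1000 nm sphere with D = 2000 nm²/s, dt = 1 s, 2000 s, 50 repeats:
  this places the last decade of the run deep in the asymptotic regime
  (k·n·t ≫ 1) where the fitted slope of S(t) is ≈ −0.95.
- The survival-decay run uses 1 Gy, dt = 1 s, 24 h, 50 repeats; the
  dose–response suite uses doses {1, 3, 6} Gy at dt = 4 s, 50 repeats per
  dose and model.  The circulant sampler is exact on any grid, so a
  coarser dt only coarsens contact detection (per-step relative
  displacement ~22 nm vs the 25 nm capture radius at dt = 4 s).
- Power-law fits are unweighted least squares on (log x, log y) within an
  explicit window; survival fits exclude grid points where mean S has
  reached zero.  The survival fit window defaults to 1–10 h, after the
  fast partner-rejoining transient.
- Degenerate inputs: zero DSBs reports S ≡ 1 with a warning; zero noise
  intensity yields exactly constant trajectories; an absorbing switching
  state (rate 0) yields a single phase.

## Limitations

- No polymer-chain coupling between the two ends of a break or along
  chromatin (Rouse-type physics), no TAD sub-compartments, no
  hydrodynamics: ends are independent walkers after induction.
- Directed runs have memoryless isotropic directions; real repair-center
  or periphery-directed transport is more organized, so the model likely
  overestimates dispersal per unit active time.
- Recruitment kinetics is a two-stage ladder with literature-scale but
  uncalibrated rates; resection, alternative end joining, homologous
  recombination and cell-cycle dependence are out of scope.
- Dicentric counting is event-based; rings/translocations and full
  karyotype reconstruction are not modelled.
- The SDD reader/writer covers a minimal dialect (header + DSB records
  with position, chromosome, genomic locus), not the full standard.
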