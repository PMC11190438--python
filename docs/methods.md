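# Methods

## The model

`her6osc.grid_model` simulates the expression of Her6 — a short-lived bHLH
repressor that autoinhibits its own transcription with a delay — in single
cells and in tissues coupled by Notch–Delta lateral inhibition. Per cell
(i, j) on a hexagonal lattice:

    dm/dt = α_m · H(p(t−τ_auto); P0_auto, n_auto) · H(⟨p⟩(t−τ_LI); P0_LI, n_LI) − μ_m m + η_m
    dp/dt = α_p m − μ_p p + η_p

with the repressive Hill function H(x; P0, n) = 1/(1+(x/P0)^n) and ⟨p⟩ the
mean protein over the cell's hexagonal neighbours. The uncoupled variant
clamps the lateral-inhibition factor to 1; a 1×1 lattice under coupling does
the same (no signal received), so the coupled model reduces exactly to the
single-cell model in that limit. Destabilisation of the protein (e.g. by a
PEST-domain fusion) is modelled as a multiplicative increase of μ_p only.

Noise follows the chemical Langevin convention: each increment is Gaussian
with variance equal to the summed production and degradation propensities
times dt, so halving dt leaves stationary variances unchanged. Integration
is Euler–Maruyama with delayed states read from the stored trajectory at the
nearest grid time; delays must sit within dt/2 of a grid multiple or the
simulator raises. Negative excursions are clipped to zero and counted
(`SimulationResult.clip_count`), the standard chemical-Langevin safeguard;
a nonzero clip rate flags a regime where the Langevin approximation is
strained.

Numerical choices: one counter-based Philox generator per simulation (seed
recorded in the result, trajectories bit-for-bit reproducible); initial
history is constant on [−max τ, 0] with per-cell levels drawn uniformly in
0.5–1.5 × the uncoupled deterministic fixed point, which avoids artificial
lattice synchrony while keeping the discard-first-half burn-in meaningful.
The hexagonal adjacency uses the odd-r offset convention with no wraparound
by default (a `periodic` flag exists); interior cells have six neighbours,
boundary cells keep only their geometric neighbours.

Default rates are an oscillation-capable reference point, not a fit:
protein half-life 11 min (μ_p = ln2/0.183 ≈ 3.78 h⁻¹), mRNA half-life
~21 min, delays 0.3 h, Hill coefficients 3–4, thresholds 1500 molecules.

## Parameter search

`her6osc.param_search` reproduces the exploration strategy: a generalised
pattern search minimising

    error(θ) = CV(protein | μ_p·1.0) − CV(protein | μ_p·1.1)

where each CV pools all cells and all time points of the last half of a
simulation. The two runs share a seed by default (common random numbers for
the contrast); each objective evaluation inside a run uses a fresh seed
derived from (master seed, run, evaluation) so the optimiser cannot overfit
a single noise realisation. Polls step ±mesh along each transformed
coordinate (log10 for rates and thresholds, linear for Hill coefficients and
delays), the mesh doubles on success (capped at 0.5) and halves on failure,
starting at 0.25 of each range. Accepted sets must pass error < −0.25 and a
mean protein abundance > 2000 at normal degradation.

The search-space bounds are a documented stand-in (the study's exact ranges
are not available): delays 0.1–1 h so ultradian 1–3 h periods are
reachable; μ_p ∈ [1, 8] h⁻¹ and μ_m ∈ [0.5, 8] h⁻¹ (minutes-scale
half-lives); Hill coefficients 2–6; repression thresholds 10²–2·10⁴
molecules and α_m ∈ [10, 5·10⁴] h⁻¹. The synthesis and threshold upper
bounds matter jointly: the model's dynamics are invariant under a common
scaling of (α_m, P0_auto, P0_LI) while absolute abundance scales
proportionally, so the α_m range must extend far enough for the
heterogeneity-increasing regimes to have representatives above the
>2000-molecule expression floor of the acceptance filter. All bounds are
configurable.

For every accepted set, per-cell statistics are recomputed at both
degradation levels from the last half of a fresh simulation, after
resampling protein traces to the 6-min imaging cadence: median CV_t, median
permutation-thresholded wavelet period, and median periodogram coherence.

## Track statistics

- CVs use the sample (n−1) standard deviation (a `ddof` switch exposes the
  population convention). Population CV pools a whole panel; CV_t is per
  cell over time, with an option to use only the last half (used for model
  output).
- Detrending subtracts a Gaussian-kernel local *linear* smooth whose
  bandwidth is set so the smoother's half-power cut-off falls at the window
  (default 4.5 h ≈ 3× the expected period). Local linear regression passes
  polynomials of degree ≤ 1 exactly, so linear ramps go entirely into the
  trend; a 1.9 h sine is attenuated by <3%. trend + residual reconstructs
  the input to machine precision.
- Hilbert fold-change: peaks/troughs are phase crossings of the analytic
  signal of the detrended trace (snapped to the local extremum within ±2
  samples to undo discrete-grid bias); adjacent peak–trough pairs are read
  off the raw normalised trace and the maximum peak/trough ratio per track
  is reported. No complete pair → NaN, not an error.
- Coherence: untapered periodogram of the (mean-removed) trace; the DC bin
  is excluded; coherence = power within ±10% of the dominant frequency over
  total power. Records with few cycles have coarse frequency resolution, so
  near-1 coherence requires a long record.
- Wavelet period: complex Morlet CWT (`cmor1.5-1.0`; an analytic wavelet
  whose ridge period matches Morse-family estimates at this time-bandwidth)
  on 40 log-spaced periods between 0.5 h and min(6 h, half the record).
  The per-time dominant period maximises |W|²; significance is assessed
  against `n_boot` random permutations of the series (default 1000, batched
  through a single vectorised CWT), with the threshold set at the 95th
  percentile of each permuted replicate's *maximum* power over all periods
  and times. Because the dominant period is itself a maximum, a pooled
  per-point null would flag pure noise essentially always; the
  max-statistic null gives an exact 5% family-wise false-positive rate for
  exchangeable series (white-noise CWT power is close to scale-independent
  under the wavelet normalisation used, so a single global threshold is
  appropriate). Time points within one dominant period of either record
  edge are excluded from the summary mean to limit cone-of-influence bias.
- Half-life: `scipy.optimize.curve_fit` of y = plateau + (y0−plateau)e^(−kt)
  with non-negative bounds; half-life = ln2/k in minutes. A non-decaying
  track returns an unbounded half-life with a flag rather than raising.

## Oscillation calling

Each detrended, control-normalised trace is fitted with two stationary GP
covariances — OU, σ²e^(−α|τ|), and OUosc, σ²e^(−α|τ|)cos(βτ) — plus a fixed
diagonal technical-noise variance estimated as the mean variance of
detrended background tracks passed through the identical normalisation.
Hyperparameters are maximised in log space with analytic gradients
(L-BFGS-B; bounds α ∈ [0.01, 20] h⁻¹, 2π/β ∈ [0.5, 10] h; diagonal jitter
10⁻⁶σ²). Five log-spaced initialisations are screened by likelihood and the
best two polished. The statistic is LLR = 2(logL_OUosc − logL_OU) × 100/n,
normalised per 100 time points so thresholds transfer across track lengths.

The decision threshold is calibrated per dataset: aperiodic tracks are
simulated from the fitted OU models (matched grids and noise), scored the
same way, and the (1 − FDR) null quantile (FDR default 3%) becomes the
threshold. Because OU is nested in OUosc the LLR is non-negative up to
optimiser tolerance; the null distribution piles near zero with a right
tail. Periods are reported as 2π/β for called oscillators only.

## Synthetic data

The generator's defaults emulate the live-imaging study conditions: 6-min
sampling, 8–10 h tracks, oscillator period 1.9 h, peak-to-trough
fold-change 1.6 (relative amplitude a = (F−1)/(F+1)), 5% multiplicative
measurement noise on reporter and control, a stable control channel, and a
background channel at one quarter of the reporter baseline. Oscillatory and
aperiodic cells are exact multivariate-normal draws from the OUosc/OU
covariances on the sampling grid — not Euler paths — so GP recovery tests
carry no discretisation bias. A multiplicative exponential trend enforces
any requested last/first ratio, and a deterministic sine mode provides
closed-form oracles. Snapshot populations sit on a jittered cubic lattice;
intensities are affine in a smooth squared-exponential Gaussian random
field whose length-scale is chosen so the field correlation at one lattice
spacing equals |ρ|, sign-flipped on the lattice chequerboard for negative
ρ. The field varies across the snapshot, so the within-snapshot sample
correlation over nearest-neighbour pairs concentrates around ρ, spanning
locally-similar (ρ ≈ +0.9) to salt-and-pepper (ρ < 0) regimes.

What the generators do **not** emulate: cell division and track splitting,
photobleaching, z-depth intensity gradients, missing time points, non-Gaussian
detector noise, and spatially structured backgrounds. Passing recovery
tests therefore demonstrates correctness of the estimators under matched
models, not robustness to every imaging artefact.

## Problem sizes used in the shipped checks

The acceptance checks run the search at a reduced scale chosen as a
desk-scale experiment: 200 optimiser runs × 50 evaluations on a 6×4 lattice
with 30 h simulations (the study-scale run, 6000 × 500 on 10×6 × 100 h, is
reachable through the same API and config). Oscillation-calling calibration
uses 2000 pure-OU tracks and a 300-track 30% mixture with 1000-track null
calibrations; wavelet summaries inside the search use 200 permutations per
track. These sizes are stated here so results can be reproduced exactly.

## Known limitations

- The pattern search is stochastic; at the reduced budget the number of
  accepted parameter sets for the coupled model is small (order 1–10) and
  seed-dependent, while the uncoupled model yields none — the contrast, not
  the count, is the reproducible object.
- Under the stand-in parameter ranges the reduced-budget search finds its
  heterogeneity increases mostly in slow (3–6 h) lateral-inhibition
  patterning regimes. There, destabilising the protein reliably raises
  single-cell amplitude (median CV_t up, e.g. 0.77 → 0.94 pooled over
  accepted sets) with a stable period, but median spectral coherence stays
  flat or dips slightly rather than rising: the destabilised dynamics are
  larger but marginally broader-band. Individual accepted sets in faster
  regimes do show the coherence increase at full simulation scale. A
  reproduction of the coherence shift as a *median* effect appears to
  require the original exploration ranges (which concentrate accepted sets
  in ultradian regimes) and the full 6000 × 500 search budget.
- The OU null for false-discovery calibration shares the real pipeline's
  mild model mismatch (measurement noise estimated from background, not
  fitted), so realised false-positive rates can sit slightly above the
  nominal FDR, as observed for the technical-control channel in tissue.
- Wavelet significance uses whole-track permutation, which destroys
  autocorrelation as well as periodicity; strongly autocorrelated aperiodic
  signals can occasionally exceed the null bound.
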