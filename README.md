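# her6osc

Stochastic delayed-feedback modelling of **Her6** expression and a complete
single-cell fluorescence time-series analysis pipeline.

Her6 (the zebrafish orthologue of HES1) is a short-lived transcriptional
repressor that inhibits its own transcription with a delay, producing
ultradian (1–3 h) protein oscillations in neural progenitors. This package
asks a quantitative question about that system: *under what circumstances
does destabilising the protein — shortening its half-life, as a PEST-domain
fusion does — increase expression heterogeneity across a tissue?* It
provides:

- **`grid_model`** — a delay-SDE model of coupled Her6 dynamics. Per cell
  (i,j) on a hexagonal lattice:

  ```
  dm/dt = α_m · H_auto(p(t−τ_auto)) · H_LI(⟨p⟩(t−τ_LI)) − μ_m m + η_m
  dp/dt = α_p m − μ_p p + η_p,     H(x; P0, n) = 1 / (1 + (x/P0)^n)
  ```

  where ⟨p⟩ is the mean protein of the hexagonal neighbours (Notch–Delta
  lateral inhibition) and η_m, η_p are chemical-Langevin noise terms scaled
  by the square root of the reaction propensities. Integration is
  Euler–Maruyama (numba-accelerated); the uncoupled single-cell variant
  sets H_LI ≡ 1.
- **`param_search`** — a generalised pattern search minimising
  `error(θ) = CV(p | μ_p·1.0) − CV(p | μ_p·1.1)`, i.e. hunting parameter
  regimes where a 10% increase in protein degradation raises population
  heterogeneity; accepted sets need `error < −0.25` and mean protein
  > 2000.
- **`summary_stats`** — population CV and per-cell CV_t, relative trend
  ratios, control-channel normalisation, 4.5 h Gaussian local-linear
  detrending, Hilbert peak-to-trough fold-change, periodogram coherence,
  Morlet-wavelet dominant periods with a permutation null, and one-phase
  decay half-life fits.
- **`oscillation_gp`** — oscillatory vs aperiodic classification by
  comparing OU (`σ²e^{−α|τ|}`) and OUosc (`σ²e^{−α|τ|}cos βτ`)
  Gaussian-process covariance fits; the log-likelihood ratio is thresholded
  against a synthetic aperiodic null at a target FDR (default 3%), with
  technical noise calibrated from background tracks.
- **`neighbour_analysis`** — nearest-neighbour pairing of 3D nuclear
  snapshots, paired intensity correlations and ordered high/low ratios,
  background-thresholded positive fractions, persistent close-pair
  selection (< 15 µm mean distance).
- **`synthetic_data`** — ground-truth generators for every stage: OU/OUosc
  tracks at the 6-min imaging cadence, trends, background channels, decay
  chases, and 3D populations with a tunable neighbour correlation ρ
  (negative ρ = "salt-and-pepper" interspersion).

See `docs/methods.md` for model assumptions, parameter defaults and
numerical choices.

## Worked example

Classify a synthetic population (30% noisy oscillators at a 1.9 h period
among aperiodic cells) and recover the mixture:

```python
from her6osc import synthetic_data as sd, oscillation_gp as og

tracks, labels = sd.generate_tracks(sd.TrackGeneratorSpec(
    n_cells=60, fraction_oscillatory=0.3, period_h=1.9, seed=3))
background = sd.generate_background_tracks(seed=4)
calls, percent, calib = og.classify_tracks(tracks, background,
                                           target_fdr=0.03, n_synth=200,
                                           seed=5)
print(f"{percent:.0f}% oscillatory, LLR threshold {calib.threshold:.2f}")
hit = calls.merge(labels, on="cell_id")
print("power:", hit[hit.oscillatory].is_oscillatory.mean(),
      " false-positive rate:", round(hit[~hit.oscillatory].is_oscillatory.mean(), 3))
```

```
30% oscillatory, LLR threshold 2.78
power: 0.9444444444444444  false-positive rate: 0.024
```

The classifier recovers the planted 30% fraction: 94% of true oscillators
are called (LLR above the null threshold) while only ~2% of aperiodic
cells are falsely flagged, inside the 3% FDR budget.

Simulate the coupled lattice model and watch heterogeneity respond to
protein destabilisation:

```python
from her6osc.grid_model import ModelParams, simulate

# a parameter set accepted by the reduced-budget pattern search
theta = dict(alpha_m=35527.5, alpha_p=40.0, mu_m=2.9, mu_p=1.3,
             P0_auto=2824.4, n_auto=3.3, tau_auto=0.6,
             P0_LI=566.3, n_LI=3.6, tau_LI=0.1)
for coupled in (True, False):
    for mult in (1.0, 1.1):
        res = simulate(ModelParams(**theta, degradation_multiplier=mult,
                                   coupled=coupled,
                                   rows=6, cols=4, t_end=30.0, seed=2))
        p = res.p[:, res.p.shape[1] // 2:]      # dynamic equilibrium only
        print(f"coupled={coupled} x{mult}: mean protein {p.mean():7.0f}   "
              f"population CV {p.std(ddof=1)/p.mean():.2f}")
```

```
coupled=True x1.0: mean protein    2717   population CV 1.00
coupled=True x1.1: mean protein    3276   population CV 1.26
coupled=False x1.0: mean protein   12122   population CV 0.46
coupled=False x1.1: mean protein   13153   population CV 0.53
```

With lateral inhibition, a 10% increase in the protein degradation rate
raises the pooled population CV by ~0.26 — the lattice moves deeper into a
salt-and-pepper patterning regime, so destabilising the repressor makes the
tissue markedly *more* heterogeneous. The same parameter vector without
coupling responds far more weakly (+0.07), which is the modelling contrast
the pattern search quantifies.

## Command line

```sh
her6osc synth tracks --out data/               # synthetic tracks + truth
her6osc analyse-tracks --tracks data/tracks.csv --out stats/
her6osc oscillations --tracks data/tracks.csv --background data/background.csv --out calls/
her6osc simulate --config model.yaml --out sim/ --seed 1
her6osc optimise --runs 200 --max-evals 50 --out search/ --seed 1
her6osc neighbours --snapshot snap.csv --background bg.csv --out nn/
```

Every run writes a `manifest.json` (config + seed + version) so outputs are
reproducible from the manifest alone.

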