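# nucleofid

Particle-tracking microrheology of chromatin loci in live-cell nuclear
time-lapses: a tested pipeline for **rigid-body nuclear registration →
statistical spot detection → persistent-track linking → ensemble MSD
statistics**, paired with a synthetic nucleus time-lapse generator so that
every stage is verifiable by parameter recovery without any external data.

## Who this is for

Labs that track fluorescently tagged chromatin-bound probes — a TetR/TA-tagged
chromosomal array, GFP-fibrillarin in nucleoli, RFP-TRF1 at telomeres,
GFP-53BP1 at damage foci — in 2-D time-lapse movies taken at multi-minute
intervals, and want to compare the mobility of transcriptionally active,
repressed, bulk and damaged chromatin.

## The model and the statistic

The central quantity is the mean squared displacement at lag time τ,

```
MSD(τ) = ⟨ (x_{t+τ} − x_t)² + (y_{t+τ} − y_t)² ⟩ ,
```

computed per track as a time average over all overlapping pairs, then averaged
within each cell, then across cells (n = number of cells; error bars are SEM
over cells). Tracks whose MSD at the final reported lag deviates from the
ensemble mean by more than 3 sample SDs are excluded in a single pass. Groups
are compared lag-by-lag with a two-sided pooled-variance Student's t-test
(uncorrected across lags). Each ensemble curve is summarized by a power-law
fit MSD = 4·D·τ^α, where α < 1 indicates subdiffusion and D is the
generalized diffusion coefficient (µm²/min^α). Turning-angle statistics
(mean resultant length R, Rayleigh test) probe for directional persistence.

Because only intranuclear motion is meaningful, each movie is first rigidly
registered on the nucleus-counterstain channel: per-frame translation by phase
correlation, rotation about the nucleus centroid by polar correlation with a
second-moment principal-axis refinement, all frames registered against frame
0. Spots are detected per frame after background-noise calibration
(difference-of-Gaussians band-pass, sub-pixel centroid, amplitude-SNR
threshold), linked frame-to-frame by conservative nearest-neighbor
assignment, and only tracks present in **every** frame are analyzed.

The synthetic generator simulates loci as 2-D fractional Brownian motion
(Hurst H = α/2, exact circulant-embedding fGn) inside an elliptical nucleus
with superimposed rigid drift + rotation, rendered as Gaussian spots on a
noisy background. Five condition presets emulate the biology: bulk ≈ active >
repressed mobility; local damage restores repressed mobility to bulk; damage
at active loci raises mobility above bulk at late times with heavy per-cell
heterogeneity.

## Worked example

Generate and analyze the five-condition synthetic study (10 cells per
condition, 30 frames at 3-minute intervals, 128×128 px):

```
$ nucleofid demo --cells 10 --frames 30 --seed 7 --out out/demo
repressed vs bulk: 9/9 lags with p < 0.05
damaged-repressed vs bulk: 0/9 lags with p < 0.05
damaged-active-late vs bulk: 9/9 lags with p < 0.05
outputs in out/demo
```

The three lines are the study's conclusion in miniature: the repressed locus
is significantly less mobile than bulk chromatin at every lag; after local
DNA damage the repressed locus becomes statistically indistinguishable from
bulk; damage at active loci measured late shows super-bulk mobility.
`out/demo/manifest.json` records the per-group power-law fits, e.g. (same
run):

| group | α̂ | D̂ (µm²/min^α) | true preset |
|---|---|---|---|
| repressed / locus | 0.802 | 0.00094 | α=0.8, D=0.0010 |
| bulk / locus | 0.754 | 0.00252 | α=0.8, D=0.0025 |
| damaged-active-late / locus | 0.869 | 0.00404 | α=0.8, D=0.0040 |

`out/demo/` also holds the full track table, per-cell and ensemble MSD
curves with SEM, the per-lag comparison table, and a log-log MSD plot.

The stages are also available individually (`nucleofid synth / register /
detect / link / msd / validate`) and as library functions
(`nucleofid.simulate_fbm_tracks`, `nucleofid.estimate_transforms`,
`nucleofid.detect_particles`, `nucleofid.link_frames`, `nucleofid.track_msd`,
…). `nucleofid.compute_fluence(15, 600, target_area=1e-12)` reproduces the
photoactivation dosimetry: 9000 J/m² to the dish, 9 nJ to a ~1 µm² target.

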