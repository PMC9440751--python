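# morphoflight

Analysis of climbing (upward escape) flight in butterflies from stereoscopic
high-speed videography — built for comparative studies of *Morpho* species
living in different forest strata (canopy vs understory), and usable for any
flapping flyer filmed by a calibrated multi-camera rig.

The package takes manually digitized 2D pixel tracks from two or more
synchronized cameras and carries them through the complete measurement
chain:

1. **Stereo geometry** — 11-parameter direct linear transformation (DLT)
   camera calibration from wand/control points, linear triangulation, and
   wand-length diagnostics.
2. **Trajectory** — a per-axis constant-acceleration Kalman filter with
   Rauch–Tung–Striebel smoothing gives position, velocity and acceleration
   of the body centroid; digitized stroke reversals cut the track into
   wingbeats (downstroke + upstroke), each summarized by eight climb
   metrics: wingbeat frequency `f_wingbeat = 1/Δt_wingbeat`, distances
   `ΔX_hor, ΔX_ver, ΔX_total`, mean speeds `U_hor, U_ver, U_total`, and the
   climb angle `γ_climb = atan(U_ver / U_hor)`.
3. **Wing kinematics** — body yaw/pitch/roll; per-wing stroke (Φ),
   deviation (θ) and rotation (H) Euler angles measured relative to the
   stroke plane (the plane normal to the body long axis through the wing
   hinge); a rigid flat-plate blade-element model (10 spanwise elements per
   wing) giving local wing speed and angle of attack
   α ∈ [0°, 90°], plus wingbeat summaries (α_wingbeat, U_wingbeat,
   β_wingbeat, stroke amplitude A_Φ).
4. **Aerodynamics** — the weight-normalized thrust scaling
   `T/mg = ½ ρ U_wing² (S/mg) C_Tα α`, morphology ratios (weight-normalized
   wing area S/mg and its reciprocal, wing loading), steady-climb force
   balance, and the "helicopter-model" regression of climb angle on body
   pitch.
5. **Statistics** — sequential (Type-I) ANOVA with the microhabitat factor
   entered before species/individual/flight/wingbeat, MANOVA (Wilks' λ with
   Rao's F), phylogenetic ANOVA whose null F distribution is simulated by
   Brownian motion on the species tree, linear regressions, Pearson
   correlations, Wilcoxon rank-sum tests and percent group contrasts.
6. **Synthetic data** — a ground-truthed simulator (articulated body + four
   rigid wings, three-camera rig at 240 frames/s, wand calibration sets,
   hierarchical canopy/understory cohorts evolved on a seven-species
   phylogeny) so every stage is testable without any video data.

## Worked example

Simulate a climbing flight (40° climb at 1.4 m/s, 5 Hz wingbeat, 114°
stroke amplitude), film it through three orthogonal cameras with 0.5 px
digitization noise, and recover everything through the full pipeline:

```python
from morphoflight import io, pipeline

cfg = io.ProjectConfig(seed=1, outdir=None, pixel_noise_sd=0.5, n_sim=500)
res = pipeline.run_pipeline(cfg)
print([round(r, 2) for r in res.calibration_rmse])
for rec, s in zip(res.records, res.summaries):
    print(f"wingbeat {rec.wingbeat_index}: f = {rec.f_wingbeat:.1f} Hz, "
          f"U_total = {rec.u_total:.2f} m/s, gamma = {rec.gamma_climb:.1f} deg, "
          f"alpha_fore = {s.alpha_fore:.1f} deg, A_phi = {s.amplitude_fore:.1f} deg")
```

prints

```
[0.58, 0.6, 0.72]
wingbeat 0: f = 5.0 Hz, U_total = 1.40 m/s, gamma = 40.1 deg, alpha_fore = 68.0 deg, A_phi = 114.4 deg
wingbeat 1: f = 5.0 Hz, U_total = 1.40 m/s, gamma = 40.0 deg, alpha_fore = 68.0 deg, A_phi = 114.9 deg
wingbeat 2: f = 5.0 Hz, U_total = 1.40 m/s, gamma = 39.9 deg, alpha_fore = 67.9 deg, A_phi = 114.3 deg
```

The calibration reprojects at ~0.6 px (the injected pixel noise), and the
recovered wingbeat metrics sit within a fraction of a percent of the
configured truth (U = 1.40 m/s, γ = 40°, A_Φ = 114°); the wingbeat angle of
attack is recovered to a few tenths of a degree.  `res.stats_report`
carries the cohort-level ANOVA/MANOVA/phylogenetic-ANOVA tables for a
synthetic canopy/understory cohort drawn from the published group-level
summary statistics.

The same chain is available from the shell:

```bash
morphoflight simulate --outdir demo --seed 1 --pixel-noise 0.5
morphoflight calibrate --points demo/calibration_points.csv --out demo/dlt.csv
morphoflight reconstruct --points demo/digitized_points.csv --dlt demo/dlt.csv --out demo/track.csv
morphoflight wingbeats --track demo/track.csv --reversals demo/reversals.csv --out demo/wingbeats.csv
```

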