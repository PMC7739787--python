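# alpinekin

Joint-kinematics analysis of alpine ski runs: from raw goniometer and
trunk-accelerometer time series to turn segmentation, inside/outside-leg
(IL/OL) contraction-mode classification, per-cycle metrics, angle–velocity
density maps, and mixed-model statistics. A synthetic run generator with
exported ground truth makes every stage testable without athlete data.

## Pipeline

1. **signal_io** (`alpinekin.io`) — run CSV + sidecar JSON metadata;
   three-posture affine goniometer calibration (raw → degrees of joint
   extension, knee full extension ≈ 180°).
2. **filtering** (`alpinekin.filtering`) — 4th-order Butterworth low-pass,
   1 Hz cutoff, applied zero-phase (no delay at any frequency). Published
   attenuation figures are validated on the single-pass transfer function:
   −80 dB/decade rolloff, 94% amplitude reduction at 2 Hz. FFT amplitude
   spectral density and dominant ("natural") frequency estimation.
3. **segmentation** (`alpinekin.segmentation`) — resultant acceleration
   AccR = √(x²+y²+z²); turn switches = prominent local minima of the
   filtered AccR; IL/OL assignment from the knee angle with one global
   alternation vote; trimming of first/last cycles, figure spans, and
   missing-data cycles; 101-point time normalization.
4. **phase_analysis** (`alpinekin.phases`) — angular velocity by central
   differences; tripartite classification (eccentric < −20 °/s,
   quasi-isometric in the closed window [−20, +20] °/s, concentric
   > +20 °/s) and the legacy bipartite extrema partition; per-cycle
   absolute/relative durations and mean/max velocity magnitudes per mode.
5. **density_viz** (`alpinekin.density`) — bivariate angle × velocity
   occurrence grids (2.5° × 5 °/s bins), normalized per (leg, discipline),
   rendered as a discipline × leg panel matrix.
6. **stats** (`alpinekin.stats`) — REML mixed model
   `Y ~ discipline * leg + (1 | skier-session)`; Wald ANOVA; Tukey-adjusted
   pairwise contrasts of estimated marginal means; mixed-model Cohen's d
   standardized by √(ID variance + residual variance), classified
   small/medium/large at 0.20/0.50/0.80.
7. **synthetic_data** (`alpinekin.synthetic`) — keyframe half-cycle
   waveforms with a controllable quasi-isometric plateau, band-limited
   (≥2 Hz) vibration noise, and an acceleration channel whose clean
   resultant has a strict minimum at every switch; exported ground truth
   (switch times, leg labels, per-sample phase labels).

## CLI

```sh
# synthetic run + ground truth
alpinekin simulate --discipline GS --turns 20 --seed 7 --fs 148.15 \
    --out run.csv --truth truth.json

# per-cycle metrics (and optional segment table)
alpinekin analyze --run run.csv --out metrics.csv --segments-out segments.csv \
    --cutoff 1.0 --order 4 --threshold 20 --min-prominence 0.05 --min-separation auto

# figures
alpinekin plot --run run.csv --out fig_density.png --density
alpinekin plot --run run.csv --out fig_spectrum.png --spectrum

# mixed-model fit on a metrics table
alpinekin stats --metrics metrics.csv --response tri_iso_rel_pct \
    --out model.json --contrasts-out contrasts.csv
```

Metrics CSV columns: `run_id, ID, discipline, leg, cycle_number, joint,
min_angle, max_angle, turn_duration_ms`, then per partition/mode
`tri_{ecc,iso,con}_{abs_ms,rel_pct,mean_vel,max_vel}`,
`bi_{ecc,con}_{abs_ms,rel_pct,mean_vel,max_vel}`, and `bi_degenerate`.
Velocities are magnitudes (deg/s); the mode carries the sign semantics.

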