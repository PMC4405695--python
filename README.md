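# vesitrack

Quantitative analysis of intracellular transport microscopy, built for
studies of how small GTPases regulate kinesin motors (the motivating
system is Rab6A regulation of the kinesin-3 motor KIF1C).  The package
covers five analysis stages that such studies combine, plus a
synthetic-data generator with known ground truth so that every stage
is verifiable by parameter recovery:

1. **Vesicle track motion statistics** — classify single-particle
   trajectories as *confined* or *linear* by the MSD exponent
   α (slope of log MSD vs. log lag: ≈2 ballistic, ≈1 diffusive, <1
   confined); summarise confined tracks by the area of their minimal
   enclosing circle, linear tracks by mean speed
   (⟨‖Δr‖/Δt⟩ over consecutive frames), pause rate (onsets of runs
   with instantaneous speed < 0.1 µm/s, per second), and
   direction-change rate (sign flips of step projections onto the
   track's first principal axis, pauses excluded); compare conditions
   with the Wilcoxon rank-sum test.
2. **Single-molecule TIRF metrics** — microtubule length from
   skeletonised masks, motors per µm (mean per-frame on-microtubule
   spot count / length), percent moving motors (mean speed > 0.12
   µm/s AND net displacement > 0.2 µm AND duration > 0.9 s, strict),
   and lifespan statistics.
3. **Golgi fragmentation score** — per cell, the fraction of Golgi
   staining residing in segmented objects larger than an area
   threshold (presets 4.11 µm² for siRNA-rescue scoring, 2.74 µm² for
   nocodazole-treated cells), optionally normalised by the cell's
   mean marker intensity; conditions compared by Welch's t-test.
4. **Colocalization and expression QC** — Pearson r between two
   channels over mask objects; background-subtracted total cell
   intensity.
5. **Equilibrium binding fits** — one-site saturation
   S(L) = B·L/(K_D + L) for pull-down titrations and microtubule
   co-sedimentation curves, with standard errors from the fit
   covariance and delta-method K_D shift ratios.

A simple detection (local maxima + Gaussian sub-pixel interpolation)
and linking (greedy nearest-neighbour with gap bridging) path lets the
pipeline start from images as well as from spot/track tables.

## Worked example

`examples/binding_curves.py` fits the three binding regimes and
prints:

```
pull-down:        Kd = 0.93 ± 0.05 µM (true 0.90), fraction-of-maximal scale
motor domain:     Kd = 0.26 ± 0.03 µM (true 0.23)
co-sedimentation: Kd 0.44 -> 4.08 µM, shift = 9.4 ± 1.1 fold (true 10)
```

Each line is a fit to simulated data with 5% multiplicative noise; the
fitted K_D (concentration at half-maximal binding) recovers the
simulation's true value within its standard error, and the K_D shift
between the paired co-sedimentation curves — the signature of a
competitor blocking the motor's microtubule binding site — is
recovered with a delta-method error bar.

The other scripts in `examples/` walk through the remaining stages:
vesicle motion statistics with a two-condition rank-sum comparison,
the full TIRF detect→link→metrics chain (printing motors/µm, percent
moving, and median lifespan per condition), Golgi fragmentation
scoring of intact vs. dispersed populations, and a configured
end-to-end pipeline run with its reproducibility manifest.

## Command line

A thin CLI mirrors the library:

```sh
vesitrack simulate --seed 1 --outdir out        # synthetic tracks
vesitrack detect stack.tiff --threshold 60      # spot detection
vesitrack link spots.csv --max-disp 0.3         # greedy linking
vesitrack motion out/tracks.csv                 # per-track reports
vesitrack tirf spots.csv mask.tiff              # motor assay metrics
vesitrack golgi golgi.tiff marker.tiff --preset sirna
vesitrack bind binding.csv --normalize
vesitrack accept --seed 0                       # recovery self-checks
vesitrack run --config cfg.yaml                 # configured pipeline
```

All parameters live in a validated YAML config with named presets
(vesicle frame interval 2 s; TIRF 0.041 s; pause threshold 0.1 µm/s;
moving-motor thresholds 0.12 µm/s / 0.2 µm / 0.9 s; Golgi area
thresholds 4.11 / 2.74 µm²); unknown keys are rejected by name, and
every run writes a manifest sufficient to regenerate its outputs.

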