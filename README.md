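# kinetocoloc

Quantification of protein recruitment to kinetochores in two-channel 3D
time-lapse fluorescence microscopy, plus the fixed-cell colocalization
statistics and NEBD-normalized kinetics that accompany such experiments.

The target users are cell biologists studying the spindle assembly
checkpoint: cells carry a kinetochore marker (e.g. RFP670-MIS12, ~46
diffraction-limited spots per nucleus) and a signal channel (e.g.
Ruby-MAD2) whose kinetochore-bound fraction rises around nuclear
envelope breakdown (NEBD). Because raw movies of this kind are rarely
shareable, the package includes a synthetic-movie generator with exact
ground truth, so every stage of the measurement chain can be validated
end to end.

## The statistic

Per frame, each channel is resliced in z to isotropic voxels and
smoothed with a Gaussian (σ = 1 voxel). Kinetochores are segmented from
the marker channel by thresholding at 1.08 × the Otsu threshold and
removing speckle with a morphological opening (radius-1 voxel cube).
The reported value is

```
coloc(t) = mean(signal | spots) / mean(signal | shell),
```

where the shell is every nuclear voxel 1–15 voxels (Euclidean) from the
nearest spot voxel — i.e. the kinetochore signal scaled to the level of
the protein in the rest of the nucleus. 1 means no enrichment; R means
R-fold enrichment. Times are minutes relative to NEBD (an input, never
detected); traces from many cells aggregate as mean ± SEM per time
point.

Fixed-cell measures: a Costes-style auto-thresholded colocalization
percentage on a maximum-projection ROI (default 4.2 µm²), and a 1D
profile-overlap percentage ∫min(a,b)/∫a along a line ROI (default 6 µm)
at the nuclear envelope. Kinetics: per-cell fluorescence normalized to
its value at NEBD, averaged as mean ± SD, with a self-contained
Mann–Whitney U test (exact null for small samples) for timing
comparisons. Details and design rationale: [docs/methods.md](docs/methods.md).

## Worked example

```python
from kinetocoloc import SyntheticParams, analyze_movie, generate_movie

params = SyntheticParams(n_frames=8, nebd_frame=4, enrichment_ratio=3.0, seed=2)
movie, truth = generate_movie(params)
trace = analyze_movie(movie, marker_channel="MIS12", signal_channel="MAD2")
```

(`examples/02_segment_and_trace.py`) prints:

```
t_rel_NEBD  measured  true  mask_vox  shell_vox  flag
        -8     2.177  2.17      3212      40486  ok
        -6     2.420  2.41      3168      40251  ok
        -4     2.522  2.52      3232      40011  ok
        -2     2.572  2.57      3248      39900  ok
         0     2.587  2.59      3247      39840  ok
         2     2.596  2.60      3223      40188  post-nebd
         4     2.593  2.60      3237      39844  post-nebd
         6     2.591  2.60      3286      39996  post-nebd
```

`measured` is the scaled colocalization recovered by the full pipeline
from the noisy movie; `true` is the generator's ground-truth enrichment
1 + f(t)·(R−1) as the recruited fraction f rises through NEBD toward its
plateau. The two agree to ~1% at every frame here. `mask_vox` and
`shell_vox` record how many voxels entered each mean; frames after NEBD
are flagged because the nucleus-mask heuristic is a pre-NEBD construct.

The other scripts in `examples/` cover movie generation and OME-TIFF
output, cohort contrasts (early vs late recruitment onset), fixed-cell
percentages, and profile/kinetics statistics. A thin CLI mirrors the
library (`kinetocoloc simulate | segment | coloc3dt | fixed-coloc |
profile | kinetics | run`); `kinetocoloc run --config pipeline.yaml`
executes multi-step configs and writes a reproducibility manifest.

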