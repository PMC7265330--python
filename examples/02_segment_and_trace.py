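"""Run the full 3D+T quantification on a synthetic movie.

Per frame: reslice to isotropic voxels, smooth (sigma = 1 voxel), segment
the marker with a 1.08-scaled Otsu threshold plus opening, build the
1-15 voxel background shell inside the nucleus, and report the mean
signal in the spots scaled to the shell mean.
"""

from kinetocoloc import SyntheticParams, analyze_movie, generate_movie

params = SyntheticParams(n_frames=8, nebd_frame=4, enrichment_ratio=3.0, seed=2)
movie, truth = generate_movie(params)

trace = analyze_movie(movie, marker_channel="MIS12", signal_channel="MAD2", cell_id="demo")

print("t_rel_NEBD  measured  true  mask_vox  shell_vox  flag")
for i in range(movie.n_frames):
    print(f"{trace.t_rel_nebd[i]:10.0f}  {trace.value[i]:8.3f}  "
          f"{truth.true_enrichment[i]:4.2f}  {trace.n_mask_voxels[i]:8d}  "
          f"{trace.n_shell_voxels[i]:9d}  {trace.flags[i]}")
# 'measured' ~ 1 means no enrichment over the nuclear pool; values track
# the ground-truth enrichment as recruitment rises through NEBD.
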