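"""Robustness of conserved control paths to edge-weight noise.

Adds Gaussian noise to every edge weight of a synthetic multilayer
network (scaled down to n=300 for speed) and re-runs the detection.  The
default objective uses only conservative weights — topology — so the CV
and the control paths are exactly unchanged; with the optional
weight-tie-break mode, noise can flip ties between equally conserved
matchings, and the per-layer edge overlap quantifies how little changes.
"""

from copath import SyntheticSpec
from copath.experiments import sweep_noise

base = SyntheticSpec(n_layers=5, n_nodes=300, n_edges=450, p_common=0.9)

df = sweep_noise(sigmas=(1.0, 25.0), base_spec=base, n_reps=3, seed=7)
print("default objective (weights ignored):")
print(df.groupby("sigma")[["cv_clean", "cv_noisy", "overlap"]].mean().round(4))

df_tb = sweep_noise(sigmas=(1.0, 25.0), base_spec=base, n_reps=3, seed=7,
                    use_weight_tiebreak=True)
print("\nweight-tie-break mode (noise can flip ties):")
print(df_tb.groupby("sigma")[["cv_clean", "cv_noisy", "overlap"]].mean().round(4))

# overlap = median per-layer Jaccard of control-path edges before/after
# noise: exactly 1.0 in the default mode, slightly below 1 with tie-breaks.
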