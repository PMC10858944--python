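"""Full pipeline in one call: mask design → PSF simulation → cortex phantom →
trial simulation → FISTA reconstruction → orientation analysis.

Runs a small configuration (48 px phantom, 1 trial per condition) and prints
the per-stage timings and the recovered-vs-planted map correlation.
"""

import json

from contourscope.config import RunConfig, run_pipeline

cfg = RunConfig(seed=7, out_dir="scratch/example_run")
cfg.mask.shape = 96
cfg.mask.n_iter = 10
cfg.phantom.shape = 48
cfg.phantom.trials_per_condition = 2
cfg.phantom.blank_trials = 2
cfg.simulate.psf_crop = 16
cfg.reconstruct.max_iter = 5

summary = run_pipeline(cfg)
print(json.dumps({k: v for k, v in summary.items()
                  if k in ("config_digest", "mask_fidelity", "timings",
                           "pref_map_vs_planted_r")}, indent=1, default=str))
print("pref_map_vs_planted_r is the correlation between the recovered and "
      "planted orientation maps after the full optical round trip; at this "
      "tiny scale it is noisy but clearly positive.")
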