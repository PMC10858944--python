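"""Orientation-column mapping on a synthetic cortex.

Generates a cortical phantom with ~1.2 cycles/mm orientation columns,
simulates flashed-grating trials (6 orientations at 4 Hz, 10 repeats plus
blanks, heartbeat artifact and shot noise), runs the analysis chain (blank
subtraction → trial averaging → 4 Hz harmonic maps → spatial bandpass →
vector-summation composite) and compares the recovered preferred-orientation
map with the planted one.
"""

import numpy as np

import contourscope as cs

phantom = cs.make_cortex_phantom((96, 96), seed=5)
protocol = cs.StimulusProtocol()

videos, labels = [], []
k = 0
for cond in list(protocol.orientations) + ["blank"]:
    for _ in range(protocol.trials_per_condition):
        k += 1
        vid = cs.generate_trial_video(phantom, protocol, cond,
                                      noise={"heartbeat_amp": 0.01}, seed=k)
        videos.append(cs.add_sensor_noise(vid, 1000.0, 0.0, seed=10_000 + k,
                                          quantize=False))
        labels.append(cond)

trials = cs.TrialSet(np.stack(videos), labels, frame_rate=protocol.frame_rate,
                     onset_frame=protocol.onset_frame,
                     pixel_pitch_obj=phantom.pixel_pitch_obj)
maps = cs.orientation_pipeline(trials)

print("pairwise map correlation vs orientation difference:")
for d, c in zip(maps.corr_deltas, maps.corr_curve):
    print(f"  {d:5.0f} deg: r = {c:+.3f}")
print("(positive at 30 deg, most negative at 90 deg — the signature of "
      "orientation columns)")

r = cs.compare_maps(maps.pref_map, phantom.pref_map, maps.roi_mask)
print(f"recovered vs planted preferred-orientation map: r = {r:.3f}")

null = cs.shuffle_null_trials(maps.trial_coefs, maps.trial_labels,
                              phantom.pref_map, n_shuffles=200, seed=1,
                              roi_mask=maps.roi_mask,
                              pixel_pitch_obj=phantom.pixel_pitch_obj)
print(f"trial-label shuffle null: mean {null.mean:+.3f}, max {null.max:.3f} "
      f"— the actual map beats every shuffle")
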