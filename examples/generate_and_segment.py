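"""Generate one synthetic deep-squat trial and locate its active span.

The generator plants the movement in t = [2, 6] s of a 10 s recording; the
segmenter finds it from the nine per-sensor difference signals (1 skeleton
centroid + 4 gyro + 4 accel) and fuses the spans by earliest-start /
latest-end.
"""

from mmhar import BehaviorLabel, generate_trial, segment_trial

trial, truth = generate_trial(BehaviorLabel.DS, user_height=1.62, seed=7)
segment = segment_trial(trial)

t0, t1 = truth["active_window"]
print(f"true active window : [{t0:.3f}, {t1:.3f}] s")
print(f"fused segment      : [{segment.t_start:.3f}, {segment.t_end:.3f}] s")
print("per-sensor spans:")
for span in segment.contributing:
    print(f"  {span.source:>9}: [{span.t_start:.3f}, {span.t_end:.3f}] s")
print(
    "\nThe fused boundaries sit within two sample intervals of the planted"
    " window; each sensor's span is detected at 5 % of its own peak"
    " difference, so the rule needs no absolute calibration."
)
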