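# mmhar — multimodal human behavior recognition

`mmhar` classifies whole-body behaviors (pitching, bat swinging, stretches,
lunges, squats, walking variants, coffee pouring — 10 classes) from two
sensing modalities recorded together: a depth-camera skeleton stream
(25 Kinect-V2 joints per frame) and four body-worn IMUs (3-axis gyroscope +
3-axis accelerometer at each elbow and ankle).  It is aimed at movement
analysis and activity-recognition work where several cheap sensors are
fused at the *decision* level rather than by feature concatenation.

## Method

**Segmentation.** Each trial contains one behavior embedded in an idle
recording.  For the camera, the per-frame centroid
`c_t = (1/25) Σ_i j_{t,i}` yields a difference signal
`C_{d,t} = ‖c_t − c_{t−1}‖`; each IMU channel yields
`G_{d,t,k} = ‖g_{t,k} − g_{t−1,k}‖` and `A_{d,t,k} = ‖a_{t,k} − a_{t−1,k}‖`.
Steps where a signal exceeds 5 % of its own maximum mark movement; the nine
per-sensor spans are fused by earliest start / latest end.

**Skeleton features.** Per frame, joints are normalized
`j′_{t,i} = (j_{t,i} − j^{SR}_t) / h_t` (SHOULDER_RIGHT origin, body height
`h_t` = HEAD to foot-midpoint distance) and projected onto a body-attached
basis: shoulder vector `S_t`, foot vector `F_t`, and normal
`N_t = S_t × F_t`, each unit-normalized.  The feature row per joint is
`f_{t,i} = (⟨N_t, j′_{t,i}⟩, ⟨F_t, j′_{t,i}⟩, ⟨S_t, j′_{t,i}⟩)`; resampling
the segment to T = 60 frames gives a T×25×3 spatio-temporal cube, flattened
to a T-step sequence of 75-vectors.  These features are invariant to user
stature, global translation and global rotation.

**Inertial features.** The fused segment is split into M = 6 equal windows;
per window, sensor and axis the features are mean, population standard
deviation and variance, giving an M-step sequence of 36-vectors per channel
(gyro, accel).

**Classification and fusion.** One classifier per modality: an LSTM
(32 hidden units, dense/sigmoid head of size 10) on the feature sequences,
or an SVM baseline on the full concatenation.  The three decisions are
fused by majority vote; three-way disagreements fall to the modality with
the largest top-1 score margin (fallback priority ACCEL > DEPTH > GYRO).
Evaluation is a stratified 30 % hold-out with per-class confusion matrices;
"average accuracy" is the mean of per-class accuracies.

The original recordings behind this design are not public, so the package
ships a synthetic trial generator (`mmhar.synthetic`) that reproduces the
dataset's structure — 10 behaviors × 10 users × 10 repetitions, body
heights in 1.29–1.80 m, 30 Hz skeleton / 100 Hz IMU streams, one active
window per trial — with hand-crafted, class-distinct motion templates.

## Worked example

```
$ python examples/generate_and_segment.py
true active window : [2.000, 6.000] s
fused segment      : [2.010, 6.000] s
```

The segmenter finds the planted movement window to within one 100 Hz IMU
sample.  Training and fusing on a small 5-class dataset:

```
$ python examples/fusion_evaluation.py
clean data, average accuracy (mean of per-class accuracies):
  DEPTH:  93.33 %
   GYRO: 100.00 %
  ACCEL: 100.00 %
  FUSED: 100.00 %

gyro degraded with heavy white noise:
  DEPTH:  20.00 %
   GYRO:  16.67 %
  ACCEL: 100.00 %
  FUSED:  83.33 %
```

With clean data every modality separates the classes and the fused vote is
perfect.  Drowning the gyroscopes in noise collapses that modality to
chance, yet the fused decision stays far above it — the vote lets intact
modalities outvote a broken one.

The same pipeline is scriptable from a shell:

```
mmhar simulate --out data --seed 7
mmhar evaluate data/manifest.jsonl --report report.json --seed 7
mmhar report report.json
```

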