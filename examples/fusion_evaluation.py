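"""Train per-modality LSTMs on a small synthetic dataset and fuse decisions.

Runs the stratified 30 % hold-out protocol on 5 behaviors x 4 users x 5
repetitions (100 trials) at a reduced epoch count, then repeats it with the
gyroscopes drowned in noise to show decision-level fusion compensating for
one bad modality.
"""

from mmhar import (
    BehaviorLabel,
    ClassifierConfig,
    GeneratorConfig,
    ModalityId,
    degrade_modality,
    evaluate,
    generate_trials,
)

cfg = GeneratorConfig(
    n_users=4,
    n_repetitions=5,
    behaviors=(BehaviorLabel.BP, BehaviorLabel.DS, BehaviorLabel.LS, BehaviorLabel.NW, BehaviorLabel.CP),
    seed=3,
)
dataset = generate_trials(cfg)
configs = {m: ClassifierConfig(epochs=80) for m in ModalityId}

print(f"{len(dataset)} trials, 30 % held out per class\n")
reports, fusion = evaluate(dataset.trials, configs, seed=3)
print("clean data, average accuracy (mean of per-class accuracies):")
for m in ModalityId:
    print(f"  {m.name:>5}: {reports[m].average_accuracy:6.2f} %")
print(f"  FUSED: {fusion.average_accuracy:6.2f} %")

degraded = degrade_modality(dataset, ModalityId.GYRO, extra_noise_sd=10.0, seed=3)
dreports, dfusion = evaluate(degraded.trials, configs, seed=3)
print("\ngyro degraded with heavy white noise:")
for m in ModalityId:
    print(f"  {m.name:>5}: {dreports[m].average_accuracy:6.2f} %")
print(f"  FUSED: {dfusion.average_accuracy:6.2f} %")
print(
    "\nThe gyro classifier collapses toward the 20 % chance level of this"
    " 5-class setup, yet the fused vote stays far above the broken"
    " modalities because decisions, not features, are combined.  Note that"
    " heavy gyro noise also widens the fused segment to the whole recording,"
    " which at this tiny training size costs the depth model accuracy too;"
    " on the full 1000-trial dataset (scripts/acceptance.py) depth stays"
    " above 99 % and fusion matches the best single modality."
)
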