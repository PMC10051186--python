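"""Train the multi-view environment classifier and post-process its output.

One first-level learner per sensor channel (15-minute trailing windows),
a meta-learner on the concatenated (class, probability) outputs, grouped
train/test split by participant, then GPS stop segmentation + the 2-5 a.m.
home rule + label smoothing.

Takes a couple of minutes: it simulates, curates and classifies six
participant-weeks.
"""

from wearaq.pipeline import run_campaign

result = run_campaign(n_participants=6, duration_days=5.0, n_train=4, seed=1)

print(f"held-out minute accuracy (model):        "
      f"{result.raw_eval['accuracy']:.1%}")
print(f"held-out accuracy after post-processing: "
      f"{result.post_eval['accuracy']:.1%}")
for pid, accs in result.per_participant.items():
    print(f"  {pid}: raw {accs['raw']:.1%} -> post {accs['post']:.1%}")
print("per-class recall (model):")
for env, rec in result.raw_eval["per_class_recall"].items():
    print(f"  {env:<10} {rec:6.1%}")
# The rule-based post-processing should never lower the accuracy; the
# largest gains come from cleaning scattered errors inside long stops.
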