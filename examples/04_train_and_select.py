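"""Train per-class IC classifiers and pick the best family per class.

Generates a labeled synthetic dataset, extracts features, validates
logistic regression / gradient boosting / linear SVM with repeated
stratified 70/30 splits, and applies the balance-aware selection rule:
ROC-AUC decides for balanced classes, PR-AUC for rare ones.
"""

from eegic import (GeneratorConfig, TaskSpec, extract_features, fit_final,
                   generate_dataset, labels_from_truth, predict,
                   repeated_split_validate, select_model)

counts = {"brain": 30, "alpha": 15, "mu": 15, "eyes_blink": 8,
          "eyes_horizontal": 7, "muscle": 15, "heart": 15,
          "channel_noise": 10}
dataset, truth = generate_dataset(GeneratorConfig(counts=counts, seed=1))
features = extract_features(dataset)
labels = labels_from_truth(truth)

report = None
for cls in ("Brain", "Eyes", "Muscle"):
    part = repeated_split_validate(
        features, labels, TaskSpec(class_name=cls, n_repeats=10, seed=0))
    report = part if report is None else report.merge(part)

print(report.summary().round(3).to_string(index=False))
selection = select_model(report)
print(f"\nselected families: {selection}")
print("positive fractions:",
      {k: round(v, 2) for k, v in report.positive_fraction.items()})

models = {cls: fit_final(features, labels, cls, family, seed=0)
          for cls, family in selection.items()}
flags = predict(models, features).flags
print(f"\ncomponents flagged per class:\n{flags.sum().to_string()}")
print("\nMean ROC-AUC above 0.9 for every class indicates the features"
      "\nrecover the class structure; flags are independent per class.")
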