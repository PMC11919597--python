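"""Train the capsule classifier on synthetic motif-planted windows.

Generates a balanced benchmark (strong planted GGG/CU/UC signal around
positives), makes the stratified 8:2 split, trains the desk-scale network
and reports the standard evaluation metrics on the held-out test split.
"""

import warnings

import capm7g as c

warnings.filterwarnings("ignore")  # early epochs can have undefined MCC

spec = c.SyntheticSpec(n_per_class=100, seed=0, signal_strength="strong")
windows, _ = c.generate(spec)
split = c.split_dataset(windows, seed=0)

config = c.CapsuleNetConfig.scaled(seed=0)
settings = c.TrainSettings(epochs=25, seed=0)
result = c.train(split.train, split.test, config, settings)

report = c.evaluate(c.predict(result.trained, split.test))
print(f"best epoch (validation MCC): {result.best_epoch}")
print(f"accuracy    : {report.accuracy:.3f}")
print(f"recall      : {report.recall:.3f}")
print(f"specificity : {report.specificity:.3f}")
print(f"F1          : {report.f1:.3f}")
print(f"MCC         : {report.mcc:.3f}")
print(f"ROC AUC     : {report.roc_auc:.3f}")
print(f"PR AUC      : {report.pr_auc:.3f}")
# Meaning: with a strong planted motif signal the capsule net separates
# modified from unmodified central guanosines nearly perfectly; with
# motif_set=[] (no signal) all of these fall to chance.
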