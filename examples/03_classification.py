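"""Train and compare the 1D CNN against LDA and SVM baselines.

Runs the full pipeline on a default synthetic library: Savitzky-Golay
smoothing, train-split z-scoring, RFE band selection (k=10), index
computation, a stratified 70/15/15 split, then training of all three
classifiers on the same features (selected bands + [MLVI, H_VSI]) and
evaluation on the held-out test split.
"""

from stresskit import RunConfig, run_pipeline

result = run_pipeline(RunConfig(seed=3))

print(f"selected bands: {sorted(int(w) for w in result.ranking.wavelengths)} nm")
print(f"feature mode:   {result.features.mode} ({result.features.length} features)\n")
print(f"{'model':>6} {'accuracy':>9} {'macro F1':>9} {'MCC':>7} {'micro AUC':>10}")
for kind in ("cnn", "svm", "lda"):
    r = result.reports[kind]
    auc = f"{r.auc_micro:.3f}" if r.auc_micro is not None else "-"
    print(f"{kind:>6} {r.accuracy:>9.3f} {r.macro_f1:>9.3f} {r.mcc:>7.3f} {auc:>10}")

print("\nAccuracy is the fraction of correct test predictions; MCC is the"
      "\nmulticlass Matthews correlation (1 = perfect, 0 = chance).  On this"
      "\ncleanly separable synthetic library all models approach the ceiling,"
      "\nwith the CNN at least matching the linear baselines.")
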