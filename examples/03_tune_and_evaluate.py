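"""Tune the SVM and evaluate it under the balanced-subset jackknife.

Builds a balanced synthetic dataset with a strong planted motif signal,
grid-searches (c, gamma) under leave-one-out, and reports Chou-form metrics.
"""

from methylsite import TrainingConfig, grid_search, jackknife_evaluate
from methylsite.synthetic import SyntheticConfig, balanced_feature_set

config = SyntheticConfig(n_proteins=100, signal_strength=0.9, seed=1)
X, y = balanced_feature_set(config, n_per_class=40, partition_seed=1)
print(f"balanced dataset: {int((y == 1).sum())} positives, "
      f"{int((y == -1).sum())} negatives, {X.shape[1]} features")

tc = TrainingConfig(grid_log2c=(-1, 3, 7), grid_log2gamma=(-9, -6, -3),
                    cv_protocol="jackknife", seed=1)
result = grid_search(X, y, tc)
print(f"best cell: c={result.best_c:g}, gamma={result.best_gamma:g} "
      f"(LOO acc {result.scores[(result.best_c, result.best_gamma)]:.3f})")

m = jackknife_evaluate(X, y, result.best_c, result.best_gamma)
print(f"jackknife metrics: Sn={m.sn:.3f} Sp={m.sp:.3f} "
      f"Acc={m.acc:.3f} MCC={m.mcc:.3f}")
print()
print("Each sample is predicted by a model trained on all the others; with a")
print("strong planted motif the pipeline recovers the signal almost")
print("perfectly, so accuracy is near 1 and MCC near its upper limit.")
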