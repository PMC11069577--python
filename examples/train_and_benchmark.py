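"""Train the random forest on planted-motif data and benchmark all four
models at realistic prevalence.

Positives are cytosines at the 3' end of GC-rich hairpin loops (the
APOBEC3A/G substrate); negatives are background rejected below the rules
threshold.  The forest trains on the 70% split at a downsampled 1:3 ratio
with half the negatives drawn from the high-rules-score pool, and is
evaluated on the held-out 30% topped up to 1 editing site per 468
non-editing sites -- the prevalence real coding sequence shows.
"""

import numpy as np

from cueditscan import benchmark as bench, ml, rules, synthetic
from cueditscan.benchmark import BenchmarkSet

SEED = 11

params = synthetic.MotifParams()
bset, _ = synthetic.make_benchmark(n_pos=200, ratio=3, params=params,
                                   seed=SEED)
train, test = bench.split_train_test(list(bset.sites), 0.7, seed=SEED)

cfg = ml.TrainingConfig(seed=SEED)
X, y = ml.build_training_set(train, cfg)
model = ml.train_model(X, y, cfg)

n_pos_test = sum(s.label for s in test)
pool, _ = synthetic.make_benchmark(1, 468 * n_pos_test + 100, params,
                                   seed=SEED + 1)
prop = bench.make_proportional_set(
    BenchmarkSet(tuple(test), 3.0, "testing"),
    [s for s in pool.sites if s.label == 0], ratio=468, seed=SEED,
    train=train)

labels = np.array([s.label for s in prop.sites], dtype=bool)
windows = [s.window for s in prop.sites]
rules_calls = np.array([rules.rules_classify(rules.rules_score(w))
                        for w in windows])
probs = ml.predict_prob_many(model, windows)
rf_calls = probs > 0.5

print(f"proportional set: {labels.sum()} editing / {(~labels).sum()} "
      f"non-editing sites (prevalence {labels.mean():.5f})")
for name, calls in [("rules", rules_calls), ("random forest", rf_calls),
                    ("union", rules_calls | rf_calls),
                    ("intersection", rules_calls & rf_calls)]:
    m = bench.compute_metrics(bench.counts_from_calls(labels, calls))
    print(f"{name:>14}: recall {100 * m.recall:5.1f}%  "
          f"precision {100 * m.precision:5.1f}%  F1 {m.f1:.2f}  MCC {m.mcc:.2f}")

auroc, auprc, rep, _ = bench.roc_and_pr_curves(probs, labels.astype(int))
print(f"random forest AUROC {auroc:.3f}, AUPRC {auprc:.3f} "
      f"(baseline AUPRC = prevalence = {rep.baseline_auprc:.5f})")

# Union recall is the upper envelope of the primaries and intersection
# precision the highest of the four -- the reason a survey uses the union
# model and a validation study the intersection model.
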