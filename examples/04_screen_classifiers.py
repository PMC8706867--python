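"""Five-method descriptor screening with the full metric suite.

Shows the evaluation metrics on a synthetic two-class descriptor dataset
and reproduces the published reference confusion-matrix example.
"""

from gruchem.screen import ConfusionMatrix, make_split, fit_classifiers, metrics_from_cm
from gruchem.synthdata import LabeledSpec, gen_labeled

# A reference confusion matrix from an external-test evaluation of a
# logistic-regression inhibitor classifier (644 test samples):
rep = metrics_from_cm(ConfusionMatrix(tp=102, fp=49, fn=42, tn=451))
print("reference matrix ->", rep.rounded())

# Synthetic data mimicking a 433-positive / 579-negative training table
X, y = gen_labeled(LabeledSpec(n_pos=433, n_neg=579, effect_size=1.5, seed=0))
split = make_split(y, train_frac=0.6, seed=0)
results = fit_classifiers(X, y, split, seed=0)
print(f"{'method':>6} {'acc':>6} {'sen':>6} {'spe':>6} {'mcc':>6} {'auc':>6}")
for method, by_split in results.items():
    r = by_split["validation"].rounded()
    print(f"{method:>6} {r['acc']:>6} {r['sen']:>6} {r['spe']:>6} "
          f"{r['mcc']:>6} {r['auc']:>6}")
# acc/sen/spe are fractions of correctly handled samples; MCC is the
# chance-corrected correlation (0 = random, 1 = perfect); random_acc in the
# reference row is the accuracy a marginal-preserving random predictor
# would reach by chance.
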