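"""Train a small network end to end on synthetic tiles and evaluate it.

Uses a deliberately tiny configuration (width multiplier 0.1, 96 px
input, 48 training tiles, 15 epochs) so the example runs in well under a
minute on one CPU; accuracy will be modest at this scale.  The training
loop follows the standard recipe — Adam, learning rate 5e-4, weight
decay 1e-5, cross-entropy — and retains the checkpoint from the epoch
with the best eval accuracy.
"""

from hahnet.data import SynthConfig, generate_synthetic_tiles, split_dataset
from hahnet.model import ModelConfig, build_model
from hahnet.train import TrainConfig, evaluate_model, train

records = generate_synthetic_tiles(SynthConfig(n_per_class=15, size=96, seed=3))
train_recs, eval_recs = split_dataset(records, (0.8, 0.2), seed=3)

model = build_model(ModelConfig(width_multiplier=0.1, input_size=96, seed=3))
print(f"model: {model.num_parameters():,} parameters, variant={model.cfg.variant}")

cfg = TrainConfig(epochs=15, batch_size=16, seed=3)
_, history = train(model, train_recs, eval_recs, cfg)
for e, (tl, ta, va) in enumerate(zip(history.train_loss,
                                     history.train_accuracy,
                                     history.test_accuracy)):
    print(f"epoch {e}: train loss {tl:.3f}, train acc {ta:.2f}, eval acc {va:.2f}")
print(f"retained checkpoint from epoch {history.best_epoch} "
      "(highest eval accuracy, earliest on ties)")

report = evaluate_model(model, eval_recs)
print(f"eval: accuracy {report.accuracy:.3f}, macro F {report.f_score:.3f}, "
      f"MCC {report.mcc:.3f}, macro AUC {report.auc:.3f}")
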