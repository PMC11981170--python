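"""Train the combined raw-FID glioma/healthy classifier end to end.

Simulates a balanced two-class cohort (glioma profile: elevated total
choline and lactate, reduced NAA), pretrains the transform block
briefly, fine-tunes the DenseNet classifier on top, and reports ROC AUC
and the confusion matrix on held-out examples.
"""

import mrsinet as M
from mrsinet.classifier_net import (ClassifierConfig, build_combined,
                                    predict, train_classifier)
from mrsinet.metrics import confusion, roc_auc
from mrsinet.transform_net import (TransformNetConfig, build_transform_net,
                                   train_transform)

paired = M.generate_dataset(2_000, master_seed=2)
labeled = M.generate_labeled_dataset(400, master_seed=3)
print(f"labeled cohort: {int(labeled.train.labels.sum())} glioma / "
      f"{int((1 - labeled.train.labels).sum())} healthy training spectra")

t_config = TransformNetConfig(
    fc_widths=(512, 512, 1024), conv_channels=(8, 8), conv_kernel=5,
    learning_rate=5e-4, batch_size=32, epochs=4, shared_channels=True)
t_model = build_transform_net(t_config, seed=2)
train_transform(t_model, paired.train, paired.validation, t_config, seed=2)
print("transform block pretrained")

c_config = ClassifierConfig(
    dense_blocks=3, layers_per_block=2, growth_rate=8, init_channels=16,
    learning_rate=1e-3, batch_size=50, epochs=8)
model = build_combined(t_model, c_config, seed=2)
_, history = train_classifier(model, labeled.train, labeled.validation,
                              c_config, seed=2)
print(f"classifier trained; best validation BCE = "
      f"{min(history.val_loss):.3f}")

probs = predict(model, labeled.test.fids)
roc = roc_auc(labeled.test.labels, probs)
conf = confusion(labeled.test.labels, probs, threshold=0.5)
print(f"held-out AUC = {roc.auc:.3f} "
      "(probability a glioma spectrum outscores a healthy one)")
print(f"sensitivity = {100 * conf.sensitivity:.1f}%  "
      f"specificity = {100 * conf.specificity:.1f}%  "
      f"(cells tp={conf.tp} fn={conf.fn} fp={conf.fp} tn={conf.tn})")
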