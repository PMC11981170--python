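"""Train the FID-to-spectrum transform block on a small synthetic set.

Generates 2,000 (augmented FID, clean spectrum) pairs, trains the
AUTOMAP-style 1D network for a few epochs and reports reconstruction
quality (MSE, SSIM, PSNR) on the held-out test split.  Runs in a couple
of minutes on one CPU; larger runs only change n and epochs.
"""

import mrsinet as M
from mrsinet.metrics import recon_report
from mrsinet.transform_net import (TransformNetConfig, build_transform_net,
                                   train_transform, transform, mse_loss)

dataset = M.generate_dataset(2_000, master_seed=1)
print(f"dataset: {len(dataset.train)} train / {len(dataset.validation)} "
      f"val / {len(dataset.test)} test pairs")

config = TransformNetConfig(
    fc_widths=(512, 512, 1024), conv_channels=(8, 8), conv_kernel=5,
    learning_rate=5e-4, batch_size=32, epochs=6, shared_channels=True)
model = build_transform_net(config, seed=1)
print(f"transform net: {model.n_parameters():,} parameters, "
      f"layers {model.layer_types()}")

state, history = train_transform(model, dataset.train, dataset.validation,
                                 config, seed=1)
print("validation MSE per epoch:",
      " ".join(f"{v:.2e}" for v in history.val_loss))

pred = transform(model, dataset.test.fids)
report = recon_report(dataset.test.targets, pred,
                      ppm_axis=dataset.test.ppm_axis)
print(f"test MSE  = {mse_loss(dataset.test.targets, pred):.2e} "
      "(squared error per normalized spectral point)")
print(f"test SSIM = {report.ssim[0]:.3f} +- {report.ssim[1]:.3f} "
      "(structural similarity to the clean spectrum)")
print(f"test PSNR = {report.psnr[0]:.1f} dB")
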