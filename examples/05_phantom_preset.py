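"""Generate spectra from the 7-metabolite phantom preset.

The phantom emulates a physical quality-control object: seven
metabolites at fixed, known concentrations (free choline instead of the
GPC/PCh pair used in brain simulation).  Useful for validating the
transform block against a ground truth with no biological variability.
"""

import numpy as np

import mrsinet as M
from mrsinet.simulate import phantom_preset

metabolites, ranges = phantom_preset()
print("phantom composition (mmol/L):")
for name in metabolites:
    lo, hi = ranges.ranges[name]
    assert lo == hi
    print(f"  {name:4s} {lo:.0f}")

dataset = M.generate_dataset(200, ranges=ranges, metabolites=metabolites,
                             master_seed=6, split_fractions=(0.8, 0.1, 0.1))
print(f"\ngenerated {len(dataset.train)}/{len(dataset.validation)}/"
      f"{len(dataset.test)} phantom spectra (train/val/test)")

# all clean targets share one composition: only field strength,
# broadening, phase and noise vary between examples
targets = dataset.train.targets
axis = dataset.train.ppm_axis
naa_bin = np.argmin(np.abs(axis - 2.01))
cho_bin = np.argmin(np.abs(axis - 3.19))
print(f"mean normalized target height at NAA (2.01 ppm): "
      f"{targets[:, naa_bin, 0].mean():.3f}")
print(f"mean normalized target height at Cho (3.19 ppm): "
      f"{targets[:, cho_bin, 0].mean():.3f}")
print("peak-height ratios are fixed by the known composition, so any "
      "deviation in a trained model's output is model error, not biology")
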