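"""Reduced-scale training presets.

The full-scale defaults in :class:`TransformNetConfig` and
:class:`ClassifierConfig` (50,000+ spectra, 200/100 epochs, small
learning rates) describe the reference regime.  These presets are the
package's desk-scale counterparts — smaller datasets, fewer epochs,
narrower layers and learning rates rescaled accordingly — chosen once so
a complete train/evaluate cycle runs on a single CPU in minutes while
preserving every architectural element (3 FC + 2 conv + deconv; dense
blocks with transitions).  See docs/methods.md for the rationale.
"""

from __future__ import annotations

from .classifier_net import ClassifierConfig
from .transform_net import TransformNetConfig

#: Paired-dataset size used by desk-scale transform training.
DESK_N_PAIRED = 12000

#: Examples per class for desk-scale classifier training.
DESK_N_PER_CLASS = 600


def desk_transform_config() -> TransformNetConfig:
    """Transform-net config for desk-scale runs (minutes on one CPU).

    Uses the shared-channel variant (one network with 2-channel output)
    because it halves the wall time per step at equal reconstruction
    quality in this regime.
    """
    return TransformNetConfig(
        fc_widths=(1024, 1024, 1024),
        conv_channels=(16, 16),
        conv_kernel=5,
        learning_rate=1e-3,
        batch_size=64,
        epochs=18,
        shared_channels=True,
    )


def desk_classifier_config() -> ClassifierConfig:
    """Combined-classifier config for desk-scale runs."""
    return ClassifierConfig(
        dense_blocks=3,
        layers_per_block=2,
        growth_rate=8,
        init_channels=16,
        kernel=3,
        learning_rate=1e-3,
        batch_size=50,
        epochs=12,
        fine_tune_transform=True,
        transform_lr_scale=0.1,
    )
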