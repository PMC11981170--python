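"""Shared fixtures: small grids, desk-scale datasets and trained models.

Training fixtures are session-scoped because they are the expensive part
of the suite; every test that consumes them treats the models as
read-only.
"""

from __future__ import annotations

import numpy as np
import pytest

import mrsinet as M
from mrsinet import presets
from mrsinet.classifier_net import build_combined, train_classifier
from mrsinet.transform_net import build_transform_net, train_transform

MASTER_SEED = 20240917


def brute_force_dft(x: np.ndarray) -> np.ndarray:
    """O(n^2) DFT oracle, fftshifted to ascending-frequency order."""
    n = len(x)
    k = np.arange(n)
    W = np.exp(-2j * np.pi * np.outer(k, k) / n)
    return np.fft.fftshift(W @ x)


@pytest.fixture(scope="session")
def grid3t():
    from mrsinet.basis import make_grid
    return make_grid(3.0)


@pytest.fixture(scope="session")
def basis3t():
    return M.build_basis(3.0)


@pytest.fixture(scope="session")
def paired_dataset():
    """Desk-scale paired (augmented FID, clean spectrum) dataset."""
    return M.generate_dataset(presets.DESK_N_PAIRED, master_seed=MASTER_SEED)


@pytest.fixture(scope="session")
def labeled_dataset():
    """Desk-scale balanced glioma/healthy dataset."""
    return M.generate_labeled_dataset(presets.DESK_N_PER_CLASS,
                                      master_seed=MASTER_SEED + 1)


@pytest.fixture(scope="session")
def trained_transform(paired_dataset):
    """Transform net trained at desk scale (the suite's slow fixture)."""
    cfg = presets.desk_transform_config()
    model = build_transform_net(cfg, seed=MASTER_SEED)
    state, history = train_transform(model, paired_dataset.train,
                                     paired_dataset.validation, cfg,
                                     seed=MASTER_SEED)
    return model, state, history


@pytest.fixture(scope="session")
def trained_classifier(trained_transform, labeled_dataset):
    """Combined model fine-tuned on the labeled desk-scale dataset."""
    transform_model, t_state, _ = trained_transform
    cfg = presets.desk_classifier_config()
    model = build_combined(dict(t_state), cfg,
                           transform_config=transform_model.config,
                           seed=MASTER_SEED)
    state, history = train_classifier(model, labeled_dataset.train,
                                      labeled_dataset.validation, cfg,
                                      seed=MASTER_SEED)
    return model, state, history


@pytest.fixture(scope="session")
def tiny_noiseless_transform():
    """A small transform net trained on a tiny noise-free task.

    Used for oracle comparisons where the mapping should be learned
    nearly exactly.
    """
    from mrsinet.simulate import AugmentParams
    aug = AugmentParams(noise_range=(0.0, 0.0), broadening_range=(0.0, 0.0),
                        phase_range=(0.0, 0.0))
    ds = M.generate_dataset(300, aug=aug, master_seed=MASTER_SEED + 2,
                            field_range=(3.0, 3.0))
    cfg = presets.desk_transform_config()
    cfg.epochs = 20
    model = build_transform_net(cfg, seed=MASTER_SEED)
    state, history = train_transform(model, ds.train, ds.validation, cfg,
                                     seed=MASTER_SEED)
    return model, ds, history
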