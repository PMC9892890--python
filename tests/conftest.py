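"""Shared fixtures.

The classifier used by the gating and end-to-end tests is trained once
per session with the full recipe (Adam 1e-3, minibatch 32, 20 epochs)
on simulator-synthesized plane-of-best-focus crops; the crop pools for
in-silico mixtures come from the same generator with a different seed.
"""

from __future__ import annotations

import pytest

import holoenum as he


@pytest.fixture(scope="session")
def optics_default() -> he.OpticalConfig:
    return he.OpticalConfig()


@pytest.fixture(scope="session")
def optics_small() -> he.OpticalConfig:
    """256x256 test field of view with a matching narrow channel."""
    return he.OpticalConfig(
        fov_px=(256, 256), channel_width_um=256.0, sample_core_width_um=160.0
    )


@pytest.fixture(scope="session")
def flow_default() -> he.FlowConfig:
    return he.FlowConfig()


@pytest.fixture(scope="session")
def trained_snet(optics_default):
    """s-Net trained with the full recipe on 3500 crops per class.

    Returns (model, history, test_crops, test_labels) with a held-out
    1500-per-class test set from an independent seed.
    """
    crops, labels = he.make_training_crops(3500, optics_default, seed=101)
    model = he.build_snet(seed=0)
    history = he.train(
        model, crops, labels, minibatch=32, epochs=20, learning_rate=1e-3, seed=0
    )
    test_crops, test_labels = he.make_training_crops(1500, optics_default, seed=102)
    return model, history, test_crops, test_labels


@pytest.fixture(scope="session")
def crop_pools(optics_default):
    """Pure-population crop pools for in-silico mixtures (tumor, wbc)."""
    crops, labels = he.make_training_crops(4000, optics_default, seed=103)
    return crops[labels == 1], crops[labels == 0]


def isolated_cells_frame(optics, rng, positions, sim=None):
    """Render one frame with isolated cells at the given (row, col)
    anchor positions (jittered), returning (cells, noisy frame)."""
    sim = sim or he.SimParams()
    cells = []
    for j, (cy, cx) in enumerate(positions):
        if rng.random() < 0.5:
            diam = rng.normal(sim.tumor_diameter_um, sim.tumor_diameter_sd_um)
            contrast = sim.tumor_amplitude_contrast
        else:
            diam = rng.normal(sim.wbc_diameter_um, sim.wbc_diameter_sd_um)
            contrast = sim.wbc_amplitude_contrast
        cells.append(
            he.SimCell(
                cell_id=j,
                class_label=he.TUMOR,
                diameter_um=float(diam),
                amplitude_contrast=contrast,
                phase_contrast_rad=0.0,
                y_um=cy + rng.uniform(-10, 10),
                z_um=rng.uniform(50, 280),
                entry_time_s=0.0,
                texture_seed=int(rng.integers(0, 2**31)),
                x_um=cx + rng.uniform(-10, 10),
            )
        )
    holo = he.project_hologram(cells, optics)
    frame = holo + rng.normal(0.0, 0.01, holo.shape)
    return cells, frame / frame.mean()
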