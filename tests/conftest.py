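import numpy as np
import pytest
from hypothesis import settings

from dpsenet import ArchitectureConfig, build_model

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

TINY = ArchitectureConfig(
    input_height=16, input_width=16, block_filters=(4, 8),
    se_reduction=4, dense_units=12, n_classes=5, variant="dual_se",
)


@pytest.fixture(scope="session")
def tiny_config():
    """A 16x16 two-block configuration cheap enough for exhaustive checks."""
    return TINY


@pytest.fixture(scope="session")
def tiny_model(tiny_config):
    return build_model(tiny_config, seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def toy_class_specs():
    """Five strongly separable textures (distinct backgrounds and densities).

    At 32x32 the realistic default classes carry little per-crop signal, so
    toy fixtures use an easier palette that a small model learns in seconds.
    """
    from dpsenet.synthetic_data import SyntheticClassSpec

    cyto = [(0.85, 0.55, 0.65), (0.55, 0.75, 0.85), (0.75, 0.85, 0.55),
            (0.90, 0.80, 0.50), (0.60, 0.55, 0.85)]
    nuc = [(0.30, 0.15, 0.50), (0.20, 0.20, 0.60), (0.45, 0.10, 0.40),
           (0.35, 0.30, 0.55), (0.25, 0.20, 0.45)]
    dens = [60, 15, 90, 30, 5]
    return tuple(
        SyntheticClassSpec(name=f"toy_{i}", nuclei_density=dens[i],
                           nucleus_radius=(2, 4), nucleus_color=nuc[i],
                           cytoplasm_color=cyto[i], noise_sd=0.02)
        for i in range(5)
    )


@pytest.fixture(scope="session")
def tiny_trained():
    """A small model trained on the easy toy textures.

    Used by explainability and training tests that need non-degenerate
    learned weights. Returned as (model, images, labels, masks).
    """
    from dpsenet.synthetic_data import GeneratorConfig, generate_arrays
    from dpsenet.training import TrainingConfig, train

    cfg = ArchitectureConfig(
        input_height=32, input_width=32, block_filters=(8, 16),
        se_reduction=4, dense_units=24, n_classes=5, variant="dual_se")
    gen = GeneratorConfig(class_specs=toy_class_specs(),
                          images_per_class=24, image_size=32, seed=7)
    images, labels, names, masks = generate_arrays(gen, return_masks=True)
    order = np.random.default_rng(0).permutation(len(labels))
    images, labels, masks = images[order], labels[order], masks[order]
    n_val = 30
    model = build_model(cfg, seed=0)
    train(model, (images[n_val:], labels[n_val:]), (images[:n_val], labels[:n_val]),
          TrainingConfig(max_epochs=20, early_stop_patience=20,
                         plateau_patience=20, seed=0))
    return model, images, labels, masks
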