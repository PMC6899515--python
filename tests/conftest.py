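import numpy as np
import pytest

import svca


@pytest.fixture(scope="session")
def small_image():
    """A 120-cell, 10-gene synthetic count image."""
    return svca.synthesize_image(120, 10, seed=101)


@pytest.fixture(scope="session")
def processed_image(small_image):
    """The same image after stabilization and total-signal regression."""
    proc = svca.preprocess_counts(small_image.expression)
    return svca.SpatialExpressionImage(
        small_image.image_id, small_image.positions, proc, small_image.gene_names
    )


@pytest.fixture(scope="session")
def medium_processed_image():
    """A 250-cell, 26-gene processed image for model-level tests."""
    img = svca.synthesize_image(250, 26, seed=77)
    proc = svca.preprocess_counts(img.expression)
    return svca.SpatialExpressionImage(img.image_id, img.positions, proc, img.gene_names)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_sim_image(base_image, y, x=None, gene_name="target"):
    """Attach a simulated target gene to a base image's state matrix."""
    state = base_image.expression if x is None else x
    expr = np.column_stack([state, y])
    return svca.SpatialExpressionImage(
        base_image.image_id,
        base_image.positions,
        expr,
        list(base_image.gene_names) + [gene_name],
    )
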