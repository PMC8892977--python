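"""Shared fixtures: small synthetic cells, oracle heatmaps, tiny nets."""

import numpy as np
import pytest

from fociquant.synthetic import (
    SyntheticCellSpec,
    build_training_set,
    make_base_cell,
    make_evaluation_cells,
    target_heatmap,
)


@pytest.fixture()
def base_cell():
    """One deterministic untreated-like cell at the default scale."""
    return make_base_cell(SyntheticCellSpec(rng_seed=42))


@pytest.fixture(scope="session")
def base_cells_20():
    rng = np.random.default_rng(7)
    return [
        make_base_cell(SyntheticCellSpec(rng_seed=int(rng.integers(2**31))))
        for _ in range(20)
    ]


@pytest.fixture(scope="session")
def eval_cells_64():
    """Treated-like cells generated at network size (64x64) so truth
    coordinates coincide with crop coordinates, plus oracle heatmaps."""
    spec = SyntheticCellSpec(image_size=64)
    cells, truths = make_evaluation_cells(
        30, rng_seed=11, min_separation=6.0, spec=spec
    )
    heatmaps = [target_heatmap(t, 64) for t in truths]
    return cells, truths, heatmaps


@pytest.fixture(scope="session")
def training_pairs_small():
    """A small augmented training set (8 bases x 4 pairs)."""
    rng = np.random.default_rng(3)
    bases = [
        make_base_cell(SyntheticCellSpec(rng_seed=int(rng.integers(2**31))))
        for _ in range(8)
    ]
    return build_training_set(bases, pairs_per_base=4, rng_seed=3)
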