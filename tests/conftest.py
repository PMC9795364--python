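import numpy as np
import pytest

from spotcorr import KernelConfig, SpatialDataset
from spotcorr.simulate import make_lattice


def build_dataset(
    n_spots: int = 20,
    n_genes: int = 3,
    regions=("A",),
    seed: int = 0,
    coords: np.ndarray | None = None,
    expression: np.ndarray | None = None,
) -> SpatialDataset:
    """Random continuous dataset on scattered coordinates, regions assigned
    round-robin."""
    rng = np.random.default_rng(seed)
    if coords is None:
        coords = rng.uniform(0, 10, size=(n_spots, 2))
    if expression is None:
        expression = rng.standard_normal((n_spots, n_genes))
    labels = np.array([regions[i % len(regions)] for i in range(n_spots)], dtype=object)
    return SpatialDataset(
        expression=expression,
        coordinates=coords,
        region_labels=labels,
        spot_ids=np.array([f"s{i}" for i in range(n_spots)], dtype=object),
        gene_ids=np.array([f"G{g}" for g in range(expression.shape[1])], dtype=object),
    )


def lattice_dataset(nx=7, ny=7, n_genes=2, regions=("A",), seed=0) -> SpatialDataset:
    coords = make_lattice(nx, ny)
    return build_dataset(
        n_spots=coords.shape[0], n_genes=n_genes, regions=regions, seed=seed,
        coords=coords,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_dataset():
    return build_dataset(n_spots=10, n_genes=3, regions=("A", "B"), seed=7)


@pytest.fixture
def kernel_config():
    return KernelConfig()
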