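import numpy as np
import pytest

from cocost import SpatialDataset
from cocost.preprocessing import standardize


def make_dataset(
    rng: np.random.Generator,
    n: int = 60,
    d: int = 12,
    prefix: str = "s",
    standardized: bool = True,
) -> SpatialDataset:
    """Random dense slice; standardized per gene unless told otherwise."""
    expr = rng.standard_normal((n, d))
    coords = rng.uniform(0.0, 10.0, size=(n, 2))
    ds = SpatialDataset(
        expr=expr,
        coords=coords,
        gene_ids=[f"g{j:03d}" for j in range(d)],
        spot_ids=[f"{prefix}{i:03d}" for i in range(n)],
        layer_tag="normalized",
    )
    return standardize(ds) if standardized else ds


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def pair(rng):
    """Aligned standardized background/target pair on the same gene set."""
    background = make_dataset(rng, n=80, d=15, prefix="b")
    target = make_dataset(rng, n=70, d=15, prefix="t")
    return background, target
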