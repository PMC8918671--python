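import numpy as np
import pytest

import spottype as st


@pytest.fixture
def toy_signatures() -> st.SignatureMatrix:
    """Three cell types with disjoint binary markers over 9 genes."""
    return st.binary_signatures(3, 3)


@pytest.fixture
def toy_tissue(toy_signatures):
    """Small synthetic tissue: 60 cells, 3 types, 10% noise, seeded."""
    model = st.make_tissue(
        60, toy_signatures, extent=(300.0, 300.0), cell_radius=10.0,
        depth=20.0, noise_fraction=0.1, seed=11,
    )
    spots, truth = st.simulate_spots(model)
    return model, spots, truth


@pytest.fixture
def toy_params() -> st.KDEParams:
    return st.KDEParams(bandwidth=10.0, width_px=150, threshold=0.05)


def grid_offset(local: st.GridSpec, full: st.GridSpec) -> tuple[int, int]:
    """(row, col) of a preview grid's origin within the full grid."""
    c0 = round((local.x_min - full.x_min) * full.scale)
    r0 = round((local.y_min - full.y_min) * full.scale)
    return r0, c0


def uniform_spots(n: int, seed: int, extent: float = 64.0, margin: float = 0.0,
                  genes=("A",)) -> st.SpotTable:
    """n uniformly placed molecules over [margin, extent-margin]²."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(margin, extent - margin, n)
    y = rng.uniform(margin, extent - margin, n)
    g = np.asarray(rng.choice(list(genes), size=n), dtype=object)
    return st.SpotTable(g, x, y)


def unit_grid(extent: int = 64, sigma_px: float = 3.0) -> st.GridSpec:
    """1 px/μm grid over [0, extent]² with a fixed pixel-unit bandwidth."""
    return st.GridSpec(x_min=0.0, y_min=0.0, scale=1.0, width_px=extent,
                       height_px=extent, bandwidth_px=sigma_px)
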