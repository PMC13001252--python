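import pandas as pd
import pytest

import tnarray as tn


@pytest.fixture(scope="session")
def small_design() -> tn.PoolingDesign:
    """2x2 plate grid of 4x6 plates: 96 wells, 16 pools."""
    return tn.build_design(2, 2, 4, 6)


@pytest.fixture(scope="session")
def reference() -> tn.ReferenceBundle:
    return tn.generate_reference(n_genes=40, seed=7)


@pytest.fixture(scope="session")
def full_scale():
    """The library-scale condition: 5x5 grid of 96-well plates, every one of
    the 2,400 wells picked, no duplicate clones."""
    ref = tn.generate_reference(n_genes=150, seed=2)
    design = tn.build_design(5, 5, 8, 12)
    placement = tn.simulate_picking(ref, design, 2400, duplicate_rate=0.0, seed=4)
    return ref, design, placement


def matrix_from_rows(design: tn.PoolingDesign, rows: dict[str, dict[str, int]],
                     positions: dict[str, int] | None = None) -> tn.PoolCountMatrix:
    """Hand-built count matrix: site_id -> {pool: count} (missing pools are 0)."""
    pools = list(design.pools)
    counts = pd.DataFrame(
        [{**{p: 0 for p in pools}, **vals} for vals in rows.values()],
        index=pd.Index(list(rows), name="site_id"),
        columns=pools,
        dtype=int,
    )
    sites = pd.DataFrame(
        {
            "position": [positions[s] if positions else 100 * (i + 1)
                         for i, s in enumerate(rows)],
            "strand": "+",
        },
        index=counts.index,
    )
    return tn.PoolCountMatrix(counts, sites)
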