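import numpy as np
import pandas as pd
import pytest

from ovarena import (
    ArenaGeometry,
    EggTable,
    SimulationConfig,
    classify_on_off,
    compute_egg_distances,
)


@pytest.fixture
def geometry():
    """150 px lawn at (500, 500), 0.01 mm/px -> 1.5 mm lawn radius."""
    return ArenaGeometry(center_xy=(500.0, 500.0), lawn_radius_px=150.0,
                         mm_per_px=0.01, corral_radius_px=300.0)


def make_egg_table(coords_by_arena, geometry, condition="mock"):
    """Build an EggTable from {arena: [(x, y), ...]} pixel coordinates."""
    rows = []
    for arena, coords in coords_by_arena.items():
        for x, y in coords:
            dc, de = compute_egg_distances((x, y), geometry)
            rows.append(
                {"arena": arena, "condition": condition, "x_px": x, "y_px": y,
                 "lawn_radius_px": geometry.lawn_radius_px, "mm_per_px": geometry.mm_per_px,
                 "dist_center_mm": dc, "dist_edge_mm": de, "off_lawn": classify_on_off(de)}
            )
    df = pd.DataFrame(rows)
    return EggTable(data=df, geometries={a: geometry for a in coords_by_arena})


@pytest.fixture
def small_egg_table(geometry):
    """Two arenas: a1 has 2 on-lawn + 1 off-lawn egg, a2 has 1 of each."""
    return make_egg_table(
        {
            "a1": [(500, 500), (600, 500), (500, 800)],
            "a2": [(550, 500), (500, 200)],
        },
        geometry,
    )


@pytest.fixture
def two_condition_counts():
    """Saturated 2-group design: mock (10 off, 90 on), predator (70, 30)."""
    return pd.DataFrame(
        {
            "arena": ["m1", "p1"],
            "condition": ["mock", "predator"],
            "n_off": [10, 70],
            "n_on": [90, 30],
        }
    )


@pytest.fixture
def sim_config():
    return SimulationConfig(seed=11)


def random_binomial_instance(rng, n_units=24, n_factors=3):
    """A random factorial counts table with <= 6 coefficients (for oracle
    comparisons); levels balanced, counts bounded away from separation."""
    factors = {}
    for j in range(n_factors):
        levels = [f"f{j}l{k}" for k in range(2)]
        factors[f"fac{j}"] = rng.choice(levels, size=n_units)
    eta = rng.normal(0, 0.8, size=n_units)
    p = 1 / (1 + np.exp(-eta))
    n = rng.integers(30, 120, size=n_units)
    y = rng.binomial(n, p)
    y = np.clip(y, 1, n - 1)  # avoid degenerate units
    return pd.DataFrame({**factors, "n_off": y, "n_on": n - y})
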