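"""Shared fixtures: compact simulated geometries that keep tests fast.

The compact test geometry keeps the native 0.1 mm/px spacing (so a 64-px ROI
spans 6.4 mm, small against the thermal structure) but shrinks the imaged
region to a 256x320 window around the ablation zone.
"""

from __future__ import annotations

import numpy as np
import pytest

from thermotex.sim import SimConfig

# probe layout for a 96x128 px micro grid (axis at y=38.4); ROIs do not fit,
# but field/probe-log tests do not need them
MICRO_PROBES = ((40, 45), (55, 45), (70, 50), (45, 55), (60, 60), (75, 65), (50, 70))


def compact_config(seed: int = 0, power: str = "P15", **overrides) -> SimConfig:
    """256x320 px at 0.1 mm/px: full ROI coverage of all 7 probes."""
    kw = dict(
        grid_height_px=256,
        grid_width_px=320,
        mm_per_px=0.1,
        power_preset=power,
        rng_seed=seed,
    )
    kw.update(overrides)
    return SimConfig(**kw)


def micro_config(seed: int = 0, duration_s: float = 10.0, **overrides) -> SimConfig:
    """Tiny 96x128 grid for field-level tests."""
    kw = dict(
        grid_height_px=96,
        grid_width_px=128,
        mm_per_px=0.1,
        duration_s=duration_s,
        probe_points=MICRO_PROBES,
        rng_seed=1,
    )
    kw.update(overrides)
    return SimConfig(**kw)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def compact_case():
    """One full-length compact case, shared by everything that reads it."""
    from thermotex.sim import generate_case

    return generate_case(compact_config(seed=7), case_id="compact7")


@pytest.fixture(scope="session")
def compact_samples(compact_case):
    from thermotex.ingest import case_to_samples

    return case_to_samples(compact_case)
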