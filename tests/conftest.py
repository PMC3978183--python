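"""Shared fixtures: the expensive simulated studies are session-scoped.

Problem sizes are scaled for a single CPU: the in-air study runs 180 views
(divisible by 18 subsets) at the 256-bin acquisition matrix rebinned to 128,
and the warm convergence ladder runs 120 views rebinned to the 64 matrix
with 6 subsets and iteration snapshots {3, 30, 60, 90}, i.e. effective
update counts IT x SUB in {18, 180, 360, 540}.
"""

from __future__ import annotations

import numpy as np
import pytest

from specres import (BackgroundSpec, GridSpec, ReconConfig, ReconVolume,
                     rebin, reconstruct, fbp)
from specres.runner import ExperimentConfig, simulate_experiment

WARM_LADDER_SUB = 6
WARM_LADDER_ITERS = (3, 30, 60, 90)
WARM_TEST_RADII = (2.0, 5.0, 8.0)


@pytest.fixture(scope="session")
def air_study():
    """Noise-free experiment B at 128 matrix: sinogram, layout, FBP + OSEM-RR."""
    cfg = ExperimentConfig(experiment="B", n_views=180, counts_per_view=None,
                           radii_cm=tuple(float(r) for r in range(2, 10)))
    sino256, layout = simulate_experiment(cfg)
    s128 = rebin(sino256, 2)
    vol_fbp = fbp(s128)
    vol_osem = reconstruct(
        s128, ReconConfig(algorithm="OSEM", iterations=10, subsets=18),
        background=BackgroundSpec.air())
    return {"config": cfg, "sino256": sino256, "sino128": s128,
            "layout": layout, "fbp": vol_fbp, "osem_10x18": vol_osem}


@pytest.fixture(scope="session")
def warm_ladder():
    """Warm-background OSEM ladder at 64 matrix with iteration snapshots."""
    cfg = ExperimentConfig(experiment="A", n_views=120, seed=1,
                           radii_cm=tuple(float(r) for r in range(2, 11)))
    sino256, layout = simulate_experiment(cfg)
    s64 = rebin(rebin(sino256, 2), 2)
    snaps: dict[int, np.ndarray] = {}

    def keep(it, x):
        if it in WARM_LADDER_ITERS:
            snaps[it] = x.copy()

    reconstruct(s64, ReconConfig(algorithm="OSEM",
                                 iterations=max(WARM_LADDER_ITERS),
                                 subsets=WARM_LADDER_SUB),
                background=BackgroundSpec.warm(), callback=keep)
    grid = GridSpec(64, s64.geometry.bin_mm)
    volumes = {it * WARM_LADDER_SUB: ReconVolume(snaps[it], grid, {})
               for it in WARM_LADDER_ITERS}
    return {"config": cfg, "layout": layout, "sino64": s64, "volumes": volumes}
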