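"""Shared fixtures: meshes and benchmark growth runs."""

from __future__ import annotations

import pytest

from vasgrow.fixtures import sphere_benchmark
from vasgrow.gbo_growth import run_gbo
from vasgrow.tissue_domain import generate_sphere_tissue


@pytest.fixture(scope="session")
def sphere_small():
    """Coarse ball of radius 10 cm (shared; treat as read-only)."""
    return generate_sphere_tissue(10.0, 2.5)


@pytest.fixture(scope="session")
def bench567():
    """The two-source sphere benchmark at 567 target terminals."""
    return sphere_benchmark(n_terminals=567)


@pytest.fixture(scope="session")
def gbo567(bench567):
    """One growth run at 567 terminals, shared by structural tests."""
    bm = bench567
    forest, claim, log = run_gbo(bm.mesh, bm.demand, bm.sources, bm.geo, bm.opt)
    return bm, forest, claim, log
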