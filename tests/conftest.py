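"""Shared fixtures: reference conformer, small pools, cached observables."""

import numpy as np
import pytest

from flexens import hydro, pool, saxs


@pytest.fixture(scope="session")
def reference():
    return pool.build_domain_fixture(160, 65, 20, seed=0)


@pytest.fixture(scope="session")
def in_pool(reference):
    return pool.build_pool(reference, 60, 0, seed=1)


@pytest.fixture(scope="session")
def out_pool(reference):
    return pool.build_pool(reference, 0, 60, seed=2)


@pytest.fixture(scope="session")
def mixed_pool(reference):
    return pool.build_pool(reference, 30, 30, seed=3)


@pytest.fixture(scope="session")
def separated_pool(reference):
    """Compact bound members plus strictly extended open members.

    Mirrors the bimodal pool structure the recovery analysis assumes: the
    open sub-pool is generated with directional persistence and filtered to
    Rg >= 28 A so that compactness correlates with linker state.
    """
    pin = pool.build_pool(reference, 60, 0, seed=7)
    pout = pool.build_pool(reference, 0, 180, seed=8, extension_bias=2.0)
    ext = [m for m in pout if m.rg() >= 28.0][:60]
    assert len(ext) == 60
    return pool.ConformerPool(pin.members + ext,
                              provenance={"mode": "MIXED", "seed": 7})


@pytest.fixture(scope="session")
def q_grid():
    return saxs.DEFAULT_Q_GRID


@pytest.fixture(scope="session")
def separated_profiles(separated_pool, q_grid):
    return saxs.pool_profile_matrix(separated_pool, q_grid)


@pytest.fixture(scope="session")
def separated_taus(separated_pool):
    return hydro.predict_pool_taus(separated_pool)


@pytest.fixture(scope="session")
def sphere_beads():
    """Point beads on a cubic lattice filling a sphere of radius 25 A."""
    R, s = 25.0, 3.0
    g = np.arange(-R, R + s, s)
    X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
    pts = np.stack([X, Y, Z], -1).reshape(-1, 3)
    return pts[(pts ** 2).sum(1) <= R * R], R


def sphere_intensity(q, R):
    """Analytic normalized solid-sphere intensity."""
    qR = np.asarray(q) * R
    return (3.0 * (np.sin(qR) - qR * np.cos(qR)) / qR ** 3) ** 2
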