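"""Shared fixtures: small toy crystals and reusable grids."""

from __future__ import annotations

import numpy as np
import pytest

from hdmphase import core, synthetic
from hdmphase.core import ReflectionSet, SpaceGroupInfo, Status, UnitCell


@pytest.fixture(scope="session")
def p1_toy():
    """Small protein-rich P1 toy whose true map is an exact common fixed
    point of both projectors (anchor for the operator-algebra tests)."""
    return synthetic.make_toy_crystal(
        cell=UnitCell(16.0, 16.0, 16.0),
        sg="P 1",
        n_blobs=10,
        solvent_fraction=0.40,
        d_min=2.0,
        seed=11,
        grid_spacing=1.0,
        exact_fixed_point=True,
    )


@pytest.fixture(scope="session")
def p212121_toy():
    """Toy crystal in P2(1)2(1)2(1) for symmetry-path coverage."""
    return synthetic.make_toy_crystal(
        cell=UnitCell(24.0, 24.0, 24.0),
        sg="P 21 21 21",
        n_blobs=6,
        solvent_fraction=0.68,
        d_min=2.0,
        seed=5,
        grid_spacing=1.0,
    )


@pytest.fixture()
def random_refls():
    """Randomly generated orthorhombic P1 reflection set (seeded)."""
    rng = np.random.default_rng(42)
    cell = UnitCell(12.0, 14.0, 16.0)
    sg = SpaceGroupInfo.from_symbol("P 1")
    hkls = []
    for h in range(0, 4):
        for k in range(-3, 4):
            for l in range(-3, 4):
                hkl = (h, k, l)
                if hkl == (0, 0, 0):
                    continue
                red = core.reduce_to_asu(np.array([hkl]), sg)[0]
                if tuple(red) == hkl:
                    hkls.append(hkl)
    hkl = np.array(hkls)
    n = len(hkl)
    return ReflectionSet(
        cell=cell,
        sg=sg,
        d_min=float(cell.d(hkl).min()),
        hkl=hkl,
        f_obs=rng.uniform(1.0, 100.0, n),
        sig_f=rng.uniform(0.1, 5.0, n),
        status=np.full(n, Status.WORK, dtype=np.int8),
    )
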