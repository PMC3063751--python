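"""Shared fixtures: toy structures, networks and fluctuograms."""

import numpy as np
import pytest

from fluctuogram.cg import AtomicStructure, ElasticNetwork
from fluctuogram.fluctgram import Fluctuogram
from fluctuogram.fluctmatch import ConvergenceTrace
from fluctuogram.synth import make_toy_network


@pytest.fixture
def default_network():
    """The standard synthetic fixture: 20 sites, 8 extra contacts, k in [1, 20]."""
    return make_toy_network(20, 8, (1.0, 20.0), seed=1)


@pytest.fixture
def rigid_network():
    """Over-braced network (bonds >= 3N-6): fully coupled normal modes."""
    return make_toy_network(10, 21, (1.0, 20.0), seed=11)


def make_ala_ala():
    """Two-residue Ala-Ala toy with synthetic coordinates.

    Alanine here carries 4 backbone atoms (N, CA, C, O) and 4 sidechain
    atoms (CB, HB1, HB2, HB3).
    """
    names, res_idx, res_names, masses, coords = [], [], [], [], []
    rng = np.random.default_rng(99)
    for r in (1, 2):
        shift = np.array([3.8 * (r - 1), 0.0, 0.0])
        for name, m in [("N", 14.007), ("CA", 12.011), ("C", 12.011),
                        ("O", 15.999), ("CB", 12.011), ("HB1", 1.008),
                        ("HB2", 1.008), ("HB3", 1.008)]:
            names.append(name)
            res_idx.append(r)
            res_names.append("ALA")
            masses.append(m)
            coords.append(shift + rng.uniform(-1, 1, 3))
    return AtomicStructure(names, np.array(res_idx), res_names,
                           np.array(masses), np.array(coords))


@pytest.fixture
def ala_ala():
    return make_ala_ala()


def fluctuogram_from_k(k_windows, n_sites=None, pool=None, seed=0):
    """Build a fluctuogram directly from per-window force-constant arrays.

    All windows share one geometry; residues are the sites themselves
    (single-site residues), so site-level and residue-level couplings
    coincide.
    """
    k_windows = [np.asarray(k, dtype=float) for k in k_windows]
    n_bonds = len(k_windows[0])
    if pool is None:
        # a star plus chain pattern guaranteeing i < j
        pool = np.array([(0, b + 1) for b in range(n_bonds)], dtype=int)
    pool = np.asarray(pool, dtype=int)
    if n_sites is None:
        n_sites = int(pool.max()) + 1
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, 30, size=(n_sites, 3))
    i, j = pool.T
    rest = np.linalg.norm(coords[j] - coords[i], axis=1)
    networks = [
        ElasticNetwork(coords, pool, rest, k, temperature=300.0)
        for k in k_windows
    ]
    return Fluctuogram(
        pool=pool,
        times=np.arange(len(k_windows), dtype=float),
        networks=networks,
        traces=[ConvergenceTrace() for _ in k_windows],
    )
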