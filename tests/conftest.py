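"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own code paths: average
ranks are recomputed from raw permutations, medians and summaries by brute
force, so that agreement is evidence rather than tautology.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from marmot.poset import Poset, VariableSpec, build_relation


def make_poset(coords, multiplicity=None) -> Poset:
    """Build a poset (with relation) directly from coordinate rows."""
    coords = np.asarray(coords, dtype=np.int64)
    if multiplicity is None:
        multiplicity = np.ones(coords.shape[0], dtype=np.int64)
    return build_relation(Poset(coords=coords, multiplicity=np.asarray(multiplicity)))


def random_poset(rng: np.random.Generator, n_profiles: int, n_coords: int = 3,
                 max_level: int = 3) -> Poset:
    """Random product-order poset with exactly ``n_profiles`` distinct profiles."""
    seen = set()
    rows = []
    while len(rows) < n_profiles:
        row = tuple(rng.integers(0, max_level + 1, size=n_coords))
        if row not in seen:
            seen.add(row)
            rows.append(row)
    return make_poset(rows)


def brute_force_average_rank(poset: Poset) -> np.ndarray:
    """AR oracle: filter raw permutations against the order relation.

    Enumerates every permutation of the elements, keeps those where each
    'below' pair appears in order, and averages 1-based positions.  Fully
    independent of the package's extension enumeration.
    """
    P = poset.n_profiles
    perms = np.array(list(itertools.permutations(range(P))), dtype=np.int64)
    # pos[e, j] = 0-based position of element j in permutation e
    pos = np.empty_like(perms)
    rows = np.arange(perms.shape[0])[:, None]
    pos[rows, perms] = np.arange(P)[None, :]
    valid = np.ones(perms.shape[0], dtype=bool)
    below_pairs = np.argwhere(poset.below)
    for i, j in below_pairs:
        valid &= pos[:, i] < pos[:, j]
    assert valid.any()
    return pos[valid].mean(axis=0) + 1.0


def brute_force_bh(p_values, q: float) -> np.ndarray:
    """Step-up FDR oracle written as the literal textbook loop."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k_star = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i / m * q:
            k_star = i
    flags = np.zeros(m, dtype=bool)
    for i in range(k_star):
        flags[order[i]] = True
    return flags


@pytest.fixture
def simple_specs():
    return [
        VariableSpec("edu", "ordered", ("low", "mid", "high")),
        VariableSpec("area", "nominal", ("A", "B", "C")),
    ]


@pytest.fixture
def tiny_population():
    """60 units, 2 ordered confounders, 3 treatments, mildly unbalanced."""
    rng = np.random.default_rng(42)
    n = 60
    df = pd.DataFrame(
        {
            "unit_id": np.arange(n),
            "age": rng.choice(["young", "mid", "old"], size=n, p=[0.4, 0.4, 0.2]),
            "edu": rng.choice(["low", "high"], size=n, p=[0.6, 0.4]),
            "treatment": rng.choice(["t1", "t2", "t3"], size=n),
            "outcome": rng.integers(0, 2, size=n),
        }
    )
    specs = [
        VariableSpec("age", "ordered", ("young", "mid", "old")),
        VariableSpec("edu", "ordered", ("low", "high")),
    ]
    return df, specs
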