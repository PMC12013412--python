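"""Shared fixtures and independent brute-force oracles.

The oracle functions deliberately use plain Python loops and ``math.log`` so
they share no code path with the vectorised implementations they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from microred.core import Community, FunctionReference, FunctionalProfile


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def naive_entropy(p) -> float:
    total = 0.0
    for pi in p:
        if pi > 0:
            total -= pi * math.log(pi)
    return total


def naive_kl(p, q) -> float:
    total = 0.0
    for pi, qi in zip(p, q):
        if pi > 0:
            total += pi * math.log(pi / qi)
    return total


def naive_sample_fr(f, n) -> float:
    total = sum(f)
    shares = [fi / total for fi in f]
    return naive_entropy(shares) - math.log(n)


def naive_abundance_fr(f, a) -> float:
    total = sum(f)
    shares = [fi / total for fi in f]
    return -naive_kl(shares, a)


def naive_interdependency(f, a) -> float:
    total = sum(f)
    shares = [fi / total for fi in f]
    restricted = [(s, ai) for s, ai in zip(shares, a) if s > 0]
    a_sum = sum(ai for _, ai in restricted)
    return naive_kl(
        [s for s, _ in restricted], [ai / a_sum for _, ai in restricted]
    )


# ---------------------------------------------------------------------------
# Community fixtures
# ---------------------------------------------------------------------------


def random_community_and_profile(rng, n=None, n_producers=None):
    """A random valid community plus an aligned profile with >=1 producer."""
    n = n or int(rng.integers(2, 12))
    abundances = rng.dirichlet(np.ones(n))
    ids = tuple(f"sp{i}" for i in range(n))
    community = Community(ids, abundances)
    k = n_producers or int(rng.integers(1, n + 1))
    contributions = np.zeros(n)
    producers = rng.choice(n, size=k, replace=False)
    contributions[producers] = rng.uniform(0.1, 5.0, size=k)
    profile = FunctionalProfile("fn", contributions)
    return community, profile


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def uniform4():
    return Community(("a", "b", "c", "d"), np.full(4, 0.25))


@pytest.fixture
def toy():
    from microred.fixtures import toy_objects

    return toy_objects()


def keystone_objects(n: int, m: int = 100):
    """Uniform community of size n, one producer, reference of m species."""
    ids = tuple(f"sp{i + 1:03d}" for i in range(n))
    community = Community(ids, np.full(n, 1.0 / n))
    contributions = np.zeros(n)
    contributions[0] = 1.0
    profile = FunctionalProfile("keystone_function", contributions)
    reference = FunctionReference(
        "keystone_function",
        frozenset({"sp001"} | {f"ref{i:03d}" for i in range(2, m + 1)}),
    )
    return community, profile, reference
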