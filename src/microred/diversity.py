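"""Classical alpha-diversity indices (natural-log convention)."""

from __future__ import annotations

import math

import numpy as np

from .core import Community, shannon_entropy


def richness(community: Community) -> int:
    """Number of species with positive abundance."""
    return int((community.abundances > 0).sum())


def shannon_diversity(community: Community) -> float:
    """Shannon entropy of the abundance vector, in nats."""
    return shannon_entropy(community.abundances)


def simpson_diversity(community: Community) -> float:
    """Simpson's diversity ``1 - sum(a_i^2)``, in [0, 1)."""
    a = community.abundances
    return float(1.0 - np.dot(a, a))


def evenness(community: Community) -> float | None:
    """Shannon entropy divided by log richness, in (0, 1].

    Undefined for single-species communities (log richness is zero); returns
    ``None`` in that case.
    """
    r = richness(community)
    if r < 2:
        return None
    return shannon_diversity(community) / math.log(r)
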