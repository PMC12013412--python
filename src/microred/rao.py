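"""Community-level multi-trait redundancy: Gower dissimilarity and Rao's Q.

This is the contrast measure: redundancy defined as the part of Simpson's
diversity not explained by abundance-weighted trait dissimilarity,
``FR = D - Q`` with ``Q = sum_ij d_ij a_i a_j``.  The keystone series — one
producer among uniformly abundant species — demonstrates how this community
measure diverges from the single-function relative-entropy measures: it grows
towards 1 with richness while the single-function measures fall.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    AlignmentError,
    Community,
    FunctionReference,
    FunctionalProfile,
    ValidationError,
)
from .core import abundance_fr as _abundance_fr
from .core import reference_taxon_fr as _reference_taxon_fr
from .core import sample_taxon_fr as _sample_taxon_fr
from .diversity import simpson_diversity

TRAIT_KINDS = ("binary", "quantitative")


@dataclass(frozen=True)
class TraitMatrix:
    """Species-by-trait values with a kind ("binary"/"quantitative") per trait."""

    species_ids: tuple[str, ...]
    trait_names: tuple[str, ...]
    values: np.ndarray
    kinds: tuple[str, ...]

    def __post_init__(self) -> None:
        ids = tuple(str(s) for s in self.species_ids)
        names = tuple(str(t) for t in self.trait_names)
        kinds = tuple(str(k) for k in self.kinds)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "species_ids", ids)
        object.__setattr__(self, "trait_names", names)
        object.__setattr__(self, "kinds", kinds)
        object.__setattr__(self, "values", vals)
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate species in trait matrix")
        if vals.ndim != 2 or vals.shape != (len(ids), len(names)):
            raise ValidationError(
                f"trait values must have shape ({len(ids)}, {len(names)}), "
                f"got {vals.shape}"
            )
        if len(kinds) != len(names):
            raise ValidationError("one kind required per trait")
        for kind in kinds:
            if kind not in TRAIT_KINDS:
                raise ValidationError(f"unknown trait kind {kind!r}")
        if not np.all(np.isfinite(vals)):
            raise ValidationError("trait values must be finite")
        for j, kind in enumerate(kinds):
            if kind == "binary" and not np.isin(vals[:, j], (0.0, 1.0)).all():
                raise ValidationError(
                    f"binary trait {names[j]!r} has values outside {{0, 1}}"
                )


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric species dissimilarities in [0, 1] with a zero diagonal."""

    species_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        ids = tuple(str(s) for s in self.species_ids)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "species_ids", ids)
        object.__setattr__(self, "values", vals)
        n = len(ids)
        if vals.shape != (n, n):
            raise ValidationError(f"expected a {n}x{n} matrix, got {vals.shape}")
        if np.any(vals < -1e-12) or np.any(vals > 1 + 1e-12):
            raise ValidationError("dissimilarities must lie in [0, 1]")
        if not np.allclose(vals, vals.T, atol=1e-12):
            raise ValidationError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(vals), 0.0, atol=1e-12):
            raise ValidationError("dissimilarity diagonal must be zero")


def gower_dissimilarity(traits: TraitMatrix) -> DissimilarityMatrix:
    """Square root of one minus Gower's general similarity coefficient.

    Traits are equally weighted; quantitative traits are range-normalised,
    binary traits compared by symmetric matching (equal -> similarity 1).
    Quantitative traits with zero range carry no information and are dropped
    with a warning.
    """
    n = len(traits.species_ids)
    sim_sum = np.zeros((n, n))
    used = 0
    for j, kind in enumerate(traits.kinds):
        col = traits.values[:, j]
        if kind == "quantitative":
            rng = col.max() - col.min()
            if rng == 0.0:
                warnings.warn(
                    f"dropping constant quantitative trait {traits.trait_names[j]!r}",
                    stacklevel=2,
                )
                continue
            sim = 1.0 - np.abs(col[:, None] - col[None, :]) / rng
        else:
            sim = (col[:, None] == col[None, :]).astype(float)
        sim_sum += sim
        used += 1
    if used == 0:
        raise ValidationError("no informative traits left after dropping constants")
    s = sim_sum / used
    d = np.sqrt(np.clip(1.0 - s, 0.0, 1.0))
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(traits.species_ids, d)


def _check_alignment(community: Community, d: DissimilarityMatrix) -> None:
    if community.species_ids != d.species_ids:
        raise AlignmentError(
            "dissimilarity matrix species order does not match the community"
        )


def rao_q(community: Community, d: DissimilarityMatrix) -> float:
    """Rao's quadratic entropy ``sum_ij d_ij a_i a_j``.

    Equals Simpson's diversity when all off-diagonal dissimilarities are 1.
    """
    _check_alignment(community, d)
    a = community.abundances
    return float(a @ d.values @ a)


def community_fr(community: Community, d: DissimilarityMatrix) -> float:
    """Community-level redundancy ``D - Q``, scaled to [0, 1]."""
    _check_alignment(community, d)
    return simpson_diversity(community) - rao_q(community, d)


def keystone_dissimilarity(n: int, producer_index: int = 0) -> DissimilarityMatrix:
    """Dissimilarity from a single binary producer/non-producer trait.

    d = 1 between the producer and every non-producer, 0 otherwise — the
    minimal trait structure for a single-function comparison.
    """
    if not 0 <= producer_index < n:
        raise ValidationError("producer index out of range")
    ids = tuple(f"sp{i + 1:03d}" for i in range(n))
    trait = np.zeros((n, 1))
    trait[producer_index, 0] = 1.0
    return gower_dissimilarity(TraitMatrix(ids, ("producer",), trait, ("binary",)))


def keystone_series(n_max: int, m: int) -> pd.DataFrame:
    """Evaluate all measures on uniform single-producer communities of size 1..n_max.

    Each community has uniform abundances and exactly one producing species; the
    reference holds ``m`` capable species (the producer plus theoretical ones).
    Returns one row per richness with columns ``richness``, ``sample_fr``,
    ``reference_fr``, ``abundance_fr`` and ``community_fr``.
    """
    if not 1 <= n_max <= m:
        raise ValidationError("need 1 <= n_max <= m")
    # m capable species: the sampled producer plus m-1 outside the sample
    reference = FunctionReference(
        "keystone_function",
        frozenset({"sp001"} | {f"ref{i + 1:03d}" for i in range(1, m)}),
    )
    rows = []
    for n in range(1, n_max + 1):
        ids = tuple(f"sp{i + 1:03d}" for i in range(n))
        community = Community(ids, np.full(n, 1.0 / n))
        contributions = np.zeros(n)
        contributions[0] = 1.0
        profile = FunctionalProfile("keystone_function", contributions)
        d = keystone_dissimilarity(n)
        rows.append(
            {
                "richness": n,
                "sample_fr": _sample_taxon_fr(profile, community),
                "reference_fr": _reference_taxon_fr(profile, community, reference),
                "abundance_fr": _abundance_fr(profile, community),
                "community_fr": community_fr(community, d),
            }
        )
    return pd.DataFrame(rows)
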