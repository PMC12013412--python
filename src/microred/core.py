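"""Relative-entropy measures of single-function redundancy and interdependency.

A community carries relative abundances ``a`` for its ``n`` species; for one
function, each species has a non-negative quantitative output ``f`` whose
normalisation ``f / sum(f)`` is the vector of *functional shares*.  All
measures here are Kullback-Leibler divergences (natural logarithm, reported in
nats) between the share vector and a baseline distribution:

* :func:`sample_taxon_fr` — negative divergence from the uniform distribution
  over the ``n`` sampled species; 0 means every species contributes equally,
  ``-log(n)`` means a single species carries the function.
* :func:`reference_taxon_fr` — same, but uniform over the ``m`` species of an
  external reference of all species able to perform the function, which makes
  values comparable across samples.
* :func:`abundance_fr` — negative divergence from the abundance vector; 0 means
  shares mirror abundances exactly.
* :func:`interdependency_index` — divergence between producer-restricted shares
  and producer-renormalised abundances; 0 iff every producer's output is
  proportional to its abundance, larger values indicate that the function
  depends on more than each species' own abundance.

Degenerate-but-expected situations (no producer at all) surface as ``None``
with a :class:`MissingReason`; structural problems (misaligned vectors,
producers outside the reference, support violations) raise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

#: Shares or fluxes with magnitude at or below this are treated as exact zeros
#: (solver noise floor); override per call where needed.
DEFAULT_ZERO_TOL = 1e-12

#: Absolute tolerance for "sums to one" checks on probability vectors.
SIMPLEX_ATOL = 1e-8


class ValidationError(ValueError):
    """Input violates a structural contract (shape, sign, normalisation)."""


class AlignmentError(ValidationError):
    """Vectors that must share a species order have incompatible shapes/ids."""


class ConsistencyError(ValidationError):
    """A producing species is absent from the function's reference set."""


class SupportViolationError(ValidationError):
    """KL divergence requested where q = 0 on the support of p."""


class MissingReason(str, Enum):
    NONE = "none"
    NO_PRODUCERS = "no_producers"
    UPTAKE_DETECTED = "uptake_detected"
    SUPPORT_VIOLATION = "support_violation"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


def _as_float_vector(values: Iterable[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if arr.size == 0:
        raise ValidationError(f"{name} must not be empty")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite entries")
    return arr


@dataclass(frozen=True)
class Community:
    """Species of one sample with strictly positive relative abundances.

    Invariants: unique species ids, every abundance > 0, abundances sum to 1
    within tolerance.  Use :meth:`from_raw` to drop zero rows and renormalise
    arbitrary non-negative input.
    """

    species_ids: tuple[str, ...]
    abundances: np.ndarray

    def __post_init__(self) -> None:
        ids = tuple(str(s) for s in self.species_ids)
        object.__setattr__(self, "species_ids", ids)
        abund = _as_float_vector(self.abundances, "abundances")
        object.__setattr__(self, "abundances", abund)
        if len(ids) != abund.size:
            raise AlignmentError(
                f"{len(ids)} species ids but {abund.size} abundances"
            )
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate species ids in community")
        if np.any(abund <= 0):
            raise ValidationError("community abundances must be strictly positive")
        total = float(abund.sum())
        if abs(total - 1.0) > SIMPLEX_ATOL:
            raise ValidationError(
                f"abundances must sum to 1 (got {total!r}); "
                "normalise upstream or use Community.from_raw"
            )

    @property
    def n(self) -> int:
        return len(self.species_ids)

    def index_of(self, species_id: str) -> int:
        return self.species_ids.index(species_id)

    @classmethod
    def from_raw(
        cls, species_ids: Sequence[str], values: Iterable[float]
    ) -> "Community":
        """Build a community from raw non-negative values.

        Zero-valued species are dropped and the remainder renormalised to sum
        to one.  Raises if nothing positive remains.
        """
        arr = _as_float_vector(values, "abundances")
        if len(species_ids) != arr.size:
            raise AlignmentError("species ids and abundances differ in length")
        if np.any(arr < 0):
            raise ValidationError("raw abundances must be non-negative")
        keep = arr > 0
        if not keep.any():
            raise ValidationError("all abundances are zero")
        kept_ids = tuple(s for s, k in zip(species_ids, keep) if k)
        kept = arr[keep]
        return cls(kept_ids, kept / kept.sum())


@dataclass(frozen=True)
class FunctionalProfile:
    """Per-species quantitative output of one function, aligned to a community.

    ``contributions`` follows the species order of the community it is paired
    with; entries are >= 0 in function units (e.g. mmol/gDW/h for secretion
    fluxes).  ``upper_bound`` is the theoretical maximum of the function; it is
    stored for provenance but enters no downstream formula.
    """

    function_id: str
    contributions: np.ndarray
    upper_bound: float | None = None

    def __post_init__(self) -> None:
        contrib = _as_float_vector(self.contributions, "contributions")
        object.__setattr__(self, "contributions", contrib)
        if np.any(contrib < 0):
            raise ValidationError(
                f"negative contribution in profile {self.function_id!r}; "
                "apply the secretion sign convention upstream"
            )

    def __len__(self) -> int:
        return int(self.contributions.size)

    def shares(self, zero_tol: float = DEFAULT_ZERO_TOL) -> np.ndarray | None:
        """Normalised share vector, or ``None`` when nothing is produced.

        Entries at or below ``zero_tol`` are zeroed before normalising so that
        solver noise cannot create spurious producers.
        """
        f = np.where(self.contributions > zero_tol, self.contributions, 0.0)
        total = f.sum()
        if total <= 0.0:
            return None
        return f / total


@dataclass(frozen=True)
class FunctionReference:
    """All species able to perform a function in theory (size ``m``).

    ``m`` is fixed per function across every sample; the reference is supplied
    explicitly rather than inferred from any one sample.
    """

    function_id: str
    capable_species: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "capable_species", frozenset(str(s) for s in self.capable_species)
        )
        if not self.capable_species:
            raise ValidationError(
                f"reference for {self.function_id!r} must contain at least one species"
            )

    @property
    def m(self) -> int:
        return len(self.capable_species)


@dataclass(frozen=True)
class RedundancyResult:
    """All measures for one (sample, function) pair plus provenance."""

    function_id: str
    sample_id: str
    sample_taxon_fr: float | None
    reference_taxon_fr: float | None
    abundance_fr: float | None
    interdependency: float | None
    n: int
    m: int
    k: int
    producer_abundance_sum: float
    missing_reason: MissingReason = MissingReason.NONE

    @property
    def is_missing(self) -> bool:
        return self.missing_reason is not MissingReason.NONE


# ---------------------------------------------------------------------------
# Entropy primitives
# ---------------------------------------------------------------------------


def _check_simplex(p: np.ndarray, name: str) -> None:
    if np.any(p < 0):
        raise ValidationError(f"{name} has negative entries")
    total = float(p.sum())
    if abs(total - 1.0) > SIMPLEX_ATOL:
        raise ValidationError(f"{name} must sum to 1, got {total!r}")


def shannon_entropy(p: Iterable[float]) -> float:
    """Shannon entropy of a probability vector in nats (0*log 0 := 0)."""
    arr = _as_float_vector(p, "p")
    _check_simplex(arr, "p")
    pos = arr[arr > 0]
    return float(-(pos * np.log(pos)).sum())


def kl_divergence(p: Iterable[float], q: Iterable[float]) -> float:
    """Kullback-Leibler divergence D(p || q) in nats.

    Requires absolute continuity: ``q`` must be positive wherever ``p`` is.
    A violation raises :class:`SupportViolationError` rather than returning
    infinity.  The result is clamped at 0 to absorb rounding when ``p == q``.
    """
    parr = _as_float_vector(p, "p")
    qarr = _as_float_vector(q, "q")
    if parr.size != qarr.size:
        raise AlignmentError(f"length mismatch: {parr.size} vs {qarr.size}")
    _check_simplex(parr, "p")
    _check_simplex(qarr, "q")
    mask = parr > 0
    if np.any(qarr[mask] == 0):
        raise SupportViolationError("q is zero on the support of p")
    val = float((parr[mask] * np.log(parr[mask] / qarr[mask])).sum())
    return max(val, 0.0)


# ---------------------------------------------------------------------------
# Redundancy / interdependency measures
# ---------------------------------------------------------------------------


def _aligned_shares(
    profile: FunctionalProfile, community: Community, zero_tol: float
) -> np.ndarray | None:
    if len(profile) != community.n:
        raise AlignmentError(
            f"profile {profile.function_id!r} has {len(profile)} entries for a "
            f"{community.n}-species community"
        )
    return profile.shares(zero_tol)


def sample_taxon_fr(
    profile: FunctionalProfile,
    community: Community,
    zero_tol: float = DEFAULT_ZERO_TOL,
) -> float | None:
    """Taxon-based redundancy against the sampled species, in [-log n, 0].

    Equals ``H(shares) - log(n)``: zero iff every sampled species contributes
    an equal positive amount, ``-log(n)`` iff a single species carries the
    whole function.  ``None`` when there is no producer.
    """
    shares = _aligned_shares(profile, community, zero_tol)
    if shares is None:
        return None
    return shannon_entropy(shares) - math.log(community.n)


def reference_taxon_fr(
    profile: FunctionalProfile,
    community: Community,
    reference: FunctionReference,
    zero_tol: float = DEFAULT_ZERO_TOL,
) -> float | None:
    """Taxon-based redundancy against a fixed reference of ``m`` capable species.

    Reference members absent from the sample contribute zero shares, so the
    value is ``H(shares) - log(m)``, in ``[-log m, 0]`` and comparable across
    samples.  Raises :class:`ConsistencyError` if a producing species is not in
    the reference.
    """
    shares = _aligned_shares(profile, community, zero_tol)
    if shares is None:
        return None
    producers = {
        sid for sid, s in zip(community.species_ids, shares) if s > 0
    }
    rogue = producers - reference.capable_species
    if rogue:
        raise ConsistencyError(
            f"species {sorted(rogue)} produce {profile.function_id!r} but are "
            "missing from its reference set"
        )
    return shannon_entropy(shares) - math.log(reference.m)


def abundance_fr(
    profile: FunctionalProfile,
    community: Community,
    zero_tol: float = DEFAULT_ZERO_TOL,
) -> float | None:
    """Abundance-based redundancy ``-D(shares || abundances)`` <= 0.

    Zero iff the share vector equals the abundance vector elementwise; the
    community invariant (all abundances positive) guarantees absolute
    continuity.  ``None`` when there is no producer.
    """
    shares = _aligned_shares(profile, community, zero_tol)
    if shares is None:
        return None
    return -kl_divergence(shares, community.abundances)


def interdependency_index(
    profile: FunctionalProfile,
    community: Community,
    zero_tol: float = DEFAULT_ZERO_TOL,
) -> float | None:
    """KL divergence between producer shares and producer-renormalised abundances.

    Restricted to the set J of species with positive shares; abundances are
    renormalised over J.  Non-negative, and exactly zero iff the output of each
    producer is proportional to its abundance (trivially so for a single
    producer).  ``None`` when there is no producer.
    """
    shares = _aligned_shares(profile, community, zero_tol)
    if shares is None:
        return None
    mask = shares > 0
    restricted_a = community.abundances[mask]
    return kl_divergence(shares[mask], restricted_a / restricted_a.sum())


def global_interdependency(
    indices: Iterable[float | None], min_count: int = 1
) -> float | None:
    """Median of per-function interdependency indices within one sample.

    Missing entries (``None``/NaN) are dropped first; if fewer than
    ``min_count`` values remain the global index itself is missing.  Even
    counts use the mean of the central pair.
    """
    values = [
        float(v) for v in indices if v is not None and not math.isnan(float(v))
    ]
    if len(values) < max(min_count, 1):
        return None
    return float(np.median(values))


def compute_all(
    profile: FunctionalProfile,
    community: Community,
    reference: FunctionReference,
    sample_id: str = "",
    zero_tol: float = DEFAULT_ZERO_TOL,
) -> RedundancyResult:
    """Evaluate every measure for one (sample, function) pair.

    No-producer profiles are recorded as missing rather than raised; structural
    errors (misalignment, producers outside the reference) propagate.
    """
    shares = _aligned_shares(profile, community, zero_tol)
    if shares is None:
        return RedundancyResult(
            function_id=profile.function_id,
            sample_id=sample_id,
            sample_taxon_fr=None,
            reference_taxon_fr=None,
            abundance_fr=None,
            interdependency=None,
            n=community.n,
            m=reference.m,
            k=0,
            producer_abundance_sum=0.0,
            missing_reason=MissingReason.NO_PRODUCERS,
        )
    mask = shares > 0
    return RedundancyResult(
        function_id=profile.function_id,
        sample_id=sample_id,
        sample_taxon_fr=sample_taxon_fr(profile, community, zero_tol),
        reference_taxon_fr=reference_taxon_fr(profile, community, reference, zero_tol),
        abundance_fr=abundance_fr(profile, community, zero_tol),
        interdependency=interdependency_index(profile, community, zero_tol),
        n=community.n,
        m=reference.m,
        k=int(mask.sum()),
        producer_abundance_sum=float(community.abundances[mask].sum()),
        missing_reason=MissingReason.NONE,
    )
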