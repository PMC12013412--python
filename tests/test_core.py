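"""Unit tests for the relative-entropy measures and their domain types."""

import math

import numpy as np
import pytest

from microred.core import (
    AlignmentError,
    Community,
    ConsistencyError,
    FunctionReference,
    FunctionalProfile,
    MissingReason,
    SupportViolationError,
    ValidationError,
    abundance_fr,
    compute_all,
    global_interdependency,
    interdependency_index,
    kl_divergence,
    reference_taxon_fr,
    sample_taxon_fr,
    shannon_entropy,
)
from conftest import keystone_objects


class TestCommunity:
    def test_valid(self):
        c = Community(("a", "b"), np.array([0.5, 0.5]))
        assert c.n == 2

    def test_rejects_zero_abundance(self):
        with pytest.raises(ValidationError):
            Community(("a", "b"), np.array([1.0, 0.0]))

    def test_rejects_unnormalised(self):
        with pytest.raises(ValidationError):
            Community(("a", "b"), np.array([0.5, 0.2]))

    def test_rejects_duplicate_ids(self):
        with pytest.raises(ValidationError):
            Community(("a", "a"), np.array([0.5, 0.5]))

    def test_length_mismatch(self):
        with pytest.raises(AlignmentError):
            Community(("a",), np.array([0.5, 0.5]))

    def test_from_raw_drops_zeros_and_normalises(self):
        c = Community.from_raw(["a", "b", "c"], [2.0, 0.0, 2.0])
        assert c.species_ids == ("a", "c")
        np.testing.assert_allclose(c.abundances, [0.5, 0.5])

    def test_from_raw_all_zero(self):
        with pytest.raises(ValidationError):
            Community.from_raw(["a"], [0.0])


class TestFunctionalProfile:
    def test_rejects_negative(self):
        with pytest.raises(ValidationError):
            FunctionalProfile("f", np.array([1.0, -0.1]))

    def test_shares_none_when_empty(self):
        assert FunctionalProfile("f", np.zeros(3)).shares() is None

    def test_shares_zero_tol(self):
        p = FunctionalProfile("f", np.array([1.0, 1e-15]))
        np.testing.assert_allclose(p.shares(), [1.0, 0.0])

    def test_reference_requires_species(self):
        with pytest.raises(ValidationError):
            FunctionReference("f", frozenset())


class TestShannonEntropy:
    def test_uniform_maximises(self):
        assert shannon_entropy([0.25] * 4) == pytest.approx(math.log(4))

    def test_degenerate(self):
        assert shannon_entropy([1.0]) == 0.0

    def test_hand_summed(self):
        # oracle: -(0.5 log 0.5 + 2 * 0.25 log 0.25) = 1.0397207708399179
        assert shannon_entropy([0.5, 0.25, 0.25]) == pytest.approx(
            1.0397207708399179, abs=1e-12
        )

    def test_rejects_unnormalised(self):
        with pytest.raises(ValidationError):
            shannon_entropy([0.5, 0.2])

    def test_rejects_negative(self):
        with pytest.raises(ValidationError):
            shannon_entropy([1.2, -0.2])


class TestKLDivergence:
    def test_identity(self):
        assert kl_divergence([0.3, 0.7], [0.3, 0.7]) == 0.0

    def test_hand_summed(self):
        # oracle: 0.5 log 2 + 0.5 log(2/3) = 0.14384103622589045
        assert kl_divergence([0.5, 0.5], [0.25, 0.75]) == pytest.approx(
            0.14384103622589045, abs=1e-12
        )

    def test_support_violation(self):
        with pytest.raises(SupportViolationError):
            kl_divergence([1.0, 0.0], [0.0, 1.0])

    def test_zero_in_p_ok(self):
        assert kl_divergence([1.0, 0.0], [0.5, 0.5]) == pytest.approx(math.log(2))

    def test_length_mismatch(self):
        with pytest.raises(AlignmentError):
            kl_divergence([1.0], [0.5, 0.5])


class TestSampleTaxonFR:
    def test_single_producer_among_100(self):
        community, profile, _ = keystone_objects(100)
        assert sample_taxon_fr(profile, community) == pytest.approx(
            -math.log(100), abs=1e-12
        )

    def test_uniform_shares_maximal(self, uniform4):
        profile = FunctionalProfile("f", np.full(4, 0.7))
        assert sample_taxon_fr(profile, uniform4) == pytest.approx(0.0, abs=1e-12)

    def test_hand_summed(self, uniform4):
        # oracle: H(0.5, 0.25, 0.25) - log 4 = -0.3465735902799727
        profile = FunctionalProfile("f", np.array([2.0, 1.0, 1.0, 0.0]))
        assert sample_taxon_fr(profile, uniform4) == pytest.approx(
            -0.3465735902799727, abs=1e-12
        )

    def test_no_producers_missing(self, uniform4):
        assert sample_taxon_fr(FunctionalProfile("f", np.zeros(4)), uniform4) is None

    def test_misaligned(self, uniform4):
        with pytest.raises(AlignmentError):
            sample_taxon_fr(FunctionalProfile("f", np.ones(3)), uniform4)


class TestReferenceTaxonFR:
    @pytest.mark.parametrize("n", [1, 7, 42, 100])
    def test_single_producer_constant(self, n):
        community, profile, reference = keystone_objects(n, m=100)
        assert reference_taxon_fr(profile, community, reference) == pytest.approx(
            -math.log(100), abs=1e-12
        )

    def test_all_reference_present_equal_shares(self):
        ids = ("a", "b", "c")
        community = Community(ids, np.array([0.2, 0.3, 0.5]))
        profile = FunctionalProfile("f", np.full(3, 1.0))
        reference = FunctionReference("f", frozenset(ids))
        assert reference_taxon_fr(profile, community, reference) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_toy_geometry(self, toy):
        # oracle: log 4 - log 7 = -0.5596157879354227
        community, profile, reference = toy
        assert reference_taxon_fr(profile, community, reference) == pytest.approx(
            math.log(4) - math.log(7), abs=1e-12
        )

    def test_producer_outside_reference(self, uniform4):
        profile = FunctionalProfile("f", np.ones(4))
        reference = FunctionReference("f", frozenset({"a", "b", "c"}))
        with pytest.raises(ConsistencyError):
            reference_taxon_fr(profile, uniform4, reference)


class TestAbundanceFR:
    def test_proportional_is_zero(self, rng):
        a = rng.dirichlet(np.ones(6))
        community = Community(tuple("abcdef"), a)
        profile = FunctionalProfile("f", 3.5 * a)
        assert abundance_fr(profile, community) == pytest.approx(0.0, abs=1e-12)

    def test_single_producer_uniform_100(self):
        community, profile, _ = keystone_objects(100)
        assert abundance_fr(profile, community) == pytest.approx(
            -math.log(100), abs=1e-12
        )

    def test_hand_summed(self):
        # oracle: -(0.5 log 2 + 0.5 log 2) = -log 2
        community = Community(("a", "b", "c"), np.array([0.25, 0.25, 0.5]))
        profile = FunctionalProfile("f", np.array([1.0, 1.0, 0.0]))
        assert abundance_fr(profile, community) == pytest.approx(
            -math.log(2), abs=1e-12
        )


class TestInterdependencyIndex:
    def test_proportional_on_support_zero(self, rng):
        a = rng.dirichlet(np.ones(8))
        community = Community(tuple(f"s{i}" for i in range(8)), a)
        f = np.zeros(8)
        f[:3] = 2.0 * a[:3]  # only 3 producers, but proportional on J
        assert interdependency_index(
            FunctionalProfile("f", f), community
        ) == pytest.approx(0.0, abs=1e-12)

    def test_single_producer_zero(self):
        community, profile, _ = keystone_objects(50)
        assert interdependency_index(profile, community) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_hand_summed(self):
        # shares (0.8, 0.2) vs restricted abundances (0.5, 0.5):
        # 0.8 log 1.6 + 0.2 log 0.4 = 0.19274475702175742
        community = Community(("a", "b", "c"), np.array([0.3, 0.3, 0.4]))
        profile = FunctionalProfile("f", np.array([0.8, 0.2, 0.0]))
        assert interdependency_index(profile, community) == pytest.approx(
            0.19274475702175742, abs=1e-12
        )


class TestGlobalInterdependency:
    def test_odd_median(self):
        assert global_interdependency([0.1, 0.2, 0.3]) == pytest.approx(0.2)

    def test_even_median_mean_of_central(self):
        assert global_interdependency([0.1, 0.2, 0.3, 0.4]) == pytest.approx(0.25)

    def test_singleton(self):
        assert global_interdependency([0.5]) == pytest.approx(0.5)

    def test_missing_dropped(self):
        assert global_interdependency([None, 0.4, float("nan")]) == pytest.approx(0.4)

    def test_min_count(self):
        assert global_interdependency([0.1], min_count=2) is None


class TestComputeAll:
    def test_keystone_composition(self):
        community, profile, reference = keystone_objects(100, m=100)
        result = compute_all(profile, community, reference, sample_id="s1")
        assert result.sample_taxon_fr == pytest.approx(-math.log(100), abs=1e-12)
        assert result.reference_taxon_fr == pytest.approx(-math.log(100), abs=1e-12)
        assert result.abundance_fr == pytest.approx(-math.log(100), abs=1e-12)
        assert result.interdependency == pytest.approx(0.0, abs=1e-12)
        assert (result.n, result.m, result.k) == (100, 100, 1)
        assert result.producer_abundance_sum == pytest.approx(0.01)
        assert result.missing_reason is MissingReason.NONE

    def test_no_producers_recorded_not_raised(self, uniform4):
        reference = FunctionReference("f", frozenset({"a"}))
        result = compute_all(FunctionalProfile("f", np.zeros(4)), uniform4, reference)
        assert result.is_missing
        assert result.missing_reason is MissingReason.NO_PRODUCERS
        assert result.sample_taxon_fr is None
        assert result.interdependency is None
        assert result.k == 0

    def test_proportional_closed_form(self, rng):
        # fj = c*aj on J  =>  abundance_fr = log(sum of producer abundances)
        a = rng.dirichlet(np.ones(10))
        ids = tuple(f"s{i}" for i in range(10))
        community = Community(ids, a)
        f = np.zeros(10)
        f[:6] = 2.0 * a[:6]
        reference = FunctionReference("f", frozenset(ids[:6]))
        result = compute_all(FunctionalProfile("f", f), community, reference)
        assert result.abundance_fr == pytest.approx(
            math.log(a[:6].sum()), abs=1e-12
        )
        assert result.interdependency == pytest.approx(0.0, abs=1e-12)
        assert result.producer_abundance_sum == pytest.approx(a[:6].sum())

    def test_misaligned_raises(self, uniform4):
        reference = FunctionReference("f", frozenset({"a"}))
        with pytest.raises(AlignmentError):
            compute_all(FunctionalProfile("f", np.ones(5)), uniform4, reference)
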