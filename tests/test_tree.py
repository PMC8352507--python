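import math

import numpy as np
import pytest

from rfpt import (
    UNCONSTRAINED,
    Dataset,
    SearchMode,
    SignProfile,
    SolutionClass,
    StepPolicy,
    TreeConfig,
    count_solutions,
    fit_neuron_step,
    grow_tree,
    perfect_tree_exists,
    sign_profile,
    verify_perfect,
)
from rfpt.tree import InvalidStateError, TreeResult, _search_exhaustive

from conftest import random_small_instance


class TestFitNeuronStep:
    def test_negative_step_tie_broken_lexicographically(self, xor_like, stump_config):
        # brute force over 3 vectors x all midpoints: best error-free
        # finalization is 1 sample, attained by (-1) peeling x=4 and (+1)
        # peeling x=1
        fit = fit_neuron_step(
            xor_like, [0], [0, 1, 2, 3], StepPolicy.FINALIZE_NEGATIVE, stump_config
        )
        assert fit.n_optimal_vectors == 2
        assert fit.neuron.coefficients == (-1.0,)
        assert fit.finalized_indices.tolist() == [3]
        assert fit.assigned_labels.tolist() == [0]

    def test_pure_node_is_unconstrained(self, stump_config):
        d = Dataset(np.array([[1.0], [5.0], [9.0]]), [0, 0, 0])
        fit = fit_neuron_step(d, [0], [0, 1, 2], StepPolicy.FINALIZE_NEGATIVE, stump_config)
        assert fit.finalized_indices.size == 3
        assert math.isinf(fit.n_optimal_vectors)

    def test_positive_step_finds_perfect_suffix(self, separable_1d, stump_config):
        fit = fit_neuron_step(
            separable_1d, [0], [0, 1, 2, 3], StepPolicy.FINALIZE_POSITIVE, stump_config
        )
        assert fit.neuron.coefficients == (1.0,)
        assert fit.neuron.threshold == pytest.approx(2.5)
        assert sorted(fit.finalized_indices.tolist()) == [2, 3]
        assert fit.n_optimal_vectors == 1

    def test_empty_finalization_is_legal(self, stump_config):
        # every sample is class 1: a negative step can finalize nothing
        d = Dataset(np.array([[1.0], [2.0]]), [1, 1])
        fit = fit_neuron_step(d, [0], [0, 1], StepPolicy.FINALIZE_NEGATIVE, stump_config)
        assert fit.finalized_indices.size == 0

    def test_empty_active_set_rejected(self, xor_like, stump_config):
        with pytest.raises(ValueError):
            fit_neuron_step(xor_like, [0], [], StepPolicy.FINALIZE_NEGATIVE, stump_config)


class TestGrowTree:
    def test_perfect_split_terminates_at_first_neuron(self, separable_1d, stump_config):
        t = grow_tree(separable_1d, [0], stump_config)
        assert t.is_perfect and t.neurons_used == 1
        assert t.neurons[0].policy is StepPolicy.FINALIZE_BOTH
        assert t.solution_class is SolutionClass.UNIQUE

    def test_interleaved_labels_need_peeling(self, xor_like, stump_config):
        t = grow_tree(xor_like, [0], stump_config)
        assert t.is_perfect and t.neurons_used <= 4
        assert verify_perfect(t, xor_like.y)
        assert t.solution_class is SolutionClass.FINITE
        assert t.solution_multiplicity == 2

    def test_pure_root(self, stump_config):
        d = Dataset(np.array([[1.0], [2.0], [3.0]]), [0, 0, 0])
        t = grow_tree(d, [0], stump_config)
        assert t.is_perfect and t.neurons_used == 1
        assert count_solutions(t) is SolutionClass.UNCONSTRAINED

    def test_contradictory_samples_never_perfect(self, stump_config):
        d = Dataset(np.array([[2.0], [2.0], [1.0]]), [0, 1, 0])
        t = grow_tree(d, [0], stump_config)
        assert not t.is_perfect
        assert not perfect_tree_exists(d, [0], stump_config)

    def test_empty_feature_subset_rejected(self, xor_like):
        with pytest.raises(ValueError):
            grow_tree(xor_like, [], TreeConfig(n_features_per_neuron=0))

    def test_step_budget_limits_depth(self):
        # strictly alternating labels along x need one peel per step
        x = np.arange(10.0)[:, None]
        y = np.arange(10) % 2
        cfg = TreeConfig(n_features_per_neuron=1, max_cycles=1, steps_per_cycle=2)
        t = grow_tree(Dataset(x, y), [0], cfg)
        assert t.neurons_used <= 2
        assert not t.is_perfect

    def test_duplicating_a_sample_preserves_perfection(self, stump_config):
        rng = np.random.default_rng(202)
        for _ in range(50):
            d = random_small_instance(rng, max_samples=7, tie_prone=True)
            t = grow_tree(d, [0], stump_config)
            if not t.is_perfect:
                continue
            i = int(rng.integers(d.n_samples))
            d2 = Dataset(
                np.vstack([d.X, d.X[i : i + 1]]), np.append(d.y, d.y[i])
            )
            t2 = grow_tree(d2, [0], stump_config)
            assert t2.is_perfect
            assert verify_perfect(t2, d2.y)

    def test_every_perfect_tree_passes_independent_verification(self, stump_config):
        rng = np.random.default_rng(77)
        checked = 0
        for _ in range(100):
            d = random_small_instance(rng, tie_prone=bool(rng.integers(2)))
            t = grow_tree(d, [0], stump_config)
            if t.is_perfect:
                assert verify_perfect(t, d.y)
                checked += 1
        assert checked > 10

    def test_finalized_sets_partition_samples_when_perfect(self, xor_like, stump_config):
        t = grow_tree(xor_like, [0], stump_config)
        seen = np.concatenate([idx for idx, _ in t.finalized if idx.size])
        assert sorted(seen.tolist()) == [0, 1, 2, 3]
        assert len(set(seen.tolist())) == seen.size


class TestOracle:
    def test_full_enumeration_matches_greedy_on_small_instances(self, stump_config):
        rng = np.random.default_rng(5)
        for i in range(60):
            d = random_small_instance(rng, tie_prone=bool(i % 2))
            assert (
                grow_tree(d, [0], stump_config).is_perfect
                == perfect_tree_exists(d, [0], stump_config)
            )

    def test_exhaustive_witness_is_verifiable(self, xor_like):
        cfg = TreeConfig(n_features_per_neuron=1, search_mode=SearchMode.FULL_ENUMERATION)
        witness = _search_exhaustive(xor_like, (0,), cfg)
        assert witness is not None
        assert verify_perfect(witness, xor_like.y)

    def test_full_enumeration_mode_through_grow_tree(self, xor_like):
        cfg = TreeConfig(n_features_per_neuron=1, search_mode=SearchMode.FULL_ENUMERATION)
        t = grow_tree(xor_like, [0], cfg)
        assert t.is_perfect and verify_perfect(t, xor_like.y)

    def test_two_feature_oracle_agreement(self):
        rng = np.random.default_rng(9)
        cfg = TreeConfig(n_features_per_neuron=2)
        for _ in range(40):
            m = int(rng.integers(2, 7))
            d = Dataset(rng.integers(0, 3, size=(m, 2)).astype(float), _both(rng, m))
            assert (
                grow_tree(d, [0, 1], cfg).is_perfect
                == perfect_tree_exists(d, [0, 1], cfg)
            )


def _both(rng, m):
    y = rng.integers(0, 2, size=m)
    if len(np.unique(y)) < 2:
        y[0] = 1 - y[0]
    return y


class TestSignProfileAndSolutions:
    def _result(self, coeff_sets):
        from rfpt import NeuronSpec

        neurons = [NeuronSpec(c, 0.0) for c in coeff_sets]
        return TreeResult(
            feature_indices=tuple(range(len(coeff_sets[0]))),
            neurons=neurons,
            finalized=[],
            per_neuron_solution_count=[1.0] * len(neurons),
            is_perfect=True,
            n_samples=0,
        )

    @pytest.mark.parametrize(
        "coeff_sets, expected",
        [
            ([(1.0, 1.0, 1.0)] * 3, SignProfile.ALL_POSITIVE),
            ([(1.0, 0.0)], SignProfile.MIXED_WITH_ZERO),
            ([(1.0, -1.0)], SignProfile.NON_MONOTONE),
            ([(0.0, 0.0), (0.0, 0.0)], SignProfile.ALL_ZERO),
            ([(-1.0,), (-1.0,)], SignProfile.ALL_NEGATIVE),
            ([(1.0,), (-1.0,)], SignProfile.NON_MONOTONE),
            ([(-1.0, 0.0)], SignProfile.MIXED_WITH_ZERO),
        ],
    )
    def test_categories_are_exclusive_and_exhaustive(self, coeff_sets, expected):
        assert sign_profile(self._result(coeff_sets)) is expected

    @pytest.mark.parametrize(
        "counts, expected, multiplicity",
        [
            ([1.0, 1.0, 1.0], SolutionClass.UNIQUE, 1),
            ([2.0, 1.0], SolutionClass.FINITE, 2),
            ([2.0, UNCONSTRAINED], SolutionClass.UNCONSTRAINED, math.inf),
        ],
    )
    def test_solution_class_from_per_neuron_counts(self, counts, expected, multiplicity):
        r = self._result([(1.0,)] * len(counts))
        r.per_neuron_solution_count = counts
        assert count_solutions(r) is expected
        assert r.solution_multiplicity == multiplicity

    def test_imperfect_tree_rejected(self):
        r = self._result([(1.0,)])
        r.is_perfect = False
        with pytest.raises(InvalidStateError):
            count_solutions(r)


class TestVerifyPerfect:
    def test_false_positive_among_finalized_fails(self):
        r = TreeResult(
            feature_indices=(0,),
            neurons=[],
            finalized=[(np.array([0, 1]), np.array([1, 0], dtype=np.int8))],
            per_neuron_solution_count=[],
            is_perfect=True,
            n_samples=2,
        )
        assert verify_perfect(r, [1, 1]) is False

    def test_exact_assignment_passes(self):
        r = TreeResult(
            feature_indices=(0,),
            neurons=[],
            finalized=[(np.array([0, 1]), np.array([1, 0], dtype=np.int8))],
            per_neuron_solution_count=[],
            is_perfect=True,
            n_samples=2,
        )
        assert verify_perfect(r, [1, 0]) is True

    def test_uncovered_sample_fails(self):
        r = TreeResult(
            feature_indices=(0,),
            neurons=[],
            finalized=[(np.array([0]), np.array([1], dtype=np.int8))],
            per_neuron_solution_count=[],
            is_perfect=True,
            n_samples=2,
        )
        assert verify_perfect(r, [1, 0]) is False
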