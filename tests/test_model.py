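import numpy as np
import pytest

import splandscape as sp
from splandscape.model import ModelError
from splandscape.patterns import MUTATION, ReadPattern

from conftest import random_structure
from oracles import mutation_pattern_prob_oracle, truncation_distribution_oracle


def single_site_candidates(constrained: bool) -> sp.CandidateSet:
    state = np.array([1 if constrained else 0], dtype=np.uint8)
    s = sp.Structure(id="s", sequence="A", pairs=frozenset(), state=state)
    return sp.CandidateSet(structures=[s])


class TestTruncationDesign:
    def test_single_unconstrained_site(self):
        X = sp.build_design_truncation(single_site_candidates(False), eta=0.2, gamma=0.0)
        np.testing.assert_allclose(X.values[:, 0], [0.2, 0.8])

    def test_single_constrained_site(self):
        X = sp.build_design_truncation(single_site_candidates(True), eta=0.2, gamma=np.array([0.05]))
        np.testing.assert_allclose(X.values[:, 0], [0.05, 0.95])

    @pytest.mark.parametrize("seed", range(8))
    def test_columns_are_distributions_and_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(2, 13))
        s = random_structure(rng, L)
        eta = rng.uniform(0, 0.9)
        gamma = rng.uniform(0, 0.5, size=L)
        X = sp.build_design_truncation(sp.CandidateSet(structures=[s]), eta, gamma)
        col = X.values[:, 0]
        assert abs(col.sum() - 1.0) < 1e-12
        if L <= 10:
            oracle = truncation_distribution_oracle(s.state, eta, gamma)
            np.testing.assert_allclose(col, oracle, atol=1e-12)

    def test_degenerate_parameters_rejected(self, bistable):
        _, a, _ = bistable
        cs = sp.CandidateSet(structures=[a])
        with pytest.raises(ModelError):
            sp.build_design_truncation(cs, eta=1.0, gamma=0.0)
        with pytest.raises(ModelError):
            sp.build_design_truncation(cs, eta=0.1, gamma=np.ones(len(a.sequence)))

    def test_all_unconstrained_reduces_to_average_profile_model(self):
        """With every site unconstrained, stop probabilities reduce to the
        single-profile drop-off model: Pr(stop at p) =
        [1-(1-gamma_p)(1-eta)] * prod_{k<p} (1-gamma_k)(1-eta)."""
        L, eta = 6, 0.17
        rng = np.random.default_rng(0)
        gamma = rng.uniform(0, 0.1, size=L)
        s = sp.Structure(id="open", sequence="A" * L, pairs=frozenset())
        X = sp.build_design_truncation(sp.CandidateSet(structures=[s]), eta, gamma)
        expected = np.empty(L + 1)
        for p in range(1, L + 1):
            pre = np.prod([(1 - gamma[k]) * (1 - eta) for k in range(p - 1)])
            expected[p - 1] = (1 - (1 - gamma[p - 1]) * (1 - eta)) * pre
        expected[L] = np.prod([(1 - gamma[k]) * (1 - eta) for k in range(L)])
        np.testing.assert_allclose(X.values[:, 0], expected, atol=1e-14)


class TestMutationDesign:
    def test_single_informative_site(self):
        cs = single_site_candidates(False)
        pats = [ReadPattern(MUTATION, ()), ReadPattern(MUTATION, (1,))]
        X = sp.build_design_mutation(cs, eta=0.2, gamma=0.0, patterns=pats)
        np.testing.assert_allclose(X.values[:, 0], [0.8, 0.2])

    def test_independent_sites_multiply(self):
        s = sp.Structure(id="s", sequence="AA", pairs=frozenset())
        cs = sp.CandidateSet(structures=[s])
        pats = [ReadPattern(MUTATION, (1, 2))]
        X = sp.build_design_mutation(cs, eta=0.2, gamma=0.0, patterns=pats)
        assert X.values[0, 0] == pytest.approx(0.04)  # eta^2

    @pytest.mark.parametrize("seed", range(6))
    def test_full_enumeration_sums_to_one_and_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        K = int(rng.integers(2, 9))
        s = random_structure(rng, K)
        eta = rng.uniform(0, 0.9)
        gamma = rng.uniform(0, 0.5, size=K)
        info = tuple(range(1, K + 1))
        cs = sp.CandidateSet(structures=[s], informative_sites=info)
        pats = sp.enumerate_mutation_patterns(info)
        X = sp.build_design_mutation(cs, eta, gamma, pats)
        assert abs(X.values[:, 0].sum() - 1.0) < 1e-12
        for pat, val in zip(pats, X.values[:, 0]):
            oracle = mutation_pattern_prob_oracle(
                s.state, eta, gamma, info, frozenset(pat.sites)
            )
            assert val == pytest.approx(oracle, abs=1e-12)

    def test_pattern_outside_informative_sites_rejected(self):
        s = sp.Structure(id="s", sequence="AAA", pairs=frozenset())
        cs = sp.CandidateSet(structures=[s], informative_sites=(1, 2))
        with pytest.raises(ModelError):
            sp.build_design_mutation(cs, 0.1, 0.0, [ReadPattern(MUTATION, (3,))])


class TestPrefilter:
    def make_candidates(self, states, L=8):
        structures = [
            sp.Structure(id=f"s{i}", sequence="A" * L, pairs=frozenset(),
                         state=np.array(st, dtype=np.uint8))
            for i, st in enumerate(states)
        ]
        return sp.CandidateSet(structures=structures)

    def test_removal_rule(self):
        # highly reactive sites H = {1,2,3,4} (beta 0.5 > eta 0.2)
        beta = np.array([0.5, 0.5, 0.5, 0.5, 0.0, 0.0, 0.0, 0.0])
        bad = [1, 1, 1, 0, 0, 0, 0, 0]   # constrains 3 of 4 > 2 -> removed
        ok = [1, 0, 0, 0, 1, 1, 0, 0]    # constrains 1 of 4 -> kept
        cs = self.make_candidates([bad, ok])
        filtered, removed = sp.prefilter(cs, beta, eta=0.2)
        assert [s.id for s in filtered] == ["s1"]
        assert removed == {"s0": [1, 2, 3]}

    def test_single_reactive_site_never_removes(self):
        # |H| = 1: even a structure constraining it is inconsistent with only
        # a single nucleotide, hence kept
        beta = np.array([0.5, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        cs = self.make_candidates([[1, 0, 0, 0, 0, 0, 0, 0]])
        filtered, removed = sp.prefilter(cs, beta, eta=0.2)
        assert len(filtered) == 1 and not removed

    def test_empty_reactive_set_is_noop(self):
        beta = np.full(8, 0.1)
        cs = self.make_candidates([[1] * 8, [0] * 8])
        filtered, removed = sp.prefilter(cs, beta, eta=0.2)
        assert len(filtered) == 2 and not removed


class TestFit:
    def test_noiseless_identifiability(self, bistable):
        _, a, b = bistable
        cs = sp.CandidateSet(structures=[a, b])
        X = sp.build_design_truncation(cs, eta=0.2, gamma=0.02)
        y = X.values @ np.array([0.7, 0.3])
        res = sp.fit(X, y)
        np.testing.assert_allclose(
            res.rho.to_numpy(), [0.7, 0.3], atol=1e-8
        )
        assert res.residual < 1e-10

    def test_single_candidate_selected_at_one(self, bistable):
        _, a, _ = bistable
        cs = sp.CandidateSet(structures=[a])
        X = sp.build_design_truncation(cs, eta=0.2, gamma=0.0)
        res = sp.fit(X, X.values[:, 0])
        assert res.selected.to_dict() == {"hairpin5p": pytest.approx(1.0)}

    def test_residual_not_worse_than_single_candidate_fits(self, bistable):
        seq, a, b = bistable
        rng = np.random.default_rng(9)
        decoys = sp.sample_random_structures(seq, 4, rng)
        cs = sp.CandidateSet(structures=[a, b] + decoys).dedup()
        X = sp.build_design_truncation(cs, eta=0.2, gamma=0.02)
        y = X.values @ np.concatenate([[0.5, 0.4], np.full(len(cs) - 2, 0.1 / (len(cs) - 2))])
        y += np.abs(np.sin(np.arange(len(y)))) * 1e-3  # deterministic misfit
        y /= y.sum()
        res = sp.fit(X, y)
        for j in range(X.values.shape[1]):
            col = X.values[:, [j]]
            rho_j, rnorm_j = np.linalg.lstsq(col, y, rcond=None)[0], None
            single_resid = np.linalg.norm(y - col @ np.clip(rho_j, 0, None))
            assert res.residual <= single_resid + 1e-12

    def test_invariant_to_candidate_order(self, bistable):
        seq, a, b = bistable
        rng = np.random.default_rng(4)
        decoys = sp.sample_random_structures(seq, 5, rng)
        structures = [a, b] + decoys
        y = None
        results = {}
        for order in (structures, structures[::-1]):
            cs = sp.CandidateSet(structures=order).dedup()
            X = sp.build_design_truncation(cs, eta=0.2, gamma=0.02)
            if y is None:
                truth = {s.id: r for s, r in zip([a, b], [0.6, 0.4])}
                y = sum(
                    truth.get(s.id, 0.0) * X.values[:, i]
                    for i, s in enumerate(cs)
                )
            results[id(order)] = sp.fit(X, y).rho.sort_index()
        r1, r2 = results.values()
        np.testing.assert_allclose(r1.to_numpy(), r2.to_numpy(), atol=1e-8)

    def test_zero_column_dropped(self):
        X = sp.DesignMatrix(
            values=np.array([[0.5, 0.0], [0.5, 0.0]]),
            pattern_index=[ReadPattern("truncation", (1,)), ReadPattern("truncation", (2,))],
            structure_index=["a", "zero"],
            mode="truncation",
        )
        res = sp.fit(X, np.array([0.5, 0.5]))
        assert res.diagnostics["dropped_columns"] == ["zero"]
        assert res.rho["zero"] == 0.0

    def test_duplicate_columns_merged(self):
        col = np.array([0.3, 0.7])
        X = sp.DesignMatrix(
            values=np.column_stack([col, col]),
            pattern_index=[ReadPattern("truncation", (1,)), ReadPattern("truncation", (2,))],
            structure_index=["a", "b"],
            mode="truncation",
        )
        res = sp.fit(X, col)
        assert res.diagnostics["merged_groups"] == [["a", "b"]]
        assert res.rho["a"] == pytest.approx(1.0) and res.rho["b"] == 0.0

    def test_threshold_selects_and_renormalizes(self, bistable):
        _, a, b = bistable
        cs = sp.CandidateSet(structures=[a, b])
        X = sp.build_design_truncation(cs, eta=0.2, gamma=0.0)
        y = X.values @ np.array([0.995, 0.005])
        res = sp.fit(X, y, threshold=0.01)
        assert res.selected_ids() == ["hairpin5p"]
        assert res.selected.sum() == pytest.approx(1.0)


def test_ideal_profile_weights_unconstrained_fraction(bistable):
    _, a, b = bistable
    prof = sp.ideal_profile([a, b], np.array([0.5, 0.5]), eta=0.2)
    # sites paired in one of the two folds sit at half the open-site level
    assert prof[np.flatnonzero(a.state)[0]] == pytest.approx(0.1)
    open_sites = (a.state == 0) & (b.state == 0)
    np.testing.assert_allclose(prof[open_sites], 0.2)
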