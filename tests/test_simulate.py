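import numpy as np
import pytest

import splandscape as sp
from splandscape.simulate import SimulationError


class TestPatternDistribution:
    def test_no_modification_no_noise_all_complete(self, bistable):
        _, a, _ = bistable
        truth = sp.GroundTruth(structures=[a], abundances=[1.0], eta=0.0, gamma=0.0)
        dist = sp.pattern_distribution(truth)
        assert dist.probs[-1] == pytest.approx(1.0)
        assert dist.probs[:-1].sum() == pytest.approx(0.0)

    def test_open_structure_geometric_stops(self):
        """A fully unconstrained RNA with no noise gives the geometric-like
        drop-off distribution eta*(1-eta)^(p-1)."""
        L, eta = 7, 0.25
        s = sp.Structure(id="open", sequence="A" * L, pairs=frozenset())
        truth = sp.GroundTruth(structures=[s], abundances=[1.0], eta=eta, gamma=0.0)
        dist = sp.pattern_distribution(truth)
        expected = [eta * (1 - eta) ** (p - 1) for p in range(1, L + 1)]
        expected.append((1 - eta) ** L)
        np.testing.assert_allclose(dist.probs, expected, atol=1e-14)

    def test_mixture_is_linear(self, bistable):
        _, a, b = bistable
        d_a = sp.pattern_distribution(
            sp.GroundTruth(structures=[a], abundances=[1.0], eta=0.2, gamma=0.01)
        )
        d_b = sp.pattern_distribution(
            sp.GroundTruth(structures=[b], abundances=[1.0], eta=0.2, gamma=0.01)
        )
        d_mix = sp.pattern_distribution(
            sp.GroundTruth(structures=[a, b], abundances=[0.5, 0.5], eta=0.2, gamma=0.01)
        )
        np.testing.assert_allclose(d_mix.probs, 0.5 * (d_a.probs + d_b.probs))

    def test_enumeration_limit_enforced(self, bistable):
        seq, a, _ = bistable
        truth = sp.GroundTruth(
            structures=[a], abundances=[1.0], eta=0.1, gamma=0.0,
            mode="mutation", informative_sites=tuple(range(1, 23)),
        )
        with pytest.raises(SimulationError, match="per"):
            sp.pattern_distribution(truth)


class TestDrawReads:
    def test_seeded_reproducibility(self, bistable):
        _, a, b = bistable
        truth = sp.GroundTruth(structures=[a, b], abundances=[0.6, 0.4], eta=0.2, gamma=0.01)
        dist = sp.pattern_distribution(truth)
        pc1 = sp.draw_reads(dist, 5000, seed=123)
        pc2 = sp.draw_reads(dist, 5000, seed=123)
        assert pc1.counts == pc2.counts

    def test_single_read(self, bistable):
        _, a, _ = bistable
        dist = sp.pattern_distribution(
            sp.GroundTruth(structures=[a], abundances=[1.0], eta=0.2, gamma=0.0)
        )
        pc = sp.draw_reads(dist, 1, seed=0)
        assert pc.total_reads == 1 and len(pc.counts) == 1

    def test_frequencies_approach_distribution(self, bistable):
        _, a, b = bistable
        truth = sp.GroundTruth(structures=[a, b], abundances=[0.6, 0.4], eta=0.2, gamma=0.01)
        dist = sp.pattern_distribution(truth)
        pc = sp.draw_reads(dist, 10**6, seed=7)
        freq = np.zeros(len(dist.patterns))
        idx = {p: i for i, p in enumerate(dist.patterns)}
        for pat, c in pc.counts.items():
            freq[idx[pat]] = c / pc.total_reads
        assert np.max(np.abs(freq - dist.probs)) < 5e-3

    def test_per_site_sampler_matches_enumeration(self, landscape33):
        """Bernoulli per-read sampling and the enumerated mixture agree in
        distribution (total variation on a deep draw)."""
        seq, folds, info = landscape33
        truth = sp.GroundTruth(
            structures=[folds["FA"], folds["FB"]], abundances=[0.5, 0.5],
            eta=0.15, gamma=0.0, mode="mutation", informative_sites=info,
        )
        from scipy.stats import chisquare

        dist = sp.pattern_distribution(truth)
        N = 200_000
        pc = sp.draw_reads_per_site(truth, N, seed=5)
        idx = {p: i for i, p in enumerate(dist.patterns)}
        observed = np.zeros(len(dist.patterns))
        for pat, c in pc.counts.items():
            observed[idx[pat]] += c
        expected = dist.probs * N
        # pool cells with small expectation, standard chi-square practice
        big = expected >= 5
        obs = np.append(observed[big], observed[~big].sum())
        exp = np.append(expected[big], expected[~big].sum())
        stat, pval = chisquare(obs, exp * obs.sum() / exp.sum())
        assert pval > 1e-3


class TestNoise:
    def test_sigma_zero_identity(self, bistable):
        _, a, _ = bistable
        pc = sp.draw_reads(
            sp.pattern_distribution(
                sp.GroundTruth(structures=[a], abundances=[1.0], eta=0.2, gamma=0.0)
            ),
            10_000, seed=1,
        )
        noisy = sp.add_count_noise(pc, 0.0, seed=2)
        assert noisy.counts == pc.counts

    def test_counts_floored_at_zero_and_seeded(self, bistable):
        _, a, _ = bistable
        pc = sp.draw_reads(
            sp.pattern_distribution(
                sp.GroundTruth(structures=[a], abundances=[1.0], eta=0.2, gamma=0.0)
            ),
            10_000, seed=1,
        )
        n1 = sp.add_count_noise(pc, 2.0, seed=3)
        n2 = sp.add_count_noise(pc, 2.0, seed=3)
        assert n1.counts == n2.counts
        assert all(c > 0 for c in n1.counts.values())

    def test_noise_degrades_recovery_on_average(self, bistable):
        """Mean abundance error grows with the count-noise level."""
        _, a, b = bistable
        truth = sp.GroundTruth(structures=[a, b], abundances=[0.6, 0.4], eta=0.2, gamma=0.0)
        dist = sp.pattern_distribution(truth)
        cs = sp.CandidateSet(structures=[a, b])
        X = sp.build_design_truncation(cs, 0.2, 0.0)
        errors = {}
        for sigma in (0.0, 1.0):
            errs = []
            for seed in range(10):
                pc = sp.draw_reads(dist, 50_000, seed=seed)
                pc = sp.add_count_noise(pc, sigma, seed=100 + seed)
                y = np.zeros(truth.L + 1)
                for pat, c in pc.counts.items():
                    y[pat.stop - 1] = c
                y = y / y.sum()
                res = sp.fit(X, y)
                errs.append(
                    abs(res.selected.get("hairpin5p", 0) - 0.6)
                    + abs(res.selected.get("hairpin3p", 0) - 0.4)
                )
            errors[sigma] = np.mean(errs)
        assert errors[1.0] > errors[0.0]


class TestDecoys:
    def test_shares_fraction_equally(self, bistable):
        seq, a, b = bistable
        decoys = sp.sample_random_structures(seq, 10, seed=0)
        truth = sp.GroundTruth(structures=[a, b], abundances=[0.6, 0.4], eta=0.2, gamma=0.0)
        spiked = sp.add_decoys(truth, decoys, fraction=0.10)
        np.testing.assert_allclose(spiked.abundances[:2], [0.54, 0.36])
        np.testing.assert_allclose(spiked.abundances[2:], 0.01)
        assert spiked.abundances.sum() == pytest.approx(1.0)

    def test_zero_fraction_identity(self, bistable):
        _, a, b = bistable
        truth = sp.GroundTruth(structures=[a, b], abundances=[0.6, 0.4], eta=0.2, gamma=0.0)
        assert sp.add_decoys(truth, [], fraction=0.0) is truth


class TestBootstrap:
    def test_degenerate_single_pattern_identical(self):
        pc = sp.bin_truncation([2] * 50, L=4)
        reps = sp.bootstrap_counts(pc, 3, seed=0)
        assert all(r.counts == pc.counts for r in reps)

    def test_seeded_reproducibility(self, bistable):
        _, a, _ = bistable
        pc = sp.draw_reads(
            sp.pattern_distribution(
                sp.GroundTruth(structures=[a], abundances=[1.0], eta=0.2, gamma=0.0)
            ),
            5000, seed=4,
        )
        r1 = sp.bootstrap_counts(pc, 2, seed=9)
        r2 = sp.bootstrap_counts(pc, 2, seed=9)
        assert [r.counts for r in r1] == [r.counts for r in r2]

    def test_spread_shrinks_with_depth(self, bistable):
        """Bootstrap spread of the abundance estimate scales roughly with
        1/sqrt(N)."""
        _, a, b = bistable
        truth = sp.GroundTruth(structures=[a, b], abundances=[0.6, 0.4], eta=0.2, gamma=0.0)
        dist = sp.pattern_distribution(truth)
        cs = sp.CandidateSet(structures=[a, b])
        X = sp.build_design_truncation(cs, 0.2, 0.0)

        def spread(N, seed):
            pc = sp.draw_reads(dist, N, seed=seed)
            estimates = []
            for rep in sp.bootstrap_counts(pc, 12, seed=seed + 1):
                y = np.zeros(truth.L + 1)
                for pat, c in rep.counts.items():
                    y[pat.stop - 1] = c
                res = sp.fit(X, y / y.sum())
                estimates.append(res.selected.get("hairpin5p", 0.0))
            return np.std(estimates)

        assert spread(200_000, 10) < spread(2_000, 20)


class TestScoreRecovery:
    def test_perfect_recovery(self, bistable):
        _, a, b = bistable
        truth = sp.GroundTruth(structures=[a, b], abundances=[0.7, 0.3], eta=0.2, gamma=0.0)
        cs = sp.CandidateSet(structures=[a, b])
        X = sp.build_design_truncation(cs, 0.2, 0.0)
        res = sp.fit(X, X.values @ np.array([0.7, 0.3]))
        score = sp.score_recovery(res, truth, cs)
        assert score.precision == 1.0 and score.recall == 1.0
        assert score.l1_error < 1e-6

    def test_decoy_only_selection_scores_zero_precision(self, bistable):
        import pandas as pd

        seq, a, b = bistable
        decoys = sp.sample_random_structures(seq, 2, seed=1)
        truth = sp.GroundTruth(structures=[a], abundances=[1.0], eta=0.2, gamma=0.0)
        cs = sp.CandidateSet(structures=[a] + decoys)
        fake = sp.FitResult(
            rho=pd.Series({"rand0": 1.0}),
            selected=pd.Series({"rand0": 1.0}),
            residual=0.0, threshold=0.01,
        )
        score = sp.score_recovery(fake, truth, cs)
        assert score.precision == 0.0 and score.recall == 0.0
        assert score.l1_error == pytest.approx(2.0)  # missed truth + spurious mass


def test_two_hairpin_landscape_design(landscape33):
    """The engineered landscape is pairwise distinguishable at informative
    sites and keeps >= 3 informative sites unpaired in every fold (the eta
    heuristic's requirement)."""
    import itertools

    seq, folds, info = landscape33
    ia = np.array(info) - 1
    for x, y in itertools.combinations(folds.values(), 2):
        assert not np.array_equal(x.state[ia], y.state[ia])
    always_open = np.all([f.state[ia] == 0 for f in folds.values()], axis=0)
    assert always_open.sum() >= 3
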