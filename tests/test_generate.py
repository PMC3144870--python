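import numpy as np
import pytest

from emothreads import (
    GeneratorSpec,
    conditional_extension_curve,
    generate,
    generate_fuel_threads,
    generate_iid,
    generate_markov,
    generate_preferential,
    iid_cluster_ccdf,
    summarize,
)
from emothreads.generate import _stationary


def _same_corpus(a, b):
    return len(a.threads) == len(b.threads) and all(
        np.array_equal(x.valences, y.valences) for x, y in zip(a, b)
    )


class TestSpecValidation:
    def test_invalid_p_vec(self):
        with pytest.raises(ValueError, match="p_vec"):
            GeneratorSpec(p_vec=(0.5, 0.2, 0.2))

    def test_markov_needs_stochastic_T(self):
        with pytest.raises(ValueError, match="row-stochastic"):
            GeneratorSpec(process="markov", T=np.eye(3) * 0.5)

    def test_preferential_needs_parameters(self):
        with pytest.raises(ValueError, match="p1_vec"):
            GeneratorSpec(process="preferential", alpha_vec=(0.1, 0.1, 0.1))
        with pytest.raises(ValueError, match="p1 values"):
            GeneratorSpec(
                process="preferential", p1_vec=(0.0, 0.5, 0.5), alpha_vec=(0, 0, 0)
            )

    def test_fuel_needs_valid_h0(self):
        with pytest.raises(ValueError, match="h0"):
            GeneratorSpec(process="fuel", h0=1.5, fuel_strength=0.0)


class TestDeterminism:
    @pytest.mark.parametrize(
        "spec_kwargs",
        [
            {"process": "iid"},
            {"process": "markov", "T": [[0.6, 0.25, 0.15], [0.2, 0.6, 0.2], [0.15, 0.25, 0.6]]},
            {
                "process": "preferential",
                "p1_vec": (0.5, 0.5, 0.5),
                "alpha_vec": (0.3, 0.1, 0.2),
            },
            {"process": "fuel", "h0": 0.1, "fuel_strength": 0.5},
        ],
        ids=["iid", "markov", "preferential", "fuel"],
    )
    def test_same_seed_same_corpus(self, spec_kwargs):
        mk = lambda: generate(GeneratorSpec(n_threads=200, seed=42, **spec_kwargs))
        assert _same_corpus(mk(), mk())

    def test_different_seeds_differ(self):
        a = generate_iid(GeneratorSpec(n_threads=100, seed=1))
        b = generate_iid(GeneratorSpec(n_threads=100, seed=2))
        assert not _same_corpus(a, b)


class TestIid:
    def test_marginals_recovered(self):
        spec = GeneratorSpec(
            p_vec=(0.19, 0.65, 0.16), n_threads=40_000, seed=3,
            thread_length_law=("geometric", 25.0),
        )
        s = summarize(generate_iid(spec))
        n = s.n_comments
        for p_true, p_hat in [(0.19, s.p_plus), (0.65, s.p_minus), (0.16, s.p_zero)]:
            se = np.sqrt(p_true * (1 - p_true) / n)
            assert abs(p_hat - p_true) < 3 * se

    def test_degenerate_marginals(self):
        spec = GeneratorSpec(p_vec=(1.0, 0.0, 0.0), n_threads=50, seed=4)
        values, _ = generate_iid(spec).flat()
        assert np.all(values == 1)

    def test_fixed_length_law(self):
        spec = GeneratorSpec(n_threads=30, seed=5, thread_length_law=("fixed", 7))
        assert all(len(t) == 7 for t in generate_iid(spec))

    def test_geometric_lengths_have_requested_mean(self):
        spec = GeneratorSpec(n_threads=50_000, seed=6, thread_length_law=("geometric", 25.0))
        lengths = np.array([len(t) for t in generate_iid(spec)])
        se = lengths.std(ddof=1) / np.sqrt(lengths.size)
        assert abs(lengths.mean() - 25.0) < 3 * se


class TestMarkov:
    T = np.array([[0.6, 0.25, 0.15], [0.2, 0.6, 0.2], [0.15, 0.25, 0.6]])

    def test_absorbing_diagonal_gives_constant_threads(self):
        spec = GeneratorSpec(process="markov", T=np.eye(3), n_threads=100, seed=7)
        for t in generate_markov(spec):
            assert len(set(t.valences.tolist())) == 1

    def test_identical_rows_reduce_to_iid_marginals(self):
        p_iid = (0.19, 0.65, 0.16)
        # rows in (-1, 0, +1) state order
        row = [0.65, 0.16, 0.19]
        spec = GeneratorSpec(
            process="markov", T=[row, row, row], p_vec=p_iid,
            n_threads=20_000, seed=8,
        )
        s = summarize(generate_markov(spec))
        n = s.n_comments
        for p_true, p_hat in [(0.19, s.p_plus), (0.65, s.p_minus), (0.16, s.p_zero)]:
            assert abs(p_hat - p_true) < 3 * np.sqrt(p_true * (1 - p_true) / n)

    def test_stationary_start_matches_pooled_marginals(self):
        spec = GeneratorSpec(process="markov", T=self.T, n_threads=30_000, seed=9)
        s = summarize(generate_markov(spec))
        pi = _stationary(self.T)  # states (-1, 0, +1)
        n = s.n_comments
        for p_true, p_hat in [(pi[0], s.p_minus), (pi[1], s.p_zero), (pi[2], s.p_plus)]:
            assert abs(p_hat - p_true) < 3 * np.sqrt(p_true * (1 - p_true) / n)


class TestPreferential:
    def test_alpha_zero_matches_iid_cluster_law(self):
        # alpha = 0, p1_e = p_e: run extension is Bernoulli(p_e), so the
        # cluster ccdf must match the geometric law within Monte-Carlo error
        from emothreads import cluster_length_distribution

        p_vec = (0.19, 0.65, 0.16)
        spec = GeneratorSpec(
            process="preferential", p_vec=p_vec,
            p1_vec=(0.19, 0.65, 0.16), alpha_vec=(0.0, 0.0, 0.0),
            n_threads=500, seed=10, thread_length_law=("fixed", 400),
        )
        corpus = generate_preferential(spec)
        dist = cluster_length_distribution(corpus, -1)
        for n in range(1, 9):
            model = iid_cluster_ccdf(0.65, n)
            se = np.sqrt(model * (1 - model) / dist.n_clusters)
            assert abs(dist.ccdf(n) - model) < 3 * se + 1e-12

    def test_hand_computed_extension_probabilities(self):
        # p1=0.5, alpha=1: a run of length 2 extends with min(1, 0.5*2) = 1,
        # so no cluster that reaches length 2 can end before the thread does
        spec = GeneratorSpec(
            process="preferential",
            p1_vec=(0.5, 0.5, 0.5), alpha_vec=(1.0, 1.0, 1.0),
            n_threads=300, seed=11, thread_length_law=("fixed", 50),
        )
        corpus = generate_preferential(spec)
        for t in corpus:
            v = t.valences
            # any maximal run of length >= 2 must extend to the thread end
            changes = np.flatnonzero(v[1:] != v[:-1]) + 1
            starts = np.concatenate([[0], changes])
            lengths = np.diff(np.append(starts, v.size))
            for s, L in zip(starts, lengths):
                if L >= 2:
                    assert s + L == v.size

    def test_curve_recovers_extension_law(self):
        spec = GeneratorSpec(
            process="preferential",
            p1_vec=(0.5, 0.5, 0.5), alpha_vec=(0.38, 0.38, 0.38),
            n_threads=30_000, seed=12, thread_length_law=("geometric", 25.0),
        )
        corpus = generate_preferential(spec)
        curve = conditional_extension_curve(corpus, 1, 10)
        for n in curve.ns():
            pt = curve.points[n]
            model = min(1.0, 0.5 * n**0.38)
            if pt.denominator < 100:
                continue
            se = np.sqrt(model * (1 - model) / pt.denominator)
            assert abs(pt.p_hat - model) <= 3 * se + 1e-12


class TestFuel:
    def test_zero_coupling_gives_geometric_lengths(self):
        h0 = 0.1
        spec = GeneratorSpec(
            process="fuel", h0=h0, fuel_strength=0.0, n_threads=30_000, seed=13
        )
        lengths = np.array([len(t) for t in generate_fuel_threads(spec)])
        assert abs(lengths.mean() - 1 / h0) < 3 * lengths.std(ddof=1) / np.sqrt(lengths.size)
        for n in (2, 4, 8, 16):
            model = (1 - h0) ** (n - 1)  # P(L >= n)
            emp = np.mean(lengths >= n)
            se = np.sqrt(model * (1 - model) / lengths.size)
            assert abs(emp - model) < 3 * se + 1e-12

    def test_positive_coupling_longer_emotional_threads(self):
        mk = lambda c, seed: np.array(
            [
                len(t)
                for t in generate_fuel_threads(
                    GeneratorSpec(
                        process="fuel", h0=0.05, fuel_strength=c,
                        n_threads=5_000, seed=seed,
                    )
                )
            ]
        )
        assert mk(1.0, 14).mean() < mk(0.0, 14).mean()
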