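import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emothreads import (
    Corpus,
    GeneratorSpec,
    Thread,
    conditional_extension_curve,
    fit_alpha,
    fit_alpha_vs_p,
    generate_iid,
    pair_joint_probability,
    reference,
)
from emothreads.preferential import ConditionalCurve, CurvePoint

from conftest import corpus_from_strings, random_small_corpus
from oracles import conditional_counts_bruteforce, pair_counts_bruteforce


class TestPairJointProbability:
    def test_hand_enumeration(self):
        # pairs in "+++-": (+,+), (+,+), (+,-)  ->  joint 2/3, p_+ = 3/4
        joint, p1 = pair_joint_probability(corpus_from_strings("+++-"), 1)
        assert joint == pytest.approx(2 / 3)
        assert p1 == pytest.approx((2 / 3) / (3 / 4))

    def test_alternating_gives_zero(self):
        joint, p1 = pair_joint_probability(corpus_from_strings("+-+-"), 1)
        assert joint == 0.0 and p1 == 0.0

    def test_constant_corpus_gives_one(self):
        joint, p1 = pair_joint_probability(corpus_from_strings("----", "--"), -1)
        assert joint == 1.0 and p1 == 1.0

    def test_all_singleton_threads_error(self):
        with pytest.raises(ValueError, match="no within-thread"):
            pair_joint_probability(corpus_from_strings("+", "-", "0"), 1)

    def test_matches_bruteforce(self, rng):
        for _ in range(30):
            corpus = random_small_corpus(rng)
            seqs = [list(map(int, t.valences)) for t in corpus]
            for e in (-1, 0, 1):
                same, total = pair_counts_bruteforce(seqs, e)
                if total == 0 or not any(e in s for s in seqs):
                    continue
                joint, _ = pair_joint_probability(corpus, e)
                assert joint == pytest.approx(same / total)


class TestConditionalExtensionCurve:
    def test_matches_bruteforce_exhaustively(self, rng):
        """The vectorised counts equal a direct scan of every position."""
        for _ in range(150):
            corpus = random_small_corpus(rng)
            seqs = [list(map(int, t.valences)) for t in corpus]
            for e in (-1, 0, 1):
                if not any(e in s for s in seqs):
                    continue
                try:
                    curve = conditional_extension_curve(corpus, e, n_max=8)
                except ValueError:
                    continue  # no pairs at all
                expected = conditional_counts_bruteforce(seqs, e, 8)
                for n, (num, den) in expected.items():
                    if den == 0:
                        assert n not in curve.points
                    else:
                        pt = curve.points[n]
                        assert (pt.numerator, pt.denominator) == (num, den)

    def test_zero_denominator_points_omitted(self):
        curve = conditional_extension_curve(corpus_from_strings("+-"), 1, n_max=5)
        assert curve.ns() == [1]

    def test_flat_for_iid_corpus(self):
        spec = GeneratorSpec(n_threads=20_000, seed=13, thread_length_law=("geometric", 25.0))
        corpus = generate_iid(spec)
        p_e = 0.65
        curve = conditional_extension_curve(corpus, -1, n_max=10)
        for n in curve.ns():
            pt = curve.points[n]
            if pt.denominator < 100:
                continue
            se = np.sqrt(p_e * (1 - p_e) / pt.denominator)
            assert abs(pt.p_hat - p_e) < 3 * se


def _exact_curve(p1, alpha, n_max=10, den=10_000):
    # p_hat set exactly to the law; counts only feed the fit weights
    pts = [
        CurvePoint(n, min(1.0, p1 * n**alpha), 0, den) for n in range(1, n_max + 1)
    ]
    return ConditionalCurve(1, pts, p1)


class TestFitAlpha:
    def test_exact_power_law_recovered(self):
        fit = fit_alpha(_exact_curve(0.5, 0.3))
        assert fit.alpha == pytest.approx(0.3, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.5, rel=1e-9)

    def test_flat_curve_gives_zero(self):
        fit = fit_alpha(_exact_curve(0.4, 0.0))
        assert fit.alpha == pytest.approx(0.0, abs=1e-12)

    def test_saturated_points_excluded(self):
        # p1=0.5, alpha=1: saturates from n=2 on; only n=1 survives -> error
        with pytest.raises(ValueError, match="at least 3 usable points"):
            fit_alpha(_exact_curve(0.5, 1.0))

    def test_too_few_points_error(self):
        curve = ConditionalCurve(1, [CurvePoint(1, 0.5, 5, 10), CurvePoint(2, 0.6, 6, 10)], 0.5)
        with pytest.raises(ValueError, match="at least 3"):
            fit_alpha(curve)

    def test_parameter_recovery_moderate_scale(self):
        from emothreads import generate_preferential

        alpha_true = 0.45
        spec = GeneratorSpec(
            process="preferential",
            p_vec=(0.19, 0.65, 0.16),
            p1_vec=(0.5, 0.5, 0.5),
            alpha_vec=(0.38, 0.05, alpha_true),
            n_threads=40_000,
            seed=17,
            thread_length_law=("geometric", 25.0),
        )
        corpus = generate_preferential(spec)
        fit = fit_alpha(conditional_extension_curve(corpus, 0, 10))
        assert fit.alpha == pytest.approx(alpha_true, abs=0.05)

    def test_iid_alpha_consistent_with_zero(self):
        corpus = generate_iid(GeneratorSpec(n_threads=20_000, seed=13))
        for e in (-1, 0, 1):
            fit = fit_alpha(conditional_extension_curve(corpus, e, 10))
            assert abs(fit.alpha) < 3 * fit.alpha_stderr


class TestFitAlphaVsP:
    def test_published_ranking_exponential_power_linear(self):
        """On the nine published (p_e, alpha_e) community points the
        exponential decay fits best, then power law, then linear."""
        pts = reference.alpha_vs_p_points()
        r2 = {
            fam: fit_alpha_vs_p(pts, fam).r_squared
            for fam in ("exponential", "power_law", "linear")
        }
        assert r2["exponential"] > r2["power_law"] > r2["linear"]

    def test_collinear_points_linear_family(self):
        pts = [(0.1, 0.5), (0.2, 0.4), (0.3, 0.3), (0.4, 0.2)]
        fit = fit_alpha_vs_p(pts, "linear")
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.A == pytest.approx(0.6) and fit.B == pytest.approx(1.0)

    def test_exact_exponential_recovered(self):
        p = np.linspace(0.1, 0.7, 6)
        pts = list(zip(p, 0.8 * np.exp(-3.0 * p)))
        for space in ("linearized", "untransformed"):
            fit = fit_alpha_vs_p(pts, "exponential", space=space)
            assert fit.A == pytest.approx(0.8, rel=1e-6)
            assert fit.B == pytest.approx(3.0, rel=1e-6)
            assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_exact_power_law_recovered(self):
        p = np.linspace(0.1, 0.7, 6)
        pts = list(zip(p, 0.1 * p**-0.9))
        fit = fit_alpha_vs_p(pts, "power_law")
        assert fit.A == pytest.approx(0.1, rel=1e-6)
        assert fit.B == pytest.approx(0.9, rel=1e-6)

    def test_degenerate_points_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_alpha_vs_p([(0.2, 0.1), (0.2, 0.3), (0.2, 0.5)], "linear")

    def test_too_few_points_error(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_alpha_vs_p([(0.1, 0.2), (0.3, 0.4)], "linear")


@settings(derandomize=True, max_examples=30)
@given(
    seqs=st.lists(
        st.lists(st.sampled_from([-1, 0, 1]), min_size=2, max_size=12),
        min_size=1,
        max_size=5,
    )
)
def test_curve_counts_match_bruteforce_property(seqs):
    corpus = Corpus([Thread(f"t{i}", s) for i, s in enumerate(seqs)])
    for e in (-1, 0, 1):
        if not any(e in s for s in seqs):
            continue
        curve = conditional_extension_curve(corpus, e, n_max=6)
        expected = conditional_counts_bruteforce(seqs, e, 6)
        for n, (num, den) in expected.items():
            if den:
                assert (curve.points[n].numerator, curve.points[n].denominator) == (num, den)
            else:
                assert n not in curve.points
        # denominators never increase with n
        dens = [curve.points[n].denominator for n in curve.ns()]
        assert all(a >= b for a, b in zip(dens, dens[1:]))
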