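"""Metrics, beta model, threshold curves, bootstrap suites, regions."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

import wsifusion as w
from wsifusion.classifier import ConstantBackend, OracleBackend
from wsifusion.evaluation import (
    CLASS_COLORS,
    BetaParams,
    ConfusionCounts,
    RegionDecision,
    SlideTuples,
    beta_loglik,
    bernoulli_ci,
    bootstrap_beta_ci,
    classify_slides,
    compute_metrics,
    confidence_score,
    confusion_counts,
    derived_metrics,
    fit_beta_mle,
    region_decision,
    render_overlay,
    round_half_away,
    slide_fraction,
    superiority_test,
    threshold_curves,
    _moments_init,
)
from wsifusion.fusion import FusionWeights


class TestConfusionCounts:
    def test_perfect_two_slide_case(self):
        c = confusion_counts(["MEN", "SFT"], ["MEN", "SFT"])
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 0, 0)

    def test_always_men_predictor(self):
        c = confusion_counts(["MEN"] * 5, ["MEN"] * 3 + ["SFT"] * 2)
        assert (c.tp, c.fp, c.tn, c.fn) == (3, 2, 0, 0)

    def test_matches_hand_tally_on_random_fixture(self):
        rng = np.random.default_rng(10)
        preds = [("MEN", "SFT")[i] for i in rng.integers(0, 2, 10)]
        labels = [("MEN", "SFT")[i] for i in rng.integers(0, 2, 10)]
        c = confusion_counts(preds, labels)
        tally = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
        for p, y in zip(preds, labels):
            key = ("t" if p == y else "f") + ("p" if p == "MEN" else "n")
            tally[key] += 1
        assert (c.tp, c.tn, c.fp, c.fn) == (
            tally["tp"],
            tally["tn"],
            tally["fp"],
            tally["fn"],
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            confusion_counts(["MEN"], ["MEN", "SFT"])


class TestComputeMetrics:
    def test_balanced_accuracy_from_published_sen_spc(self):
        d = derived_metrics(sen=87.77, spc=97.55, prc=97.68)
        assert round_half_away(d["bac"]) == 92.66

    def test_all_perfect(self):
        r = compute_metrics(ConfusionCounts(1, 1, 0, 0))
        assert all(v == 100.0 for v in r.rounded().values())

    def test_hand_arithmetic_case(self):
        r = compute_metrics(ConfusionCounts(tp=3, fn=1, fp=2, tn=4)).rounded()
        assert r["acc"] == 70.00
        assert r["sen"] == 75.00
        assert r["spc"] == 66.67
        assert r["prc"] == 60.00
        assert r["f1"] == 66.67

    def test_identities_hold_exactly_before_rounding(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            tp, tn, fp, fn = rng.integers(1, 40, 4)
            r = compute_metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            assert r.bac == (r.sen + r.spc) / 2.0
            assert r.roc_approx == (r.sen + r.prc) / 2.0
            assert r.f1 == 2.0 * r.prc * r.sen / (r.prc + r.sen)

    def test_zero_denominator_flagged_undefined_not_zero(self):
        r = compute_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
        assert r.sen is None and r.prc is None and r.f1 is None
        assert r.spc == 100.0

    def test_rounding_is_half_away_from_zero(self):
        assert round_half_away(92.655) == 92.66
        assert round_half_away(-0.005) == -0.01


class TestSlideFraction:
    def test_all_men(self):
        assert slide_fraction(["MEN"] * 4).p_men == 1.0

    def test_three_quarters(self):
        assert slide_fraction(["MEN", "MEN", "MEN", "SFT"]).p_men == 0.75

    def test_matches_count_oracle(self):
        rng = np.random.default_rng(2)
        decisions = [("MEN", "SFT")[i] for i in rng.integers(0, 2, 30)]
        f = slide_fraction(decisions)
        assert f.n_men == sum(d == "MEN" for d in decisions)
        assert f.p_men == f.n_men / 30

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no patch decisions"):
            slide_fraction([])


class TestFitBetaMle:
    def test_parameter_recovery_from_simulated_sample(self):
        rng = np.random.default_rng(17)
        sample = rng.beta(5.0, 2.0, size=500)
        fit = fit_beta_mle(sample)
        assert abs(fit.alpha - 5.0) / 5.0 < 0.15
        assert abs(fit.beta - 2.0) / 2.0 < 0.15

    def test_mirror_symmetric_sample_gives_equal_shapes(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0.05, 0.95, 100)
        sample = np.concatenate([x, 1.0 - x])
        fit = fit_beta_mle(sample)
        assert abs(fit.alpha - fit.beta) < 1e-6

    def test_mle_dominates_method_of_moments(self):
        rng = np.random.default_rng(8)
        sample = np.clip(rng.beta(3.0, 7.0, 80), 1e-4, 1 - 1e-4)
        fit = fit_beta_mle(sample)
        a0, b0 = _moments_init(sample)
        assert beta_loglik(fit, sample) >= beta_loglik(BetaParams(a0, b0), sample) - 1e-9

    def test_agrees_with_scipy_fit_oracle(self):
        rng = np.random.default_rng(23)
        sample = rng.beta(2.5, 4.0, 300)
        ours = fit_beta_mle(sample)
        a_sp, b_sp, _, _ = stats.beta.fit(np.clip(sample, 1e-4, 1 - 1e-4), floc=0, fscale=1)
        assert ours.alpha == pytest.approx(a_sp, rel=1e-3)
        assert ours.beta == pytest.approx(b_sp, rel=1e-3)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_beta_mle([1.0, 1.0, 1.0])


def _independent_beta_cdf(t: float, a: float, b: float) -> float:
    """CDF by numerical integration of the density, avoiding betainc."""
    norm = math.gamma(a) * math.gamma(b) / math.gamma(a + b)
    val, _ = integrate.quad(lambda x: x ** (a - 1) * (1 - x) ** (b - 1) / norm, 0.0, t)
    return val


class TestThresholdCurves:
    def test_mirror_pair_puts_j_max_at_half(self):
        curve = threshold_curves(BetaParams(8, 2), BetaParams(2, 8))
        assert curve.t_at_j_max == pytest.approx(0.5, abs=1e-9)

    def test_identical_distributions_have_zero_j(self):
        curve = threshold_curves(BetaParams(3, 3), BetaParams(3, 3))
        assert np.max(np.abs(curve.j)) < 1e-12

    def test_j_max_matches_numerical_integration_oracle(self):
        curve = threshold_curves(BetaParams(8, 2), BetaParams(2, 8))

        def j_oracle(t):
            return (1 - _independent_beta_cdf(t, 8, 2)) + _independent_beta_cdf(t, 2, 8) - 1

        # the reported maximum equals the oracle evaluated at the argmax ...
        assert curve.j_max == pytest.approx(j_oracle(curve.t_at_j_max), abs=1e-9)
        # ... and no coarse-grid threshold does better than the grid argmax
        assert max(j_oracle(t) for t in curve.thresholds[::25]) <= curve.j_max + 1e-9

    def test_monotonicity_invariants(self):
        curve = threshold_curves(BetaParams(6.5, 1.2), BetaParams(0.8, 4.0))
        assert np.all(np.diff(curve.sen) <= 1e-12)
        assert np.all(np.diff(curve.spc) >= -1e-12)
        np.testing.assert_allclose(curve.j, curve.sen + curve.spc - 1.0)

    def test_slide_classification_at_threshold(self):
        fr = [
            w.SlideFraction("a", 9, 1, "MEN"),
            w.SlideFraction("b", 1, 9, "SFT"),
        ]
        assert classify_slides(fr, 0.5) == ["MEN", "SFT"]


@pytest.fixture(scope="module")
def counts():
    rng = np.random.default_rng(5)
    p = rng.beta(6, 2, size=15)
    return [(int(round(pi * 40)), 40 - int(round(pi * 40))) for pi in p]


class TestBootstrapBetaCI:
    def test_fixed_seed_reproducibility(self, counts):
        a = bootstrap_beta_ci(counts, b=200, seed=3)
        b = bootstrap_beta_ci(counts, b=200, seed=3)
        assert a == b

    def test_ci_contains_point_estimate(self, counts):
        ci = bootstrap_beta_ci(counts, b=1000, seed=1)
        assert ci.alpha_ci[0] <= ci.estimate.alpha <= ci.alpha_ci[1]
        assert ci.beta_ci[0] <= ci.estimate.beta <= ci.beta_ci[1]

    def test_ci_width_shrinks_with_more_slides(self):
        rng = np.random.default_rng(9)

        def group(n):
            p = rng.beta(5, 3, size=n)
            return [(int(round(pi * 60)), 60 - int(round(pi * 60))) for pi in p]

        small = bootstrap_beta_ci(group(10), b=400, seed=2)
        large = bootstrap_beta_ci(group(100), b=400, seed=2)
        width = lambda ci: ci[1] - ci[0]
        assert width(large.alpha_ci) < width(small.alpha_ci)
        assert width(large.beta_ci) < width(small.beta_ci)

    def test_too_few_slides_rejected(self):
        with pytest.raises(ValueError, match="2 slides"):
            bootstrap_beta_ci([(5, 5)])


class TestSuperiorityTest:
    def make_slides(self, l0_err: float, agg_err: float, n=100, seed=0):
        rng = np.random.default_rng(seed)
        slides = []
        for label in ("MEN", "SFT"):
            truth = label == "MEN"
            l0 = np.where(rng.random(n) < l0_err, ~np.full(n, truth), truth)
            agg = np.where(rng.random(n) < agg_err, ~np.full(n, truth), truth)
            slides.append(SlideTuples(label, l0.astype(bool), agg.astype(bool)))
        return slides

    def test_no_signal_when_aggregate_equals_level0(self):
        slides = []
        rng = np.random.default_rng(1)
        for label in ("MEN", "SFT"):
            truth = label == "MEN"
            calls = np.where(rng.random(50) < 0.2, not truth, truth).astype(bool)
            slides.append(SlideTuples(label, calls, calls.copy()))
        p_fp, p_fn = superiority_test(slides, b=199, seed=4)
        assert p_fp == 1.0 and p_fn == 1.0

    def test_perfect_aggregate_reaches_floor_p_value(self):
        # level 0 errs on 30% of tuples; a size-100 resample essentially never
        # draws zero errors (0.7**100 < 1e-15), so every sample favors the
        # aggregate and the add-one p-value hits its floor 1/(B+1)
        assert 0.7**100 < 1e-15
        slides = self.make_slides(l0_err=0.3, agg_err=0.0, seed=2)
        p_fp, p_fn = superiority_test(slides, b=999, seed=7)
        assert p_fp == pytest.approx(1 / 1000)
        assert p_fn == pytest.approx(1 / 1000)

    def test_fixed_seed_reproducibility(self):
        slides = self.make_slides(l0_err=0.25, agg_err=0.1, seed=3)
        assert superiority_test(slides, b=299, seed=5) == superiority_test(
            slides, b=299, seed=5
        )

    def test_requires_both_classes(self):
        slides = self.make_slides(0.1, 0.0)[:1]
        with pytest.raises(ValueError, match="per class"):
            superiority_test(slides)


class TestBernoulliCI:
    def test_zero_successes_lower_bound_is_zero(self):
        lo, hi = bernoulli_ci(0, 10)
        assert lo == 0.0 and hi < 1.0

    def test_all_successes_upper_bound_is_one(self):
        lo, hi = bernoulli_ci(10, 10)
        assert hi == 1.0 and lo > 0.0

    def test_matches_beta_quantile_oracle(self):
        lo, hi = bernoulli_ci(95, 100)
        import statsmodels.stats.proportion as smp

        lo_sm, hi_sm = smp.proportion_confint(95, 100, alpha=0.05, method="beta")
        assert lo == pytest.approx(lo_sm, abs=1e-12)
        assert hi == pytest.approx(hi_sm, abs=1e-12)


@pytest.fixture(scope="module")
def slide():
    return w.generate_slide(w.SlideSpec("MEN", seed=31, base_size=1024))


class TestRegionDecision:
    def test_oracle_backend_on_pure_men_slide(self, slide):
        pyr, _ = slide
        backends = [OracleBackend("MEN")] * 3
        rd = region_decision(
            pyr, backends, FusionWeights(0.4, 0.3, 0.3), (0, 0, 1024), tile_size=32
        )
        assert rd.combined == pytest.approx((1.0, 0.0))
        assert rd.label == "MEN"
        assert rd.color == CLASS_COLORS["MEN"]

    def test_constant_backend_ties_to_men(self, slide):
        pyr, _ = slide
        backends = [ConstantBackend(0.5)] * 3
        rd = region_decision(
            pyr, backends, FusionWeights(1 / 3, 1 / 3, 1 / 3), (0, 0, 1024), tile_size=32
        )
        assert rd.combined == pytest.approx((0.5, 0.5))
        assert rd.label == "MEN"

    def test_matches_brute_force_average_oracle(self, slide):
        """Per-level mean probability pairs recomputed tile by tile."""
        pyr, _ = slide

        class GradedBackend:
            def predict_proba(self, patch):
                m = float(patch.mean()) / 255.0
                m = min(max(m, 0.0), 1.0)
                return w.ProbVector(m, 1.0 - m)

        backends = [GradedBackend()] * 3
        weights = FusionWeights(0.5, 0.25, 0.25)
        rd = region_decision(pyr, backends, weights, (0, 0, 1024), tile_size=64)
        for lvl in range(3):
            d = pyr.downsamples[lvl]
            raster = pyr.levels[lvl][: 1024 // d, : 1024 // d]
            vals = []
            for ty in range(0, raster.shape[0], 64):
                for tx in range(0, raster.shape[1], 64):
                    m = float(raster[ty : ty + 64, tx : tx + 64].mean()) / 255.0
                    vals.append((m, 1.0 - m))
            mean = np.mean(vals, axis=0)
            mean = mean / mean.sum()
            assert rd.per_level[lvl] == pytest.approx(tuple(mean))
        combined = sum(
            wt * np.array(p) for wt, p in zip(weights.as_array(), rd.per_level)
        )
        assert rd.combined == pytest.approx(tuple(combined))

    def test_region_outside_bounds_rejected(self, slide):
        pyr, _ = slide
        with pytest.raises(ValueError, match="exceeds|divisible"):
            region_decision(
                pyr,
                [ConstantBackend()] * 3,
                FusionWeights(1 / 3, 1 / 3, 1 / 3),
                (512, 512, 1024),
                tile_size=32,
            )

    def test_overlay_colors_regions(self, slide):
        pyr, _ = slide
        rd = region_decision(
            pyr,
            [OracleBackend("SFT")] * 3,
            FusionWeights(1 / 3, 1 / 3, 1 / 3),
            (0, 0, 1024),
            tile_size=32,
        )
        out = render_overlay(pyr, [rd], opacity=1.0)
        assert tuple(out[0, 0]) == rd.color


class TestConfidenceScore:
    def test_every_patch_correct_gives_hundred(self):
        regions = [
            RegionDecision((0, 0, 64), ((1.0, 0.0),) * 3, (1.0, 0.0), "MEN", ((4, 0),) * 3)
        ]
        assert confidence_score(regions, "MEN") == 100.0

    def test_mean_of_regional_ratios(self):
        def region(n_ok, n_total):
            return RegionDecision(
                (0, 0, 64),
                ((0.5, 0.5),) * 3,
                (0.5, 0.5),
                "MEN",
                ((n_ok, n_total - n_ok), (0, 0), (0, 0)),
            )

        regions = [region(20, 20), region(18, 20), region(19, 20)]
        assert confidence_score(regions, "MEN") == pytest.approx(95.0)

    def test_matches_global_tally_oracle(self):
        rng = np.random.default_rng(14)
        regions = []
        expected = []
        for _ in range(6):
            counts = tuple((int(a), int(b)) for a, b in rng.integers(1, 20, (3, 2)))
            regions.append(
                RegionDecision((0, 0, 64), ((0.5, 0.5),) * 3, (0.5, 0.5), "MEN", counts)
            )
            ok = sum(c[0] for c in counts)
            total = sum(c[0] + c[1] for c in counts)
            expected.append(ok / total)
        assert confidence_score(regions, "MEN") == pytest.approx(100 * np.mean(expected))
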