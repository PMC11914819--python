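"""Metrics, regional decisions and coloring, confidence scores, and the
beta/bootstrap statistical suite.

Patch-level performance is summarised by the usual confusion-matrix metrics
(MEN is the positive class).  Slide-level behaviour is modelled through the
per-slide fraction of patches called MEN, p(MEN), fitted per class as a beta
distribution by maximum likelihood; from the two fitted distributions the
theoretical sensitivity / specificity / precision and Youden index J are
traced over decision thresholds, and the J-maximising threshold gives the
slide-level operating point.  Uncertainty is quantified by a parametric
slide bootstrap on the beta shape parameters, exact Clopper-Pearson
(Bernoulli) intervals on the metrics, and a paired resampling test of
whether the weighted aggregate beats the finest single level on false
positives and false negatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import special, stats

from .classifier import Backend, ProbVector
from .fusion import FusionWeights, wmv_predict
from .pyramid import PyramidImage, PatchWindow, map_point, read_region

POSITIVE_CLASS = "MEN"
NEGATIVE_CLASS = "SFT"

# Region coloring, matching the convention "blue = MEN, green = SFT".
CLASS_COLORS = {"MEN": (40, 70, 220), "SFT": (40, 180, 70)}


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (so 92.655 -> 92.66, -0.005 -> -0.01)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


# --------------------------------------------------------------------------
# Confusion counts and metric identities


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Percentages, full precision; None marks an undefined metric (zero
    denominator), never silently 0."""

    acc: float | None
    sen: float | None
    spc: float | None
    prc: float | None
    bac: float | None
    roc_approx: float | None
    f1: float | None

    def rounded(self, ndigits: int = 2) -> dict:
        return {
            k: (None if v is None else round_half_away(v, ndigits))
            for k, v in self.__dict__.items()
        }


def confusion_counts(predictions: Sequence[str], labels: Sequence[str]) -> ConfusionCounts:
    """Exact counts with MEN as the positive class."""
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels must be aligned")
    if len(labels) == 0:
        raise ValueError("empty evaluation set")
    tp = tn = fp = fn = 0
    for p, y in zip(predictions, labels):
        if y == POSITIVE_CLASS:
            if p == POSITIVE_CLASS:
                tp += 1
            else:
                fn += 1
        else:
            if p == POSITIVE_CLASS:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else 100.0 * num / den


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy, sensitivity TP/(TP+FN), specificity, precision, balanced
    accuracy, the (SEN+PRC)/2 "ROC approximated" summary, and F1.

    Derived metrics are computed from the full-precision primaries, so the
    identities bac = (sen+spc)/2, roc = (sen+prc)/2 and the harmonic-mean F1
    hold exactly before any rounding.
    """
    if c.n == 0:
        raise ValueError("empty confusion counts")
    acc = _ratio(c.tp + c.tn, c.n)
    sen = _ratio(c.tp, c.tp + c.fn)
    spc = _ratio(c.tn, c.tn + c.fp)
    prc = _ratio(c.tp, c.tp + c.fp)
    bac = None if sen is None or spc is None else (sen + spc) / 2.0
    roc = None if sen is None or prc is None else (sen + prc) / 2.0
    if sen is None or prc is None or sen + prc == 0:
        f1 = None
    else:
        f1 = 2.0 * prc * sen / (prc + sen)
    return MetricsReport(acc=acc, sen=sen, spc=spc, prc=prc, bac=bac, roc_approx=roc, f1=f1)


def derived_metrics(sen: float, spc: float, prc: float) -> dict:
    """BAC, ROC-approx and F1 from already-known primary percentages."""
    return {
        "bac": (sen + spc) / 2.0,
        "roc_approx": (sen + prc) / 2.0,
        "f1": 2.0 * prc * sen / (prc + sen),
    }


# --------------------------------------------------------------------------
# Slide fractions and the beta model


@dataclass(frozen=True)
class SlideFraction:
    slide_id: str
    n_men: int
    n_sft: int
    true_label: str

    def __post_init__(self) -> None:
        if self.n_men < 0 or self.n_sft < 0 or self.n_men + self.n_sft == 0:
            raise ValueError("patch counts must be non-negative with a positive sum")

    @property
    def p_men(self) -> float:
        return self.n_men / (self.n_men + self.n_sft)


def jeffreys_fraction(f: SlideFraction) -> float:
    """Jeffreys-smoothed MEN fraction (n_MEN + 0.5) / (n + 1).

    Raw fractions of exactly 0 or 1 carry no likelihood under any beta
    density; the half-count continuity correction — the same smoothing the
    slide bootstrap uses for its Beta(n_MEN+0.5, n_SFT+0.5) draws — keeps
    the group fit well-defined even when a classifier is perfect on a
    slide.
    """
    return (f.n_men + 0.5) / (f.n_men + f.n_sft + 1.0)


def slide_fraction(
    decisions: Sequence[str], slide_id: str = "", true_label: str = POSITIVE_CLASS
) -> SlideFraction:
    """Fraction of one slide's patch decisions called MEN."""
    if len(decisions) == 0:
        raise ValueError("slide has no patch decisions")
    n_men = sum(1 for d in decisions if d == POSITIVE_CLASS)
    return SlideFraction(
        slide_id=slide_id, n_men=n_men, n_sft=len(decisions) - n_men, true_label=true_label
    )


@dataclass(frozen=True)
class BetaParams:
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError(f"shape parameters must be positive: {self}")
        if not (np.isfinite(self.alpha) and np.isfinite(self.beta)):
            raise ValueError(f"shape parameters must be finite: {self}")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


_CLAMP = 1e-4


def beta_loglik(params: BetaParams, x: np.ndarray) -> float:
    return float(np.sum(stats.beta.logpdf(x, params.alpha, params.beta)))


def _moments_init(x: np.ndarray) -> tuple[float, float]:
    m, v = float(x.mean()), float(x.var())
    if v <= 0 or v >= m * (1 - m):
        return (1.0, 1.0)
    common = m * (1 - m) / v - 1.0
    return (max(m * common, 1e-3), max((1 - m) * common, 1e-3))


def fit_beta_mle(fractions: Sequence[float], tol: float = 1e-8, max_iter: int = 500) -> BetaParams:
    """Maximum-likelihood beta fit of a set of fractions.

    Values are clamped to [1e-4, 1 - 1e-4] (a fraction of exactly 0 or 1 has
    infinite log-density under any beta), initialised by the method of
    moments, then refined by a damped Newton iteration on the digamma
    score equations until the parameter change drops below ``tol``.
    """
    x = np.clip(np.asarray(fractions, dtype=np.float64), _CLAMP, 1.0 - _CLAMP)
    if x.size < 2:
        raise ValueError("need at least 2 fractions to fit a beta distribution")
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate sample: all fractions identical after clamping")

    n = x.size
    slog_x = float(np.sum(np.log(x)))
    slog_1mx = float(np.sum(np.log1p(-x)))

    def loglik(a: float, b: float) -> float:
        return (a - 1) * slog_x + (b - 1) * slog_1mx - n * float(special.betaln(a, b))

    a, b = _moments_init(x)
    ll = loglik(a, b)
    for _ in range(max_iter):
        psi_ab = special.digamma(a + b)
        g = np.array(
            [
                slog_x - n * (special.digamma(a) - psi_ab),
                slog_1mx - n * (special.digamma(b) - psi_ab),
            ]
        )
        tri_ab = special.polygamma(1, a + b)
        # Hessian of the log-likelihood (negative definite near the optimum)
        H = -n * np.array(
            [
                [special.polygamma(1, a) - tri_ab, -tri_ab],
                [-tri_ab, special.polygamma(1, b) - tri_ab],
            ]
        )
        try:
            delta = np.linalg.solve(H, -g)
        except np.linalg.LinAlgError:
            break
        step = 1.0
        while step > 1e-8:
            na, nb = a + step * delta[0], b + step * delta[1]
            if na > 0 and nb > 0:
                nll = loglik(na, nb)
                if nll >= ll - 1e-12:
                    break
            step /= 2.0
        else:
            break
        moved = max(abs(na - a), abs(nb - b))
        a, b, ll = na, nb, nll
        if moved < tol:
            break
    return BetaParams(alpha=float(a), beta=float(b))


# --------------------------------------------------------------------------
# Threshold curves and the Youden operating point


@dataclass(frozen=True)
class ThresholdCurve:
    thresholds: np.ndarray
    sen: np.ndarray
    spc: np.ndarray
    prc: np.ndarray
    j: np.ndarray

    @property
    def j_max_index(self) -> int:
        return int(np.argmax(self.j))

    @property
    def t_at_j_max(self) -> float:
        return float(self.thresholds[self.j_max_index])

    @property
    def j_max(self) -> float:
        return float(self.j[self.j_max_index])


def threshold_curves(
    beta_men: BetaParams,
    beta_sft: BetaParams,
    prior_men: float = 0.5,
    step: float = 0.001,
) -> ThresholdCurve:
    """Theoretical SEN/SPC/PRC/J over p(MEN) thresholds.

    A slide is called MEN when its p(MEN) meets the threshold t, so
    SEN(t) = 1 - F_MEN(t) and SPC(t) = F_SFT(t) with F the fitted beta CDFs;
    precision folds in the class prior (0.5 for a balanced cohort).  J_max
    is taken at the grid argmax over t = step ... 1 - step.
    """
    m = round(1.0 / step)
    t = np.arange(1, m) / m
    sen = 1.0 - stats.beta.cdf(t, beta_men.alpha, beta_men.beta)
    spc = stats.beta.cdf(t, beta_sft.alpha, beta_sft.beta)
    denom = sen * prior_men + (1.0 - spc) * (1.0 - prior_men)
    with np.errstate(invalid="ignore", divide="ignore"):
        prc = np.where(denom > 0, sen * prior_men / np.where(denom > 0, denom, 1.0), np.nan)
    return ThresholdCurve(thresholds=t, sen=sen, spc=spc, prc=prc, j=sen + spc - 1.0)


def classify_slides(
    fractions: Sequence[SlideFraction], threshold: float
) -> list[str]:
    """Slide-level calls: MEN when p(MEN) >= threshold."""
    return [POSITIVE_CLASS if f.p_men >= threshold else NEGATIVE_CLASS for f in fractions]


# --------------------------------------------------------------------------
# Bootstrap suites


@dataclass(frozen=True)
class BetaBootstrapCI:
    estimate: BetaParams
    alpha_ci: tuple[float, float]
    beta_ci: tuple[float, float]
    n_failures: int
    b: int


def bootstrap_beta_ci(
    slide_counts: Sequence[tuple[int, int]],
    b: int = 1000,
    seed: int | None = 0,
    level: float = 0.95,
) -> BetaBootstrapCI:
    """Basic bootstrap CIs on the beta shape parameters of one slide group.

    Each bootstrap sample resamples slides with replacement and, for every
    selected slide, draws p(MEN) from Beta(n_MEN + 0.5, n_SFT + 0.5) — the
    Jeffreys posterior of the slide's own patch counts — then refits the
    MLE.  Limits are the basic-bootstrap reflections
    (2*theta_hat - q_{1-a/2}, 2*theta_hat - q_{a/2}).  Degenerate bootstrap
    samples (fit failures) are skipped and counted.
    """
    counts = [(int(nm), int(ns)) for nm, ns in slide_counts]
    if len(counts) < 2:
        raise ValueError("need at least 2 slides per group")
    # point estimate on the same half-count smoothing the resamples use
    observed = [(nm + 0.5) / (nm + ns + 1.0) for nm, ns in counts]
    estimate = fit_beta_mle(observed)

    rng = np.random.default_rng(seed)
    alphas, betas = [], []
    failures = 0
    k = len(counts)
    for _ in range(b):
        idx = rng.integers(0, k, size=k)
        draws = [rng.beta(counts[i][0] + 0.5, counts[i][1] + 0.5) for i in idx]
        try:
            fit = fit_beta_mle(draws)
        except ValueError:
            failures += 1
            continue
        alphas.append(fit.alpha)
        betas.append(fit.beta)
    if not alphas:
        raise ValueError("every bootstrap sample failed to fit")
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2

    def basic(theta: float, samples: list[float]) -> tuple[float, float]:
        q_lo, q_hi = np.quantile(samples, [lo_q, hi_q])
        return (2 * theta - float(q_hi), 2 * theta - float(q_lo))

    return BetaBootstrapCI(
        estimate=estimate,
        alpha_ci=basic(estimate.alpha, alphas),
        beta_ci=basic(estimate.beta, betas),
        n_failures=failures,
        b=b,
    )


@dataclass(frozen=True)
class SlideTuples:
    """Per-slide patch decision tuples: for each patch, the Level 0 call and
    the weighted-aggregate call, as booleans (True = called MEN)."""

    true_label: str
    level0_men: np.ndarray
    aggregate_men: np.ndarray

    def __post_init__(self) -> None:
        if len(self.level0_men) != len(self.aggregate_men):
            raise ValueError("tuple components must be aligned")
        if len(self.level0_men) == 0:
            raise ValueError("slide has no decision tuples")


def superiority_test(
    slides: Sequence[SlideTuples],
    b: int = 999,
    seed: int | None = 0,
) -> tuple[float, float]:
    """Paired resampling test: does the weighted aggregate beat Level 0?

    Each bootstrap sample picks one slide per ground-truth class at random,
    resamples its decision tuples with replacement (same size), and records
    the false-positive rate on the SFT slide and the false-negative rate on
    the MEN slide for both Level 0 and the aggregate.  The one-sided
    add-one p-value counts samples where the aggregate fails to be strictly
    better: p = (1 + #{aggregate_rate >= level0_rate}) / (B + 1).
    Returns (p_FP, p_FN).
    """
    men_slides = [s for s in slides if s.true_label == POSITIVE_CLASS]
    sft_slides = [s for s in slides if s.true_label == NEGATIVE_CLASS]
    if not men_slides or not sft_slides:
        raise ValueError("need at least one slide per class")
    rng = np.random.default_rng(seed)
    worse_fp = worse_fn = 0
    for _ in range(b):
        s_sft = sft_slides[rng.integers(0, len(sft_slides))]
        s_men = men_slides[rng.integers(0, len(men_slides))]
        i_sft = rng.integers(0, len(s_sft.level0_men), size=len(s_sft.level0_men))
        i_men = rng.integers(0, len(s_men.level0_men), size=len(s_men.level0_men))
        fp_l0 = float(s_sft.level0_men[i_sft].mean())
        fp_agg = float(s_sft.aggregate_men[i_sft].mean())
        fn_l0 = float(1.0 - s_men.level0_men[i_men].mean())
        fn_agg = float(1.0 - s_men.aggregate_men[i_men].mean())
        if fp_agg >= fp_l0:
            worse_fp += 1
        if fn_agg >= fn_l0:
            worse_fn += 1
    return ((1 + worse_fp) / (b + 1), (1 + worse_fn) / (b + 1))


def bernoulli_ci(successes: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson exact interval for a Bernoulli probability."""
    if not 0 <= successes <= trials or trials <= 0:
        raise ValueError(f"invalid counts: {successes}/{trials}")
    a = 1.0 - level
    lower = 0.0 if successes == 0 else float(
        stats.beta.ppf(a / 2, successes, trials - successes + 1)
    )
    upper = 1.0 if successes == trials else float(
        stats.beta.ppf(1 - a / 2, successes + 1, trials - successes)
    )
    return (lower, upper)


# --------------------------------------------------------------------------
# Regional decisions, coloring and confidence


@dataclass(frozen=True)
class RegionDecision:
    """One region's fused call: per-level averaged probability pairs, the
    weighted combination, tile tallies per level, and the display color."""

    region_l0: tuple[int, int, int]  # (x, y, size) in level-0 pixels
    per_level: tuple[tuple[float, float], ...]
    combined: tuple[float, float]
    label: str
    tile_counts: tuple[tuple[int, int], ...]  # per level: (n called MEN, n called SFT)

    @property
    def color(self) -> tuple[int, int, int]:
        return CLASS_COLORS[self.label]


def region_decision(
    pyramid: PyramidImage,
    backends: Sequence[Backend],
    weights: FusionWeights,
    region_l0: tuple[int, int, int],
    tile_size: int = 256,
    tie_break: str = POSITIVE_CLASS,
) -> RegionDecision:
    """Classify one aligned region of the slide at every level.

    The level-local footprint of ``region_l0`` is tiled into
    ``tile_size`` x ``tile_size`` patches, every tile is classified by that
    level's backend, the probability pairs are averaged and renormalised per
    level, and the level pairs are combined with the fusion weights; the
    color label is the argmax of the combined pair (ties to MEN).
    """
    x0, y0, size = region_l0
    if size <= 0:
        raise ValueError("region size must be positive")
    per_level: list[tuple[float, float]] = []
    tallies: list[tuple[int, int]] = []
    for lvl in range(pyramid.n_levels):
        d = pyramid.downsamples[lvl]
        lx, ly = map_point((x0, y0), 1, d)
        lsize = size // d
        if size % d or lsize % tile_size:
            raise ValueError(
                f"region edge {size} must be divisible by tile_size*downsample "
                f"({tile_size}*{d}) at level {lvl}"
            )
        w, h = pyramid.level_dimensions(lvl)
        if lx + lsize > w or ly + lsize > h:
            raise ValueError(f"region {region_l0} exceeds level {lvl} bounds")
        pairs = []
        n_men = n_sft = 0
        for ty in range(ly, ly + lsize, tile_size):
            for tx in range(lx, lx + lsize, tile_size):
                patch = read_region(pyramid, lvl, PatchWindow(lvl, tx, ty, tile_size))
                p = backends[lvl].predict_proba(patch)
                pairs.append((p.p_men, p.p_sft))
                if p.label == POSITIVE_CLASS:
                    n_men += 1
                else:
                    n_sft += 1
        mean = np.mean(pairs, axis=0)
        mean = mean / mean.sum()
        per_level.append((float(mean[0]), float(mean[1])))
        tallies.append((n_men, n_sft))
    probs = [ProbVector(p_men=m, p_sft=s) for m, s in per_level]
    decision = wmv_predict(probs, weights, tie_break=tie_break)
    return RegionDecision(
        region_l0=region_l0,
        per_level=tuple(per_level),
        combined=decision.combined,
        label=decision.label,
        tile_counts=tuple(tallies),
    )


def confidence_score(regions: Sequence[RegionDecision], true_label: str) -> float:
    """Mean over regions of the fraction of correctly classified tiles
    (pooled across levels within each region), as a percentage."""
    if len(regions) == 0:
        raise ValueError("need at least one region")
    idx = 0 if true_label == POSITIVE_CLASS else 1
    ratios = []
    for r in regions:
        correct = sum(t[idx] for t in r.tile_counts)
        total = sum(t[0] + t[1] for t in r.tile_counts)
        ratios.append(correct / total)
    return 100.0 * float(np.mean(ratios))


def render_overlay(
    pyramid: PyramidImage,
    regions: Sequence[RegionDecision],
    opacity: float = 0.4,
) -> np.ndarray:
    """Color the coarsest-level raster by regional class (blue MEN, green
    SFT) at the given opacity; returns an RGB array."""
    coarse = pyramid.n_levels - 1
    d = pyramid.downsamples[coarse]
    canvas = pyramid.levels[coarse].astype(np.float64).copy()
    if canvas.ndim == 2:
        canvas = np.stack([canvas] * 3, axis=-1)
    for r in regions:
        x, y, size = r.region_l0
        lx, ly, ls = x // d, y // d, size // d
        block = canvas[ly : ly + ls, lx : lx + ls]
        block[:] = (1 - opacity) * block + opacity * np.array(r.color, dtype=np.float64)
    return np.clip(np.floor(canvas + 0.5), 0, 255).astype(np.uint8)
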