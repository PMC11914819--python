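"""Weighted majority voting over per-level classifier outputs.

The fused patch decision is ``argmax_c sum_i w_i * P_i(c | x)`` with one
non-negative weight per pyramid level, the weights summing to one.  Two
weight-derivation routes are provided: normalising the per-level accuracies,
and an exhaustive grid search over the weight simplex (the selection
procedure used by the pipeline).  Grid arithmetic is carried out in integer
grid units so a step of 0.001 suffers no floating-point drift.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .classifier import ProbVector

TIE_BREAK_DEFAULT = "MEN"


@dataclass(frozen=True)
class FusionWeights:
    """Per-level voting weights: non-negative, summing to one."""

    w0: float
    w1: float
    w2: float

    def __post_init__(self) -> None:
        ws = (self.w0, self.w1, self.w2)
        if any(w < 0 for w in ws):
            raise ValueError(f"weights must be non-negative: {ws}")
        if abs(sum(ws) - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1: {ws}")

    def as_array(self) -> np.ndarray:
        return np.array([self.w0, self.w1, self.w2])

    def to_json(self, search: dict | None = None) -> str:
        obj = {"w0": self.w0, "w1": self.w1, "w2": self.w2}
        if search is not None:
            obj["search"] = search
        return json.dumps(obj, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FusionWeights":
        obj = json.loads(text)
        return cls(w0=obj["w0"], w1=obj["w1"], w2=obj["w2"])


@dataclass(frozen=True)
class PatchDecision:
    """One fused patch decision with its per-level inputs."""

    per_level: tuple[ProbVector, ...]
    combined: tuple[float, float]
    label: str


def normalized_weights(accuracies: Sequence[float]) -> FusionWeights:
    """Weights proportional to the per-level accuracies (w_i = a_i / sum a).

    Scale-invariant: any common rescaling of the accuracies gives the same
    weights, so percentages and fractions are interchangeable.
    """
    a = np.asarray(accuracies, dtype=np.float64)
    if a.shape != (3,):
        raise ValueError(f"expected 3 accuracies, got shape {a.shape}")
    if np.any(a <= 0):
        raise ValueError(f"accuracies must be positive, got {accuracies}")
    w = a / a.sum()
    return FusionWeights(w0=float(w[0]), w1=float(w[1]), w2=float(w[2]))


def wmv_predict(
    probs: Sequence[ProbVector],
    weights: FusionWeights,
    tie_break: str = TIE_BREAK_DEFAULT,
) -> PatchDecision:
    """Weighted majority vote over one patch's per-level probabilities.

    Exact ties of the combined scores go to ``tie_break`` (MEN by default).
    """
    if len(probs) != 3:
        raise ValueError(f"expected 3 probability vectors, got {len(probs)}")
    w = weights.as_array()
    men = float(np.dot(w, [p.p_men for p in probs]))
    sft = float(np.dot(w, [p.p_sft for p in probs]))
    if men > sft:
        label = "MEN"
    elif sft > men:
        label = "SFT"
    else:
        label = tie_break
    return PatchDecision(per_level=tuple(probs), combined=(men, sft), label=label)


def _as_pmen_matrix(per_level_probs: Sequence[Sequence]) -> np.ndarray:
    """(3, n) matrix of MEN probabilities from lists of ProbVectors or floats."""
    rows = []
    for level in per_level_probs:
        rows.append(
            [p.p_men if isinstance(p, ProbVector) else float(p) for p in level]
        )
    P = np.asarray(rows, dtype=np.float64)
    if P.shape[0] != 3:
        raise ValueError(f"expected probabilities for 3 levels, got {P.shape[0]}")
    return P


@dataclass(frozen=True)
class GridSearchResult:
    weights: FusionWeights
    accuracy: float
    step: float


def grid_search_weights(
    per_level_probs: Sequence[Sequence],
    labels: Sequence[str],
    step: float = 0.001,
    tie_break: str = TIE_BREAK_DEFAULT,
) -> GridSearchResult:
    """Exhaustive scan of the weight simplex at the given step.

    w0 and w1 range over the grid (combinations with w0 + w1 > 1 skipped)
    and w2 = 1 - w0 - w1.  The returned weights maximise fused patch
    accuracy; score ties go to the first grid point encountered scanning w0
    ascending, then w1 ascending.  The degenerate corners (1,0,0), (0,1,0),
    (0,0,1) are grid points, so the optimum always matches or beats every
    single level on the search set.
    """
    P = _as_pmen_matrix(per_level_probs)
    n = P.shape[1]
    if n == 0:
        raise ValueError("empty evaluation set")
    if len(labels) != n:
        raise ValueError("labels and probabilities must be aligned")
    m = round(1.0 / step)
    if abs(m * step - 1.0) > 1e-9 or m < 1:
        raise ValueError(f"step {step} does not divide 1 into an integer grid")

    y_men = np.array([l == "MEN" for l in labels])

    # integer-thousandths grid in scan order (w0 asc, then w1 asc)
    a_all, b_all = [], []
    for a in range(m + 1):
        b = np.arange(m - a + 1)
        a_all.append(np.full(b.shape, a))
        b_all.append(b)
    A = np.concatenate(a_all)
    B = np.concatenate(b_all)
    C = m - A - B
    G = np.stack([A, B, C], axis=1).astype(np.float64)

    best_idx, best_correct = 0, -1
    chunk = max(1, int(5_000_000 // max(n, 1)))
    for start in range(0, G.shape[0], chunk):
        block = G[start : start + chunk]
        scores = block @ P  # (g, n) combined MEN score in grid units
        pred_men = scores * 2.0 >= m  # combined p_men >= 0.5, ties to MEN
        if tie_break != "MEN":
            pred_men = scores * 2.0 > m
        correct = (pred_men == y_men).sum(axis=1)
        i = int(np.argmax(correct))  # first max within block = scan order
        if correct[i] > best_correct:
            best_correct = int(correct[i])
            best_idx = start + i
    a, b, c = (int(v) for v in G[best_idx])
    weights = FusionWeights(w0=a / m, w1=b / m, w2=c / m)
    return GridSearchResult(weights=weights, accuracy=best_correct / n, step=step)


def save_weights(path: str | Path, result: GridSearchResult) -> None:
    Path(path).write_text(
        result.weights.to_json(search={"step": result.step, "accuracy": result.accuracy})
    )
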