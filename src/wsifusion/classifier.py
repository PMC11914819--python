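"""Per-level patch classification behind a pluggable contract.

A classifier backend is anything exposing ``predict_proba(patch) ->
ProbVector``; fusion and evaluation accept any such object, so a heavyweight
external model (a fine-tuned vision transformer, say) drops in without
changing the pipeline.  The built-in reference backend keeps the framework
self-contained: 26 hand-crafted texture features fed to a two-class
multinomial logistic model trained by full-batch gradient descent.  It is a
first-class, deterministic classifier in its own right, adequate for the
textures the synthetic cohort produces.

Feature layout (all finite, all in [0, 1]):

* 16-bin normalised grayscale histogram (sums to 1);
* 8-bin gradient-orientation histogram over [0, pi), magnitude-weighted and
  normalised (all zeros when the patch has no gradient energy);
* grayscale mean / 255 and grayscale std / 255.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np

from .filtering import rec601_gray

CLASSES = ("MEN", "SFT")
N_GRAY_BINS = 16
N_ORIENT_BINS = 8
N_FEATURES = N_GRAY_BINS + N_ORIENT_BINS + 2
FEATURE_VERSION = "hist16-orient8-v1"


@dataclass(frozen=True)
class ProbVector:
    """Two-class probabilities from one backend on one patch."""

    p_men: float
    p_sft: float

    def __post_init__(self) -> None:
        if self.p_men < 0 or self.p_sft < 0:
            raise ValueError(f"probabilities must be non-negative: {self}")
        if abs(self.p_men + self.p_sft - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1: {self}")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_men, self.p_sft])

    @property
    def label(self) -> str:
        # deterministic tie rule: MEN wins exact ties
        return "MEN" if self.p_men >= self.p_sft else "SFT"


class Backend(Protocol):
    """The classifier contract used by fusion and evaluation."""

    def predict_proba(self, patch: np.ndarray) -> ProbVector: ...


def extract_features(patch: np.ndarray) -> np.ndarray:
    """Deterministic 26-dimensional texture descriptor of an RGB patch."""
    if np.asarray(patch).size == 0:
        raise ValueError("patch is empty")
    gray = rec601_gray(patch)

    hist, _ = np.histogram(gray, bins=N_GRAY_BINS, range=(0.0, 256.0))
    hist = hist / gray.size

    gy, gx = np.gradient(gray)
    mag = np.hypot(gx, gy)
    total = mag.sum()
    if total > 0:
        orient = np.mod(np.arctan2(gy, gx), np.pi)
        ohist, _ = np.histogram(orient, bins=N_ORIENT_BINS, range=(0.0, np.pi), weights=mag)
        ohist = ohist / total
    else:
        ohist = np.zeros(N_ORIENT_BINS)

    return np.concatenate([hist, ohist, [gray.mean() / 255.0, gray.std() / 255.0]])


def orientation_anisotropy(patch: np.ndarray) -> float:
    """Circular resultant length of the gradient-orientation distribution.

    0 for perfectly isotropic texture, 1 when every gradient shares one
    orientation; the statistic that separates streaked from blobby texture.
    """
    gray = rec601_gray(patch)
    gy, gx = np.gradient(gray)
    mag = np.hypot(gx, gy)
    total = mag.sum()
    if total == 0:
        return 0.0
    angle = 2.0 * np.arctan2(gy, gx)  # doubled: orientations, not directions
    return float(np.hypot((mag * np.cos(angle)).sum(), (mag * np.sin(angle)).sum()) / total)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1.0
    epochs: int = 5000
    seed: int = 0


@dataclass
class ReferenceModel:
    """2 x 27 weight matrix (bias in the last column) plus its training
    provenance."""

    weights: np.ndarray
    config: TrainConfig
    feature_version: str = FEATURE_VERSION
    loss_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.shape != (2, N_FEATURES + 1):
            raise ValueError(f"weights must be 2 x {N_FEATURES + 1}, got {self.weights.shape}")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")

    def to_json(self) -> str:
        return json.dumps(
            {
                "weights": self.weights.tolist(),
                "config": {
                    "learning_rate": self.config.learning_rate,
                    "epochs": self.config.epochs,
                    "seed": self.config.seed,
                },
                "feature_version": self.feature_version,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "ReferenceModel":
        obj = json.loads(text)
        return cls(
            weights=np.array(obj["weights"]),
            config=TrainConfig(**obj["config"]),
            feature_version=obj["feature_version"],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceModel":
        return cls.from_json(Path(path).read_text())


def _softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _design(features: np.ndarray) -> np.ndarray:
    X = np.asarray(features, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    return np.hstack([X, np.ones((X.shape[0], 1))])


def fit_reference(
    features: Sequence[np.ndarray],
    labels: Sequence[str],
    config: TrainConfig = TrainConfig(),
) -> ReferenceModel:
    """Fit the two-class multinomial logistic model by full-batch gradient
    descent from a zero initialisation.

    Full-batch updates make the trajectory independent of example order, and
    zero epochs leave the zero model (uniform predictions).  The default
    step size keeps the cross-entropy loss non-increasing for features
    bounded in [0, 1].
    """
    if len(features) != len(labels):
        raise ValueError("features and labels must be aligned")
    if len(features) == 0:
        raise ValueError("no training examples")
    present = set(labels)
    if not present.issuperset(CLASSES):
        raise ValueError(f"need at least one example per class, got only {sorted(present)}")
    X = _design(np.vstack(features))
    y = np.array([CLASSES.index(l) for l in labels])
    Y = np.eye(2)[y]
    n = X.shape[0]

    W = np.zeros((2, X.shape[1]))
    losses: list[float] = []
    for _ in range(config.epochs):
        P = _softmax(X @ W.T)
        losses.append(float(-np.mean(np.log(P[np.arange(n), y] + 1e-300))))
        grad = (P - Y).T @ X / n
        W = W - config.learning_rate * grad
    return ReferenceModel(weights=W, config=config, loss_history=losses)


def predict_proba_features(model: ReferenceModel, features: np.ndarray) -> np.ndarray:
    """Class probabilities for one feature vector or a stack of them."""
    X = _design(features)
    P = _softmax(X @ model.weights.T)
    return P[0] if np.asarray(features).ndim == 1 else P


def predict_proba(model: ReferenceModel, patch: np.ndarray) -> ProbVector:
    p = predict_proba_features(model, extract_features(patch))
    return ProbVector(p_men=float(p[0]), p_sft=float(p[1]))


@dataclass
class ReferenceBackend:
    """Contract adapter around a trained :class:`ReferenceModel`."""

    model: ReferenceModel
    apply_circular_mask: bool = False
    mask_fill: tuple[int, int, int] = (255, 255, 255)

    def predict_proba(self, patch: np.ndarray) -> ProbVector:
        if self.apply_circular_mask:
            from .filtering import circular_mask

            patch = circular_mask(patch, self.mask_fill)
        return predict_proba(self.model, patch)


@dataclass(frozen=True)
class ConstantBackend:
    """Mock backend emitting one fixed probability pair for every patch."""

    p_men: float = 0.5

    def predict_proba(self, patch: np.ndarray) -> ProbVector:
        return ProbVector(p_men=self.p_men, p_sft=1.0 - self.p_men)


@dataclass(frozen=True)
class OracleBackend:
    """Backend that reads the ground-truth slide label — an upper bound used
    to validate the surrounding pipeline arithmetic."""

    true_label: str

    def predict_proba(self, patch: np.ndarray) -> ProbVector:
        return ProbVector(p_men=1.0, p_sft=0.0) if self.true_label == "MEN" else ProbVector(
            p_men=0.0, p_sft=1.0
        )
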