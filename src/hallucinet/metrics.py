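"""Realism and input-dependence metrics for synthetic outputs.

The Inception Score is computed in its single-split form: given per-image
class distributions p(y|x_n) and their marginal p_hat(y),

    IS = exp( (1/N) * sum_n KL( p(y|x_n) || p_hat(y) ) )

with natural logarithms and 0*log0 := 0. The score lies in
[1, min(N, C)]: it is maximal when every image is classified confidently
(one-hot rows) and the rows cover distinct classes, which is exactly the
operational definition of "individually recognisable, collectively
diverse". Here the fixture classifier's softmax plays the inception
network's role; any classifier satisfying the ClassifierNetwork contract
(a `logits(images) -> (N, C)` method) can be substituted.

input_dependence is a spontaneity proxy: the Pearson correlation between
input and output pixels. Spontaneous (input-independent) synthesis drives
it toward zero; input-seeded synthesis keeps it high.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import as_batch


@dataclass
class InceptionScoreResult:
    score: float
    n: int
    c: int
    per_image_kl: np.ndarray

    def to_dict(self) -> dict:
        return {"score": self.score, "N": self.n, "C": self.c,
                "per_image_kl": [float(v) for v in self.per_image_kl]}


def _validate_probs(probs: np.ndarray) -> np.ndarray:
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2 or probs.shape[0] < 1:
        raise ValueError(f"expected (N, C) probability matrix, got {probs.shape}")
    if not np.isfinite(probs).all() or (probs < 0).any():
        raise ValueError("probabilities must be finite and non-negative")
    if np.abs(probs.sum(axis=1) - 1.0).max() > 1e-6:
        raise ValueError("probability rows must sum to 1 (within 1e-6)")
    return probs


def inception_score(probs: np.ndarray) -> InceptionScoreResult:
    """exp of the mean per-image KL(p(y|x) || marginal)."""
    probs = _validate_probs(probs)
    marginal = probs.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        logratio = np.where(probs > 0, np.log(probs / marginal), 0.0)
    per_image_kl = (probs * logratio).sum(axis=1)
    score = float(np.exp(per_image_kl.mean()))
    return InceptionScoreResult(score=score, n=probs.shape[0], c=probs.shape[1],
                                per_image_kl=per_image_kl)


def softmax_probs(classifier, images: np.ndarray) -> np.ndarray:
    """Class distributions from the classifier's categorical layer."""
    logits = classifier.logits(as_batch(images))
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def score_image_set(images: np.ndarray | list, classifier) -> InceptionScoreResult:
    """Inception Score of an image set under a classifier."""
    batch = as_batch(np.stack(list(images)) if isinstance(images, list) else images)
    return inception_score(softmax_probs(classifier, batch))


def input_dependence(input_image: np.ndarray, output_image: np.ndarray) -> float:
    """Pearson correlation of flattened pixels; 0 if either image is constant."""
    a = np.asarray(input_image, dtype=float).ravel()
    b = np.asarray(output_image, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {input_image.shape} vs {output_image.shape}")
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
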