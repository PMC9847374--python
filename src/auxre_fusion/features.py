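"""The two evidence channels fused downstream.

Channel one is a Fisher linear discriminant trained on one-hot encoded
14-mer contexts of validated AuxREs versus non-AuxREs; it yields a raw
discriminant score ``a1`` and a logistic posterior ``a2`` for the AuxRE
hypothesis.  Channel two is motif overrepresentation of the core word over
the analysed promoter set against a background Markov model; it yields a
log2 observed/expected enrichment ``b1`` and a binomial z-score ``b2``.

Overrepresentation is a property of the word shared by all its occurrences;
per-occurrence discrimination comes from the LDA on the flanked context.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit

from .motif_scan import CORE_LENGTH, count_word
from .sequence_io import UpstreamSequence

logger = logging.getLogger(__name__)

LABEL_POS = "AuxRE"
LABEL_NEG = "non-AuxRE"

CONTEXT_LENGTH = 14
_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

#: Ridge added to the shrunk pooled covariance; keeps the separable limit
#: finite without visibly perturbing well-conditioned fits.
_RIDGE = 1e-6


@dataclass(frozen=True)
class TrainingMotif:
    """A labelled 14-mer context used to train the discriminant."""

    context: str
    label: str

    def __post_init__(self) -> None:
        if len(self.context) != CONTEXT_LENGTH:
            raise ValueError(
                f"context must be {CONTEXT_LENGTH} chars, got {self.context!r}"
            )
        if self.label not in (LABEL_POS, LABEL_NEG):
            raise ValueError(f"label must be {LABEL_POS!r} or {LABEL_NEG!r}")


@dataclass(frozen=True)
class FeaturePoint:
    """The four graph-axis features of one motif occurrence."""

    a1: float  # LDA discriminant score
    a2: float  # logistic posterior for H1, in [0, 1]
    b1: float  # log2 observed/expected enrichment
    b2: float  # binomial z-score

    def __post_init__(self) -> None:
        vals = (self.a1, self.a2, self.b1, self.b2)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"non-finite feature values {vals}")
        if not 0.0 <= self.a2 <= 1.0:
            raise ValueError(f"a2 must lie in [0, 1], got {self.a2}")

    def get(self, name: str) -> float:
        return getattr(self, name)


FEATURE_NAMES = ("a1", "a2", "b1", "b2")


def one_hot(context: str) -> np.ndarray:
    """One-hot encode a 14-mer context: 4 indicators per position, 56 total.

    Case is ignored; '.' padding (and any non-ACGT character such as N)
    encodes as an all-zero column.
    """
    x = np.zeros(4 * CONTEXT_LENGTH)
    for pos, ch in enumerate(context.upper()):
        j = _BASE_INDEX.get(ch)
        if j is not None:
            x[4 * pos + j] = 1.0
    return x


@dataclass(frozen=True)
class LdaModel:
    """Fitted Fisher discriminant over one-hot context features."""

    weights: np.ndarray  # length 56
    intercept: float
    mean_pos: np.ndarray
    mean_neg: np.ndarray
    shrinkage: float

    def score(self, context: str) -> float:
        return float(self.weights @ one_hot(context) + self.intercept)


def train_lda(
    training: Sequence[TrainingMotif], shrinkage: float = 0.1
) -> LdaModel:
    """Fit Fisher's linear discriminant on labelled contexts.

    The pooled within-class covariance is shrunk toward its diagonal by
    ``shrinkage`` (plus a tiny ridge), which stabilises the 56-dimensional
    fit at small sample sizes.  The fit depends only on class sufficient
    statistics, so it is deterministic and order-independent.
    """
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must lie in [0, 1]")
    X = np.array([one_hot(t.context) for t in training])
    y = np.array([t.label == LABEL_POS for t in training])
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos < 5 or n_neg < 5:
        raise ValueError(
            f"need at least 5 examples per class, got {n_pos} AuxRE / {n_neg} non-AuxRE"
        )

    mu_pos = X[y].mean(axis=0)
    mu_neg = X[~y].mean(axis=0)
    # maximum-likelihood class covariances, so the fit is an exact function
    # of class means and second moments (duplication-invariant)
    cov_pos = np.cov(X[y], rowvar=False, bias=True)
    cov_neg = np.cov(X[~y], rowvar=False, bias=True)
    pooled = (n_pos * cov_pos + n_neg * cov_neg) / (n_pos + n_neg)
    shrunk = (1.0 - shrinkage) * pooled + shrinkage * np.diag(np.diag(pooled))
    shrunk = shrunk + _RIDGE * np.eye(shrunk.shape[0])

    try:
        w = np.linalg.solve(shrunk, mu_pos - mu_neg)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "covariance is singular after shrinkage; increase the shrinkage value"
        ) from err
    if not np.all(np.isfinite(w)):
        raise ValueError(
            "covariance is ill-conditioned; increase the shrinkage value"
        )
    intercept = float(-0.5 * w @ (mu_pos + mu_neg))
    return LdaModel(
        weights=w,
        intercept=intercept,
        mean_pos=mu_pos,
        mean_neg=mu_neg,
        shrinkage=shrinkage,
    )


def lda_features(model: LdaModel, occ) -> tuple[float, float]:
    """Discriminant score and logistic H1 posterior for an occurrence.

    ``occ`` may be a MotifOccurrence (its context is used) or a bare
    context string.  Under equal priors, ``a2 = logistic(a1)``.
    """
    context = getattr(occ, "context", occ)
    a1 = model.score(context)
    a2 = float(expit(a1))
    return a1, a2


@dataclass(frozen=True)
class MarkovBackground:
    """Background sequence model for expected word counts.

    Order 0 uses single-base frequencies; order 1 additionally conditions
    each base on its predecessor.
    """

    order: int
    base_freqs: dict[str, float]
    transition: dict[str, dict[str, float]] | None = None

    def word_prob(self, word: str) -> float:
        p = self.base_freqs[word[0]]
        for prev, cur in zip(word, word[1:]):
            if self.order == 0:
                p *= self.base_freqs[cur]
            else:
                p *= self.transition[prev][cur]
        return p


def estimate_background(
    promoters: Sequence[UpstreamSequence], order: int = 0
) -> MarkovBackground:
    """Estimate a Markov background (order 0 or 1) from the promoters.

    Pseudocount 1 per base/transition keeps the composition strictly
    positive; N bases are excluded from the counts.
    """
    if order not in (0, 1):
        raise ValueError("background order must be 0 or 1")
    if not promoters:
        raise ValueError("cannot estimate background from an empty promoter list")
    counts = {b: 1.0 for b in _BASES}
    trans = {a: {b: 1.0 for b in _BASES} for a in _BASES}
    for rec in promoters:
        for ch in rec.seq:
            if ch in counts:
                counts[ch] += 1.0
        for prev, cur in zip(rec.seq, rec.seq[1:]):
            if prev in trans and cur in trans:
                trans[prev][cur] += 1.0
    total = sum(counts.values())
    base_freqs = {b: c / total for b, c in counts.items()}
    transition = None
    if order == 1:
        transition = {
            a: {b: c / sum(row.values()) for b, c in row.items()}
            for a, row in trans.items()
        }
    return MarkovBackground(order=order, base_freqs=base_freqs, transition=transition)


def overrepresentation(
    word: str,
    promoters: Sequence[UpstreamSequence],
    background: MarkovBackground,
) -> tuple[float, float]:
    """Enrichment of a hexamer word over the promoter set.

    obs is the total forward-strand overlapping count; exp sums
    ``(length - 5) * p(word)`` over promoters.  ``b1`` is the
    pseudocounted log2 ratio, ``b2`` the normal approximation to the
    binomial z-score.
    """
    if not promoters:
        raise ValueError("empty promoter list")
    p = background.word_prob(word)
    obs = sum(count_word(rec, word) for rec in promoters)
    exp = sum((rec.length - (CORE_LENGTH - 1)) * p for rec in promoters)
    b1 = float(np.log2((obs + 0.5) / (exp + 0.5)))
    b2 = float((obs - exp) / np.sqrt(exp * (1.0 - p)))
    return b1, b2


def compute_features(
    model: LdaModel,
    core: str,
    context: str,
    promoters: Sequence[UpstreamSequence],
    background: MarkovBackground,
    word_cache: dict[str, tuple[float, float]] | None = None,
) -> FeaturePoint:
    """Assemble the four-axis feature point for one candidate motif."""
    a1, a2 = lda_features(model, context)
    if word_cache is not None and core in word_cache:
        b1, b2 = word_cache[core]
    else:
        b1, b2 = overrepresentation(core, promoters, background)
        if word_cache is not None:
            word_cache[core] = (b1, b2)
    return FeaturePoint(a1=a1, a2=a2, b1=b1, b2=b2)
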