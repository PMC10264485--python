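"""Count-based language models and per-token surprisal.

Surprisal of a token is the negative log probability the model assigns it
given the preceding sentence context:

    Surprisal(w_t) = -log P(w_t | w_1 ... w_{t-1})

An n-gram model conditions on the previous ``order - 1`` tokens.  Two
smoothers are offered: add-k, and interpolated absolute discounting
(Kneser-Ney style recursion down to a uniform base distribution).  Both
yield strictly positive probabilities over the vocabulary plus the
end-of-sentence marker, so surprisal is always finite and non-negative.
"""

from __future__ import annotations

import math
import string
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "BOS",
    "EOS",
    "UNK",
    "tokenize",
    "read_corpus",
    "TokenSurprisal",
    "NgramLanguageModel",
    "train_ngram",
    "sentence_surprisal",
    "surprisal_table",
]

BOS = "<s>"
EOS = "</s>"
UNK = "<unk>"

_PUNCT_TABLE = str.maketrans("", "", string.punctuation)


def tokenize(text: str) -> list[str]:
    """Lowercase, strip ASCII punctuation, split on whitespace."""
    return [
        tok
        for tok in text.lower().translate(_PUNCT_TABLE).split()
        if tok
    ]


def read_corpus(path) -> list[list[str]]:
    """Read a one-sentence-per-line UTF-8 corpus into token lists."""
    sentences = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            toks = tokenize(line)
            if toks:
                sentences.append(toks)
    return sentences


@dataclass(frozen=True)
class TokenSurprisal:
    """Probability and surprisal of one token in sentence context."""

    sentence_id: int
    position: int  # 1-based
    word: str
    probability: float
    surprisal: float


class NgramLanguageModel(BaseEstimator):
    """Trainable n-gram language model producing per-token surprisal.

    Parameters
    ----------
    order : int
        Model order; 1 is a unigram model. Contexts are padded with
        ``order - 1`` begin markers and every sentence contributes one
        end-marker event.
    smoothing : {"add_k", "absolute_discounting"}
        ``add_k`` adds ``k`` pseudo-counts to every outcome.
        ``absolute_discounting`` subtracts ``discount`` from observed
        counts and interpolates recursively with lower orders, bottoming
        out in a uniform distribution.
    k : float
        Pseudo-count for add-k smoothing.
    discount : float
        Discount in (0, 1) for absolute discounting.
    log_base : {"e", "2"}
        Natural log (nats) or base 2 (bits).
    hapax_unk : bool
        If True, training tokens occurring exactly once are replaced by the
        unknown marker, giving the unknown type real probability mass.
    """

    def __init__(
        self,
        order: int = 3,
        smoothing: str = "add_k",
        k: float = 1.0,
        discount: float = 0.75,
        log_base: str = "e",
        hapax_unk: bool = True,
    ):
        self.order = order
        self.smoothing = smoothing
        self.k = k
        self.discount = discount
        self.log_base = log_base
        self.hapax_unk = hapax_unk

    # -- training ----------------------------------------------------------

    def fit(self, X: Iterable[Sequence[str]], y=None) -> "NgramLanguageModel":
        """Count padded n-grams over an iterable of token lists."""
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.smoothing not in ("add_k", "absolute_discounting"):
            raise ValueError(f"unknown smoothing {self.smoothing!r}")
        if self.log_base not in ("e", "2"):
            raise ValueError(f"unknown log base {self.log_base!r}")
        sentences = [list(s) for s in X]
        if not sentences:
            raise ValueError("corpus is empty")

        totals = Counter(tok for s in sentences for tok in s)
        if self.hapax_unk:
            vocab = {w for w, c in totals.items() if c > 1}
        else:
            vocab = set(totals)
        self.vocabulary_ = vocab | {UNK}
        # Outcome space: vocabulary plus the end marker.  A pure unigram
        # model has no notion of sentence termination, so the end marker
        # only participates for order >= 2.
        self._count_eos = self.order >= 2
        self.n_outcomes_ = len(self.vocabulary_) + (1 if self._count_eos else 0)

        # counts_[n] maps a length-(n-1) context tuple to a Counter of
        # next tokens; kept for every order <= self.order so absolute
        # discounting can interpolate downward.
        self.counts_: list[dict[tuple, Counter]] = [
            defaultdict(Counter) for _ in range(self.order + 1)
        ]
        for s in sentences:
            toks = [t if t in vocab else UNK for t in s]
            padded = [BOS] * (self.order - 1) + toks
            if self._count_eos:
                padded = padded + [EOS]
            for i in range(self.order - 1, len(padded)):
                w = padded[i]
                for n in range(1, self.order + 1):
                    ctx = tuple(padded[i - (n - 1) : i])
                    self.counts_[n][ctx][w] += 1
        self.context_totals_: list[dict[tuple, int]] = [
            {ctx: sum(c.values()) for ctx, c in level.items()}
            for level in self.counts_
        ]
        return self

    # -- probabilities -----------------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "counts_"):
            raise RuntimeError("model is not fitted")

    def _map_token(self, tok: str) -> str:
        return tok if tok in self.vocabulary_ or tok == EOS else UNK

    def probability(self, word: str, context: Sequence[str]) -> float:
        """P(word | context) under the configured smoother.

        ``context`` is the preceding token sequence (may be shorter than
        ``order - 1``; it is padded with begin markers).  Out-of-vocabulary
        tokens map to the unknown marker.
        """
        self._check_fitted()
        w = self._map_token(word)
        ctx = [BOS] * max(0, self.order - 1 - len(context)) + [
            self._map_token(t) for t in context
        ]
        ctx_tuple = tuple(ctx[len(ctx) - (self.order - 1) :])
        if self.smoothing == "add_k":
            return self._prob_add_k(w, ctx_tuple)
        return self._prob_abs_discount(w, ctx_tuple, self.order)

    def _prob_add_k(self, w: str, ctx: tuple) -> float:
        c = self.counts_[self.order].get(ctx, None)
        num = (c[w] if c is not None else 0) + self.k
        den = self.context_totals_[self.order].get(ctx, 0) + (
            self.k * self.n_outcomes_
        )
        if den == 0:
            raise ValueError(
                "zero-count context with k = 0; use k > 0 for unseen contexts"
            )
        return num / den

    def _prob_abs_discount(self, w: str, ctx: tuple, n: int) -> float:
        if n == 0:
            return 1.0 / self.n_outcomes_
        level = self.counts_[n]
        total = self.context_totals_[n].get(ctx, 0)
        lower = self._prob_abs_discount(w, ctx[1:] if ctx else (), n - 1)
        if total == 0:
            return lower
        counter = level[ctx]
        c = counter.get(w, 0)
        d = self.discount
        backoff_mass = d * len(counter) / total
        return max(c - d, 0.0) / total + backoff_mass * lower

    def context_distribution(self, context: Sequence[str]) -> dict[str, float]:
        """Full smoothed next-token distribution (vocabulary + end marker)."""
        self._check_fitted()
        outcomes = sorted(self.vocabulary_) + ([EOS] if self._count_eos else [])
        return {w: self.probability(w, context) for w in outcomes}

    # -- surprisal ---------------------------------------------------------

    def _log(self, p: float) -> float:
        return -math.log2(p) if self.log_base == "2" else -math.log(p)

    def sentence_surprisal(
        self, sentence: Sequence[str], sentence_id: int = 0
    ) -> list[TokenSurprisal]:
        """One surprisal record per token, in order (markers excluded)."""
        self._check_fitted()
        if not sentence:
            raise ValueError("sentence is empty")
        out = []
        for i, word in enumerate(sentence):
            p = self.probability(word, sentence[:i])
            out.append(
                TokenSurprisal(
                    sentence_id=sentence_id,
                    position=i + 1,
                    word=word.lower(),
                    probability=p,
                    surprisal=self._log(p),
                )
            )
        return out

    def surprisal_table(
        self, corpus: Iterable[Sequence[str]]
    ) -> pd.DataFrame:
        """Surprisal records for a whole corpus as a tidy table."""
        rows = []
        for sid, sentence in enumerate(corpus):
            rows.extend(self.sentence_surprisal(sentence, sentence_id=sid))
        return pd.DataFrame(
            [r.__dict__ for r in rows],
            columns=["sentence_id", "position", "word", "probability", "surprisal"],
        )


def train_ngram(
    corpus: Iterable[Sequence[str]],
    order: int = 3,
    smoothing: str = "add_k",
    **kwargs,
) -> NgramLanguageModel:
    """Thin functional wrapper over :class:`NgramLanguageModel`."""
    return NgramLanguageModel(order=order, smoothing=smoothing, **kwargs).fit(
        corpus
    )


def sentence_surprisal(
    model: NgramLanguageModel, sentence: Sequence[str], sentence_id: int = 0
) -> list[TokenSurprisal]:
    return model.sentence_surprisal(sentence, sentence_id=sentence_id)


def surprisal_table(
    model: NgramLanguageModel, corpus: Iterable[Sequence[str]]
) -> pd.DataFrame:
    return model.surprisal_table(corpus)
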