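"""Orthography-Semantics Consistency (OSC) scoring.

OSC quantifies how reliably a word's written form points to its meaning.  For
a target word *t* with orthographic relatives r_1 ... r_k — every lexicon word
that contains *t* as a contiguous substring, including *t* itself —

    OSC(t) = sum_x f_rx * cos(t, r_x) / sum_x f_rx

i.e. the frequency-weighted mean cosine similarity between the target's
embedding and its relatives' embeddings.  A word whose only relative is
itself (or whose relatives are all collinear with it) scores exactly 1;
such rows are flagged degenerate because downstream analyses exclude them.

Raw frequency counts are used as weights (no log transform).  If every
relative has zero frequency the unweighted mean of cosines is returned and
the row is flagged, avoiding a 0/0 while preserving the defining formula's
limit behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .lexicon import Lexicon, LexiconEntry

__all__ = [
    "DegenerateEmbeddingError",
    "TargetNotInLexiconError",
    "cosine_similarity",
    "extract_relatives",
    "OscResult",
    "compute_osc",
    "compute_osc_table",
    "OscScorer",
    "write_osc_table",
]

#: |osc - 1| below this counts as "OSC equal to 1" for the degenerate flag.
DEGENERATE_TOL = 1e-9


class DegenerateEmbeddingError(ValueError):
    """A zero-norm embedding entered a cosine computation."""


class TargetNotInLexiconError(KeyError):
    """The requested target word is not a lexicon entry."""


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two non-zero vectors of equal dimension."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateEmbeddingError("degenerate embedding: zero norm")
    return float(np.dot(u, v) / (nu * nv))


def extract_relatives(target: str, lexicon: Lexicon) -> list[LexiconEntry]:
    """All lexicon entries containing ``target`` as a contiguous substring.

    The match is position-free (prefix, infix or suffix) and includes the
    target's own entry.  Results are lexicographically ordered.
    """
    target = target.lower()
    if target not in lexicon:
        raise TargetNotInLexiconError(f"target not in lexicon: {target!r}")
    return [lexicon[w] for w in lexicon.words if target in w]


@dataclass
class OscResult:
    """OSC for one target: the relatives behind it and the score itself."""

    target: str
    relatives: list[tuple[str, float, float]] = field(default_factory=list)
    osc: float = float("nan")
    degenerate_flag: bool = False
    missing_flag: bool = False
    zero_frequency_fallback: bool = False

    @property
    def n_relatives(self) -> int:
        return len(self.relatives)


def compute_osc(
    target: str,
    lexicon: Lexicon,
    degenerate_tol: float = DEGENERATE_TOL,
) -> OscResult:
    """Frequency-weighted mean cosine between a target and its relatives.

    Relatives lacking an embedding are skipped (they cannot contribute a
    cosine).  If the target itself lacks an embedding the result carries
    ``missing_flag`` and an NaN score.
    """
    target = target.lower()
    entry = lexicon[target] if target in lexicon else None
    if entry is None:
        raise TargetNotInLexiconError(f"target not in lexicon: {target!r}")
    if entry.vector is None or np.linalg.norm(entry.vector) == 0.0:
        return OscResult(target=target, missing_flag=True)

    triples: list[tuple[str, float, float]] = []
    for rel in extract_relatives(target, lexicon):
        if rel.vector is None:
            continue
        cos = cosine_similarity(entry.vector, rel.vector)
        triples.append((rel.word, rel.frequency, cos))

    weights = np.array([f for _, f, _ in triples])
    cosines = np.array([c for _, _, c in triples])
    total = weights.sum()
    if total > 0:
        osc = float(np.dot(weights, cosines) / total)
        fallback = False
    else:  # every relative (incl. target) has zero frequency
        osc = float(cosines.mean())
        fallback = True
    return OscResult(
        target=target,
        relatives=triples,
        osc=osc,
        degenerate_flag=abs(osc - 1.0) < degenerate_tol,
        zero_frequency_fallback=fallback,
    )


def compute_osc_table(
    lexicon: Lexicon,
    targets: list[str] | None = None,
    degenerate_tol: float = DEGENERATE_TOL,
) -> pd.DataFrame:
    """OSC for every requested target (default: the whole lexicon).

    Rows are flagged (missing / degenerate / zero-frequency fallback), never
    silently dropped.  An empty target list yields an empty table.
    """
    if len(lexicon) == 0:
        raise ValueError("lexicon is empty")
    if targets is None:
        targets = lexicon.words
    rows = []
    for t in targets:
        r = compute_osc(t, lexicon, degenerate_tol=degenerate_tol)
        rows.append(
            {
                "word": r.target,
                "osc": r.osc,
                "n_relatives": r.n_relatives,
                "degenerate_flag": r.degenerate_flag,
                "missing_flag": r.missing_flag,
                "zero_frequency_fallback": r.zero_frequency_fallback,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "word",
            "osc",
            "n_relatives",
            "degenerate_flag",
            "missing_flag",
            "zero_frequency_fallback",
        ],
    )


def write_osc_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


class OscScorer(BaseEstimator, TransformerMixin):
    """Scikit-learn style wrapper around OSC scoring.

    ``fit`` takes a :class:`~lexread.lexicon.Lexicon`; ``transform`` maps a
    sequence of word strings to their OSC scores (NaN where the score is
    missing).  ``score_table`` returns the full flagged table.

    Parameters
    ----------
    degenerate_tol : float
        Tolerance within which a score counts as exactly 1.
    """

    def __init__(self, degenerate_tol: float = DEGENERATE_TOL):
        self.degenerate_tol = degenerate_tol

    def fit(self, X: Lexicon, y=None) -> "OscScorer":
        if not isinstance(X, Lexicon):
            raise TypeError("OscScorer.fit expects a Lexicon")
        if len(X) == 0:
            raise ValueError("lexicon is empty")
        self.lexicon_ = X
        self.n_words_ = len(X)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "lexicon_"):
            raise RuntimeError("OscScorer is not fitted")
        out = np.empty(len(X), dtype=float)
        for i, w in enumerate(X):
            out[i] = compute_osc(
                w, self.lexicon_, degenerate_tol=self.degenerate_tol
            ).osc
        return out

    def score_table(self, targets: list[str] | None = None) -> pd.DataFrame:
        if not hasattr(self, "lexicon_"):
            raise RuntimeError("OscScorer is not fitted")
        return compute_osc_table(
            self.lexicon_, targets, degenerate_tol=self.degenerate_tol
        )
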