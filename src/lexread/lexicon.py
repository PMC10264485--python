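"""Lexicon container: word forms, corpus frequencies, semantic embeddings.

The lexicon is the substrate for orthography-semantics consistency scoring:
every entry carries an orthographic form, a non-negative corpus frequency and
(optionally) a real-valued embedding vector.  All forms are lowercased on
entry; embeddings within one lexicon share a single dimension.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "LexiconEntry",
    "Lexicon",
    "read_word2vec_text",
    "read_frequency_table",
    "build_lexicon",
]


@dataclass(frozen=True)
class LexiconEntry:
    """One lexicon row: orthographic form, frequency, embedding (or None)."""

    word: str
    frequency: float
    vector: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.word:
            raise ValueError("lexicon entry word must be non-empty")
        if self.frequency < 0:
            raise ValueError(f"negative frequency for {self.word!r}")


class Lexicon:
    """Ordered, case-normalised collection of :class:`LexiconEntry`.

    Words are lowercased; duplicate forms are rejected.  Entries may lack an
    embedding (``vector is None``), in which case downstream consistency
    scores for them are flagged as missing rather than silently dropped.
    """

    def __init__(self, entries: Iterable[LexiconEntry]):
        self._entries: dict[str, LexiconEntry] = {}
        dim: int | None = None
        for e in entries:
            w = e.word.lower()
            if w in self._entries:
                raise ValueError(f"duplicate lexicon word {w!r}")
            vec = e.vector
            if vec is not None:
                vec = np.asarray(vec, dtype=float)
                if vec.ndim != 1:
                    raise ValueError(f"embedding for {w!r} is not a vector")
                if dim is None:
                    dim = vec.size
                elif vec.size != dim:
                    raise ValueError(
                        f"embedding dimension mismatch for {w!r}: "
                        f"{vec.size} != {dim}"
                    )
            self._entries[w] = LexiconEntry(w, float(e.frequency), vec)
        self._dim = dim
        self._words = sorted(self._entries)

    @classmethod
    def from_arrays(
        cls,
        words: Iterable[str],
        frequencies: Iterable[float],
        vectors: np.ndarray | None = None,
    ) -> "Lexicon":
        words = list(words)
        freqs = list(frequencies)
        if len(words) != len(freqs):
            raise ValueError("words and frequencies differ in length")
        if vectors is None:
            vecs: list[np.ndarray | None] = [None] * len(words)
        else:
            vectors = np.asarray(vectors, dtype=float)
            if vectors.shape[0] != len(words):
                raise ValueError("vectors and words differ in length")
            vecs = list(vectors)
        return cls(
            LexiconEntry(w, f, v) for w, f, v in zip(words, freqs, vecs)
        )

    @property
    def dim(self) -> int | None:
        """Embedding dimension (None if no entry has a vector)."""
        return self._dim

    @property
    def words(self) -> list[str]:
        """All forms, lexicographically sorted."""
        return list(self._words)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, word: str) -> bool:
        return word.lower() in self._entries

    def __getitem__(self, word: str) -> LexiconEntry:
        return self._entries[word.lower()]

    def __iter__(self) -> Iterator[LexiconEntry]:
        for w in self._words:
            yield self._entries[w]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "word": self._words,
                "frequency": [self._entries[w].frequency for w in self._words],
                "has_vector": [
                    self._entries[w].vector is not None for w in self._words
                ],
            }
        )


def read_word2vec_text(path: str | Path) -> dict[str, np.ndarray]:
    """Read embeddings in word2vec text format.

    First line is ``"<n_words> <dim>"``; each following line is
    ``"word v1 ... vdim"`` (space separated).  Words are lowercased; on
    case collisions the first occurrence wins.
    """
    path = Path(path)
    vectors: dict[str, np.ndarray] = {}
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: malformed word2vec header {header!r}")
        n_words, dim = int(header[0]), int(header[1])
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise ValueError(
                    f"{path}:{lineno}: expected {dim + 1} fields, "
                    f"got {len(parts)}"
                )
            word = parts[0].lower()
            vectors.setdefault(word, np.array(parts[1:], dtype=float))
    if len(vectors) not in (n_words, 0) and len(vectors) > n_words:
        raise ValueError(f"{path}: more vectors than declared in header")
    return vectors


def read_frequency_table(
    path: str | Path, sep: str = "\t", header: bool = False
) -> dict[str, float]:
    """Read a two-column word/count table (TSV by default)."""
    df = pd.read_csv(
        path,
        sep=sep,
        header=0 if header else None,
        names=None if header else ["word", "count"],
        dtype={0: str},
    )
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns")
    words = df.iloc[:, 0].astype(str).str.lower()
    counts = pd.to_numeric(df.iloc[:, 1])
    if (counts < 0).any():
        raise ValueError(f"{path}: negative frequencies")
    out: dict[str, float] = {}
    for w, c in zip(words, counts):
        out[w] = out.get(w, 0.0) + float(c)
    return out


def build_lexicon(
    vectors: Mapping[str, np.ndarray],
    frequencies: Mapping[str, float],
    default_frequency: float = 0.0,
) -> Lexicon:
    """Assemble a lexicon from an embedding table and a frequency table.

    The word list is the embedding vocabulary (a word without a vector cannot
    enter similarity computations); words absent from the frequency table get
    ``default_frequency``.
    """
    entries = [
        LexiconEntry(w, frequencies.get(w.lower(), default_frequency), v)
        for w, v in vectors.items()
    ]
    return Lexicon(entries)
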