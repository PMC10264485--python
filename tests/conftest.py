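import numpy as np
import pytest

from lexread.lexicon import Lexicon, LexiconEntry


@pytest.fixture
def cup_lexicon():
    """Lexicon for relative-extraction checks (prefix family around 'cup')."""
    d = np.array([1.0, 0.0, 0.0])
    return Lexicon(
        LexiconEntry(w, 10.0, d)
        for w in ["cup", "cupboard", "cupid", "cut", "cap"]
    )


def random_lexicon(rng, n_words=30, dim=10, allow_missing=False):
    """Random lexicon with realistic substring overlap between words."""
    letters = list("abcdef")  # small alphabet so substrings do occur
    words = set()
    while len(words) < n_words:
        L = int(rng.integers(2, 7))
        words.add("".join(rng.choice(letters, size=L)))
    words = sorted(words)
    freqs = rng.integers(0, 1000, size=len(words)).astype(float)
    vectors = [rng.normal(size=dim) for _ in words]
    if allow_missing:
        drop = rng.choice(len(words), size=max(1, len(words) // 10), replace=False)
        for i in drop:
            vectors[i] = None
    entries = [
        LexiconEntry(w, f, v) for w, f, v in zip(words, freqs, vectors)
    ]
    return Lexicon(entries), words, dict(zip(words, freqs)), dict(zip(words, vectors))


@pytest.fixture
def lexicon_factory():
    return random_lexicon


def spr_records(seed, n_subjects=10, n_sentences=30, surface_form="linear",
                **config_kwargs):
    """Assembled modelling records from a synthetic self-paced reading run."""
    from lexread.assembly import apply_exclusions
    from lexread.synthetic import (
        SyntheticConfig,
        make_corpus,
        make_lexicon,
        make_spr_dataset,
        modelling_records,
    )

    cfg = SyntheticConfig(
        seed=seed, n_subjects=n_subjects, n_sentences=n_sentences,
        surface_form=surface_form, beta_intercept=5.63,
        beta_surprisal=-0.003, **config_kwargs,
    )
    rng = np.random.default_rng(cfg.seed)
    lex, truth = make_lexicon(cfg, rng)
    sents, truth = make_corpus(cfg, truth, rng)
    _, truth = make_spr_dataset(cfg, (lex, truth), (sents, truth), rng)
    rec, _ = apply_exclusions(modelling_records(truth), mode="spr")
    return rec, truth, cfg


@pytest.fixture
def spr_records_factory():
    return spr_records
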