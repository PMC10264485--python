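"""Synthetic lexicons, corpora and reading-behaviour datasets.

Every pipeline stage is testable without external resources: the generator
emits (a) a lexicon of morphological-looking families — a stem plus suffixed
members sharing a semantic core vector to a controllable degree — giving
consistency scores spread over ~0-1 with an atom at exactly 1 (single-member
families); (b) a Markov-chain corpus whose true per-token surprisal is known
from the generating transition probabilities; and (c) eye-tracking fixation
streams or self-paced reading times whose log durations follow a planted
additive model with a configurable interaction surface between consistency
and surprisal, per-subject and per-word normal random effects, and lognormal
residual noise.

Fixation streams include refixations (a word's gaze split into two
fixations), regressions (a look back to an earlier word followed by a return
fixation, so right-bounded and go-past times exceed gaze) and skips.  The
measures module applied to a generated stream recovers the intended gaze
durations exactly.

All randomness flows through one integer seed; regeneration is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lexicon import Lexicon, LexiconEntry

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "make_lexicon",
    "make_corpus",
    "make_markov_corpus",
    "make_eyetracking_dataset",
    "make_spr_dataset",
    "modelling_records",
]

_STEM_ALPHABET = "abcdefghijklm"
_SUFFIX_ALPHABET = "nopqrstuvwxyz"


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic datasets.

    Defaults emulate the structure of a sentence-reading study: a few dozen
    subjects reading independent single-line sentences, log reading times
    near exp(5.4) ~ 220 ms with residual SD 0.25 on the log scale, subject
    and word intercept SDs of 0.10 and 0.05, and an interaction surface
    between consistency (osc, ~0-1) and surprisal (nats, roughly 0-12 under
    the sparse-transition chain).  The planted bilinear coefficients are of
    the order of magnitude conventional for log-ms reading-time regressions
    (e.g. an interaction of 0.006).  The "dip" surface is a negative
    Gaussian bump on log duration centred at mid-range consistency and
    mid-range surprisal — faster reading where both are unremarkable.
    """

    seed: int = 0
    # lexicon
    n_families: int = 150
    family_size_min: int = 1
    family_size_max: int = 8
    coherence: float | None = None  # None: per-family U(0, 1)
    embedding_dim: int = 50
    stem_length_min: int = 3
    stem_length_max: int = 6
    suffix_length: int = 3
    zipf_exponent: float = 1.1
    max_frequency: float = 200_000.0
    # corpus
    n_sentences: int = 40
    sentence_length_min: int = 6
    sentence_length_max: int = 12
    dirichlet_alpha: float = 0.1
    # reading behaviour
    n_subjects: int = 40
    subject_sd: float = 0.10
    word_sd: float = 0.05
    residual_sd: float = 0.25
    beta_intercept: float = 5.36
    beta_length: float = 0.006
    beta_log_frequency: float = -0.01
    beta_position: float = -0.007
    surface_form: str = "dip"  # "linear" | "dip"
    beta_osc: float = -0.039
    beta_surprisal: float = 0.03
    beta_interaction: float = 0.006
    dip_amplitude: float = -0.15
    dip_center_osc: float = 0.4
    dip_center_surprisal: float | None = None  # None: median true surprisal
    dip_width_osc: float = 0.15
    dip_width_surprisal: float = 1.5
    # fixation stream shape
    p_skip: float = 0.10
    p_refixation: float = 0.30
    p_regression: float = 0.15
    regression_log_mean: float = 5.0
    regression_log_sd: float = 0.3

    def __post_init__(self) -> None:
        for name in ("subject_sd", "word_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.coherence is not None and not 0.0 <= self.coherence <= 1.0:
            raise ValueError("coherence must lie in [0, 1]")
        if self.surface_form not in ("linear", "dip"):
            raise ValueError(f"unknown surface form {self.surface_form!r}")
        for p in ("p_skip", "p_refixation", "p_regression"):
            if not 0.0 <= getattr(self, p) <= 1.0:
                raise ValueError(f"{p} must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Everything the generator knows that downstream stages must recover."""

    config: SyntheticConfig
    lexicon_truth: pd.DataFrame | None = None  # word, family, is_stem, freq, osc
    token_truth: pd.DataFrame | None = None  # sentence_id, position, word, surprisal
    transition_matrix: np.ndarray | None = None
    start_distribution: np.ndarray | None = None
    states: list[str] = field(default_factory=list)
    subject_effects: dict = field(default_factory=dict)
    word_effects: dict = field(default_factory=dict)
    records: pd.DataFrame | None = None  # per-token covariates + intended DV
    surface_center_surprisal: float | None = None

    def surface(self, osc: np.ndarray, surprisal: np.ndarray) -> np.ndarray:
        """True interaction-surface contribution to log duration."""
        cfg = self.config
        osc = np.asarray(osc, dtype=float)
        surprisal = np.asarray(surprisal, dtype=float)
        if cfg.surface_form == "linear":
            return (
                cfg.beta_osc * osc
                + cfg.beta_surprisal * surprisal
                + cfg.beta_interaction * osc * surprisal
            )
        c_s = self.surface_center_surprisal
        if c_s is None:
            raise ValueError("surface centre undefined; generate a corpus first")
        bump = cfg.dip_amplitude * np.exp(
            -(
                (osc - cfg.dip_center_osc) ** 2 / (2 * cfg.dip_width_osc**2)
                + (surprisal - c_s) ** 2 / (2 * cfg.dip_width_surprisal**2)
            )
        )
        return cfg.beta_surprisal * surprisal + bump


# ---------------------------------------------------------------------------
# lexicon


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _distinct_strings(
    rng: np.random.Generator, n: int, length: int, alphabet: str
) -> list[str]:
    if n > len(alphabet) ** length * 0.5:
        raise ValueError(
            f"cannot draw {n} collision-free strings of length {length} "
            f"over {len(alphabet)} letters; increase the length"
        )
    seen: set[str] = set()
    letters = list(alphabet)
    while len(seen) < n:
        seen.add("".join(rng.choice(letters, size=length)))
    return sorted(seen)


def _substring_free_stems(
    rng: np.random.Generator, n: int, len_min: int, len_max: int, alphabet: str
) -> list[str]:
    """Distinct stems of varying length, none a substring of another.

    Stems use one alphabet half and suffixes the other, so the substring-free
    property over stems extends to the full lexicon (no stem can reappear
    inside another family's suffixed members).
    """
    capacity = sum(len(alphabet) ** L for L in range(len_min, len_max + 1))
    if n > capacity * 0.25:
        raise ValueError(
            f"cannot draw {n} substring-free stems with lengths "
            f"{len_min}-{len_max} over {len(alphabet)} letters"
        )
    letters = list(alphabet)
    stems: list[str] = []
    attempts = 0
    while len(stems) < n:
        attempts += 1
        if attempts > 200 * n:
            raise ValueError("stem sampling failed; widen the length range")
        L = int(rng.integers(len_min, len_max + 1))
        cand = "".join(rng.choice(letters, size=L))
        if any(cand in s or s in cand for s in stems):
            continue
        stems.append(cand)
    return stems


def make_lexicon(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[Lexicon, GroundTruth]:
    """Generate a family-structured lexicon with known consistency scores.

    Each family is a stem (drawn over one alphabet half) plus suffixed
    members (suffixes over the other half), so no stem can occur inside
    another family's words.  Member embeddings are
    ``alpha * core + sqrt(1 - alpha^2) * noise`` (unit-normalised); at
    coherence 1 every stem scores exactly 1, at coherence 0 a stem's
    expected score is its own frequency share.  Frequencies follow a
    Zipf-like law over a random ranking of all word forms.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    stems = _substring_free_stems(
        rng,
        config.n_families,
        config.stem_length_min,
        config.stem_length_max,
        _STEM_ALPHABET,
    )
    d = config.embedding_dim

    words: list[str] = []
    families: list[int] = []
    is_stem: list[bool] = []
    coherences: list[float] = []
    vectors: list[np.ndarray] = []
    for fam, stem in enumerate(stems):
        size = int(
            rng.integers(config.family_size_min, config.family_size_max + 1)
        )
        alpha = (
            config.coherence
            if config.coherence is not None
            else float(rng.uniform())
        )
        core = _unit(rng.normal(size=d))
        n_suffix = max(size - 1, 0)
        suffixes = _distinct_strings(
            rng, max(n_suffix, 1), config.suffix_length, _SUFFIX_ALPHABET
        )[:n_suffix]
        members = [stem] + [stem + s for s in suffixes]
        for w in members:
            noise = rng.normal(size=d)
            noise -= noise @ core * core  # orthogonal to the family core
            vec = alpha * core + np.sqrt(max(1.0 - alpha**2, 0.0)) * _unit(noise)
            vectors.append(_unit(vec))
            words.append(w)
            families.append(fam)
            is_stem.append(w == stem)
            coherences.append(alpha)

    # Zipf-like frequencies over a random ranking of all forms
    ranks = rng.permutation(len(words)) + 1
    freqs = np.maximum(
        np.floor(config.max_frequency / ranks.astype(float) ** config.zipf_exponent),
        1.0,
    )

    lex = Lexicon(
        LexiconEntry(w, f, v) for w, f, v in zip(words, freqs, vectors)
    )

    # ground-truth consistency by direct evaluation of the defining formula
    vec_by_word = dict(zip(words, vectors))
    freq_by_word = dict(zip(words, freqs))
    osc_truth = []
    for t in words:
        num = den = 0.0
        tv = vec_by_word[t]
        for w in words:
            if t in w:
                c = float(tv @ vec_by_word[w])
                num += freq_by_word[w] * c
                den += freq_by_word[w]
        osc_truth.append(num / den)

    truth = GroundTruth(
        config=config,
        lexicon_truth=pd.DataFrame(
            {
                "word": words,
                "family": families,
                "is_stem": is_stem,
                "coherence": coherences,
                "frequency": freqs,
                "osc": osc_truth,
            }
        ),
    )
    return lex, truth


# ---------------------------------------------------------------------------
# corpora


def make_markov_corpus(
    n_states: int,
    target_tokens: int,
    alpha: float = 2.0,
    end_probability: float = 0.1,
    seed: int = 0,
    max_length: int = 80,
    states: list[str] | None = None,
) -> tuple[list[list[str]], pd.DataFrame, np.ndarray, np.ndarray]:
    """Corpus from a first-order chain with an explicit sentence-end event.

    Rows of the transition matrix cover the states plus an end column, so a
    trained n-gram model's end-of-sentence mass is part of the ground truth
    and estimated continuation probabilities are consistent with the stored
    true surprisals.  Returns (sentences, per-token truth, transitions
    including the end column, start distribution).
    """
    rng = np.random.default_rng(seed)
    if states is None:
        states = [f"w{i:02d}" for i in range(n_states)]
    K = len(states)
    T = rng.dirichlet(np.full(K, alpha), size=K) * (1.0 - end_probability)
    T = np.hstack([T, np.full((K, 1), end_probability)])
    pi = rng.dirichlet(np.full(K, alpha))

    sentences: list[list[str]] = []
    rows = []
    total = 0
    sid = 0
    while total < target_tokens:
        toks: list[str] = []
        cur = int(rng.choice(K, p=pi))
        toks.append(states[cur])
        rows.append((sid, 1, states[cur], -np.log(pi[cur])))
        while len(toks) < max_length:
            nxt = int(rng.choice(K + 1, p=T[cur]))
            if nxt == K:
                break
            toks.append(states[nxt])
            rows.append((sid, len(toks), states[nxt], -np.log(T[cur, nxt])))
            cur = nxt
        sentences.append(toks)
        total += len(toks)
        sid += 1
    truth = pd.DataFrame(
        rows, columns=["sentence_id", "position", "word", "surprisal"]
    )
    return sentences, truth, T, pi


def make_corpus(
    config: SyntheticConfig,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> tuple[list[list[str]], GroundTruth]:
    """Sentences over the lexicon's stem words from a sparse Markov chain.

    Sentence lengths are uniform on the configured range; true surprisal of
    each token is the negative log of its generating transition probability
    (start-distribution probability for sentence-initial tokens).  Sparse
    Dirichlet rows give the per-token surprisals a wide spread (roughly
    0-12 nats at the defaults).
    """
    if truth.lexicon_truth is None:
        raise ValueError("generate a lexicon first")
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    stems = truth.lexicon_truth.loc[
        truth.lexicon_truth["is_stem"], "word"
    ].tolist()
    K = len(stems)
    T = rng.dirichlet(np.full(K, config.dirichlet_alpha), size=K)
    if np.any(T.sum(axis=1) <= 0):  # pragma: no cover
        raise ValueError("degenerate transition row")
    pi = rng.dirichlet(np.full(K, max(config.dirichlet_alpha * 5, 0.5)))

    sentences: list[list[str]] = []
    rows = []
    for sid in range(config.n_sentences):
        length = int(
            rng.integers(config.sentence_length_min, config.sentence_length_max + 1)
        )
        cur = int(rng.choice(K, p=pi))
        toks = [stems[cur]]
        rows.append((sid, 1, stems[cur], -np.log(pi[cur])))
        for pos in range(2, length + 1):
            nxt = int(rng.choice(K, p=T[cur]))
            toks.append(stems[nxt])
            rows.append((sid, pos, stems[nxt], -np.log(T[cur, nxt])))
            cur = nxt
        sentences.append(toks)

    truth.token_truth = pd.DataFrame(
        rows, columns=["sentence_id", "position", "word", "surprisal"]
    )
    truth.transition_matrix = T
    truth.start_distribution = pi
    truth.states = stems
    truth.surface_center_surprisal = (
        config.dip_center_surprisal
        if config.dip_center_surprisal is not None
        else float(truth.token_truth["surprisal"].median())
    )
    return sentences, truth


# ---------------------------------------------------------------------------
# reading behaviour


def _token_records(
    config: SyntheticConfig, truth: GroundTruth, rng: np.random.Generator
) -> pd.DataFrame:
    """Per (subject, token) covariates, planted effects and intended log DV."""
    lex = truth.lexicon_truth.set_index("word")
    tokens = truth.token_truth
    subjects = [f"s{i:02d}" for i in range(config.n_subjects)]
    truth.subject_effects = {
        s: float(rng.normal(0.0, config.subject_sd)) for s in subjects
    }
    word_types = sorted(tokens["word"].unique())
    truth.word_effects = {
        w: float(rng.normal(0.0, config.word_sd)) for w in word_types
    }

    base = tokens.copy()
    base["osc"] = lex.loc[base["word"], "osc"].to_numpy()
    base["frequency"] = lex.loc[base["word"], "frequency"].to_numpy()
    base["length"] = base["word"].str.len()
    base["log_frequency"] = np.log(base["frequency"])

    reps = []
    for s in subjects:
        df = base.copy()
        df.insert(0, "subject_id", s)
        reps.append(df)
    rec = pd.concat(reps, ignore_index=True)
    mu = (
        config.beta_intercept
        + config.beta_length * rec["length"]
        + config.beta_log_frequency * rec["log_frequency"]
        + config.beta_position * rec["position"]
        + truth.surface(rec["osc"].to_numpy(), rec["surprisal"].to_numpy())
        + rec["subject_id"].map(truth.subject_effects)
        + rec["word"].map(truth.word_effects)
    )
    eps = rng.normal(0.0, config.residual_sd, size=len(rec))
    rec["mu"] = np.asarray(mu, dtype=float)
    rec["log_duration"] = rec["mu"] + eps
    rec["duration_ms"] = np.exp(rec["log_duration"])
    return rec


def make_eyetracking_dataset(
    config: SyntheticConfig,
    lexicon_pair: tuple[Lexicon, GroundTruth],
    corpus_pair: tuple[list[list[str]], GroundTruth],
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Fixation streams whose derived gaze equals the planted durations.

    Per word token the intended gaze is drawn from the planted log-linear
    model and emitted as one or two contiguous fixations; with probability
    ``p_regression`` a look-back to a random earlier word plus a return
    fixation are appended before moving on (inflating right-bounded and
    go-past times but not gaze); with probability ``p_skip`` the word is
    skipped entirely.
    """
    truth = corpus_pair[1]
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    rec = _token_records(config, truth, rng)

    fix_rows = []
    skipped = np.zeros(len(rec), dtype=bool)
    gaze_intended = np.full(len(rec), np.nan)
    rec_sorted = rec.sort_values(
        ["subject_id", "sentence_id", "position"]
    )
    for (subj, sid), trial in rec_sorted.groupby(
        ["subject_id", "sentence_id"], sort=True
    ):
        ev = 0
        fixated_positions: list[int] = []
        for idx, row in trial.iterrows():
            pos = int(row["position"])
            if rng.uniform() < config.p_skip:
                skipped[idx] = True
                continue
            gaze = float(row["duration_ms"])
            if rng.uniform() < config.p_refixation:
                share = rng.uniform(0.35, 0.65)
                d1 = gaze * share
                parts = [d1, gaze - d1]
            else:
                parts = [gaze]
            # store the same left-to-right float sum the measure extractor
            # accumulates, so the round trip is bit-exact
            acc = parts[0]
            for d in parts[1:]:
                acc += d
            gaze_intended[idx] = acc
            for d in parts:
                ev += 1
                fix_rows.append((subj, sid, ev, pos, d))
            if fixated_positions and rng.uniform() < config.p_regression:
                back = int(rng.choice(fixated_positions))
                ev += 1
                fix_rows.append(
                    (
                        subj,
                        sid,
                        ev,
                        back,
                        float(
                            np.exp(
                                rng.normal(
                                    config.regression_log_mean,
                                    config.regression_log_sd,
                                )
                            )
                        ),
                    )
                )
                ev += 1
                fix_rows.append(
                    (
                        subj,
                        sid,
                        ev,
                        pos,
                        float(
                            np.exp(
                                rng.normal(
                                    config.regression_log_mean,
                                    config.regression_log_sd,
                                )
                            )
                        ),
                    )
                )
            fixated_positions.append(pos)

    rec["skipped"] = skipped
    rec["intended_gaze"] = gaze_intended
    truth.records = rec
    fixations = pd.DataFrame(
        fix_rows,
        columns=["subject", "sentence", "event_index", "word_index", "duration_ms"],
    )
    return fixations, truth


def make_spr_dataset(
    config: SyntheticConfig,
    lexicon_pair: tuple[Lexicon, GroundTruth],
    corpus_pair: tuple[list[list[str]], GroundTruth],
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Self-paced reading times from the planted log-linear model."""
    truth = corpus_pair[1]
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    rec = _token_records(config, truth, rng)
    rec["skipped"] = False
    rec["intended_gaze"] = rec["duration_ms"]
    truth.records = rec
    table = rec[["subject_id", "sentence_id", "position", "word", "duration_ms"]]
    table = table.rename(columns={"duration_ms": "rt"}).reset_index(drop=True)
    return table, truth


def modelling_records(
    truth: GroundTruth, dv: str = "intended_gaze"
) -> pd.DataFrame:
    """Modelling table straight from stored ground truth (no estimation).

    Used by recovery simulations: covariates are the generator's own OSC and
    surprisal values, the DV the planted duration.  Skipped tokens are
    dropped; degenerate-consistency rows are kept (exclusion is the
    assembly stage's job).
    """
    rec = truth.records
    if rec is None:
        raise ValueError("no generated records on this GroundTruth")
    df = rec.loc[~rec["skipped"]].copy()
    df["dv"] = df[dv]
    df = df[df["dv"].notna()]
    df["log_dv"] = np.log(df["dv"])
    df["word_type"] = df["word"]
    df["osc_missing"] = df["osc"].isna()
    df["min_first_pass_duration"] = df["dv"]
    df["gaze_aux"] = df["dv"]
    return df[
        [
            "subject_id",
            "sentence_id",
            "position",
            "word_type",
            "dv",
            "log_dv",
            "osc",
            "osc_missing",
            "surprisal",
            "length",
            "log_frequency",
            "min_first_pass_duration",
            "gaze_aux",
        ]
    ].reset_index(drop=True)
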