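"""First-pass eye-movement measures from raw fixation streams.

For each word of a trial (one subject reading one sentence) four dependent
variables are derived from the ordered fixation sequence:

first-fixation duration
    duration of the first fixation on the word, reported only when the word
    received more than one first-pass fixation (the "first of many").
gaze duration
    sum of the contiguous run of fixations on the word starting at first
    entry, i.e. all fixations before the eyes leave the word in any direction.
right-bounded time
    sum of all fixations on the word from first entry until the first
    fixation on any word to its right.
regression-path (go-past) time
    sum of all fixations on the word *and on earlier words* from first entry
    until the first fixation on any word to its right.

First-pass measures are only defined when the word is entered in first pass
(no word to its right was fixated earlier in the trial); a word entered only
through a regression is flagged ``regressive_entry``.  A never-fixated word
is flagged ``skipped``.  If the trial ends before the eyes move past the
word, accumulation runs to the end of the trial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = ["Fixation", "WordReadingMeasures", "compute_trial_measures",
           "compute_measures", "read_fixation_report"]

NA = float("nan")


@dataclass(frozen=True)
class Fixation:
    """One fixation event within a trial."""

    subject_id: object
    sentence_id: object
    event_index: int
    word_index: int  # 1-based interest-area position
    duration: float  # ms, > 0


@dataclass
class WordReadingMeasures:
    """The four reading-time measures for one word token in one trial."""

    subject_id: object
    sentence_id: object
    word_index: int
    first_fixation: float = NA
    n_first_pass_fixations: int = 0
    gaze: float = NA
    right_bounded: float = NA
    regression_path: float = NA
    min_first_pass_duration: float = NA
    skipped_flag: bool = False
    regressive_entry_flag: bool = False


def compute_trial_measures(
    fixations: Sequence[tuple[int, float]] | Sequence[Fixation],
    sentence_length: int,
    subject_id: object = None,
    sentence_id: object = None,
) -> list[WordReadingMeasures]:
    """Derive per-word measures from one trial's ordered fixation stream.

    ``fixations`` may be ``(word_index, duration)`` pairs (assumed already in
    temporal order) or :class:`Fixation` records, whose ``event_index`` must
    be strictly increasing.
    """
    events: list[tuple[int, float]] = []
    last_ev = None
    for fx in fixations:
        if isinstance(fx, Fixation):
            if last_ev is not None and fx.event_index <= last_ev:
                raise ValueError(
                    f"event_index not strictly increasing at {fx.event_index}"
                )
            last_ev = fx.event_index
            w, d = fx.word_index, fx.duration
        else:
            w, d = fx
        w = int(w)
        if not 1 <= w <= sentence_length:
            raise ValueError(
                f"word_index {w} outside sentence of length {sentence_length}"
            )
        if not d > 0:
            raise ValueError(f"non-positive fixation duration {d}")
        events.append((w, float(d)))
    if not events:
        raise ValueError("fixation stream is empty")

    recs = [
        WordReadingMeasures(subject_id, sentence_id, w)
        for w in range(1, sentence_length + 1)
    ]
    entered: set[int] = set()
    run_active: dict[int, bool] = {}
    rb_open: set[int] = set()
    max_word_seen = 0
    prev_word = None

    for w, d in events:
        # a change of word permanently closes the previous word's gaze run
        if prev_word is not None and prev_word != w:
            run_active[prev_word] = False
        # a fixation on w closes the first-pass window of every word left of w
        for v in [v for v in rb_open if v < w]:
            rb_open.discard(v)

        r = recs[w - 1]
        if w not in entered:
            entered.add(w)
            if max_word_seen > w:
                r.regressive_entry_flag = True
            else:
                run_active[w] = True
                rb_open.add(w)
                r.first_fixation = d
                r.n_first_pass_fixations = 1
                r.gaze = d
                r.min_first_pass_duration = d
        elif run_active.get(w, False):
            # contiguous refixation within the first-pass run
            r.n_first_pass_fixations += 1
            r.gaze += d
            r.min_first_pass_duration = min(r.min_first_pass_duration, d)

        # right-bounded / regression-path accumulation over open windows
        if w in rb_open:
            rb = recs[w - 1]
            rb.right_bounded = (
                d if math.isnan(rb.right_bounded) else rb.right_bounded + d
            )
        for v in rb_open:
            if w <= v:
                rv = recs[v - 1]
                rv.regression_path = (
                    d
                    if math.isnan(rv.regression_path)
                    else rv.regression_path + d
                )

        max_word_seen = max(max_word_seen, w)
        prev_word = w

    for r in recs:
        if r.word_index not in entered:
            r.skipped_flag = True
        if r.n_first_pass_fixations <= 1:
            r.first_fixation = NA  # first-of-many convention
    return recs


def compute_measures(
    fixations: pd.DataFrame,
    sentence_lengths: dict | None = None,
) -> pd.DataFrame:
    """Per-(subject, sentence, word) measures for a whole fixation report.

    ``fixations`` needs columns ``subject, sentence, event_index, word_index,
    duration_ms``.  Sentence lengths default to the maximum word index
    observed for each sentence across subjects.
    """
    required = {"subject", "sentence", "event_index", "word_index", "duration_ms"}
    missing = required - set(fixations.columns)
    if missing:
        raise ValueError(f"fixation report lacks columns {sorted(missing)}")
    if sentence_lengths is None:
        sentence_lengths = (
            fixations.groupby("sentence")["word_index"].max().to_dict()
        )
    rows = []
    for (subj, sent), trial in fixations.groupby(
        ["subject", "sentence"], sort=True
    ):
        trial = trial.sort_values("event_index")
        if trial["event_index"].duplicated().any():
            raise ValueError(
                f"duplicate event_index in trial ({subj}, {sent})"
            )
        fx = [
            Fixation(subj, sent, int(e), int(w), float(d))
            for e, w, d in zip(
                trial["event_index"], trial["word_index"], trial["duration_ms"]
            )
        ]
        rows.extend(
            compute_trial_measures(
                fx, int(sentence_lengths[sent]), subject_id=subj, sentence_id=sent
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def read_fixation_report(path) -> pd.DataFrame:
    """Read a tab-separated fixation report with a header row."""
    df = pd.read_csv(path, sep="\t")
    return df
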