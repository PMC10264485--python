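"""Independent reference implementations used to cross-check the package.

These are deliberately written in the most literal style possible (double
loops, per-word declarative scans) and share no code with the implementations
they check.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_osc(words, frequencies, vectors, target):
    """Direct double-loop evaluation of the consistency score.

    ``vectors`` maps word -> array or None.  Returns (osc, n_relatives) or
    (nan, 0) when the target has no embedding.
    """
    tv = vectors[target]
    if tv is None:
        return float("nan"), 0
    num = 0.0
    den = 0.0
    cosines = []
    for w in words:
        if target in w and vectors[w] is not None:
            c = float(
                np.dot(tv, vectors[w])
                / (np.linalg.norm(tv) * np.linalg.norm(vectors[w]))
            )
            f = frequencies[w]
            num += f * c
            den += f
            cosines.append(c)
    if den == 0:
        return float(np.mean(cosines)), len(cosines)
    return num / den, len(cosines)


def simulate_measures(events, sentence_length):
    """Per-word declarative scan over a fixation event list.

    ``events`` is a list of (word_index, duration).  Returns a dict per word:
    first_fixation (first-of-many), n_first_pass, gaze, right_bounded,
    regression_path, skipped, regressive_entry.  NaN marks undefined values.
    """
    NA = float("nan")
    out = {}
    words_seq = [w for w, _ in events]
    for w in range(1, sentence_length + 1):
        rec = dict(
            first_fixation=NA, n_first_pass=0, gaze=NA, right_bounded=NA,
            regression_path=NA, skipped=False, regressive_entry=False,
        )
        if w not in words_seq:
            rec["skipped"] = True
            out[w] = rec
            continue
        i0 = words_seq.index(w)
        if any(v > w for v in words_seq[:i0]):
            rec["regressive_entry"] = True
            out[w] = rec
            continue
        # contiguous first-pass run from first entry
        run = []
        for v, d in events[i0:]:
            if v != w:
                break
            run.append(d)
        rec["n_first_pass"] = len(run)
        rec["gaze"] = sum(run)
        if len(run) > 1:
            rec["first_fixation"] = run[0]
        # window until the first fixation right of w (or trial end)
        exit_i = len(events)
        for j in range(i0, len(events)):
            if events[j][0] > w:
                exit_i = j
                break
        window = events[i0:exit_i]
        rec["right_bounded"] = sum(d for v, d in window if v == w)
        rec["regression_path"] = sum(d for _, d in window)
        out[w] = rec
    return out


def all_fixation_sequences(max_len, n_words, durations):
    """Every fixation sequence up to max_len over n_words x durations."""
    seqs = []

    def extend(prefix, length):
        if length == 0:
            seqs.append(tuple(prefix))
            return
        for w in range(1, n_words + 1):
            for d in durations:
                extend(prefix + [(w, d)], length - 1)

    for L in range(1, max_len + 1):
        extend([], L)
    return seqs


def ols_coefficients(X, y):
    """Plain normal-equations least squares."""
    return np.linalg.solve(X.T @ X, X.T @ y)


def nan_eq(a, b, tol=1e-9):
    """Equality treating NaN == NaN."""
    if isinstance(a, float) and isinstance(b, float):
        if math.isnan(a) and math.isnan(b):
            return True
    return abs(a - b) <= tol
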