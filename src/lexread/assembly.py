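"""Join reading measures with covariates and apply exclusion rules.

Assembly produces one modelling record per (subject, word token): the chosen
dependent variable plus OSC, surprisal, word length, natural-log frequency
and sentence position.  Exclusions mirror standard practice for this kind of
reading-time analysis and are applied in a fixed order with a per-step
accounting report:

1. OSC missing (no consistency score available for the word type);
2. OSC degenerate (score equal to 1: the word has no informative relatives);
3. duration bounds — eye tracking: any first-pass fixation shorter than
   50 ms or gaze longer than 1,200 ms; self-paced reading: reading time
   shorter than 150 ms or longer than 1,500 ms.

All bounds are strict inequalities: values exactly at a bound survive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_THRESHOLDS",
    "ExclusionReport",
    "attach_covariates",
    "apply_exclusions",
]

DEFAULT_THRESHOLDS = {
    "eyetracking": (50.0, 1200.0),  # min fixation ms, max gaze ms
    "spr": (150.0, 1500.0),  # min RT ms, max RT ms
}

#: auxiliary columns kept on records for the exclusion stage
_AUX_COLS = ["min_first_pass_duration", "gaze_aux"]


@dataclass
class ExclusionReport:
    """Counts removed per rule, in application order."""

    steps: list[dict] = field(default_factory=list)
    final_count: int = 0

    def add(self, rule: str, n_before: int, n_removed: int) -> None:
        self.steps.append(
            {
                "rule": rule,
                "n_before": int(n_before),
                "n_removed": int(n_removed),
                "pct_of_step_input": (
                    round(100.0 * n_removed / n_before, 4) if n_before else 0.0
                ),
            }
        )

    def to_dict(self) -> dict:
        return {"steps": self.steps, "final_count": int(self.final_count)}

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _check_unique(df: pd.DataFrame, keys: list[str], source: str) -> None:
    dup = df.duplicated(subset=keys)
    if dup.any():
        offenders = df.loc[dup, keys].head(10).to_dict("records")
        raise ValueError(f"duplicate keys in {source}: {offenders}")


def attach_covariates(
    measures: pd.DataFrame,
    osc_table: pd.DataFrame,
    surprisal_table: pd.DataFrame,
    frequency_table: dict | pd.DataFrame,
    dv: str = "gaze",
    mode: str = "eyetracking",
) -> tuple[pd.DataFrame, dict]:
    """Inner-join measures with OSC, surprisal and frequency covariates.

    ``measures`` is either the eye-movement measure table (one row per
    subject/sentence/word with the four measures) or a self-paced reading
    table with an ``rt`` column; the word identity comes from the surprisal
    table via (sentence, position).  Returns the record table and a
    missing-value accounting dict.  Duplicate keys in any source are an
    error.
    """
    acct: dict[str, int] = {}
    m = measures.copy()
    if mode == "eyetracking":
        m = m.rename(columns={"word_index": "position", "sentence": "sentence_id"})
    key = ["subject_id", "sentence_id", "position"]
    if "subject" in m.columns and "subject_id" not in m.columns:
        m = m.rename(columns={"subject": "subject_id"})
    # word identity is taken from the surprisal table (the tokenised corpus)
    m = m.drop(columns=[c for c in ("word",) if c in m.columns])
    _check_unique(m, key, "measures")

    sp = surprisal_table.copy()
    sp["word"] = sp["word"].astype(str).str.lower()
    _check_unique(sp, ["sentence_id", "position"], "surprisal table")

    osc = osc_table.copy()
    osc["word"] = osc["word"].astype(str).str.lower()
    _check_unique(osc, ["word"], "osc table")

    if isinstance(frequency_table, pd.DataFrame):
        freq = dict(
            zip(
                frequency_table["word"].astype(str).str.lower(),
                frequency_table["count"].astype(float),
            )
        )
    else:
        freq = {str(k).lower(): float(v) for k, v in frequency_table.items()}

    n0 = len(m)
    df = m.merge(
        sp[["sentence_id", "position", "word", "surprisal"]],
        on=["sentence_id", "position"],
        how="inner",
    )
    acct["surprisal unavailable"] = n0 - len(df)

    n1 = len(df)
    osc_cols = osc[["word", "osc", "degenerate_flag", "missing_flag"]].rename(
        columns={"degenerate_flag": "osc_degenerate", "missing_flag": "osc_missing"}
    )
    df = df.merge(osc_cols, on="word", how="left")
    # a word absent from the OSC table is OSC-missing, kept for the report
    df["osc_missing"] = np.where(
        df["osc_missing"].isna(), True, df["osc_missing"]
    ).astype(bool)
    df["osc_degenerate"] = np.where(
        df["osc_degenerate"].isna(), False, df["osc_degenerate"]
    ).astype(bool)
    acct["osc table rows matched"] = int((~df["osc_missing"]).sum())

    # dependent variable
    if mode == "eyetracking":
        if dv not in ("first_fixation", "gaze", "right_bounded", "regression_path"):
            raise ValueError(f"unknown eye-tracking DV {dv!r}")
        df["dv"] = df[dv]
        df["gaze_aux"] = df["gaze"]
    elif mode == "spr":
        df["dv"] = df["rt"]
        df["gaze_aux"] = np.nan
        df["min_first_pass_duration"] = np.nan
    else:
        raise ValueError(f"unknown mode {mode!r}")
    n2 = len(df)
    df = df[df["dv"].notna() & (df["dv"] > 0)]
    acct["DV missing"] = n2 - len(df)

    df["log_dv"] = np.log(df["dv"].astype(float))
    df["word_type"] = df["word"]
    df["length"] = df["word"].str.len()
    counts = df["word"].map(freq)
    acct["frequency unavailable"] = int(counts.isna().sum())
    df = df[counts.notna()].copy()
    counts = counts.dropna()
    zero = counts <= 0
    acct["zero frequency adjusted to 1"] = int(zero.sum())
    df["log_frequency"] = np.log(counts.clip(lower=1.0).astype(float))

    cols = key + [
        "word_type",
        "dv",
        "log_dv",
        "osc",
        "osc_missing",
        "osc_degenerate",
        "surprisal",
        "length",
        "log_frequency",
    ] + _AUX_COLS
    out = df[cols].reset_index(drop=True)
    acct["records assembled"] = len(out)
    return out, acct


def apply_exclusions(
    records: pd.DataFrame,
    mode: str = "eyetracking",
    thresholds: tuple[float, float] | None = None,
    degenerate_tol: float = 1e-9,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the exclusion rules in fixed order and report per-step counts.

    Rules (in order): OSC missing, OSC equal to 1, duration bounds.  The
    operation is idempotent: applying it to its own output removes nothing.
    """
    if mode not in DEFAULT_THRESHOLDS:
        raise ValueError(f"unknown mode {mode!r}")
    lo, hi = thresholds if thresholds is not None else DEFAULT_THRESHOLDS[mode]
    report = ExclusionReport()
    df = records

    osc_missing = df["osc"].isna() | df.get(
        "osc_missing", pd.Series(False, index=df.index)
    ).astype(bool)
    n = len(df)
    df = df[~osc_missing]
    report.add("OSC missing", n, n - len(df))

    degenerate = (df["osc"] - 1.0).abs() < degenerate_tol
    n = len(df)
    df = df[~degenerate]
    report.add("OSC degenerate (= 1)", n, n - len(df))

    n = len(df)
    if mode == "eyetracking":
        min_fix = df["min_first_pass_duration"]
        gaze = df["gaze_aux"] if "gaze_aux" in df.columns else df["dv"]
        too_short = min_fix.notna() & (min_fix < lo)
        too_long = gaze.notna() & (gaze > hi)
        bad = too_short | too_long
        rule = f"fixation < {lo:g} ms or gaze > {hi:g} ms"
    else:
        bad = (df["dv"] < lo) | (df["dv"] > hi)
        rule = f"RT < {lo:g} ms or RT > {hi:g} ms"
    df = df[~bad]
    report.add(rule, n, n - len(df))

    report.final_count = len(df)
    return df.reset_index(drop=True), report
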