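"""Behavioural scoring of the oddball task and the proficiency split.

A correct response is a button press 200-1200 ms (half-open window) after
a deviant; presses after standards are false alarms.  Subjects are divided
into proficient and non-proficient implant users by a median split on the
hit rate for the difficult deviant via the implant ear, with ties going to
the non-proficient side (performance strictly above the median counts as
proficient).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthdata import TrialSequence


@dataclass
class BehavioralScore:
    """Per-deviant hit rate and mean RT for one subject x ear."""

    hit_rate: dict[str, float]
    mean_rt_ms: dict[str, float]
    n_hits: dict[str, int]
    n_deviants: dict[str, int]
    false_alarm_rate: float
    listening_effort: float | None = None


def score_responses(
    seq: TrialSequence,
    responses: list[tuple[int, float | None]],
    window_ms: tuple[float, float] = (200.0, 1200.0),
) -> BehavioralScore:
    """Score per-trial responses against the half-open response window.

    ``responses`` maps trial index to the first press latency (ms after
    that trial's onset) or None; later presses in the same window are
    already discarded upstream, and a press falling into two successive
    trial windows is attributed to the earlier trial by construction.
    """
    lo, hi = window_ms
    rt_map: dict[int, float] = {}
    for i, r in responses:
        if r is None:
            continue
        if r < 0:
            raise ValueError(f"response before trial onset (trial {i}, rt {r})")
        if i not in rt_map:  # first press counts
            rt_map[i] = r
    hits: dict[str, list[float]] = {}
    n_dev: dict[str, int] = {}
    fa = 0
    n_std = 0
    for i, code in enumerate(seq.codes):
        if code == "standard":
            n_std += 1
            if i in rt_map:
                fa += 1
            continue
        n_dev[code] = n_dev.get(code, 0) + 1
        r = rt_map.get(i)
        if r is not None and lo <= r < hi:
            hits.setdefault(code, []).append(r)
    hit_rate = {c: len(hits.get(c, [])) / n for c, n in n_dev.items()}
    mean_rt = {
        c: float(np.mean(hits[c])) if hits.get(c) else float("nan") for c in n_dev
    }
    n_hits = {c: len(hits.get(c, [])) for c in n_dev}
    return BehavioralScore(
        hit_rate, mean_rt, n_hits, n_dev, fa / n_std if n_std else 0.0
    )


@dataclass
class ProficiencyGroup:
    assignment: dict[str, str]  # subject -> "proficient" | "non_proficient"
    threshold: float
    degenerate: bool = False


def median_split(key_by_subject: dict[str, float]) -> ProficiencyGroup:
    """Median split: strictly above the median -> proficient, else not."""
    if len(key_by_subject) < 2:
        raise ValueError("need at least 2 subjects for a median split")
    values = np.array(list(key_by_subject.values()), float)
    threshold = float(np.median(values))
    degenerate = bool(np.all(values == values[0]))
    assignment = {
        s: ("proficient" if v > threshold else "non_proficient")
        for s, v in key_by_subject.items()
    }
    return ProficiencyGroup(assignment, threshold, degenerate)


def summarize_subject_table(tbl: pd.DataFrame) -> pd.DataFrame:
    """n, mean, sample SD, min, max for every numeric column."""
    rows = {}
    for col in tbl.columns:
        numeric = pd.to_numeric(tbl[col], errors="coerce")
        if numeric.notna().sum() == 0:
            continue
        bad = tbl[col].notna() & numeric.isna()
        if bad.any():
            raise ValueError(
                f"non-numeric cell in column {col!r}, row {int(np.flatnonzero(bad)[0])}"
            )
        vals = numeric.dropna()
        rows[col] = {
            "n": int(vals.size),
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
            "min": float(vals.min()),
            "max": float(vals.max()),
        }
    return pd.DataFrame(rows).T
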