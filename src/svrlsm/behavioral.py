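"""Behavioral scoring for the two working-memory domains.

Phonological working memory (PWM) is indexed by forward digit span: the
longest list length at which both of two lists are repeated correctly,
plus half a point for every isolated correct list at longer lengths.

Orthographic working memory (OWM) is indexed by spelling. Spelling is
scored at the letter level: the accuracy of a response is one minus the
normalized Damerau-Levenshtein distance to the target, so that a single
substitution in a four-letter word costs 25% and a transposition counts
as one letter error. Deficit typing follows the classical dysgraphia
taxonomy: sensitivity to word frequency (or phonologically plausible
errors) marks an orthographic long-term memory (OLTM) deficit, while
sensitivity to word length marks an OWM (graphemic-buffer) deficit.

A categorical analysis variable separates the two: selective OWM = -1,
selective OLTM = +1, the variable is demeaned over those carrying a
code, and dual-deficit participants are then fixed at 0.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    DegenerateCovariateError,
    InvalidCohortError,
    InvalidInputError,
    UndefinedTestError,
)

__all__ = [
    "SpellingTrial",
    "DigitSpanRecord",
    "DeficitProfile",
    "damerau_levenshtein",
    "letter_accuracy",
    "letter_counts",
    "digit_span",
    "effect_chi_square",
    "effect_test",
    "classify_deficits",
    "classify_from_pvalues",
    "construct_owm_variable",
    "z_normalize",
    "load_table3",
    "table3_discordances",
    "parse_p_value",
    "read_spelling_trials",
    "read_digit_span_records",
]

#: Word-frequency bin boundaries, occurrences per million: low < 15, high > 60.
FREQ_LOW_BELOW = 15.0
FREQ_HIGH_ABOVE = 60.0
#: Word-length bins in letters: short = 4-5, long = 7-8.
SHORT_LENGTHS = (4, 5)
LONG_LENGTHS = (7, 8)

DEFICIT_TYPES = ("OWM", "OLTM", "OWM+OLTM", "none")


def _normalize_deficit_label(label: str) -> str:
    out = label.strip().replace(" ", "")
    if out.lower() == "none":
        return "none"
    if out not in ("OWM", "OLTM", "OWM+OLTM"):
        raise InvalidInputError(f"unrecognized deficit label: {label!r}")
    return out


@dataclass(frozen=True)
class SpellingTrial:
    """One written-spelling trial: a target word and the produced response."""

    target: str
    response: str
    frequency_per_million: float
    list_source: str = "other"

    def __post_init__(self):
        if not self.target or not self.target.strip():
            raise InvalidInputError("spelling target must be a non-empty string")
        if self.frequency_per_million < 0:
            raise InvalidInputError("word frequency must be non-negative")
        object.__setattr__(self, "target", self.target.strip().upper())
        object.__setattr__(self, "response", self.response.strip().upper())


@dataclass(frozen=True)
class DigitSpanRecord:
    """Forward digit-span administration: per list length, lists given and correct.

    Two lists are presented at each length from 2 up, stopping after the
    first length at which both lists fail.
    """

    trials: Mapping[int, tuple[int, int]]

    MIN_LENGTH = 2
    MAX_LENGTH = 9

    def __post_init__(self):
        stopped_at = None
        for length in sorted(self.trials):
            administered, correct = self.trials[length]
            if not (self.MIN_LENGTH <= length <= self.MAX_LENGTH):
                raise InvalidInputError(f"list length {length} outside 2..9")
            if not (0 <= administered <= 2) or not (0 <= correct <= administered):
                raise InvalidInputError(
                    f"length {length}: need 0 <= correct <= administered <= 2, "
                    f"got administered={administered}, correct={correct}"
                )
            if stopped_at is not None and administered > 0:
                raise InvalidInputError(
                    f"lists administered at length {length} after both lists "
                    f"failed at length {stopped_at} (stopping rule violated)"
                )
            if administered == 2 and correct == 0 and stopped_at is None:
                stopped_at = length


@dataclass(frozen=True)
class DeficitProfile:
    """Per-participant spelling-deficit evidence and the derived type."""

    participant_id: str
    freq_effect_p: float
    length_effect_p: float
    ppe_present: bool
    oltm_deficit: bool
    owm_deficit: bool
    deficit_type: str = field(init=False)

    def __post_init__(self):
        if self.owm_deficit and self.oltm_deficit:
            dtype = "OWM+OLTM"
        elif self.owm_deficit:
            dtype = "OWM"
        elif self.oltm_deficit:
            dtype = "OLTM"
        else:
            dtype = "none"
        object.__setattr__(self, "deficit_type", dtype)


# ---------------------------------------------------------------------------
# Letter-level spelling accuracy
# ---------------------------------------------------------------------------

def damerau_levenshtein(a: str, b: str) -> int:
    """Damerau-Levenshtein distance (Lowrance-Wagner algorithm).

    The minimum number of unit-cost substitutions, insertions,
    deletions and adjacent transpositions turning ``a`` into ``b``; a
    transposed pair counts as one edit, matching the convention that a
    letter-order error is a single letter error. This is the
    unrestricted distance: edits may compose freely, so it never
    exceeds the optimal-string-alignment variant.
    """
    la, lb = len(a), len(b)
    if la == 0:
        return lb
    if lb == 0:
        return la
    inf = la + lb
    h = [[inf] * (lb + 2) for _ in range(la + 2)]
    for i in range(la + 1):
        h[i + 1][1] = i
    for j in range(lb + 1):
        h[1][j + 1] = j
    da: dict[str, int] = {}
    for i in range(1, la + 1):
        db = 0
        for j in range(1, lb + 1):
            i1 = da.get(b[j - 1], 0)
            j1 = db
            if a[i - 1] == b[j - 1]:
                cost = 0
                db = j
            else:
                cost = 1
            h[i + 1][j + 1] = min(
                h[i][j] + cost,
                h[i + 1][j] + 1,
                h[i][j + 1] + 1,
                h[i1][j1] + (i - i1 - 1) + 1 + (j - j1 - 1),
            )
        da[a[i - 1]] = i
    return h[la + 1][lb + 1]


def letter_accuracy(target: str, response: str) -> float:
    """Letter accuracy of a spelling response in [0, 1].

    Defined as ``1 - d / max(|target|, |response|)`` with *d* the
    Damerau-Levenshtein distance, so COAT written as COET scores 0.75
    and as CUAD scores 0.50.
    """
    target = target.strip().upper()
    response = response.strip().upper()
    if not target:
        raise InvalidInputError("target must be non-empty")
    denom = max(len(target), len(response))
    d = damerau_levenshtein(target, response)
    return float(np.clip(1.0 - d / denom, 0.0, 1.0))


def letter_counts(trial: SpellingTrial) -> tuple[int, int]:
    """(correct, incorrect) letter counts for one trial.

    The trial contributes ``max(|target|, |response|)`` letter slots;
    the edit distance gives the number scored incorrect.
    """
    total = max(len(trial.target), len(trial.response))
    wrong = min(damerau_levenshtein(trial.target, trial.response), total)
    return total - wrong, wrong


# ---------------------------------------------------------------------------
# Digit span
# ---------------------------------------------------------------------------

def digit_span(record: DigitSpanRecord) -> float:
    """Score a digit-span administration.

    The span is the longest length with both lists correct (0 if none),
    plus 0.5 for each correct list at longer lengths. Two lists at
    length 2, one of two at length 3 and none at length 4 scores 2.5.
    """
    best = 0
    for length, (administered, correct) in record.trials.items():
        if administered >= 2 and correct == 2 and length > best:
            best = length
    extra = sum(
        correct
        for length, (_, correct) in record.trials.items()
        if length > best
    )
    return best + 0.5 * extra


# ---------------------------------------------------------------------------
# Frequency / length effects on spelling
# ---------------------------------------------------------------------------

def _assign_bin(trial: SpellingTrial, split: str) -> int | None:
    """Return 0 (low-freq / short), 1 (high-freq / long), or None if unbinned."""
    if split == "frequency":
        if trial.frequency_per_million < FREQ_LOW_BELOW:
            return 0
        if trial.frequency_per_million > FREQ_HIGH_ABOVE:
            return 1
        return None
    if split == "length":
        if len(trial.target) in SHORT_LENGTHS:
            return 0
        if len(trial.target) in LONG_LENGTHS:
            return 1
        return None
    raise InvalidInputError(f"split must be 'frequency' or 'length', got {split!r}")


@dataclass(frozen=True)
class EffectTestResult:
    """Chi-square test of a spelling-performance split, plus cell accuracies."""

    p_value: float
    statistic: float
    table: np.ndarray  # 2x2: rows = (low/short, high/long), cols = (correct, wrong)
    accuracy_low: float  # low-frequency or short-word letter accuracy
    accuracy_high: float  # high-frequency or long-word letter accuracy


def effect_test(
    trials: Sequence[SpellingTrial],
    split: Literal["frequency", "length"],
) -> EffectTestResult:
    """Chi-square test of letter accuracy across a frequency or length split.

    Builds a 2x2 table of (letters correct, letters incorrect) by bin.
    Words falling in neither bin (6-letter or mid-frequency words) are
    excluded, matching the design of graded spelling batteries. No
    continuity correction is applied.
    """
    counts = np.zeros((2, 2), dtype=float)
    for trial in trials:
        cell = _assign_bin(trial, split)
        if cell is None:
            continue
        good, bad = letter_counts(trial)
        counts[cell, 0] += good
        counts[cell, 1] += bad
    if counts[0].sum() == 0 or counts[1].sum() == 0:
        raise UndefinedTestError(
            f"{split} effect test undefined: a split cell has zero letters"
        )
    if counts[:, 0].sum() == 0 or counts[:, 1].sum() == 0:
        # all letters correct (or all wrong) in both cells: no association
        stat, p = 0.0, 1.0
    else:
        stat, p, _, _ = stats.chi2_contingency(counts, correction=False)
    acc = counts[:, 0] / counts.sum(axis=1)
    return EffectTestResult(float(p), float(stat), counts, float(acc[0]), float(acc[1]))


def effect_chi_square(
    trials: Sequence[SpellingTrial],
    split: Literal["frequency", "length"],
) -> float:
    """p-value of the frequency or length effect on letter accuracy."""
    return effect_test(trials, split).p_value


def classify_from_pvalues(
    freq_effect_p: float,
    ppe_present: bool,
    length_effect_p: float,
    alpha: float = 0.05,
    participant_id: str = "",
) -> DeficitProfile:
    """Type a spelling deficit from pre-computed effect p-values.

    OLTM deficit: significant frequency effect and/or phonologically
    plausible errors. OWM deficit: significant length effect. Used when
    only summary statistics (not trials) are available, so no
    directionality guard can be applied.
    """
    oltm = (freq_effect_p < alpha) or ppe_present
    owm = length_effect_p < alpha
    return DeficitProfile(participant_id, freq_effect_p, length_effect_p,
                          ppe_present, oltm, owm)


def classify_deficits(
    trials: Sequence[SpellingTrial],
    ppe_present: bool,
    alpha: float = 0.05,
    participant_id: str = "",
    directional: bool = True,
) -> DeficitProfile:
    """Classify a participant's spelling deficit from trial-level data.

    With ``directional=True`` (default) an effect only counts toward a
    deficit when it goes the deficit-consistent way: low-frequency worse
    than high-frequency for OLTM, long words worse than short for OWM.
    """
    freq = effect_test(trials, "frequency")
    length = effect_test(trials, "length")
    freq_sig = freq.p_value < alpha
    length_sig = length.p_value < alpha
    if directional:
        freq_sig = freq_sig and freq.accuracy_low < freq.accuracy_high
        length_sig = length_sig and length.accuracy_high < length.accuracy_low
    oltm = freq_sig or ppe_present
    owm = length_sig
    return DeficitProfile(participant_id, freq.p_value, length.p_value,
                          ppe_present, oltm, owm)


# ---------------------------------------------------------------------------
# The categorical OWM analysis variable
# ---------------------------------------------------------------------------

def construct_owm_variable(
    profiles: Iterable,
    demean_scope: Literal["selective", "all"] = "selective",
) -> dict[str, float]:
    """Build the categorical OWM variable from deficit types.

    Selective OWM participants are coded -1 and selective OLTM
    participants +1; the variable is demeaned; dual-deficit (OWM+OLTM)
    participants are then set to 0. ``demean_scope`` controls whether
    the mean is taken over the coded participants only (default,
    following the order of operations in which dual-deficit cases carry
    no value yet) or over the full cohort with dual cases provisionally
    at 0.

    Accepts :class:`DeficitProfile` objects, ``(participant_id,
    deficit_type)`` pairs, or a mapping of id to deficit label.
    Participants typed ``none`` are rejected: the analysis is defined
    only over dysgraphic participants.
    """
    if isinstance(profiles, Mapping):
        items = list(profiles.items())
    else:
        items = [
            (p.participant_id, p.deficit_type) if isinstance(p, DeficitProfile) else tuple(p)
            for p in profiles
        ]
    raw: dict[str, float] = {}
    dual: list[str] = []
    for pid, label in items:
        label = _normalize_deficit_label(label)
        if label == "none":
            raise InvalidCohortError(
                f"participant {pid!r} has no spelling deficit; the OWM "
                "analysis is defined only over dysgraphic participants"
            )
        if label == "OWM":
            raw[pid] = -1.0
        elif label == "OLTM":
            raw[pid] = 1.0
        else:
            dual.append(pid)
    if not raw:
        raise InvalidCohortError("no participant with a selective OWM or OLTM deficit")
    if demean_scope == "selective":
        mean = float(np.mean(list(raw.values())))
    elif demean_scope == "all":
        mean = float(sum(raw.values()) / (len(raw) + len(dual)))
    else:
        raise InvalidInputError(f"unknown demean_scope {demean_scope!r}")
    out = {pid: value - mean for pid, value in raw.items()}
    for pid in dual:
        out[pid] = 0.0
    return out


def z_normalize(values: Sequence[float], ddof: int = 0) -> np.ndarray:
    """Demean and scale to unit standard deviation.

    The population convention (``ddof=0``) divides by the group standard
    deviation; set ``ddof=1`` for the sample convention.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2 or np.all(arr == arr.flat[0]):
        raise DegenerateCovariateError(
            "z-normalization requires at least two distinct values"
        )
    sd = arr.std(ddof=ddof)
    return (arr - arr.mean()) / sd


# ---------------------------------------------------------------------------
# Packaged behavioral fixture and CSV interfaces
# ---------------------------------------------------------------------------

def parse_p_value(text) -> float:
    """Parse a printed p-value; censored values like ``<0.001`` map to the bound."""
    if isinstance(text, (int, float)):
        return float(text)
    text = text.strip()
    if text.startswith("<"):
        return float(text[1:])
    return float(text)


def load_table3() -> pd.DataFrame:
    """Load the packaged 37-participant behavioral summary table.

    Columns: participant_id, ppvt_percentile, digit_span, freq_p
    (printed frequency-effect p-value, possibly censored), ppe
    (phonologically plausible errors present), length_p, deficit_type.
    Numeric companions freq_p_value / length_p_value are parsed floats.
    """
    ref = importlib.resources.files("svrlsm.data").joinpath("behavioral_profiles.csv")
    with ref.open() as fh:
        df = pd.read_csv(fh, dtype={"freq_p": str, "length_p": str})
    df["ppe"] = df["ppe"].map({"Yes": True, "No": False})
    df["freq_p_value"] = df["freq_p"].map(parse_p_value)
    df["length_p_value"] = df["length_p"].map(parse_p_value)
    df["deficit_type"] = df["deficit_type"].map(_normalize_deficit_label)
    return df


def table3_discordances(alpha: float = 0.05) -> pd.DataFrame:
    """Rows of the packaged table whose printed deficit label disagrees
    with a pure alpha-threshold rule on the printed p-values.

    The published labels reflect adjudications beyond the printed
    statistics; discordant rows are reported, never relabeled.
    """
    df = load_table3()
    rule = [
        classify_from_pvalues(f, p, l, alpha=alpha).deficit_type
        for f, p, l in zip(df["freq_p_value"], df["ppe"], df["length_p_value"])
    ]
    df = df.assign(rule_type=rule)
    return df[df["rule_type"] != df["deficit_type"]].reset_index(drop=True)


def read_spelling_trials(path) -> dict[str, list[SpellingTrial]]:
    """Read trial-level spelling data from CSV.

    Expected columns: participant_id, target, response,
    frequency_per_million (and optionally list_source).
    """
    df = pd.read_csv(path, keep_default_na=False)
    out: dict[str, list[SpellingTrial]] = {}
    for row in df.itertuples(index=False):
        trial = SpellingTrial(
            target=str(row.target),
            response=str(row.response),
            frequency_per_million=float(row.frequency_per_million),
            list_source=str(getattr(row, "list_source", "other")),
        )
        out.setdefault(str(row.participant_id), []).append(trial)
    return out


def read_digit_span_records(path) -> dict[str, DigitSpanRecord]:
    """Read digit-span administrations from CSV.

    Expected columns: participant_id, list_length, administered, correct.
    """
    df = pd.read_csv(path)
    out: dict[str, DigitSpanRecord] = {}
    for pid, grp in df.groupby("participant_id"):
        trials = {
            int(r.list_length): (int(r.administered), int(r.correct))
            for r in grp.itertuples(index=False)
        }
        out[str(pid)] = DigitSpanRecord(trials)
    return out
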