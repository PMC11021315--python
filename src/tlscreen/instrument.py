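"""Declarative model of the telephone language screener and its deterministic scoring.

The screener consists of nine language subtasks — connected-speech informative
units (IU), Spelling, Semantic Association, Naming to Description of nouns and
verbs, a six-command Comprehension and Memory Load task (CML), and repetition
of words, non-words and sentences — whose raw scores sum into a 0-68 total.
An extra Backward Digit Span (BDS) task yields two outcomes (total sequences
correct and longest sequence recalled) but never contributes to the total.

Everything here is pure arithmetic on validated records; missing subtask
scores raise, they are never imputed.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator


class InstrumentError(ValueError):
    """Base error for instrument validation and scoring."""


class MissingScoreError(InstrumentError):
    """A required subtask score is absent from a record."""


class SpecificationError(InstrumentError):
    """An item response does not match the declared item structure."""


class SubtestSpec(BaseModel):
    """One subtask: its item count, maximum score and total-score membership."""

    model_config = ConfigDict(frozen=True)

    name: str
    n_items: int = Field(gt=0)
    max_score: int = Field(gt=0)
    included_in_total: bool


class InstrumentSpec(BaseModel):
    """Full declarative structure of the screener.

    ``cml_item_maxima`` allocates the CML's 15 points across its six commands
    (package convention: alternating three-/two-step commands, configurable);
    ``bds_sequence_lengths`` is the digit-span trial list (two sequences per
    length for lengths 2-4, one each for 5 and 6, bounding BDS-Total at 8 and
    BDS-WM at 6); ``tbcli_item_groups`` is the 1+1+4+1 item composition of the
    seven-point composite language index drawn from two other telephone
    screeners.
    """

    model_config = ConfigDict(frozen=True)

    name: str = "TLS"
    description: str = ""
    subtests: tuple[SubtestSpec, ...]
    cml_item_maxima: tuple[int, ...] = (3, 2, 3, 2, 3, 2)
    bds_sequence_lengths: tuple[int, ...] = (2, 2, 3, 3, 4, 4, 5, 6)
    tbcli_item_groups: tuple[int, ...] = (1, 1, 4, 1)

    @field_validator("cml_item_maxima")
    @classmethod
    def _cml_sums_to_fifteen(cls, v: tuple[int, ...]) -> tuple[int, ...]:
        if sum(v) != 15:
            raise ValueError(f"CML per-command maxima must sum to 15, got {sum(v)}")
        return v

    @property
    def total_contributing(self) -> tuple[SubtestSpec, ...]:
        return tuple(s for s in self.subtests if s.included_in_total)

    @property
    def total_max(self) -> int:
        return sum(s.max_score for s in self.total_contributing)

    @property
    def tbcli_max(self) -> int:
        return sum(self.tbcli_item_groups)

    def subtest(self, name: str) -> SubtestSpec:
        for s in self.subtests:
            if s.name == name:
                return s
        raise KeyError(f"unknown subtest {name!r}")

    def validate_record(self, record: "ParticipantRecord") -> None:
        """Check every present score against its subtask range and require all
        total-contributing subtasks. Raises on first violation."""
        for s in self.total_contributing:
            if s.name not in record.scores:
                raise MissingScoreError(
                    f"record {record.id!r}: missing score for subtask {s.name!r}"
                )
        for name, rs in record.scores.items():
            spec = self.subtest(name)
            if not (0 <= rs <= spec.max_score):
                raise InstrumentError(
                    f"record {record.id!r}: score {rs} for {name!r} outside "
                    f"[0, {spec.max_score}]"
                )


def load_instrument_spec(path: Optional[str] = None) -> InstrumentSpec:
    """Load an InstrumentSpec from JSON; by default, the packaged fixture."""
    if path is None:
        text = (
            resources.files("tlscreen").joinpath("data/instrument_spec.json").read_text()
        )
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    return InstrumentSpec(**json.loads(text))


DEFAULT_SPEC = load_instrument_spec()


class ParticipantRecord(BaseModel):
    """One examinee: demographics plus raw subtask scores.

    ``bds_trials`` is the ordered digit-span trial record as (sequence length,
    passed) pairs; ``cs_counts`` holds examiner-produced connected-speech
    counts (words, sentences, nouns, verbs, function_words).
    """

    model_config = ConfigDict(frozen=True)

    id: str
    age: int = Field(ge=18, le=120, description="age in completed years")
    education: int = Field(ge=1, le=30, description="years of education")
    sex: str
    scores: dict[str, int] = Field(default_factory=dict)
    bds_trials: Optional[tuple[tuple[int, bool], ...]] = None
    cs_counts: Optional[dict[str, int]] = None

    @field_validator("sex")
    @classmethod
    def _sex_category(cls, v: str) -> str:
        if v not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {v!r}")
        return v


class CmlItemResponse(BaseModel):
    """Component-wise response to one CML command.

    ``component_flags`` are the pass/fail outcomes of the command's actions in
    the order performed; ``order_correct`` records whether the serial order
    was respected. ``item_max`` is the command's point allocation: equal to
    the number of components when no order point is at stake, or components+1
    when correct serial order earns an extra point.
    """

    model_config = ConfigDict(frozen=True)

    component_flags: tuple[bool, ...]
    order_correct: bool
    item_max: int = Field(gt=0)


def total_score(record: ParticipantRecord, spec: InstrumentSpec = DEFAULT_SPEC) -> int:
    """Sum of the nine total-contributing subtask scores (0-68).

    BDS outcomes never contribute. A missing contributing subtask raises
    :class:`MissingScoreError` — there is no silent zero.
    """
    spec.validate_record(record)
    return sum(record.scores[s.name] for s in spec.total_contributing)


def score_cml_item(resp: CmlItemResponse) -> int:
    """Score one CML command: one point per correct component, plus the order
    point (when the item carries one) iff every component was correct and the
    serial order respected. Never exceeds ``item_max``.
    """
    n_comp = len(resp.component_flags)
    if resp.item_max == n_comp:
        has_order_point = False
    elif resp.item_max == n_comp + 1:
        has_order_point = True
    else:
        raise SpecificationError(
            f"item_max {resp.item_max} incompatible with {n_comp} component actions"
        )
    score = sum(resp.component_flags)
    if has_order_point and resp.order_correct and all(resp.component_flags):
        score += 1
    return min(score, resp.item_max)


def tbcli_score(item_flags: Sequence[bool], spec: InstrumentSpec = DEFAULT_SPEC) -> int:
    """Seven-item composite language index: plain sum of pass flags.

    The composite is assembled from two other telephone screeners as
    1 naming + 1 sentence repetition + 4 naming + 1 bi-phasic command.
    """
    expected = spec.tbcli_max
    if len(item_flags) != expected:
        raise SpecificationError(
            f"TBCLI expects {expected} item flags "
            f"(groups {spec.tbcli_item_groups}), got {len(item_flags)}"
        )
    return int(sum(bool(f) for f in item_flags))


def bds_outcomes(trials: Sequence[tuple[int, bool]]) -> tuple[int, int]:
    """Backward digit span outcomes from the full trial record.

    Returns ``(bds_total, bds_wm)``: the number of passed sequences (sustained
    attention) and the longest passed length (working-memory capacity, 0 if
    none). Sequence lengths must be non-decreasing across trials; examiner
    discontinuation rules are not modelled — the full record is consumed.
    """
    if len(trials) == 0:
        raise InstrumentError("empty digit-span trial list")
    lengths = [t[0] for t in trials]
    if any(b < a for a, b in zip(lengths, lengths[1:])):
        raise InstrumentError("digit-span sequence lengths must be non-decreasing")
    passed = [ln for ln, ok in trials if ok]
    return len(passed), (max(passed) if passed else 0)


def cs_ratio_measures(counts: dict[str, int]) -> dict[str, float]:
    """Advanced connected-speech measures: word/sentence counts plus
    noun, verb and function-word proportions of total words."""
    words = counts.get("words", 0)
    if words <= 0:
        raise InstrumentError("connected-speech ratios undefined for words <= 0")
    out: dict[str, float] = {
        "words": float(words),
        "sentences": float(counts.get("sentences", 0)),
    }
    for key, name in (
        ("nouns", "nouns_ratio"),
        ("verbs", "verbs_ratio"),
        ("function_words", "function_ratio"),
    ):
        c = counts.get(key, 0)
        if not (0 <= c <= words):
            raise InstrumentError(f"count {key}={c} outside [0, words={words}]")
        out[name] = c / words
    return out


def ceiling_rate(totals: Sequence[float], percentile: float = 95.0) -> float:
    """Fraction of scores at or above the empirical ``percentile``-th
    percentile of the same sample (linear-interpolation quantile)."""
    arr = np.asarray(totals, dtype=float)
    if arr.size == 0:
        raise InstrumentError("empty score list")
    threshold = np.percentile(arr, percentile)
    return float(np.mean(arr >= threshold))
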