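"""Cohort file I/O, run manifests and atomic writes.

Cohort files are UTF-8 CSV with a mandatory header: ``id, age,
education_years, sex`` followed by one column per subtask raw score (names
fixed by the instrument spec). The decimal separator defaults to the dot; a
``decimal`` argument converts comma-decimal exports at load time. Unknown
extra columns are accepted with a warning (forward compatibility); malformed
rows are rejected with their line numbers.

All writes are atomic (write to a temp file, then rename), so an
interrupted run never leaves a partial artifact. Every pipeline artifact is
accompanied by a JSON manifest recording inputs, seed and package version.
"""

from __future__ import annotations

import json
import os
import warnings
from typing import Optional

import pandas as pd

from . import __version__
from .instrument import DEFAULT_SPEC, InstrumentSpec

DEMOGRAPHIC_COLUMNS = ("id", "age", "education_years", "sex")


class CohortFormatError(ValueError):
    """Malformed cohort file; the message lists offending rows and fields."""


def atomic_write_text(text: str, path: str) -> None:
    tmp = f"{path}.tmp"
    with open(tmp, "w", encoding="utf-8") as fh:
        fh.write(text)
    os.replace(tmp, path)


def atomic_write_frame(frame: pd.DataFrame, path: str) -> None:
    atomic_write_text(frame.to_csv(index=False), path)


def write_manifest(path: str, command: str, seed: Optional[int], **params) -> None:
    manifest = {
        "command": command,
        "seed": seed,
        "package_version": __version__,
        "parameters": params,
    }
    atomic_write_text(json.dumps(manifest, indent=1, default=str), path)


def write_cohort(cohort: pd.DataFrame, path: str) -> None:
    atomic_write_frame(cohort, path)


def read_cohort(
    path: str,
    spec: InstrumentSpec = DEFAULT_SPEC,
    decimal: str = ".",
) -> pd.DataFrame:
    """Load and validate a cohort CSV.

    Checks the demographic columns and every recognised subtask score column
    against the instrument spec; rejects the file with a row-and-field
    listing when any row is invalid. Unknown columns pass through with a
    warning.
    """
    frame = pd.read_csv(path, decimal=decimal)
    missing = [c for c in DEMOGRAPHIC_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing required column(s) {missing}")
    known = (
        set(DEMOGRAPHIC_COLUMNS)
        | {s.name for s in spec.subtests}
        | {"total"}
        # advanced connected-speech measures (normed but not subtask scores)
        | {"cs_words", "cs_sentences", "cs_nouns_ratio", "cs_verbs_ratio",
           "cs_function_ratio"}
    )
    extra = [c for c in frame.columns if c not in known]
    if extra:
        warnings.warn(f"{path}: ignoring unknown column(s) {extra}", stacklevel=2)

    problems: list[str] = []
    for idx, row in frame.iterrows():
        line = idx + 2  # header is line 1
        age, edu, sex = row["age"], row["education_years"], row["sex"]
        if not (18 <= age <= 120):
            problems.append(f"line {line}: age {age} outside [18, 120]")
        if not (1 <= edu <= 30):
            problems.append(f"line {line}: education_years {edu} outside [1, 30]")
        if sex not in ("male", "female"):
            problems.append(f"line {line}: sex {sex!r} not male/female")
        for s in spec.subtests:
            if s.name in frame.columns and not pd.isna(row[s.name]):
                rs = row[s.name]
                if not (0 <= rs <= s.max_score):
                    problems.append(
                        f"line {line}: {s.name} score {rs} outside [0, {s.max_score}]"
                    )
    if problems:
        raise CohortFormatError(f"{path}: invalid rows:\n" + "\n".join(problems))
    return frame
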