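"""Shared domain types and tabular I/O.

Conventions used throughout the package:

* key, trial, and block indices are 1-based (file columns store them 1-based),
  so the within-block position formula ``ROUND((i-1)/k)+1`` applies verbatim
  to the stored first-key index ``i``;
* behavioral timestamps are milliseconds from session start; imaging
  interfaces use seconds.  The conversion happens exactly once, in
  :func:`write_events_table`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

DEFAULT_ALPHABET = frozenset({1, 2, 3, 4})


@dataclass(frozen=True)
class SequenceSpec:
    """The target key sequence participants tap repeatedly.

    Parameters
    ----------
    codes:
        Ordered key codes of the sequence.  The default task uses the
        five-element sequence 4-1-3-2-4 tapped on a four-key pad.
    alphabet:
        The set of valid key codes.
    """

    codes: tuple[int, ...]
    alphabet: frozenset[int] = DEFAULT_ALPHABET

    def __post_init__(self) -> None:
        if len(self.codes) < 2:
            raise ValueError("sequence must have at least 2 keys")
        bad = set(self.codes) - self.alphabet
        if bad:
            raise ValueError(f"sequence codes {sorted(bad)} outside alphabet")

    @property
    def k(self) -> int:
        """Sequence length (number of keys per correct trial)."""
        return len(self.codes)


@dataclass(frozen=True)
class Keypress:
    """One timestamped key event; the atomic behavioral record."""

    subject: str
    block: int  # 1-based
    key: int
    onset: float  # ms from session start


@dataclass(frozen=True)
class BlockLayout:
    """Block structure of a tapping session.

    The default layout is 14 performance blocks of 60 keypresses each,
    separated by 15-s rests.
    """

    n_blocks: int = 14
    keys_per_block: int = 60
    rest_duration: float = 15.0  # s
    block_onsets: tuple[float, ...] | None = None  # s from run start

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.keys_per_block < 1:
            raise ValueError("n_blocks and keys_per_block must be positive")
        if self.block_onsets is not None and len(self.block_onsets) != self.n_blocks:
            raise ValueError("block_onsets length must equal n_blocks")


@dataclass(frozen=True)
class Trial:
    """A parsed segment of a block: a correct sequence, an error, or a
    residual (leading/trailing) run of keys.

    ``key_span`` is the 1-based inclusive (first, last) within-block key
    index; ``ordinal`` is the 1-based within-block trial ordinal.  ``keys``
    and ``times`` carry the segment's key codes and onset times (ms).
    """

    kind: str  # "correct" | "error" | "residual"
    key_span: tuple[int, int]
    ordinal: int
    onset_time: float  # ms, first key
    offset_time: float  # ms, last key
    keys: tuple[int, ...]
    times: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("correct", "error", "residual"):
            raise ValueError(f"unknown trial kind {self.kind!r}")
        if len(self.keys) != self.key_span[1] - self.key_span[0] + 1:
            raise ValueError("key_span inconsistent with keys")

    @property
    def n_keys(self) -> int:
        return len(self.keys)


@dataclass(frozen=True)
class ErrorAnnotation:
    """Per-error annotation: type, first wrong key, restarts, duration.

    ``first_wrong_ordinal`` (1-based position of the first wrong key within
    the error) is present only for ``wrong_key`` errors; incomplete sequences
    (<= 3 correct prefix keys) and one-missing-key errors (exactly 4) have no
    wrong key by definition.  ``duration`` spans the onset transition through
    the offset transition (t_next - t_prev), so that even single-key errors
    carry a meaningful duration.
    """

    error_type: str  # "wrong_key" | "incomplete_sequence" | "missing_one_key"
    first_wrong_ordinal: int | None
    n_before: int
    n_after: int
    length_keys: int
    duration: float  # ms
    n_restart_attempts: int

    def __post_init__(self) -> None:
        if self.error_type == "wrong_key":
            if self.first_wrong_ordinal is None:
                raise ValueError("wrong_key error requires first_wrong_ordinal")
            if self.n_before != self.first_wrong_ordinal - 1:
                raise ValueError("n_before must equal first_wrong_ordinal - 1")
            if self.length_keys != self.n_before + self.n_after + 1:
                raise ValueError("length_keys inconsistent")
        elif self.error_type in ("incomplete_sequence", "missing_one_key"):
            if self.first_wrong_ordinal is not None:
                raise ValueError(f"{self.error_type} has no first wrong key")
        else:
            raise ValueError(f"unknown error_type {self.error_type!r}")


@dataclass(frozen=True)
class Period:
    """Seven (or six, at block end) consecutive trials centered on an error
    or on a position-matched control sequence.

    The 4th trial is the center; ``position`` is its within-block position.
    """

    kind: str  # "error" | "control"
    trials: tuple[Trial, ...]
    position: int
    subject: str
    block: int
    annotation: ErrorAnnotation | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("error", "control"):
            raise ValueError(f"unknown period kind {self.kind!r}")
        if len(self.trials) not in (6, 7):
            raise ValueError("period must contain 6 or 7 trials")

    @property
    def center(self) -> Trial:
        return self.trials[3]


PAPER_SEQUENCE = SequenceSpec(codes=(4, 1, 3, 2, 4))
PAPER_LAYOUT = BlockLayout(n_blocks=14, keys_per_block=60, rest_duration=15.0)

KEYPRESS_COLUMNS = ["subject", "block", "key", "onset_ms"]
EVENTS_COLUMNS = ["onset", "duration", "trial_type", "block", "ordinal", "error_type"]


def read_keypress_log(
    path: str | Path,
    alphabet: frozenset[int] = DEFAULT_ALPHABET,
) -> pd.DataFrame:
    """Read and validate a tab-separated keypress log.

    Expected columns: ``subject``, ``block``, ``key``, ``onset_ms``.  Records
    are returned sorted by (subject, block, onset).  Onsets must strictly
    increase within each (subject, block); key codes must belong to the
    alphabet.  Violations raise ``ValueError`` naming the offending row.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in KEYPRESS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"keypress log missing columns {missing}")
    df = df[KEYPRESS_COLUMNS].copy()
    df["subject"] = df["subject"].astype(str)
    df["block"] = df["block"].astype(int)
    df["key"] = df["key"].astype(int)
    df["onset_ms"] = df["onset_ms"].astype(float)

    bad_key = ~df["key"].isin(list(alphabet))
    if bad_key.any():
        row = int(df.index[bad_key][0])
        raise ValueError(f"unknown key code {df.loc[row, 'key']} at row {row}")

    for (subj, block), grp in df.groupby(["subject", "block"], sort=False):
        onsets = grp["onset_ms"].to_numpy()
        diffs = onsets[1:] - onsets[:-1]
        if (diffs <= 0).any():
            idx = int(grp.index[1:][diffs <= 0][0])
            raise ValueError(
                f"non-monotone onset at row {idx} (subject {subj}, block {block})"
            )

    return df.sort_values(["subject", "block", "onset_ms"], kind="stable").reset_index(
        drop=True
    )


def write_keypress_log(df: pd.DataFrame, path: str | Path) -> None:
    """Write a keypress table as TSV (columns subject, block, key, onset_ms)."""
    df[KEYPRESS_COLUMNS].to_csv(path, sep="\t", index=False)


def keypresses_to_frame(records: Iterable[Keypress]) -> pd.DataFrame:
    rows = [(r.subject, r.block, r.key, r.onset) for r in records]
    return pd.DataFrame(rows, columns=KEYPRESS_COLUMNS)


def iter_blocks(df: pd.DataFrame):
    """Yield ((subject, block), keys array, onset_ms array) per block in order."""
    for (subj, block), grp in df.groupby(["subject", "block"], sort=True):
        yield (subj, int(block)), grp["key"].to_numpy(), grp["onset_ms"].to_numpy()


def events_frame(
    parsed: Sequence[tuple[int, Trial, ErrorAnnotation | None]],
) -> pd.DataFrame:
    """Build a BIDS-style events table (onset/duration in seconds) from parsed
    trials.  ``parsed`` holds (block, trial, annotation-or-None) triples, or
    (subject, block, trial, annotation) for multi-subject tables.
    Overlapping trial spans within a (subject, block) are rejected.
    """
    seen: dict[tuple, list[tuple[int, int]]] = {}
    rows = []
    has_subject = False
    for rec in parsed:
        if len(rec) == 4:
            subject, block, trial, ann = rec
            has_subject = True
        else:
            block, trial, ann = rec
            subject = None
        for span in seen.setdefault((subject, block), []):
            if trial.key_span[0] <= span[1] and span[0] <= trial.key_span[1]:
                raise ValueError(
                    f"overlapping trial spans {span} and {trial.key_span} in block {block}"
                )
        seen[(subject, block)].append(trial.key_span)
        row = {
            "onset": trial.onset_time / 1000.0,
            "duration": (trial.offset_time - trial.onset_time) / 1000.0,
            "trial_type": trial.kind,
            "block": block,
            "ordinal": trial.ordinal,
            "error_type": ann.error_type if ann is not None else "n/a",
        }
        if subject is not None:
            row["subject"] = subject
        rows.append(row)
    cols = EVENTS_COLUMNS + (["subject"] if has_subject else [])
    return pd.DataFrame(rows, columns=cols)


def write_events_table(
    parsed: Sequence[tuple[int, Trial, ErrorAnnotation | None]],
    path: str | Path,
) -> pd.DataFrame:
    """Write the events table for one subject to ``path`` (TSV) and return it."""
    df = events_frame(parsed)
    df.to_csv(path, sep="\t", index=False)
    return df


def read_events_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("onset", "duration", "trial_type") if c not in df.columns]
    if missing:
        raise ValueError(f"events table missing columns {missing}")
    return df
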