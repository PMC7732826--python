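"""Isolated-error selection and position-matched control construction.

An error is *eligible* when it is surrounded by enough correct trials
(default: at least three before and three after, or two after when the
error's trailing correct run closes the block), lasted longer than a minimum
duration, and is not an extended run of more than ``max_keys`` keys.  Each
eligible error, with its neighbours, forms a 7-trial (or 6-trial, at block
end) period whose within-block position is given by the first-key index of
the error via ``ROUND((i - 1) / k) + 1``.

Control periods are windows of consecutive correct trials at the same
within-block position, matched to errors pseudo-randomly, one control per
error, without reuse of a control's center trial within a set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import ErrorAnnotation, Period, SequenceSpec, Trial


@dataclass(frozen=True)
class SelectionConfig:
    """Eligibility thresholds for errors of interest.

    ``min_duration`` is a strict lower bound in ms (errors lasting 0.5 s or
    less are excluded); ``max_keys`` is inclusive (errors of more than 20
    keys — the material of four correct trials — are excluded).
    """

    min_pre: int = 3
    min_post: int = 3
    min_post_if_last: int = 2
    min_duration: float = 500.0  # ms, strict
    max_keys: int = 20  # inclusive

    def __post_init__(self) -> None:
        if min(self.min_pre, self.min_post, self.min_post_if_last) < 1:
            raise ValueError("trial-count thresholds must be positive")
        if self.min_post_if_last > self.min_post:
            raise ValueError("min_post_if_last must not exceed min_post")


@dataclass
class MatchedPairSet:
    """Position-matched (error period, control period) pairs for one subject."""

    pairs: list[tuple[Period, Period]]
    seed: int
    excluded: list[tuple[Period, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def control_center_ids(self) -> set[tuple[str, int, int]]:
        return {
            (c.subject, c.block, c.center.ordinal) for _, c in self.pairs
        }


def within_block_position(i: int, k: int) -> int:
    """Within-block position of a trial from its 1-based first-key index.

    ``ROUND((i - 1) / k) + 1`` with ROUND = nearest integer, halves away
    from zero (halves never arise for odd k such as the default k = 5).
    """
    if i < 1 or k < 2:
        raise ValueError("require i >= 1 and k >= 2")
    q = (i - 1) / k
    return int(math.floor(q + 0.5)) + 1


def _period_from_error(
    trials: list[tuple[Trial, ErrorAnnotation | None]],
    j: int,
    n_post: int,
    cfg: SelectionConfig,
    subject: str,
    block: int,
    k: int,
) -> Period:
    window = [t for t, _ in trials[j - cfg.min_pre : j + n_post + 1]]
    err, ann = trials[j]
    return Period(
        kind="error",
        trials=tuple(window),
        position=within_block_position(err.key_span[0], k),
        subject=subject,
        block=block,
        annotation=ann,
    )


def select_errors(
    parsed: dict[tuple[str, int], list[tuple[Trial, ErrorAnnotation | None]]],
    cfg: SelectionConfig,
    seq: SequenceSpec,
) -> tuple[list[Period], list[dict]]:
    """Apply the eligibility rules to every annotated error of a session.

    Returns (eligible error periods, exclusion records).  Every detected
    error appears in exactly one of the two outputs, so counts reconcile.
    """
    periods: list[Period] = []
    excluded: list[dict] = []
    for (subject, block), trials in sorted(parsed.items()):
        n = len(trials)
        for j, (tr, ann) in enumerate(trials):
            if tr.kind != "error":
                continue
            assert ann is not None

            def _exclude(reason: str) -> None:
                excluded.append(
                    {
                        "subject": subject,
                        "block": block,
                        "ordinal": tr.ordinal,
                        "reason": reason,
                    }
                )

            n_pre = 0
            while j - n_pre - 1 >= 0 and trials[j - n_pre - 1][0].kind == "correct":
                n_pre += 1
            n_post = 0
            while j + n_post + 1 < n and trials[j + n_post + 1][0].kind == "correct":
                n_post += 1
            reaches_end = j + n_post == n - 1

            if n_pre < cfg.min_pre:
                _exclude(f"only {n_pre} preceding correct trials")
            elif n_post < cfg.min_post and not (
                reaches_end and n_post >= cfg.min_post_if_last
            ):
                _exclude(f"only {n_post} following correct trials")
            elif ann.duration <= cfg.min_duration:
                _exclude(f"duration {ann.duration:.0f} ms <= {cfg.min_duration:.0f} ms")
            elif ann.length_keys > cfg.max_keys:
                _exclude(f"{ann.length_keys} keys > {cfg.max_keys}")
            else:
                take_post = min(n_post, cfg.min_post)
                periods.append(
                    _period_from_error(trials, j, take_post, cfg, subject, block, seq.k)
                )
    return periods, excluded


def enumerate_controls(
    parsed: dict[tuple[str, int], list[tuple[Trial, ErrorAnnotation | None]]],
    cfg: SelectionConfig,
    seq: SequenceSpec,
) -> list[Period]:
    """Enumerate candidate error-free control periods.

    Every run of >= 7 consecutive correct trials yields a 7-trial candidate
    at each alignment; additionally, a run of >= 6 correct trials that closes
    its block yields one 6-trial candidate ending at the block's last trial
    (mirroring the 6-trial error periods admitted at block end).  The
    candidate's position is the within-block position of its 4th trial.
    """
    window = cfg.min_pre + 1 + cfg.min_post  # 7 with defaults
    end_window = cfg.min_pre + 1 + cfg.min_post_if_last  # 6 with defaults
    candidates: list[Period] = []
    for (subject, block), trials in sorted(parsed.items()):
        n = len(trials)
        # maximal runs of correct trials
        i = 0
        while i < n:
            if trials[i][0].kind != "correct":
                i += 1
                continue
            j = i
            while j < n and trials[j][0].kind == "correct":
                j += 1
            run = [t for t, _ in trials[i:j]]
            for s in range(0, len(run) - window + 1):
                w = run[s : s + window]
                candidates.append(
                    Period(
                        kind="control",
                        trials=tuple(w),
                        position=within_block_position(w[3].key_span[0], seq.k),
                        subject=subject,
                        block=block,
                    )
                )
            if j == n and len(run) >= end_window:
                w = run[-end_window:]
                candidates.append(
                    Period(
                        kind="control",
                        trials=tuple(w),
                        position=within_block_position(w[3].key_span[0], seq.k),
                        subject=subject,
                        block=block,
                    )
                )
            i = j
    return candidates


def enumerate_single_error_block_positions(
    seq: SequenceSpec,
    keys_per_block: int = 60,
    cfg: SelectionConfig | None = None,
    transition_ms: float = 300.0,
) -> list[int]:
    """Eligible error positions over all single-error blocks of a fixed size.

    Enumerates every block of ``keys_per_block`` keys consisting of ``p``
    correct leading trials, a single error run, and ``q`` correct trailing
    trials (the error length is whatever remains), runs the real parser,
    annotator, and eligibility rules on each, and returns the sorted set of
    within-block positions of the errors that survive.  Transition times are
    uniform and chosen so the duration filter passes for any error length.

    For the default task (60 keys, k = 5, >=3 correct trials before and
    after or 2 at block end, <= 20 keys) the result spans positions 4..10.
    """
    from .segmentation import parse_session  # local import avoids a cycle
    import pandas as pd

    cfg = cfg or SelectionConfig()
    k = seq.k
    positions: set[int] = set()
    max_trials = keys_per_block // k
    for p in range(0, max_trials + 1):
        for q in range(0, max_trials + 1):
            n_err = keys_per_block - k * (p + q)
            if n_err < 1:
                continue
            filler = min(c for c in sorted(seq.alphabet) if c != seq.codes[0])
            keys = list(seq.codes) * p + [filler] * n_err + list(seq.codes) * q
            onsets = [transition_ms * (i + 1) for i in range(len(keys))]
            df = pd.DataFrame(
                {"subject": "s", "block": 1, "key": keys, "onset_ms": onsets}
            )
            parsed = parse_session(df, seq)
            periods, _ = select_errors(parsed, cfg, seq)
            positions.update(pp.position for pp in periods)
    return sorted(positions)


def _center_id(p: Period) -> tuple[str, int, int]:
    return (p.subject, p.block, p.center.ordinal)


def _sorted_controls(controls: list[Period]) -> list[Period]:
    return sorted(controls, key=_center_id)


def match_positions(
    errors: list[Period],
    controls: list[Period],
    seed: int,
    forbidden_centers: set[tuple[str, int, int]] | None = None,
) -> MatchedPairSet:
    """Draw one position-matched control per error, without center reuse.

    For each error (in (block, ordinal) order) the candidates are the
    controls at the same within-block position whose center trial has not
    yet been used; one is chosen uniformly at random over the
    lexicographically ordered candidates.  Errors with no available control
    are excluded with reason.  Identical inputs and seed give identical
    output.
    """
    rng = np.random.default_rng(seed)
    used: set[tuple[str, int, int]] = set(forbidden_centers or set())
    pool = _sorted_controls(controls)
    pairs: list[tuple[Period, Period]] = []
    excluded: list[tuple[Period, str]] = []
    for err in sorted(errors, key=lambda p: (p.subject, p.block, p.center.ordinal)):
        avail = [
            c
            for c in pool
            if c.position == err.position
            and c.subject == err.subject
            and _center_id(c) not in used
        ]
        if not avail:
            excluded.append((err, "no positional match"))
            continue
        choice = avail[int(rng.integers(len(avail)))]
        used.add(_center_id(choice))
        pairs.append((err, choice))
    return MatchedPairSet(pairs=pairs, seed=seed, excluded=excluded)


def second_matched_set(
    set1: MatchedPairSet,
    controls: list[Period],
    seed2: int,
) -> tuple[MatchedPairSet, MatchedPairSet]:
    """Build a second, disjoint matched set over the same errors.

    Matching is re-run with set 1's control centers forbidden; errors that
    cannot be matched to a distinct control are dropped from *both* sets so
    the two sets cover the same errors.  Returns (pruned set 1, set 2).
    """
    errors = [e for e, _ in set1.pairs]
    set2 = match_positions(
        errors, controls, seed2, forbidden_centers=set1.control_center_ids()
    )
    matched2_ids = {_center_id(e) for e, _ in set2.pairs}
    kept_pairs = [
        (e, c) for e, c in set1.pairs if _center_id(e) in matched2_ids
    ]
    dropped = [
        (e, "no distinct control for set 2")
        for e, _ in set1.pairs
        if _center_id(e) not in matched2_ids
    ]
    set1_pruned = MatchedPairSet(
        pairs=kept_pairs, seed=set1.seed, excluded=set1.excluded + dropped
    )
    return set1_pruned, set2
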