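"""Segmentation of keypress streams into correct trials, errors, and
residual runs, plus per-error annotation.

The parse rule is a greedy left-to-right tiling: whenever the next k keys
match the target sequence a correct trial is emitted and the cursor advances
by k; otherwise the current key joins the running non-trial segment.  Maximal
non-trial runs *between* two correct trials become single error trials;
leading/trailing runs become residual trials (they lack a flanking correct
trial on one side and are excluded from error analyses but never dropped, so
trial spans always partition the block).

A consequence of greedy tiling is that an error's keys can never contain a
full sequence match — the scan would have claimed it as a correct trial.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import ErrorAnnotation, SequenceSpec, Trial, iter_blocks


def parse_block(
    keys,
    seq: SequenceSpec,
    times=None,
) -> list[Trial]:
    """Greedily segment one block's key stream into trials.

    Parameters
    ----------
    keys:
        Ordered key codes of the block (non-empty).
    seq:
        Target sequence.
    times:
        Optional onset times (ms) aligned with ``keys``.  When omitted,
        key indices are used as surrogate times.

    Returns
    -------
    list of :class:`~tapslip.core.Trial` whose key spans partition
    ``1..len(keys)``.
    """
    keys = tuple(int(k) for k in keys)
    if not keys:
        raise ValueError("empty key stream")
    if times is None:
        times = tuple(float(i) for i in range(len(keys)))
    else:
        times = tuple(float(t) for t in times)
        if len(times) != len(keys):
            raise ValueError("times and keys length mismatch")

    k = seq.k
    codes = seq.codes
    n = len(keys)

    segments: list[tuple[str, int, int]] = []  # (kind, start0, end0) inclusive
    run_start: int | None = None
    c = 0
    while c < n:
        if c + k <= n and keys[c : c + k] == codes:
            if run_start is not None:
                segments.append(("run", run_start, c - 1))
                run_start = None
            segments.append(("correct", c, c + k - 1))
            c += k
        else:
            if run_start is None:
                run_start = c
            c += 1
    if run_start is not None:
        segments.append(("run", run_start, n - 1))

    correct_idx = [i for i, s in enumerate(segments) if s[0] == "correct"]

    trials: list[Trial] = []
    for i, (kind, s0, e0) in enumerate(segments):
        if kind == "run":
            # a run is an error only when flanked by correct trials on both sides
            flanked = correct_idx and correct_idx[0] < i < correct_idx[-1]
            kind = "error" if flanked else "residual"
        trials.append(
            Trial(
                kind=kind,
                key_span=(s0 + 1, e0 + 1),
                ordinal=len(trials) + 1,
                onset_time=times[s0],
                offset_time=times[e0],
                keys=keys[s0 : e0 + 1],
                times=times[s0 : e0 + 1],
            )
        )
    return trials


def annotate_error(
    error_keys,
    seq: SequenceSpec,
    timestamps,
    t_prev: float,
    t_next: float,
    next_trial_first_key: int | None = None,
) -> ErrorAnnotation:
    """Annotate one error: type, first wrong key, restart attempts, duration.

    The first wrong key is located by prefix matching: the longest leading
    run of ``error_keys`` that equals a prefix of the sequence counts as
    correct keys; the next key is the first wrong one.  If the whole error is
    a correct prefix, the error has no wrong key: it is an incomplete
    sequence (prefix of <= 3 correct keys) or a one-missing-key error
    (exactly 4, i.e. exactly one key short of a correct trial).

    Restart attempts are occurrences of the sequence's first transition
    (4->1 for the default task) among consecutive error-key pairs; the
    bridge pair formed by the error's last key and the first key of the
    following correct trial is checked against the same transition.

    Duration is ``t_next - t_prev``: the window from the last key of the
    preceding correct trial to the first key of the following one, spanning
    the onset and offset transitions.
    """
    error_keys = tuple(int(x) for x in error_keys)
    timestamps = tuple(float(t) for t in timestamps)
    if not error_keys:
        raise ValueError("empty error")
    if len(error_keys) != len(timestamps):
        raise ValueError("timestamps length mismatch")
    if not (t_prev < timestamps[0] and t_next > timestamps[-1]):
        raise ValueError("t_prev/t_next must bracket the error timestamps")
    if error_keys == seq.codes:
        raise ValueError("error equal to the full sequence is impossible after greedy parse")

    codes = seq.codes
    m = 0
    while m < len(error_keys) and m < seq.k and error_keys[m] == codes[m]:
        m += 1

    first_transition = (codes[0], codes[1])
    n_restarts = sum(
        1
        for a, b in zip(error_keys, error_keys[1:])
        if (a, b) == first_transition
    )
    if (
        next_trial_first_key is not None
        and (error_keys[-1], next_trial_first_key) == first_transition
    ):
        n_restarts += 1

    duration = t_next - t_prev

    if m == len(error_keys):
        # whole error is a correct prefix: no wrong key was pressed
        etype = "missing_one_key" if m == seq.k - 1 else "incomplete_sequence"
        return ErrorAnnotation(
            error_type=etype,
            first_wrong_ordinal=None,
            n_before=m,
            n_after=0,
            length_keys=len(error_keys),
            duration=duration,
            n_restart_attempts=n_restarts,
        )
    return ErrorAnnotation(
        error_type="wrong_key",
        first_wrong_ordinal=m + 1,
        n_before=m,
        n_after=len(error_keys) - m - 1,
        length_keys=len(error_keys),
        duration=duration,
        n_restart_attempts=n_restarts,
    )


def transition_times(
    trial: Trial,
    prev_key_time: float | None = None,
    next_key_time: float | None = None,
) -> dict:
    """Within-trial, onset, and offset transition durations (ms) of a trial.

    ``within`` holds successive differences of the trial's key times (k-1
    values for a correct trial, none for a single-key error); ``onset`` is
    the transition into the trial's first key from the preceding key of the
    block, ``offset`` the transition out of its last key.  Transitions
    without a flanking key are ``None`` (absent), never zero — the first
    trial of a block has no onset transition.
    """
    t = np.asarray(trial.times, dtype=float)
    within = tuple(np.diff(t)) if len(t) > 1 else ()
    onset = None if prev_key_time is None else float(t[0] - prev_key_time)
    offset = None if next_key_time is None else float(next_key_time - t[-1])
    return {"within": within, "onset": onset, "offset": offset}


def _annotate_parsed(trials: list[Trial], seq: SequenceSpec):
    """Pair each trial with its ErrorAnnotation (None for non-errors)."""
    out: list[tuple[Trial, ErrorAnnotation | None]] = []
    for i, tr in enumerate(trials):
        if tr.kind != "error":
            out.append((tr, None))
            continue
        t_prev = trials[i - 1].times[-1]
        t_next = trials[i + 1].times[0]
        nxt_key = trials[i + 1].keys[0]
        ann = annotate_error(
            tr.keys, seq, tr.times, t_prev=t_prev, t_next=t_next,
            next_trial_first_key=nxt_key,
        )
        out.append((tr, ann))
    return out


def parse_session(
    df: pd.DataFrame, seq: SequenceSpec
) -> dict[tuple[str, int], list[tuple[Trial, ErrorAnnotation | None]]]:
    """Parse and annotate every (subject, block) of a keypress table.

    Returns a mapping ``(subject, block) -> [(Trial, annotation-or-None)]``.
    """
    out = {}
    for (subj, block), keys, onsets in iter_blocks(df):
        trials = parse_block(keys, seq, times=onsets)
        out[(subj, block)] = _annotate_parsed(trials, seq)
    return out
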