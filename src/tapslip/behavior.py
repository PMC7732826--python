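"""Block-normalized slowing metrics and group-level statistics.

Speed is measured as the transition duration between consecutive keypresses.
Every duration is expressed as percent deviation from the block's reference
speed — the mean of the four within-sequence transitions over all correct
trials of that block — so 0% means block-typical speed and +100% means twice
the block-typical transition duration.  The normalization makes all slowing
metrics invariant to a rescaling of a block's timebase.

Group statistics follow a two-stage summary flow: measures are aggregated
within subject first (errors weighted equally), then tested across subjects
with one-sample/paired t tests or a repeated-measures ANOVA with
Greenhouse-Geisser correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ErrorAnnotation, Period, Trial
from .selection import MatchedPairSet

TRIAL_ROLES = ("PreE2", "PreE1", "error", "PostE1", "PostE2")
PHASES = ("onset", "within_pre", "within_post", "offset")


@dataclass
class SlowingProfile:
    """Slowing (%) of one error period, by phase and by trial role.

    Phases with no constituent transition (e.g. ``within_pre`` for an error
    whose first key is already wrong) are ``None`` — absent, not zero.
    """

    block_reference: float  # ms
    phases: dict  # phase name -> % or None
    trials: dict  # role -> % or None


@dataclass
class GroupStat:
    """One group-level test result."""

    name: str  # "t" or "F"
    statistic: float | None
    dof: tuple[float, ...]
    p: float | None
    direction: int | None = None  # sign of the effect
    correction: str = "none"
    epsilon: float | None = None
    note: str = ""


def block_reference(trials: list[Trial]) -> float | None:
    """Mean within-trial transition duration (ms) over a block's correct
    trials; ``None`` when the block has no correct trial."""
    diffs: list[float] = []
    for t in trials:
        if t.kind != "correct":
            continue
        diffs.extend(np.diff(t.times))
    if not diffs:
        return None
    return float(np.mean(diffs))


def block_references(parsed) -> dict:
    """Per-(subject, block) reference speeds from a parsed session."""
    return {
        key: block_reference([t for t, _ in trs]) for key, trs in parsed.items()
    }


def slowing(duration, reference: float | None):
    """Percent slowing of a transition relative to the block reference:
    ``100 * (duration - reference) / reference``.  Absent reference or
    duration propagates as ``None``."""
    if reference is None or duration is None:
        return None
    if reference <= 0:
        raise ValueError("reference must be positive")
    return 100.0 * (np.asarray(duration, dtype=float) - reference) / reference


def _trial_slowing(trial: Trial, reference: float) -> float:
    """Mean slowing of a correct trial's within-sequence transitions."""
    return float(np.mean(slowing(np.diff(trial.times), reference)))


def error_phase_profile(period: Period, reference: float) -> SlowingProfile:
    """Phase-resolved slowing of one error period.

    * ``onset``: transition from the last key of PreE1 into the first error
      key; ``offset``: transition from the last error key into PostE1.
    * ``within_pre`` / ``within_post``: mean slowing of transitions among
      error keys strictly before / after the first wrong key.  Transitions
      touching the first wrong key itself belong to neither bin; errors with
      no wrong key (incomplete sequences) put all their internal transitions
      in ``within_pre``.
    * trial roles PreE2..PostE2 carry the mean slowing of each flanking
      correct trial's four within-sequence transitions; the ``error`` role
      is the mean over all error transitions (onset + within + offset), the
      quantity summarized as "slowing within the error".
    """
    if period.kind != "error":
        raise ValueError("error_phase_profile needs an error period")
    err = period.center
    ann = period.annotation
    assert ann is not None
    pre1 = period.trials[2]
    post1 = period.trials[4]

    onset = float(slowing(err.times[0] - pre1.times[-1], reference))
    offset = float(slowing(post1.times[0] - err.times[-1], reference))

    within = np.diff(err.times)  # transition j is between keys j+1 and j+2
    fwo = ann.first_wrong_ordinal
    if fwo is None:
        pre_tr = within
        post_tr = within[:0]
    else:
        # pair (j, j+1) in 1-based key ordinals; both strictly before/after fwo
        pre_tr = within[: max(fwo - 2, 0)]
        post_tr = within[fwo:]
    within_pre = float(np.mean(slowing(pre_tr, reference))) if len(pre_tr) else None
    within_post = float(np.mean(slowing(post_tr, reference))) if len(post_tr) else None

    error_level = float(
        np.mean(slowing(np.concatenate([[err.times[0] - pre1.times[-1]], within,
                                        [post1.times[0] - err.times[-1]]]), reference))
    )

    trials = {
        "PreE2": _trial_slowing(period.trials[1], reference),
        "PreE1": _trial_slowing(pre1, reference),
        "error": error_level,
        "PostE1": _trial_slowing(post1, reference),
        "PostE2": _trial_slowing(period.trials[5], reference)
        if len(period.trials) == 7
        else None,
    }
    phases = {
        "onset": onset,
        "within_pre": within_pre,
        "within_post": within_post,
        "offset": offset,
    }
    return SlowingProfile(block_reference=reference, phases=phases, trials=trials)


def control_profile(period: Period, reference: float) -> dict:
    """Trial-role slowing of a control period (all trials correct)."""
    roles = {}
    for role, idx in zip(TRIAL_ROLES, (1, 2, 3, 4, 5)):
        if idx < len(period.trials):
            roles[role] = _trial_slowing(period.trials[idx], reference)
        else:
            roles[role] = None
    return roles


def period_profile(pairs: MatchedPairSet, references: dict) -> pd.DataFrame:
    """Per-subject trial-wise slowing for error and control periods.

    Returns one row per (subject, condition) with columns PreE2..PostE2 and,
    for the error condition, the phase means.  Errors are weighted equally
    within subject; subjects with no pairs are absent.
    """
    rows: dict[tuple[str, str], list[dict]] = {}
    for err, ctl in pairs.pairs:
        ref_e = references.get((err.subject, err.block))
        ref_c = references.get((ctl.subject, ctl.block))
        if ref_e is None or ref_c is None:
            continue
        prof = error_phase_profile(err, ref_e)
        rows.setdefault((err.subject, "error"), []).append(
            {**prof.trials, **prof.phases}
        )
        rows.setdefault((ctl.subject, "control"), []).append(
            control_profile(ctl, ref_c)
        )
    out = []
    for (subject, cond), recs in sorted(rows.items()):
        df = pd.DataFrame(recs)
        agg = df.mean(skipna=True).to_dict()
        out.append({"subject": subject, "condition": cond, "n_periods": len(recs), **agg})
    return pd.DataFrame(out)


def block_initiation_slowing(parsed, references: dict) -> pd.DataFrame:
    """Slowing (%) of the first correct trial of each block — the speed cost
    of (re)starting the sequence after rest."""
    rows = []
    for (subject, block), trials in sorted(parsed.items()):
        ref = references.get((subject, block))
        if ref is None:
            continue
        first = next((t for t, _ in trials if t.kind == "correct"), None)
        if first is None:
            continue
        rows.append(
            {
                "subject": subject,
                "block": block,
                "initiation_slowing": _trial_slowing(first, ref),
            }
        )
    return pd.DataFrame(rows)


def one_sample_t(values, popmean: float = 0.0) -> GroupStat:
    """Two-tailed one-sample t test against ``popmean``."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    n = len(x)
    if n < 2:
        return GroupStat("t", None, (max(n - 1, 0),), None, note="n < 2")
    if np.allclose(x, x[0]):
        if x[0] == popmean:
            return GroupStat("t", 0.0, (n - 1,), 1.0, direction=0)
        return GroupStat("t", None, (n - 1,), None, note="zero variance")
    res = stats.ttest_1samp(x, popmean)
    return GroupStat(
        "t",
        float(res.statistic),
        (n - 1,),
        float(res.pvalue),
        direction=int(np.sign(res.statistic)),
    )


def paired_t(a, b) -> GroupStat:
    """Two-tailed paired t test (a vs b), pairwise-complete."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    keep = ~(np.isnan(a) | np.isnan(b))
    return one_sample_t(a[keep] - b[keep], 0.0)


def gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the sample covariance of conditions.

    ``data`` is subjects x conditions.  Epsilon is computed from the
    double-centered covariance matrix; it equals 1 exactly for 2-level
    designs and is bounded below by 1/(k-1).
    """
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    S = np.cov(data, rowvar=False)
    row = S.mean(axis=0, keepdims=True)
    grand = S.mean()
    Sc = S - row - row.T + grand
    tr = np.trace(Sc)
    denom = (k - 1) * np.sum(Sc**2)
    if denom <= 0:
        return 1.0
    return float(tr**2 / denom)


def rm_anova(data) -> GroupStat:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser correction.

    ``data`` is subjects x conditions (complete cases only).  The F ratio is
    MS(condition) / MS(condition x subject); the p value uses GG-adjusted
    degrees of freedom ``eps*(k-1), eps*(k-1)(n-1)``.
    """
    data = np.asarray(data, dtype=float)
    data = data[~np.isnan(data).any(axis=1)]
    n, k = data.shape
    if n < 2 or k < 2:
        return GroupStat("F", None, (0, 0), None, note="need >= 2 subjects and conditions")
    grand = data.mean()
    subj_means = data.mean(axis=1)
    cond_means = data.mean(axis=0)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_tot = np.sum((data - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (k - 1) * (n - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    if ms_err <= 0:
        return GroupStat("F", None, (df_cond, df_err), None, note="zero error variance")
    eps = gg_epsilon(data)
    F = ms_cond / ms_err
    p = float(stats.f.sf(F, eps * df_cond, eps * df_err))
    return GroupStat(
        "F",
        float(F),
        (eps * df_cond, eps * df_err),
        p,
        correction="Greenhouse-Geisser",
        epsilon=eps,
    )
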