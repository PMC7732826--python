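"""Synthetic keypress sessions and BOLD series with known ground truth.

The behavioral generator emulates continuous self-paced tapping of the
default 5-key sequence: blocks end after exactly ``keys_per_block`` presses
(a trailing partial sequence becomes a residual tail, as in real data),
inter-press intervals are log-normal (positive, right-skewed), speed drifts
mildly across blocks, and scheduled errors are inserted with their type's
key pattern and phase-specific slowing multipliers (error onset/within/
offset, pre-error, post-error, block initiation).

The BOLD generator synthesizes the signal the mixed block/event GLM assumes
— sustained block activity, GO transients, per-trial transients with
role-specific deltas at error-period trials — at a 10x finer time grid than
the analysis microtime, then adds AR(1) noise and a sinusoidal drift, so the
generator and the fitter share neither time base nor drift basis.

Every generator returns a ``truth`` dict sufficient to score any stage's
output without re-simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .core import BlockLayout, PAPER_LAYOUT, PAPER_SEQUENCE, SequenceSpec
from .glm import AcquisitionSpec, HrfSpec, canonical_hrf

# default error-type mix: wrong-key errors at each possible ordinal of the
# first wrong key, plus incomplete sequences (1..3 correct prefix keys).
DEFAULT_TYPE_MIX = {
    ("wrong_key", 1): 0.20,
    ("wrong_key", 2): 0.15,
    ("wrong_key", 3): 0.15,
    ("wrong_key", 4): 0.15,
    ("wrong_key", 5): 0.15,
    ("incomplete", 1): 0.05,
    ("incomplete", 2): 0.05,
    ("incomplete", 3): 0.10,
}


@dataclass
class BehaviorGenSpec:
    """World parameters of the behavioral generator.

    Defaults mirror the task this package analyzes: 14 blocks x 60 keys of
    the 4-1-3-2-4 sequence, ~0.3 errors per block (about 4 per session, the
    observed per-subject average), 250-ms median transitions, error-phase
    slowing x1.5 and post-error slowing x1.1 (the package's stated recovery
    targets of +50% and +10%).
    """

    n_subjects: int = 54
    layout: BlockLayout = PAPER_LAYOUT
    seq: SequenceSpec = PAPER_SEQUENCE
    base_mean: float = 250.0  # ms
    base_sd: float = 50.0  # ms
    block_drift: float = 0.005  # fractional slowdown per block
    error_rate: float = 0.3  # P(one error) per block
    schedule: list | None = None  # explicit [(subject_idx, block, n_pre, type, ordinal)]
    type_mix: dict = field(default_factory=lambda: dict(DEFAULT_TYPE_MIX))
    mult_pre: float = 1.0
    mult_onset: float = 1.5
    mult_within: float = 1.5
    mult_offset: float = 1.5
    mult_post_e1: float = 1.1
    mult_initiation: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for m in (
            self.mult_pre, self.mult_onset, self.mult_within,
            self.mult_offset, self.mult_post_e1, self.mult_initiation,
        ):
            if m <= 0:
                raise ValueError("multipliers must be positive")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")


def _error_keys(seq: SequenceSpec, etype: str, ordinal: int) -> tuple[int, ...]:
    """Key pattern of one scheduled error.

    ``wrong_key`` at ordinal o: o-1 correct prefix keys then one wrong key
    (never the expected key, and never the sequence's first key at o=1, so
    the greedy parse keeps the error intact).  ``incomplete``: a bare
    correct prefix of ``ordinal`` (< k-1) keys.
    """
    codes = seq.codes
    if etype == "wrong_key":
        expected = codes[ordinal - 1]
        forbidden = {expected}
        if ordinal == 1:
            forbidden.add(codes[0])
        wrong = min(k for k in sorted(seq.alphabet) if k not in forbidden)
        return codes[: ordinal - 1] + (wrong,)
    if etype == "incomplete":
        if ordinal >= seq.k - 1:
            raise ValueError("incomplete prefix must be shorter than k-1")
        return codes[:ordinal]
    raise ValueError(f"unknown error type {etype!r}")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    cv2 = (sd / mean) ** 2
    sig2 = math.log1p(cv2)
    mu = math.log(mean) - sig2 / 2.0
    return mu, math.sqrt(sig2)


def _sample_type(rng: np.random.Generator, mix: dict):
    items = sorted(mix.items())
    weights = np.array([w for _, w in items], dtype=float)
    weights = weights / weights.sum()
    j = rng.choice(len(items), p=weights)
    return items[j][0]


def gen_behavior(spec: BehaviorGenSpec) -> tuple[pd.DataFrame, dict]:
    """Generate a keypress log for ``spec.n_subjects`` subjects.

    Returns (keypress table, truth).  ``truth`` records the spec's
    parameters, per-subject block onsets (s), and every scheduled error
    (block, preceding correct trials, within-block position, type, first
    wrong ordinal, key span in the emitted stream).
    """
    rng = np.random.default_rng(spec.seed)
    mu, sig = _lognormal_params(spec.base_mean, spec.base_sd)
    k = spec.seq.k
    rows = []
    truth_errors = []
    block_onsets_s: dict[str, list[float]] = {}

    explicit = {}
    if spec.schedule is not None:
        for entry in spec.schedule:
            s_idx, block, n_pre, etype, ordinal = entry
            explicit.setdefault((s_idx, block), []).append((n_pre, etype, ordinal))
            if len(explicit[(s_idx, block)]) > 1:
                raise ValueError(
                    f"schedule places multiple errors in subject {s_idx} block {block}: "
                    f"{explicit[(s_idx, block)]}"
                )

    for s_idx in range(spec.n_subjects):
        subject = f"sub{s_idx + 1:02d}"
        t_ms = 0.0
        onsets = []
        for block in range(1, spec.layout.n_blocks + 1):
            block_mult = 1.0 + spec.block_drift * (block - 1)
            onsets.append(t_ms / 1000.0)

            # plan the block: (key, multiplier for the transition into it)
            if spec.schedule is not None:
                plan_err = explicit.get((s_idx, block), [None])[0]
            elif rng.random() < spec.error_rate:
                n_pre = int(rng.integers(3, 8))  # eligible placements
                etype, ordinal = _sample_type(rng, spec.type_mix)
                plan_err = (n_pre, etype, ordinal)
            else:
                plan_err = None

            keys: list[int] = []
            mults: list[float] = []

            def _emit_correct(trial_idx: int, is_first: bool, is_pre: bool, is_post: bool):
                within = spec.mult_initiation if is_first else (
                    spec.mult_pre if is_pre else (
                        spec.mult_post_e1 if is_post else 1.0))
                for j, code in enumerate(spec.seq.codes):
                    keys.append(code)
                    mults.append(1.0 if j == 0 else within)

            trial_idx = 0
            err_span = None
            while len(keys) < spec.layout.keys_per_block:
                if plan_err is not None and trial_idx == plan_err[0]:
                    n_pre, etype, ordinal = plan_err
                    ekeys = _error_keys(spec.seq, etype, ordinal)
                    start = len(keys) + 1
                    for j, code in enumerate(ekeys):
                        keys.append(code)
                        mults.append(spec.mult_onset if j == 0 else spec.mult_within)
                    err_span = (start, len(keys))
                    plan_err = ("done", etype, ordinal, n_pre)
                    continue
                is_post_error = (
                    plan_err is not None
                    and plan_err[0] == "done"
                    and err_span is not None
                    and len(keys) == err_span[1]
                )
                is_pre_error = (
                    plan_err is not None
                    and plan_err[0] != "done"
                    and trial_idx == plan_err[0] - 1
                )
                _emit_correct(trial_idx, trial_idx == 0, is_pre_error, is_post_error)
                if is_post_error:
                    mults[err_span[1]] = spec.mult_offset  # transition out of error
                trial_idx += 1

            keys = keys[: spec.layout.keys_per_block]
            mults = mults[: spec.layout.keys_per_block]

            durs = np.exp(rng.normal(mu, sig, size=len(keys))) * block_mult
            durs *= np.asarray(mults)
            times = t_ms + np.cumsum(durs)
            for key, onset in zip(keys, times):
                rows.append((subject, block, key, float(onset)))
            t_ms = times[-1] + spec.layout.rest_duration * 1000.0

            if err_span is not None and err_span[1] <= spec.layout.keys_per_block:
                _, etype, ordinal, n_pre = plan_err
                truth_errors.append(
                    {
                        "subject": subject,
                        "block": block,
                        "n_pre_correct": n_pre,
                        "position": n_pre + 1,
                        "error_type": etype,
                        "first_wrong_ordinal": ordinal if etype == "wrong_key" else None,
                        "key_span": err_span,
                    }
                )
        block_onsets_s[subject] = onsets

    df = pd.DataFrame(rows, columns=["subject", "block", "key", "onset_ms"])
    truth = {
        "kind": "behavior",
        "seed": spec.seed,
        "params": {
            "n_subjects": spec.n_subjects,
            "base_mean": spec.base_mean,
            "base_sd": spec.base_sd,
            "block_drift": spec.block_drift,
            "error_rate": spec.error_rate,
            "mult_pre": spec.mult_pre,
            "mult_onset": spec.mult_onset,
            "mult_within": spec.mult_within,
            "mult_offset": spec.mult_offset,
            "mult_post_e1": spec.mult_post_e1,
            "mult_initiation": spec.mult_initiation,
        },
        "block_onsets_s": block_onsets_s,
        "errors": truth_errors,
    }
    return df, truth


@dataclass
class BoldGenSpec:
    """World parameters of the BOLD generator.

    Amplitudes are in arbitrary BOLD units: every correct trial emits a
    transient of ``beta_trial``; trials inside an error period additionally
    carry their role's delta (default: instantaneous +1 at the error,
    delayed -1 at PostE1/PostE2 — the accumbens-like pattern the pipeline
    must recover).  Noise is AR(1) with coefficient ``phi`` plus a
    sinusoidal drift slower than the analysis high-pass cutoff.
    """

    acq: AcquisitionSpec = AcquisitionSpec()
    beta_block: float = 1.0
    beta_go: float = 1.0
    beta_trial: float = 0.5
    role_deltas: dict = field(
        default_factory=lambda: {
            "PreE2": 0.0, "PreE1": 0.0, "E": 1.0, "PostE1": -1.0, "PostE2": -1.0,
        }
    )
    phi: float = 0.3
    noise_sd: float = 1.0
    drift_amplitude: float = 1.0
    drift_period: float = 250.0  # s
    spatial_profile: tuple[float, ...] = (1.0,)
    fine_oversampling: int = 10  # relative to the analysis microtime
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 < self.phi < 1.0:
            raise ValueError("|phi| must be < 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def n_scans_for(duration_s: float, tr: float, pad_s: float = 20.0) -> int:
    """Scans needed to cover a session plus a post-stimulus pad."""
    return int(math.ceil((duration_s + pad_s) / tr))


def gen_bold(
    parsed_subject,
    pairs_subject,
    spec: BoldGenSpec,
) -> tuple[np.ndarray, dict]:
    """Synthesize BOLD series for one subject's parsed session.

    ``parsed_subject`` maps (subject, block) -> [(Trial, annotation)];
    ``pairs_subject`` is the subject's matched pair set (role deltas apply to
    the error periods' trials).  Returns (n_scans x n_series array, truth).
    """
    acq = spec.acq
    rng = np.random.default_rng(spec.seed)
    fine = acq.microtime_bins * spec.fine_oversampling
    dt = acq.tr / fine
    n_fine = acq.n_scans * fine
    kernel = canonical_hrf(dt, HrfSpec())

    u = np.zeros(n_fine)

    def _add(onset_s: float, amplitude: float, duration_s: float = 0.0) -> None:
        # onsets are quantized to the analysis microtime grid (events are
        # time-locked there); synthesis still runs on the 10x finer grid
        dt_micro = acq.tr / acq.microtime_bins
        i0 = int(round(onset_s / dt_micro)) * spec.fine_oversampling
        if i0 >= n_fine or i0 < 0:
            raise ValueError(f"event at {onset_s:.1f}s outside the scanned interval")
        if duration_s <= 0:
            u[i0] += amplitude
        else:
            # trapezoid-integrated epoch: grid-independent plateau height
            i1 = min(int(round((onset_s + duration_s) / dt)), n_fine - 1)
            i1 = max(i1, i0 + 1)
            u[i0] += amplitude * dt / 2.0
            u[i0 + 1 : i1] += amplitude * dt
            u[i1] += amplitude * dt / 2.0

    # role deltas at error-period trials
    delta_at: dict[tuple[int, int], float] = {}  # (block, first key index) -> delta
    role_idx = {"PreE2": 1, "PreE1": 2, "E": 3, "PostE1": 4, "PostE2": 5}
    for err, _ctl in pairs_subject.pairs:
        for role, idx in role_idx.items():
            if idx < len(err.trials):
                tr = err.trials[idx]
                delta_at[(err.block, tr.key_span[0])] = spec.role_deltas.get(role, 0.0)

    for (subject, block), trials in sorted(parsed_subject.items()):
        t_first = trials[0][0].times[0] / 1000.0
        t_last = trials[-1][0].times[-1] / 1000.0
        _add(t_first, spec.beta_go)
        _add(t_first, spec.beta_block, duration_s=t_last - t_first)
        for tr, _ann in trials:
            if tr.kind == "residual":
                continue
            amp = spec.beta_trial + delta_at.get((block, tr.key_span[0]), 0.0)
            _add(tr.times[0] / 1000.0, amp)

    clean_fine = np.convolve(u, kernel)[:n_fine]
    clean = clean_fine[::fine]

    t_scan = np.arange(acq.n_scans) * acq.tr
    drift = spec.drift_amplitude * np.sin(2 * np.pi * t_scan / spec.drift_period)

    n_series = len(spec.spatial_profile)
    Y = np.empty((acq.n_scans, n_series))
    for j, w in enumerate(spec.spatial_profile):
        eps = rng.normal(0.0, spec.noise_sd, size=acq.n_scans)
        ar = lfilter([1.0], [1.0, -spec.phi], eps)
        Y[:, j] = w * clean + drift + ar

    truth = {
        "kind": "bold",
        "seed": spec.seed,
        "betas": {
            "block": spec.beta_block,
            "go": spec.beta_go,
            "trial": spec.beta_trial,
            "role_deltas": dict(spec.role_deltas),
        },
        "phi": spec.phi,
        "noise_sd": spec.noise_sd,
        "drift": {"amplitude": spec.drift_amplitude, "period": spec.drift_period},
        "spatial_profile": list(spec.spatial_profile),
        "clean": clean,
    }
    return Y, truth


FIXTURES = ("tiny-session", "one-error-block", "paper-layout")


def make_fixture(name: str, seed: int = 0):
    """Deterministic small datasets used by the tests and docs.

    * ``tiny-session``: 1 subject, 3 blocks of 30 keys, error-prone.
    * ``one-error-block``: 1 subject, one 60-key block with a single
      eligible error at within-block position 6.
    * ``paper-layout``: 2 subjects under the default 14 x 60 layout.

    Returns (keypress table, truth, BehaviorGenSpec).
    """
    if name == "tiny-session":
        spec = BehaviorGenSpec(
            n_subjects=1,
            layout=BlockLayout(n_blocks=3, keys_per_block=30, rest_duration=15.0),
            error_rate=0.5,
            seed=seed,
        )
    elif name == "one-error-block":
        spec = BehaviorGenSpec(
            n_subjects=1,
            layout=BlockLayout(n_blocks=1, keys_per_block=60, rest_duration=15.0),
            schedule=[(0, 1, 5, "wrong_key", 3)],
            seed=seed,
        )
    elif name == "paper-layout":
        spec = BehaviorGenSpec(n_subjects=2, seed=seed)
    else:
        raise ValueError(f"unknown fixture {name!r}; available: {FIXTURES}")
    df, truth = gen_behavior(spec)
    return df, truth, spec
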