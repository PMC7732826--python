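"""Mixed block/event-related GLM with AR(1) prewhitening.

The first-level model follows the mixed design used for continuous tapping
tasks: a boxcar spanning each performance block captures sustained activity,
stick (zero-duration) regressors time-locked to trial onsets capture
trial-wise transients, and a stick at each block onset absorbs the GO-cue
transient.  All task regressors are convolved with a canonical double-gamma
hemodynamic response; low-frequency drift is absorbed by a discrete-cosine
high-pass basis (cutoff 128 s by default) included as nuisance columns, and
motion parameters enter unconvolved.

Because stick regressors of adjacent trials are nearly collinear after HRF
convolution, each modeled trial role gets its own model (the separate-models
scheme): one model per within-block trial ordinal for errorless blocks, and
one per error-period role (PreE2, PreE1, E, PostE1, PostE2), the latter also
carrying the regressor of the position-matched control trials so the
error-vs-control contrast is estimated within one model.

Serial correlation is handled by two-pass prewhitening: an OLS fit, a pooled
lag-1 residual autocorrelation estimate (AR(1) + white noise model class),
then a refit on AR(1)-whitened data and design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .behavior import GroupStat, one_sample_t, rm_anova
from .selection import MatchedPairSet

ERROR_ROLES = ("PreE2", "PreE1", "E", "PostE1", "PostE2")
_ROLE_TRIAL_INDEX = {"PreE2": 1, "PreE1": 2, "E": 3, "PostE1": 4, "PostE2": 5}


@dataclass(frozen=True)
class AcquisitionSpec:
    """Scan timing: TR (s), number of scans, microtime resolution, and
    high-pass cutoff (s)."""

    tr: float = 2.65
    n_scans: int = 200
    microtime_bins: int = 16
    highpass_cutoff: float = 128.0

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        if self.highpass_cutoff <= 2 * self.tr:
            raise ValueError("high-pass cutoff must exceed 2*TR")

    @property
    def duration(self) -> float:
        return self.tr * self.n_scans


@dataclass(frozen=True)
class HrfSpec:
    """Canonical double-gamma HRF parameters (SPM-style defaults): response
    peak at 6 s, undershoot at 16 s, unit dispersions, response:undershoot
    amplitude ratio 6, 32-s support."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    ratio: float = 6.0
    length: float = 32.0


@dataclass
class ModelSpec:
    """One first-level model: block epochs, GO sticks, and the modeled event
    regressors (name -> (onsets s, durations s))."""

    model_id: str
    block_onsets: np.ndarray
    block_durations: np.ndarray
    events: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    go_onsets: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.events) != len(set(self.events)):
            raise ValueError("regressor labels must be unique")


@dataclass
class DesignMatrix:
    X: np.ndarray  # n_scans x p
    names: list[str]

    def column(self, name: str) -> int:
        return self.names.index(name)

    @property
    def shape(self):
        return self.X.shape


@dataclass
class GLMFit:
    beta: np.ndarray  # p x n_series
    sigma2: np.ndarray  # n_series
    phi: float
    dof: float
    names: list[str]
    Xw: np.ndarray  # whitened design

    def beta_named(self, name: str) -> np.ndarray:
        return self.beta[self.names.index(name)]


@dataclass(frozen=True)
class RoiSpec:
    """A spherical ROI: center in mm (volume frame) and radius in mm
    (6 mm default; 4 mm for basal-ganglia/thalamus ROIs)."""

    name: str
    center: tuple[float, float, float]
    radius: float = 6.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")


def canonical_hrf(dt: float, spec: HrfSpec = HrfSpec()) -> np.ndarray:
    """Sample the double-gamma HRF on [0, length) at step ``dt``, normalized
    to unit peak.  The kernel is zero at t = 0."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, spec.length, dt)
    peak = stats.gamma.pdf(t, spec.peak_delay / spec.peak_dispersion,
                           scale=spec.peak_dispersion)
    under = stats.gamma.pdf(t, spec.undershoot_delay / spec.undershoot_dispersion,
                            scale=spec.undershoot_dispersion)
    h = peak - under / spec.ratio
    return h / np.max(np.abs(h))


def dct_highpass_basis(n_scans: int, tr: float, cutoff: float) -> np.ndarray:
    """Discrete-cosine drift basis up to the cutoff period (constant term
    excluded; the intercept is a separate column)."""
    order = int(np.floor(2.0 * n_scans * tr / cutoff))
    n = np.arange(n_scans)
    cols = [
        np.sqrt(2.0 / n_scans) * np.cos(np.pi * (2 * n + 1) * r / (2 * n_scans))
        for r in range(1, order + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n_scans, 0))


def _convolved_column(
    onsets, durations, acq: AcquisitionSpec, kernel: np.ndarray
) -> np.ndarray:
    """Build one task regressor: impulse/boxcar train at microtime
    resolution, convolved with the HRF, sampled at scan times."""
    dt = acq.tr / acq.microtime_bins
    n_fine = acq.n_scans * acq.microtime_bins
    u = np.zeros(n_fine)
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    durations = np.atleast_1d(np.asarray(durations, dtype=float))
    if durations.size == 1:
        durations = np.full(onsets.shape, durations[0])
    # sticks carry unit mass (a Dirac: the column is the shifted kernel);
    # epochs approximate the continuous convolution, so bins carry height*dt
    for onset, dur in zip(onsets, durations):
        if onset < 0 or onset > acq.duration:
            raise ValueError(f"event at {onset:.2f}s outside the scanned interval")
        i0 = int(round(onset / dt))
        if dur <= 0:
            if i0 < n_fine:
                u[i0] += 1.0
        else:
            # trapezoid-rule integration of the epoch (half-weight endpoints)
            i1 = min(int(round((onset + dur) / dt)), n_fine - 1)
            i1 = max(i1, i0 + 1)
            u[i0] += dt / 2.0
            u[i0 + 1 : i1] += dt
            u[i1] += dt / 2.0
    conv = np.convolve(u, kernel)[:n_fine]
    return conv[:: acq.microtime_bins]


def build_design(
    model: ModelSpec,
    acq: AcquisitionSpec,
    hrf: HrfSpec = HrfSpec(),
    motion: np.ndarray | None = None,
) -> DesignMatrix:
    """Assemble the design matrix for one model.

    Column order: block boxcar, GO sticks, event regressors (all convolved),
    then DCT drift columns and motion parameters (unconvolved), intercept
    last.
    """
    dt = acq.tr / acq.microtime_bins
    kernel = canonical_hrf(dt, hrf)
    cols = [
        _convolved_column(model.block_onsets, model.block_durations, acq, kernel)
    ]
    names = ["block"]
    if model.go_onsets is not None and len(model.go_onsets):
        cols.append(_convolved_column(model.go_onsets, 0.0, acq, kernel))
        names.append("go")
    for name, (onsets, durations) in model.events.items():
        cols.append(_convolved_column(onsets, durations, acq, kernel))
        names.append(name)
    dct = dct_highpass_basis(acq.n_scans, acq.tr, acq.highpass_cutoff)
    for r in range(dct.shape[1]):
        cols.append(dct[:, r])
        names.append(f"dct{r + 1}")
    if motion is not None:
        motion = np.atleast_2d(np.asarray(motion, dtype=float))
        if motion.shape[0] != acq.n_scans:
            raise ValueError("motion parameters must have n_scans rows")
        for j in range(motion.shape[1]):
            cols.append(motion[:, j] - motion[:, j].mean())
            names.append(f"motion{j + 1}")
    cols.append(np.ones(acq.n_scans))
    names.append("intercept")
    return DesignMatrix(X=np.column_stack(cols), names=names)


def generate_model_suite(
    parsed,
    pairs: MatchedPairSet,
    trials_per_block: int,
    onset_policy: str = "trial_onset",
    duration_policy: str = "stick",
) -> list[ModelSpec]:
    """Emit the separate-models suite for one subject.

    One model per within-block trial ordinal of *errorless* blocks (12 for
    the default layout of 60 keys / 5-key sequence), plus one model per
    error-period role; each role model carries the role's event regressor
    and the regressor of the corresponding position-matched control trials.

    Onsets are taken from the behavioral timestamps (seconds).  With
    ``onset_policy="first_wrong_key"`` error events are time-locked to the
    first wrong key instead of the error's first key; with
    ``duration_policy="actual_duration"`` events carry their actual span
    instead of zero duration.
    """
    if onset_policy not in ("trial_onset", "first_wrong_key"):
        raise ValueError(f"unknown onset policy {onset_policy!r}")
    if duration_policy not in ("stick", "actual_duration"):
        raise ValueError(f"unknown duration policy {duration_policy!r}")

    block_onsets, block_durs, go_onsets = [], [], []
    errorless: dict[int, list] = {}  # ordinal -> onsets (s)
    errorless_durs: dict[int, list] = {}
    for (subject, block), trials in sorted(parsed.items()):
        t_first = trials[0][0].times[0] / 1000.0
        t_last = trials[-1][0].times[-1] / 1000.0
        block_onsets.append(t_first)
        block_durs.append(t_last - t_first)
        go_onsets.append(t_first)
        if any(t.kind == "error" for t, _ in trials):
            continue
        corrects = [t for t, _ in trials if t.kind == "correct"]
        for ordinal, tr in enumerate(corrects, start=1):
            errorless.setdefault(ordinal, []).append(tr.times[0] / 1000.0)
            errorless_durs.setdefault(ordinal, []).append(
                (tr.times[-1] - tr.times[0]) / 1000.0
            )

    block_onsets = np.asarray(block_onsets)
    block_durs = np.asarray(block_durs)
    go_onsets = np.asarray(go_onsets)

    def _dur(raw):
        if duration_policy == "stick":
            return np.zeros(len(raw))
        return np.asarray(raw, dtype=float)

    models: list[ModelSpec] = []
    for ordinal in range(1, trials_per_block + 1):
        onsets = np.asarray(errorless.get(ordinal, []), dtype=float)
        durs = _dur(errorless_durs.get(ordinal, []))
        models.append(
            ModelSpec(
                model_id=f"trial{ordinal:02d}",
                block_onsets=block_onsets,
                block_durations=block_durs,
                go_onsets=go_onsets,
                events={f"trial{ordinal:02d}": (onsets, durs)},
            )
        )

    def _event_onset(trial, ann) -> float:
        if (
            onset_policy == "first_wrong_key"
            and ann is not None
            and ann.first_wrong_ordinal is not None
        ):
            return trial.times[ann.first_wrong_ordinal - 1] / 1000.0
        return trial.times[0] / 1000.0

    for role in ERROR_ROLES:
        idx = _ROLE_TRIAL_INDEX[role]
        e_on, e_dur, c_on, c_dur = [], [], [], []
        for err, ctl in pairs.pairs:
            if idx >= len(err.trials) or idx >= len(ctl.trials):
                continue
            etr, ctr = err.trials[idx], ctl.trials[idx]
            ann = err.annotation if role == "E" else None
            e_on.append(_event_onset(etr, ann))
            e_dur.append((etr.times[-1] - etr.times[0]) / 1000.0)
            c_on.append(ctr.times[0] / 1000.0)
            c_dur.append((ctr.times[-1] - ctr.times[0]) / 1000.0)
        models.append(
            ModelSpec(
                model_id=f"role_{role}",
                block_onsets=block_onsets,
                block_durations=block_durs,
                go_onsets=go_onsets,
                events={
                    f"{role}_error": (np.asarray(e_on), _dur(e_dur)),
                    f"{role}_control": (np.asarray(c_on), _dur(c_dur)),
                },
            )
        )
    return models


def _whiten_matrix_apply(A: np.ndarray, phi: float) -> np.ndarray:
    """Apply the AR(1) whitening transform row-wise to columns of A."""
    W = np.empty_like(A, dtype=float)
    W[0] = A[0] * np.sqrt(1.0 - phi**2)
    W[1:] = A[1:] - phi * A[:-1]
    return W


def fit_prewhitened(Y: np.ndarray, design: DesignMatrix) -> GLMFit:
    """Fit the GLM with two-pass AR(1) prewhitening.

    Pass 1: OLS, pooled lag-1 autocorrelation of residuals across all series
    (the AR(1)+white-noise model class).  Pass 2: whiten Y and X with the
    estimated coefficient and refit.  Rank-deficient designs are rejected
    naming near-collinear columns.
    """
    X = design.X
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError("Y rows must equal design rows")
    if n <= p + 2:
        raise ValueError("need n_scans > columns + 2")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the columns involved in the deficiency via QR pivoting
        from scipy.linalg import qr

        _, R, piv = qr(X, pivoting=True, mode="economic")
        bad = [design.names[j] for j in piv[rank:]]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")

    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    num = np.sum(resid[1:] * resid[:-1])
    den = np.sum(resid**2)
    # lag-1 autocorrelation of OLS residuals is biased low by ~rank/n
    # (projection onto the residual space); first-order correction applied
    phi = float(num / den) + rank / n if den > 0 else 0.0
    phi = float(np.clip(phi, -0.99, 0.99))

    Xw = _whiten_matrix_apply(X, phi)
    Yw = _whiten_matrix_apply(Y, phi)
    beta_w, *_ = np.linalg.lstsq(Xw, Yw, rcond=None)
    resid_w = Yw - Xw @ beta_w
    dof = n - rank
    sigma2 = np.sum(resid_w**2, axis=0) / dof
    return GLMFit(
        beta=beta_w, sigma2=sigma2, phi=phi, dof=float(dof),
        names=design.names, Xw=Xw,
    )


@dataclass
class ContrastResult:
    value: np.ndarray
    t: np.ndarray
    p: np.ndarray
    dof: float


def t_contrast(fit: GLMFit, c) -> ContrastResult:
    """t statistic for the linear combination c'beta on the whitened fit;
    two-tailed p with the fit's residual dof."""
    c = np.asarray(c, dtype=float)
    if c.shape[0] != fit.beta.shape[0]:
        raise ValueError("contrast length must equal number of regressors")
    if not np.any(c):
        raise ValueError("all-zero contrast")
    value = c @ fit.beta
    XtX_inv = np.linalg.pinv(fit.Xw.T @ fit.Xw)
    var_scale = float(c @ XtX_inv @ c)
    se = np.sqrt(fit.sigma2 * var_scale)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, value / se, np.nan)
    p = 2.0 * stats.t.sf(np.abs(t), fit.dof)
    return ContrastResult(value=value, t=t, p=p, dof=fit.dof)


def contrast_vector(design_names: list[str], weights: dict[str, float]) -> np.ndarray:
    c = np.zeros(len(design_names))
    for name, w in weights.items():
        c[design_names.index(name)] = w
    return c


def matched_contrast(fit: GLMFit, role: str, mode: str = "pooled") -> np.ndarray:
    """Error-vs-control contrast value(s) for a role model.

    ``pooled`` contrasts the two condition regressors (+1, -1); ``per_pair``
    expects one regressor per trial (names ``{role}_error_<i>`` /
    ``{role}_control_<i>``) and averages pairwise beta differences.  The two
    agree exactly on balanced noiseless designs.
    """
    if mode == "pooled":
        c = np.zeros(fit.beta.shape[0])
        c[fit.names.index(f"{role}_error")] = 1.0
        c[fit.names.index(f"{role}_control")] = -1.0
        return c @ fit.beta
    if mode == "per_pair":
        e_idx = [i for i, n in enumerate(fit.names) if n.startswith(f"{role}_error_")]
        c_idx = [i for i, n in enumerate(fit.names) if n.startswith(f"{role}_control_")]
        if len(e_idx) != len(c_idx) or not e_idx:
            raise ValueError("per-pair mode needs matching per-trial regressors")
        diffs = fit.beta[e_idx] - fit.beta[c_idx]
        return diffs.mean(axis=0)
    raise ValueError(f"unknown mode {mode!r}")


def sphere_roi_values(
    volume: np.ndarray,
    roi: RoiSpec,
    voxel_size: float | tuple[float, float, float] = 3.0,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> float | None:
    """Mean of voxels whose centers lie within the ROI sphere (inclusive).

    ``voxel_size`` is the mm edge length (scalar or per-axis); ``origin``
    the mm coordinate of voxel (0,0,0)'s center.  Returns ``None`` when no
    voxel center falls inside the sphere.
    """
    vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    idx = np.indices(volume.shape).reshape(3, -1).T
    centers = idx * vs + np.asarray(origin)
    d2 = np.sum((centers - np.asarray(roi.center)) ** 2, axis=1)
    mask = d2 <= roi.radius**2
    if not mask.any():
        return None
    return float(volume.reshape(-1)[mask].mean())


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance threshold under Bonferroni correction."""
    if n_tests < 1:
        raise ValueError("n_tests must be positive")
    return alpha / n_tests


def second_level(values: np.ndarray, n_rois: int | None = None, alpha: float = 0.05):
    """Random-effects one-sample t tests across subjects.

    ``values`` is subjects x units (ROIs or voxels).  Returns a list of
    :class:`~tapslip.behavior.GroupStat`, each flagged for significance at
    the Bonferroni-corrected threshold when ``n_rois`` is given.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    thr = bonferroni_threshold(alpha, n_rois) if n_rois else alpha
    out = []
    for j in range(values.shape[1]):
        st = one_sample_t(values[:, j])
        if st.p is not None and n_rois:
            st.correction = "Bonferroni" if st.p < thr else st.correction
        out.append(st)
    return out


def phase_course_anova(values: np.ndarray) -> GroupStat:
    """Within-subject ANOVA over the PreE2..PostE2 phase course
    (subjects x roles), GG-corrected."""
    return rm_anova(values)
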