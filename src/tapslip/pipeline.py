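"""End-to-end orchestration: parse -> select/match -> behavior stats ->
first-level GLM -> group stats, with reproducible per-stage seeds.

One global seed fans out to per-stage seeds by stable hashing of the stage
name, so a stage re-run in isolation sees the same randomness as inside the
full pipeline.  Every exclusion (eligibility filters, unmatched errors,
subjects without pairs) is logged so counts reconcile.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, glm, simulate
from .core import (
    BlockLayout,
    PAPER_LAYOUT,
    PAPER_SEQUENCE,
    SequenceSpec,
    read_keypress_log,
    events_frame,
)
from .segmentation import parse_session
from .selection import (
    MatchedPairSet,
    SelectionConfig,
    enumerate_controls,
    match_positions,
    second_matched_set,
    select_errors,
)

log = logging.getLogger("tapslip")


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed derived by stable hashing (always < 2**31)."""
    return zlib.crc32(f"{global_seed}:{stage}".encode()) & 0x7FFFFFFF


@dataclass
class RunConfig:
    """Pipeline configuration (see ``RunConfig.from_yaml``)."""

    seq: SequenceSpec = PAPER_SEQUENCE
    layout: BlockLayout = PAPER_LAYOUT
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    acq: glm.AcquisitionSpec = field(default_factory=glm.AcquisitionSpec)
    onset_policy: str = "trial_onset"
    duration_policy: str = "stick"
    matched_mode: str = "pooled"
    seed: int = 0
    keypress_log: str | None = None
    bold_tsv: str | None = None  # time-by-series TSV
    motion_tsv: str | None = None
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        seq = raw.get("sequence", {})
        layout = raw.get("layout", {})
        acq = raw.get("acquisition", {})
        sel = raw.get("selection", {})
        g = raw.get("glm", {})
        return cls(
            seq=SequenceSpec(tuple(seq.get("codes", PAPER_SEQUENCE.codes))),
            layout=BlockLayout(
                n_blocks=layout.get("n_blocks", PAPER_LAYOUT.n_blocks),
                keys_per_block=layout.get("keys_per_block", PAPER_LAYOUT.keys_per_block),
                rest_duration=layout.get("rest_duration", PAPER_LAYOUT.rest_duration),
            ),
            selection=SelectionConfig(**sel),
            acq=glm.AcquisitionSpec(
                tr=acq.get("tr", 2.65),
                n_scans=acq.get("n_scans", 200),
                microtime_bins=acq.get("microtime_bins", 16),
                highpass_cutoff=acq.get("highpass_cutoff", 128.0),
            ),
            onset_policy=g.get("onset_policy", "trial_onset"),
            duration_policy=g.get("duration_policy", "stick"),
            matched_mode=g.get("matched_mode", "pooled"),
            seed=raw.get("rng_seed", 0),
            keypress_log=raw.get("paths", {}).get("keypress_log"),
            bold_tsv=raw.get("paths", {}).get("bold_tsv"),
            motion_tsv=raw.get("paths", {}).get("motion_tsv"),
            out_dir=raw.get("paths", {}).get("out_dir", "results"),
        )


def build_matched_sets(
    parsed,
    cfg: SelectionConfig,
    seq: SequenceSpec,
    seed: int,
    make_set2: bool = True,
):
    """Select eligible errors, enumerate controls, and build matched sets.

    Returns (set1, set2-or-None, exclusion records).
    """
    errors, excluded = select_errors(parsed, cfg, seq)
    controls = enumerate_controls(parsed, cfg, seq)
    set1 = match_positions(errors, controls, seed)
    set2 = None
    if make_set2:
        set1, set2 = second_matched_set(set1, controls, stage_seed(seed, "set2"))
    for err, reason in set1.excluded:
        log.info(
            "excluded error: subject %s block %d ordinal %d (%s)",
            err.subject, err.block, err.center.ordinal, reason,
        )
    return set1, set2, excluded


def pairs_for_subject(pairs: MatchedPairSet, subject: str) -> MatchedPairSet:
    sub_pairs = [(e, c) for e, c in pairs.pairs if e.subject == subject]
    return MatchedPairSet(pairs=sub_pairs, seed=pairs.seed)


def behavior_stage(parsed, set1: MatchedPairSet) -> dict[str, pd.DataFrame]:
    """Per-subject slowing profiles and Fig-3-style group statistics."""
    refs = behavior.block_references(parsed)
    profile = behavior.period_profile(set1, refs)
    initiation = behavior.block_initiation_slowing(parsed, refs)

    stats_rows = []
    err = profile[profile.condition == "error"]
    for role in behavior.TRIAL_ROLES:
        if role in err.columns:
            st = behavior.one_sample_t(err[role].to_numpy())
            stats_rows.append(
                {
                    "measure": f"{role}_slowing_vs_0",
                    "stat": st.name,
                    "value": st.statistic,
                    "dof": st.dof[0],
                    "p": st.p,
                }
            )
    group = pd.DataFrame(stats_rows)
    return {"profile": profile, "initiation": initiation, "group": group}


def first_level_stage(
    parsed,
    pairs: MatchedPairSet,
    Y_by_subject: dict[str, np.ndarray],
    acq: glm.AcquisitionSpec,
    trials_per_block: int,
    onset_policy: str = "trial_onset",
    duration_policy: str = "stick",
    motion_by_subject: dict | None = None,
) -> pd.DataFrame:
    """Fit the separate-models suite per subject; return matched contrasts
    per role and series."""
    rows = []
    subjects = sorted({s for (s, _b) in parsed})
    for subject in subjects:
        if subject not in Y_by_subject:
            continue
        sub_parsed = {k: v for k, v in parsed.items() if k[0] == subject}
        sub_pairs = pairs_for_subject(pairs, subject)
        if not sub_pairs.pairs:
            log.info("subject %s dropped from GLM stage: no matched pairs", subject)
            continue
        models = glm.generate_model_suite(
            sub_parsed, sub_pairs, trials_per_block,
            onset_policy=onset_policy, duration_policy=duration_policy,
        )
        motion = (motion_by_subject or {}).get(subject)
        Y = Y_by_subject[subject]
        for model in models:
            if not model.model_id.startswith("role_"):
                continue
            role = model.model_id.removeprefix("role_")
            if len(model.events[f"{role}_error"][0]) == 0:
                continue
            design = glm.build_design(model, acq, motion=motion)
            fit = glm.fit_prewhitened(Y, design)
            vals = glm.matched_contrast(fit, role)
            for j, v in enumerate(np.atleast_1d(vals)):
                rows.append(
                    {"subject": subject, "role": role, "series": j, "contrast": float(v)}
                )
    return pd.DataFrame(rows)


def group_stage(first_level: pd.DataFrame) -> pd.DataFrame:
    """One-sample t per role/series across subjects, plus the phase-course
    repeated-measures ANOVA per series."""
    rows = []
    for (role, series), grp in first_level.groupby(["role", "series"]):
        st = behavior.one_sample_t(grp["contrast"].to_numpy())
        rows.append(
            {
                "measure": f"{role}_error_vs_control",
                "series": series,
                "stat": st.name,
                "value": st.statistic,
                "dof": st.dof[0],
                "p": st.p,
            }
        )
    for series, grp in first_level.groupby("series"):
        wide = grp.pivot_table(
            index="subject", columns="role", values="contrast"
        ).reindex(columns=list(glm.ERROR_ROLES))
        wide = wide.dropna()
        if len(wide) >= 2:
            st = behavior.rm_anova(wide.to_numpy())
            rows.append(
                {
                    "measure": "phase_course_anova",
                    "series": series,
                    "stat": st.name,
                    "value": st.statistic,
                    "dof": st.dof,
                    "p": st.p,
                }
            )
    return pd.DataFrame(rows)


def phase_course_recovery_run(
    seed: int,
    n_subjects: int = 20,
    roles: tuple[str, ...] = ("E", "PostE1", "PostE2"),
) -> dict[str, float]:
    """One seeded end-to-end run: synthetic behavior + BOLD -> parse ->
    match -> role-model GLMs -> group-mean matched contrasts per role.

    The generator injects the instantaneous-positive / delayed-negative
    pattern (+1 at the error, -1 at PostE1 and PostE2); the return value is
    the group mean error-vs-control contrast per role, which a faithful
    pipeline should sign-recover.
    """
    bspec = simulate.BehaviorGenSpec(
        n_subjects=n_subjects, seed=stage_seed(seed, "behavior")
    )
    df, _ = simulate.gen_behavior(bspec)
    parsed = parse_session(df, bspec.seq)
    set1, _, _ = build_matched_sets(
        parsed, SelectionConfig(), bspec.seq, stage_seed(seed, "match"),
        make_set2=False,
    )
    per_subject: dict[str, dict[str, float]] = {}
    for subject in sorted({s for (s, _b) in parsed}):
        sub_parsed = {k: v for k, v in parsed.items() if k[0] == subject}
        sub_pairs = pairs_for_subject(set1, subject)
        if not sub_pairs.pairs:
            continue
        dur = max(trs[-1][0].times[-1] for trs in sub_parsed.values()) / 1000.0
        acq = glm.AcquisitionSpec(n_scans=simulate.n_scans_for(dur, 2.65))
        bold_spec = simulate.BoldGenSpec(
            acq=acq, seed=stage_seed(seed, f"bold:{subject}")
        )
        Y, _ = simulate.gen_bold(sub_parsed, sub_pairs, bold_spec)
        models = glm.generate_model_suite(sub_parsed, sub_pairs, 12)
        vals = {}
        for role in roles:
            model = next(m for m in models if m.model_id == f"role_{role}")
            if len(model.events[f"{role}_error"][0]) == 0:
                continue
            design = glm.build_design(model, acq)
            fit = glm.fit_prewhitened(Y, design)
            vals[role] = float(glm.matched_contrast(fit, role)[0])
        per_subject[subject] = vals
    return {
        role: float(np.mean([v[role] for v in per_subject.values() if role in v]))
        for role in roles
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; write numeric tables and provenance metadata under
    ``config.out_dir``.  Deterministic for fixed config and seed."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.keypress_log:
        df = read_keypress_log(config.keypress_log, alphabet=config.seq.alphabet)
        truth = None
    else:
        spec = simulate.BehaviorGenSpec(
            layout=config.layout, seq=config.seq,
            seed=stage_seed(config.seed, "behavior"),
        )
        df, truth = simulate.gen_behavior(spec)

    parsed = parse_session(df, config.seq)
    events = events_frame(
        [(subj, blk, t, a) for (subj, blk), trs in sorted(parsed.items()) for t, a in trs]
    )
    events.to_csv(out / "events.tsv", sep="\t", index=False)

    set1, set2, excluded = build_matched_sets(
        parsed, config.selection, config.seq,
        stage_seed(config.seed, "match"),
    )
    pd.DataFrame(excluded).to_csv(out / "exclusions.tsv", sep="\t", index=False)
    pairs_rows = [
        {
            "subject": e.subject,
            "block": e.block,
            "position": e.position,
            "error_center_span": f"{e.center.key_span[0]}-{e.center.key_span[1]}",
            "control_center_span": f"{c.center.key_span[0]}-{c.center.key_span[1]}",
            "set": 1,
        }
        for e, c in set1.pairs
    ] + [
        {
            "subject": e.subject,
            "block": e.block,
            "position": e.position,
            "error_center_span": f"{e.center.key_span[0]}-{e.center.key_span[1]}",
            "control_center_span": f"{c.center.key_span[0]}-{c.center.key_span[1]}",
            "set": 2,
        }
        for e, c in (set2.pairs if set2 else [])
    ]
    pd.DataFrame(pairs_rows).to_csv(out / "pairs.tsv", sep="\t", index=False)

    beh = behavior_stage(parsed, set1)
    beh["profile"].to_csv(out / "behavior_profile.tsv", sep="\t", index=False)
    beh["group"].to_csv(out / "behavior_group.tsv", sep="\t", index=False)

    imaging_ran = False
    if config.bold_tsv:
        bold = pd.read_csv(config.bold_tsv, sep="\t")
        subjects = sorted({s for (s, _b) in parsed})
        if len(subjects) == 1:
            Y_by_subject = {subjects[0]: bold.to_numpy(dtype=float)}
            fl = first_level_stage(
                parsed, set1, Y_by_subject, config.acq,
                trials_per_block=config.layout.keys_per_block // config.seq.k,
                onset_policy=config.onset_policy,
                duration_policy=config.duration_policy,
            )
            fl.to_csv(out / "first_level.tsv", sep="\t", index=False)
            imaging_ran = True
        else:
            log.info("BOLD TSV input supports single-subject runs; skipping imaging")
    else:
        log.info("no BOLD inputs configured; imaging stages skipped")

    meta = {
        "seed": config.seed,
        "n_pairs_set1": len(set1),
        "n_pairs_set2": len(set2) if set2 else 0,
        "n_excluded_errors": len(excluded),
        "imaging": imaging_ran,
        "synthetic": truth is not None,
    }
    with open(out / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    return {"parsed": parsed, "set1": set1, "set2": set2, "behavior": beh, "meta": meta}
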