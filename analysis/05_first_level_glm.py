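"""Synthesize BOLD for each subject and fit the separate role models.

The generator injects +1 at errors and -1 at the two post-error trials on
top of uniform per-trial transients, with AR(1) noise and slow drift.  Each
role model (PreE2..PostE2) carries the role's stick regressor plus the
matched-control regressor; the error-vs-control contrast per subject is the
+1/-1 combination of their betas.  Writes per-subject contrasts.
"""

from pathlib import Path

import pandas as pd

from tapslip import glm, simulate
from tapslip.core import PAPER_SEQUENCE, read_keypress_log
from tapslip.pipeline import (
    build_matched_sets,
    first_level_stage,
    pairs_for_subject,
    stage_seed,
)
from tapslip.segmentation import parse_session
from tapslip.selection import SelectionConfig

OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"
SEED = 20260918

def main() -> None:
    df = read_keypress_log(OUT / "keypresses.tsv")
    parsed = parse_session(df, PAPER_SEQUENCE)
    set1, _, _ = build_matched_sets(
        parsed, SelectionConfig(), PAPER_SEQUENCE, stage_seed(SEED, "match")
    )
    rows = []
    for subject in sorted({s for s, _ in parsed}):
        sub_parsed = {k: v for k, v in parsed.items() if k[0] == subject}
        sub_pairs = pairs_for_subject(set1, subject)
        if not sub_pairs.pairs:
            print(f"{subject}: no matched pairs, skipped")
            continue
        dur = max(t[-1][0].times[-1] for t in sub_parsed.values()) / 1000.0
        acq = glm.AcquisitionSpec(n_scans=simulate.n_scans_for(dur, 2.65))
        Y, _ = simulate.gen_bold(
            sub_parsed, sub_pairs,
            simulate.BoldGenSpec(acq=acq, seed=stage_seed(SEED, f"bold:{subject}")),
        )
        fl = first_level_stage(
            sub_parsed, sub_pairs, {subject: Y}, acq, trials_per_block=12
        )
        rows.append(fl)
    out = pd.concat(rows, ignore_index=True)
    out.to_csv(OUT / "first_level_contrasts.tsv", sep="\t", index=False)
    print("\nmean error-vs-control contrast per role:")
    print(out.groupby("role").contrast.mean().round(3).to_string())

if __name__ == "__main__":
    main()
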