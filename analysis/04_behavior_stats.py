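"""Block-normalized slowing around errors, per subject and at the group
level.

Slowing is percent deviation from each block's mean within-correct-trial
transition duration.  Reports the PreE2..PostE2 trial course for error and
control periods and one-sample t tests of each error-period role against
block-typical speed (0%).
"""

from pathlib import Path

import pandas as pd

from tapslip import behavior
from tapslip.core import PAPER_SEQUENCE, read_keypress_log
from tapslip.pipeline import behavior_stage, build_matched_sets, stage_seed
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
    tables = behavior_stage(parsed, set1)
    tables["profile"].to_csv(OUT / "behavior_profile.tsv", sep="\t", index=False)
    tables["group"].to_csv(OUT / "behavior_group.tsv", sep="\t", index=False)
    tables["initiation"].to_csv(OUT / "block_initiation.tsv", sep="\t", index=False)

    prof = tables["profile"]
    for cond in ("error", "control"):
        sub = prof[prof.condition == cond]
        means = sub[list(behavior.TRIAL_ROLES)].mean().round(2)
        print(f"{cond} periods (group mean % slowing):\n{means.to_string()}\n")
    print("group tests (vs 0%):")
    print(tables["group"].round(3).to_string(index=False))

if __name__ == "__main__":
    main()
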