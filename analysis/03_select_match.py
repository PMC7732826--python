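"""Apply the isolated-error rules and build position-matched control sets.

Eligible errors need >= 3 correct trials on each side (2 after, at block
end), > 0.5 s duration, and <= 20 keys; each gets one error-free 7-trial
control period at the same within-block position (set 1), and a second,
disjoint control (set 2) where available.  Writes pairs and exclusions.
"""

from pathlib import Path

import pandas as pd

from tapslip.core import PAPER_SEQUENCE, read_keypress_log
from tapslip.pipeline import build_matched_sets, stage_seed
from tapslip.segmentation import parse_session
from tapslip.selection import SelectionConfig

OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"
SEED = 20260918

def main() -> None:
    df = read_keypress_log(OUT / "keypresses.tsv")
    parsed = parse_session(df, PAPER_SEQUENCE)
    set1, set2, excluded = build_matched_sets(
        parsed, SelectionConfig(), PAPER_SEQUENCE, stage_seed(SEED, "match")
    )
    rows = [
        {
            "subject": e.subject, "block": e.block, "position": e.position,
            "error_span": f"{e.center.key_span[0]}-{e.center.key_span[1]}",
            "control_ordinal": c.center.ordinal, "set": sid,
        }
        for sid, ms in ((1, set1), (2, set2))
        for e, c in ms.pairs
    ]
    pd.DataFrame(rows).to_csv(OUT / "pairs.tsv", sep="\t", index=False)
    pd.DataFrame(excluded).to_csv(OUT / "exclusions.tsv", sep="\t", index=False)
    print(f"eligible+matched pairs: set1={len(set1)}, set2={len(set2)}")
    print(f"ineligible errors: {len(excluded)}")
    pos = pd.Series([e.position for e, _ in set1.pairs])
    print("position distribution (set 1):")
    print(pos.value_counts().sort_index().to_string())

if __name__ == "__main__":
    main()
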