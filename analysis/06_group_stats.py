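"""Group-level inference on the matched contrasts.

Random-effects one-sample t per role across subjects, the PreE2..PostE2
phase-course repeated-measures ANOVA (Greenhouse-Geisser corrected), and
the Bonferroni threshold for a 25-ROI family.
"""

from pathlib import Path

import pandas as pd

from tapslip import glm
from tapslip.pipeline import group_stage

OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"

def main() -> None:
    fl = pd.read_csv(OUT / "first_level_contrasts.tsv", sep="\t")
    group = group_stage(fl)
    group.to_csv(OUT / "group_stats.tsv", sep="\t", index=False)
    print(group.round(4).to_string(index=False))
    thr = glm.bonferroni_threshold(0.05, 25)
    print(f"\nBonferroni threshold for 25 ROIs at alpha=0.05: p < {thr:.3f}")

if __name__ == "__main__":
    main()
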