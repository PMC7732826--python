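"""Generate the synthetic tapping session the downstream analyses use.

A desk-scale cohort (12 subjects) under the default task layout: 14 blocks
of 60 keypresses of the sequence 4-1-3-2-4, 15-s rests, log-normal
inter-press intervals (250 +/- 50 ms), mild across-block slowing, ~0.3
errors per block, error-phase slowing x1.5 and post-error slowing x1.1.
Writes the keypress log and its ground-truth sidecar under results/.
"""

import json
from pathlib import Path

from tapslip import simulate
from tapslip.core import write_keypress_log

OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"
SEED = 20260918

def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = simulate.BehaviorGenSpec(n_subjects=12, seed=SEED)
    df, truth = simulate.gen_behavior(spec)
    write_keypress_log(df, OUT / "keypresses.tsv")
    with open(OUT / "keypresses.truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, default=str)
    n_err = len(truth["errors"])
    print(f"wrote {len(df)} keypresses for {spec.n_subjects} subjects")
    print(f"scheduled errors: {n_err} ({n_err / spec.n_subjects:.2f} per subject)")

if __name__ == "__main__":
    main()
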