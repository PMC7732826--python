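"""Segment the keypress log into trials and errors; write the events table.

Reports the trial-type breakdown and the error-type distribution the
annotator recovers (first wrong key at ordinal 1..5, or an incomplete
sequence with no wrong key).
"""

from pathlib import Path

from tapslip.core import PAPER_SEQUENCE, events_frame, read_keypress_log
from tapslip.segmentation import parse_session

OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"

def main() -> None:
    df = read_keypress_log(OUT / "keypresses.tsv")
    parsed = parse_session(df, PAPER_SEQUENCE)
    events = events_frame(
        [(s, b, t, a) for (s, b), trs in sorted(parsed.items()) for t, a in trs]
    )
    events.to_csv(OUT / "events.tsv", sep="\t", index=False)
    print(events.trial_type.value_counts().to_string())
    errs = events[events.trial_type == "error"]
    print("\nerror types:")
    print(errs.error_type.value_counts().to_string())

if __name__ == "__main__":
    main()
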