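import numpy as np
import pandas as pd
import pytest

from tapslip.core import PAPER_SEQUENCE, BlockLayout
from tapslip.segmentation import parse_session
from tapslip.selection import SelectionConfig
from tapslip import simulate


@pytest.fixture(scope="session")
def seq():
    return PAPER_SEQUENCE


@pytest.fixture(scope="session")
def sel_cfg():
    return SelectionConfig()


def make_block_frame(keys, transition_ms=300.0, subject="s", block=1):
    """One-block keypress table with uniform transitions."""
    onsets = [transition_ms * (i + 1) for i in range(len(keys))]
    return pd.DataFrame(
        {"subject": subject, "block": block, "key": list(keys), "onset_ms": onsets}
    )


@pytest.fixture(scope="session")
def small_session(seq):
    """A parsed 1-subject synthetic session with several errors."""
    spec = simulate.BehaviorGenSpec(
        n_subjects=1,
        layout=BlockLayout(n_blocks=6, keys_per_block=60, rest_duration=15.0),
        error_rate=0.6,
        seed=7,
    )
    df, truth = simulate.gen_behavior(spec)
    return parse_session(df, seq), truth
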