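import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from probeval import CountProfile, ReactivityProfile, RnaRecord, SecondaryStructure

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def make_reactivity(values, bases=None, valid=None, rna_id="x", mode="mutation"):
    values = np.asarray(values, dtype=float)
    if bases is None:
        bases = "A" * len(values)
    if valid is None:
        valid = ~np.isnan(values)
    return ReactivityProfile(
        rna_id=rna_id, bases=bases, reactivity=values,
        valid=np.asarray(valid, bool), mode=mode,
    )


def make_structure(dotbracket, sequence=None, rna_id="x"):
    if sequence is None:
        sequence = "A" * len(dotbracket)
    return SecondaryStructure.from_dotbracket(
        RnaRecord(id=rna_id, sequence=sequence), dotbracket
    )


def make_counts(depth, events, bases=None, rna_id="x", channel="plus",
                mode="mutation"):
    depth = np.asarray(depth, dtype=np.int64)
    if bases is None:
        bases = "A" * len(depth)
    return CountProfile(rna_id=rna_id, channel=channel, mode=mode,
                        bases=bases, depth=depth,
                        events=np.asarray(events, dtype=np.int64))


@pytest.fixture
def toy_counts():
    return make_counts(depth=[600, 700, 800], events=[6, 0, 80], bases="ACG")
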