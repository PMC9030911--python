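import numpy as np
import pytest

from tripletrial import TrialConfig, fixture_roster
from tripletrial.randomize import TripletAssignment
from tripletrial.records import ParticipantRecord


@pytest.fixture(scope="session")
def paper_roster():
    """Participant-level reconstruction of the published count tables."""
    return fixture_roster()


@pytest.fixture
def rng():
    return np.random.default_rng(20140501)


def make_triplet_records(arm_outcomes, stratum="consistent", prefix="T"):
    """Build records + triplets from per-triplet (control, fear, social)
    outcome tuples; an entry of None is a missing week-6 outcome."""
    records, triplets = [], []
    flag = 1 if stratum == "consistent" else 0
    arms = ("control", "fear", "social")
    for t, outcomes in enumerate(arm_outcomes):
        members = []
        for pos, (arm, y) in enumerate(zip(arms, outcomes)):
            rid = f"{prefix}{t}{pos}"
            records.append(ParticipantRecord(
                id=rid, baseline_consistent=flag, arm=arm, outcome_wk6=y))
            members.append(rid)
        triplets.append(TripletAssignment(stratum=stratum,
                                          member_ids=tuple(members)))
    return records, triplets


@pytest.fixture
def null_config():
    return TrialConfig().null()
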