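from __future__ import annotations

import pytest

from rivalscore.trial_data import Session, Trial


def build_session(spec, participant_id="p1", vviq=None):
    """Compact session builder: spec is a list of (kind, cue, response) triples."""
    trials = tuple(
        Trial(index=i, kind=k, cue=c, response=r)
        for i, (k, c, r) in enumerate(spec, start=1)
    )
    return Session(participant_id=participant_id, trials=trials, vviq=vviq)


@pytest.fixture
def session_builder():
    return build_session


@pytest.fixture
def two_participant_log(tmp_path):
    """A 2-participant, 4-trial fixture log on disk."""
    path = tmp_path / "log.csv"
    path.write_text(
        "participant_id,trial_index,trial_type,cue,response\n"
        "p1,1,rivalry,R,red\n"
        "p1,2,rivalry,B,mixed\n"
        "p2,1,rivalry,B,blue\n"
        "p2,2,mock_red,R,red\n"
    )
    return path
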