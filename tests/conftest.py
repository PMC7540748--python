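import itertools

import numpy as np
import pandas as pd
import pytest

from eventdep.trial_data import DEFAULT_ROLES, ParticipantDataset

PAIRS = [(c, t) for c, t in itertools.permutations(DEFAULT_ROLES, 2)]


def dataset_from_outcomes(outcomes, participant_id="P001", condition_id="cond",
                          roles=DEFAULT_ROLES):
    """Build a ParticipantDataset from an (n_events, 6) truthy array.

    Columns follow the canonical directed-pair order; a hand-rolled builder so
    tests do not depend on the package's own simulator or loader.
    """
    outcomes = np.asarray(outcomes)
    rows = []
    for e in range(outcomes.shape[0]):
        for j, (cue, target) in enumerate(PAIRS):
            rows.append({
                "participant_id": participant_id,
                "condition_id": condition_id,
                "event_id": e + 1,
                "cue_role": cue,
                "target_role": target,
                "response": "correct" if outcomes[e, j] else "incorrect",
                "block": pd.NA,
                "trial_index": pd.NA,
            })
    return ParticipantDataset(participant_id, pd.DataFrame(rows), tuple(roles))


@pytest.fixture
def all_correct_dataset():
    return dataset_from_outcomes(np.ones((15, 6), dtype=bool))


@pytest.fixture
def all_or_none_dataset():
    """Half the events fully retrieved, half fully forgotten: the textbook
    holistic participant at 50% accuracy."""
    out = np.zeros((16, 6), dtype=bool)
    out[:8] = True
    return dataset_from_outcomes(out)
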