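"""Shared fixtures: a fast reduced-size session and the full default cohort.

The reduced session keeps the 15-block structure but shrinks episodes per
block so unit tests run quickly; the default cohort is generated once at
full size (5 subjects, study conditions) for the group-level checks.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from errp_exo.montage import build_montage
from errp_exo.preprocess import preprocess_session
from errp_exo.protocol import build_protocol
from errp_exo.synth import iter_cohort, synth_session


@pytest.fixture(scope="session")
def montage_fx():
    return build_montage()


def _mini_protocol(seed: int):
    base = build_protocol(seed)
    return dataclasses.replace(base, episodes_per_block=2, events_per_episode=(8, 10))


@pytest.fixture(scope="session")
def mini_rec():
    """Reduced-size single-subject session (15 blocks x 2 episodes)."""
    return synth_session(1, 11, protocol=_mini_protocol(11))


@pytest.fixture(scope="session")
def mini_epochs(mini_rec, montage_fx):
    return preprocess_session(mini_rec, montage_fx)


@pytest.fixture(scope="session")
def default_cohort(montage_fx):
    """Full default 5-subject cohort, preprocessed.

    Per subject: error-block epoch sets for the three modalities, the
    subject's error-minus-correct Cz difference wave, and traits.  Raw
    streams are discarded as soon as each subject is processed.
    """
    subjects = []
    for rec in iter_cohort(5, seed=20):
        eps = preprocess_session(rec, montage_fx)
        eeg_err = eps["eeg"].error_blocks()
        cz = list(eeg_err.channel_names).index("Cz")
        diff = (eeg_err.data[eeg_err.labels == 1, cz].mean(0)
                - eeg_err.data[eeg_err.labels == 0, cz].mean(0))
        subjects.append({
            "subject_id": rec.subject_id,
            "traits": rec.traits,
            "epochs": {m: eps[m].error_blocks() for m in ("eeg", "emg", "kinematics")},
            "cz_diff": diff.astype(np.float64),
            "eeg_times": eps["eeg"].times.copy(),
            "kin_times": eps["kinematics"].times.copy(),
        })
    return subjects


@pytest.fixture(scope="session")
def null_session(montage_fx):
    """Zero-effect session: error and non-error trials share one distribution."""
    rec = synth_session(1, 77, effect_scale=0.0)
    return preprocess_session(rec, montage_fx)
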