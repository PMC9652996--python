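"""Electrode montage for the 30-channel recording (27 scalp + 3 EOG).

Scalp positions come from the standard extended 10-20 layout bundled with
MNE, projected onto the unit sphere; the three EOG electrodes (forehead,
left and right outer canthus) get fixed approximate facial positions.
TP9/TP10 are the mastoid acquisition reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: acquisition channel order (paper montage)
EEG_CHANNEL_NAMES: tuple[str, ...] = (
    "FP1", "FP2", "F3", "F4", "F7", "F8", "FC1", "FC2", "FC5", "FC6",
    "C3", "C4", "T7", "T8", "CP5", "CP6", "P3", "P4", "P7", "P8",
    "TP9", "TP10", "O1", "O2", "Fz", "Cz", "Pz", "EOG1", "EOG2", "EOG3",
)
EOG_CHANNELS: tuple[str, ...] = ("EOG1", "EOG2", "EOG3")
SCALP_CHANNELS: tuple[str, ...] = tuple(c for c in EEG_CHANNEL_NAMES if c not in EOG_CHANNELS)
REFERENCE_CHANNELS: tuple[str, ...] = ("TP9", "TP10")

#: our labels -> MNE standard_1020 names (case differences only)
MNE_NAME_MAP: dict[str, str] = {"FP1": "Fp1", "FP2": "Fp2"}

_EOG_POSITIONS = {
    "EOG1": np.array([0.0, 0.95, 0.31]),    # forehead
    "EOG2": np.array([-0.82, 0.55, -0.16]), # left outer canthus
    "EOG3": np.array([0.82, 0.55, -0.16]),  # right outer canthus
}


@dataclass(frozen=True)
class Montage:
    """Channel labels with unit-sphere positions."""

    channel_names: tuple[str, ...] = EEG_CHANNEL_NAMES
    positions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.channel_names) != set(EEG_CHANNEL_NAMES):
            raise ValueError("montage must carry exactly the acquisition channel set")
        for ref in REFERENCE_CHANNELS:
            if ref not in self.channel_names:
                raise ValueError(f"reference channel {ref} missing")

    def index(self, name: str) -> int:
        return self.channel_names.index(name)

    def position_array(self, names: tuple[str, ...] | None = None) -> np.ndarray:
        names = names or self.channel_names
        return np.stack([self.positions[n] for n in names])


def build_montage() -> Montage:
    """Standard 10-20 scalp positions (unit sphere) plus facial EOG sites."""
    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        std = mne.channels.make_standard_montage("standard_1020").get_positions()["ch_pos"]
    positions: dict[str, np.ndarray] = {}
    for name in EEG_CHANNEL_NAMES:
        if name in EOG_CHANNELS:
            p = _EOG_POSITIONS[name]
        else:
            p = np.asarray(std[MNE_NAME_MAP.get(name, name)], dtype=float)
        positions[name] = p / np.linalg.norm(p)
    return Montage(channel_names=EEG_CHANNEL_NAMES, positions=positions)
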