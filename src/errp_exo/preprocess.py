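"""EEG/EMG/kinematics preprocessing and event-locked epoching.

The EEG chain mirrors standard ERP practice: zero-phase Hamming windowed
sinc FIR bandpass (1-20 Hz) on EEG and EOG, kurtosis-based bad-channel
detection (two-sided 5% threshold) with spherical-spline interpolation,
blink correction by least-squares regression on the three EOG channels, and
re-referencing to the common average of the scalp channels.  Epochs are
extracted time-locked to movement-event onsets with half-open sample
windows: [0, 1.0) s for EEG, [-0.2, 1.5) s for EMG envelopes and
kinematics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sstats

from errp_exo.montage import EOG_CHANNELS, MNE_NAME_MAP, Montage, SCALP_CHANNELS
from errp_exo.protocol import ExperimentEvent, SessionProtocol
from errp_exo.synth import MultimodalRecording

logger = logging.getLogger(__name__)

#: default epoch windows (seconds, half-open) per modality
EPOCH_WINDOWS: dict[str, tuple[float, float]] = {
    "eeg": (0.0, 1.0),
    "emg": (-0.2, 1.5),
    "kinematics": (-0.2, 1.5),
}


def bandpass_fir(
    stream: np.ndarray,
    rate: float,
    low: float = 1.0,
    high: float = 20.0,
) -> np.ndarray:
    """Zero-phase Hamming windowed sinc FIR bandpass.

    Delegates to MNE's FIR designer (hamming window, zero-phase by
    delay-compensated linear-phase application).  Requires rate > 2*high.
    """
    if rate <= 2 * high:
        raise ValueError(f"sampling rate {rate} too low for a {high} Hz passband edge")
    import mne

    x = np.atleast_2d(np.asarray(stream, dtype=np.float64))
    out = mne.filter.filter_data(
        x, sfreq=rate, l_freq=low, h_freq=high,
        fir_window="hamming", fir_design="firwin", phase="zero", verbose="ERROR",
    )
    return out.astype(np.float64) if stream.ndim > 1 else out[0]


def kurtosis_bad_channels(
    eeg: np.ndarray,
    alpha: float = 0.05,
) -> list[int]:
    """Flag channels with outlying excess kurtosis.

    Channel-wise excess kurtosis is z-scored across channels; channels whose
    |z| exceeds the two-sided normal bound at ``alpha`` (1.96 at 5%) are
    flagged.  A single pass is used.  Identical channels yield zero spread
    and no flags.
    """
    eeg = np.asarray(eeg)
    if eeg.shape[0] < 3:
        raise ValueError("need at least 3 channels to z-score kurtosis")
    k = sstats.kurtosis(eeg, axis=1, fisher=True, bias=True)
    spread = np.std(k)
    if spread == 0:
        return []
    z = (k - np.mean(k)) / spread
    bound = sstats.norm.ppf(1.0 - alpha / 2.0)
    return [int(i) for i in np.nonzero(np.abs(z) > bound)[0]]


def interpolate_channels(
    eeg: np.ndarray,
    bad: list[int],
    montage: Montage,
    channel_names: tuple[str, ...] | None = None,
    rate: float = 1000.0,
    method: str = "spline",
) -> np.ndarray:
    """Replace bad scalp channels by spherical-spline interpolation.

    ``method='distance'`` falls back to inverse-distance weighted averaging
    of the good channels.  All-bad input is rejected.
    """
    names = channel_names or SCALP_CHANNELS
    eeg = np.asarray(eeg, dtype=np.float64)
    if eeg.shape[0] != len(names):
        raise ValueError("channel count does not match channel names")
    if not bad:
        return eeg.copy()
    if len(bad) >= len(names):
        raise ValueError("cannot interpolate: no good channels left")
    for b in bad:
        if names[b] in EOG_CHANNELS:
            raise ValueError("only scalp channels can be interpolated")

    if method == "distance":
        pos = montage.position_array(tuple(names))
        out = eeg.copy()
        good = [i for i in range(len(names)) if i not in bad]
        for b in bad:
            d = np.linalg.norm(pos[good] - pos[b], axis=1)
            w = 1.0 / np.maximum(d, 1e-6) ** 2
            out[b] = (w[:, None] * eeg[good]).sum(0) / w.sum()
        return out
    if method != "spline":
        raise ValueError(f"unknown interpolation method {method!r}")

    import warnings

    import mne

    mne_names = [MNE_NAME_MAP.get(n, n) for n in names]
    info = mne.create_info(mne_names, rate, "eeg")
    raw = mne.io.RawArray(eeg * 1e-6, info, verbose="ERROR")  # uV -> V
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        raw.set_montage(mne.channels.make_standard_montage("standard_1020"),
                        match_case=False, verbose="ERROR")
    raw.info["bads"] = [mne_names[b] for b in bad]
    raw.interpolate_bads(reset_bads=True, mode="accurate", verbose="ERROR")
    return raw.get_data() * 1e6


def eog_regress(eeg: np.ndarray, eog: np.ndarray) -> np.ndarray:
    """Subtract the least-squares EOG projection from each scalp channel.

    Regression coefficients are fitted on the full continuous (filtered)
    record, channel-wise: eeg_clean = eeg - B @ eog with
    B = eeg @ eog^T (eog @ eog^T)^{-1}.  Rank-deficient EOG is rejected.
    """
    eeg = np.asarray(eeg, dtype=np.float64)
    eog = np.asarray(eog, dtype=np.float64)
    # silent EOG channels carry nothing to regress out
    active = np.ptp(eog, axis=1) > 0
    if not active.any():
        return eeg.copy()
    eog = eog[active]
    gram = eog @ eog.T
    if np.linalg.matrix_rank(gram) < eog.shape[0]:
        raise ValueError("EOG channels are rank deficient; cannot regress")
    coeffs = np.linalg.solve(gram, eog @ eeg.T).T  # (n_eeg, n_eog_active)
    return eeg - coeffs @ eog


def common_average_reference(eeg: np.ndarray) -> np.ndarray:
    """Subtract the per-sample mean across (scalp) channels."""
    eeg = np.asarray(eeg, dtype=np.float64)
    if eeg.shape[0] < 2:
        raise ValueError("CAR needs at least 2 channels")
    return eeg - eeg.mean(axis=0, keepdims=True)


# --------------------------------------------------------------------------
# epoching
# --------------------------------------------------------------------------

@dataclass
class EpochSet:
    """Event-locked trial tensor for one modality."""

    data: np.ndarray              # (trials, channels, samples)
    labels: np.ndarray            # 1 = error, 0 = non_error
    modality: str                 # eeg | emg | kinematics
    window: tuple[float, float]   # s relative to onset, half-open
    rate: float
    channel_names: tuple[str, ...]
    schemes: np.ndarray           # per-trial scheme strings
    block_error_rates: np.ndarray # per-trial assigned block error rate
    event_indices: np.ndarray     # index into the originating event list
    times: np.ndarray = field(init=False)

    LABEL_NAMES = ("non_error", "error")

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.labels):
            raise ValueError("labels must align with trials")
        self.times = self.window[0] + np.arange(self.data.shape[2]) / self.rate

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def select(self, mask: np.ndarray) -> "EpochSet":
        out = replace(
            self,
            data=self.data[mask],
            labels=self.labels[mask],
            schemes=self.schemes[mask],
            block_error_rates=self.block_error_rates[mask],
            event_indices=self.event_indices[mask],
        )
        return out

    def error_blocks(self, scheme: str | None = None) -> "EpochSet":
        """Trials from blocks with a nonzero assigned error rate.

        These are the trials used for error/non-error classification; an
        optional scheme restricts further (``'combined'``/None keeps both).
        """
        mask = self.block_error_rates > 0
        if scheme not in (None, "combined"):
            mask &= self.schemes == scheme
        return self.select(mask)


def epoch(
    stream: np.ndarray,
    rate: float,
    events: list[ExperimentEvent],
    window: tuple[float, float] | None = None,
    modality: str = "eeg",
    channel_names: tuple[str, ...] | None = None,
    protocol: SessionProtocol | None = None,
    baseline: tuple[float, float] | None = None,
) -> EpochSet:
    """Slice event-locked trials out of a continuous stream.

    Windows are half-open in samples ([0, 1) s at 1000 Hz is exactly 1000
    samples).  Events whose window falls outside the recording are dropped
    with a log entry.  Labels follow the events' error flags; per-trial
    scheme and block error rate are carried for downstream grouping.
    ``baseline`` (seconds relative to onset, within the window) subtracts
    the per-trial, per-channel mean of that interval; no baseline is
    applied by default.
    """
    stream = np.atleast_2d(np.asarray(stream))
    window = window or EPOCH_WINDOWS[modality]
    n = stream.shape[1]
    lo = int(round(window[0] * rate))
    n_samp = int(round((window[1] - window[0]) * rate))
    trials, labels, schemes, rates_, idxs = [], [], [], [], []
    for i, ev in enumerate(events):
        start = int(round(ev.onset_time * rate)) + lo
        if start < 0 or start + n_samp > n:
            logger.info("dropping event %d (%s): window outside recording", i, modality)
            continue
        trials.append(stream[:, start : start + n_samp])
        labels.append(1 if ev.is_error else 0)
        schemes.append(ev.scheme)
        rates_.append(protocol.blocks[ev.block_id].error_rate if protocol is not None else np.nan)
        idxs.append(i)
    if not trials:
        raise ValueError("no epochable events inside the recording")
    data = np.stack(trials).astype(np.float32)
    if baseline is not None:
        b0 = int(round((baseline[0] - window[0]) * rate))
        b1 = int(round((baseline[1] - window[0]) * rate))
        if not 0 <= b0 < b1 <= data.shape[2]:
            raise ValueError("baseline interval must lie inside the epoch window")
        data = data - data[:, :, b0:b1].mean(axis=2, keepdims=True)
    return EpochSet(
        data=data,
        labels=np.asarray(labels, dtype=np.int8),
        modality=modality,
        window=window,
        rate=rate,
        channel_names=tuple(channel_names or (f"ch{i}" for i in range(stream.shape[0]))),
        schemes=np.asarray(schemes, dtype=object),
        block_error_rates=np.asarray(rates_, dtype=float),
        event_indices=np.asarray(idxs, dtype=int),
    )


# --------------------------------------------------------------------------
# full chains
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PreprocessConfig:
    bandpass: tuple[float, float] = (1.0, 20.0)
    kurtosis_alpha: float = 0.05
    interpolation: str = "spline"
    baseline_correct: bool = False      # off: chain applies no baseline step
    car_includes_eog: bool = False


def preprocess_eeg(
    recording: MultimodalRecording,
    montage: Montage,
    config: PreprocessConfig = PreprocessConfig(),
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Filter -> bad-channel interpolation -> EOG regression -> CAR.

    Returns the cleaned continuous scalp array (uV) and its channel names.
    """
    names = recording.channel_names
    scalp_idx = [i for i, c in enumerate(names) if c not in EOG_CHANNELS]
    eog_idx = [i for i, c in enumerate(names) if c in EOG_CHANNELS]
    scalp_names = tuple(names[i] for i in scalp_idx)

    filtered = bandpass_fir(recording.eeg.astype(np.float64), recording.eeg_rate,
                            *config.bandpass)
    scalp = filtered[scalp_idx]
    eog = filtered[eog_idx]
    bads = kurtosis_bad_channels(scalp, config.kurtosis_alpha)
    if bads:
        logger.info("interpolating %d bad channels: %s", len(bads),
                    [scalp_names[b] for b in bads])
        scalp = interpolate_channels(scalp, bads, montage, scalp_names,
                                     recording.eeg_rate, config.interpolation)
    scalp = eog_regress(scalp, eog)
    if config.car_includes_eog:
        both = common_average_reference(np.vstack([scalp, eog]))
        scalp = both[: len(scalp_idx)]
    else:
        scalp = common_average_reference(scalp)
    return scalp, scalp_names


def preprocess_session(
    recording: MultimodalRecording,
    montage: Montage,
    config: PreprocessConfig = PreprocessConfig(),
) -> dict[str, EpochSet]:
    """Run all three modality chains and return event-locked epoch sets."""
    scalp, scalp_names = preprocess_eeg(recording, montage, config)
    out = {
        "eeg": epoch(scalp, recording.eeg_rate, recording.events,
                     modality="eeg", channel_names=scalp_names,
                     protocol=recording.protocol,
                     # the EEG window has no pre-onset samples, so the
                     # optional baseline uses the first 100 ms post onset
                     baseline=(0.0, 0.1) if config.baseline_correct else None),
        "emg": epoch(recording.emg_rms, recording.emg_rms_rate, recording.events,
                     modality="emg", channel_names=("biceps", "triceps"),
                     protocol=recording.protocol),
        "kinematics": epoch(recording.kin_velocity[None, :], recording.kin_rate,
                            recording.events, modality="kinematics",
                            channel_names=("elbow_velocity",),
                            protocol=recording.protocol),
    }
    return out
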