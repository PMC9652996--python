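"""Synthetic multimodal cohort generator.

Emulates the statistical structure of the exosuit tracking sessions: 30
channels of EEG/EOG at 1000 Hz with 1/f background activity, blink
artifacts, and event-locked ERP components whose error-condition morphology
matches the reported grand averages (positive peak ~270 ms, error-related
negativity ~340 ms with a -2 uV fronto-central difference at Cz, sustained
positivity 400-600 ms, late negativity ~685 ms); biceps/triceps EMG as an
amplitude-modulated band-limited carrier at 2222 Hz with a sliding-window
RMS envelope at 222 Hz and error-evoked bursts beginning ~0.5 s after the
error trigger; and 100 Hz elbow kinematics with error-locked velocity
transients at ~350 ms (~18 deg/s under gravity compensation, ~31 deg/s
under the myoprocessor).

Between-subject variation (amplitude, latency, noise level) reproduces the
reported inter-subject ERP heterogeneity.  All randomness flows from one
seed; sessions are byte-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from errp_exo.montage import EOG_CHANNELS, Montage, build_montage
from errp_exo.protocol import (
    ExperimentEvent,
    ProtocolTiming,
    SessionProtocol,
    build_protocol,
    generate_session_events,
)

EEG_RATE = 1000.0
EMG_RAW_RATE = 2222.0
EMG_RMS_STRIDE = 10                      # raw samples per envelope sample
EMG_RMS_RATE = EMG_RAW_RATE / EMG_RMS_STRIDE  # 222.2 Hz
EMG_RMS_WINDOW = 0.1                     # s, sliding RMS window
KIN_RATE = 100.0


# --------------------------------------------------------------------------
# template definitions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ErpComponent:
    """One Gaussian ERP component at its peak channel.

    ``error_scale``/``nonerror_scale`` weight the component in the two trial
    conditions; a component with scales (1, 0) appears only on error trials
    and therefore carries the error-minus-correct difference wave.
    """

    name: str
    latency: float        # s post event onset
    amplitude: float      # uV at the peak channel
    width: float          # s, Gaussian sigma
    error_scale: float = 1.0
    nonerror_scale: float = 0.0


@dataclass(frozen=True)
class ERPTemplateSet:
    components: tuple[ErpComponent, ...]
    peak_channel: str = "Cz"
    topo_sigma: float = 0.6   # Gaussian falloff (unit-sphere chord) from peak channel
    # amplitudes are defined at the peak channel AFTER common-average
    # referencing (the convention in which grand averages are reported);
    # the topography is rescaled so CAR leaves the peak-channel weight at 1
    car_normalized: bool = True

    def difference_wave(self, times: np.ndarray) -> np.ndarray:
        """Noise-free error-minus-correct template at the peak channel."""
        out = np.zeros_like(times)
        for c in self.components:
            out += (c.error_scale - c.nonerror_scale) * c.amplitude * np.exp(
                -0.5 * ((times - c.latency) / c.width) ** 2
            )
        return out


def default_erp_templates() -> ERPTemplateSet:
    return ERPTemplateSet(
        components=(
            # movement-locked response shared by both conditions
            ErpComponent("motor", 0.150, 1.0, 0.040, 1.0, 1.0),
            ErpComponent("p270", 0.270, 1.2, 0.045, 1.0, 0.0),
            # component amplitude/latency calibrated so the error-minus-
            # correct difference, measured after the 1-20 Hz bandpass and
            # CAR of the analysis chain, bottoms out at -2.0 uV at 340 ms:
            # the flanking positivities overlap (~ +0.7 uV at 340 ms) and
            # the 1 Hz highpass reshapes the broad composite
            ErpComponent("ern", 0.334, -2.74, 0.050, 1.0, 0.0),
            ErpComponent("late_positivity", 0.500, 1.2, 0.100, 1.0, 0.0),
            ErpComponent("late_negativity", 0.685, -1.0, 0.050, 1.0, 0.0),
        )
    )


@dataclass(frozen=True)
class MotorTemplateSet:
    """Error-evoked EMG burst and elbow-velocity transient templates."""

    emg_burst_onset: float = 0.5      # s post error trigger
    emg_burst_width: float = 0.20     # s, half-width of the burst bump
    emg_burst_amp: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "gravity": {"biceps": 0.25, "triceps": 0.30},
        "myoprocessor": {"biceps": 0.40, "triceps": 0.30},
    })
    emg_baseline: dict[str, float] = field(default_factory=lambda: {
        "unassisted": 0.10, "gravity": 0.06, "myoprocessor": 0.14,
    })
    movement_emg_amp: float = 0.15    # movement-locked activation bump
    velocity_peak_latency: float = 0.350   # s post event onset
    velocity_peak_width: float = 0.070     # s, Gaussian sigma
    velocity_peak_amp: dict[str, float] = field(default_factory=lambda: {
        "gravity": 18.0, "myoprocessor": 31.0,   # deg/s
    })
    movement_amplitude_deg: float = 13.0   # elbow excursion per grid step
    velocity_noise_rms: float = 2.0        # deg/s
    # single-trial response variability: wearers react to some errors
    # strongly and barely to others; amplitudes are truncated-normal with
    # mean 1 and the latencies jitter trial-to-trial
    trial_amp_sd: float = 0.5
    trial_amp_floor: float = 0.05
    emg_latency_jitter_sd: float = 0.08    # s
    vel_latency_jitter_sd: float = 0.03    # s
    subject_latency_sd: float = 0.015      # s, used by the smear correction

    def velocity_trial_scale(self) -> float:
        """Single-trial multiplier making the expected grand-average
        transient peak equal ``velocity_peak_amp``.

        Corrects for (i) the mean of the truncated-normal trial amplitude
        and (ii) the peak reduction when Gaussian transients with jittered
        latencies are averaged (area is kept, the width grows to
        sqrt(w^2 + sigma_jitter^2)); the printed peak values are
        grand-average measurements, so the calibration is defined on that
        scale.
        """
        from scipy.stats import norm

        if self.trial_amp_sd == 0:
            sig_j2 = self.vel_latency_jitter_sd**2 + self.subject_latency_sd**2
            return float(np.sqrt(self.velocity_peak_width**2 + sig_j2)
                         / self.velocity_peak_width)
        z0 = (self.trial_amp_floor - 1.0) / self.trial_amp_sd
        amp_mean = (1.0 + (self.trial_amp_floor - 1.0) * norm.cdf(z0)
                    + self.trial_amp_sd * norm.pdf(z0))
        sig_j2 = self.vel_latency_jitter_sd**2 + self.subject_latency_sd**2
        smear = self.velocity_peak_width / np.sqrt(self.velocity_peak_width**2 + sig_j2)
        return float(1.0 / (amp_mean * smear))


@dataclass(frozen=True)
class NoiseConfig:
    alpha: float = 1.0          # 1/f^alpha spectral exponent above the knee
    # broadband per-channel RMS, calibrated so subject-level EEG decoding
    # lands in the 70-85% range typical of single-trial ErrP classification
    rms_uv: float = 3.5
    knee_hz: float = 1.0        # spectrum flat below the knee
    blink_rate_per_min: float = 10.0
    blink_amp_uv: float = 120.0
    blink_duration: float = 0.3
    eog_noise_uv: float = 15.0


#: fixed frontal projection weights of the blink artifact onto scalp channels
BLINK_SCALP_WEIGHTS: dict[str, float] = {
    "FP1": 0.35, "FP2": 0.35, "F7": 0.15, "F8": 0.15,
    "F3": 0.12, "F4": 0.12, "Fz": 0.10, "FC1": 0.05, "FC2": 0.05,
}
BLINK_EOG_WEIGHTS: dict[str, float] = {"EOG1": 1.0, "EOG2": 0.8, "EOG3": 0.8}


@dataclass(frozen=True)
class SubjectTraits:
    """Between-subject variation applied multiplicatively/additively.

    Neural and muscular response amplitudes vary substantially between
    subjects (25% SD); the error-evoked velocity transient is device-driven
    (valve override -> pressure drop -> arm acceleration), so its
    between-subject scaling is tighter (10% SD).
    """

    erp_amp: float = 1.0        # scales ERP amplitudes
    motor_amp: float = 1.0      # scales EMG bursts
    vel_amp: float = 1.0        # scales the velocity transient
    latency_shift: float = 0.0  # s, added to all component latencies
    noise_factor: float = 1.0   # scales background noise RMS


def draw_subject_traits(
    rng: np.random.Generator,
    amp_sd: float = 0.25,
    vel_amp_sd: float = 0.10,
    latency_sd: float = 0.015,
    noise_log_sd: float = 0.1,
) -> SubjectTraits:
    return SubjectTraits(
        erp_amp=float(max(0.3, 1.0 + amp_sd * rng.standard_normal())),
        motor_amp=float(max(0.3, 1.0 + amp_sd * rng.standard_normal())),
        vel_amp=float(max(0.5, 1.0 + vel_amp_sd * rng.standard_normal())),
        latency_shift=float(latency_sd * rng.standard_normal()),
        noise_factor=float(np.exp(noise_log_sd * rng.standard_normal())),
    )


# --------------------------------------------------------------------------
# stream generators
# --------------------------------------------------------------------------

def pink_noise(
    n_samples: int,
    n_channels: int,
    rate: float,
    rng: np.random.Generator,
    alpha: float = 1.0,
    knee_hz: float = 1.0,
    rms: float = 1.0,
) -> np.ndarray:
    """1/f^alpha Gaussian noise with a low-frequency knee, unit-RMS scaled.

    The spectrum is flat below ``knee_hz`` so total power does not diverge
    with record length; each channel is normalised to ``rms``.
    """
    from scipy import fft as sfft

    n_fft = sfft.next_fast_len(n_samples)
    freqs = sfft.rfftfreq(n_fft, 1.0 / rate)
    shaping = 1.0 / np.maximum(freqs, knee_hz) ** (alpha / 2.0)
    shaping[0] = 0.0  # no DC
    out = np.empty((n_channels, n_samples), dtype=np.float32)
    for ch in range(n_channels):
        spec = sfft.rfft(rng.standard_normal(n_fft)) * shaping
        x = sfft.irfft(spec, n=n_fft)[:n_samples]
        x *= rms / np.sqrt(np.mean(x**2))
        out[ch] = x.astype(np.float32)
    return out


def _blink_waveform(rate: float, duration: float) -> np.ndarray:
    """Stereotyped biphasic blink: dominant positive lobe, small rebound."""
    t = np.arange(int(round(duration * rate))) / rate
    w = np.exp(-0.5 * ((t - 0.10) / 0.045) ** 2) - 0.3 * np.exp(-0.5 * ((t - 0.22) / 0.06) ** 2)
    return w


def _add_at(stream: np.ndarray, start: int, waveform: np.ndarray) -> None:
    """Add ``waveform`` into ``stream`` at sample ``start`` with edge clipping."""
    n = stream.shape[-1]
    s, e = max(start, 0), min(start + len(waveform), n)
    if s < e:
        stream[..., s:e] += waveform[s - start : e - start]


def synth_eeg(
    events: list[ExperimentEvent],
    duration: float,
    montage: Montage,
    templates: ERPTemplateSet | None = None,
    noise_cfg: NoiseConfig | None = None,
    rng: np.random.Generator | None = None,
    traits: SubjectTraits = SubjectTraits(),
    effect_scale: float = 1.0,
    rate: float = EEG_RATE,
) -> np.ndarray:
    """Synthesise the 30-channel EEG/EOG stream in microvolts (float32).

    Background 1/f noise on every channel, blink artifacts projected onto
    the EOG and frontal channels, and event-locked ERP templates whose
    error-specific components are weighted by ``effect_scale`` (0 makes the
    two trial conditions statistically identical).
    """
    templates = templates or default_erp_templates()
    noise_cfg = noise_cfg or NoiseConfig()
    rng = rng or np.random.default_rng(0)
    n = int(round(duration * rate))
    names = montage.channel_names
    n_ch = len(names)
    eog_idx = [montage.index(c) for c in EOG_CHANNELS]

    eeg = pink_noise(n, n_ch, rate, rng, noise_cfg.alpha, noise_cfg.knee_hz,
                     noise_cfg.rms_uv * traits.noise_factor)
    for i in eog_idx:
        eeg[i] *= noise_cfg.eog_noise_uv / noise_cfg.rms_uv

    # blink artifacts: homogeneous Poisson train over the record
    if noise_cfg.blink_rate_per_min > 0:
        n_blinks = rng.poisson(noise_cfg.blink_rate_per_min * duration / 60.0)
        blink = _blink_waveform(rate, noise_cfg.blink_duration)
        weights = np.zeros(n_ch)
        for name, w in {**BLINK_SCALP_WEIGHTS, **BLINK_EOG_WEIGHTS}.items():
            weights[montage.index(name)] = w
        for t0 in np.sort(rng.uniform(0, duration - noise_cfg.blink_duration, n_blinks)):
            amp = noise_cfg.blink_amp_uv * rng.uniform(0.7, 1.3)
            start = int(round(t0 * rate))
            for ci in np.nonzero(weights)[0]:
                _add_at(eeg[ci], start, (amp * weights[ci] * blink).astype(np.float32))

    # spatial weights: Gaussian falloff from the peak channel over the scalp
    center = montage.positions[templates.peak_channel]
    topo = np.zeros(n_ch)
    scalp = []
    for i, name in enumerate(names):
        if name in EOG_CHANNELS:
            continue
        d = np.linalg.norm(montage.positions[name] - center)
        topo[i] = np.exp(-0.5 * (d / templates.topo_sigma) ** 2)
        scalp.append(i)
    if templates.car_normalized:
        # CAR maps weights w -> w - mean(w); rescale so the peak channel
        # keeps weight 1 after re-referencing
        topo /= 1.0 - topo[scalp].mean()

    # event-locked components
    t_tmpl = np.arange(int(round(1.0 * rate))) / rate
    scalp_idx = np.nonzero(topo)[0]
    for ev in events:
        wave = np.zeros_like(t_tmpl)
        for c in templates.components:
            scale = (c.nonerror_scale + effect_scale * (c.error_scale - c.nonerror_scale)
                     if ev.is_error else c.nonerror_scale)
            if scale == 0.0:
                continue
            lat = c.latency + traits.latency_shift
            wave += scale * traits.erp_amp * c.amplitude * np.exp(
                -0.5 * ((t_tmpl - lat) / c.width) ** 2
            )
        start = int(round(ev.onset_time * rate))
        for ci in scalp_idx:
            _add_at(eeg[ci], start, (topo[ci] * wave).astype(np.float32))
    return eeg


def _block_spans(events: list[ExperimentEvent], pad: float = 2.0) -> dict[int, tuple[float, float]]:
    spans: dict[int, tuple[float, float]] = {}
    for ev in events:
        lo, hi = spans.get(ev.block_id, (np.inf, -np.inf))
        spans[ev.block_id] = (min(lo, ev.onset_time - pad), max(hi, ev.onset_time + pad))
    return spans


def synth_emg(
    events: list[ExperimentEvent],
    duration: float,
    templates: MotorTemplateSet | None = None,
    rng: np.random.Generator | None = None,
    traits: SubjectTraits = SubjectTraits(),
    effect_scale: float = 1.0,
    carrier_uv: float = 100.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw biceps/triceps EMG at 2222 Hz plus its RMS envelope at 222 Hz.

    The raw signal is a 20-450 Hz band-limited Gaussian carrier amplitude-
    modulated by a normalised activation envelope: a scheme-dependent
    baseline (myoprocessor > unassisted > gravity), a movement-locked bump
    per event, and an error-evoked burst beginning ``emg_burst_onset``
    (~0.5 s) after the error trigger.  The RMS envelope uses a 100 ms
    sliding window with a 10-sample stride.
    """
    templates = templates or MotorTemplateSet()
    rng = rng or np.random.default_rng(0)
    n = int(round(duration * EMG_RAW_RATE))
    t_burst = np.arange(int(round(1.0 * EMG_RAW_RATE))) / EMG_RAW_RATE

    envelope = np.zeros((2, n))  # rows: biceps, triceps
    for blk, (lo, hi) in _block_spans(events).items():
        scheme = next(e.scheme for e in events if e.block_id == blk)
        base = templates.emg_baseline[scheme]
        s, e = max(int(lo * EMG_RAW_RATE), 0), min(int(hi * EMG_RAW_RATE), n)
        envelope[:, s:e] = base
    for ev in events:
        start = int(round(ev.onset_time * EMG_RAW_RATE))
        move = templates.movement_emg_amp * np.exp(-0.5 * ((t_burst - 0.30) / 0.15) ** 2)
        _add_at(envelope[0], start, move)
        _add_at(envelope[1], start, 0.6 * move)
        if ev.is_error:
            jit = templates.emg_latency_jitter_sd * rng.standard_normal()
            center = templates.emg_burst_onset + templates.emg_burst_width + jit
            shape = np.exp(-0.5 * ((t_burst - center) / templates.emg_burst_width) ** 2)
            shape[t_burst < templates.emg_burst_onset + jit] = 0.0  # burst begins ~+0.5 s
            amps = templates.emg_burst_amp[ev.scheme]
            k = effect_scale * traits.motor_amp * max(
                templates.trial_amp_floor, 1.0 + templates.trial_amp_sd * rng.standard_normal())
            _add_at(envelope[0], start, k * amps["biceps"] * shape)
            _add_at(envelope[1], start, k * amps["triceps"] * shape)
    np.clip(envelope, 0.0, 1.0, out=envelope)

    sos = signal.butter(4, [20.0, 450.0], btype="bandpass", fs=EMG_RAW_RATE, output="sos")
    raw = np.empty((2, n), dtype=np.float32)
    for m in range(2):
        carrier = signal.sosfiltfilt(sos, rng.standard_normal(n))
        carrier /= np.sqrt(np.mean(carrier**2))
        raw[m] = (carrier_uv * envelope[m] * carrier).astype(np.float32)

    rms = rms_envelope(raw, EMG_RAW_RATE, window=EMG_RMS_WINDOW, stride=EMG_RMS_STRIDE)
    return raw, rms


def rms_envelope(
    raw: np.ndarray,
    rate: float = EMG_RAW_RATE,
    window: float = EMG_RMS_WINDOW,
    stride: int = EMG_RMS_STRIDE,
) -> np.ndarray:
    """Sliding-window RMS of a raw EMG array (channels x samples)."""
    from scipy.ndimage import uniform_filter1d

    win = int(round(window * rate))
    sq = uniform_filter1d(np.asarray(raw, dtype=np.float64) ** 2, size=win, axis=-1, mode="nearest")
    return np.sqrt(np.maximum(sq[..., ::stride], 0.0)).astype(np.float32)


def synth_kinematics(
    events: list[ExperimentEvent],
    duration: float,
    templates: MotorTemplateSet | None = None,
    rng: np.random.Generator | None = None,
    traits: SubjectTraits = SubjectTraits(),
    effect_scale: float = 1.0,
    control_traces: dict[int, "np.ndarray"] | None = None,
    rate: float = KIN_RATE,
) -> tuple[np.ndarray, np.ndarray]:
    """Elbow angle (deg) and angular velocity (deg/s) at 100 Hz.

    Tracking movements are minimum-jerk steps of alternating random
    direction; error events add a flexion-signed velocity transient peaking
    ``velocity_peak_latency`` (~350 ms) after onset with scheme-dependent
    amplitude.  When ``control_traces`` maps an event index to a closed-loop
    simulator velocity trace (deg/s at 100 Hz), that trace replaces the
    template transient for the event.
    """
    templates = templates or MotorTemplateSet()
    rng = rng or np.random.default_rng(0)
    n = int(round(duration * rate))
    vel = (templates.velocity_noise_rms * rng.standard_normal(n)).astype(np.float64)
    # smooth the noise to plausible kinematic bandwidth (~5 Hz)
    sos = signal.butter(2, 5.0, fs=rate, output="sos")
    vel = signal.sosfiltfilt(sos, vel)
    vel *= templates.velocity_noise_rms / max(np.sqrt(np.mean(vel**2)), 1e-12)

    move_dur = 1.4
    t_move = np.arange(int(round(move_dur * rate))) / rate
    s = t_move / move_dur
    minjerk_vel = (30 * s**2 - 60 * s**3 + 30 * s**4) / move_dur  # integrates to 1
    t_tr = np.arange(int(round(1.0 * rate))) / rate
    for i, ev in enumerate(events):
        start = int(round(ev.onset_time * rate))
        if control_traces is not None and i in control_traces:
            _add_at(vel, start, np.asarray(control_traces[i], dtype=np.float64))
            continue
        sign = 1.0 if rng.random() < 0.5 else -1.0
        _add_at(vel, start, sign * templates.movement_amplitude_deg * minjerk_vel)
        if ev.is_error:
            amp = (templates.velocity_peak_amp[ev.scheme] * templates.velocity_trial_scale()
                   * effect_scale * traits.vel_amp
                   * max(templates.trial_amp_floor,
                         1.0 + templates.trial_amp_sd * rng.standard_normal()))
            lat = (templates.velocity_peak_latency + traits.latency_shift
                   + templates.vel_latency_jitter_sd * rng.standard_normal())
            _add_at(vel, start, amp * np.exp(-0.5 * ((t_tr - lat) / templates.velocity_peak_width) ** 2))
    angle = 90.0 + np.cumsum(vel) / rate
    return angle.astype(np.float32), vel.astype(np.float32)


# --------------------------------------------------------------------------
# session / cohort assembly
# --------------------------------------------------------------------------

@dataclass
class MultimodalRecording:
    """One synthetic subject session: synchronized streams + event markers."""

    subject_id: int
    rng_seed: int
    protocol: SessionProtocol
    events: list[ExperimentEvent]
    channel_names: tuple[str, ...]
    eeg: np.ndarray          # (30, n) uV at eeg_rate
    eeg_rate: float
    emg_raw: np.ndarray      # (2, n) uV at emg_raw_rate; rows biceps, triceps
    emg_raw_rate: float
    emg_rms: np.ndarray      # (2, m) uV at emg_rms_rate
    emg_rms_rate: float
    kin_angle: np.ndarray    # (n,) deg at kin_rate
    kin_velocity: np.ndarray # (n,) deg/s at kin_rate
    kin_rate: float
    traits: SubjectTraits = field(default_factory=SubjectTraits)

    @property
    def duration(self) -> float:
        return self.eeg.shape[1] / self.eeg_rate

    def stream(self, modality: str) -> tuple[np.ndarray, float]:
        if modality == "eeg":
            return self.eeg, self.eeg_rate
        if modality == "emg":
            return self.emg_rms, self.emg_rms_rate
        if modality == "kinematics":
            return self.kin_velocity[None, :], self.kin_rate
        raise ValueError(f"unknown modality {modality!r}")


def synth_session(
    subject_id: int,
    seed: int | np.random.SeedSequence,
    protocol: SessionProtocol | None = None,
    erp_templates: ERPTemplateSet | None = None,
    motor_templates: MotorTemplateSet | None = None,
    noise_cfg: NoiseConfig | None = None,
    effect_scale: float = 1.0,
    timing: ProtocolTiming | None = None,
    traits: SubjectTraits | None = None,
    montage: Montage | None = None,
    tail: float = 3.0,
) -> MultimodalRecording:
    """Compose protocol + the three stream generators into one session."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_proto, s_traits, s_eeg, s_emg, s_kin = ss.spawn(5)
    proto_seed = int(s_proto.generate_state(1)[0] % (2**31))
    if protocol is None:
        protocol = build_protocol(proto_seed)
    events = generate_session_events(protocol, np.random.default_rng(s_proto), timing)
    duration = events[-1].onset_time + tail
    mont = montage or build_montage()
    if traits is None:
        traits = draw_subject_traits(np.random.default_rng(s_traits))

    eeg = synth_eeg(events, duration, mont, erp_templates, noise_cfg,
                    np.random.default_rng(s_eeg), traits, effect_scale)
    emg_raw, emg_rms = synth_emg(events, duration, motor_templates,
                                 np.random.default_rng(s_emg), traits, effect_scale)
    angle, vel = synth_kinematics(events, duration, motor_templates,
                                  np.random.default_rng(s_kin), traits, effect_scale)
    return MultimodalRecording(
        subject_id=subject_id,
        rng_seed=proto_seed,
        protocol=protocol,
        events=events,
        channel_names=mont.channel_names,
        eeg=eeg, eeg_rate=EEG_RATE,
        emg_raw=emg_raw, emg_raw_rate=EMG_RAW_RATE,
        emg_rms=emg_rms, emg_rms_rate=EMG_RMS_RATE,
        kin_angle=angle, kin_velocity=vel, kin_rate=KIN_RATE,
        traits=traits,
    )


def synth_cohort(
    n_subjects: int = 5,
    seed: int = 0,
    **session_kwargs,
) -> list[MultimodalRecording]:
    """Generate an n-subject cohort with between-subject variation."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    seeds = np.random.SeedSequence(seed).spawn(n_subjects)
    return [synth_session(i + 1, s, **session_kwargs) for i, s in enumerate(seeds)]


def iter_cohort(n_subjects: int = 5, seed: int = 0, **session_kwargs):
    """Yield cohort sessions one at a time (memory-friendly)."""
    for i, s in enumerate(np.random.SeedSequence(seed).spawn(n_subjects)):
        yield synth_session(i + 1, s, **session_kwargs)
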