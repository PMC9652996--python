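"""Interchange formats: delimited streams + JSON sidecars, events TSV,
epoch containers, hierarchical YAML configs, EDF reading.

The canonical lossless on-disk dialect for a recording is one tab-delimited
text file per stream (samples x channels, float32-exact ``%.9g``) plus a
``sidecar.json`` naming rates, channels and provenance.  Events are
tab-delimited with BIDS-events-like columns.  EDF files can be read (via
MNE) for real-world data; epochs persist as a binary array container
(``.npz``) with a JSON sidecar.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from errp_exo.protocol import BlockSpec, ExperimentEvent, SessionProtocol
from errp_exo.preprocess import EpochSet
from errp_exo.synth import MultimodalRecording, SubjectTraits

EVENT_COLUMNS = ("onset", "duration", "block", "episode", "scheme",
                 "is_error", "error_type", "is_correct")


# --------------------------------------------------------------------------
# events
# --------------------------------------------------------------------------

def write_events_tsv(events: list[ExperimentEvent], path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {
            "onset": ev.onset_time, "duration": 0.0, "block": ev.block_id,
            "episode": ev.episode_id, "scheme": ev.scheme,
            "is_error": int(ev.is_error), "error_type": ev.error_type,
            "is_correct": int(ev.is_correct_step),
        }
        for ev in events
    ]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, sep="\t", index=False)
    return path

def read_events_tsv(path: str | Path) -> list[ExperimentEvent]:
    df = pd.read_csv(path, sep="\t")
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"events table missing column(s): {sorted(missing)}")
    events = []
    counters: dict[tuple[int, int], int] = {}
    for _, r in df.iterrows():
        key = (int(r["block"]), int(r["episode"]))
        counters[key] = counters.get(key, -1) + 1
        events.append(ExperimentEvent(
            block_id=int(r["block"]), episode_id=int(r["episode"]),
            event_id=counters[key], onset_time=float(r["onset"]),
            scheme=str(r["scheme"]), is_error=bool(r["is_error"]),
            error_type=str(r["error_type"]), is_correct_step=bool(r["is_correct"]),
        ))
    return events


# --------------------------------------------------------------------------
# protocol config
# --------------------------------------------------------------------------

def write_protocol_yaml(protocol: SessionProtocol, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "rng_seed": protocol.rng_seed,
        "episodes_per_block": protocol.episodes_per_block,
        "events_per_episode": list(protocol.events_per_episode),
        "blocks": [{"scheme": b.scheme, "error_rate": b.error_rate} for b in protocol.blocks],
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path

def read_protocol_yaml(path: str | Path) -> SessionProtocol:
    doc = yaml.safe_load(Path(path).read_text())
    try:
        return SessionProtocol(
            blocks=tuple(BlockSpec(b["scheme"], float(b["error_rate"])) for b in doc["blocks"]),
            episodes_per_block=int(doc["episodes_per_block"]),
            events_per_episode=tuple(doc["events_per_episode"]),
            rng_seed=int(doc["rng_seed"]),
        )
    except KeyError as e:
        raise ValueError(f"protocol config missing field {e.args[0]!r}") from e


# --------------------------------------------------------------------------
# recordings (delimited + sidecar dialect)
# --------------------------------------------------------------------------

def _write_stream(path: Path, data: np.ndarray, columns: tuple[str, ...]) -> None:
    # %.9g round-trips float32 exactly
    np.savetxt(path, np.asarray(data, dtype=np.float32).T, delimiter="\t",
               fmt="%.9g", header="\t".join(columns), comments="")

def _read_stream(path: Path, expected: tuple[str, ...] | None = None) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    if expected is not None and tuple(df.columns) != tuple(expected):
        raise ValueError(f"{path.name}: channel mismatch, expected {expected}, "
                         f"found {tuple(df.columns)}")
    return df.to_numpy(dtype=np.float32).T


def write_recording(recording: MultimodalRecording, out_dir: str | Path) -> Path:
    """Write one session in the delimited + JSON-sidecar dialect."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sidecar = {
        "subject_id": recording.subject_id,
        "rng_seed": recording.rng_seed,
        "units": {"eeg": "uV", "emg": "uV", "kinematics": "deg, deg/s"},
        "rates": {
            "eeg": recording.eeg_rate, "emg_raw": recording.emg_raw_rate,
            "emg_rms": recording.emg_rms_rate, "kinematics": recording.kin_rate,
        },
        "channels": {
            "eeg": list(recording.channel_names),
            "emg_raw": ["biceps", "triceps"], "emg_rms": ["biceps", "triceps"],
            "kinematics": ["angle", "velocity"],
        },
        "traits": dataclasses.asdict(recording.traits),
    }
    (out / "sidecar.json").write_text(json.dumps(sidecar, indent=1))
    _write_stream(out / "eeg.tsv", recording.eeg, recording.channel_names)
    _write_stream(out / "emg_raw.tsv", recording.emg_raw, ("biceps", "triceps"))
    _write_stream(out / "emg_rms.tsv", recording.emg_rms, ("biceps", "triceps"))
    _write_stream(out / "kinematics.tsv",
                  np.vstack([recording.kin_angle, recording.kin_velocity]),
                  ("angle", "velocity"))
    write_events_tsv(recording.events, out / "events.tsv")
    write_protocol_yaml(recording.protocol, out / "protocol.yaml")
    return out


def read_recording(in_dir: str | Path) -> MultimodalRecording:
    """Read a session written by :func:`write_recording` (lossless)."""
    src = Path(in_dir)
    try:
        sidecar = json.loads((src / "sidecar.json").read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"malformed sidecar.json: {e}") from e
    for f in ("rates", "channels", "subject_id", "rng_seed"):
        if f not in sidecar:
            raise ValueError(f"sidecar.json missing field {f!r}")
    rates = sidecar["rates"]
    chans = sidecar["channels"]
    eeg = _read_stream(src / "eeg.tsv", tuple(chans["eeg"]))
    emg_raw = _read_stream(src / "emg_raw.tsv", tuple(chans["emg_raw"]))
    emg_rms = _read_stream(src / "emg_rms.tsv", tuple(chans["emg_rms"]))
    kin = _read_stream(src / "kinematics.tsv", tuple(chans["kinematics"]))
    events = read_events_tsv(src / "events.tsv")
    protocol = read_protocol_yaml(src / "protocol.yaml")
    traits = SubjectTraits(**sidecar.get("traits", {}))
    return MultimodalRecording(
        subject_id=int(sidecar["subject_id"]), rng_seed=int(sidecar["rng_seed"]),
        protocol=protocol, events=events,
        channel_names=tuple(chans["eeg"]),
        eeg=eeg, eeg_rate=float(rates["eeg"]),
        emg_raw=emg_raw, emg_raw_rate=float(rates["emg_raw"]),
        emg_rms=emg_rms, emg_rms_rate=float(rates["emg_rms"]),
        kin_angle=kin[0], kin_velocity=kin[1], kin_rate=float(rates["kinematics"]),
        traits=traits,
    )


def read_signal_edf(path: str | Path) -> tuple[np.ndarray, float, tuple[str, ...]]:
    """Read an EDF signal file: (channels x samples, rate, channel names)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="ERROR")
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), tuple(raw.ch_names)


# --------------------------------------------------------------------------
# epochs and results
# --------------------------------------------------------------------------

def write_epochs(epochs: EpochSet, path: str | Path) -> Path:
    """Persist an EpochSet as <path>.npz plus <path>.json sidecar."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), data=epochs.data,
             labels=epochs.labels,
             block_error_rates=epochs.block_error_rates,
             event_indices=epochs.event_indices,
             schemes=np.asarray(epochs.schemes, dtype="U16"))
    meta = {
        "modality": epochs.modality, "window": list(epochs.window),
        "rate": epochs.rate, "channel_names": list(epochs.channel_names),
        "label_names": list(EpochSet.LABEL_NAMES),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path.with_suffix(".npz")

def read_epochs(path: str | Path) -> EpochSet:
    path = Path(path)
    with np.load(path.with_suffix(".npz"), allow_pickle=False) as z:
        arrays = {k: z[k] for k in z.files}
    try:
        meta = json.loads(path.with_suffix(".json").read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"malformed epochs sidecar: {e}") from e
    return EpochSet(
        data=arrays["data"], labels=arrays["labels"],
        modality=meta["modality"], window=tuple(meta["window"]),
        rate=float(meta["rate"]), channel_names=tuple(meta["channel_names"]),
        schemes=arrays["schemes"].astype(object),
        block_error_rates=arrays["block_error_rates"],
        event_indices=arrays["event_indices"],
    )


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable config echo."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
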