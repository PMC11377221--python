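"""Session persistence: deterministic columnar archives, optional EDF reading.

A session directory holds ``eeg.npy`` (channels x samples, microvolts),
``emg.npy`` (2 x samples, millivolts), and a ``meta.json`` sidecar with the
sampling rate, channel names, and — for synthetic data — the ground-truth
onsets and leg labels. The .npy format carries no timestamps and the JSON
is written with sorted keys, so the same recording always produces
bit-identical files.

EDF recordings are read through mne when available (reading only; this
package does not write EDF).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from mrcp.synthgen import SessionRecording, SubjectProfile


def save_session(rec: SessionRecording, out_dir: str | Path) -> Path:
    """Write one session as eeg.npy + emg.npy + meta.json; deterministic."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.save(out / "eeg.npy", rec.eeg)
    np.save(out / "emg.npy", rec.emg)
    meta = {
        "fs": rec.fs,
        "channel_names": rec.channel_names,
        "true_onsets": rec.true_onsets.tolist(),
        "leg_labels": rec.leg_labels,
        "subject_id": rec.subject_id,
        "session_id": rec.session_id,
        "profile": asdict(rec.profile) if rec.profile is not None else None,
    }
    (out / "meta.json").write_text(json.dumps(meta, sort_keys=True, indent=1) + "\n")
    return out


def load_session(path: str | Path) -> SessionRecording:
    """Load a session from an archive directory or an EDF file."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return _load_edf(path)
    meta = json.loads((path / "meta.json").read_text())
    return SessionRecording(
        eeg=np.load(path / "eeg.npy"),
        emg=np.load(path / "emg.npy"),
        fs=meta["fs"],
        channel_names=meta["channel_names"],
        true_onsets=np.asarray(meta["true_onsets"], dtype=int),
        leg_labels=meta["leg_labels"],
        subject_id=meta.get("subject_id", 0),
        session_id=meta.get("session_id", 0),
        profile=(SubjectProfile(**meta["profile"])
                 if meta.get("profile") else None),
    )


def _load_edf(path: Path) -> SessionRecording:
    """Read an EDF recording; EMG channels are those whose name contains
    'EMG' (case-insensitive), everything else is treated as EEG."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError("reading EDF requires the optional mne dependency") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    names = raw.ch_names
    data = raw.get_data()
    emg_idx = [i for i, n in enumerate(names) if "emg" in n.lower()]
    eeg_idx = [i for i in range(len(names)) if i not in emg_idx]
    emg = data[emg_idx] * 1e3 if emg_idx else np.zeros((2, data.shape[1]))
    return SessionRecording(
        eeg=data[eeg_idx] * 1e6,  # mne uses volts internally
        emg=emg,
        fs=float(raw.info["sfreq"]),
        channel_names=[names[i] for i in eeg_idx],
        true_onsets=np.array([], dtype=int),
        leg_labels=[],
    )
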