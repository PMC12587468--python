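"""On-disk formats: HDF5 recordings/features/models, CSV hypnograms, JSON maps.

Recordings use an HDF5 container with datasets ``/signals`` (channels x
samples) and ``/fs`` plus a JSON channel->region map attribute; feature
tensors store ``/features`` (windows x R x R x F), ``/freqs``, ``/valid_mask``
and a JSON metadata attribute; SAE models store ``/A``, ``/b``, ``/C_diag``,
``/H``, ``/mu`` and metadata.  Hypnograms travel as plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .features import FeatureTensor, Recording
from .hypnogram import TransitionMatrix
from .sae import ElectomeModel
from .states import state_name


def write_recording(path, recording: Recording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=recording.signals)
        f.create_dataset("fs", data=recording.fs)
        meta = {
            "channel_region_map": {str(k): v for k, v in recording.channel_region_map.items()},
            "emg_channel": recording.emg_channel,
            "subject_id": recording.subject_id,
            "session_id": recording.session_id,
        }
        f.attrs["meta"] = json.dumps(meta)


def read_recording(path) -> Recording:
    try:
        with h5py.File(path, "r") as f:
            signals = f["signals"][...]
            fs = float(f["fs"][()])
            meta = json.loads(f.attrs["meta"])
    except OSError as e:
        raise OSError(f"cannot read recording {path}: {e}") from e
    return Recording(
        signals=signals,
        fs=fs,
        channel_region_map={int(k): v for k, v in meta["channel_region_map"].items()},
        emg_channel=meta.get("emg_channel"),
        subject_id=meta.get("subject_id", ""),
        session_id=meta.get("session_id", ""),
    )


def write_truth_csv(path, truth, window_s: float = 2.0) -> None:
    n = len(truth)
    pd.DataFrame(
        {
            "window_index": np.arange(n),
            "start_s": np.arange(n) * window_s,
            "end_s": (np.arange(n) + 1) * window_s,
            "label": [state_name(int(s)) for s in truth.state_sequence],
        }
    ).to_csv(path, index=False)


def write_features(path, tensor: FeatureTensor) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=tensor.values)
        f.create_dataset("freqs", data=tensor.freqs)
        f.create_dataset("valid_mask", data=tensor.valid_mask)
        f.attrs["meta"] = json.dumps(
            {
                "regions": tensor.regions,
                "window_s": tensor.window_s,
                "normalization_scalar": tensor.normalization_scalar,
                "subject_id": tensor.subject_id,
                "session_id": tensor.session_id,
            }
        )


def read_features(path) -> FeatureTensor:
    with h5py.File(path, "r") as f:
        values = f["features"][...]
        freqs = f["freqs"][...]
        valid = f["valid_mask"][...]
        meta = json.loads(f.attrs["meta"])
    return FeatureTensor(
        values=values, freqs=freqs, regions=meta["regions"],
        valid_mask=valid, window_s=meta.get("window_s", 2.0),
        normalization_scalar=meta.get("normalization_scalar"),
        subject_id=meta.get("subject_id", ""), session_id=meta.get("session_id", ""),
    )


def write_model(path, model: ElectomeModel) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("A", data=model.A)
        f.create_dataset("b", data=model.b)
        f.create_dataset("C_diag", data=model.c_diag)
        f.create_dataset("H", data=model.H)
        f.create_dataset("mu", data=model.mu)
        f.attrs["meta"] = json.dumps(
            {
                "regions": model.regions,
                "freqs": None if model.freqs is None else np.asarray(model.freqs).tolist(),
                "state_order": ["wake", "nrem", "rem"],
                "seed": model.seed,
                "version": 1,
            }
        )


def read_model(path) -> ElectomeModel:
    with h5py.File(path, "r") as f:
        A = f["A"][...]
        b = f["b"][...]
        c = f["C_diag"][...]
        H = f["H"][...]
        mu = float(f["mu"][()])
        meta = json.loads(f.attrs["meta"])
    freqs = meta.get("freqs")
    return ElectomeModel(
        A=A, b=b, c_diag=c, H=H, mu=mu,
        regions=meta.get("regions", []),
        freqs=None if freqs is None else np.asarray(freqs),
        seed=meta.get("seed", 0),
    )


def write_transitions(path, tm: TransitionMatrix) -> None:
    Path(path).write_text(
        json.dumps(
            {"probs": tm.probs.tolist(), "smoothing": tm.smoothing, "source": tm.source},
            indent=2,
        )
    )


def read_transitions(path) -> TransitionMatrix:
    payload = json.loads(Path(path).read_text())
    return TransitionMatrix(
        np.asarray(payload["probs"], dtype=float),
        smoothing=payload.get("smoothing", 1.0),
        source=payload.get("source", ""),
    )
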