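"""The package's own on-disk archive for epochs and evoked waveforms.

One file = an 8-byte magic string, a 4-byte little-endian header length, a
UTF-8 JSON header (shapes, time axis, labels, provenance), then the data
tensor as little-endian float32.  CSV export is provided for spreadsheet
consumers.
"""

from __future__ import annotations

import json
import struct

import numpy as np
import pandas as pd

from .containers import Epochs, EvokedWaveform

__all__ = [
    "save_evoked",
    "load_evoked",
    "save_epochs",
    "load_epochs",
    "evoked_to_csv",
]

_MAGIC = b"PRESTIM1"


def _write(path, header: dict, payload: np.ndarray) -> None:
    header = dict(header)
    header["shape"] = list(payload.shape)
    blob = json.dumps(header, sort_keys=True).encode("utf-8")
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<I", len(blob)))
        fh.write(blob)
        fh.write(np.ascontiguousarray(payload, dtype="<f4").tobytes())


def _read(path) -> tuple[dict, np.ndarray]:
    with open(path, "rb") as fh:
        magic = fh.read(8)
        if magic != _MAGIC:
            raise ValueError(f"{path}: not a prestim archive (bad magic {magic!r})")
        (hlen,) = struct.unpack("<I", fh.read(4))
        header = json.loads(fh.read(hlen).decode("utf-8"))
        payload = np.frombuffer(fh.read(), dtype="<f4").astype(float)
    return header, payload.reshape(header["shape"])


def save_evoked(path, evoked: EvokedWaveform) -> None:
    _write(
        path,
        {
            "kind": "evoked",
            "times_ms": evoked.times.tolist(),
            "channel_names": list(evoked.channel_names),
            "n": evoked.n,
            "condition": evoked.condition,
            "lock": evoked.lock,
        },
        evoked.data,
    )


def load_evoked(path) -> EvokedWaveform:
    header, data = _read(path)
    if header.get("kind") != "evoked":
        raise ValueError(f"{path}: archive holds {header.get('kind')!r}, not evoked")
    return EvokedWaveform(
        data=data,
        times=np.asarray(header["times_ms"], dtype=float),
        channel_names=tuple(header["channel_names"]),
        n=int(header["n"]),
        condition=header["condition"],
        lock=header["lock"],
    )


def save_epochs(path, epochs: Epochs) -> None:
    _write(
        path,
        {
            "kind": "epochs",
            "times_ms": epochs.times.tolist(),
            "channel_names": list(epochs.channel_names),
            "labels": [str(x) for x in epochs.labels],
            "rejected": epochs.rejected.astype(int).tolist(),
            "reject_reason": [str(x) for x in epochs.reject_reason],
            "sampling_rate": epochs.sampling_rate,
            "lock": epochs.lock,
        },
        epochs.data,
    )


def load_epochs(path) -> Epochs:
    header, data = _read(path)
    if header.get("kind") != "epochs":
        raise ValueError(f"{path}: archive holds {header.get('kind')!r}, not epochs")
    return Epochs(
        data=data,
        times=np.asarray(header["times_ms"], dtype=float),
        channel_names=tuple(header["channel_names"]),
        labels=np.asarray(header["labels"], dtype=object),
        sampling_rate=float(header["sampling_rate"]),
        lock=header["lock"],
        rejected=np.asarray(header["rejected"], dtype=bool),
        reject_reason=np.asarray(header["reject_reason"], dtype=object),
    )


def evoked_to_csv(path, evoked: EvokedWaveform) -> None:
    """One column per channel, indexed by time in milliseconds."""
    frame = pd.DataFrame(
        evoked.data.T, index=pd.Index(evoked.times, name="time_ms"),
        columns=list(evoked.channel_names),
    )
    frame.to_csv(path)
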