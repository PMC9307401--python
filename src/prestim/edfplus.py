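"""EDF+ exchange format: a 16-bit writer, a validating reader, event sidecars.

Recordings are written as EDF+C files with physical units of microvolts and
the trial markers embedded as EDF+ annotations using the label grammar

    ``blk:E=<value>``   reward parameter of the block (once, at t=0)
    ``dec:<side>``      decision marker, side in {left, right}
    ``fb:<valence>``    feedback marker, valence in {gain, loss}

A tab-separated sidecar (columns ``sample`` and ``label``, same grammar) is
written alongside as a fallback for software that drops annotations.

Reading delegates the heavy lifting to MNE after a structural validation
pass that reports truncation with the offending byte offset.
"""

from __future__ import annotations

import os
import warnings
from math import ceil

import numpy as np

from . import montage
from .containers import Event, EventList, RawRecording

__all__ = [
    "EdfParseError",
    "write_edf",
    "read_edf",
    "write_events_tsv",
    "read_events_tsv",
]

_ANNOTATION_LABEL = "EDF Annotations"


class EdfParseError(ValueError):
    """The file is not a structurally valid EDF/EDF+ recording."""


def _fit(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"field {text!r} does not fit in {width} bytes")
    return b.ljust(width)


def _fmt_float(v: float) -> str:
    s = f"{v:.5g}"
    if len(s) > 8:
        s = f"{v:.3g}"
    return s


def _event_annotations(events: EventList) -> list[tuple[float, str]]:
    fs = events.sampling_rate
    out: list[tuple[float, str]] = []
    if len(events):
        out.append((0.0, f"blk:E={events[0].block_E:g}"))
    for ev in events:
        out.append((ev.sample / fs, f"dec:{ev.decision_side}"))
        out.append((events.feedback_sample(ev) / fs, f"fb:{ev.feedback}"))
    return out


def write_edf(
    path,
    raw: RawRecording,
    events: EventList | None = None,
    record_duration: float = 1.0,
) -> None:
    """Write a recording (and optionally its trial markers) as EDF+C.

    Samples are quantised to 16 bits over each channel's symmetric physical
    range, so the round-trip error is at most one quantisation step.
    """
    fs = raw.sampling_rate
    spr = fs * record_duration
    if abs(spr - round(spr)) > 1e-9:
        raise ValueError(
            "sampling_rate x record_duration must be an integer number of samples"
        )
    spr = int(round(spr))
    n_records = ceil(raw.n_samples / spr)

    # per-channel symmetric physical range, parsed back from its ASCII form
    # so writer and reader use bit-identical scale factors
    phys_max: list[float] = []
    for ch in range(raw.n_channels):
        amax = float(np.max(np.abs(raw.data[ch]))) or 1.0
        phys_max.append(float(_fmt_float(amax * 1.0001)))

    ann_records = _annotation_records(events, n_records, record_duration)
    ann_spr = max(ceil(max(len(b) for b in ann_records) / 2), 8)

    ns = raw.n_channels + 1  # + annotation signal
    header = b"".join(
        [
            _fit("0", 8),
            _fit("X X X X", 80),
            _fit("Startdate 01-JAN-2000 X X X", 80),
            _fit("01.01.00", 8),
            _fit("00.00.00", 8),
            _fit(str(256 * (ns + 1)), 8),
            _fit("EDF+C", 44),
            _fit(str(n_records), 8),
            _fit(f"{record_duration:g}", 8),
            _fit(str(ns), 4),
        ]
    )

    labels = [_fit(n, 16) for n in raw.channel_names] + [_fit(_ANNOTATION_LABEL, 16)]
    transducers = [_fit("AgAgCl electrode", 80)] * raw.n_channels + [_fit("", 80)]
    dims = [_fit("uV", 8)] * raw.n_channels + [_fit("", 8)]
    pmins = [_fit(_fmt_float(-p), 8) for p in phys_max] + [_fit("-1", 8)]
    pmaxs = [_fit(_fmt_float(p), 8) for p in phys_max] + [_fit("1", 8)]
    dmins = [_fit("-32768", 8)] * ns
    dmaxs = [_fit("32767", 8)] * ns
    prefilters = [_fit("", 80)] * ns
    sprs = [_fit(str(spr), 8)] * raw.n_channels + [_fit(str(ann_spr), 8)]
    reserved = [_fit("", 32)] * ns

    with open(path, "wb") as fh:
        fh.write(header)
        for block in (
            labels, transducers, dims, pmins, pmaxs,
            dmins, dmaxs, prefilters, sprs, reserved,
        ):
            fh.writelines(block)

        scales = np.array([2.0 * p / 65535.0 for p in phys_max])
        for rec in range(n_records):
            s0 = rec * spr
            s1 = min(s0 + spr, raw.n_samples)
            chunk = raw.data[:, s0:s1]
            if s1 - s0 < spr:  # pad the final record with the edge value
                pad = np.repeat(chunk[:, -1:], spr - (s1 - s0), axis=1)
                chunk = np.concatenate([chunk, pad], axis=1)
            dig = np.rint(chunk / scales[:, None]).astype(np.int64)
            dig = np.clip(dig, -32768, 32767).astype("<i2")
            fh.write(dig.tobytes())
            fh.write(ann_records[rec].ljust(ann_spr * 2, b"\x00"))


def _annotation_records(
    events: EventList | None, n_records: int, record_duration: float
) -> list[bytes]:
    """Time-stamped annotation lists, one byte string per data record."""
    per_record: list[list[tuple[float, str]]] = [[] for _ in range(n_records)]
    if events is not None:
        for onset, desc in _event_annotations(events):
            idx = min(int(onset / record_duration), n_records - 1)
            per_record[idx].append((onset, desc))
    out = []
    for rec in range(n_records):
        tal = f"+{rec * record_duration:g}\x14\x14\x00".encode("ascii")
        for onset, desc in per_record[rec]:
            tal += f"+{onset:.7g}\x14{desc}\x14\x00".encode("ascii")
        out.append(tal)
    return out


def _validate_edf(path) -> None:
    size = os.path.getsize(path)
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise EdfParseError(
                f"{path}: truncated fixed header, file ends at byte {len(head)} "
                "(256 required)"
            )
        try:
            ns = int(head[252:256].decode("ascii").strip())
            n_records = int(head[236:244].decode("ascii").strip())
            header_bytes = int(head[184:192].decode("ascii").strip())
        except ValueError as exc:
            raise EdfParseError(f"{path}: malformed header fields: {exc}") from exc
        sig = fh.read(ns * 256)
        if len(sig) < ns * 256:
            raise EdfParseError(
                f"{path}: truncated signal headers, file ends at byte "
                f"{256 + len(sig)} ({header_bytes} required)"
            )
        spr_off = ns * 216
        try:
            sprs = [
                int(sig[spr_off + 8 * i : spr_off + 8 * (i + 1)].decode().strip())
                for i in range(ns)
            ]
        except ValueError as exc:
            raise EdfParseError(
                f"{path}: malformed samples-per-record fields: {exc}"
            ) from exc
    expected = header_bytes + n_records * sum(sprs) * 2
    if size < expected:
        raise EdfParseError(
            f"{path}: truncated EDF file, expected {expected} bytes but the "
            f"file ends at byte {size}"
        )


def read_edf(path) -> tuple[RawRecording, EventList]:
    """Read an EDF/EDF+ recording and its annotated trial markers.

    Raises :class:`EdfParseError` (naming the byte offset) on truncated
    files.  If the file carries no annotations an empty event list is
    returned with a warning; use :func:`read_events_tsv` for the sidecar.
    """
    _validate_edf(path)
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mne_raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    names = tuple(mne_raw.ch_names)
    fs = float(mne_raw.info["sfreq"])
    data = mne_raw.get_data() * 1e6  # V -> uV
    positions = montage.positions_2d(names)
    raw = RawRecording(
        data=data,
        sampling_rate=fs,
        channel_names=names,
        montage_positions=positions,
        reference_label="as-recorded",
    )

    ann = mne_raw.annotations
    records = sorted(zip(ann.onset, ann.description)) if len(ann) else []
    if not records:
        warnings.warn(f"{path}: no annotations found; returning an empty event list")
        return raw, EventList(events=[], sampling_rate=fs)

    block_E = float("nan")
    pending: tuple[int, str] | None = None
    parsed: list[Event] = []
    delay_s = 1.0
    for onset, desc in records:
        desc = desc.strip()
        if desc.startswith("blk:E="):
            block_E = float(desc[len("blk:E=") :])
        elif desc.startswith("dec:"):
            pending = (int(round(onset * fs)), desc[len("dec:") :])
        elif desc.startswith("fb:") and pending is not None:
            sample, side = pending
            delay_s = onset - sample / fs
            parsed.append(
                Event(
                    sample=sample,
                    decision_side=side,
                    feedback=desc[len("fb:") :],
                    block_E=block_E,
                )
            )
            pending = None
    return raw, EventList(
        events=parsed,
        sampling_rate=fs,
        feedback_delay_s=round(delay_s, 6) if parsed else 1.0,
    )


def write_events_tsv(path, events: EventList) -> None:
    """Tab-separated event sidecar: columns ``sample`` and ``label``."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample\tlabel\n")
        if len(events):
            fh.write(f"0\tblk:E={events[0].block_E:g}\n")
        for ev in events:
            fh.write(f"{ev.sample}\tdec:{ev.decision_side}\n")
            fh.write(f"{events.feedback_sample(ev)}\tfb:{ev.feedback}\n")


def read_events_tsv(path, sampling_rate: float) -> EventList:
    """Read a tab-separated event sidecar back into an :class:`EventList`."""
    block_E = float("nan")
    pending: tuple[int, str] | None = None
    parsed: list[Event] = []
    delay = int(round(sampling_rate))
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("sample"):
            raise ValueError(f"{path}: not an event sidecar (missing header)")
        for line in fh:
            line = line.strip()
            if not line:
                continue
            sample_s, label = line.split("\t")
            sample = int(sample_s)
            if label.startswith("blk:E="):
                block_E = float(label[len("blk:E=") :])
            elif label.startswith("dec:"):
                pending = (sample, label[len("dec:") :])
            elif label.startswith("fb:") and pending is not None:
                dec_sample, side = pending
                delay = sample - dec_sample
                parsed.append(
                    Event(
                        sample=dec_sample,
                        decision_side=side,
                        feedback=label[len("fb:") :],
                        block_E=block_E,
                    )
                )
                pending = None
    return EventList(
        events=parsed,
        sampling_rate=sampling_rate,
        feedback_delay_s=delay / sampling_rate,
    )
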