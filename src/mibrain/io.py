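"""Reading and writing recordings and analysis tables.

Recordings travel as either European Data Format (EDF) files or plain
delimited text (one channel per row, a ``#``-prefixed header carrying labels,
sampling rate and reference). EDF reading goes through ``mne.io.read_raw_edf``;
writing uses a minimal EDF writer implemented here (16-bit samples, per-channel
physical scaling recorded in the header, signals scaled to occupy +/-90% of the
digital range so round-trips are predictable to one quantisation step).
"""

from __future__ import annotations

import datetime
import json

from pathlib import Path
from typing import Optional

import numpy as np

from .mi import MIMatrix
from .recording import EEGRecording

_EDF_DIG_MAX = 32767
_EDF_DIG_MIN = -32768


def _ascii_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} characters")
    return s.ljust(width).encode("ascii")


def _fit8(value: float) -> str:
    """Format a float into at most 8 ASCII characters (EDF numeric field)."""
    for fmt in ("{:.8g}", "{:.6g}", "{:.4g}", "{:.3g}", "{:.2g}"):
        s = fmt.format(float(value))
        if len(s) <= 8:
            return s
    raise ValueError(f"cannot fit {value} into 8 characters")


def write_edf(recording: EEGRecording, path) -> Path:
    """Write a recording as a 16-bit EDF file.

    Uses 1-second data records, so the sampling rate must be an integer and
    the recording is truncated to a whole number of seconds. Each channel is
    scaled so its extreme sample sits at 90% of the digital range; physical
    min/max in the header make the scaling reversible.
    """
    path = Path(path)
    fs = recording.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_records = recording.n_samples // fs
    if n_records < 1:
        raise ValueError("recording shorter than one 1-s EDF data record")
    n_ch = recording.n_channels
    data = recording.data[:, : n_records * fs]

    phys_max = np.maximum(np.abs(data).max(axis=1) / 0.9, 1e-6)
    phys_min = -phys_max
    # the standard EDF affine mapping (matching what readers invert)
    slope = (phys_max - phys_min) / (_EDF_DIG_MAX - _EDF_DIG_MIN)
    digital = np.clip(
        np.round((data - phys_min[:, None]) / slope[:, None] + _EDF_DIG_MIN),
        _EDF_DIG_MIN,
        _EDF_DIG_MAX,
    ).astype("<i2")

    start = datetime.datetime(2000, 1, 1)
    header = b"".join(
        [
            _ascii_field("0", 8),
            _ascii_field("X X X X", 80),
            _ascii_field(f"Startdate 01-JAN-2000 X X mibrain ref={recording.reference}"[:80], 80),
            _ascii_field(start.strftime("%d.%m.%y"), 8),
            _ascii_field(start.strftime("%H.%M.%S"), 8),
            _ascii_field(256 * (n_ch + 1), 8),
            _ascii_field("", 44),
            _ascii_field(n_records, 8),
            _ascii_field(1, 8),
            _ascii_field(n_ch, 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(_ascii_field(lbl, 16) for lbl in recording.channel_labels),
            b"".join(_ascii_field("", 80) for _ in range(n_ch)),
            b"".join(_ascii_field("uV", 8) for _ in range(n_ch)),
            b"".join(_ascii_field(_fit8(phys_min[c]), 8) for c in range(n_ch)),
            b"".join(_ascii_field(_fit8(phys_max[c]), 8) for c in range(n_ch)),
            b"".join(_ascii_field(_EDF_DIG_MIN, 8) for _ in range(n_ch)),
            b"".join(_ascii_field(_EDF_DIG_MAX, 8) for _ in range(n_ch)),
            b"".join(_ascii_field("", 80) for _ in range(n_ch)),
            b"".join(_ascii_field(fs, 8) for _ in range(n_ch)),
            b"".join(_ascii_field("", 32) for _ in range(n_ch)),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        for r in range(n_records):
            block = digital[:, r * fs : (r + 1) * fs]
            fh.write(block.tobytes())  # channel-major within the record
    return path


def read_edf(path) -> EEGRecording:
    """Read an EDF file into an :class:`EEGRecording` (data in microvolts)."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts for uV-dimensioned channels
    return EEGRecording(
        data=data,
        sampling_rate=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
        reference="as-recorded",
    )


def write_text_recording(recording: EEGRecording, path) -> Path:
    """Write a recording as delimited text: a header line, then one
    tab-separated row per channel."""
    path = Path(path)
    with open(path, "w") as fh:
        labels = ",".join(recording.channel_labels)
        fh.write(
            f"# channels={labels} rate={recording.sampling_rate!r} "
            f"reference={recording.reference}\n"
        )
        np.savetxt(fh, recording.data, delimiter="\t", fmt="%.10g")
    return path


def read_text_recording(path) -> EEGRecording:
    """Read the delimited-text recording format written by
    :func:`write_text_recording`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing '#' header line with channels= and rate=")
        fields = dict(
            token.split("=", 1) for token in header.lstrip("# ").split() if "=" in token
        )
        for required in ("channels", "rate"):
            if required not in fields:
                raise ValueError(f"{path}: header missing {required}= field")
        labels = tuple(fields["channels"].split(","))
        rows = [line.split() for line in fh if line.strip()]
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"{path}: rows have mismatched lengths {sorted(lengths)}")
    data = np.array(rows, dtype=float)
    if data.shape[0] != len(labels):
        raise ValueError(f"{path}: {data.shape[0]} data rows for {len(labels)} labels")
    return EEGRecording(
        data=data,
        sampling_rate=float(fields["rate"]),
        channel_labels=labels,
        reference=fields.get("reference", "unknown"),
    )


def read_recording(path, format: Optional[str] = None) -> EEGRecording:
    """Dispatch on ``format`` or the file extension (.edf / .txt / .tsv)."""
    path = Path(path)
    if format is None:
        ext = path.suffix.lower()
        format = {".edf": "edf", ".txt": "text", ".tsv": "text", ".csv": "text"}.get(ext)
        if format is None:
            raise ValueError(
                f"unknown extension {ext!r} for {path}; supported formats: edf, text"
            )
    if format == "edf":
        return read_edf(path)
    if format == "text":
        return read_text_recording(path)
    raise ValueError(f"unknown format {format!r}; supported formats: edf, text")


def write_recording(recording: EEGRecording, path, format: Optional[str] = None) -> Path:
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "text"
    if format == "edf":
        return write_edf(recording, path)
    return write_text_recording(recording, path)


def write_mi_matrix(mi: MIMatrix, path, sidecar: Optional[dict] = None) -> Path:
    """Write an MI matrix as labelled TSV plus a JSON sidecar with provenance
    (histogram spec, epoch count, and any extra fields supplied)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(mi.channel_labels) + "\n")
        for i, label in enumerate(mi.channel_labels):
            row = "\t".join(f"{v:.10g}" for v in mi.values[i])
            fh.write(f"{label}\t{row}\n")
    meta = {"n_epochs": int(mi.n_epochs), "n_channels": int(mi.n_channels)}
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_mi_matrix(path) -> MIMatrix:
    path = Path(path)
    with open(path) as fh:
        labels = fh.readline().rstrip("\n").split("\t")[1:]
        rows = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rows.append([float(v) for v in parts[1:]])
    values = np.array(rows)
    return MIMatrix(values=values, per_epoch=values[None, :, :], channel_labels=tuple(labels))
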