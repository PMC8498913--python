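"""Recording and epoch I/O: EDF+ and CSV with a JSON sidecar, NPZ epochs.

EDF is the interchange format (16-bit physical-unit encoding, class
intervals as EDF+ annotations); CSV + JSON sidecar is the debug-friendly
dialect. EDF files are written by a small self-contained EDF+ writer and read
back through :mod:`mne`, which doubles as an independent check on the writer.
"""

from __future__ import annotations

import json
import math
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from mibci.preprocess import EpochSet, WindowSpec
from mibci.simulate import MontageSpec, Recording


class RecordingParseError(ValueError):
    """A recording file could not be parsed or failed validation."""


# ---------------------------------------------------------------- CSV + JSON


def write_recording_csv(rec: Recording, path: str | Path) -> Path:
    """One column per channel (header = labels) + ``<stem>.json`` sidecar."""
    path = Path(path)
    frame = pd.DataFrame(rec.data.T, columns=list(rec.montage.channel_labels))
    frame.to_csv(path, index=False, float_format="%.4f")
    sidecar = {
        "fs": rec.fs,
        "montage": {
            "channel_labels": list(rec.montage.channel_labels),
            "reference_label": rec.montage.reference_label,
            "ground_label": rec.montage.ground_label,
        },
        "annotations": [
            {"start_s": s, "end_s": e, "class_id": c} for s, e, c in rec.annotations
        ],
        "subject_id": rec.subject_id,
        "trial_id": rec.trial_id,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_recording_csv(path: str | Path, montage: MontageSpec | None = None) -> Recording:
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise RecordingParseError(f"missing JSON sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    frame = pd.read_csv(path)
    m = MontageSpec(
        tuple(meta["montage"]["channel_labels"]),
        meta["montage"]["reference_label"],
        meta["montage"]["ground_label"],
    )
    if montage is not None and tuple(frame.columns) != montage.channel_labels:
        raise RecordingParseError(
            f"CSV channels {tuple(frame.columns)} do not match montage "
            f"{montage.channel_labels}"
        )
    if tuple(frame.columns) != m.channel_labels:
        raise RecordingParseError("CSV header disagrees with sidecar montage")
    return Recording(
        data=frame.to_numpy().T,
        fs=float(meta["fs"]),
        montage=m,
        annotations=[
            (a["start_s"], a["end_s"], a["class_id"]) for a in meta["annotations"]
        ],
        subject_id=int(meta.get("subject_id", 0)),
        trial_id=int(meta.get("trial_id", 0)),
    )


# --------------------------------------------------------------------- EDF+

_EDF_ANNOT_BYTES_PER_RECORD = 120  # room for the timestamp TAL + a few events


def _edf_str(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_recording_edf(rec: Recording, path: str | Path) -> Path:
    """Minimal EDF+C writer: 16-bit samples, µV, annotations as TALs.

    One data record per second; physical min/max are taken from the data
    extrema (widened if degenerate). Each class-interval annotation is stored
    as a time-stamped annotation list in the data record containing its
    onset.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch = rec.n_channels
    n_records = math.ceil(rec.n_samples / fs)
    pad = n_records * fs - rec.n_samples
    data = np.pad(rec.data, ((0, 0), (0, pad)))

    pmin, pmax = float(data.min()), float(data.max())
    if pmax <= pmin:
        warnings.warn("constant recording; widening EDF physical range", stacklevel=2)
        pmin, pmax = pmin - 1.0, pmax + 1.0
    dmin, dmax = -32768, 32767
    scale = (pmax - pmin) / (dmax - dmin)
    digital = np.round((data - pmin) / scale + dmin).astype("<i2")

    n_sig = n_ch + 1  # + EDF Annotations channel
    annot_samples = _EDF_ANNOT_BYTES_PER_RECORD // 2

    header = b""
    header += _edf_str("0", 8)
    header += _edf_str(f"X X X subject_{rec.subject_id}", 80)
    header += _edf_str(f"Startdate X X X trial_{rec.trial_id}", 80)
    header += _edf_str("01.01.00", 8) + _edf_str("00.00.00", 8)
    header += _edf_str(256 * (1 + n_sig), 8)
    header += _edf_str("EDF+C", 44)
    header += _edf_str(n_records, 8)
    header += _edf_str(1, 8)  # record duration, seconds
    header += _edf_str(n_sig, 4)

    labels = [f"EEG {ch}" for ch in rec.montage.channel_labels] + ["EDF Annotations"]
    transducers = ["AgAgCl electrode"] * n_ch + [""]
    units = ["uV"] * n_ch + [""]
    phys_min = [f"{pmin:.4f}"[:8]] * n_ch + ["-1"]
    phys_max = [f"{pmax:.4f}"[:8]] * n_ch + ["1"]
    dig_min = [str(dmin)] * n_sig
    dig_max = [str(dmax)] * n_sig
    prefilter = [""] * n_sig
    n_samp = [str(fs)] * n_ch + [str(annot_samples)]
    for values, width in (
        (labels, 16),
        (transducers, 80),
        (units, 8),
        (phys_min, 8),
        (phys_max, 8),
        (dig_min, 8),
        (dig_max, 8),
        (prefilter, 80),
        (n_samp, 8),
        ([""] * n_sig, 32),
    ):
        for v in values:
            header += _edf_str(v, width)

    events_by_record: dict[int, list[bytes]] = {}
    for start, end, cls in rec.annotations:
        tal = f"+{start:g}\x15{end - start:g}\x14{cls}\x14\x00".encode("ascii")
        events_by_record.setdefault(int(start), []).append(tal)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes(order="C"))
            tal = f"+{r}\x14\x14\x00".encode("ascii")
            for ev in events_by_record.get(r, []):
                tal += ev
            if len(tal) > _EDF_ANNOT_BYTES_PER_RECORD:
                raise ValueError("annotation text overflows the EDF record")
            fh.write(tal.ljust(_EDF_ANNOT_BYTES_PER_RECORD, b"\x00"))
    return path


def read_recording_edf(
    path: str | Path, montage: MontageSpec | None = None
) -> Recording:
    """Read an EDF/EDF+ file via mne; annotations become class intervals."""
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="ERROR")
    except Exception as exc:  # pragma: no cover - mne error text varies
        raise RecordingParseError(f"cannot parse EDF file {path}: {exc}") from exc
    labels = tuple(
        ch[4:] if ch.startswith("EEG ") else ch for ch in raw.ch_names
    )
    m = montage or MontageSpec(channel_labels=labels)
    if len(labels) != m.n_channels or (montage is not None and labels != m.channel_labels):
        raise RecordingParseError(
            f"EDF channels {labels} do not match montage {m.channel_labels}"
        )
    data = raw.get_data() * 1e6  # mne loads volts; recordings are µV
    annotations = [
        (float(a["onset"]), float(a["onset"]) + float(a["duration"]), str(a["description"]))
        for a in raw.annotations
    ]
    return Recording(
        data=data,
        fs=float(raw.info["sfreq"]),
        montage=m,
        annotations=annotations,
    )


def write_recording(rec: Recording, path: str | Path, format: str = "edf") -> Path:
    if format == "edf":
        return write_recording_edf(rec, path)
    if format == "csv":
        return write_recording_csv(rec, path)
    raise ValueError(f"unknown format {format!r}")


def read_recording(
    path: str | Path, format: str | None = None, montage: MontageSpec | None = None
) -> Recording:
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    if format == "edf":
        return read_recording_edf(path, montage)
    if format == "csv":
        return read_recording_csv(path, montage)
    raise ValueError(f"unknown format {format!r}")


# ------------------------------------------------------------------- epochs


def write_epochs(epochs: EpochSet, path: str | Path) -> Path:
    path = Path(path)
    np.savez_compressed(
        path,
        windows=epochs.windows,
        labels=epochs.labels.astype(str),
        fs=epochs.fs,
        length_s=epochs.window_spec.length_s,
        overlap_frac=epochs.window_spec.overlap_frac,
        provenance=np.asarray(epochs.provenance, dtype=np.float64).reshape(-1, 3),
        channel_labels=np.asarray(epochs.channel_labels or [], dtype=str),
    )
    return path


def read_epochs(path: str | Path) -> EpochSet:
    with np.load(path, allow_pickle=False) as z:
        spec = WindowSpec(float(z["length_s"]), float(z["overlap_frac"]))
        prov = [
            (int(s), int(t), float(st)) for s, t, st in z["provenance"]
        ]
        chans = tuple(z["channel_labels"].tolist()) or None
        return EpochSet(
            z["windows"], z["labels"].astype(object), spec, float(z["fs"]), prov, chans
        )
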