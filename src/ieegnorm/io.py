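"""Recording and channel-metadata I/O.

A :class:`Recording` is an in-memory multichannel iEEG segment: a
``channels x time`` array of potentials in microvolts plus a sampling
rate.  Recordings are read either from EDF (European Data Format, via
:mod:`mne`) or from a plain tabular format designed so that complete
datasets can live in version control: a CSV with one header row of
channel labels and one column per channel, with the sampling rate in a
YAML sidecar (``<name>.yaml`` next to the data file, key ``fs``).

Channel metadata travels as a :class:`pandas.DataFrame` ("channel
table") with one row per contact: ``channel_id``, millimetre
coordinates ``x, y, z`` and boolean clinical flags
``soz, early_propagation, lesion, bad, white_matter, spike``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, ValidationError

#: clinical flag columns of a channel table, in canonical order
CHANNEL_FLAGS = ("soz", "early_propagation", "lesion", "bad", "white_matter", "spike")


@dataclass
class Recording:
    """A multichannel time series of iEEG potentials (µV)."""

    samples: np.ndarray          # (n_channels, n_times)
    fs: float                    # sampling rate, Hz
    channel_ids: list[str]
    start_time: float | None = None   # seconds, informational only

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValidationError("samples must be a channels x time matrix")
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_ids) != self.samples.shape[0]:
            raise ValidationError(
                f"{len(self.channel_ids)} channel ids for "
                f"{self.samples.shape[0]} signal rows"
            )
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValidationError("duplicate channel labels")
        if not np.all(np.isfinite(self.samples)):
            raise DataError("non-finite samples in recording")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Length of the recording in seconds."""
        return self.n_times / self.fs

    def copy_with(self, **changes) -> "Recording":
        return replace(self, **changes)


# ---------------------------------------------------------------------------
# tabular format
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".yaml")


def _load_tabular(path: Path, fs: float | None) -> Recording:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    raw_ids = [c.strip() for c in header.split(",")]
    if len(set(raw_ids)) != len(raw_ids):   # pandas would mangle these to A.1
        raise ValidationError(f"duplicate channel labels in {path}")
    frame = pd.read_csv(path)
    ids = [str(c) for c in frame.columns]
    if fs is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise ValidationError(
                f"no sampling rate: pass fs or provide sidecar {sidecar} with key 'fs'"
            )
        meta = yaml.safe_load(sidecar.read_text()) or {}
        if "fs" not in meta:
            raise ValidationError(f"sidecar {sidecar} is missing required field 'fs'")
        fs = float(meta["fs"])
    return Recording(frame.to_numpy().T, fs, ids)


def _save_tabular(rec: Recording, path: Path) -> None:
    pd.DataFrame(rec.samples.T, columns=rec.channel_ids).to_csv(path, index=False)
    _sidecar_path(path).write_text(yaml.safe_dump({"fs": float(rec.fs)}))


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _load_edf(path: Path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    # mne returns SI volts; the package convention is microvolts
    data = raw.get_data() * 1e6
    return Recording(data, float(raw.info["sfreq"]), list(raw.ch_names))


def _edf_field(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def _save_edf(rec: Recording, path: Path) -> None:
    """Minimal EDF writer: one-second data records, 16-bit samples, µV.

    The sampling rate must be a whole number and the recording a whole
    number of seconds, so every data record is complete.
    """
    fs = rec.fs
    if fs != int(fs):
        raise ValidationError(f"EDF writing needs an integer sampling rate, got {fs}")
    spr = int(fs)  # samples per 1 s record, per signal
    if rec.n_times % spr:
        raise ValidationError(
            "EDF writing needs a whole number of seconds "
            f"({rec.n_times} samples at {spr} Hz)"
        )
    n_records = rec.n_times // spr
    n_sig = rec.n_channels

    # physical scaling per channel; a flat channel still needs a nonzero span
    pmin = rec.samples.min(axis=1)
    pmax = rec.samples.max(axis=1)
    span = pmax - pmin
    pad = np.where(span > 0, 0.0, 1.0)
    pmin, pmax = pmin - pad, pmax + pad
    dmin, dmax = -32768, 32767

    header = b"".join([
        _edf_field("0", 8),
        _edf_field("X X X X", 80),
        _edf_field("Startdate X X X X", 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(str(256 * (1 + n_sig)), 8),
        _edf_field("", 44),
        _edf_field(str(n_records), 8),
        _edf_field("1", 8),
        _edf_field(str(n_sig), 4),
    ])
    per_sig = b"".join(
        b"".join(_edf_field(fmt(i), width) for i in range(n_sig))
        for fmt, width in [
            (lambda i: rec.channel_ids[i], 16),
            (lambda i: "", 80),
            (lambda i: "uV", 8),
            (lambda i: f"{pmin[i]:.6g}", 8),
            (lambda i: f"{pmax[i]:.6g}", 8),
            (lambda i: str(dmin), 8),
            (lambda i: str(dmax), 8),
            (lambda i: "", 80),
            (lambda i: str(spr), 8),
            (lambda i: "", 32),
        ]
    )
    # re-derive gain from the *printed* physical range so that writer and
    # reader agree to within one quantisation step
    pmin_r = np.array([float(f"{v:.6g}") for v in pmin])
    pmax_r = np.array([float(f"{v:.6g}") for v in pmax])
    gain = (dmax - dmin) / (pmax_r - pmin_r)

    digital = np.rint((rec.samples - pmin_r[:, None]) * gain[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_sig)
        for r in range(n_records):
            block = digital[:, r * spr:(r + 1) * spr]
            fh.write(block.tobytes())


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def load_recording(path, format: str | None = None, fs: float | None = None) -> Recording:
    """Read a recording from EDF or from the tabular CSV + sidecar format.

    Parameters
    ----------
    path
        File to read.
    format
        ``"edf"`` or ``"tabular"``; inferred from the extension when omitted.
    fs
        Sampling rate override for tabular files without a sidecar.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "tabular"
    if format == "edf":
        return _load_edf(path)
    if format == "tabular":
        return _load_tabular(path, fs)
    raise ValidationError(f"unknown recording format {format!r}")


def save_recording(rec: Recording, path, format: str | None = None) -> None:
    """Write a recording as EDF or tabular CSV (+ YAML sidecar)."""
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "tabular"
    if format == "edf":
        _save_edf(rec, path)
    elif format == "tabular":
        _save_tabular(rec, path)
    else:
        raise ValidationError(f"unknown recording format {format!r}")


def read_channel_table(path) -> pd.DataFrame:
    """Read and validate a channel table CSV.

    Required columns: ``channel_id, x, y, z``; missing flag columns are
    filled as ``False``.
    """
    table = pd.read_csv(path)
    return validate_channel_table(table)


def validate_channel_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"channel_id", "x", "y", "z"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"channel table is missing columns {sorted(missing)}")
    table = table.copy()
    table["channel_id"] = table["channel_id"].astype(str)
    if table["channel_id"].duplicated().any():
        dupes = table.loc[table["channel_id"].duplicated(), "channel_id"].tolist()
        raise ValidationError(f"duplicate channel ids in table: {dupes}")
    coords = table[["x", "y", "z"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(coords)):
        raise DataError("non-finite contact coordinates")
    for flag in CHANNEL_FLAGS:
        if flag not in table.columns:
            table[flag] = False
        table[flag] = table[flag].astype(bool)
    return table


def write_channel_table(table: pd.DataFrame, path) -> None:
    cols = ["channel_id", "x", "y", "z", *CHANNEL_FLAGS]
    extra = [c for c in table.columns if c not in cols]
    validate_channel_table(table)[cols + extra].to_csv(path, index=False)
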