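"""Recording preprocessing: channel exclusion, common average
referencing, anti-aliased resampling and fixed-length segment
extraction.

The pipeline order is fixed as exclusion -> CAR -> resample -> segment.
Exclusion policy differs by role: normative cohorts drop every channel
carrying a clinical flag (seizure onset zone, early propagation, lesion,
bad contact, white matter), whereas patient recordings keep all grey
matter channels — including those in the seizure onset zone — and drop
only bad and white-matter contacts.
"""

from __future__ import annotations

import warnings
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import DataError, ValidationError
from .io import Recording

#: flags dropped under each exclusion policy
EXCLUSION_POLICIES = {
    "normative": ("soz", "early_propagation", "lesion", "bad", "white_matter"),
    "patient": ("bad", "white_matter"),
}


def exclude_channels(rec: Recording, table: pd.DataFrame, policy: str) -> Recording:
    """Drop flagged channels according to the normative or patient policy."""
    if policy not in EXCLUSION_POLICIES:
        raise ValidationError(
            f"unknown policy {policy!r}, expected one of {sorted(EXCLUSION_POLICIES)}"
        )
    table = table.set_index("channel_id") if "channel_id" in table.columns else table
    missing = [c for c in rec.channel_ids if c not in table.index]
    if missing:
        raise ValidationError(f"channels missing from channel table: {missing}")
    flags = table.loc[rec.channel_ids, list(EXCLUSION_POLICIES[policy])].to_numpy(bool)
    keep = ~flags.any(axis=1)
    if not keep.any():
        raise DataError(f"no channels remain after {policy!r} exclusion")
    return rec.copy_with(
        samples=rec.samples[keep],
        channel_ids=[c for c, k in zip(rec.channel_ids, keep) if k],
    )


def common_average_reference(rec: Recording) -> Recording:
    """Subtract the across-channel mean at every time sample."""
    if rec.n_channels < 2:
        raise DataError("common average reference needs at least 2 channels")
    return rec.copy_with(samples=rec.samples - rec.samples.mean(axis=0, keepdims=True))


def resample_to(rec: Recording, target_fs: float, *, warn_below: float = 160.0) -> Recording:
    """Polyphase rational downsampling with an FIR anti-alias filter.

    Upsampling is refused: the normative pipeline only ever reduces the
    rate (e.g. 512 -> 200 Hz).  Rates at or below ``warn_below`` Hz
    leave less than 2x headroom over the 80 Hz analysis ceiling and
    trigger a warning.
    """
    if target_fs <= 0:
        raise ValidationError(f"target sampling rate must be positive, got {target_fs}")
    if target_fs > rec.fs:
        raise ValidationError(
            f"refusing to upsample from {rec.fs} Hz to {target_fs} Hz"
        )
    if target_fs <= warn_below:
        warnings.warn(
            f"target rate {target_fs} Hz leaves little headroom above the "
            "80 Hz analysis band",
            stacklevel=2,
        )
    if target_fs == rec.fs:
        return rec
    ratio = Fraction(target_fs / rec.fs).limit_denominator(1000)
    out = sps.resample_poly(rec.samples, ratio.numerator, ratio.denominator, axis=1)
    return rec.copy_with(samples=out, fs=float(target_fs))


def extract_segment(rec: Recording, start: float, duration: float = 70.0) -> Recording:
    """Cut a contiguous ``duration``-second slice starting at ``start`` s."""
    if duration <= 0:
        raise ValidationError(f"segment duration must be positive, got {duration}")
    if start < 0:
        raise ValidationError(f"segment start must be non-negative, got {start}")
    i0 = int(round(start * rec.fs))
    n = int(round(duration * rec.fs))
    if i0 + n > rec.n_times:
        raise ValidationError(
            f"segment [{start}, {start + duration}) s exceeds the "
            f"{rec.duration:.3f} s recording"
        )
    return rec.copy_with(
        samples=rec.samples[:, i0:i0 + n],
        start_time=(rec.start_time or 0.0) + start,
    )


def preprocess(
    rec: Recording,
    table: pd.DataFrame,
    policy: str,
    *,
    target_fs: float = 200.0,
    start: float = 0.0,
    duration: float | None = 70.0,
) -> Recording:
    """Run the full fixed-order chain: exclude -> CAR -> resample -> segment.

    ``duration=None`` keeps the whole (remaining) recording.
    """
    rec = exclude_channels(rec, table, policy)
    rec = common_average_reference(rec)
    rec = resample_to(rec, target_fs)
    if duration is None:
        duration = rec.duration - start
    return extract_segment(rec, start, duration)
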