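"""Welch spectral estimation and relative band power.

Band power is estimated per contact in five canonical bands —
delta 1–4 Hz, theta 4–8 Hz, alpha 8–13 Hz, beta 13–30 Hz and
gamma 30–80 Hz — from a Welch periodogram (2 s Hamming windows,
1 s overlap, per-segment mean removal).  The gamma band excludes
47.5–52.5 Hz and 57.5–62.5 Hz so that both 50 Hz and 60 Hz power-line
artefacts (and their immediate sidebands) never enter the estimate.

Band powers are log10-transformed and L1-normalised per contact
(divided by the sum of absolute values) to give *relative band power*,
the quantity all downstream normative mapping operates on.

Conventions (documented because the band edges touch):

* a PSD bin belongs to a band when its centre frequency lies in
  ``[lo, hi)`` — shared edges go to the upper band;
* exclusion sub-ranges are applied with the same half-open rule;
* band power is the rectangular-rule integral (bin density x bin width).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal as sps

from .errors import DataError, ValidationError
from .io import Recording

#: powers at or below this (µV², total bin mass) indicate a dead channel
MIN_BAND_POWER = 1e-15


@dataclass(frozen=True)
class FrequencyBand:
    """A named frequency interval with optional excluded sub-ranges."""

    name: str
    lo: float
    hi: float
    exclusions: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi:
            raise ValidationError(f"band {self.name}: need 0 < lo < hi")
        for elo, ehi in self.exclusions:
            if not (self.lo <= elo < ehi <= self.hi):
                raise ValidationError(
                    f"band {self.name}: exclusion ({elo}, {ehi}) not nested in "
                    f"[{self.lo}, {self.hi}]"
                )


def canonical_bands() -> tuple[FrequencyBand, ...]:
    """The five standard iEEG bands with gamma power-line exclusions."""
    return (
        FrequencyBand("delta", 1.0, 4.0),
        FrequencyBand("theta", 4.0, 8.0),
        FrequencyBand("alpha", 8.0, 13.0),
        FrequencyBand("beta", 13.0, 30.0),
        FrequencyBand("gamma", 30.0, 80.0, ((47.5, 52.5), (57.5, 62.5))),
    )


BAND_NAMES = tuple(b.name for b in canonical_bands())


def bands_to_dicts(bands) -> list[dict]:
    return [
        {"name": b.name, "lo": b.lo, "hi": b.hi,
         "exclusions": [list(e) for e in b.exclusions]}
        for b in bands
    ]


def bands_from_dicts(items) -> tuple[FrequencyBand, ...]:
    try:
        return tuple(
            FrequencyBand(
                d["name"], float(d["lo"]), float(d["hi"]),
                tuple((float(lo), float(hi)) for lo, hi in d.get("exclusions", ())),
            )
            for d in items
        )
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"malformed band definition: {exc}") from exc


def load_bands(path) -> tuple[FrequencyBand, ...]:
    """Load band definitions from a YAML/JSON file (list of mappings)."""
    items = yaml.safe_load(Path(path).read_text())
    if not isinstance(items, list):
        raise ValidationError(f"band file {path} must contain a list of bands")
    return bands_from_dicts(items)


@dataclass
class PSD:
    """One-sided Welch power spectral density, µV²/Hz per channel."""

    freqs: np.ndarray            # (n_freqs,), 0 .. fs/2
    density: np.ndarray          # (n_channels, n_freqs) or (n_freqs,)
    n_segments: int = 1
    channel_ids: list[str] | None = None

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def welch_psd(
    x: np.ndarray,
    fs: float,
    window_s: float = 2.0,
    overlap_s: float = 1.0,
) -> PSD:
    """Welch PSD with Hamming taper and per-segment mean removal.

    ``x`` may be one channel ``(n,)`` or a stack ``(n_channels, n)``;
    the estimate is one-sided with density scaling, so integrating over
    ``[0, fs/2]`` recovers the signal variance (up to taper leakage).
    """
    x = np.asarray(x, dtype=float)
    if overlap_s >= window_s:
        raise ValidationError("overlap must be shorter than the window")
    nperseg = int(round(window_s * fs))
    noverlap = int(round(overlap_s * fs))
    n = x.shape[-1]
    if n < nperseg:
        raise DataError(
            f"signal of {n} samples is shorter than one {nperseg}-sample window"
        )
    freqs, density = sps.welch(
        x, fs=fs, window="hamming", nperseg=nperseg, noverlap=noverlap,
        detrend="constant", scaling="density", axis=-1,
    )
    n_segments = (n - nperseg) // (nperseg - noverlap) + 1
    return PSD(freqs=freqs, density=density, n_segments=n_segments)


def band_power(psd: PSD, band: FrequencyBand) -> np.ndarray | float:
    """Integrate the PSD over a band, skipping its excluded sub-ranges.

    Returns a scalar for a single-channel PSD, else one value per channel.
    """
    nyquist = psd.freqs[-1]
    if band.hi > nyquist + psd.df / 2:
        raise ValidationError(
            f"band {band.name} [{band.lo}, {band.hi}) exceeds the "
            f"{nyquist:g} Hz spectral range"
        )
    mask = (psd.freqs >= band.lo) & (psd.freqs < band.hi)
    for elo, ehi in band.exclusions:
        mask &= ~((psd.freqs >= elo) & (psd.freqs < ehi))
    power = psd.density[..., mask].sum(axis=-1) * psd.df
    return power if np.ndim(power) else float(power)


def relative_band_power(
    rec: Recording,
    bands: tuple[FrequencyBand, ...] | None = None,
    window_s: float = 2.0,
    overlap_s: float = 1.0,
) -> pd.DataFrame:
    """Per-contact relative band power: log10 band powers, L1-normalised.

    Returns a DataFrame indexed by channel id with one column per band.
    Raises :class:`DataError` if any band power is at or below
    ``MIN_BAND_POWER`` (a flat or dead channel).
    """
    bands = canonical_bands() if bands is None else bands
    psd = welch_psd(rec.samples, rec.fs, window_s, overlap_s)
    powers = np.column_stack([band_power(psd, b) for b in bands])
    if np.any(powers <= MIN_BAND_POWER):
        bad = [rec.channel_ids[i]
               for i in np.nonzero((powers <= MIN_BAND_POWER).any(axis=1))[0]]
        raise DataError(f"degenerate (near-zero) band power on channels {bad}")
    logp = np.log10(powers)
    rel = logp / np.abs(logp).sum(axis=1, keepdims=True)
    return pd.DataFrame(rel, index=pd.Index(rec.channel_ids, name="channel_id"),
                        columns=[b.name for b in bands])
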