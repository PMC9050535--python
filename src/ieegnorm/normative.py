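"""Normative map construction and serialization.

The normative map holds, for every region x band cell, the mean and
sample standard deviation (n-1 denominator) of relative band power
across the participants that had electrode coverage there, together
with the participant count.  Cells covered by fewer than
``min_participants`` participants are masked as unavailable: their z
scores would be dominated by estimation noise.  Cells with zero
variance are kept but flagged degenerate and are likewise never scored.

Maps serialize losslessly to JSON, carrying their band definitions,
parcellation identity and build parameters so that scoring a patient
against a mismatched map fails loudly rather than silently.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError
from .localization import RegionBandPower
from .spectral import FrequencyBand, bands_from_dicts, bands_to_dicts, canonical_bands

MAP_SCHEMA_VERSION = 1

#: sigma at or below this counts as zero variance (relative band power is O(1))
DEGENERATE_SIGMA = 1e-12


@dataclass
class NormativeMap:
    """Per region x band normative mean, SD and participant count."""

    mu: pd.DataFrame             # NaN where unavailable
    sigma: pd.DataFrame
    n: pd.DataFrame              # int participant counts (0 where never covered)
    meta: dict = field(default_factory=dict)

    @property
    def bands(self) -> tuple[str, ...]:
        return tuple(self.mu.columns)

    @property
    def regions(self) -> list[str]:
        return list(self.mu.index)

    def band_definitions(self) -> tuple[FrequencyBand, ...]:
        return bands_from_dicts(self.meta["bands"])

    def scoreable(self) -> pd.DataFrame:
        """Boolean mask of cells usable for z scoring (available, σ>0)."""
        return self.mu.notna() & self.sigma.notna() & (self.sigma > DEGENERATE_SIGMA)


def build_normative_map(
    cohort: list[RegionBandPower],
    min_participants: int = 5,
    bands: tuple[FrequencyBand, ...] | None = None,
    parcellation_id: str = "unspecified",
) -> NormativeMap:
    """Build the normative distribution over a participant cohort.

    Missing (uncovered) participant cells are ignored, never treated as
    zeros.  Cells with fewer than ``min_participants`` contributing
    participants are masked unavailable; zero-variance cells are flagged
    degenerate with a warning and excluded from scoring.
    """
    if len(cohort) < 2:
        raise ValidationError(f"need at least 2 participants, got {len(cohort)}")
    band_set = cohort[0].bands
    for p in cohort[1:]:
        if p.bands != band_set:
            raise ValidationError(
                f"inconsistent band sets across participants: {band_set} vs {p.bands}"
            )
    bands = canonical_bands() if bands is None else bands
    if tuple(b.name for b in bands) != band_set:
        raise ValidationError(
            f"band definitions {tuple(b.name for b in bands)} do not match "
            f"participant tables {band_set}"
        )
    # region universe in first-appearance order across the cohort
    regions = list(dict.fromkeys(r for p in cohort for r in p.values.index))
    index = pd.Index(regions, name="region_id")
    stack = np.stack([p.values.reindex(index).to_numpy(float) for p in cohort])
    n = np.isfinite(stack).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # empty-slice means
        mu = np.nanmean(stack, axis=0)
        sigma = np.nanstd(stack, axis=0, ddof=1)
    unavailable = n < min_participants
    mu[unavailable] = np.nan
    sigma[unavailable] = np.nan
    if not np.any(~unavailable):
        raise DataError(
            f"no region/band cell reaches min_participants={min_participants}"
        )
    degenerate = (~unavailable) & (sigma <= DEGENERATE_SIGMA)
    sigma[degenerate] = 0.0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} normative cell(s) have zero variance and "
            "will not be scoreable",
            stacklevel=2,
        )
    cols = list(band_set)
    return NormativeMap(
        mu=pd.DataFrame(mu, index=index, columns=cols),
        sigma=pd.DataFrame(sigma, index=index, columns=cols),
        n=pd.DataFrame(n, index=index, columns=cols, dtype=int),
        meta={
            "version": MAP_SCHEMA_VERSION,
            "bands": bands_to_dicts(bands),
            "parcellation": parcellation_id,
            "min_participants": int(min_participants),
            "n_participants": len(cohort),
        },
    )


def summarize_map(nmap: NormativeMap) -> pd.DataFrame:
    """Tidy table of normative means (regions x bands, NaN = unavailable)."""
    return nmap.mu.copy()


def save_map(nmap: NormativeMap, path) -> None:
    cells = []
    for region in nmap.regions:
        for band in nmap.bands:
            mu = nmap.mu.at[region, band]
            sd = nmap.sigma.at[region, band]
            cells.append({
                "region": region,
                "band": band,
                "mu": None if pd.isna(mu) else float(mu),
                "sigma": None if pd.isna(sd) else float(sd),
                "n": int(nmap.n.at[region, band]),
            })
    Path(path).write_text(json.dumps({"meta": nmap.meta, "cells": cells}, indent=1))


def load_map(path) -> NormativeMap:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"map file {path} is not valid JSON: {exc}") from exc
    if not isinstance(payload, dict) or "meta" not in payload or "cells" not in payload:
        raise ValidationError(f"map file {path} lacks the meta/cells structure")
    meta = payload["meta"]
    if meta.get("version") != MAP_SCHEMA_VERSION:
        raise ValidationError(
            f"map schema version {meta.get('version')!r} != {MAP_SCHEMA_VERSION}"
        )
    required = {"region", "band", "mu", "sigma", "n"}
    for cell in payload["cells"]:
        if not required <= set(cell):
            raise ValidationError(
                f"map cell missing fields {sorted(required - set(cell))}"
            )
    frame = pd.DataFrame(payload["cells"])
    regions = list(dict.fromkeys(frame["region"]))
    bands = [b["name"] for b in meta["bands"]]
    def pivot(col, dtype=float):
        t = frame.pivot(index="region", columns="band", values=col)
        t = t.reindex(index=regions, columns=bands)
        t.index.name = "region_id"
        t.columns.name = None
        return t.astype(dtype)
    nmap = NormativeMap(mu=pivot("mu"), sigma=pivot("sigma"),
                        n=pivot("n", int), meta=meta)
    return nmap


def check_band_compatibility(nmap: NormativeMap,
                             bands: tuple[FrequencyBand, ...]) -> None:
    """Refuse to use a map whose band definitions differ from the analysis."""
    if bands_to_dicts(bands) != nmap.meta["bands"]:
        raise ValidationError(
            "band definitions of the normative map do not match the requested "
            "analysis; rebuild the map or adjust the configuration"
        )


def leave_one_out_zscores(values: np.ndarray) -> np.ndarray:
    """|z| of each participant scored against the map built from the others.

    ``values`` is a ``participants x regions x bands`` array with NaN
    for uncovered cells.  For each participant the held-out mean and
    sample SD are computed from the remaining participants' finite
    values; cells with fewer than 2 remaining participants or zero
    remaining variance come back NaN.  Used for map calibration checks.
    """
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    v0 = np.where(finite, v, 0.0)
    n = finite.sum(axis=0)                       # per-cell counts
    s1 = v0.sum(axis=0)
    s2 = (v0 ** 2).sum(axis=0)
    n_lo = n[None] - finite                      # held-out counts per participant
    s1_lo = s1[None] - v0
    s2_lo = s2[None] - v0 ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        mu_lo = s1_lo / n_lo
        var_lo = (s2_lo - n_lo * mu_lo ** 2) / (n_lo - 1)
        var_lo = np.clip(var_lo, 0.0, None)      # guard tiny negative round-off
        z = np.abs(v - mu_lo) / np.sqrt(var_lo)
    z[~finite | (n_lo < 2) | (var_lo <= DEGENERATE_SIGMA ** 2)] = np.nan
    return z
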