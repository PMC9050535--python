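"""Patient abnormality scoring against the normative map.

Each patient region x band value x is converted to an absolute z score
|z| = |x - mu| / sigma against the corresponding normative cell, and
the per-region abnormality is summarised as maxz, the maximum |z| over
the bands that could be scored.  Missing bands are ignored in the max
(never treated as zero) so partial coverage cannot deflate a region's
abnormality; regions with no scoreable band at all are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError
from .localization import RegionBandPower
from .normative import NormativeMap

logger = logging.getLogger(__name__)


@dataclass
class AbnormalityProfile:
    """Per-region |z| table, maxz summary and resection labels."""

    zscores: pd.DataFrame        # region x band |z|, NaN where unscoreable
    maxz: pd.Series              # per region, only regions with >=1 scored band
    resected: pd.Series | None   # bool, aligned to maxz where known
    coverage: pd.Series
    patient_id: str | None = None


def zscore_regions(patient: RegionBandPower, nmap: NormativeMap) -> pd.DataFrame:
    """Absolute z of every patient cell against the normative map.

    Cells are NaN when the patient had no coverage there or the map
    cell is unavailable/degenerate.  Raises :class:`DataError` when no
    cell at all can be scored and :class:`ValidationError` on a band-set
    mismatch.
    """
    if patient.bands != nmap.bands:
        raise ValidationError(
            f"patient bands {patient.bands} do not match map bands {nmap.bands}"
        )
    x = patient.values.reindex(index=nmap.mu.index)
    ok = nmap.scoreable()
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - nmap.mu).abs() / nmap.sigma
    z = z.where(ok)
    # keep only regions the patient actually covered, in patient order
    covered = [r for r in patient.values.index if r in z.index]
    dropped = [r for r in patient.values.index if r not in z.index]
    if dropped:
        logger.warning("%d patient region(s) absent from the normative map: %s",
                       len(dropped), dropped)
    z = z.loc[covered]
    if not np.isfinite(z.to_numpy(float)).any():
        raise DataError("no overlapping scoreable cells between patient and map")
    return z


def max_abnormality(ztable: pd.DataFrame) -> pd.Series:
    """Per-region maximum |z| over scored bands; all-missing regions drop."""
    if ztable.shape[0] == 0:
        raise DataError("empty z-score table")
    maxz = ztable.max(axis=1, skipna=True)
    maxz = maxz[ztable.notna().any(axis=1)]
    maxz.name = "max_abs_z"
    return maxz


def abnormality_profile(patient: RegionBandPower, nmap: NormativeMap,
                        patient_id: str | None = None) -> AbnormalityProfile:
    """Score a patient and assemble the per-region abnormality summary."""
    z = zscore_regions(patient, nmap)
    maxz = max_abnormality(z)
    resected = None
    if patient.resected is not None:
        resected = patient.resected.reindex(maxz.index)
    coverage = patient.coverage.reindex(maxz.index).fillna(0).astype(int)
    return AbnormalityProfile(
        zscores=z, maxz=maxz, resected=resected, coverage=coverage,
        patient_id=patient_id or patient.participant_id,
    )


def profile_to_frame(profile: AbnormalityProfile) -> pd.DataFrame:
    """Flat export: region_id, z_<band>..., max_abs_z, resected, coverage."""
    out = profile.zscores.loc[profile.maxz.index].add_prefix("z_")
    out["max_abs_z"] = profile.maxz
    if profile.resected is not None:
        out["resected"] = profile.resected
    out["coverage"] = profile.coverage
    out.index.name = "region_id"
    return out
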