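"""Contact-to-region assignment, regional aggregation and resection labels.

A parcellation is supplied as a table of labelled 3D points in the same
millimetre space as the contacts — one centroid per region or a voxel
point cloud (repeated ``region_id`` rows).  Each contact is assigned to
the region owning the nearest point (minimum Euclidean distance; exact
ties go to the earlier-listed region).

Resections are point clouds too.  A contact counts as removed when it
lies within ``radius_mm`` (default 5 mm, inclusive) of any mask point;
a region counts as resected when strictly more than ``threshold``
(default 25%) of its contacts were removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import DataError, ValidationError

REGION_COLS = ("region_id", "x", "y", "z")


def validate_parcellation(parc: pd.DataFrame) -> pd.DataFrame:
    missing = set(REGION_COLS) - set(parc.columns)
    if missing:
        raise ValidationError(f"parcellation is missing columns {sorted(missing)}")
    if len(parc) == 0:
        raise ValidationError("empty parcellation")
    parc = parc.copy()
    parc["region_id"] = parc["region_id"].astype(str)
    if not np.all(np.isfinite(parc[["x", "y", "z"]].to_numpy(float))):
        raise DataError("non-finite parcellation coordinates")
    return parc


def parcellation_regions(parc: pd.DataFrame) -> list[str]:
    """Region ids in first-appearance order."""
    return list(dict.fromkeys(parc["region_id"].astype(str)))


@dataclass
class RegionBandPower:
    """One participant's region x band relative band power.

    ``values`` is indexed by region id with one column per band; regions
    without electrode coverage hold NaN (never zero).  ``coverage``
    counts contacts per region; ``resected`` flags are present for
    patients once a resection has been labelled.
    """

    values: pd.DataFrame
    coverage: pd.Series
    resected: pd.Series | None = None
    participant_id: str | None = None

    def __post_init__(self) -> None:
        covered = self.coverage.reindex(self.values.index).fillna(0) >= 1
        bad = self.values.loc[covered].isna().any(axis=1)
        if bad.any():
            raise ValidationError(
                f"non-finite band power in covered regions {list(bad.index[bad])}"
            )

    @property
    def bands(self) -> tuple[str, ...]:
        return tuple(self.values.columns)


def assign_contacts(contacts: pd.DataFrame, parc: pd.DataFrame) -> pd.DataFrame:
    """Assign every contact to the region owning its nearest parcellation point.

    Returns a copy of ``contacts`` with a ``region_id`` column.  With
    equidistant candidates the earlier-listed parcellation row wins,
    which makes the rule deterministic and order-stable.
    """
    parc = validate_parcellation(parc)
    xyz = contacts[["x", "y", "z"]].to_numpy(float)
    pts = parc[["x", "y", "z"]].to_numpy(float)
    nearest = cdist(xyz, pts).argmin(axis=1)   # argmin takes the first minimum
    out = contacts.copy()
    out["region_id"] = parc["region_id"].to_numpy()[nearest]
    return out


def aggregate_to_regions(
    contact_bp: pd.DataFrame,
    assignment: pd.DataFrame,
    regions: list[str] | None = None,
    participant_id: str | None = None,
) -> RegionBandPower:
    """Average contact-level relative band power within each region.

    ``contact_bp`` is indexed by channel id (one column per band);
    ``assignment`` maps ``channel_id`` to ``region_id``.  ``regions``
    fixes the full region universe so uncovered regions appear as NaN
    rows; by default only regions seen in the assignment appear.
    """
    a = assignment.set_index("channel_id") if "channel_id" in assignment.columns else assignment
    missing = [c for c in contact_bp.index if c not in a.index]
    if missing:
        raise ValidationError(f"contacts without region assignment: {missing}")
    region_of = a.loc[contact_bp.index, "region_id"].astype(str)
    grouped = contact_bp.groupby(region_of.to_numpy())
    means = grouped.mean()
    counts = grouped.size()
    if regions is None:
        regions = list(means.index)
    index = pd.Index([str(r) for r in regions], name="region_id")
    return RegionBandPower(
        values=means.reindex(index),
        coverage=counts.reindex(index).fillna(0).astype(int),
        participant_id=participant_id,
    )


def label_resected_contacts(
    contacts: pd.DataFrame,
    mask_points: pd.DataFrame | np.ndarray,
    radius_mm: float = 5.0,
) -> pd.DataFrame:
    """Flag contacts lying within ``radius_mm`` (inclusive) of the resection.

    ``mask_points`` is an ``(n, 3)`` array or a DataFrame with x, y, z
    columns giving the resected tissue as a point cloud.
    """
    pts = (mask_points[["x", "y", "z"]].to_numpy(float)
           if isinstance(mask_points, pd.DataFrame)
           else np.asarray(mask_points, dtype=float))
    if pts.size == 0:
        raise DataError("empty resection mask")
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValidationError(f"resection mask must be n x 3, got {pts.shape}")
    xyz = contacts[["x", "y", "z"]].to_numpy(float)
    dmin = cdist(xyz, pts).min(axis=1)
    out = contacts.copy()
    out["removed"] = dmin <= radius_mm
    return out


def label_resected_regions(
    assignment: pd.DataFrame,
    threshold: float = 0.25,
) -> pd.Series:
    """Per-region resected flag: strictly more than ``threshold`` of the
    region's contacts removed.

    ``assignment`` needs ``region_id`` and ``removed`` columns.  Only
    regions with at least one contact appear in the result.
    """
    if "removed" not in assignment.columns:
        raise ValidationError("contacts have no 'removed' flags; label contacts first")
    frac = assignment.groupby(assignment["region_id"].astype(str))["removed"].mean()
    out = frac > threshold
    out.name = "resected"
    out.index.name = "region_id"
    return out
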