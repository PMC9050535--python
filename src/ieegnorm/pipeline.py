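"""End-to-end orchestration of the analysis stages.

These functions chain the modules in the fixed order the analysis
defines — exclusion -> common average reference -> resample -> segment
-> Welch relative band power -> region aggregation -> normative map /
abnormality scoring -> DRS — and are exactly what the CLI wraps.
"""

from __future__ import annotations

import logging

import pandas as pd

from .abnormality import AbnormalityProfile, abnormality_profile
from .config import PipelineConfig
from .io import Recording
from .localization import (RegionBandPower, aggregate_to_regions,
                           assign_contacts, label_resected_contacts,
                           label_resected_regions, parcellation_regions)
from .normative import NormativeMap, build_normative_map, check_band_compatibility
from .preprocess import preprocess
from .spectral import relative_band_power
from .stats import PatientResult, patient_drs

logger = logging.getLogger(__name__)


def contact_band_power(rec: Recording, channels: pd.DataFrame, policy: str,
                       cfg: PipelineConfig) -> pd.DataFrame:
    """Preprocess a recording and return per-contact relative band power."""
    n0 = rec.n_channels
    rec = preprocess(rec, channels, policy, target_fs=cfg.target_fs,
                     start=cfg.segment_start, duration=cfg.segment_duration)
    logger.info("preprocess: %d of %d channels retained (%s policy)",
                rec.n_channels, n0, policy)
    return relative_band_power(rec, cfg.band_objects(),
                               cfg.welch_window_s, cfg.welch_overlap_s)


def participant_region_tables(rec: Recording, channels: pd.DataFrame,
                              parcellation: pd.DataFrame, policy: str,
                              cfg: PipelineConfig,
                              participant_id: str | None = None,
                              ) -> RegionBandPower:
    """One participant through band power, localization and aggregation."""
    bp = contact_band_power(rec, channels, policy, cfg)
    assigned = assign_contacts(channels[channels["channel_id"].isin(bp.index)],
                               parcellation)
    return aggregate_to_regions(bp, assigned,
                                regions=parcellation_regions(parcellation),
                                participant_id=participant_id)


def build_map_from_cohort(cohort: list[RegionBandPower], cfg: PipelineConfig,
                          parcellation_id: str = "unspecified") -> NormativeMap:
    return build_normative_map(cohort, cfg.min_participants,
                               cfg.band_objects(), parcellation_id)


def score_patient(rec: Recording, channels: pd.DataFrame,
                  parcellation: pd.DataFrame, mask: pd.DataFrame,
                  nmap: NormativeMap, cfg: PipelineConfig,
                  patient_id: str | None = None) -> AbnormalityProfile:
    """Score one patient recording: band power, regions, resection labels,
    |z| against the map and per-region maxz."""
    check_band_compatibility(nmap, cfg.band_objects())
    bp = contact_band_power(rec, channels, "patient", cfg)
    retained = channels[channels["channel_id"].isin(bp.index)]
    assigned = assign_contacts(retained, parcellation)
    assigned = label_resected_contacts(assigned, mask, cfg.radius_mm)
    region_flags = label_resected_regions(assigned, cfg.resected_fraction)
    patient = aggregate_to_regions(bp, assigned,
                                   regions=parcellation_regions(parcellation),
                                   participant_id=patient_id)
    patient.resected = region_flags.reindex(patient.values.index)
    return abnormality_profile(patient, nmap, patient_id)


def profile_drs(profile: AbnormalityProfile,
                outcome: str | None = None) -> PatientResult:
    if profile.resected is None:
        raise ValueError("profile has no resection labels")
    return patient_drs(profile.maxz, profile.resected,
                       patient_id=profile.patient_id or "", outcome=outcome)
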