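"""Synthetic cohorts with the statistical structure the analysis assumes.

Two generation paths share one ground truth:

* **signal path** — every contact gets a 70 s, 200 Hz time series built
  from a 1/f^chi Gaussian background (spectral shaping) plus narrowband
  oscillations whose per-region amplitudes follow smooth spatial
  gradients, so each band dominates a different part of the synthetic
  brain (as real normative maps show: alpha posterior, delta anterior
  temporal, and so on).  Participants differ by lognormal amplitude
  jitter; electrode coverage is partial and contacts sit with a few mm
  of jitter around region centroids.

* **fast region-level path** — region x band relative band-power values
  are drawn directly from Normal(M, sd) around the analytic expectation
  M of the same profiles, skipping signal synthesis.  This is the path
  for cohort-scale statistical experiments.

Patients plant ``n_abnormal`` abnormal regions (one randomly chosen
band each, shifted by ``effect_size`` normative SDs); the resection
covers those regions for simulated good outcomes and misses them
(resecting an equal number of unremarkable regions) for poor outcomes.
Resections are emitted as point-cloud masks so the 5 mm / 25% labelling
path is exercised, not bypassed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import CHANNEL_FLAGS, Recording
from .localization import RegionBandPower
from .spectral import FrequencyBand, canonical_bands

#: oscillation centre frequencies per canonical band (Hz)
CENTRE_FREQS = {"delta": 2.5, "theta": 6.0, "alpha": 10.5, "beta": 20.0, "gamma": 40.0}

#: baseline oscillation amplitudes per band (µV); lower bands stronger,
#: mirroring the generally higher low-frequency power of iEEG
BASE_AMPLITUDES = {"delta": 9.0, "theta": 7.0, "alpha": 6.0, "beta": 4.0, "gamma": 2.0}


@dataclass
class SimulationConfig:
    """Study conditions for synthetic cohorts.

    ``effect_size`` is in units of the normative between-participant SD;
    ``coverage`` is the per-region probability that a participant's
    implantation samples the region.
    """

    n_regions: int = 20
    n_normative: int = 50
    n_patients: int = 30            # per outcome group
    coverage: float = 0.8
    n_abnormal: int = 5             # planted abnormal regions per patient
    n_resected: int = 5             # regions removed by the simulated surgery
    effect_size: float = 3.0        # planted shift, normative-SD units
    fs: float = 200.0
    duration: float = 70.0
    background_exponent: float = 2.0     # chi of the 1/f^chi background
    background_scale: float = 30.0       # µV²/Hz at 1 Hz
    amp_jitter_log: float = 0.2          # sigma of lognormal amplitude jitter
    region_value_sd: float = 0.02        # fast-path SD of relative band power
    contacts_max: int = 3                # 1..contacts_max contacts per region
    contact_jitter_mm: float = 3.0
    region_spacing_mm: float = 20.0
    gradient_depth: float = 0.6          # spatial modulation of amplitudes
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_regions, self.n_normative, self.n_patients,
               self.n_abnormal, self.n_resected, self.contacts_max) < 1:
            raise ValidationError("all counts must be >= 1")
        if self.effect_size < 0:
            raise ValidationError("effect size must be >= 0")
        if not 0 < self.coverage <= 1:
            raise ValidationError("coverage must be in (0, 1]")
        if not 0.5 <= self.background_exponent <= 2.5:
            raise ValidationError("background exponent outside [0.5, 2.5]")
        if self.fs < 200:
            raise ValidationError("simulation sampling rate must be >= 200 Hz")
        if self.duration < 10:
            raise ValidationError("simulated recordings must be >= 10 s")
        if self.n_abnormal + self.n_resected >= self.n_regions:
            raise ValidationError(
                "need n_regions > n_abnormal + n_resected to leave spared regions"
            )

    def rng(self, seed: int | None = None) -> np.random.Generator:
        return np.random.default_rng(self.seed if seed is None else seed)


# ---------------------------------------------------------------------------
# atlas and spectral profiles
# ---------------------------------------------------------------------------

def make_parcellation(cfg: SimulationConfig) -> pd.DataFrame:
    """Region centroids on a 3D grid, one point per region."""
    i = np.arange(cfg.n_regions)
    s = cfg.region_spacing_mm
    return pd.DataFrame({
        "region_id": [f"R{k:02d}" for k in i],
        "x": s * (i % 5), "y": s * ((i // 5) % 5), "z": s * (i // 25),
    })


def make_region_profiles(cfg: SimulationConfig) -> pd.DataFrame:
    """Per-region oscillation amplitudes with smooth spatial gradients.

    Each band's amplitude is modulated sinusoidally across the region
    index with a band-specific phase, so different regions are dominated
    by different bands — the structure normative maps exist to capture.
    """
    bands = list(CENTRE_FREQS)
    i = np.arange(cfg.n_regions)
    amps = {
        b: BASE_AMPLITUDES[b]
        * (1 + cfg.gradient_depth * np.cos(2 * np.pi * i / cfg.n_regions
                                           - 2 * np.pi * k / len(bands)))
        for k, b in enumerate(bands)
    }
    out = pd.DataFrame(amps, index=[f"R{k:02d}" for k in i])
    out.index.name = "region_id"
    return out


def _background_band_mass(band: FrequencyBand, scale: float, chi: float) -> float:
    """Integral of scale * f^-chi over the band minus its exclusions."""
    def integral(lo, hi):
        if chi == 1.0:
            return scale * np.log(hi / lo)
        return scale * (hi ** (1 - chi) - lo ** (1 - chi)) / (1 - chi)
    mass = integral(band.lo, band.hi)
    for elo, ehi in band.exclusions:
        mass -= integral(elo, ehi)
    return mass


def expected_band_powers(amps: pd.Series, cfg: SimulationConfig,
                         bands=None) -> np.ndarray:
    """Analytic band powers of a profile: background mass + a²/2 per band."""
    bands = canonical_bands() if bands is None else bands
    return np.array([
        _background_band_mass(b, cfg.background_scale, cfg.background_exponent)
        + float(amps[b.name]) ** 2 / 2
        for b in bands
    ])


def expected_relative_band_power(profiles: pd.DataFrame,
                                 cfg: SimulationConfig) -> pd.DataFrame:
    """Analytic relative band power per region (log10 + L1), the ground
    truth the pipeline should recover from synthetic cohorts."""
    rows = np.stack([expected_band_powers(profiles.loc[r], cfg)
                     for r in profiles.index])
    logp = np.log10(rows)
    rel = logp / np.abs(logp).sum(axis=1, keepdims=True)
    return pd.DataFrame(rel, index=profiles.index,
                        columns=[b.name for b in canonical_bands()])


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------

def simulate_channel(amps: pd.Series, cfg: SimulationConfig,
                     rng: np.random.Generator,
                     duration: float | None = None) -> np.ndarray:
    """One contact's time series: shaped 1/f^chi noise + band oscillations.

    The background is synthesized in the frequency domain so its
    one-sided PSD equals ``background_scale * f**-chi`` in expectation;
    each band contributes a random-phase cosine at its centre frequency
    with the profile's amplitude (power a²/2 concentrated in-band).
    """
    duration = cfg.duration if duration is None else duration
    n = int(round(duration * cfg.fs))
    freqs = np.fft.rfftfreq(n, 1 / cfg.fs)
    psd = np.zeros_like(freqs)
    psd[1:] = cfg.background_scale * freqs[1:] ** -cfg.background_exponent
    # complex Gaussian spectrum with E|Z|² matched to the target density
    z = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    spectrum = z * np.sqrt(psd * cfg.fs * n / 4)
    x = np.fft.irfft(spectrum, n)
    t = np.arange(n) / cfg.fs
    for band in canonical_bands():
        a = float(amps[band.name])
        if a > 0:
            phase = rng.uniform(0, 2 * np.pi)
            x += a * np.cos(2 * np.pi * CENTRE_FREQS[band.name] * t + phase)
    return x


@dataclass
class SyntheticParticipant:
    participant_id: str
    recording: Recording
    channels: pd.DataFrame          # channel table incl. region ground truth


def _implant(cfg: SimulationConfig, rng: np.random.Generator,
             force_regions: set[str] = frozenset()) -> pd.DataFrame:
    """Random partial electrode coverage: per covered region, 1..contacts_max
    contacts jittered around the centroid.  ``force_regions`` are always
    covered (patient implantations target the suspicious tissue)."""
    parc = make_parcellation(cfg)
    covered = rng.random(cfg.n_regions) < cfg.coverage
    regions = [r for r, c in zip(parc["region_id"], covered) if c]
    regions = list(dict.fromkeys([*regions, *sorted(force_regions)]))
    rows = []
    for region in regions:
        cx, cy, cz = parc.set_index("region_id").loc[region, ["x", "y", "z"]]
        for k in range(int(rng.integers(1, cfg.contacts_max + 1))):
            jx, jy, jz = rng.uniform(-cfg.contact_jitter_mm,
                                     cfg.contact_jitter_mm, 3)
            rows.append({"channel_id": f"{region}c{k}", "x": cx + jx,
                         "y": cy + jy, "z": cz + jz, "true_region": region})
    table = pd.DataFrame(rows)
    for flag in CHANNEL_FLAGS:
        table[flag] = False
    return table


def _participant_amps(profiles: pd.DataFrame, cfg: SimulationConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    jitter = np.exp(cfg.amp_jitter_log * rng.standard_normal(profiles.shape))
    return profiles * jitter


def simulate_participant(profiles: pd.DataFrame, cfg: SimulationConfig,
                         rng: np.random.Generator, participant_id: str,
                         amp_multipliers: pd.DataFrame | None = None,
                         force_regions: set[str] = frozenset(),
                         ) -> SyntheticParticipant:
    channels = _implant(cfg, rng, force_regions)
    amps = _participant_amps(profiles, cfg, rng)
    if amp_multipliers is not None:
        amps = amps * amp_multipliers
    samples = np.stack([
        simulate_channel(amps.loc[row.true_region], cfg, rng)
        for row in channels.itertuples()
    ])
    rec = Recording(samples, cfg.fs, list(channels["channel_id"]))
    return SyntheticParticipant(participant_id, rec, channels)


def simulate_normative_cohort(cfg: SimulationConfig,
                              rng: np.random.Generator | None = None,
                              ) -> list[SyntheticParticipant]:
    """Signal-path normative cohort with partial coverage."""
    rng = cfg.rng() if rng is None else rng
    profiles = make_region_profiles(cfg)
    return [simulate_participant(profiles, cfg, rng, f"N{i:03d}")
            for i in range(cfg.n_normative)]


def _plant(cfg: SimulationConfig, rng: np.random.Generator,
           regions: list[str]) -> tuple[list[str], list[str]]:
    """Choose planted abnormal regions and the band shifted in each."""
    bands = list(CENTRE_FREQS)
    planted = sorted(rng.choice(regions, size=cfg.n_abnormal, replace=False))
    planted_bands = [bands[int(rng.integers(len(bands)))] for _ in planted]
    return planted, planted_bands


def _resection(cfg: SimulationConfig, rng: np.random.Generator,
               outcome: str, planted: list[str],
               candidates: list[str]) -> list[str]:
    normal = [r for r in candidates if r not in planted]
    if outcome == "good":        # surgery covers the abnormal tissue
        extra = max(0, cfg.n_resected - len(planted))
        return planted + sorted(rng.choice(normal, size=extra, replace=False))
    if outcome == "poor":        # surgery misses it entirely
        return sorted(rng.choice(normal, size=cfg.n_resected, replace=False))
    raise ValidationError(f"outcome must be 'good' or 'poor', got {outcome!r}")


def resection_mask_points(parc: pd.DataFrame, resected: list[str],
                          ball_mm: float = 4.0) -> pd.DataFrame:
    """Point-cloud resection mask: a small ball of points per removed region."""
    offsets = np.array([[0, 0, 0], [ball_mm, 0, 0], [-ball_mm, 0, 0],
                        [0, ball_mm, 0], [0, -ball_mm, 0],
                        [0, 0, ball_mm], [0, 0, -ball_mm]], dtype=float)
    centres = parc.set_index("region_id").loc[resected, ["x", "y", "z"]].to_numpy(float)
    pts = (centres[:, None, :] + offsets[None]).reshape(-1, 3)
    return pd.DataFrame(pts, columns=["x", "y", "z"])


@dataclass
class SyntheticPatient:
    patient_id: str
    outcome: str                       # 'good' | 'poor'
    recording: Recording | None        # None on the fast path
    channels: pd.DataFrame | None
    mask: pd.DataFrame | None
    tables: RegionBandPower | None     # fast-path region-level values
    truth: dict = field(default_factory=dict)


def simulate_patient(cfg: SimulationConfig, outcome: str,
                     rng: np.random.Generator,
                     patient_id: str = "P000") -> SyntheticPatient:
    """Signal-path patient: recording + channel table + resection mask.

    Planted regions get their chosen band's oscillation amplitude scaled
    by ``exp(effect_size * amp_jitter_log)`` — an ``effect_size``-SD
    shift on the log-amplitude scale that the between-participant
    jitter defines.
    """
    profiles = make_region_profiles(cfg)
    parc = make_parcellation(cfg)
    planted, planted_bands = _plant(cfg, rng, list(profiles.index))
    mult = pd.DataFrame(1.0, index=profiles.index, columns=profiles.columns)
    for region, band in zip(planted, planted_bands):
        mult.at[region, band] = np.exp(cfg.effect_size * cfg.amp_jitter_log)
    part = simulate_participant(profiles, cfg, rng, patient_id,
                                amp_multipliers=mult,
                                force_regions=set(planted))
    covered = list(dict.fromkeys(part.channels["true_region"]))
    resected = _resection(cfg, rng, outcome, planted, covered)
    mask = resection_mask_points(parc, resected)
    truth = {"planted_regions": planted, "planted_bands": planted_bands,
             "resected_regions": resected, "outcome": outcome}
    return SyntheticPatient(patient_id, outcome, part.recording,
                            part.channels, mask, tables=None, truth=truth)


# ---------------------------------------------------------------------------
# fast region-level path
# ---------------------------------------------------------------------------

def simulate_normative_tables(cfg: SimulationConfig,
                              rng: np.random.Generator | None = None,
                              ) -> list[RegionBandPower]:
    """Region-level normative cohort: values ~ Normal(M, region_value_sd)
    around the analytic profile expectation M, with partial coverage."""
    rng = cfg.rng() if rng is None else rng
    M = expected_relative_band_power(make_region_profiles(cfg), cfg)
    out = []
    for i in range(cfg.n_normative):
        covered = rng.random(cfg.n_regions) < cfg.coverage
        values = M + cfg.region_value_sd * rng.standard_normal(M.shape)
        values[~covered] = np.nan
        coverage = pd.Series(
            np.where(covered, rng.integers(1, cfg.contacts_max + 1,
                                           cfg.n_regions), 0),
            index=M.index, name="coverage")
        out.append(RegionBandPower(values=values, coverage=coverage,
                                   participant_id=f"N{i:03d}"))
    return out


def simulate_patient_tables(cfg: SimulationConfig, outcome: str,
                            rng: np.random.Generator,
                            patient_id: str = "P000") -> SyntheticPatient:
    """Fast-path patient: region-level values with planted shifts and
    region-level resection labels, sharing the signal path's truth
    record structure."""
    M = expected_relative_band_power(make_region_profiles(cfg), cfg)
    planted, planted_bands = _plant(cfg, rng, list(M.index))
    covered = rng.random(cfg.n_regions) < cfg.coverage
    covered |= M.index.isin(planted)
    values = M + cfg.region_value_sd * rng.standard_normal(M.shape)
    for region, band in zip(planted, planted_bands):
        sign = 1.0 if rng.random() < 0.5 else -1.0
        values.at[region, band] += sign * cfg.effect_size * cfg.region_value_sd
    values[~covered] = np.nan
    covered_ids = [r for r, c in zip(M.index, covered) if c]
    resected = _resection(cfg, rng, outcome, planted, covered_ids)
    flags = pd.Series(False, index=pd.Index(covered_ids, name="region_id"),
                      name="resected")
    flags[resected] = True
    coverage = pd.Series(np.where(covered, 1, 0), index=M.index, name="coverage")
    tables = RegionBandPower(values=values, coverage=coverage,
                             resected=flags, participant_id=patient_id)
    truth = {"planted_regions": planted, "planted_bands": planted_bands,
             "resected_regions": resected, "outcome": outcome}
    return SyntheticPatient(patient_id, outcome, None, None, None,
                            tables=tables, truth=truth)


def simulate_patient_cohort_tables(cfg: SimulationConfig,
                                   rng: np.random.Generator | None = None,
                                   ) -> list[SyntheticPatient]:
    """``n_patients`` good plus ``n_patients`` poor fast-path patients."""
    rng = cfg.rng() if rng is None else rng
    out = [simulate_patient_tables(cfg, "good", rng, f"G{i:03d}")
           for i in range(cfg.n_patients)]
    out += [simulate_patient_tables(cfg, "poor", rng, f"B{i:03d}")
            for i in range(cfg.n_patients)]
    return out


def config_to_dict(cfg: SimulationConfig) -> dict:
    return asdict(cfg)
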