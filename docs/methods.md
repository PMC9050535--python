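# Methods

This note records the model, the parameter choices and the numerical
conventions behind `ieegnorm`, including the places where the design
was genuinely open and what the synthetic cohorts do and do not show.

## Pipeline model

**Preprocessing.** The fixed stage order is channel exclusion → common
average reference (CAR) → polyphase resampling to 200 Hz → 70 s segment
extraction. Exclusion policy is role-dependent: normative recordings
drop channels flagged seizure-onset, early-propagation, lesional, bad
or white-matter; patient recordings keep all grey-matter channels
(including the seizure onset zone — the abnormality score must be free
to find it) and drop only bad and white-matter contacts. CAR is
computed over the retained channels. The order CAR-then-resample is a
convention: both operations are linear, and for an ideal anti-alias
filter they commute; fixing one order makes outputs bit-reproducible.
Resampling is rational polyphase with an FIR anti-alias filter
(`scipy.signal.resample_poly`); upsampling is refused, and targets at
or below 160 Hz warn because they leave <2× headroom over the 80 Hz
analysis ceiling. Non-finite samples are rejected at load time rather
than imputed.

**Spectral estimation.** Welch PSD with 2 s Hamming windows, 1 s
overlap, per-segment mean removal (standard practice; it keeps DC
leakage out of the delta band), one-sided density scaling. A 70 s
segment at 200 Hz yields ⌊(70−2)/1⌋+1 = 69 averaged segments. Band
power is the rectangular-rule integral over PSD bins whose centre
frequency lies in [lo, hi); the five canonical bands touch at 4, 8, 13
and 30 Hz, and the half-open convention assigns shared edges to the
upper band so nothing is double counted. Exclusion sub-ranges
(47.5–52.5 and 57.5–62.5 Hz in gamma, guarding 50 and 60 Hz mains and
sidebands) are removed with the same half-open rule from any band they
intersect. Per contact, the five band powers are log₁₀-transformed and
divided by the sum of their absolute values. Using Σ|pⱼ| rather than
Σpⱼ keeps the unit-L1 invariant valid even when some log-powers are
negative (possible for band masses below 1 µV²); signs are retained.
Powers at or below 10⁻¹⁵ µV² raise an error — a dead channel should
surface, not be clamped. Whether "band power" is the integral or the
mean density over the band only changes each band by a fixed constant,
which the per-contact normalization partially absorbs; the integral is
implemented.

**Localization.** Contacts are assigned to the region owning the
nearest supplied parcellation point (centroid or voxel cloud, same
millimetre space); exact ties go to the earlier-listed region, making
assignment deterministic and order-stable. Contact-level relative band
power is averaged within regions *after* the per-contact log/L1
transform. Regions without contacts hold NaN, never zero. A contact is
"removed" when its minimum distance to the resection point cloud is
≤ 5 mm (inclusive — the plain reading of "within 5 mm"); a region is
resected when strictly more than 25% of its contacts were removed.

**Normative map.** Per region × band cell: sample mean and sample SD
(n−1) over participants with coverage; missing participant cells are
ignored. Cells with fewer than `min_participants` (default 5)
contributors are masked unavailable — a z-score against a 2-participant
SD is noise. This threshold is a deliberate addition; nothing in the
underlying approach mandates one, but low-n cells destabilize
everything downstream. Zero-variance cells (σ ≤ 10⁻¹², the numerical
zero for values of magnitude ≤ 1) are flagged degenerate and never
scored. Maps serialize to JSON carrying band definitions, parcellation
identity and build parameters; scoring against a map whose band edges
differ from the analysis configuration is a hard error, not a warning.

**Abnormality.** |zᵢⱼ| = |xᵢⱼ − μᵢⱼ| / σᵢⱼ wherever both the patient
value and a scoreable map cell exist; per region, maxzᵢ is the maximum
over *defined* bands. Missing bands are ignored rather than zero-filled
so partial coverage cannot deflate abnormality; regions with no
scoreable band are dropped (with a logged count) because the score is
undefined there, and no clipping or winsorizing is applied to extreme
z. No multiple-testing correction: z is a ranking score, not a test.

**Outcome statistics.** DRS is implemented through midranks
(U_S = R_S − n_S(n_S+1)/2, DRS = U_S/(n_R n_S)), oriented so DRS > 0.5
means spared tissue was the more abnormal. Patients lacking a resected
or a spared scored region are excluded with a reason, never scored 0.5.
The three pre-specified cohort tests are: good-outcome DRS < 0.5
(left-tailed one-sample t), poor-outcome DRS > 0.5 (right-tailed),
good < poor (left-tailed two-sample t, pooled variance by default with
a Welch option). Outcome discrimination is the Mann–Whitney AUC of DRS
for the poor-outcome class. Chi-squared utilities use Pearson's
statistic without continuity correction, df = 1.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, with two
paths sharing one ground truth.

*Signal path.* Each contact's series is 1/f^χ Gaussian background
(synthesized by frequency-domain shaping so the one-sided PSD equals
`background_scale·f^−χ` in expectation) plus one random-phase cosine
per band at the region's profile amplitude. Default χ = 2 and a
30 µV²/Hz scale at 1 Hz give plausibly iEEG-like spectra; band
amplitudes (9, 7, 6, 4, 2 µV for δ…γ) fall with frequency and are
modulated sinusoidally across regions with band-specific phases, so
each band dominates a different part of the synthetic brain.
Participants differ by lognormal amplitude jitter (σ_log = 0.2);
coverage is partial (probability 0.8 per region), with 1–3 contacts
per covered region jittered ≤3 mm around centroids. Since the profile
band powers have closed form (background integral + a²/2), the
expected relative band power per region is analytic and serves as
ground truth for recovery tests.

*Fast region-level path.* Region × band values are drawn
Normal(M, 0.02) around that analytic expectation M, skipping signal
synthesis; this is the path for cohort-scale statistical experiments.
The between-participant SD 0.02 is a free knob (no quantitative
within-region variance is available to estimate it from), chosen to
give z-scores of realistic magnitude.

*Patients.* Each patient plants `n_abnormal` abnormal regions, one
randomly chosen band each, shifted by `effect_size` normative SDs
(fast path: ±effect·σ added to the drawn value; signal path: the
band's amplitude is scaled by exp(effect·σ_log), an effect-sized shift
on the log-amplitude scale that the participant jitter defines — in
scored-z units this lands somewhat below the nominal effect because
Welch noise and the L1 coupling also feed the normative σ). Good
outcomes get resections covering the planted regions; poor outcomes
get resections of equally many unremarkable regions, sparing every
planted one. Signal-path resections are emitted as point-cloud balls
around the removed regions' centroids so the 5 mm / >25% labelling
path is exercised, not bypassed. Defaults: 20 regions, 5 planted, 5
resected, effect 3 SD, 50 normative participants, 30 patients per
group. The 5/20 abnormal burden mirrors the poor-outcome picture of
multiple abnormal regions left in place; with a much sparser burden
(e.g. 3/20) the per-patient DRS sign becomes dominated by
normal-vs-normal rank noise and single patients are not reliably
directional, although group means still separate.

*What passing tests do not show.* The synthetic cohorts contain no
epileptiform transients, no electrode geometry, no spatial correlation
beyond the smooth amplitude gradients, no covariate structure
(age/sex/state) and Gaussian region values; calibration and recovery
results on them validate the pipeline's statistics, not clinical
performance on real iEEG.

## Numerical and scale choices

- All randomness flows through `numpy.random.default_rng` seeded from
  a single config value; identical seeds give bit-identical outputs.
- EDF writing uses 1 s data records with per-channel physical scaling
  re-derived from the printed header fields, so write→read agrees to
  within one 16-bit quantization step. EDF requires integer sampling
  rates and whole-second durations; the tabular CSV + YAML-sidecar
  format has no such limits and is the fixture format.
- Experiment sizes in the test battery (200-participant leave-one-out
  calibration, 200 planted-recovery repeats, 100 + 60 simulated
  participants for the cohort replication) were chosen as the smallest
  cohorts at which the binomial/Monte-Carlo error of the checked
  quantity is comfortably inside the asserted tolerance.
- Leave-one-out z-scores are computed from cohort sums
  (μ₋ᵢ, σ₋ᵢ from S₁, S₂ minus the held-out value), so the 200-fold
  scan is vectorized rather than 200 map rebuilds; a direct
  recomputation cross-checks it in the unit tests.

## Known limitations

- No covariate adjustment, hemisphere symmetrization or spatial
  smoothing of the map; no multitaper/wavelet spectra; no time-resolved
  abnormality.
- The nearest-point operationalization of "closest region" depends on
  how the parcellation is sampled (centroid vs voxel cloud).
- Imaging is out of scope: parcellations and resections enter as
  coordinate point clouds prepared elsewhere.
- DRS treats regions as exchangeable; it ignores region size and
  spatial adjacency.
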