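"""Outcome statistics: DRS, tailed t tests, ROC/AUC, dice and chi-squared.

DRS — the distinguishability of resected and spared regions — is the
tie-aware probability that a randomly chosen spared region is more
abnormal than a randomly chosen resected region:

    DRS = (1 / (n_R n_S)) sum_r sum_s [ 1(s > r) + 0.5 * 1(s = r) ]

equivalently the normalised Mann-Whitney U statistic, equivalently the
area under the ROC curve separating the two groups.  DRS > 0.5 means
abnormal tissue was spared by the surgery; DRS < 0.5 means the resected
tissue was the more abnormal.  Cohort-level hypotheses are evaluated
with tailed one- and two-sample t tests and the outcome discrimination
of DRS with an AUC over patients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import DataError, ValidationError

#: outcome labels (International League Against Epilepsy classes)
GOOD_OUTCOME = "ILAE1_2"     # free of disabling seizures
POOR_OUTCOME = "ILAE3plus"   # persistent seizures


@dataclass
class PatientResult:
    patient_id: str
    drs: float
    n_resected: int
    n_spared: int
    outcome: str | None = None
    segment_id: str | None = None


@dataclass
class CohortResult:
    """Per-patient DRS plus the pre-specified cohort tests."""

    patients: pd.DataFrame            # patient_id, drs, outcome, n_resected, n_spared
    good_below_half: tuple[float, float]   # (t, p), left tail vs 0.5
    poor_above_half: tuple[float, float]   # (t, p), right tail vs 0.5
    good_vs_poor: tuple[float, float]      # (t, p), left tail, good < poor
    auc: float                             # DRS discriminating poor outcome
    group_means: dict[str, float]
    group_sds: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "n_good": int((self.patients["outcome"] == GOOD_OUTCOME).sum()),
            "n_poor": int((self.patients["outcome"] == POOR_OUTCOME).sum()),
            "good_below_half": {"t": self.good_below_half[0], "p": self.good_below_half[1]},
            "poor_above_half": {"t": self.poor_above_half[0], "p": self.poor_above_half[1]},
            "good_vs_poor": {"t": self.good_vs_poor[0], "p": self.good_vs_poor[1]},
            "auc": self.auc,
            "group_means": self.group_means,
            "group_sds": self.group_sds,
        }


def drs(resected, spared) -> float:
    """Tie-aware P(spared more abnormal than resected) via midranks.

    Implemented with the rank-sum identity U_S = R_S - n_S (n_S + 1) / 2,
    DRS = U_S / (n_R n_S); midranks handle ties, so exactly equal
    abnormalities contribute 1/2.
    """
    r = np.asarray(resected, dtype=float)
    s = np.asarray(spared, dtype=float)
    if r.size == 0 or s.size == 0:
        raise DataError("DRS needs at least one resected and one spared value")
    if not (np.all(np.isfinite(r)) and np.all(np.isfinite(s))):
        raise DataError("non-finite abnormality values in DRS input")
    ranks = sstats.rankdata(np.concatenate([s, r]))
    u_spared = ranks[:s.size].sum() - s.size * (s.size + 1) / 2
    return float(u_spared / (r.size * s.size))


def patient_drs(maxz: pd.Series, resected: pd.Series,
                patient_id: str = "", outcome: str | None = None) -> PatientResult:
    """DRS of one patient from per-region maxz and resected flags.

    Patients without at least one resected and one spared scored region
    cannot be scored; a :class:`DataError` is raised so callers exclude
    them explicitly rather than defaulting to 0.5.
    """
    flags = resected.reindex(maxz.index)
    if flags.isna().any():
        raise ValidationError(
            f"regions without resection labels: {list(flags.index[flags.isna()])}"
        )
    flags = flags.astype(bool)
    r = maxz[flags].to_numpy()
    s = maxz[~flags].to_numpy()
    if r.size == 0 or s.size == 0:
        raise DataError(
            f"patient {patient_id or '?'} has no "
            f"{'resected' if r.size == 0 else 'spared'} scored regions"
        )
    return PatientResult(patient_id=patient_id, drs=drs(r, s),
                         n_resected=int(r.size), n_spared=int(s.size),
                         outcome=outcome)


def roc_auc(scores, labels, positive=POOR_OUTCOME) -> float:
    """AUC as the normalised Mann-Whitney statistic of positive vs
    negative scores (ties count 1/2); identical to
    ``drs(negative_scores, positive_scores)``."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive
    if pos.all() or not pos.any():
        raise DataError("AUC needs both outcome classes present")
    return drs(scores[~pos], scores[pos])


def one_sample_t_tailed(values, null_value: float = 0.5, tail: str = "left"
                        ) -> tuple[float, float]:
    """One-sample Student t against ``null_value`` with a one-sided p."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise DataError(f"one-sample t test needs n >= 2, got {v.size}")
    if np.ptp(v) == 0:
        raise DataError("zero variance: t statistic undefined")
    alternative = {"left": "less", "right": "greater"}.get(tail)
    if alternative is None:
        raise ValidationError(f"tail must be 'left' or 'right', got {tail!r}")
    res = sstats.ttest_1samp(v, null_value, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def two_sample_t_tailed(group_a, group_b, tail: str = "left",
                        pooled: bool = True) -> tuple[float, float]:
    """Two-sample t with a one-sided p; ``tail='left'`` tests
    mean(a) < mean(b).  Pooled-variance Student t by default
    (df = n_a + n_b - 2); ``pooled=False`` switches to Welch."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DataError("two-sample t test needs n >= 2 in each group")
    alternative = {"left": "less", "right": "greater"}.get(tail)
    if alternative is None:
        raise ValidationError(f"tail must be 'left' or 'right', got {tail!r}")
    res = sstats.ttest_ind(a, b, equal_var=pooled, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def dice_overlap(set_a, set_b) -> float:
    """Dice coefficient 2|A∩B| / (|A| + |B|) of two region-id sets."""
    a, b = set(set_a), set(set_b)
    if not a and not b:
        raise DataError("dice overlap of two empty sets is undefined")
    return 2 * len(a & b) / (len(a) + len(b))


def chi2_2x2(table) -> tuple[float, float]:
    """Pearson chi-squared on a 2x2 table, df=1, no continuity correction."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if np.any(t < 0) or np.any(t != np.rint(t)):
            raise ValidationError("counts must be non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise DataError("chi-squared undefined with a zero margin")
    chi2, p, _, _ = sstats.chi2_contingency(t, correction=False)
    return float(chi2), float(p)


def run_cohort_analysis(patients: list[PatientResult],
                        pooled: bool = True) -> CohortResult:
    """The pre-specified cohort analysis over per-patient DRS values.

    (i) left-tailed one-sample t of good-outcome DRS against 0.5,
    (ii) right-tailed one-sample t of poor-outcome DRS against 0.5,
    (iii) left-tailed two-sample t of good vs poor DRS, and
    (iv) AUC of DRS for discriminating the poor-outcome class.
    """
    rows = []
    for p in patients:
        if p.outcome not in (GOOD_OUTCOME, POOR_OUTCOME):
            raise ValidationError(
                f"patient {p.patient_id}: outcome must be {GOOD_OUTCOME} or "
                f"{POOR_OUTCOME}, got {p.outcome!r}"
            )
        rows.append({"patient_id": p.patient_id, "drs": p.drs,
                     "outcome": p.outcome, "n_resected": p.n_resected,
                     "n_spared": p.n_spared})
    frame = pd.DataFrame(rows)
    good = frame.loc[frame["outcome"] == GOOD_OUTCOME, "drs"].to_numpy()
    poor = frame.loc[frame["outcome"] == POOR_OUTCOME, "drs"].to_numpy()
    if good.size < 2 or poor.size < 2:
        raise DataError("cohort analysis needs >= 2 patients per outcome group")
    return CohortResult(
        patients=frame,
        good_below_half=one_sample_t_tailed(good, 0.5, "left"),
        poor_above_half=one_sample_t_tailed(poor, 0.5, "right"),
        good_vs_poor=two_sample_t_tailed(good, poor, "left", pooled=pooled),
        auc=roc_auc(frame["drs"], frame["outcome"], positive=POOR_OUTCOME),
        group_means={GOOD_OUTCOME: float(good.mean()), POOR_OUTCOME: float(poor.mean())},
        group_sds={GOOD_OUTCOME: float(good.std(ddof=1)), POOR_OUTCOME: float(poor.std(ddof=1))},
    )
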