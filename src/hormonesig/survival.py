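"""Gene-signature survival stratification.

Scores each patient by the signed mean z-score of a gene signature, splits
the cohort at the score quartiles into signature-high and signature-low
groups (the middle half is excluded from testing), estimates Kaplan-Meier
survival curves with the product-limit estimator, and compares the two
groups with a from-scratch two-group log-rank test. The estimator and test
are implemented from first principles because they are the analytical core
of this stage; an external survival library is used only as an independent
cross-check in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import GeneSignature
from .errors import ConfigError, DataError
from .matrix import FeatureMatrix


@dataclass
class SurvivalCohort:
    """Right-censored follow-up data: time >= 0 and event flag (1 = death)."""

    patients: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if len(self.patients) != len(self.time) or len(self.time) != len(self.event):
            raise DataError("patients, time and event must have equal length")
        if np.any(self.time < 0):
            raise DataError("follow-up times must be non-negative")
        if not np.isin(self.event, (0, 1)).all():
            raise DataError("event flags must be 0 (censored) or 1 (death)")

    def __len__(self) -> int:
        return len(self.patients)

    def subset(self, ids: Sequence[str]) -> "SurvivalCohort":
        idx = [self.patients.index(p) for p in ids]
        return SurvivalCohort(
            [self.patients[i] for i in idx], self.time[idx], self.event[idx]
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"patient_id": self.patients, "time": self.time, "event": self.event}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SurvivalCohort":
        df = pd.read_csv(path, sep="\t")
        return cls(df["patient_id"].astype(str).tolist(), df["time"].to_numpy(),
                   df["event"].to_numpy())


@dataclass
class StratifiedGroups:
    high: list[str]
    low: list[str]
    middle: list[str]
    cut_low: float
    cut_high: float


@dataclass
class KMCurve:
    """Product-limit survival estimate: S(t) after each distinct event time."""

    times: np.ndarray      # distinct event times, ascending
    survival: np.ndarray   # S(t) just after each event time
    n_risk: np.ndarray     # at risk just before each event time
    n_event: np.ndarray    # deaths at each event time

    def at(self, t: float) -> float:
        """S(t); 1 before the first event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "n_risk": self.n_risk,
             "n_event": self.n_event, "survival": self.survival}
        )

    def median(self) -> float:
        """Smallest event time with S(t) <= 0.5; inf if never reached."""
        below = np.flatnonzero(self.survival <= 0.5)
        return float(self.times[below[0]]) if below.size else np.inf


@dataclass
class LogRankResult:
    statistic: float
    p_value: float
    df: int = 1

    def as_dict(self) -> dict:
        return {"chi2": self.statistic, "df": self.df, "p_value": self.p_value}


@dataclass
class SurvivalReport:
    groups: StratifiedGroups
    curve_high: KMCurve
    curve_low: KMCurve
    test: LogRankResult
    scores: pd.Series
    excluded_genes: list[str] = field(default_factory=list)


def signature_score(expression: FeatureMatrix, signature: GeneSignature) -> tuple[pd.Series, list[str]]:
    """Signed mean z-score of the signature genes, per patient.

    Each present gene is z-scored across patients and multiplied by its
    signature direction (+1 up, -1 down); the score is the mean over genes.
    Zero-variance genes are excluded with a warning; genes absent from the
    matrix are reported in the returned exclusion list.
    """
    present = [g for g in signature.genes if g in set(expression.features)]
    absent = [g for g in signature.genes if g not in set(expression.features)]
    if not present:
        raise DataError("no signature gene is present in the expression matrix")
    X = expression.data.loc[present]
    sds = X.std(axis=1, ddof=0)
    flat = list(X.index[sds == 0])
    if flat:
        warnings.warn(f"excluding zero-variance signature genes: {flat[:5]}")
        X = X.loc[sds > 0]
        sds = sds[sds > 0]
    z = X.sub(X.mean(axis=1), axis=0).div(sds, axis=0)
    signs = pd.Series({g: signature.directions[g] for g in z.index})
    scores = z.mul(signs, axis=0).mean(axis=0)
    scores.name = "score"
    return scores, absent + flat


def quartile_stratify(scores: pd.Series) -> StratifiedGroups:
    """Split patients at the 25th/75th score percentiles.

    Quantiles use linear interpolation between order statistics; patients
    strictly above the 75th percentile are "high", strictly below the 25th
    "low", everything else (including boundary ties) is middle and excluded
    from testing.
    """
    if len(scores) < 8:
        raise ConfigError(f"need >= 8 patients to stratify, got {len(scores)}")
    values = scores.to_numpy(dtype=float)
    if np.all(values == values[0]):
        raise DataError("all scores identical; stratification impossible")
    cut_low, cut_high = np.quantile(values, [0.25, 0.75])
    high = sorted(scores.index[values > cut_high])
    low = sorted(scores.index[values < cut_low])
    middle = sorted(set(scores.index) - set(high) - set(low))
    if not high or not low:
        raise DataError("a stratum is empty; scores too heavily tied")
    return StratifiedGroups(high, low, middle, float(cut_low), float(cut_high))


def km_estimate(cohort: SurvivalCohort) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    S(t) = prod over event times t_i <= t of (1 - d_i / n_i) with d_i deaths
    at t_i and n_i at risk just before t_i; patients censored at an event
    time still count as at risk there (events processed before censorings).
    """
    if len(cohort) == 0:
        raise DataError("empty cohort")
    event_times = np.unique(cohort.time[cohort.event == 1])
    surv, n_risk, n_event = [], [], []
    s = 1.0
    for t in event_times:
        at_risk = int(np.sum(cohort.time >= t))
        deaths = int(np.sum((cohort.time == t) & (cohort.event == 1)))
        s *= 1.0 - deaths / at_risk
        surv.append(s)
        n_risk.append(at_risk)
        n_event.append(deaths)
    return KMCurve(
        times=event_times,
        survival=np.array(surv),
        n_risk=np.array(n_risk, dtype=int),
        n_event=np.array(n_event, dtype=int),
    )


def log_rank(group1: SurvivalCohort, group2: SurvivalCohort) -> LogRankResult:
    """Two-group log-rank test from first principles.

    At each distinct event time the observed deaths in group 1 are compared
    with the expectation under the hypergeometric model given the pooled
    risk sets; chi2 = (sum O - sum E)^2 / sum V on 1 df, with tied event
    times pooled.
    """
    if len(group1) == 0 or len(group2) == 0:
        raise DataError("both groups must be non-empty")
    t1, e1, t2, e2 = group1.time, group1.event, group2.time, group2.event
    if e1.sum() + e2.sum() == 0:
        raise DataError("log-rank needs >= 1 event")
    event_times = np.unique(np.concatenate([t1[e1 == 1], t2[e2 == 1]]))
    O = E = V = 0.0
    for t in event_times:
        n1 = np.sum(t1 >= t)
        n2 = np.sum(t2 >= t)
        d1 = np.sum((t1 == t) & (e1 == 1))
        d2 = np.sum((t2 == t) & (e2 == 1))
        n, d = n1 + n2, d1 + d2
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if V == 0:
        raise DataError("zero total variance; log-rank undefined")
    chi2 = (O - E) ** 2 / V
    p = float(stats.chi2.sf(chi2, df=1))
    return LogRankResult(float(chi2), max(p, 5e-324))


def run_survival(
    cohort: SurvivalCohort,
    expression: FeatureMatrix,
    signature: GeneSignature,
) -> SurvivalReport:
    """Score, stratify, estimate and test in one pass."""
    if set(cohort.patients) - set(expression.samples):
        raise DataError("cohort patients missing from expression matrix")
    scores, excluded = signature_score(expression, signature)
    scores = scores.loc[cohort.patients]
    groups = quartile_stratify(scores)
    high = cohort.subset(groups.high)
    low = cohort.subset(groups.low)
    return SurvivalReport(
        groups=groups,
        curve_high=km_estimate(high),
        curve_low=km_estimate(low),
        test=log_rank(high, low),
        scores=scores,
        excluded_genes=excluded,
    )
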