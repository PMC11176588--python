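"""Risk-score survival stratification for gene clusters.

A cluster of genes is scored per patient as the Cox linear predictor

    risk = sum_i Exp_i * beta_i,

with beta from a multivariate Cox proportional-hazards fit (delegated to
lifelines).  Patients are split at the median risk score into high/low
groups, Kaplan-Meier curves are estimated per group, and the two-group
log-rank test measures separation.  The Kaplan-Meier estimator and the
log-rank statistic are implemented natively so they can be checked against
closed-form hand computations.

Fitting the coefficients and testing the split on the same patients
overstates significance (the fitted score is the direction in expression
space most associated with the observed survival).  ``evaluate_cluster``
therefore defaults to a split-sample design - coefficients estimated on a
training half, the stratification tested on the held-out half - under which
the log-rank p-value is valid; ``validation="resubstitution"`` reproduces
the classical single-cohort workflow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

HIGH = "high"
LOW = "low"


class SurvivalError(ValueError):
    """Raised for malformed survival inputs or impossible stratifications."""


@dataclass
class SurvivalData:
    """Follow-up times, event indicators and gene expression for one cohort.

    ``expression`` is genes x samples on the same scale the coefficients
    will be applied to; ``time`` is positive follow-up in study units and
    ``event`` is 1 for an observed death, 0 for censoring.
    """

    time: pd.Series
    event: pd.Series
    expression: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.time.index.equals(self.event.index):
            raise SurvivalError("time and event indices differ")
        if (self.time <= 0).any():
            raise SurvivalError("survival times must be positive")
        if not set(self.event.unique()) <= {0, 1}:
            raise SurvivalError("event indicators must be 0/1")
        missing = [s for s in self.time.index if s not in self.expression.columns]
        if missing:
            raise SurvivalError(f"samples without expression: {missing[:5]}")
        self.expression = self.expression.loc[:, self.time.index]

    @property
    def samples(self) -> pd.Index:
        return self.time.index

    def subset(self, samples: Sequence[str]) -> "SurvivalData":
        s = list(samples)
        return SurvivalData(self.time.loc[s], self.event.loc[s], self.expression[s])


@dataclass
class KMCurve:
    """Kaplan-Meier product-limit curve: S(t) at each distinct event time."""

    times: np.ndarray
    at_risk: np.ndarray
    survival: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t); 1 before the first event."""
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if ti <= t:
                s = si
            else:
                break
        return s


@dataclass
class LogrankResult:
    chi2: float
    p: float


@dataclass
class RiskModel:
    """Cox coefficients, per-sample risk scores and the median-split groups."""

    genes: list[str]
    beta: pd.Series
    scores: pd.Series
    threshold: float
    groups: pd.Series


@dataclass
class ClusterEvaluation:
    model: RiskModel
    km_high: KMCurve
    km_low: KMCurve
    logrank: LogrankResult
    test_samples: pd.Index


def read_survival(path: str | Path, expression: pd.DataFrame) -> SurvivalData:
    """Read a (sample, time, event) TSV and join per-sample expression."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    for k in ("sample", "time", "event"):
        if k not in cols:
            raise SurvivalError(f"{path}: survival table needs column {k!r}")
    df = df.rename(columns={cols[k]: k for k in ("sample", "time", "event")})
    df = df.set_index("sample")
    return SurvivalData(df["time"].astype(float), df["event"].astype(int), expression)


def risk_score(expression: pd.DataFrame, beta: pd.Series) -> pd.Series:
    """Per-sample linear risk score: dot product of expression and beta."""
    missing = [g for g in beta.index if g not in expression.index]
    if missing:
        raise SurvivalError(f"coefficient genes absent from expression: {missing[:5]}")
    scores = expression.loc[beta.index].T @ beta
    scores.name = "risk_score"
    return scores


def median_split(scores: pd.Series) -> pd.Series:
    """Label samples high/low risk at the median score.

    Scores strictly above the median are high risk; ties at the median go
    to the low-risk group.
    """
    if len(scores) < 4:
        raise SurvivalError("median split needs >=4 samples")
    if scores.nunique() == 1:
        raise SurvivalError("all risk scores identical; no split possible")
    med = scores.median()
    groups = pd.Series(np.where(scores > med, HIGH, LOW), index=scores.index, name="risk_group")
    return groups


def km_estimate(time: Sequence[float] | pd.Series, event: Sequence[int] | pd.Series) -> KMCurve:
    """Native Kaplan-Meier product-limit estimator.

    Censored observations reduce the risk set without producing a step.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if len(t) == 0:
        raise SurvivalError("empty survival sample")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e == 1])
    surv = []
    at_risk = []
    s = 1.0
    for ti in event_times:
        n = int((t >= ti).sum())
        d = int(((t == ti) & (e == 1)).sum())
        s *= 1.0 - d / n
        at_risk.append(n)
        surv.append(s)
    return KMCurve(event_times, np.array(at_risk), np.array(surv))


def logrank_test(
    time_a: Sequence[float] | pd.Series,
    event_a: Sequence[int] | pd.Series,
    time_b: Sequence[float] | pd.Series,
    event_b: Sequence[int] | pd.Series,
) -> LogrankResult:
    """Two-group log-rank test on one degree of freedom (two-sided).

    Uses the standard hypergeometric variance at each distinct event time.
    """
    ta = np.asarray(time_a, dtype=float)
    ea = np.asarray(event_a, dtype=int)
    tb = np.asarray(time_b, dtype=float)
    eb = np.asarray(event_b, dtype=int)
    if len(ta) == 0 or len(tb) == 0:
        raise SurvivalError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise SurvivalError("log-rank test needs at least one event")
    times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    o1 = e1 = v = 0.0
    for t in times:
        n1 = int((ta >= t).sum())
        n2 = int((tb >= t).sum())
        n = n1 + n2
        d1 = int(((ta == t) & (ea == 1)).sum())
        d2 = int(((tb == t) & (eb == 1)).sum())
        d = d1 + d2
        if n == 0 or d == 0:
            continue
        o1 += d1
        e1 += n1 * d / n
        if n > 1:
            v += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if v == 0:
        return LogrankResult(0.0, 1.0)
    chi2 = (o1 - e1) ** 2 / v
    return LogrankResult(float(chi2), float(stats.chi2.sf(chi2, 1)))


def fit_cox(data: SurvivalData, genes: Sequence[str], penalizer: float = 0.01) -> pd.Series:
    """Multivariate Cox proportional-hazards coefficients via lifelines."""
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    missing = [g for g in genes if g not in data.expression.index]
    if missing:
        raise SurvivalError(f"cluster genes absent from expression: {missing[:5]}")
    df = data.expression.loc[list(genes)].T.copy()
    df["time"] = data.time
    df["event"] = data.event
    try:
        cph = CoxPHFitter(penalizer=penalizer)
        cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as err:  # pragma: no cover - depends on data
        raise SurvivalError(f"Cox fit did not converge: {err}") from err
    beta = cph.params_.loc[list(genes)]
    beta.name = "beta"
    return beta


def evaluate_cluster(
    genes: Sequence[str],
    data: SurvivalData,
    beta: pd.Series | None = None,
    validation: str = "split",
    train_fraction: float = 0.5,
    penalizer: float = 0.01,
    random_state: int | None = None,
) -> ClusterEvaluation:
    """Full prognostic evaluation of a gene cluster.

    Fits the multivariate Cox model (unless ``beta`` is supplied), computes
    risk scores, median-splits the evaluation cohort and compares the
    Kaplan-Meier curves of the two groups with a log-rank test.

    validation
        ``"split"`` (default): coefficients are estimated on a random
        training half and the split/test run on the held-out half, keeping
        the log-rank p-value honest.  ``"resubstitution"``: fit and test on
        the full cohort (classical workflow; anti-conservative).  When
        ``beta`` is supplied the coefficients are external, so the full
        cohort is evaluated regardless.
    """
    genes = list(genes)
    if validation not in ("split", "resubstitution"):
        raise SurvivalError(f"unknown validation mode {validation!r}")
    if beta is not None:
        fitted = beta.reindex(genes)
        if fitted.isna().any():
            raise SurvivalError("supplied beta does not cover all cluster genes")
        eval_data = data
    elif validation == "split":
        rng = np.random.default_rng(random_state)
        samples = np.array(data.samples)
        perm = rng.permutation(len(samples))
        n_train = max(2, int(round(train_fraction * len(samples))))
        train = data.subset(samples[perm[:n_train]])
        eval_data = data.subset(samples[np.sort(perm[n_train:])])
        fitted = fit_cox(train, genes, penalizer=penalizer)
    else:
        eval_data = data
        fitted = fit_cox(data, genes, penalizer=penalizer)

    scores = risk_score(eval_data.expression, fitted)
    groups = median_split(scores)
    hi = groups.index[groups == HIGH]
    lo = groups.index[groups == LOW]
    km_hi = km_estimate(eval_data.time.loc[hi], eval_data.event.loc[hi])
    km_lo = km_estimate(eval_data.time.loc[lo], eval_data.event.loc[lo])
    lr = logrank_test(
        eval_data.time.loc[hi], eval_data.event.loc[hi],
        eval_data.time.loc[lo], eval_data.event.loc[lo],
    )
    model = RiskModel(genes, fitted, scores, float(scores.median()), groups)
    return ClusterEvaluation(model, km_hi, km_lo, lr, eval_data.samples)
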