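"""Survival-model evaluation: concordance, per-window ROC/AUC, Kaplan-Meier
calibration, probability-band risk stratification, and group comparisons.

Discrimination is summarized two ways: Harrell's c-index on the final-window
risk score (last-follow-up information), and a time-dependent AUC per window
where cases are patients dead by the window boundary, controls are patients
known to be alive beyond it, and patients already censored out are excluded.
Calibration splits the test group into seven equally numerous bins by
predicted survival and compares each bin's mean prediction with the
Kaplan-Meier actual at the horizon.  Stratification cuts predicted survival
at fixed probability cutpoints into five prognostic subgroups whose KM curves
are compared pairwise with log-rank tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from lifelines.utils import concordance_index as _lifelines_cindex
from scipy import stats
from sklearn.metrics import roc_auc_score

from .red import CENSORED_OUT, DEAD

__all__ = [
    "concordance_index",
    "window_roc_auc",
    "KMCurve",
    "km_estimate",
    "log_rank_test",
    "mann_whitney",
    "CalibrationBin",
    "calibration_bins",
    "stratify_by_probability",
    "EvaluationReport",
    "evaluate_report",
]

DEFAULT_CUTPOINTS = (0.96, 0.78, 0.53, 0.32)


def concordance_index(risk: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Harrell's c over comparable pairs (higher risk should fail earlier);
    risk ties count 0.5.  Raises if no pair is comparable."""
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if not (len(risk) == len(time) == len(event)):
        raise ValueError("risk, time and event must align")
    try:
        return float(_lifelines_cindex(time, -risk, event))
    except ZeroDivisionError as exc:
        raise ValueError("no comparable pairs for the concordance index") from exc


def window_roc_auc(
    S: np.ndarray, status: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Per-window AUC of the predicted survival probability.

    At window i: cases are DEAD (E_i = 1), controls AT_RISK, censored-out
    patients excluded; the AUC is rank-based (Mann-Whitney statistic), with
    mid-rank tie handling.  Windows lacking cases or controls are NaN and
    excluded from the mean/SD; all-degenerate input raises.
    """
    S = np.asarray(S, dtype=float)
    status = np.asarray(status)
    if S.shape != status.shape:
        raise ValueError("S and status must have identical shape")
    aucs = np.full(S.shape[1], np.nan)
    for wi in range(S.shape[1]):
        include = status[:, wi] != CENSORED_OUT
        cases = status[include, wi] == DEAD
        if cases.any() and (~cases).any():
            # higher risk (= lower predicted survival) should mark cases
            aucs[wi] = roc_auc_score(cases, 1.0 - S[include, wi])
    valid = aucs[~np.isnan(aucs)]
    if len(valid) == 0:
        raise ValueError("every window is degenerate (no cases or no controls)")
    sd = float(np.std(valid, ddof=1)) if len(valid) > 1 else 0.0
    return aucs, float(valid.mean()), sd


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate: S is non-increasing with S(0) = 1;
    ties at a time process deaths before censorings."""

    times: tuple[float, ...]
    survival: tuple[float, ...]
    at_risk: tuple[int, ...]

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(np.asarray(self.times), t, side="right") - 1
        return 1.0 if idx < 0 else self.survival[idx]


def km_estimate(time: np.ndarray, event: np.ndarray) -> KMCurve:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(time) == 0:
        raise ValueError("empty cohort")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    tbl = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 else kmf.event_table
    times = tbl.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    at_risk = tbl["at_risk"].to_numpy(dtype=int)
    return KMCurve(tuple(times), tuple(surv), tuple(at_risk))


def log_rank_test(
    time_a, event_a, time_b, event_b
) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and its tail p-value."""
    event_a = np.asarray(event_a, dtype=int)
    event_b = np.asarray(event_b, dtype=int)
    if len(event_a) == 0 or len(event_b) == 0:
        raise ValueError("both groups must be non-empty")
    if event_a.sum() + event_b.sum() == 0:
        raise ValueError("log-rank test requires at least one event")
    res = _lifelines_logrank(time_a, time_b, event_observed_A=event_a, event_observed_B=event_b)
    return float(res.test_statistic), float(res.p_value)


def mann_whitney(sample1, sample2) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.  Exact enumeration for combined n <= 12
    without ties; otherwise the normal approximation with tie correction."""
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    no_ties = len(np.unique(combined)) == len(combined)
    method = "exact" if (len(combined) <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class CalibrationBin:
    bin_id: int
    mean_predicted: float
    km_actual: float
    size: int


def calibration_bins(
    S_horizon: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    n_bins: int = 7,
    horizon: float = 60.0,
) -> list[CalibrationBin]:
    """Rank patients by predicted survival at the horizon, cut into
    equally numerous bins (remainders to the lowest-rank bins), and compare
    each bin's mean prediction with the KM actual at the horizon."""
    S_horizon = np.asarray(S_horizon, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = len(S_horizon)
    if n < n_bins:
        raise ValueError("fewer patients than calibration bins")
    order = np.argsort(S_horizon, kind="stable")
    base, extra = divmod(n, n_bins)
    bins, start = [], 0
    for b in range(n_bins):
        size = base + (1 if b < extra else 0)
        members = order[start : start + size]
        start += size
        km = km_estimate(time[members], event[members])
        bins.append(
            CalibrationBin(
                bin_id=b + 1,
                mean_predicted=float(S_horizon[members].mean()),
                km_actual=float(km.survival_at(horizon)),
                size=int(size),
            )
        )
    return bins


def stratify_by_probability(
    S: np.ndarray, cutpoints: tuple[float, ...] = DEFAULT_CUTPOINTS
) -> np.ndarray:
    """Assign prognostic subgroups 1..len(cutpoints)+1 from predicted
    survival, using half-open bands: with the default cutpoints, group 1 is
    S in [0.96, 1], group 2 [0.78, 0.96), ..., group 5 [0, 0.32) — an
    exhaustive partition of [0, 1].  Group 1 is the best prognosis."""
    cp = np.asarray(cutpoints, dtype=float)
    if np.any(np.diff(cp) >= 0) or np.any(cp <= 0) or np.any(cp >= 1):
        raise ValueError("cutpoints must be strictly decreasing inside (0, 1)")
    S = np.asarray(S, dtype=float)
    if np.any((S < 0) | (S > 1)):
        raise ValueError("survival probabilities must lie in [0, 1]")
    return 1 + (S[:, None] < cp[None, :]).sum(axis=1)


@dataclass
class EvaluationReport:
    """Aggregated evaluation of one model on one cohort split."""

    c_index: float
    aucs: list  # per window; None where degenerate
    auc_mean: float
    auc_sd: float
    calibration: list  # CalibrationBin dicts
    calibration_horizon: float
    subgroups: dict  # group id -> {n, km_times, km_survival}
    logrank_neighbors: list  # {pair, statistic, p}
    stratification_horizon: float
    seed: int | None = None
    config_hash: str | None = None
    extras: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "EvaluationReport":
        return cls(**json.loads(text))


def evaluate_report(
    S: np.ndarray,
    status: np.ndarray,
    risk: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    boundaries: np.ndarray,
    n_calibration_bins: int = 7,
    calibration_horizon: float = 60.0,
    cutpoints: tuple[float, ...] = DEFAULT_CUTPOINTS,
    seed: int | None = None,
    config_hash: str | None = None,
) -> EvaluationReport:
    """Assemble the full protocol into one serializable report.

    ``S`` is the (n, W) predicted survival matrix, ``status`` the (n, W)
    window status codes, ``risk`` the final-window risk score used for the
    c-index, and ``boundaries`` the window end times in months.
    """
    boundaries = np.asarray(boundaries, dtype=float)
    c = concordance_index(risk, time, event)
    aucs, auc_mean, auc_sd = window_roc_auc(S, status)

    cal_idx = int(np.searchsorted(boundaries, calibration_horizon, side="right")) - 1
    cal_idx = max(cal_idx, 0)
    cal = calibration_bins(
        S[:, cal_idx], time, event, n_bins=n_calibration_bins, horizon=calibration_horizon
    )

    strat_horizon = float(boundaries[-1])
    groups = stratify_by_probability(S[:, -1], cutpoints)
    subgroups = {}
    for g in range(1, len(cutpoints) + 2):
        members = groups == g
        if members.sum() == 0:
            subgroups[str(g)] = {"n": 0, "km_times": [], "km_survival": []}
            continue
        km = km_estimate(time[members], event[members])
        subgroups[str(g)] = {
            "n": int(members.sum()),
            "km_times": list(km.times),
            "km_survival": list(km.survival),
        }
    logrank = []
    present = [g for g in range(1, len(cutpoints) + 2) if (groups == g).sum() > 0]
    for a, b in zip(present[:-1], present[1:]):
        ma, mb = groups == a, groups == b
        if event[ma].sum() + event[mb].sum() == 0:
            continue
        stat, p = log_rank_test(time[ma], event[ma], time[mb], event[mb])
        logrank.append({"pair": [a, b], "statistic": stat, "p": p})

    return EvaluationReport(
        c_index=c,
        aucs=[None if np.isnan(a) else float(a) for a in aucs],
        auc_mean=auc_mean,
        auc_sd=auc_sd,
        calibration=[asdict(b) for b in cal],
        calibration_horizon=float(calibration_horizon),
        subgroups=subgroups,
        logrank_neighbors=logrank,
        stratification_horizon=strat_horizon,
        seed=seed,
        config_hash=config_hash,
    )
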