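"""Kaplan-Meier / log-rank screening and k-means risk stratification.

The product-limit estimator and the two-group log-rank statistic are
implemented directly (they are the quantities under test and are
cross-checked against lifelines in the test suite); k-means comes from
scikit-learn with a fixed seeded protocol.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .errors import (
    DegenerateClusteringError,
    InsufficientCohortError,
    InvalidArgumentError,
    InvalidGroupingError,
)


class KMCurve:
    """Product-limit survival estimate: a right-continuous step function."""

    def __init__(self, times: np.ndarray, survival: np.ndarray):
        self.times = times
        self.survival = survival

    def __call__(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        if len(self.times) == 0:  # no events observed
            out = np.ones_like(t)
        else:
            idx = np.searchsorted(self.times, t, side="right") - 1
            out = np.where(idx < 0, 1.0, self.survival[np.maximum(idx, 0)])
        return float(out) if out.ndim == 0 else out

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival})


def _check_records(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    time = records["time_days"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=int)
    if len(time) == 0:
        raise InvalidArgumentError("no survival records")
    if np.any(time <= 0):
        raise InvalidArgumentError("survival times must be > 0")
    if not np.isin(event, [0, 1]).all():
        raise InvalidArgumentError("event must be 0/1")
    return time, event


def km_curve(records: pd.DataFrame) -> KMCurve:
    """Kaplan-Meier estimate from (time_days, event) records."""
    time, event = _check_records(records)
    order = np.argsort(time, kind="mergesort")
    time, event = time[order], event[order]
    event_times = np.unique(time[event == 1])
    n = len(time)
    surv = []
    s = 1.0
    for t in event_times:
        at_risk = np.sum(time >= t)
        deaths = np.sum((time == t) & (event == 1))
        s *= 1.0 - deaths / at_risk
        surv.append(s)
    return KMCurve(event_times, np.asarray(surv))


def logrank_test(groups: pd.Series | np.ndarray, records: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test: (chi2, p) with 1 df.

    ``groups`` holds two labels aligned with ``records`` rows. At each
    distinct event time the observed-minus-expected events in group 1 are
    accumulated with the hypergeometric variance.
    """
    time, event = _check_records(records)
    g = np.asarray(groups)
    if len(g) != len(time):
        raise InvalidArgumentError("groups and records must align")
    labels = np.unique(g)
    if len(labels) != 2:
        raise InvalidGroupingError(f"need exactly 2 non-empty groups, got {len(labels)}")
    if event.sum() == 0:
        raise InvalidGroupingError("no events observed")
    in1 = g == labels[0]
    event_times = np.unique(time[event == 1])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = time >= t
        n_j = at_risk.sum()
        n1_j = (at_risk & in1).sum()
        d_j = ((time == t) & (event == 1)).sum()
        d1_j = ((time == t) & (event == 1) & in1).sum()
        e1_j = d_j * n1_j / n_j
        o_minus_e += d1_j - e1_j
        if n_j > 1:
            var += d_j * (n1_j / n_j) * (1 - n1_j / n_j) * (n_j - d_j) / (n_j - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e ** 2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def median_split(feature: np.ndarray | pd.Series) -> np.ndarray:
    """'high' for values strictly above the median, 'low' otherwise."""
    v = np.asarray(feature, dtype=float)
    if len(v) < 2:
        raise InvalidArgumentError("need >= 2 values")
    if np.unique(v).size < 2:
        raise InvalidArgumentError("constant feature cannot be split")
    med = np.median(v)
    return np.where(v > med, "high", "low")


def univariate_screen(features: pd.DataFrame, records: pd.DataFrame,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Median-split log-rank p per feature row, aligned on shared samples."""
    shared = sorted(set(features.columns) & set(records["sample_id"]))
    if len(shared) < 2:
        raise InsufficientCohortError(f"only {len(shared)} shared samples")
    recs = records.set_index("sample_id").loc[shared].reset_index()
    rows = []
    for feature_id, values in features[shared].iterrows():
        v = values.to_numpy(dtype=float)
        if np.unique(v).size < 2:
            rows.append((feature_id, np.nan, False))
            continue
        groups = median_split(v)
        if len(np.unique(groups)) < 2:
            rows.append((feature_id, np.nan, False))
            continue
        _, p = logrank_test(groups, recs)
        rows.append((feature_id, p, p < alpha))
    return pd.DataFrame(rows, columns=["feature", "p_value", "significant"])


def _cumulative_hazard_at(time: np.ndarray, event: np.ndarray, t_eval: float) -> float:
    """Nelson-Aalen cumulative hazard at t_eval."""
    ch = 0.0
    for t in np.unique(time[event == 1]):
        if t > t_eval:
            break
        at_risk = np.sum(time >= t)
        deaths = np.sum((time == t) & (event == 1))
        ch += deaths / at_risk
    return ch


def multivariate_stratify(sig_features: pd.DataFrame, records: pd.DataFrame,
                          seed: int = 0, n_restarts: int = 10,
                          zscore: bool = True) -> tuple[pd.Series, float]:
    """k-means (k=2) risk grouping of samples from significant features.

    Features are z-scored per feature, clustered with k-means++ seeded
    initialization and ``n_restarts`` restarts; the cluster with the higher
    Nelson-Aalen cumulative hazard at the median follow-up time is labeled
    high_risk. Returns (sample -> {low_risk, high_risk}, log-rank p).
    """
    if len(sig_features) < 1:
        raise InvalidArgumentError("need >= 1 significant feature")
    shared = sorted(set(sig_features.columns) & set(records["sample_id"]))
    if len(shared) < 4:
        raise InsufficientCohortError(f"only {len(shared)} shared samples (need >= 4)")
    recs = records.set_index("sample_id").loc[shared].reset_index()
    X = sig_features[shared].to_numpy(dtype=float).T  # samples x features
    if zscore:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    km = KMeans(n_clusters=2, n_init=n_restarts, random_state=seed).fit(X)
    labels = km.labels_
    if len(np.unique(labels)) < 2:
        raise DegenerateClusteringError("k-means produced an empty cluster")

    time = recs["time_days"].to_numpy(dtype=float)
    event = recs["event"].to_numpy(dtype=int)
    t_med = float(np.median(time))
    hazards = []
    for c in (0, 1):
        sel = labels == c
        ch = _cumulative_hazard_at(time[sel], event[sel], t_med)
        hazards.append((ch, event[sel].mean()))
    # higher cumulative hazard (event rate as tie-break) = high risk
    if hazards[0][0] != hazards[1][0]:
        high = int(np.argmax([h for h, _ in hazards]))
    else:
        high = int(np.argmax([r for _, r in hazards]))
    grouping = pd.Series(np.where(labels == high, "high_risk", "low_risk"),
                         index=shared, name="risk_group")
    _, p = logrank_test(grouping.to_numpy(), recs)
    return grouping, p
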