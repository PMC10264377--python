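"""Evaluation statistics implemented from first principles.

AUC with DeLong structural-component confidence intervals, Pearson
correlation with the t-transform p-value, the Kaplan–Meier product-limit
estimator, the two-group log-rank test and Harrell's concordance index.

Tie conventions, stated once:

* AUC — tied score pairs count 1/2 (Mann–Whitney convention).
* Log-rank — subjects with identical event times are handled through the
  common risk set at that time (hypergeometric variance with the tie
  correction).
* Harrell's C — pairs are admissible when the shorter time carries an event
  and the times differ; tied risk scores in an admissible pair count 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .exceptions import DegenerateDataError


@dataclass(frozen=True)
class AUCResult:
    auc: float
    ci_low: float
    ci_high: float
    se: float
    alpha: float = 0.05


@dataclass
class SurvivalSample:
    """One subject: follow-up time, event indicator (1 = observed), label."""

    time: float
    event: int
    group: Optional[str] = None
    risk: Optional[float] = None


def _split_scores(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise DegenerateDataError("AUC requires both classes present")
    return pos, neg


def auc_delong(scores, labels, alpha: float = 0.05) -> AUCResult:
    """AUC (Mann–Whitney with half-credit ties) and DeLong normal CI.

    The variance uses DeLong's structural components: for each positive the
    mean placement against all negatives and vice versa; the CI is clipped
    to [0, 1].
    """
    pos, neg = _split_scores(scores, labels)
    m, n = len(pos), len(neg)
    # placement matrix: psi(x, y) = 1 if x > y, 0.5 if equal, 0 otherwise
    diff = pos[:, None] - neg[None, :]
    psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
    auc = float(psi.mean())
    v10 = psi.mean(axis=1)          # structural components of positives
    v01 = psi.mean(axis=0)          # ... of negatives
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    se = float(np.sqrt(var))
    z = sps.norm.ppf(1 - alpha / 2)
    lo = float(np.clip(auc - z * se, 0.0, 1.0))
    hi = float(np.clip(auc + z * se, 0.0, 1.0))
    return AUCResult(auc=auc, ci_low=lo, ci_high=hi, se=se, alpha=alpha)


def pearson_r(x, y) -> Tuple[float, float]:
    """Product-moment correlation and its two-sided t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("pearson_r needs two equal-length vectors, n >= 3")
    xd, yd = x - x.mean(), y - y.mean()
    sx, sy = np.sqrt((xd ** 2).sum()), np.sqrt((yd ** 2).sum())
    if sx == 0 or sy == 0:
        raise DegenerateDataError("zero variance in pearson_r input")
    r = float(np.clip((xd * yd).sum() / (sx * sy), -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2 * sps.t.sf(abs(t), df=n - 2))
    return r, p


def _unpack_surv(samples) -> Tuple[np.ndarray, np.ndarray]:
    if isinstance(samples, tuple) and len(samples) == 2:
        t, e = samples
    elif len(samples) and isinstance(samples[0], SurvivalSample):
        t = [s.time for s in samples]
        e = [s.event for s in samples]
    else:
        arr = np.asarray(samples, dtype=float)
        t, e = arr[:, 0], arr[:, 1]
    t = np.asarray(t, dtype=float)
    e = np.asarray(e).astype(int)
    if np.any(t <= 0):
        raise ValueError("survival times must be positive")
    return t, e


@dataclass
class KMCurve:
    """Kaplan–Meier product-limit estimate: right-continuous step function."""

    times: np.ndarray          # distinct event times, ascending
    survival: np.ndarray       # S(t) just after each event time
    median: Optional[float]    # earliest time with S <= 0.5, None if not reached

    def at(self, t: float) -> float:
        """S(t); 1 before the first event."""
        i = np.searchsorted(self.times, t, side="right")
        return 1.0 if i == 0 else float(self.survival[i - 1])


def km_curve(samples) -> KMCurve:
    """Product-limit estimator over (time, event) samples."""
    t, e = _unpack_surv(samples)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    n = len(t)
    s = 1.0
    times, surv = [], []
    at_risk = n
    i = 0
    while i < n:
        ti = t[i]
        d = 0
        removed = 0
        while i < n and t[i] == ti:
            d += e[i]
            removed += 1
            i += 1
        if d > 0:
            s *= 1.0 - d / at_risk
            times.append(ti)
            surv.append(s)
        at_risk -= removed
    surv = np.asarray(surv)
    times = np.asarray(times)
    below = np.flatnonzero(surv <= 0.5)
    median = float(times[below[0]]) if below.size else None
    return KMCurve(times=times, survival=surv, median=median)


def logrank_test(group_a, group_b) -> Tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic, two-sided p), 1 df.

    Observed-minus-expected events in group A accumulated over the pooled
    distinct event times, with the hypergeometric variance at each time.
    """
    ta, ea = _unpack_surv(group_a)
    tb, eb = _unpack_surv(group_b)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise DegenerateDataError("no events in either group")
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    g = np.concatenate([np.zeros(len(ta), int), np.ones(len(tb), int)])
    event_times = np.unique(t[e == 1])
    O_minus_E = 0.0
    V = 0.0
    for ti in event_times:
        at_risk = t >= ti
        n_i = at_risk.sum()
        n_a = (at_risk & (g == 0)).sum()
        died = (t == ti) & (e == 1)
        d_i = died.sum()
        d_a = (died & (g == 0)).sum()
        O_minus_E += d_a - d_i * n_a / n_i
        if n_i > 1:
            V += (d_i * (n_a / n_i) * (1 - n_a / n_i)
                  * (n_i - d_i) / (n_i - 1))
    if V == 0:
        return 0.0, 1.0
    chi2 = float(O_minus_E ** 2 / V)
    p = float(sps.chi2.sf(chi2, df=1))
    return chi2, p


def concordance_index(risk, samples) -> float:
    """Harrell's C by exhaustive pair enumeration.

    Fraction of admissible pairs in which the subject with the higher risk
    score fails first; tied risks count 1/2.  A pair (i, j) is admissible
    when t_i < t_j and subject i had an event.
    """
    risk = np.asarray(risk, dtype=float)
    t, e = _unpack_surv(samples)
    n = len(t)
    num = 0.0
    den = 0
    for i in range(n):
        if e[i] != 1:
            continue
        for j in range(n):
            if t[i] < t[j]:
                den += 1
                if risk[i] > risk[j]:
                    num += 1.0
                elif risk[i] == risk[j]:
                    num += 0.5
    if den == 0:
        raise DegenerateDataError("no admissible pairs for concordance")
    return float(num / den)
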