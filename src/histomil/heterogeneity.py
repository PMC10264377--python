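"""Intratumor-heterogeneity statistics and subtype calling.

Per patient, the 99th percentiles of the tile-level basal-like and classical
component scores (pooled over all of the patient's slides) summarize the most
differentiated tumor contingents.  Their absolute difference ``delta``
separates clearly differentiated tumors from unclear ones via a 1-D
two-component Gaussian mixture; among unclear tumors, a cutoff on
``max_level = max(p99_bas, p99_cla)`` distinguishes *hybrid* tumors (both
phenotypes clearly present) from *intermediary* ones (neither reached).

Also here: the clear-RNA-subtype rule (cohort-median filter on the scaled
basal/classical difference), the pure-vs-mixed macro call for RNA-classical
patients, basal-fraction binning, and the tile-subsampling robustness
experiment that mimics tumor-poor biopsies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError
from .stats import auc_delong

SUBTYPES = ("main_classical", "main_basal", "hybrid", "intermediary")


# --------------------------------------------------------------------------
# 1-D Gaussian mixture via EM
# --------------------------------------------------------------------------

@dataclass
class GMM1DFit:
    """Two-component (generally k-component) 1-D Gaussian mixture fit.

    Components are canonically ordered by decreasing mean: component 0 is
    the high-mean component.
    """

    k: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    loglik: float
    responsibilities: np.ndarray
    loglik_trace: List[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False

    def posterior(self, x) -> np.ndarray:
        """Responsibilities of each component at new points x: (n, k)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        log_p = (np.log(self.weights)[None, :]
                 - 0.5 * np.log(2 * np.pi * self.variances)[None, :]
                 - 0.5 * (x[:, None] - self.means[None, :]) ** 2
                 / self.variances[None, :])
        log_p -= log_p.max(axis=1, keepdims=True)
        p = np.exp(log_p)
        return p / p.sum(axis=1, keepdims=True)


def fit_gmm_1d(x, k: int = 2, tol: float = 1e-6, max_iter: int = 500,
               seed: int = 0) -> GMM1DFit:
    """EM fit of a k-component 1-D Gaussian mixture.

    Initialization is quantile-based (component means at the (i+0.5)/k
    quantiles, equal weights, pooled variance), hence deterministic; the
    seed is accepted for interface uniformity.  Variances are floored at
    ``1e-8 * var(x)``.  Stops when the log-likelihood improves by less than
    ``tol``.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = len(x)
    if n < 2 * k:
        raise ValueError(f"need at least {2 * k} points for k={k}")
    if x.max() == x.min():
        raise DegenerateDataError("all values identical; mixture undefined")
    vx = float(np.var(x))
    floor = 1e-8 * vx
    means = np.quantile(x, [(i + 0.5) / k for i in range(k)])
    variances = np.full(k, vx)
    weights = np.full(k, 1.0 / k)

    trace: List[float] = []
    prev = -np.inf
    converged = False
    for it in range(1, max_iter + 1):
        # E-step
        log_comp = (np.log(weights)[None, :]
                    - 0.5 * np.log(2 * np.pi * variances)[None, :]
                    - 0.5 * (x[:, None] - means[None, :]) ** 2
                    / variances[None, :])
        m = log_comp.max(axis=1, keepdims=True)
        lse = m.ravel() + np.log(np.exp(log_comp - m).sum(axis=1))
        ll = float(lse.sum())
        trace.append(ll)
        resp = np.exp(log_comp - lse[:, None])
        if ll - prev < tol and it > 1:
            converged = True
            break
        prev = ll
        # M-step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        variances = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        variances = np.maximum(variances, floor)

    order = np.argsort(-means)       # high-mean component first
    fit = GMM1DFit(k=k, weights=weights[order], means=means[order],
                   variances=variances[order], loglik=trace[-1],
                   responsibilities=resp[:, order], loglik_trace=trace,
                   n_iter=len(trace), converged=converged)
    return fit


# --------------------------------------------------------------------------
# percentile scores and subtype calling
# --------------------------------------------------------------------------

def percentile_scores(basal_scores, classical_scores,
                      q: float = 0.99) -> Tuple[float, float]:
    """qth percentile (linear interpolation between order statistics) of a
    patient's tile-level basal and classical scores pooled over slides."""
    b = np.asarray(basal_scores, dtype=float).ravel()
    c = np.asarray(classical_scores, dtype=float).ravel()
    if b.size == 0 or c.size == 0:
        raise ValueError("empty tile scores")
    return float(np.quantile(b, q)), float(np.quantile(c, q))


@dataclass
class HeterogeneityCall:
    """Final per-patient heterogeneity call."""

    patient_id: str
    p99_bas: float
    p99_cla: float
    delta: float
    max_level: float
    clear: bool
    subtype: str


@dataclass
class HeterogeneityResults:
    """Cohort-level subtype calls plus the fitted mixture machinery."""

    calls: List[HeterogeneityCall]
    gmm_delta: GMM1DFit
    gmm_max: Optional[GMM1DFit]
    cutoff: float

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame([vars(c) for c in self.calls])

    def counts(self) -> pd.Series:
        return self.table["subtype"].value_counts().reindex(SUBTYPES, fill_value=0)

    def summary(self) -> str:
        cts = self.counts()
        n = len(self.calls)
        lines = ["Heterogeneity subtype calls",
                 f"  patients:          {n}",
                 f"  delta GMM means:   {self.gmm_delta.means.round(4).tolist()}",
                 f"  max-level cutoff:  {self.cutoff:.4f}"]
        for s in SUBTYPES:
            lines.append(f"  {s:<16} {cts[s]:>4}  ({100 * cts[s] / n:.1f}%)")
        return "\n".join(lines)


def call_subtypes(patient_ids: Sequence[str], p99_bas, p99_cla,
                  cutoff: Optional[float] = None,
                  seed: int = 0) -> HeterogeneityResults:
    """Four-way heterogeneity subtype call for a cohort.

    Step 1: a 2-component GMM on ``delta = |p99_bas - p99_cla|`` splits
    clearly differentiated patients (high-mean component, by maximum
    responsibility) from unclear ones; clear patients are main_basal when
    p99_bas > p99_cla, else main_classical (ties break to classical).

    Step 2: unclear patients split on ``max_level``: at or above the cutoff
    both phenotypes are clearly present somewhere in the tumor (*hybrid*),
    below it neither is reached (*intermediary*).  Unless overridden, the
    cutoff is the smallest point where the high-mean component of a GMM on
    max_level takes posterior responsibility >= 0.5.
    """
    p99_bas = np.asarray(p99_bas, dtype=float).ravel()
    p99_cla = np.asarray(p99_cla, dtype=float).ravel()
    ids = list(patient_ids)
    n = len(ids)
    if not (len(p99_bas) == len(p99_cla) == n):
        raise ValueError("patient_ids, p99_bas, p99_cla must align")
    if n < 8:
        raise ValueError("cohort too small for subtype calling (need >= 8)")
    delta = np.abs(p99_bas - p99_cla)
    max_level = np.maximum(p99_bas, p99_cla)

    gmm_delta = fit_gmm_1d(delta, k=2, seed=seed)
    clear = gmm_delta.responsibilities[:, 0] >= 0.5   # high-mean component

    gmm_max = None
    if cutoff is None:
        gmm_max = fit_gmm_1d(max_level, k=2, seed=seed)
        grid = np.linspace(max_level.min(), max_level.max(), 4097)
        post_hi = gmm_max.posterior(grid)[:, 0]
        above = np.flatnonzero(post_hi >= 0.5)
        cutoff = float(grid[above[0]]) if above.size else float(np.inf)

    calls = []
    for i, pid in enumerate(ids):
        if clear[i]:
            subtype = "main_basal" if p99_bas[i] > p99_cla[i] else "main_classical"
        else:
            subtype = "hybrid" if max_level[i] >= cutoff else "intermediary"
        calls.append(HeterogeneityCall(
            patient_id=pid, p99_bas=float(p99_bas[i]), p99_cla=float(p99_cla[i]),
            delta=float(delta[i]), max_level=float(max_level[i]),
            clear=bool(clear[i]), subtype=subtype))
    return HeterogeneityResults(calls=calls, gmm_delta=gmm_delta,
                                gmm_max=gmm_max, cutoff=cutoff)


# --------------------------------------------------------------------------
# bulk-RNA clarity, macro calls, basal-fraction bins
# --------------------------------------------------------------------------

def clear_rna_subtype(basal, classical) -> np.ndarray:
    """Boolean per sample: clear RNA subtype by the cohort-median rule.

    Each component is z-scored across the cohort; a sample is *clear* when
    the absolute difference of its scaled components is strictly above the
    cohort median of those differences (so at most half the cohort is clear).
    """
    b = np.asarray(basal, dtype=float)
    c = np.asarray(classical, dtype=float)
    if len(b) < 2 or len(b) != len(c):
        raise ValueError("need two aligned vectors with n >= 2")
    for name, v in (("basal", b), ("classical", c)):
        if np.std(v) == 0:
            raise DegenerateDataError(f"zero variance in component {name!r}")
    zb = (b - b.mean()) / b.std()
    zc = (c - c.mean()) / c.std()
    d = np.abs(zb - zc)
    return d > np.median(d)


def macro_classical_call(slide_scores, threshold: float = 0.2) -> str:
    """Pure vs mixed call for an RNA-classical patient.

    ``pure`` iff every slide's basal-ness score is strictly below the
    threshold; a single slide at or above it makes the tumor ``mixed``.
    """
    s = np.asarray(slide_scores, dtype=float).ravel()
    if s.size == 0:
        raise ValueError("need at least one slide score")
    return "pure" if np.all(s < threshold) else "mixed"


BASAL_BINS = ("lt5", "5to20", "gt20")


def basal_fraction(tile_basal_scores, tile_threshold: float = 0.5,
                   tile_classical_scores=None) -> Tuple[float, str]:
    """Share of a patient's tumor tiles identified as basal-like, binned.

    A tile counts as basal-like when its (cohort-scaled) basal score exceeds
    ``tile_threshold`` and — when classical scores are supplied — its basal
    score also exceeds its classical score.  Bins are left-closed,
    right-open in percent: [0,5), [5,20), [20,100].
    """
    b = np.asarray(tile_basal_scores, dtype=float).ravel()
    if b.size == 0:
        raise ValueError("empty tile scores")
    is_basal = b > tile_threshold
    if tile_classical_scores is not None:
        c = np.asarray(tile_classical_scores, dtype=float).ravel()
        is_basal &= b > c
    frac = float(is_basal.mean())
    if frac < 0.05:
        b_ = "lt5"
    elif frac < 0.20:
        b_ = "5to20"
    else:
        b_ = "gt20"
    return frac, b_


def minmax_scale(values, ref=None) -> np.ndarray:
    """Min–max scale to [0,1] against a reference pool (default: itself)."""
    v = np.asarray(values, dtype=float)
    ref = v if ref is None else np.asarray(ref, dtype=float)
    lo, hi = ref.min(), ref.max()
    if hi == lo:
        raise DegenerateDataError("constant scores; min-max scaling undefined")
    return np.clip((v - lo) / (hi - lo), 0.0, 1.0)


def cohort_basal_fractions(patient_ids: Sequence[str],
                           basal_per_patient: Sequence[np.ndarray],
                           classical_per_patient: Optional[Sequence] = None,
                           tile_threshold: float = 0.5) -> pd.DataFrame:
    """Basal-fraction table for a cohort.

    Tile basal scores are min–max scaled against the pooled tumor tiles of
    the whole cohort before thresholding, so the "identified as basal-like"
    rule is cohort-consistent.
    """
    pool = np.concatenate([np.asarray(b, float).ravel()
                           for b in basal_per_patient])
    rows = []
    for i, pid in enumerate(patient_ids):
        b = minmax_scale(np.asarray(basal_per_patient[i], float).ravel(), pool)
        c = None
        if classical_per_patient is not None:
            c = np.asarray(classical_per_patient[i], float).ravel()
            c = minmax_scale(c, np.concatenate(
                [np.asarray(x, float).ravel() for x in classical_per_patient]))
        frac, bin_ = basal_fraction(b, tile_threshold, c)
        rows.append({"patient_id": pid, "basal_fraction": frac, "bin": bin_})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# tile-subsampling robustness (tumor-poor biopsy emulation)
# --------------------------------------------------------------------------

def subsample_robustness(results, bags, labels,
                         fractions: Sequence[float] = (0.75, 0.5, 0.25),
                         n_reps: int = 20, seed: int = 0,
                         ci: float = 0.95) -> pd.DataFrame:
    """Slide-classification AUC under per-slide tile subsampling.

    For each fraction, tiles are subsampled uniformly without replacement per
    slide (minimum one tile), the fitted classifier re-scores the reduced
    bags and the AUC against the labels is recorded; the table reports the
    mean and a percentile interval over ``n_reps`` repeats, plus the
    full-tile AUC as fraction 1.0.
    """
    from .slide_models import _as_array
    bags = [_as_array(b) for b in bags]
    labels = np.asarray(labels).astype(int)
    full_scores = np.array([results.predict(b)[0] for b in bags])
    full_auc = auc_delong(full_scores, labels).auc
    rows = [{"fraction": 1.0, "auc_mean": full_auc,
             "auc_low": full_auc, "auc_high": full_auc, "n_reps": 1}]
    rng = np.random.default_rng(seed)
    a = (1 - ci) / 2
    for frac in fractions:
        aucs = []
        for _ in range(n_reps):
            scores = np.empty(len(bags))
            for j, X in enumerate(bags):
                m = max(1, int(round(frac * X.shape[0])))
                idx = rng.choice(X.shape[0], size=m, replace=False)
                scores[j] = results.predict(X[np.sort(idx)])[0]
            aucs.append(auc_delong(scores, labels).auc)
        aucs = np.asarray(aucs)
        rows.append({"fraction": float(frac), "auc_mean": float(aucs.mean()),
                     "auc_low": float(np.quantile(aucs, a)),
                     "auc_high": float(np.quantile(aucs, 1 - a)),
                     "n_reps": n_reps})
    return pd.DataFrame(rows)
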