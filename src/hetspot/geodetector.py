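"""Geographical detector: spatial stratified heterogeneity statistics.

The q-statistic asks how much of the spatial variance of an outcome Y
(here village GI incidence) is explained by stratifying the villages on a
candidate factor X:

    q = 1 − SSW / SST,   SSW = Σ_i N_i σ_i²,   SST = N σ²,

with population (1/N) variances so SSW and SST are literal sums of squares.
q = 0 when the strata explain nothing, q = 1 when Y is constant within each
stratum.  The interaction detector overlays two stratifications and
classifies the joint explanatory power q12 against q1 and q2 (nonlinear
enhancement when q12 exceeds q1 + q2, etc.).

Significance is assessed by a permutation test (shuffling stratum labels),
which is exact at these sample sizes and assumption-free; this is stated in
the result metadata because the classical alternative is a noncentral-F
approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Stratification",
    "QResult",
    "stratify",
    "q_statistic",
    "interaction_q",
    "INTERACTION_CLASSES",
]

INTERACTION_CLASSES = (
    "nonlinear-enhance",
    "bi-enhance",
    "independent",
    "uni-weaken",
    "nonlinear-weaken",
)

_CLASS_TOL = 1e-9


@dataclass
class Stratification:
    """Stratum label per village for one factor."""

    labels: pd.Series  # village_id -> stratum label
    method: str
    n_classes: int

    @property
    def m(self) -> int:
        return self.labels.nunique()


def stratify(values_per_village, method: str = "quantile", n_classes: int = 5) -> Stratification:
    """Discretize a continuous factor into strata.

    ``quantile`` uses equal-count classes, ``equal-interval`` equal-width
    classes.  Assignment is deterministic: quantile ties are broken by value
    order then village ID.  A constant factor collapses to one stratum with
    a warning.
    """
    vals = pd.Series(values_per_village, dtype=float)
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if vals.isna().any():
        raise ValueError("factor values contain NaN")
    if vals.nunique() == 1:
        warnings.warn("constant factor collapses to a single stratum", stacklevel=2)
        return Stratification(pd.Series(0, index=vals.index), method, n_classes)
    if method == "quantile":
        # rank by (value, village id) for deterministic ties
        srt = sorted(vals.index, key=lambda i: (vals[i], str(i)))
        ranks = pd.Series({vid: r for r, vid in enumerate(srt)})
        labels = (ranks * n_classes // len(vals)).astype(int)
        labels = labels.reindex(vals.index)
    elif method == "equal-interval":
        lo, hi = vals.min(), vals.max()
        width = (hi - lo) / n_classes
        labels = np.minimum(((vals - lo) / width).astype(int), n_classes - 1)
        labels = pd.Series(labels, index=vals.index)
    else:
        raise ValueError(f"unknown stratification method {method!r}")
    counts = labels.value_counts()
    if (counts == 0).any():
        labels = labels.map({v: i for i, v in enumerate(sorted(labels.unique()))})
    return Stratification(labels, method, n_classes)


@dataclass
class QResult:
    q: float
    ssw: float
    sst: float
    p_value: float
    strata_stats: pd.DataFrame
    interaction_class: str | None = None


def _q_from_labels(y: np.ndarray, labels: np.ndarray) -> tuple[float, float, float, pd.DataFrame]:
    n = len(y)
    sst = n * y.var()  # population variance -> literal sum of squares
    rows = []
    ssw = 0.0
    for lab in pd.unique(labels):
        sub = y[labels == lab]
        ssw += len(sub) * sub.var()
        rows.append({"stratum": lab, "N": len(sub), "mean": sub.mean(), "var": sub.var()})
    stats = pd.DataFrame(rows).set_index("stratum")
    return 1.0 - ssw / sst, ssw, sst, stats


def q_statistic(
    y_per_village,
    stratification: Stratification,
    n_permutations: int = 999,
    rng: np.random.Generator | None = None,
) -> QResult:
    """q = 1 − SSW/SST with a permutation p-value.

    Raises on constant Y (SST = 0 makes q undefined).  Empty strata are
    impossible by construction; strata of size 1 contribute zero to SSW.
    """
    y = pd.Series(y_per_village, dtype=float)
    labels = stratification.labels.reindex(y.index)
    if labels.isna().any():
        raise ValueError("stratification missing some villages")
    if len(y) < 2:
        raise ValueError("need at least two villages")
    yv = y.to_numpy()
    lv = labels.to_numpy()
    if np.var(yv) == 0:
        raise ValueError("constant outcome: SST = 0, q undefined")
    q, ssw, sst, stats = _q_from_labels(yv, lv)
    if rng is None:
        rng = np.random.default_rng(0)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(lv)
        qp, _, _, _ = _q_from_labels(yv, perm)
        if qp >= q:
            exceed += 1
    p = (exceed + 1.0) / (n_permutations + 1.0)
    return QResult(q, ssw, sst, p, stats)


def interaction_q(
    y_per_village,
    strat_x1: Stratification,
    strat_x2: Stratification,
    n_permutations: int = 999,
    rng: np.random.Generator | None = None,
) -> QResult:
    """Overlay q of two factors with the enhancement/weakening class.

    The overlay stratification is the Cartesian intersection of the two
    label sets (empty combinations simply do not occur in the data).  The
    class compares q12 with q1 and q2 at a small tolerance:

    * q12 > q1 + q2 → nonlinear-enhance
    * q12 > max(q1, q2) → bi-enhance
    * q12 = q1 + q2 → independent
    * min < q12 < max → uni-weaken
    * q12 < min(q1, q2) → nonlinear-weaken
    """
    y = pd.Series(y_per_village, dtype=float)
    l1 = strat_x1.labels.reindex(y.index)
    l2 = strat_x2.labels.reindex(y.index)
    if l1.isna().any() or l2.isna().any():
        raise ValueError("stratifications missing some villages")
    combo = l1.astype(str) + "|" + l2.astype(str)
    if combo.nunique() < 2:
        raise ValueError("overlay leaves fewer than two non-empty strata")
    if rng is None:
        rng = np.random.default_rng(0)
    overlay = Stratification(combo, "overlay", combo.nunique())
    res12 = q_statistic(y, overlay, n_permutations, rng)
    q1 = _q_from_labels(y.to_numpy(), l1.to_numpy())[0]
    q2 = _q_from_labels(y.to_numpy(), l2.to_numpy())[0]
    q12 = res12.q
    tol = _CLASS_TOL
    if q12 > q1 + q2 + tol:
        cls = "nonlinear-enhance"
    elif abs(q12 - (q1 + q2)) <= tol:
        cls = "independent"
    elif q12 > max(q1, q2) - tol:
        cls = "bi-enhance"
    elif q12 < min(q1, q2) - tol:
        cls = "nonlinear-weaken"
    else:
        cls = "uni-weaken"
    res12.interaction_class = cls
    return res12


def factor_table(
    y_per_village,
    factors: pd.DataFrame,
    method: str = "quantile",
    n_classes: int = 5,
    n_permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """q and permutation p per factor column; mirrors a factor-detector table."""
    rows = []
    for k, col in enumerate(factors.columns):
        strat = stratify(factors[col], method, n_classes)
        res = q_statistic(
            y_per_village, strat, n_permutations, np.random.default_rng(seed + k)
        )
        rows.append({"factor": col, "q": res.q, "p_value": res.p_value})
    out = pd.DataFrame(rows).set_index("factor")
    out.attrs["inference"] = "permutation test on stratum labels"
    return out
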