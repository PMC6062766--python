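"""Behavioral phase-state scoring and nonparametric group comparisons.

Locust phase state is scored per individual by a fixed binary logistic model
of three arena-assay covariates exported by the video tracker:

    eta    = -2.110 + 0.005 * attraction_index
                    + 0.012 * total_distance
                    + 0.015 * total_duration
    P_greg = exp(eta) / (1 + exp(eta))

``P_greg`` of 1 means fully gregarious behavior, 0 fully solitarious.  The
coefficients come fixed from prior work and presume the original tracker's
units; the model is unit-fragile by construction.

Group comparisons (e.g. dsRNA-injected vs dsGFP control) use the two-sided
Mann-Whitney U test: exact p by full enumeration of the null distribution
for small tie-free samples, otherwise a normal approximation with tie and
continuity corrections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm, rankdata

__all__ = [
    "PhaseModel",
    "DEFAULT_PHASE_MODEL",
    "BehaviorSummary",
    "PhaseScore",
    "phase_probability",
    "phase_score",
    "score_table",
    "mann_whitney",
    "MannWhitneyResult",
    "exact_u_null_distribution",
    "knockdown_report",
    "COVARIATES",
]

COVARIATES = ("attraction_index", "total_distance", "total_duration")


@dataclass(frozen=True)
class PhaseModel:
    """Fixed logistic coefficients of the behavioral phase-state model."""

    intercept: float = -2.110
    coef_attraction: float = 0.005
    coef_distance: float = 0.012
    coef_duration: float = 0.015

    def eta(self, attraction: float, distance: float, duration: float) -> float:
        return (
            self.intercept
            + self.coef_attraction * attraction
            + self.coef_distance * distance
            + self.coef_duration * duration
        )


DEFAULT_PHASE_MODEL = PhaseModel()


@dataclass(frozen=True)
class BehaviorSummary:
    """One individual's tracked covariates (tracker units)."""

    individual_id: str
    attraction_index: float
    total_distance: float
    total_duration: float
    group: str = ""

    def __post_init__(self) -> None:
        for name in COVARIATES:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{self.individual_id}: non-finite {name}")
        if self.total_distance < 0 or self.total_duration < 0:
            raise ValueError(
                f"{self.individual_id}: distance/duration must be non-negative"
            )


@dataclass(frozen=True)
class PhaseScore:
    individual_id: str
    eta: float
    p_greg: float


def phase_probability(
    attraction: float,
    distance: float,
    duration: float,
    model: PhaseModel = DEFAULT_PHASE_MODEL,
) -> float:
    """P_greg for raw covariate values (the model is defined on all reals).

    Overflow-safe for arbitrarily large |eta| (saturates to exactly 0 or 1).
    """
    return float(expit(model.eta(attraction, distance, duration)))


def phase_score(
    summary: BehaviorSummary, model: PhaseModel = DEFAULT_PHASE_MODEL
) -> PhaseScore:
    """Logistic phase-state probability for one tracked individual."""
    eta = model.eta(
        summary.attraction_index, summary.total_distance, summary.total_duration
    )
    return PhaseScore(summary.individual_id, eta, float(expit(eta)))


def score_table(
    individuals: Sequence[BehaviorSummary],
    model: PhaseModel = DEFAULT_PHASE_MODEL,
) -> pd.DataFrame:
    """Per-individual scores with group labels, one row per individual."""
    rows = []
    for b in individuals:
        s = phase_score(b, model)
        rows.append(
            {
                "individual_id": b.individual_id,
                "group": b.group,
                "attraction_index": b.attraction_index,
                "total_distance": b.total_distance,
                "total_duration": b.total_duration,
                "eta": s.eta,
                "p_greg": s.p_greg,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MannWhitneyResult:
    n_x: int
    n_y: int
    u_x: float  # U statistic of the first sample
    u_y: float
    p_value: float
    method: str  # 'exact' or 'normal-approx'
    median_x: float
    median_y: float


def exact_u_null_distribution(n: int, m: int) -> np.ndarray:
    """Exact tie-free null distribution of U: P(U = u) for u = 0..n*m.

    Dynamic-programming count of the number of rank arrangements giving each
    U value, normalised by C(n+m, n).  Symmetric about n*m/2.
    """
    if n < 1 or m < 1:
        raise ValueError("both sample sizes must be >= 1")
    # U values are in bijection with partitions fitting an n x m box, so the
    # count polynomial is the Gaussian binomial [n+m choose n]_q, built as
    # the product over k=1..n of (1 - q^(m+k)) / (1 - q^k).
    size = n * m + 1
    counts = np.zeros(size, dtype=float)
    counts[0] = 1.0
    for k in range(1, n + 1):
        new = counts.copy()
        if m + k < size:
            new[m + k:] -= counts[: size - (m + k)]
        for u in range(k, size):  # divide by (1 - q^k)
            new[u] += new[u - k]
        counts = new
    total = counts.sum()
    return counts / total


def _exact_two_sided_p(u: float, n: int, m: int) -> float:
    dist = exact_u_null_distribution(n, m)
    center = n * m / 2.0
    dev = abs(u - center)
    us = np.arange(n * m + 1)
    return float(dist[np.abs(us - center) >= dev - 1e-12].sum())


def mann_whitney(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    U is computed from rank sums with midranks for ties.  ``mode='auto'``
    uses the exact null by full enumeration when max(n, m) <= 10 and the
    pooled data are tie-free, otherwise a normal approximation with tie and
    continuity corrections.  ``mode='exact'`` forces enumeration (error on
    ties); ``mode='normal-approx'`` forces the approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("samples must be finite")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks
    r_x = ranks[:n].sum()
    u_x = r_x - n * (n + 1) / 2.0
    u_y = n * m - u_x

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if mode == "auto":
        use_exact = max(n, m) <= 10 and not has_ties
    elif mode == "exact":
        if has_ties:
            raise ValueError("exact mode requires tie-free data")
        use_exact = True
    elif mode == "normal-approx":
        use_exact = False
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if use_exact:
        p = _exact_two_sided_p(u_x, n, m)
        method = "exact"
    else:
        mu = n * m / 2.0
        N = n + m
        tie_term = float(((tie_counts**3 - tie_counts).sum()) / (N * (N - 1)))
        sigma2 = n * m / 12.0 * ((N + 1) - tie_term)
        if sigma2 <= 0:
            p = 1.0  # all observations identical
        else:
            # continuity correction toward the mean
            z = (u_x - mu - 0.5 * np.sign(u_x - mu)) / math.sqrt(sigma2)
            p = min(1.0, 2.0 * float(norm.sf(abs(z))))
        method = "normal-approx"
    return MannWhitneyResult(
        n_x=n,
        n_y=m,
        u_x=float(u_x),
        u_y=float(u_y),
        p_value=float(min(p, 1.0)),
        method=method,
        median_x=float(np.median(x)),
        median_y=float(np.median(y)),
    )


# ---------------------------------------------------------------------------
# Knockdown report
# ---------------------------------------------------------------------------


def knockdown_report(
    treated: Sequence[BehaviorSummary],
    control: Sequence[BehaviorSummary],
    model: PhaseModel = DEFAULT_PHASE_MODEL,
    mode: str = "auto",
    ratio: str = "mean",
) -> pd.DataFrame:
    """Treated-vs-control comparison of covariates and phase scores.

    One row per covariate plus one for ``p_greg``: percent-of-control
    (treated/control ratio of means by default, medians behind the flag),
    group medians and the two-sided Mann-Whitney test.  A zero control mean
    leaves the percent undefined (NaN) with ``percent_flag`` set.
    """
    if not treated or not control:
        raise ValueError("both groups must be non-empty")
    if ratio not in {"mean", "median"}:
        raise ValueError(f"unknown ratio mode {ratio!r}")
    loc = np.mean if ratio == "mean" else np.median
    t_scores = np.array([phase_score(b, model).p_greg for b in treated])
    c_scores = np.array([phase_score(b, model).p_greg for b in control])

    rows = []
    for name in COVARIATES:
        t_vals = np.array([getattr(b, name) for b in treated], dtype=float)
        c_vals = np.array([getattr(b, name) for b in control], dtype=float)
        res = mann_whitney(t_vals, c_vals, mode=mode)
        c_loc = float(loc(c_vals))
        undefined = c_loc == 0.0
        percent = float("nan") if undefined else float(loc(t_vals)) / c_loc * 100.0
        rows.append(
            {
                "measure": name,
                "n_treated": len(treated),
                "n_control": len(control),
                "treated_median": res.median_x,
                "control_median": res.median_y,
                "percent_of_control": percent,
                "percent_flag": "undefined: zero control" if undefined else "",
                "U": res.u_x,
                "p_value": res.p_value,
                "method": res.method,
            }
        )
    res = mann_whitney(t_scores, c_scores, mode=mode)
    rows.append(
        {
            "measure": "p_greg",
            "n_treated": len(treated),
            "n_control": len(control),
            "treated_median": res.median_x,
            "control_median": res.median_y,
            "percent_of_control": float("nan"),
            "percent_flag": "not applicable",
            "U": res.u_x,
            "p_value": res.p_value,
            "method": res.method,
        }
    )
    return pd.DataFrame(rows)
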