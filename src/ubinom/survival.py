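"""Signature scoring, density-peak stratification and survival analysis.

A gene-signature score per sample is the geometric mean of the signature
genes' expression, computed in log2 space (so it is the arithmetic mean
of the log2 values).  Patients are dichotomized at the density minimum
between the two dominant peaks of a Gaussian kernel density estimate of
the score (median split when the density is unimodal), and the strata
are compared with Kaplan–Meier curves, the log-rank test and a
single-covariate Cox proportional-hazards fit.

The Cox fit is a Newton maximization of the partial likelihood with
Breslow handling of tied event times; Kaplan–Meier and log-rank are
delegated to lifelines.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .differential import welch_t

__all__ = [
    "CoxResult",
    "signature_score",
    "density_dichotomize",
    "km_estimate",
    "logrank_test",
    "cox_hr",
    "compare_scores",
    "trim_by_survival",
]

logger = logging.getLogger(__name__)

_COHORT_COLUMNS = {"time", "event"}


def _check_cohort(cohort: pd.DataFrame) -> None:
    missing = _COHORT_COLUMNS - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    if (cohort["time"] < 0).any():
        raise ValueError("negative follow-up times")
    if not cohort["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0 (censored) or 1 (event)")


def signature_score(
    m: pd.DataFrame, genes: Sequence[str]
) -> pd.Series:
    """Geometric-mean signature score per sample, reported in log2 space.

    *m* holds log2-scale nonnegative expression (features × samples).
    The score is the arithmetic mean of the log2 values over the
    signature genes present in the matrix — identically the log2 of the
    geometric mean of the linear values.  Missing genes are logged, not
    imputed; zero genes present is an error.
    """
    present = [g for g in genes if g in m.index]
    absent = [g for g in genes if g not in m.index]
    if absent:
        logger.warning("%d signature genes absent from matrix: %s",
                       len(absent), absent[:10])
    if not present:
        raise ValueError("no signature genes present in the matrix")
    sub = m.loc[present]
    if (sub.to_numpy() < 0).any():
        raise ValueError("signature scoring expects nonnegative log2-scale values")
    return sub.mean(axis=0).rename("score")


def silverman_bandwidth(x: np.ndarray) -> float:
    """Classic univariate Silverman rule: 0.9·min(sd, IQR/1.34)·n^{-1/5}."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * len(x) ** (-0.2)


def density_dichotomize(
    scores: Sequence[float], grid_size: int = 512
) -> tuple[float, np.ndarray, dict]:
    """Split scores into high/low at the valley between density peaks.

    A Gaussian KDE (Silverman bandwidth) is evaluated on *grid_size*
    points over [min − 3h, max + 3h].  With two or more local maxima the
    threshold is the location of the density minimum between the two
    highest peaks; a unimodal density falls back to the median.
    Deterministic for fixed input; translation-equivariant.

    Returns ``(threshold, labels, info)`` with labels ``"high"`` for
    score > threshold and ``"low"`` otherwise, and *info* recording the
    bandwidth, grid and rule used.
    """
    x = np.asarray(scores, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 samples to stratify")
    if np.ptp(x) == 0:
        raise ValueError("all scores identical; no stratification possible")
    h = silverman_bandwidth(x)
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, grid_size)
    dens = np.exp(-0.5 * ((grid[:, None] - x[None, :]) / h) ** 2).sum(axis=1)
    dens /= len(x) * h * np.sqrt(2 * np.pi)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = np.flatnonzero(interior) + 1
    rule = "median_fallback"
    if len(peaks) >= 2:
        top2 = sorted(peaks[np.argsort(dens[peaks])[-2:]])
        lo, hi = top2
        valley = lo + int(np.argmin(dens[lo : hi + 1]))
        threshold = float(grid[valley])
        rule = "between_peaks_minimum"
    else:
        threshold = float(np.median(x))
    labels = np.where(x > threshold, "high", "low")
    info = {
        "bandwidth": float(h),
        "grid_min": float(grid[0]),
        "grid_max": float(grid[-1]),
        "grid_size": grid_size,
        "n_peaks": int(len(peaks)),
        "rule": rule,
    }
    return threshold, labels, info


def km_estimate(cohort: pd.DataFrame, stratum: str | None = None) -> pd.DataFrame:
    """Kaplan–Meier product-limit curve as a (time, survival) step table.

    *cohort* needs columns ``time`` and ``event`` (plus ``stratum`` when
    a stratum label is requested).  The returned table starts at
    (0, 1.0) and is right-continuous and non-increasing.
    """
    _check_cohort(cohort)
    if stratum is not None:
        cohort = cohort[cohort["stratum"] == stratum]
        if cohort.empty:
            raise ValueError(f"no samples in stratum {stratum!r}")
    kmf = KaplanMeierFitter()
    kmf.fit(cohort["time"], cohort["event"])
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(dtype=float),
         "survival": sf.iloc[:, 0].to_numpy(dtype=float)}
    )


def logrank_test(cohort: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) with two-sided p.

    *cohort* needs columns ``time``, ``event`` and ``stratum`` with
    exactly two stratum labels and at least one event overall.
    """
    _check_cohort(cohort)
    if "stratum" not in cohort.columns:
        raise ValueError("cohort table missing 'stratum' column")
    strata = sorted(cohort["stratum"].unique())
    if len(strata) != 2:
        raise ValueError(f"log-rank needs exactly 2 strata, got {strata}")
    if cohort["event"].sum() < 1:
        raise ValueError("log-rank needs at least one event")
    a = cohort[cohort["stratum"] == strata[0]]
    b = cohort[cohort["stratum"] == strata[1]]
    res = _ll_logrank(a["time"], b["time"], a["event"], b["event"])
    return float(res.test_statistic), float(res.p_value)


@dataclass(frozen=True)
class CoxResult:
    """Single-covariate Cox proportional-hazards fit."""

    coef: float
    hr: float
    se: float
    p_value: float
    converged: bool
    n: int
    n_events: int
    flag: str = ""


def cox_hr(
    time: Sequence[float],
    event: Sequence[int],
    covariate: Sequence[float],
    max_iter: int = 50,
    tol: float = 1e-10,
) -> CoxResult:
    """Newton maximization of the Cox partial likelihood (Breslow ties).

    Fits ``h(t|x) = h0(t)·exp(βx)`` for a single covariate.  Returns the
    hazard ratio exp(β), the coefficient, its standard error from the
    observed information, and a two-sided Wald p value.  Non-convergence
    and monotone likelihood (perfect separation) are flagged, never
    returned as silent numbers.
    """
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=int)
    x = np.asarray(covariate, dtype=float)
    if not (len(t) == len(d) == len(x)):
        raise ValueError("time, event and covariate must have equal length")
    if d.sum() < 1:
        raise ValueError("Cox fit needs at least one event")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")
    # sort by descending time so risk sets are cumulative prefixes
    order = np.argsort(-t, kind="mergesort")
    t, d, x = t[order], d[order], x[order]
    # index of the last tied position for each time (risk set boundary)
    # risk set at event time t_i = all subjects with time >= t_i
    risk_end = np.searchsorted(-t, -t, side="right")  # exclusive prefix end
    ev = np.flatnonzero(d == 1)

    beta = 0.0
    converged = False
    flag = ""
    for _ in range(max_iter):
        w = np.exp(beta * x)
        s0 = np.cumsum(w)
        s1 = np.cumsum(w * x)
        s2 = np.cumsum(w * x * x)
        idx = risk_end[ev] - 1
        r0, r1, r2 = s0[idx], s1[idx], s2[idx]
        grad = float(np.sum(x[ev] - r1 / r0))
        info = float(np.sum(r2 / r0 - (r1 / r0) ** 2))
        if info <= 1e-12:
            flag = "singular_information"
            break
        step = grad / info
        beta += np.clip(step, -5.0, 5.0)
        if abs(beta) > 20:
            flag = "monotone_likelihood"
            break
        if abs(step) < tol:
            converged = True
            break
    if not converged and not flag:
        flag = "max_iter"
    w = np.exp(beta * x)
    s0 = np.cumsum(w)
    s1 = np.cumsum(w * x)
    s2 = np.cumsum(w * x * x)
    idx = risk_end[ev] - 1
    r0, r1, r2 = s0[idx], s1[idx], s2[idx]
    info = float(np.sum(r2 / r0 - (r1 / r0) ** 2))
    se = float(1.0 / np.sqrt(info)) if info > 0 else float("inf")
    z = beta / se if np.isfinite(se) and se > 0 else 0.0
    p = float(2 * stats.norm.sf(abs(z)))
    if flag:
        logger.warning("cox_hr: %s (beta=%.3g)", flag, beta)
    return CoxResult(
        coef=float(beta),
        hr=float(np.exp(beta)),
        se=se,
        p_value=p,
        converged=converged,
        n=len(t),
        n_events=int(d.sum()),
        flag=flag,
    )


def compare_scores(
    groups: Mapping[str, Sequence[float]]
) -> pd.DataFrame:
    """Pairwise Welch t comparisons of labeled score lists.

    ``difference`` is mean(second) − mean(first) in each pair; p values
    are two-sided.  Routes through the same Welch implementation as the
    differential tests.
    """
    for label, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 samples")
    rows = []
    for (la, va), (lb, vb) in itertools.combinations(groups.items(), 2):
        a = np.asarray(va, dtype=float)
        b = np.asarray(vb, dtype=float)
        stat, p = welch_t(b, a)
        rows.append(
            {
                "group_a": la,
                "group_b": lb,
                "difference": float(b.mean() - a.mean()),
                "t": stat,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def trim_by_survival(
    m: pd.DataFrame,
    cohort: pd.DataFrame,
    genes: Sequence[str],
    k: int = 20,
) -> list[str]:
    """Trim a signature to the *k* genes most associated with survival.

    Each gene's expression (a row of *m*, columns aligned to the cohort's
    sample order) is fit as the sole covariate of a univariate Cox model;
    genes are ranked by ascending p value (ties broken lexicographically)
    and the top *k* are retained.  The output is always a subset of the
    input signature.
    """
    _check_cohort(cohort)
    present = [g for g in genes if g in m.index]
    if k > len(present):
        raise ValueError(f"k={k} exceeds the {len(present)} genes present")
    samples = cohort["sample_id"] if "sample_id" in cohort.columns else cohort.index
    expr = m.loc[present, list(samples)]
    ranked = []
    for gene in present:
        res = cox_hr(cohort["time"], cohort["event"], expr.loc[gene])
        ranked.append((res.p_value, gene))
    ranked.sort()
    return [g for _, g in ranked[:k]]
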