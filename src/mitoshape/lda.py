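"""Single-hit Poisson limiting-dilution frequency estimation.

In a limiting-dilution spheroid assay, wells seeded with ``d`` cells stay
negative only if none of the ``d`` cells is an active (self-renewing) cell.
Under the single-hit Poisson model with active-cell frequency ``f``,

    P(well negative | dose d) = exp(-f * d),

so the well outcomes are binomial with a complementary log-log link and a
log-dose offset: cloglog P(positive) = log f + log d.  The frequency is the
single free parameter; this module maximizes the binomial log-likelihood in
log f directly, takes the 95% confidence interval from the profile
likelihood (chi-square_1 cutoff 3.841), and compares two groups with a
likelihood-ratio test of a shared frequency against separate ones.

Design choices: the profile interval is preferred to a Wald interval
because the likelihood in log f is visibly skewed at 24 wells per dose;
datasets with every well negative (or every well positive) have no interior
maximum and are reported as one-sided bounds with a ``boundary`` flag
rather than a point estimate; the search is capped at f = 1, the largest
frequency the single-hit model can mean (at most one active cell per
plated cell).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["LDAEstimate", "lda_fit", "lda_compare", "read_wells_csv"]

_CHI2_95 = stats.chi2.ppf(0.95, 1)  # 3.841...
_LOG_F_MIN = math.log(1e-12)  # effective zero on the search scale


@dataclass(frozen=True)
class LDAEstimate:
    """Active-cell frequency estimate with 95% profile-likelihood interval.

    frequency : MLE of the per-plated-cell frequency (NaN for boundary data)
    ci_low, ci_high : 95% interval endpoints (one-sided at the boundary)
    loglik : maximized binomial log-likelihood
    boundary : None for interior data, else "all-negative" / "all-positive"
    """

    frequency: float
    ci_low: float
    ci_high: float
    loglik: float
    boundary: str | None = None

    @property
    def one_in(self) -> float:
        """Frequency in the conventional '1 active cell in N' form."""
        return 1.0 / self.frequency


def _validate(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    for col in ("dose", "wells", "positive"):
        if col not in df.columns:
            raise ValueError(f"wells table missing column {col!r}")
    dose = df["dose"].to_numpy(dtype=float)
    wells = df["wells"].to_numpy(dtype=float)
    pos = df["positive"].to_numpy(dtype=float)
    if len(dose) == 0:
        raise ValueError("empty wells table")
    if np.any(dose < 1):
        raise ValueError("doses must be >= 1")
    if np.any(pos < 0) or np.any(pos > wells):
        raise ValueError("need 0 <= positive <= wells")
    return dose, wells, pos


def _loglik(logf: float, dose, wells, pos) -> float:
    fd = math.exp(logf) * dose
    # log P(positive) = log(1 - exp(-fd)); log P(negative) = -fd
    with np.errstate(divide="ignore"):
        lp = np.log(-np.expm1(-fd))
    return float(np.sum(pos * lp) - np.sum((wells - pos) * fd))


def _score(logf: float, dose, wells, pos) -> float:
    # d loglik / d logf; stationary where expected positives match observed
    f = math.exp(logf)
    fd = f * dose
    w = fd / -np.expm1(-fd) * np.exp(-fd)  # fd * P(neg)/P(pos)
    return float(np.sum(pos * w) - np.sum((wells - pos) * fd))


def lda_fit(data: pd.DataFrame) -> LDAEstimate:
    """Fit the single-hit frequency to a (dose, wells, positive) table.

    For interior data (not every well negative, not every well positive)
    returns the MLE with its 95% profile-likelihood interval.  For a single
    dose ``d`` with negative fraction ``q`` the MLE reduces to the closed
    form ``-ln(q) / d``, which the numeric fit reproduces.
    """
    dose, wells, pos = _validate(data)
    total_pos, total_wells = pos.sum(), wells.sum()

    if total_pos == 0:
        # likelihood -f * sum(wells*dose), maximal as f -> 0: upper bound only
        ub = _CHI2_95 / 2.0 / float(np.sum(wells * dose))
        return LDAEstimate(math.nan, 0.0, ub, 0.0, boundary="all-negative")
    if total_pos == total_wells:
        # likelihood increasing in f: lower bound only
        target = -_CHI2_95 / 2.0
        lb = math.exp(
            optimize.brentq(
                lambda x: _loglik(x, dose, wells, pos) - target, _LOG_F_MIN, 0.0,
                xtol=1e-12,
            )
        )
        return LDAEstimate(math.nan, lb, math.inf, 0.0, boundary="all-positive")

    # interior: score is positive at tiny f, negative at large f (unimodal)
    lo, hi = _LOG_F_MIN, 0.0
    if _score(hi, dose, wells, pos) > 0:
        # best fit at the f = 1 cap of the single-hit model
        logf_hat = 0.0
    else:
        logf_hat = optimize.brentq(
            _score, lo, hi, args=(dose, wells, pos), xtol=1e-14
        )
    ll_hat = _loglik(logf_hat, dose, wells, pos)
    target = ll_hat - _CHI2_95 / 2.0

    def drop(x: float) -> float:
        return _loglik(x, dose, wells, pos) - target

    ci_lo = math.exp(optimize.brentq(drop, _LOG_F_MIN, logf_hat, xtol=1e-12))
    ci_hi = 1.0 if logf_hat == 0.0 or drop(0.0) > 0 else math.exp(
        optimize.brentq(drop, logf_hat, 0.0, xtol=1e-12)
    )
    return LDAEstimate(math.exp(logf_hat), ci_lo, ci_hi, ll_hat, boundary=None)


def _max_loglik(data: pd.DataFrame) -> float:
    """Supremum of the log-likelihood, finite for boundary data too."""
    dose, wells, pos = _validate(data)
    if pos.sum() == 0:
        return 0.0  # f -> 0 limit
    if pos.sum() == wells.sum():
        return 0.0  # f -> inf limit (P(positive) -> 1 in every well)
    est = lda_fit(data)
    return est.loglik


def lda_compare(a: pd.DataFrame, b: pd.DataFrame) -> tuple[float, float]:
    """Likelihood-ratio test of equal frequency between two groups.

    Null: one shared frequency fits both well tables; alternative: separate
    frequencies.  Returns (LR statistic, p-value) with 1 df.  Symmetric in
    the group order.
    """
    ll_sep = _max_loglik(a) + _max_loglik(b)
    pooled = pd.concat(
        [a[["dose", "wells", "positive"]], b[["dose", "wells", "positive"]]],
        ignore_index=True,
    )
    ll_shared = _max_loglik(pooled)
    stat = max(0.0, 2.0 * (ll_sep - ll_shared))
    return stat, float(stats.chi2.sf(stat, 1))


def read_wells_csv(path) -> dict[str, pd.DataFrame]:
    """Read a (group, dose, wells, positive) CSV into per-group tables.

    A missing ``group`` column yields a single group named ``"all"``.
    """
    df = pd.read_csv(path)
    if "group" not in df.columns:
        return {"all": df}
    return {str(g): grp.reset_index(drop=True) for g, grp in df.groupby("group", sort=False)}
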