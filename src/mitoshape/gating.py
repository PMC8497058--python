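"""Bivariate fission x fusion5 subpopulation gating and scatter statistics.

Cells are placed into one of three mutually exclusive gates on the
(fission, fusion5) plane:

``HF``
    hyperfused: ``fusion5 > 80`` (strict).
``Int``
    intermediate: ``fission`` in [0.15, 0.4] and ``fusion5`` in [40, 80],
    both closed -- smaller fused networks coexisting with fragments.
``Other``
    everything else.

A cell at exactly fusion5 = 80 is Int, never HF: the HF bound is strict and
the Int box closed, so the two gates cannot overlap.  Gate abundances across
populations are compared with a Pearson chi-square test (no continuity
correction), and the strength of the inverse fission--fusion5 relationship
within a population is summarized by Pearson r together with the residual
standard error of the OLS fit of fusion5 on fission.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GateConfig",
    "GateTable",
    "DEFAULT_GATES",
    "classify_cell",
    "classify_table",
    "gate_table",
    "correlation_scatter",
    "fusion1_hi_fraction",
]

GATE_LABELS = ("HF", "Int", "Other")


@dataclass(frozen=True)
class GateConfig:
    """Gate bounds on the (fission, fusion5) plane.

    ``hf_fusion5_min`` is an exclusive lower bound; the Int ranges are
    closed intervals; ``fusion1_hi_min`` is the exclusive bound for the
    single-dominant-element fraction.
    """

    hf_fusion5_min: float = 80.0
    int_fission_range: tuple[float, float] = (0.15, 0.4)
    int_fusion5_range: tuple[float, float] = (40.0, 80.0)
    fusion1_hi_min: float = 80.0

    def __post_init__(self) -> None:
        for lo, hi in (self.int_fission_range, self.int_fusion5_range):
            if lo > hi:
                raise ValueError("range bounds must satisfy min <= max")
        if not 0 <= self.hf_fusion5_min <= 100 or not 0 <= self.fusion1_hi_min <= 100:
            raise ValueError("percent bounds must lie in [0, 100]")
        if self.int_fusion5_range[1] > self.hf_fusion5_min:
            raise ValueError("Int fusion5 upper bound must not exceed the HF bound")


DEFAULT_GATES = GateConfig()


def classify_cell(record, config: GateConfig = DEFAULT_GATES) -> str:
    """Gate label for one metric record (anything with fission/fusion5)."""
    fission = record["fission"] if isinstance(record, (dict, pd.Series)) else record.fission
    fusion5 = record["fusion5"] if isinstance(record, (dict, pd.Series)) else record.fusion5
    if fusion5 > config.hf_fusion5_min:
        return "HF"
    f_lo, f_hi = config.int_fission_range
    g_lo, g_hi = config.int_fusion5_range
    if f_lo <= fission <= f_hi and g_lo <= fusion5 <= g_hi:
        return "Int"
    return "Other"


def classify_table(table: pd.DataFrame, config: GateConfig = DEFAULT_GATES) -> pd.Series:
    """Vectorized gate labels for a metrics table."""
    fission = table["fission"].to_numpy()
    fusion5 = table["fusion5"].to_numpy()
    hf = fusion5 > config.hf_fusion5_min
    f_lo, f_hi = config.int_fission_range
    g_lo, g_hi = config.int_fusion5_range
    inter = (
        ~hf
        & (fission >= f_lo)
        & (fission <= f_hi)
        & (fusion5 >= g_lo)
        & (fusion5 <= g_hi)
    )
    out = np.where(hf, "HF", np.where(inter, "Int", "Other"))
    return pd.Series(out, index=table.index, name="gate")


@dataclass(frozen=True)
class GateTable:
    """Gate composition of >= 2 populations with the chi-square comparison.

    counts / fractions : population x {HF, Int, Other} DataFrames
    chi2, dof, pvalue  : Pearson chi-square on the counts table
    fusion1_hi         : per-population fraction of cells with fusion1 above
                         the configured bound
    scatter            : per-population Pearson r(fission, fusion5) and OLS
                         residual standard error
    """

    counts: pd.DataFrame
    fractions: pd.DataFrame
    chi2: float
    dof: int
    pvalue: float
    fusion1_hi: pd.Series
    scatter: pd.DataFrame


def gate_table(table: pd.DataFrame, config: GateConfig = DEFAULT_GATES) -> GateTable:
    """Gate every cell, tabulate per-population composition, and test it.

    Requires at least two populations (there is nothing to compare
    otherwise).  Warns when any expected count falls below 5, where the
    chi-square approximation degrades.
    """
    pops = table["population"].unique()
    if len(pops) < 2:
        raise ValueError("gate_table needs >= 2 populations to compare")
    gates = classify_table(table, config)
    counts = (
        pd.crosstab(table["population"], gates)
        .reindex(index=pops, columns=list(GATE_LABELS), fill_value=0)
        .astype(int)
    )
    fractions = counts.div(counts.sum(axis=1), axis=0)
    # drop empty gate columns: chi2_contingency rejects all-zero margins
    nonzero = counts.loc[:, counts.sum(axis=0) > 0]
    chi2, p, dof, expected = stats.chi2_contingency(nonzero, correction=False)
    if (expected < 5).any():
        warnings.warn("expected count < 5 in some cell; chi-square is approximate")
    fusion1_hi = table.groupby("population", sort=False).apply(
        lambda g: fusion1_hi_fraction(g, config), include_groups=False
    )
    scatter_rows = {}
    for pop, grp in table.groupby("population", sort=False):
        try:
            r, sd = correlation_scatter(grp)
        except ValueError:
            r, sd = np.nan, np.nan
        scatter_rows[pop] = {"pearson_r": r, "residual_sd": sd}
    scatter = pd.DataFrame.from_dict(scatter_rows, orient="index")
    return GateTable(counts, fractions, float(chi2), int(dof), float(p), fusion1_hi, scatter)


def correlation_scatter(table: pd.DataFrame) -> tuple[float, float]:
    """Pearson r and OLS residual SD for one population's (fission, fusion5).

    The residual SD is the regression standard error sqrt(SSR / (n - 2)) of
    fusion5 regressed on fission; it is the explicit operationalization of
    "scatter around the regression line".  Degenerate inputs (< 3 cells or
    zero variance in either metric) raise.
    """
    x = table["fission"].to_numpy(dtype=float)
    y = table["fusion5"].to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError("correlation_scatter needs >= 3 cells")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate variance: a metric is constant")
    r = float(stats.pearsonr(x, y).statistic)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    residual_sd = float(np.sqrt(np.sum(resid**2) / (x.size - 2)))
    return r, residual_sd


def fusion1_hi_fraction(table: pd.DataFrame, config: GateConfig = DEFAULT_GATES) -> float:
    """Fraction of cells whose largest element exceeds the fusion1 bound."""
    if len(table) == 0:
        raise ValueError("empty population")
    return float((table["fusion1"].to_numpy() > config.fusion1_hi_min).mean())
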