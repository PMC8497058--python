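"""Robust quadrant gating of two-channel immunofluorescence intensities.

Dot plots of paired marker intensities (e.g. Sox2 vs Krt15) are split into
four quadrants by a per-channel robust signal threshold

    threshold = median + 1.5 * MAD,

where MAD is the raw median absolute deviation from the median -- no normal
consistency factor.  Because the threshold never falls below the median, at
most half of the sample that defines it can be called "hi" on that channel;
"hi" is strictly greater than the threshold, so a degenerate MAD of zero
does not flood the hi quadrants with ties.

By default thresholds are computed on a designated reference (control)
population and applied uniformly, so hi/lo percentages are comparable across
populations; per-population thresholds are available as an explicit mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["QuadrantTable", "mad_threshold", "quadrant_table"]

QUADRANTS = ("hi-hi", "hi-lo", "lo-hi", "lo-lo")


def mad_threshold(values) -> float:
    """median + 1.5 x MAD of ``values`` (MAD unscaled)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("mad_threshold needs at least one value")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite intensity values")
    med = np.median(arr)
    mad = np.median(np.abs(arr - med))
    return float(med + 1.5 * mad)


@dataclass(frozen=True)
class QuadrantTable:
    """Quadrant composition of one or more populations under shared cuts.

    thresholds  : {"ch1": t1, "ch2": t2} in a.u.
    counts      : population x {hi-hi, hi-lo, lo-hi, lo-lo} counts
    percentages : same table as percentages summing to 100 per population
    chi2, dof, pvalue : Pearson chi-square across populations (NaN when a
                  single population is tabulated)
    """

    thresholds: dict
    counts: pd.DataFrame
    percentages: pd.DataFrame
    chi2: float
    dof: int
    pvalue: float


def quadrant_table(
    table: pd.DataFrame,
    reference: str | None = None,
    per_population: bool = False,
) -> QuadrantTable:
    """Threshold both channels and tabulate quadrant percentages.

    Parameters
    ----------
    table : DataFrame
        Columns ``population, ch1, ch2`` (one row per cell).
    reference : str, optional
        Population whose intensities define the thresholds for everyone.
        Required unless ``per_population`` is set.
    per_population : bool
        Compute thresholds separately within each population instead of on
        the reference sample.  Percentages are then not comparable across
        populations against a common cut.
    """
    pops = list(table["population"].unique())
    if per_population:
        thr = {
            pop: (mad_threshold(g["ch1"]), mad_threshold(g["ch2"]))
            for pop, g in table.groupby("population", sort=False)
        }
        t1 = table["population"].map({p: t[0] for p, t in thr.items()})
        t2 = table["population"].map({p: t[1] for p, t in thr.items()})
        thresholds = {p: {"ch1": t[0], "ch2": t[1]} for p, t in thr.items()}
    else:
        if reference is None:
            raise ValueError("reference population required (or per_population=True)")
        if reference not in pops:
            raise ValueError(f"reference population {reference!r} not in table")
        ref = table[table["population"] == reference]
        t1 = mad_threshold(ref["ch1"])
        t2 = mad_threshold(ref["ch2"])
        thresholds = {"ch1": float(t1), "ch2": float(t2)}
    hi1 = table["ch1"].to_numpy() > np.asarray(t1, dtype=float)
    hi2 = table["ch2"].to_numpy() > np.asarray(t2, dtype=float)
    quad = np.where(
        hi1,
        np.where(hi2, "hi-hi", "hi-lo"),
        np.where(hi2, "lo-hi", "lo-lo"),
    )
    counts = (
        pd.crosstab(table["population"], pd.Series(quad, index=table.index, name="quadrant"))
        .reindex(index=pops, columns=list(QUADRANTS), fill_value=0)
        .astype(int)
    )
    percentages = counts.div(counts.sum(axis=1), axis=0) * 100.0
    if len(pops) >= 2:
        nonzero = counts.loc[:, counts.sum(axis=0) > 0]
        chi2, p, dof, _ = stats.chi2_contingency(nonzero, correction=False)
    else:
        chi2, p, dof = np.nan, np.nan, 0
    return QuadrantTable(thresholds, counts, percentages, float(chi2), int(dof), float(p))
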