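"""Cell-cycle phase composition per cluster and G1-to-S reciprocity.

Phase labels are consumed as emitted by upstream single-cell scoring (three
levels: G0/G1, S, G2M); nothing is rescored here.  For two clusters A and B
within a population the reciprocity statistic is

    reciprocity = (G1% / S%) in cluster A  /  (G1% / S%) in cluster B,

which quantifies opposed shifts of cell-cycle residency between the two
clusters: a value of 1 means identical G1-vs-S balance, large values mean
cluster A is G1-shifted exactly where cluster B is S-shifted.  The statistic
is invariant to each population's total cell count and inverts exactly under
swapping A and B.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "PHASES",
    "ReciprocityResult",
    "phase_counts",
    "phase_fractions",
    "reciprocity",
]

PHASES = ("G0/G1", "S", "G2M")


def phase_counts(cells: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a per-cell (population, cluster, phase) table into counts."""
    for col in ("population", "cluster", "phase"):
        if col not in cells.columns:
            raise ValueError(f"missing column {col!r}")
    out = (
        cells.groupby(["population", "cluster", "phase"], sort=False)
        .size()
        .rename("count")
        .reset_index()
    )
    return out


def phase_fractions(counts: pd.DataFrame) -> pd.DataFrame:
    """Phase percentages per (population, cluster), summing to 100.

    ``counts`` is long-format with columns population, cluster, phase,
    count.  Groups with zero total are dropped with a warning.
    """
    import warnings

    if "count" not in counts.columns:
        raise ValueError("expected long-format counts with a 'count' column")
    if (counts["count"] < 0).any():
        raise ValueError("negative counts")
    wide = (
        counts.pivot_table(
            index=["population", "cluster"],
            columns="phase",
            values="count",
            aggfunc="sum",
            fill_value=0,
        )
    )
    totals = wide.sum(axis=1)
    empty = totals == 0
    if empty.any():
        warnings.warn(f"dropping {int(empty.sum())} empty (population, cluster) group(s)")
        wide = wide[~empty]
        totals = totals[~empty]
    pct = wide.div(totals, axis=0) * 100.0
    pct.columns.name = "phase"
    return pct


@dataclass(frozen=True)
class ReciprocityResult:
    """Per-population G1/S ratios for two clusters and their quotient.

    table : DataFrame indexed by population with columns ratio_a, ratio_b,
            reciprocity, and (when a reference is given) fold_vs_reference.
    cluster_a, cluster_b : the compared cluster labels
    reference : the reference population, if any
    """

    table: pd.DataFrame
    cluster_a: object
    cluster_b: object
    reference: str | None = None


def reciprocity(
    counts: pd.DataFrame,
    cluster_a,
    cluster_b,
    reference: str | None = None,
    pseudocount: bool = False,
    g1_phase: str = "G0/G1",
    s_phase: str = "S",
) -> ReciprocityResult:
    """G1-to-S reciprocity between two clusters, per population.

    Raises when any required (population, cluster) group is missing or has
    an S percentage of zero; ``pseudocount=True`` instead adds 0.5 to every
    phase count of every group before forming percentages (an explicitly
    opted-in regularization -- the default refuses to quietly smooth a
    headline ratio).
    """
    pct = _fractions_allow_float(counts, pseudocount=pseudocount)
    for ph in (g1_phase, s_phase):
        if ph not in pct.columns:
            raise ValueError(f"phase {ph!r} absent from the table")

    rows = {}
    for pop in counts["population"].unique():
        ratios = {}
        for tag, cl in (("a", cluster_a), ("b", cluster_b)):
            key = (pop, cl)
            if key not in pct.index:
                raise ValueError(f"cluster {cl!r} missing in population {pop!r}")
            g1 = pct.loc[key, g1_phase]
            s = pct.loc[key, s_phase]
            if s == 0:
                raise ValueError(
                    f"S fraction is zero in population {pop!r}, cluster {cl!r}: "
                    "G1/S ratio undefined (pass pseudocount=True to regularize)"
                )
            ratios[tag] = g1 / s
        rows[pop] = {
            "ratio_a": ratios["a"],
            "ratio_b": ratios["b"],
            "reciprocity": ratios["a"] / ratios["b"],
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "population"
    if reference is not None:
        if reference not in table.index:
            raise ValueError(f"reference population {reference!r} not present")
        table["fold_vs_reference"] = (
            table["reciprocity"] / table.loc[reference, "reciprocity"]
        )
    return ReciprocityResult(table, cluster_a, cluster_b, reference)


def _fractions_allow_float(counts: pd.DataFrame, pseudocount: bool = False) -> pd.DataFrame:
    wide = counts.pivot_table(
        index=["population", "cluster"],
        columns="phase",
        values="count",
        aggfunc="sum",
        fill_value=0.0,
    )
    if pseudocount:
        # +0.5 per phase cell, including phases absent from a group's rows
        wide = wide + 0.5
    wide = wide[wide.sum(axis=1) > 0]
    return wide.div(wide.sum(axis=1), axis=0) * 100.0
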