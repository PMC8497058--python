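"""Per-cell mitochondrial shape metrics from skeleton component lengths.

A cell's mitochondrial network, as emitted by confocal-stack skeletonization,
is reduced here to the multiset of its component lengths (in micrometres).
Three scalar summaries describe where the cell sits on the fission--fusion
axis:

``fission``
    total mitochondria number / total mitochondrial length (units 1/um).
    Higher values mean a more fragmented network.
``fusion_k`` (reported for k = 1 and k = 5)
    100 x (sum of the k largest component lengths) / (total length).
    ``fusion5 = 100`` means essentially all mitochondrial mass sits in at
    most five networks; ``fusion1 > 80`` means a single element dominates.

Both metrics quantify the steady-state outcome of fission/fusion, not the
kinetics of either process.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MitoCell",
    "MetricRecord",
    "fission_metric",
    "fusion_k_metric",
    "metrics_table",
    "read_cells_csv",
    "write_cells_csv",
    "write_metrics_csv",
]


@dataclass
class MitoCell:
    """One cell's mitochondrial network as a bag of component lengths (um).

    Parameters
    ----------
    cell_id : str
        Unique identifier within a dataset.
    population : str
        Sample / condition label (e.g. ``"Parental"``).
    lengths : array-like of float
        Component lengths in micrometres; all strictly positive and finite,
        at least one component.
    archetype : str, optional
        Generator-side ground-truth label; absent for real data.
    """

    cell_id: str
    population: str
    lengths: np.ndarray
    archetype: str | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.lengths, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError(f"cell {self.cell_id!r}: need >= 1 component length")
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ValueError(
                f"cell {self.cell_id!r}: lengths must be positive and finite"
            )
        object.__setattr__(self, "lengths", arr)

    @property
    def n_components(self) -> int:
        return int(self.lengths.size)

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())


@dataclass(frozen=True)
class MetricRecord:
    """Per-cell metric row: fission (1/um), fusion1/fusion5 (percent)."""

    cell_id: str
    population: str
    fission: float
    fusion1: float
    fusion5: float
    n_components: int
    total_length: float
    archetype: str | None = None


def fission_metric(cell: MitoCell) -> float:
    """Component count divided by total length (1/um)."""
    return cell.n_components / cell.total_length


def fusion_k_metric(cell: MitoCell, k: int) -> float:
    """Percentage of total length held by the ``k`` largest components.

    When the cell has fewer than ``k`` components the whole network is
    counted and the metric is exactly 100.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if cell.n_components <= k:
        return 100.0
    # partial selection: only the top-k sum matters, ties are irrelevant
    top = np.partition(cell.lengths, cell.n_components - k)[-k:]
    return 100.0 * float(top.sum()) / cell.total_length


def metrics_table(cells: Sequence[MitoCell]) -> pd.DataFrame:
    """Tabulate metrics for a list of cells, one row per cell, input order.

    Returns a DataFrame with columns ``cell_id, population, fission,
    fusion1, fusion5, n_components, total_length`` (plus ``archetype``
    when any cell carries one). Raises on duplicate cell ids.
    """
    if len(cells) == 0:
        raise ValueError("metrics_table needs at least one cell")
    ids = [c.cell_id for c in cells]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate cell_id(s): {dupes[:5]}")
    rows = []
    for c in cells:
        rows.append(
            {
                "cell_id": c.cell_id,
                "population": c.population,
                "fission": fission_metric(c),
                "fusion1": fusion_k_metric(c, 1),
                "fusion5": fusion_k_metric(c, 5),
                "n_components": c.n_components,
                "total_length": c.total_length,
                "archetype": c.archetype,
            }
        )
    df = pd.DataFrame(rows)
    if df["archetype"].isna().all():
        df = df.drop(columns="archetype")
    return df


def write_cells_csv(cells: Iterable[MitoCell], path) -> None:
    """Write cells in long format: cell_id, population, component_index, length_um."""
    rows = []
    for c in cells:
        for i, ln in enumerate(c.lengths):
            rows.append((c.cell_id, c.population, i, ln))
    pd.DataFrame(
        rows, columns=["cell_id", "population", "component_index", "length_um"]
    ).to_csv(path, index=False)


def read_cells_csv(path) -> list[MitoCell]:
    """Read the long-format component-length table back into cells.

    Rejects nonpositive, NaN or infinite lengths outright: silently dropping
    rows would shift every downstream metric distribution.
    """
    df = pd.read_csv(path)
    required = {"cell_id", "population", "length_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cells CSV missing columns: {sorted(missing)}")
    bad = ~np.isfinite(df["length_um"]) | (df["length_um"] <= 0)
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} row(s) with nonpositive or non-finite length_um"
        )
    cells = []
    for (cid, pop), grp in df.groupby(["cell_id", "population"], sort=False):
        cells.append(MitoCell(str(cid), str(pop), grp["length_um"].to_numpy()))
    return cells


def write_metrics_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
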