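"""Stochastic fission--fusion simulator and companion input generators.

The simulator stands in for the raw microscopy data the analysis normally
consumes.  A cell's mitochondrial mass ``total_length`` (um) is conserved and
partitioned into linear components.  Two reactions act on the partition:

* **fission** -- component *i* breaks at rate ``k_fis * len_i`` at a
  uniformly placed breakpoint; a split producing a daughter shorter than
  ``min_len`` is rejected (the optical resolution floor of skeletonization:
  such fragments would not be resolved as separate components);
* **fusion** -- every unordered pair of components merges at rate ``k_fus``
  (well-mixed mass action).

Events are drawn by the standard stochastic simulation (Gillespie) rule and
the chain is run for a fixed number of *accepted* events from a single fused
component, which makes the cost deterministic.  At stationarity the balance
``k_fis * L ~ k_fus * n^2 / 2`` puts the mean component count near
``sqrt(2 * (k_fis/k_fus) * L)``, so the rate ratio is the single knob that
moves a cell along the fragmented--hyperfused axis.  The rates are
calibration knobs for generating realistic steady-state shape distributions;
they make no claim about biological kinetics.

Also here: log-normal two-channel immunofluorescence intensity mixtures with
planted hi/lo states, multinomial cluster x phase tables, and binomial
limiting-dilution well outcomes under the single-hit Poisson model.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .metrics import MitoCell

__all__ = [
    "SimParams",
    "PopulationSpec",
    "ChannelSpec",
    "IntensitySpec",
    "simulate_cell",
    "simulate_population",
    "simulate_intensities",
    "simulate_lda_wells",
    "simulate_phase_table",
    "HYPERFUSED",
    "INTERMEDIATE",
    "FRAGMENTED",
]


@dataclass(frozen=True)
class SimParams:
    """Parameters of the fission--fusion chain for one cell.

    total_length : conserved mitochondrial mass, um
    k_fis        : fission rate per um per unit time
    k_fus        : fusion rate per unordered component pair per unit time
    min_len      : minimum resolvable fragment, um
    n_events     : accepted-event burn-in count
    seed         : RNG seed for this cell's stream
    """

    total_length: float = 100.0
    k_fis: float = 1.0
    k_fus: float = 1.0
    min_len: float = 0.2
    n_events: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.total_length > 0 and np.isfinite(self.total_length)):
            raise ValueError("total_length must be positive and finite")
        if self.k_fis < 0 or self.k_fus < 0:
            raise ValueError("rates must be nonnegative")
        if self.k_fis == 0 and self.k_fus == 0:
            raise ValueError("k_fis and k_fus cannot both be zero")
        if not (0 < self.min_len < self.total_length):
            raise ValueError("need 0 < min_len < total_length")
        if self.n_events < 0:
            raise ValueError("n_events must be >= 0")


# Archetypes for mixture populations.  The ratio k_fis/k_fus sets the mean
# component count n ~ sqrt(2 * ratio * L); with L = 100 um these land the
# three archetypes in the hyperfused (fusion5 = 100), intermediate
# (fission 0.15-0.4, fusion5 40-80) and fragmented regimes respectively.
HYPERFUSED = SimParams(total_length=100.0, k_fis=0.02, k_fus=1.0)
INTERMEDIATE = SimParams(total_length=100.0, k_fis=2.5, k_fus=1.0)
FRAGMENTED = SimParams(total_length=100.0, k_fis=12.0, k_fus=1.0)


@dataclass(frozen=True)
class PopulationSpec:
    """A named mixture of cell archetypes.

    ``archetype_mix`` is a list of (SimParams, weight) pairs; weights are
    probabilities of a cell being drawn from each archetype.
    """

    name: str
    n_cells: int
    archetype_mix: Sequence[tuple[SimParams, float]]

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if len(self.archetype_mix) == 0:
            raise ValueError("archetype_mix must be nonempty")
        w = np.array([w for _, w in self.archetype_mix], dtype=float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0, atol=1e-9):
            raise ValueError("archetype weights must be >= 0 and sum to 1")


def _derive_seed(master_seed: int, *offsets: int) -> int:
    """Counter-offset child seed; stable across platforms, < 2**32."""
    ss = np.random.SeedSequence([int(master_seed), *map(int, offsets)])
    return int(ss.generate_state(1)[0])


def simulate_cell(
    params: SimParams,
    cell_id: str = "cell0",
    population: str = "sim",
    archetype: str | None = None,
) -> MitoCell:
    """Run the fission--fusion chain for one cell and return its partition.

    Starts from a single component of ``total_length`` and applies
    ``n_events`` accepted events.  Rejected fission attempts (daughter below
    ``min_len``) do not count.  If no event can ever be accepted (e.g.
    ``k_fus = 0`` with every component shorter than ``2 * min_len``) the
    current partition is returned as-is.
    """
    rng = random.Random(_derive_seed(params.seed))
    L = params.total_length
    k_fis, k_fus, min_len = params.k_fis, params.k_fus, params.min_len
    lengths: list[float] = [L]

    fis_rate = k_fis * L  # invariant under both reactions: mass is conserved
    accepted = 0
    while accepted < params.n_events:
        n = len(lengths)
        fus_rate = k_fus * n * (n - 1) / 2.0
        if fus_rate == 0.0:
            # only fission remains; stop if no component can legally split
            if fis_rate == 0.0 or max(lengths) < 2.0 * min_len:
                break
        if rng.random() * (fis_rate + fus_rate) < fis_rate:
            # fission: pick component with probability proportional to length
            u = rng.random() * L
            acc = 0.0
            i = n - 1
            for j, ln in enumerate(lengths):
                acc += ln
                if u <= acc:
                    i = j
                    break
            ln = lengths[i]
            b = rng.random() * ln
            if b < min_len or ln - b < min_len:
                continue  # unresolvable daughter: attempt rejected
            lengths[i] = b
            lengths.append(ln - b)
        else:
            i = rng.randrange(n)
            j = rng.randrange(n - 1)
            if j >= i:
                j += 1
            if j < i:
                i, j = j, i
            lengths[i] += lengths.pop(j)
        accepted += 1

    return MitoCell(
        cell_id=cell_id,
        population=population,
        lengths=np.array(lengths),
        archetype=archetype,
    )


def simulate_population(spec: PopulationSpec, seed: int = 0) -> list[MitoCell]:
    """Simulate ``spec.n_cells`` cells from the archetype mixture.

    Each cell gets its own RNG stream derived from ``seed`` and its index,
    so populations are reproducible and order-stable regardless of how they
    are generated.  The per-archetype ``seed`` fields inside the mix are
    ignored here.  The drawn archetype index is recorded on each cell as
    ``arch<k>``.
    """
    weights = np.array([w for _, w in spec.archetype_mix])
    assign_rng = np.random.default_rng(_derive_seed(seed, 0xA551))
    assignments = assign_rng.choice(len(weights), size=spec.n_cells, p=weights)
    cells = []
    for i, k in enumerate(assignments):
        params = replace(spec.archetype_mix[k][0], seed=_derive_seed(seed, i))
        cells.append(
            simulate_cell(
                params,
                cell_id=f"{spec.name}_{i:05d}",
                population=spec.name,
                archetype=f"arch{k}",
            )
        )
    return cells


@dataclass(frozen=True)
class ChannelSpec:
    """Log-normal lo/hi mixture for one immunofluorescence channel (a.u.)."""

    lo_logmean: float = 0.0
    lo_logsd: float = 0.3
    hi_logmean: float = 1.6
    hi_logsd: float = 0.3
    hi_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.lo_logsd <= 0 or self.hi_logsd <= 0:
            raise ValueError("log-sd must be > 0")
        if not 0.0 <= self.hi_fraction <= 1.0:
            raise ValueError("hi_fraction must be in [0, 1]")


@dataclass(frozen=True)
class IntensitySpec:
    """Two-channel intensity mixture with correlated hi states.

    ``hi_correlation`` is the Pearson correlation of the two binary hi
    indicators; it is clipped into the Frechet-feasible range implied by the
    two hi fractions (with a warning) before sampling.
    """

    ch1: ChannelSpec
    ch2: ChannelSpec
    hi_correlation: float = 0.0

    def __post_init__(self) -> None:
        if not -1.0 <= self.hi_correlation <= 1.0:
            raise ValueError("|hi_correlation| must be <= 1")


def simulate_intensities(
    spec: IntensitySpec,
    n_cells: int,
    seed: int = 0,
    population: str = "sim",
) -> pd.DataFrame:
    """Draw per-cell two-channel intensities with planted hi/lo truth.

    Returns columns ``cell_id, population, ch1, ch2, truth_ch1, truth_ch2``
    where truth columns are the planted binary hi indicators.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(_derive_seed(seed, 0x1F7))
    p1, p2 = spec.ch1.hi_fraction, spec.ch2.hi_fraction
    q1, q2 = 1.0 - p1, 1.0 - p2
    # joint P(hi, hi) from the indicator correlation, clipped to feasibility
    p11 = p1 * p2 + spec.hi_correlation * np.sqrt(p1 * q1 * p2 * q2)
    lo_b, hi_b = max(0.0, p1 + p2 - 1.0), min(p1, p2)
    if p11 < lo_b - 1e-12 or p11 > hi_b + 1e-12:
        warnings.warn("hi_correlation infeasible for the hi fractions; clipped")
    p11 = float(np.clip(p11, lo_b, hi_b))
    probs = np.array([p11, p1 - p11, p2 - p11, 1.0 - p1 - p2 + p11])
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum()
    joint = rng.choice(4, size=n_cells, p=probs)  # 0=hh 1=hl 2=lh 3=ll
    hi1 = (joint == 0) | (joint == 1)
    hi2 = (joint == 0) | (joint == 2)

    def draw(ch: ChannelSpec, hi: np.ndarray) -> np.ndarray:
        mu = np.where(hi, ch.hi_logmean, ch.lo_logmean)
        sd = np.where(hi, ch.hi_logsd, ch.lo_logsd)
        return np.exp(rng.normal(mu, sd))

    return pd.DataFrame(
        {
            "cell_id": [f"{population}_{i:05d}" for i in range(n_cells)],
            "population": population,
            "ch1": draw(spec.ch1, hi1),
            "ch2": draw(spec.ch2, hi2),
            "truth_ch1": hi1.astype(int),
            "truth_ch2": hi2.astype(int),
        }
    )


def simulate_lda_wells(
    frequency: float,
    doses: Sequence[int] = (1, 10, 100, 1000),
    wells_per_dose: int = 24,
    seed: int = 0,
) -> pd.DataFrame:
    """Binomial well outcomes under the single-hit Poisson model.

    Each well seeded with ``d`` cells turns positive with probability
    ``1 - exp(-frequency * d)``.  Returns columns ``dose, wells, positive``.
    """
    if not 0.0 < frequency <= 1.0:
        raise ValueError("frequency must be in (0, 1]")
    if wells_per_dose < 1:
        raise ValueError("wells_per_dose must be >= 1")
    doses = np.asarray(doses, dtype=int)
    if np.any(doses < 1):
        raise ValueError("doses must be >= 1")
    rng = np.random.default_rng(_derive_seed(seed, 0x1DA))
    p = 1.0 - np.exp(-frequency * doses)
    positive = rng.binomial(wells_per_dose, p)
    return pd.DataFrame(
        {"dose": doses, "wells": wells_per_dose, "positive": positive}
    )


def simulate_phase_table(
    phase_probs: dict[tuple[str, str], Sequence[float]],
    n_cells: dict[tuple[str, str], int],
    seed: int = 0,
    phases: Sequence[str] = ("G0/G1", "S", "G2M"),
) -> pd.DataFrame:
    """Multinomial cluster x phase counts with planted phase probabilities.

    ``phase_probs`` maps (population, cluster) to a probability vector over
    ``phases``; ``n_cells`` gives the group sizes.  Returns long-format
    counts: ``population, cluster, phase, count``.
    """
    rng = np.random.default_rng(_derive_seed(seed, 0xCE11))
    rows = []
    for key in phase_probs:
        pop, cluster = key
        probs = np.asarray(phase_probs[key], dtype=float)
        if probs.shape != (len(phases),) or not np.isclose(probs.sum(), 1.0):
            raise ValueError(f"bad phase probabilities for group {key}")
        counts = rng.multinomial(n_cells[key], probs)
        for ph, c in zip(phases, counts):
            rows.append((pop, cluster, ph, int(c)))
    return pd.DataFrame(rows, columns=["population", "cluster", "phase", "count"])
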