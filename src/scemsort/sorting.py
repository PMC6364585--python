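"""Sorting measures, randomized-reassignment null, and sorting indices.

Sorting of a two-type aggregate is quantified by three measures: the mean
radius of type-1 cells about their own centre of mass (``X_r``, small
when type 1 gathers centrally), the number of type-1/type-1 neighbour
pairs in the cell contact graph (``X_n``), and the fraction of the free
(non-interfacial) cell surface contributed by type 2 (``X_s``).  Each
measure is standardised against a null distribution obtained by randomly
reassigning the type labels over cells -- keeping the spatial
configuration and the type counts fixed -- yielding the sorting index

    S = orientation * (X - E(X)) / (3 * sigma(X)),

which is ~0 for a randomly mixed aggregate and ~1 for a sorted one.  The
radius measure carries orientation -1 (sorted means *small* radius); the
neighbour and surface measures carry +1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cortex
from .core import Aggregate, InteractionTable, find_neighbours

__all__ = [
    "AggregateSnapshot",
    "SortingMeasures",
    "NullStats",
    "ORIENTATIONS",
    "cell_contact_graph",
    "summarize",
    "radius_measure",
    "neighbour_measure",
    "surface_measure",
    "measures",
    "randomized_null",
    "sorting_index",
    "sorting_indices",
    "sorting_report",
]

ORIENTATIONS = {"radius": -1.0, "neighbour": +1.0, "surface": +1.0}


class DegenerateNullError(ValueError):
    """Null distribution has zero spread; the index is undefined."""


@dataclass(frozen=True)
class AggregateSnapshot:
    """Geometry summary of a typed aggregate, sufficient for all measures.

    ``contacts`` is an (E, 2) array of cell-index pairs; ``free_area`` is
    the non-interfacial surface area per cell.  Instances come either
    from :func:`summarize` (simulation states) or from the synthetic
    fixture generator.
    """

    centres: np.ndarray
    types: np.ndarray
    contacts: np.ndarray
    free_area: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "centres",
                           np.asarray(self.centres, float).reshape(-1, 3))
        object.__setattr__(self, "types",
                           np.asarray(self.types, np.int8).reshape(-1))
        c = np.asarray(self.contacts, np.int64).reshape(-1, 2)
        object.__setattr__(self, "contacts", c)
        object.__setattr__(self, "free_area",
                           np.asarray(self.free_area, float).reshape(-1))
        n = len(self.centres)
        if len(self.types) != n or len(self.free_area) != n:
            raise ValueError("per-cell arrays must have equal length")
        if c.size and c.max() >= n:
            raise ValueError("contact pair refers to a missing cell")

    @property
    def n_cells(self) -> int:
        return len(self.centres)


@dataclass(frozen=True)
class SortingMeasures:
    X_r: float
    X_n: int
    X_s: float


@dataclass(frozen=True)
class NullStats:
    """Moments and range of one measure under label reassignment."""

    mean: float
    sd: float
    max: float
    min: float
    n_shuffles: int


def cell_contact_graph(agg: Aggregate, table: InteractionTable,
                       pairs: np.ndarray | None = None) -> np.ndarray:
    """Cell pairs with at least one element pair within interaction range.

    Two cells are neighbours as soon as any of their elements interact --
    even where the pair force is currently zero -- so the criterion is
    purely range-based.  Returns an (E, 2) array of cell-index pairs.
    """
    if pairs is None:
        pairs = find_neighbours(agg.positions, table.max_cutoff)
    if len(pairs) == 0:
        return np.empty((0, 2), dtype=np.int64)
    cp = np.sort(np.c_[agg.cell_ids[pairs[:, 0]],
                       agg.cell_ids[pairs[:, 1]]], axis=1)
    cp = cp[cp[:, 0] != cp[:, 1]]
    return np.unique(cp, axis=0)


def summarize(agg: Aggregate, table: InteractionTable) -> AggregateSnapshot:
    """Extract an :class:`AggregateSnapshot` from a simulation state."""
    _, free = cortex.interface_free_areas(agg)
    return AggregateSnapshot(centres=agg.cell_centres(),
                             types=agg.cell_types.copy(),
                             contacts=cell_contact_graph(agg, table),
                             free_area=free, time=agg.time)


# ---------------------------------------------------------------------------
# Measures
# ---------------------------------------------------------------------------

def _measures_vectorized(snap: AggregateSnapshot,
                         type1_masks: np.ndarray):
    """All three measures for a (S, C) boolean stack of type-1 masks."""
    M = type1_masks.astype(float)
    k = M.sum(axis=1)
    if np.any(k == 0):
        raise ValueError("every labelling needs at least one type-1 cell")
    centroids = (M @ snap.centres) / k[:, None]
    d = np.linalg.norm(snap.centres[None, :, :] - centroids[:, None, :],
                       axis=2)
    X_r = (M * d).sum(axis=1) / k
    if len(snap.contacts):
        e0, e1 = snap.contacts[:, 0], snap.contacts[:, 1]
        X_n = (type1_masks[:, e0] & type1_masks[:, e1]).sum(axis=1)
    else:
        X_n = np.zeros(len(M), dtype=int)
    total_free = snap.free_area.sum()
    if total_free <= 0:
        raise ValueError("aggregate has no free surface; the surface "
                         "measure is undefined")
    X_s = ((1.0 - M) @ snap.free_area) / total_free
    return X_r, X_n, X_s


def radius_measure(snap: AggregateSnapshot) -> float:
    """Mean distance of type-1 cells from the type-1 centre of mass."""
    if not np.any(snap.types == 1):
        raise ValueError("no type-1 cells; the radius measure is undefined")
    X_r, _, _ = _measures_vectorized(snap, (snap.types == 1)[None, :])
    return float(X_r[0])


def neighbour_measure(snap: AggregateSnapshot) -> int:
    """Number of contact-graph edges joining two type-1 cells."""
    if len(snap.contacts) == 0:
        return 0
    t1 = snap.types == 1
    return int((t1[snap.contacts[:, 0]] & t1[snap.contacts[:, 1]]).sum())


def surface_measure(snap: AggregateSnapshot) -> float:
    """Fraction of the aggregate's free surface contributed by type 2."""
    total = snap.free_area.sum()
    if total <= 0:
        raise ValueError("aggregate has no free surface; the surface "
                         "measure is undefined")
    return float(snap.free_area[snap.types == 2].sum() / total)


def measures(snap: AggregateSnapshot) -> SortingMeasures:
    return SortingMeasures(X_r=radius_measure(snap),
                           X_n=neighbour_measure(snap),
                           X_s=surface_measure(snap))


# ---------------------------------------------------------------------------
# Randomised-reassignment null
# ---------------------------------------------------------------------------

def randomized_null(snap: AggregateSnapshot, n_shuffles: int,
                    rng: np.random.Generator) -> dict[str, NullStats]:
    """Null statistics of all measures under random type reassignment.

    Each shuffle permutes the type labels over cells, preserving the
    spatial configuration and the number of each type, and recomputes the
    three measures.  Returns mean, sd, max and min per measure.  The
    snapshot itself is immutable and is returned to the caller untouched.
    """
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be >= 2")
    C = snap.n_cells
    k = int((snap.types == 1).sum())
    if k == 0 or k == C:
        raise ValueError("both cell types must be present")
    # ranks of C uniforms per row -> k smallest become type 1 (ties have
    # probability zero with float uniforms)
    u = rng.random((n_shuffles, C))
    masks = u <= np.partition(u, k - 1, axis=1)[:, k - 1][:, None]
    X_r, X_n, X_s = _measures_vectorized(snap, masks)
    out = {}
    for name, X in (("radius", X_r), ("neighbour", X_n), ("surface", X_s)):
        X = np.asarray(X, float)
        out[name] = NullStats(mean=float(X.mean()), sd=float(X.std()),
                              max=float(X.max()), min=float(X.min()),
                              n_shuffles=n_shuffles)
    return out


def sorting_index(X: float, null: NullStats, orientation: float) -> float:
    """Standardised sorting index ``orientation * (X - E) / (3 sd)``."""
    if null.sd <= 0:
        raise DegenerateNullError("null distribution has zero sd")
    return float(orientation * (X - null.mean) / (3.0 * null.sd))


def sorting_indices(snap: AggregateSnapshot, n_shuffles: int,
                    rng: np.random.Generator) -> dict[str, float]:
    """Convenience: measures + null + all three indices in one call."""
    m = measures(snap)
    null = randomized_null(snap, n_shuffles, rng)
    return {
        "S_r": sorting_index(m.X_r, null["radius"], ORIENTATIONS["radius"]),
        "S_n": sorting_index(m.X_n, null["neighbour"],
                             ORIENTATIONS["neighbour"]),
        "S_s": sorting_index(m.X_s, null["surface"],
                             ORIENTATIONS["surface"]),
    }


def sorting_report(snapshots, n_shuffles: int, rng: np.random.Generator,
                   tau_C: float | None = None) -> pd.DataFrame:
    """Per-snapshot measures, null moments and indices as a DataFrame."""
    rows = []
    for snap in snapshots:
        m = measures(snap)
        null = randomized_null(snap, n_shuffles, rng)
        row = {"T": snap.time, "n_cells": snap.n_cells,
               "X_r": m.X_r, "X_n": m.X_n, "X_s": m.X_s}
        if tau_C:
            row["T_over_tau_C"] = snap.time / tau_C
        for name, key, X in (("radius", "r", m.X_r),
                             ("neighbour", "n", m.X_n),
                             ("surface", "s", m.X_s)):
            ns = null[name]
            row[f"E_X{key}"] = ns.mean
            row[f"sd_X{key}"] = ns.sd
            row[f"S_{key}"] = sorting_index(X, ns, ORIENTATIONS[name])
        rows.append(row)
    return pd.DataFrame(rows)
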