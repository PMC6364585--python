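"""Cell growth and division: element insertion, plane splitting, growth runs.

Cells grow by stochastic insertion of cytoplasm elements near the centre
of mass, at a per-step rate calibrated so a cell's element count doubles
over one cell-cycle time ``tau_C``.  A cell that reaches its target
element count divides: its elements are partitioned by a uniformly random
plane through the centre of mass into two daughters.  Under symmetric
division both daughters inherit the parent type; under asymmetric
division each event has a 50% chance of producing two parent-type
daughters and a 50% chance of producing one daughter of each type.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import cortex
from .core import Aggregate, ModelParams, advance

__all__ = [
    "LifecycleParams",
    "seed_cell",
    "grow_cell",
    "divide_cell",
    "run_to_cell_count",
    "make_initial_aggregate",
]


@dataclass(frozen=True)
class LifecycleParams:
    tau_C: float = 40.0
    target_elements: int = 32
    division_mode: str = "asymmetric"  # or "symmetric"
    p_switch: float = 0.5
    start_at: int = 10
    stop_at: int = 30

    def __post_init__(self) -> None:
        if self.tau_C <= 0:
            raise ValueError("tau_C must be > 0")
        if not 0 <= self.p_switch <= 1:
            raise ValueError("p_switch must lie in [0, 1]")
        if self.division_mode not in ("symmetric", "asymmetric"):
            raise ValueError("division_mode must be symmetric or asymmetric")
        if self.target_elements < 8:
            raise ValueError("target_elements must be >= 8 so daughters "
                             "keep >= 4 elements")


def seed_cell(n_elements: int, params: ModelParams,
              rng: np.random.Generator, cell_type: int = 1,
              relax_steps: int = 600, min_sep: float = 0.7) -> Aggregate:
    """Create one relaxed cell.

    Elements are dart-thrown uniformly into a ball with a minimum mutual
    separation (so initial repulsive forces stay bounded), then relaxed
    under the full dynamics.
    """
    radius = 0.75 * n_elements ** (1.0 / 3.0)
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n_elements:
        cand = rng.uniform(-radius, radius, size=3)
        tries += 1
        if tries % 5000 == 0:
            radius *= 1.1  # loosen if packing is tight
        if np.dot(cand, cand) > radius * radius:
            continue
        if pts and np.min(np.linalg.norm(np.array(pts) - cand,
                                         axis=1)) < min_sep:
            continue
        pts.append(cand)
    agg = Aggregate(np.array(pts), np.zeros(n_elements, dtype=int),
                    [cell_type])
    advance(agg, params, rng, relax_steps)
    return agg


def grow_cell(agg: Aggregate, cid: int, lp: LifecycleParams,
              rng: np.random.Generator, offset_sd: float = 0.3) -> bool:
    """Insert one cytoplasm element near the cell's centre of mass.

    No-op (returns False) if the cell already holds its target count.  The
    insertion point is the centre of mass plus a small Gaussian offset, so
    the new element always starts inside the cortical hull.
    """
    idx = agg.cell_indices(cid)
    if len(idx) >= lp.target_elements:
        return False
    com = agg.positions[idx].mean(axis=0)
    # rejection-sample the offset so the newborn element does not land on
    # top of an existing one (which would blow up the repulsion)
    best, best_d = None, -1.0
    for _ in range(25):
        cand = com + rng.normal(0.0, offset_sd, size=3)
        dmin = np.linalg.norm(agg.positions - cand, axis=1).min()
        if dmin > best_d:
            best, best_d = cand, dmin
        if dmin >= 0.65:
            break
    new = best
    agg.positions = np.vstack([agg.positions, new])
    agg.cell_ids = np.append(agg.cell_ids, cid)
    agg.etypes = np.append(agg.etypes, np.uint8(0))
    agg.label_same = np.append(agg.label_same, False)
    agg.label_other = np.append(agg.label_other, False)
    agg.measure_contact = np.append(agg.measure_contact, False)
    agg.adhesion_factors = np.append(agg.adhesion_factors, 1.0)
    agg.invalidate()
    return True


def _daughter_types(parent_type: int, lp: LifecycleParams,
                    rng: np.random.Generator):
    if lp.division_mode == "symmetric":
        return parent_type, parent_type
    if rng.random() >= lp.p_switch:
        return parent_type, parent_type
    return (1, 2) if rng.random() < 0.5 else (2, 1)


def divide_cell(agg: Aggregate, cid: int, lp: LifecycleParams,
                rng: np.random.Generator, max_tries: int = 200) -> int:
    """Split a cell by a random plane through its centre of mass.

    Elements on the negative side move to a new cell appended to the
    aggregate; the parent keeps its id.  Planes leaving either daughter
    with fewer than 4 elements are redrawn.  Daughter types follow the
    division mode.  Returns the new cell id.  Element count is conserved.
    """
    idx = agg.cell_indices(cid)
    if len(idx) < 8:
        raise ValueError(f"cell {cid} too small to divide ({len(idx)})")
    com = agg.positions[idx].mean(axis=0)
    for _ in range(max_tries):
        normal = rng.normal(size=3)
        normal /= np.linalg.norm(normal)
        side = (agg.positions[idx] - com) @ normal
        neg = idx[side < 0]
        if 4 <= len(neg) <= len(idx) - 4:
            break
    else:
        raise RuntimeError(f"could not find a valid division plane for "
                           f"cell {cid}")
    new_cid = agg.n_cells
    agg.cell_ids[neg] = new_cid
    t1, t2 = _daughter_types(int(agg.cell_types[cid]), lp, rng)
    agg.cell_types[cid] = t1
    agg.cell_types = np.append(agg.cell_types, np.int8(t2))
    agg.invalidate()
    return new_cid


def run_to_cell_count(agg: Aggregate, params: ModelParams,
                      lp: LifecycleParams, rng: np.random.Generator,
                      observer=None, snapshot_every: float | None = None,
                      min_time: float = 0.0,
                      max_steps: int = 2_000_000) -> list:
    """Interleave dynamics, growth and division until ``stop_at`` cells.

    Immature cells insert elements at per-step probability
    ``n * ln2 * dt / tau_C`` (count doubles over one cycle); cells at
    their target count divide immediately while the aggregate is below
    ``stop_at``.  If ``observer`` is given it is called on the aggregate
    every ``snapshot_every`` time units (and once at the end); the list of
    its return values is returned.  ``min_time`` keeps pure dynamics
    running when no divisions are pending.
    """
    dt = params.dynamics.dt
    ln2 = math.log(2.0)
    snapshots = []
    next_snap = agg.time
    steps = 0
    while agg.n_cells < lp.stop_at or agg.time < min_time:
        if steps >= max_steps:
            raise RuntimeError(f"run_to_cell_count exceeded {max_steps} steps")
        counts = np.bincount(agg.cell_ids, minlength=agg.n_cells)
        for cid in range(agg.n_cells):
            if counts[cid] < lp.target_elements:
                if rng.random() < counts[cid] * ln2 * dt / lp.tau_C:
                    grow_cell(agg, cid, lp, rng)
            elif agg.n_cells < lp.stop_at:
                divide_cell(agg, cid, lp, rng)
        advance(agg, params, rng, 1)
        steps += 1
        if observer is not None and snapshot_every is not None \
                and agg.time >= next_snap:
            snapshots.append(observer(agg))
            next_snap = agg.time + snapshot_every
    if agg.network is None or agg.network_age is None:
        cortex.refresh(agg, params.table, params.cortex)
    if observer is not None:
        snapshots.append(observer(agg))
    return snapshots


def make_initial_aggregate(params: ModelParams, lp: LifecycleParams,
                           rng: np.random.Generator,
                           type_ratio: float = 0.5) -> Aggregate:
    """Grow a founder cell into a relaxed ``start_at``-cell aggregate.

    The founder grows with symmetric all-type-1 division up to
    ``lp.start_at`` cells; the two biological types are then assigned at
    random in the requested ratio (type-1 fraction).
    """
    agg = seed_cell(lp.target_elements // 2, params, rng)
    grow_lp = LifecycleParams(
        tau_C=lp.tau_C, target_elements=lp.target_elements,
        division_mode="symmetric", start_at=1, stop_at=lp.start_at)
    run_to_cell_count(agg, params, grow_lp, rng)
    # settle, then label
    advance(agg, params, rng, max(1, int(0.5 * lp.tau_C
                                         / params.dynamics.dt)))
    n1 = int(round(type_ratio * agg.n_cells))
    types = np.full(agg.n_cells, 2, dtype=np.int8)
    types[rng.permutation(agg.n_cells)[:n1]] = 1
    agg.cell_types = types
    agg.invalidate()
    cortex.refresh(agg, params.table, params.cortex)
    return agg
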