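"""Element-level mechanics: Morse interactions, neighbour search, Langevin stepping.

Each cell is a cloud of point elements interacting through short-ranged
Morse potentials.  Elements belonging to the same cell attract and repel
one another (bulk cohesion); elements in different cells always repel at
short range, and cortex elements of different cells additionally share an
adhesive attraction whose strength is set by the maximum attractive force
``A_M``.  Positions evolve by overdamped Langevin dynamics

    gamma * dx/dt = F(x) + zeta,

integrated with an explicit Euler--Maruyama step.  Reduced units are used
throughout: the drag coefficient ``gamma`` and the Morse equilibrium
separation ``re`` both equal 1, which fixes the time and length scales.
All forces (cortical tension ``gamma_m``, adhesion ``A_M``) are quoted in
these units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "CYTOPLASM",
    "CORTEX",
    "MorseParams",
    "InteractionTable",
    "DynamicsParams",
    "ModelParams",
    "Element",
    "Aggregate",
    "ConsistencyError",
    "StepSizeError",
    "morse_potential",
    "morse_force",
    "find_neighbours",
    "total_forces",
    "langevin_step",
    "advance",
]

# Element type codes (stored as a compact uint8 array on the aggregate).
CYTOPLASM = 0
CORTEX = 1


class ConsistencyError(RuntimeError):
    """Raised when forces are requested from a stale cortex network."""


class StepSizeError(RuntimeError):
    """Raised when a single step would move an element further than re/2."""


# ---------------------------------------------------------------------------
# Morse potential
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MorseParams:
    """Parameters of a Morse pair potential.

    Attributes
    ----------
    De : float
        Well depth; the potential tends to ``De`` at large separation in
        the zero-at-minimum convention used here.
    a : float
        Inverse interaction range.
    re : float
        Equilibrium separation (the minimum of the potential).
    cutoff : float
        Truncation radius.  ``numpy.inf`` disables truncation.  With a
        finite cutoff the potential is shift-truncated so that it is
        continuous (zero) at the cutoff; the force is simply zeroed there.
    """

    De: float
    a: float
    re: float = 1.0
    cutoff: float = np.inf

    def __post_init__(self) -> None:
        if self.De < 0:
            raise ValueError("Morse well depth De must be >= 0")
        if self.a <= 0 or self.re <= 0:
            raise ValueError("Morse a and re must be > 0")
        if self.cutoff <= self.re:
            raise ValueError("Morse cutoff must exceed re")


def _morse_raw_potential(r: np.ndarray, p: MorseParams) -> np.ndarray:
    d = np.exp(-p.a * (r - p.re))
    return p.De * (d * d - 2.0 * d + 1.0)


def morse_potential(r, p: MorseParams):
    """Morse pair potential ``De(e^{-2a(r-re)} - 2e^{-a(r-re)} + 1)``.

    The potential is zero at ``r = re`` and tends to ``De`` as ``r`` grows.
    With a finite ``p.cutoff`` the value is shifted by ``-V(cutoff)`` below
    the cutoff and is exactly zero beyond it, keeping the potential
    continuous at truncation.

    Parameters
    ----------
    r : float or array
        Pair separation(s); must be strictly positive.
    p : MorseParams

    Returns
    -------
    float or ndarray of the same shape as ``r``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("separation r must be > 0")
    v = _morse_raw_potential(r, p)
    if np.isfinite(p.cutoff):
        v = v - _morse_raw_potential(np.asarray(p.cutoff), p)
        v = np.where(r <= p.cutoff, v, 0.0)
    return v if v.ndim else float(v)


def morse_force(r, p: MorseParams):
    """Signed scalar Morse force ``-dV/dr`` (positive = repulsive).

    Positive for ``r < re`` (repulsion), negative for ``re < r < cutoff``
    (attraction), zero at ``re`` and beyond the cutoff.  The maximum
    attractive force ``a*De/2`` occurs at ``r = re + ln(2)/a``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("separation r must be > 0")
    d = np.exp(-p.a * (r - p.re))
    f = 2.0 * p.a * p.De * (d * d - d)
    if np.isfinite(p.cutoff):
        f = np.where(r <= p.cutoff, f, 0.0)
    return f if f.ndim else float(f)


# ---------------------------------------------------------------------------
# Interaction table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InteractionTable:
    """Pairwise interaction rules by element type and cell membership.

    Same-cell pairs interact through a Morse interaction whose repulsive
    branch comes from ``intra`` and whose attractive branch from
    ``cohesion`` (``intra`` itself when ``cohesion`` is None); splitting
    the branches lets element packing stay stiff while bulk cohesion -- a
    residual, beta-insensitive surface tension -- can be tuned
    independently.  Pairs in different cells always feel the repulsive
    branch of the ``repulsion`` potential only (cells exclude each other
    without sticking).  Cortex--cortex pairs in different cells
    additionally feel the attractive branch of a sharp adhesive Morse
    interaction whose well depth follows the maximum-attractive-force
    relation ``De = 2*A_M/a``: the printed adhesion magnitude ``A_M`` is
    exactly the peak attractive force of one pair, and the narrow well
    keeps the adhesive binding energy per unit area small against the
    cortical tension scale.
    """

    intra: MorseParams
    repulsion: MorseParams
    #: attractive branch of the same-cell interaction.  Splitting the two
    #: branches lets element packing stay stiff (``intra`` repulsion)
    #: while bulk cohesion -- which acts as a residual, beta-insensitive
    #: surface tension -- stays weak.  ``None`` means use ``intra`` for
    #: both branches.
    cohesion: MorseParams | None = None
    adhesion_a: float = 14.0
    adhesion_re: float = 1.0
    adhesion_cutoff: float = 1.6
    #: 2x2 symmetric matrix of maximum adhesive force by (type-1-indexed) pair.
    A_M: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))

    def __post_init__(self) -> None:
        A = np.asarray(self.A_M, dtype=float)
        if A.shape != (2, 2) or not np.allclose(A, A.T):
            raise ValueError("A_M must be a symmetric 2x2 matrix")
        if np.any(A < 0):
            raise ValueError("adhesion magnitudes must be >= 0")
        object.__setattr__(self, "A_M", A)

    def adhesive_params(self, type_a: int, type_b: int) -> MorseParams:
        """Adhesive Morse parameters for a pair of cell types (1 or 2)."""
        am = self.A_M[type_a - 1, type_b - 1]
        return MorseParams(De=2.0 * am / self.adhesion_a, a=self.adhesion_a,
                           re=self.adhesion_re, cutoff=self.adhesion_cutoff)

    def lookup(self, etype_a: int, etype_b: int, same_cell: bool):
        """Return ``(MorseParams, adhesive_flag)`` for an element pair.

        ``adhesive_flag`` marks inter-cell cortex--cortex pairs, which
        carry the additional A_M-scaled attraction; the returned params are
        the base (bulk/repulsive) interaction and are symmetric in the two
        element types.
        """
        if same_cell:
            return self.intra, False
        adhesive = etype_a == CORTEX and etype_b == CORTEX
        return self.repulsion, adhesive

    @property
    def max_cutoff(self) -> float:
        cuts = [self.adhesion_cutoff]
        for p in (self.intra, self.repulsion):
            if np.isfinite(p.cutoff):
                cuts.append(p.cutoff)
        return max(cuts)


@dataclass(frozen=True)
class DynamicsParams:
    """Overdamped Langevin parameters (drag, noise, step size, seed)."""

    gamma_drag: float = 1.0
    noise_amplitude: float = 1.0
    dt: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma_drag <= 0:
            raise ValueError("gamma_drag must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.noise_amplitude < 0:
            raise ValueError("noise_amplitude must be >= 0")


@dataclass(frozen=True)
class ModelParams:
    """Bundle of all mechanical parameters used by the integrated stepper.

    ``cortex`` is a :class:`scemsort.cortex.CortexParams`; it is typed
    loosely here to keep the module dependency one-way.
    """

    table: InteractionTable
    cortex: object
    dynamics: DynamicsParams
    #: cortex reallocation / retriangulation stride, in steps (1 = every step)
    realloc_stride: int = 1

    def with_(self, **kw) -> "ModelParams":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# Aggregate container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Element:
    """Read-only view of a single element (row of the aggregate arrays)."""

    position: np.ndarray
    etype: str  # "cytoplasm" | "cortex"
    cell_id: int
    interface_label: frozenset  # subset of {"same_type", "other_type"}


class Aggregate:
    """All cells and elements of a simulation, with derived caches.

    The engine is array-based: ``positions`` is ``(N, 3)`` float,
    ``etypes`` is ``(N,)`` uint8 (0 = cytoplasm, 1 = cortex), ``cell_ids``
    maps each element to a cell index ``0..n_cells-1`` and ``cell_types``
    holds the biological type (1 or 2) of each cell.  Derived state (the
    cortical tension network, interface labels and adhesion normalisation
    factors, owned by :mod:`scemsort.cortex`) is cached on the aggregate
    together with an age counter so the stepper can detect staleness.
    """

    def __init__(self, positions, cell_ids, cell_types, etypes=None, time=0.0):
        self.positions = np.array(positions, dtype=float).reshape(-1, 3)
        n = len(self.positions)
        self.cell_ids = np.array(cell_ids, dtype=np.int64).reshape(n)
        self.cell_types = np.array(cell_types, dtype=np.int8).reshape(-1)
        if self.cell_ids.size and self.cell_ids.max() >= len(self.cell_types):
            raise ValueError("cell_ids refer to a missing cell")
        if np.any((self.cell_types != 1) & (self.cell_types != 2)):
            raise ValueError("cell types must be 1 or 2")
        if etypes is None:
            etypes = np.zeros(n, dtype=np.uint8)
        self.etypes = np.array(etypes, dtype=np.uint8).reshape(n)
        self.time = float(time)
        # derived caches, maintained by scemsort.cortex.refresh
        self.network = None
        self.label_same = np.zeros(n, dtype=bool)
        self.label_other = np.zeros(n, dtype=bool)
        self.measure_contact = np.zeros(n, dtype=bool)
        self.adhesion_factors = np.ones(n, dtype=float)
        self.network_age = None  # None = never refreshed

    # -- basic queries ------------------------------------------------
    @property
    def n_elements(self) -> int:
        return len(self.positions)

    @property
    def n_cells(self) -> int:
        return len(self.cell_types)

    def cell_indices(self, cid: int) -> np.ndarray:
        return np.flatnonzero(self.cell_ids == cid)

    def centre_of_mass(self, cid: int) -> np.ndarray:
        idx = self.cell_indices(cid)
        if idx.size == 0:
            raise ValueError(f"cell {cid} has no elements")
        return self.positions[idx].mean(axis=0)

    def cell_centres(self) -> np.ndarray:
        """Per-cell centre of mass (unweighted element mean), shape (C, 3)."""
        out = np.zeros((self.n_cells, 3))
        counts = np.bincount(self.cell_ids, minlength=self.n_cells).astype(float)
        for k in range(3):
            out[:, k] = np.bincount(self.cell_ids, weights=self.positions[:, k],
                                    minlength=self.n_cells)
        if np.any(counts == 0):
            raise ValueError("every cell must own at least one element")
        return out / counts[:, None]

    def element(self, i: int) -> Element:
        labels = set()
        if self.label_same[i]:
            labels.add("same_type")
        if self.label_other[i]:
            labels.add("other_type")
        return Element(
            position=self.positions[i].copy(),
            etype="cortex" if self.etypes[i] == CORTEX else "cytoplasm",
            cell_id=int(self.cell_ids[i]),
            interface_label=frozenset(labels),
        )

    def copy(self) -> "Aggregate":
        agg = Aggregate(self.positions.copy(), self.cell_ids.copy(),
                        self.cell_types.copy(), self.etypes.copy(), self.time)
        agg.network = self.network
        agg.label_same = self.label_same.copy()
        agg.label_other = self.label_other.copy()
        agg.measure_contact = self.measure_contact.copy()
        agg.adhesion_factors = self.adhesion_factors.copy()
        agg.network_age = self.network_age
        return agg

    def invalidate(self) -> None:
        """Drop derived caches after a structural change (growth/division)."""
        self.network = None
        self.network_age = None


# ---------------------------------------------------------------------------
# Neighbour search
# ---------------------------------------------------------------------------

def find_neighbours(positions, cutoff: float) -> np.ndarray:
    """All unordered index pairs with separation <= cutoff, as an (M, 2) array.

    Backed by a k-d tree; each pair appears exactly once with i < j.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    positions = np.asarray(positions, dtype=float)
    if len(positions) < 2:
        return np.empty((0, 2), dtype=np.int64)
    tree = cKDTree(positions)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if pairs.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    return np.sort(pairs.astype(np.int64), axis=1)


# ---------------------------------------------------------------------------
# Force assembly
# ---------------------------------------------------------------------------

def _scatter_pair_forces(n, i, j, fmag, unit) -> np.ndarray:
    """Accumulate signed scalar pair forces into per-element 3-vectors.

    ``unit`` points from j to i; a positive ``fmag`` therefore pushes the
    pair apart.  Pairwise antisymmetry (Newton's third law) is exact by
    construction, so internal forces always sum to zero.
    """
    forces = np.zeros((n, 3))
    contrib = fmag[:, None] * unit
    for k in range(3):
        forces[:, k] = (np.bincount(i, weights=contrib[:, k], minlength=n)
                        - np.bincount(j, weights=contrib[:, k], minlength=n))
    return forces


def total_forces(agg: Aggregate, table: InteractionTable,
                 pairs: np.ndarray | None = None,
                 max_network_age: int | None = None) -> np.ndarray:
    """Sum all mechanical forces on every element, shape (N, 3).

    Contributions: (i) intra-cell Morse forces, (ii) inter-cell repulsion
    for every pair plus density-normalised adhesive attraction for
    cortex--cortex pairs, (iii) constant-magnitude cortical tension along
    the edges of the triangulated cortex network (with the interfacial
    factor beta already folded into the cached per-edge magnitudes).

    Raises :class:`ConsistencyError` if the cortex network has never been
    built or is older than ``max_network_age`` steps.
    """
    if agg.network is None or agg.network_age is None:
        raise ConsistencyError("cortex network has not been built; "
                               "call scemsort.cortex.refresh first")
    if max_network_age is not None and agg.network_age > max_network_age:
        raise ConsistencyError(
            f"cortex network is {agg.network_age} steps old "
            f"(allowed {max_network_age})")

    n = agg.n_elements
    if pairs is None:
        pairs = find_neighbours(agg.positions, table.max_cutoff)
    if len(pairs) == 0:
        fmag = np.empty(0)
        forces = np.zeros((n, 3))
    else:
        i, j = pairs[:, 0], pairs[:, 1]
        dvec = agg.positions[i] - agg.positions[j]
        r = np.linalg.norm(dvec, axis=1)
        r = np.maximum(r, 1e-12)
        unit = dvec / r[:, None]

        same = agg.cell_ids[i] == agg.cell_ids[j]
        fmag = np.zeros(len(pairs))

        # (i) same-cell interaction: stiff repulsive branch plus (weaker)
        # attractive cohesion branch
        if np.any(same):
            frep = np.maximum(morse_force(r[same], table.intra), 0.0)
            coh = table.cohesion if table.cohesion is not None \
                else table.intra
            fatt = np.minimum(morse_force(r[same], coh), 0.0)
            fmag[same] = frep + fatt

        inter = ~same
        if np.any(inter):
            # (ii a) repulsive-only baseline between cells
            frep = morse_force(r[inter], table.repulsion)
            fmag[inter] = np.maximum(frep, 0.0)
            # (ii b) adhesive Morse interaction between cortex elements
            # of different cells, scaled by the local-density factors
            cortex_pair = (inter & (agg.etypes[i] == CORTEX)
                           & (agg.etypes[j] == CORTEX))
            if np.any(cortex_pair):
                ic, jc = i[cortex_pair], j[cortex_pair]
                ta = agg.cell_types[agg.cell_ids[ic]]
                tb = agg.cell_types[agg.cell_ids[jc]]
                am = table.A_M[ta - 1, tb - 1]
                De = 2.0 * am / table.adhesion_a
                d = np.exp(-table.adhesion_a * (r[cortex_pair]
                                                - table.adhesion_re))
                fad = 2.0 * table.adhesion_a * De * (d * d - d)
                # attractive branch only: the peak pull is exactly A_M;
                # hard-core exclusion is the bulk repulsion's job
                fad = np.minimum(fad, 0.0)
                fad[r[cortex_pair] > table.adhesion_cutoff] = 0.0
                fad *= (agg.adhesion_factors[ic] * agg.adhesion_factors[jc])
                fmag[cortex_pair] += fad
        forces = _scatter_pair_forces(n, i, j, fmag, unit)

    # (iii) cortical tension edges (constant magnitude, attractive)
    forces += agg.network.tension_forces(agg.positions, n)
    return forces


# ---------------------------------------------------------------------------
# Time stepping
# ---------------------------------------------------------------------------

def langevin_step(agg: Aggregate, forces: np.ndarray, dp: DynamicsParams,
                  rng: np.random.Generator) -> Aggregate:
    """Advance positions by one overdamped Euler--Maruyama step, in place.

    ``x <- x + (dt/gamma) (F + zeta)`` with ``zeta`` i.i.d. Gaussian of
    standard deviation ``noise_amplitude`` per component.  A guard rejects
    steps that would displace any element by more than ``re/2`` (with
    ``re = 1`` in reduced units), which indicates an unstable step size.
    """
    kick = forces
    if dp.noise_amplitude > 0:
        kick = forces + rng.normal(0.0, dp.noise_amplitude,
                                   size=forces.shape)
    disp = (dp.dt / dp.gamma_drag) * kick
    dmax = float(np.max(np.abs(disp))) if disp.size else 0.0
    if dmax >= 0.5:
        raise StepSizeError(
            f"max per-step displacement {dmax:.3g} >= re/2; "
            f"reduce dt (currently {dp.dt}) or check forces")
    agg.positions += disp
    agg.time += dp.dt
    if agg.network_age is not None:
        agg.network_age += 1
    return agg


def advance(agg: Aggregate, params: ModelParams, rng: np.random.Generator,
            n_steps: int) -> Aggregate:
    """Run ``n_steps`` of dynamics, refreshing the cortex machinery on the
    configured stride.  Mutates and returns ``agg``."""
    from . import cortex  # local import keeps core importable standalone

    stride = max(1, params.realloc_stride)
    dp = params.dynamics
    for s in range(n_steps):
        if agg.network is None or agg.network_age is None \
                or agg.network_age >= stride:
            cortex.refresh(agg, params.table, params.cortex)
        forces = total_forces(agg, params.table, max_network_age=stride)
        try:
            langevin_step(agg, forces, dp, rng)
        except StepSizeError:
            # rare contact spike (e.g. a freshly inserted element landing
            # close to a neighbour): resolve it with refined sub-steps,
            # recomputing forces each time; a genuine blow-up still raises
            sub = replace(dp, dt=dp.dt / 10.0)
            for _ in range(10):
                cortex.refresh(agg, params.table, params.cortex)
                forces = total_forces(agg, params.table,
                                      max_network_age=stride)
                langevin_step(agg, forces, sub, rng)
    return agg
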