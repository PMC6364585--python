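"""Synthetic labelled aggregates and geometric doublet fixtures.

These generators build aggregate-like objects directly from geometry --
no dynamics involved -- so the sorting-analysis machinery can be
exercised (and its estimators calibrated) on configurations whose ground
truth is known by construction.
"""

from __future__ import annotations

import numpy as np

from .core import Aggregate
from .sorting import AggregateSnapshot

__all__ = [
    "generate_labelled_aggregate",
    "synthetic_truncated_doublet",
]


def _pack_centres(n: int, rng: np.random.Generator,
                  spacing: float = 2.0, iters: int = 400) -> np.ndarray:
    """Pack n points into a compact blob with pair distance ~ spacing.

    Soft-sphere relaxation: overlapping pairs repel, a weak central pull
    keeps the cloud compact.  Deterministic given the generator state.
    """
    radius = 0.6 * spacing * n ** (1.0 / 3.0)
    pos = rng.normal(scale=radius, size=(n, 3))
    for _ in range(iters):
        d = pos[:, None, :] - pos[None, :, :]
        r = np.linalg.norm(d, axis=2)
        np.fill_diagonal(r, np.inf)
        overlap = np.maximum(spacing - r, 0.0)
        push = (overlap / r)[:, :, None] * d
        pos += 0.3 * push.sum(axis=1)
        pos -= 0.04 * pos  # central pull
    return pos


def generate_labelled_aggregate(n_cells: int, type_ratio: float = 0.5,
                                arrangement: str = "shuffled",
                                rng: np.random.Generator | None = None,
                                cell_radius: float = 1.0
                                ) -> AggregateSnapshot:
    """Geometrically plausible packed aggregate with typed cells.

    ``arrangement`` controls the label pattern: ``shuffled`` assigns
    types at random, ``sorted`` places type 1 on the cells closest to the
    aggregate centroid (inside-out sorted), and ``shell`` inverts that
    (type 1 outside).  ``type_ratio`` is the type-1 fraction.  Contacts
    join cells closer than 1.15 cell diameters; the free area per cell is
    a sphere area minus one kissing-number patch per contact, so interior
    (high-degree) cells contribute little free surface.
    """
    if n_cells < 2:
        raise ValueError("need at least 2 cells")
    k1 = int(round(type_ratio * n_cells))
    if not 0 < k1 < n_cells:
        if type_ratio in (0.0, 1.0):  # single-type aggregate is allowed
            k1 = int(round(type_ratio * n_cells))
        else:
            raise ValueError(f"type_ratio {type_ratio} infeasible for "
                             f"{n_cells} cells")
    rng = np.random.default_rng() if rng is None else rng
    spacing = 2.0 * cell_radius
    centres = _pack_centres(n_cells, rng, spacing=spacing)
    centres -= centres.mean(axis=0)

    d = np.linalg.norm(centres[:, None] - centres[None, :], axis=2)
    iu = np.triu_indices(n_cells, 1)
    touching = d[iu] < 1.15 * spacing
    contacts = np.c_[iu[0][touching], iu[1][touching]]

    area = 4.0 * np.pi * cell_radius ** 2
    degree = np.bincount(contacts.ravel(), minlength=n_cells)
    free = np.maximum(area - degree * area / 12.0, 0.02 * area)

    r = np.linalg.norm(centres, axis=1)
    types = np.full(n_cells, 2, dtype=np.int8)
    if arrangement == "shuffled":
        types[rng.permutation(n_cells)[:k1]] = 1
    elif arrangement == "sorted":
        types[np.argsort(r)[:k1]] = 1
    elif arrangement == "shell":
        types[np.argsort(r)[::-1][:k1]] = 1
    else:
        raise ValueError(f"unknown arrangement {arrangement!r}")
    return AggregateSnapshot(centres=centres, types=types,
                             contacts=contacts, free_area=free)


# ---------------------------------------------------------------------------
# Truncated-sphere doublet (known interface proportion by construction)
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    polar = np.arccos(1.0 - 2.0 * k / n)
    azim = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.c_[np.cos(azim) * np.sin(polar),
                 np.sin(azim) * np.sin(polar), np.cos(polar)]


def _sunflower_disc(n: int, radius: float) -> np.ndarray:
    k = np.arange(n) + 0.5
    rr = radius * np.sqrt(k / n)
    azim = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.c_[rr * np.cos(azim), rr * np.sin(azim), np.zeros(n)]


def synthetic_truncated_doublet(beta: float, R: float = 1.5,
                                spacing: float = 0.85,
                                gap: float = 1.0) -> Aggregate:
    """Two truncated-sphere shells at the force-balance contact angle.

    The contact angle satisfies ``cos(theta/2) = beta``; each cell is a
    spherical shell of radius ``R`` with the facing cap removed, plus a
    flat interface disc, with the two discs ``gap`` apart.  The exact
    interface proportion of the continuum shape is ``(1-beta)/(3-beta)``,
    which makes this fixture the ground truth for calibrating and testing
    the interface-area estimator.  Elements are placed at roughly uniform
    ``spacing`` on both parts.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")
    c = beta
    cell_area = 0.866 * spacing ** 2
    n_sphere = int(round(4.0 * np.pi * R ** 2 / cell_area))
    sphere = _fibonacci_sphere(n_sphere) * R
    a = R * np.sqrt(max(1.0 - c * c, 1e-12))
    n_disc = max(3, int(round(np.pi * a * a / cell_area)))
    parts, owners = [], []
    for sgn in (-1, +1):
        centre_z = sgn * (R * c + gap / 2.0)
        free = sphere[-sgn * sphere[:, 2] < R * c] + [0, 0, centre_z]
        disc = _sunflower_disc(n_disc, a) + [0, 0, sgn * gap / 2.0]
        pts = np.vstack([free, disc])
        parts.append(pts)
        owners.append(np.full(len(pts), 0 if sgn < 0 else 1))
    return Aggregate(np.vstack(parts), np.concatenate(owners), [1, 1])
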