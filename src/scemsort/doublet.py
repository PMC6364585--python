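"""Cell-doublet experiments: interface proportion and the force-balance model.

A doublet is made the way aggregates make them: one cell divides into two
identical daughters, which then relax to mechanical equilibrium without
growth.  The cell--cell interface area is the summed area of all surface
triangles whose three vertex elements each interact (within the adhesive
interaction range) with the neighbouring cell, and the interface
proportion ``I_P`` is that area divided by the total surface area of both
cells.

The analytic benchmark is the linear force balance (LFB) model of the
doublet vertex: with interfacial-to-cortical tension ratio
``beta = gamma_c / gamma_m`` and adhesion neglected, the contact angle
obeys ``beta = cos(theta/2)`` and the interface proportion is
``I_P = (1 - beta) / (3 - beta)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cortex
from .core import Aggregate, ModelParams, advance
from .lifecycle import LifecycleParams, divide_cell, seed_cell
from .runio import make_model_params

logger = logging.getLogger(__name__)

__all__ = [
    "DoubletResult",
    "lfb_interface_proportion",
    "lfb_beta_from_angle",
    "make_doublet",
    "measure_interface_proportion",
    "run_doublet",
    "scan_phase_diagram",
]


# ---------------------------------------------------------------------------
# Linear force balance model
# ---------------------------------------------------------------------------

def lfb_interface_proportion(beta: float) -> float:
    """LFB prediction ``I_P = (1 - beta) / (3 - beta)`` for ``beta`` in [0, 1].

    Equals 1/3 at beta = 0 (two hemispheres) and 0 at beta = 1 (tangent
    spheres).
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must lie in [0, 1], got {beta}")
    return (1.0 - beta) / (3.0 - beta)


def lfb_beta_from_angle(theta: float) -> float:
    """Tension ratio from the doublet contact angle: ``beta = cos(theta/2)``."""
    if not 0.0 <= theta <= np.pi:
        raise ValueError(f"theta must lie in [0, pi], got {theta}")
    return float(np.cos(theta / 2.0))


# ---------------------------------------------------------------------------
# Simulated doublets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoubletResult:
    I_P: float
    interface_area: float
    total_surface_area: float
    beta: float
    A_M: float
    gamma_m: float
    converged: bool = True

    @property
    def alpha(self) -> float:
        return self.A_M / self.gamma_m if self.gamma_m > 0 else np.inf


def measure_interface_proportion(agg: Aggregate,
                                 params: ModelParams) -> DoubletResult:
    """Instantaneous interface proportion of a (refreshed) doublet."""
    interface, free = cortex.interface_free_areas(agg)
    total = float(interface.sum() + free.sum())
    iface = float(interface.sum())
    return DoubletResult(
        I_P=iface / total if total > 0 else 0.0,
        interface_area=iface, total_surface_area=total,
        beta=float(params.cortex.beta[0, 0]),
        A_M=float(params.table.A_M[0, 0]),
        gamma_m=float(params.cortex.gamma_m))


def make_doublet(params: ModelParams, rng: np.random.Generator, *,
                 n_elements_per_cell: int = 32, seed_relax_steps: int = 500,
                 window_steps: int = 400, sample_every: int = 10,
                 min_windows: int = 4, max_windows: int = 15,
                 rel_tol: float = 0.01):
    """Divide one cell into two and relax to mechanical equilibrium.

    The parent holds twice the per-cell element count; after the division
    the doublet relaxes in windows of ``window_steps`` steps, sampling
    ``I_P`` every ``sample_every`` steps.  Relaxation stops when the
    windowed mean of ``I_P`` changes by less than ``rel_tol`` (relative,
    with a small absolute floor) between consecutive windows.  Returns
    ``(aggregate, I_P_window_mean, converged)``; the reported value is the
    final-window mean.  Cells separating at zero adhesion is a valid
    outcome (``I_P = 0``), not an error.
    """
    agg = seed_cell(2 * n_elements_per_cell, params, rng,
                    relax_steps=seed_relax_steps)
    divide_cell(agg, 0, LifecycleParams(division_mode="symmetric",
                                        target_elements=8), rng)
    prev_mean = None
    converged = False
    mean = 0.0
    for _ in range(max_windows):
        samples = []
        for _ in range(window_steps // sample_every):
            advance(agg, params, rng, sample_every)
            samples.append(measure_interface_proportion(agg, params).I_P)
        mean = float(np.mean(samples))
        if prev_mean is not None:
            if abs(mean - prev_mean) < max(rel_tol * abs(prev_mean), 0.005):
                converged = True
                if _ + 1 >= min_windows:
                    break
        prev_mean = mean
    return agg, mean, converged


def run_doublet(beta: float, A_M: float, gamma_m: float, *, seed: int,
                n_elements_per_cell: int = 32, **relax_kw) -> DoubletResult:
    """End-to-end doublet experiment for one parameter point and seed."""
    params = make_model_params(beta=beta, A_M=A_M, gamma_m=gamma_m,
                               seed=seed)
    rng = np.random.default_rng(seed)
    agg, ip, converged = make_doublet(
        params, rng, n_elements_per_cell=n_elements_per_cell, **relax_kw)
    final = measure_interface_proportion(agg, params)
    return DoubletResult(I_P=ip, interface_area=final.interface_area,
                         total_surface_area=final.total_surface_area,
                         beta=beta, A_M=A_M, gamma_m=gamma_m,
                         converged=converged)


def scan_phase_diagram(betas, A_Ms, gamma_ms, seeds, *,
                       n_elements_per_cell: int = 32,
                       **relax_kw) -> pd.DataFrame:
    """Doublet experiments over a full (beta, A_M, gamma_m) x seed grid.

    One row per run, with an ``error`` column recording individual
    failures (the scan continues past them).
    """
    rows = []
    for beta in np.atleast_1d(betas):
        for am in np.atleast_1d(A_Ms):
            for gm in np.atleast_1d(gamma_ms):
                for seed in np.atleast_1d(seeds):
                    row = {"beta": float(beta), "A_M": float(am),
                           "gamma_m": float(gm), "seed": int(seed),
                           "alpha": float(am / gm) if gm > 0 else np.inf,
                           "I_P": np.nan, "converged": False, "error": ""}
                    try:
                        res = run_doublet(
                            float(beta), float(am), float(gm),
                            seed=int(seed),
                            n_elements_per_cell=n_elements_per_cell,
                            **relax_kw)
                        row.update(I_P=res.I_P, converged=res.converged)
                    except Exception as exc:  # noqa: BLE001 - scan survives
                        row["error"] = f"{type(exc).__name__}: {exc}"
                        logger.warning("doublet run failed at %s: %s",
                                       row, exc)
                    rows.append(row)
    return pd.DataFrame(rows)
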