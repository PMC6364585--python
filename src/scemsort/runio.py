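"""Run configuration, parameter presets, logging and trajectory I/O."""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (Aggregate, DynamicsParams, InteractionTable, ModelParams,
                   MorseParams)
from .cortex import CortexParams

logger = logging.getLogger("scemsort")

__all__ = [
    "SCHEMA_VERSION",
    "PRESETS",
    "SchemaVersionError",
    "RunConfig",
    "make_model_params",
    "write_trajectory",
    "read_trajectory",
    "export_off",
    "setup_logging",
]

SCHEMA_VERSION = 1

# Scale presets: element counts and shuffle counts for desk-scale testing
# versus production-quality runs.
PRESETS = {
    "test": {"elements_per_cell": 32, "n_shuffles": 1_000},
    "production": {"elements_per_cell": 128, "n_shuffles": 10_000},
}


class SchemaVersionError(RuntimeError):
    """Trajectory file schema does not match this package version."""


def _beta_matrix(beta) -> np.ndarray:
    """Scalar beta means: vary the type-1/type-1 factor, all others 1."""
    if np.ndim(beta) == 0:
        B = np.ones((2, 2))
        B[0, 0] = float(beta)
        return B
    return np.asarray(beta, dtype=float)


def _adhesion_matrix(A_M) -> np.ndarray:
    if np.ndim(A_M) == 0:
        return np.full((2, 2), float(A_M))
    return np.asarray(A_M, dtype=float)


def make_model_params(beta=1.0, A_M=0.0, gamma_m=1.0, *,
                      De_intra=0.05, De_cohesion=0.05, a=4.0, re=1.0, cutoff=2.5,
                      adhesion_a=14.0, adhesion_re=1.0, adhesion_cutoff=1.6,
                      dt=0.01, noise_amplitude=1.0, gamma_drag=1.0,
                      seed=0, realloc_stride=1) -> ModelParams:
    """Assemble a full mechanical parameter set from headline knobs.

    ``beta`` may be a scalar (interpreted as the type-1/type-1 interfacial
    tension factor, all other factors 1 -- the convention used for the
    sorting phase diagrams) or a full symmetric 2x2 matrix.  ``A_M`` may
    likewise be a scalar (all cell-type pairs adhere equally) or a 2x2
    matrix for differential-adhesion runs.  All values are in reduced
    units (drag = 1, Morse equilibrium separation = 1).

    The adhesive well is sharp (``adhesion_a = 14``): with the well depth
    tied to the peak force by ``De = 2 A_M / a``, sharpness is what keeps
    the adhesive binding energy per unit area small against the cortical
    tension scale, so adhesion acts as a contact zipper rather than a
    surface energy of its own.  Interface labelling and measurement apply
    their own distance/facing gates (see
    :class:`scemsort.cortex.CortexParams`).
    """
    intra = MorseParams(De=De_intra, a=a, re=re, cutoff=cutoff)
    cohesion = MorseParams(De=De_cohesion, a=a, re=re, cutoff=cutoff)
    table = InteractionTable(intra=intra, repulsion=intra,
                             cohesion=cohesion,
                             adhesion_a=adhesion_a, adhesion_re=adhesion_re,
                             adhesion_cutoff=adhesion_cutoff,
                             A_M=_adhesion_matrix(A_M))
    cp = CortexParams(gamma_m=gamma_m, beta=_beta_matrix(beta))
    dp = DynamicsParams(gamma_drag=gamma_drag,
                        noise_amplitude=noise_amplitude, dt=dt, seed=seed)
    return ModelParams(table=table, cortex=cp, dynamics=dp,
                       realloc_stride=realloc_stride)


@dataclass
class RunConfig:
    """Structured-text run configuration with full parameter echo."""

    seed: int
    scale: str = "test"
    beta: float = 1.0
    A_M: float = 0.0
    gamma_m: float = 1.0
    tau_C: float = 40.0
    start_at: int = 10
    stop_at: int = 30
    division_mode: str = "asymmetric"
    type_ratio: float = 0.5
    snapshot_every: float = 10.0
    out_dir: str = "runs"
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale not in PRESETS:
            raise ValueError(f"unknown scale preset {self.scale!r}")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        if "seed" not in data:
            raise ValueError("config must set a seed")
        known = {f.name for f in dataclasses.fields(cls)} - {"overrides"}
        kwargs = {k: v for k, v in data.items() if k in known}
        kwargs["overrides"] = {k: v for k, v in data.items()
                               if k not in known}
        return cls(**kwargs)

    @property
    def elements_per_cell(self) -> int:
        return self.overrides.get("elements_per_cell",
                                  PRESETS[self.scale]["elements_per_cell"])

    @property
    def n_shuffles(self) -> int:
        return self.overrides.get("n_shuffles",
                                  PRESETS[self.scale]["n_shuffles"])

    def model_params(self) -> ModelParams:
        keys = ("De_intra", "De_cohesion", "a", "re", "cutoff", "adhesion_a",
                "adhesion_cutoff", "dt", "noise_amplitude", "gamma_drag",
                "realloc_stride")
        extra = {k: self.overrides[k] for k in keys if k in self.overrides}
        return make_model_params(beta=self.beta, A_M=self.A_M,
                                 gamma_m=self.gamma_m, seed=self.seed,
                                 **extra)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["elements_per_cell"] = self.elements_per_cell
        d["n_shuffles"] = self.n_shuffles
        return d

    def echo(self, log: logging.Logger = logger) -> None:
        for key, val in sorted(self.to_dict().items()):
            log.info("config %s = %r", key, val)


def setup_logging(logfile=None, level=logging.INFO) -> None:
    handlers = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=level, handlers=handlers, force=True,
        format="%(asctime)s %(name)s %(levelname)s %(message)s")


# ---------------------------------------------------------------------------
# Trajectory I/O (columnar CSV with a versioned header)
# ---------------------------------------------------------------------------

_COLUMNS = ["snapshot", "t", "element", "cell", "cell_type", "etype",
            "x", "y", "z"]


def _snapshot_frame(k: int, agg: Aggregate) -> pd.DataFrame:
    return pd.DataFrame({
        "snapshot": k,
        "t": agg.time,
        "element": np.arange(agg.n_elements),
        "cell": agg.cell_ids,
        "cell_type": agg.cell_types[agg.cell_ids],
        "etype": agg.etypes,
        "x": agg.positions[:, 0],
        "y": agg.positions[:, 1],
        "z": agg.positions[:, 2],
    })


def write_trajectory(path, snapshots, config: dict | None = None) -> None:
    """Write aggregates as a versioned columnar CSV (lossless round trip)."""
    path = Path(path)
    frames = [_snapshot_frame(k, agg) for k, agg in enumerate(snapshots)]
    table = (pd.concat(frames, ignore_index=True) if frames
             else pd.DataFrame(columns=_COLUMNS))
    meta = {"schema": SCHEMA_VERSION, "config": config or {}}
    with open(path, "w") as fh:
        fh.write(f"# scemsort-trajectory {json.dumps(meta)}\n")
        table.to_csv(fh, index=False)


def read_trajectory(path):
    """Read back a trajectory written by :func:`write_trajectory`.

    Returns ``(snapshots, config)`` where snapshots is a list of
    :class:`Aggregate`.  Raises :class:`SchemaVersionError` on a header or
    version mismatch.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# scemsort-trajectory "):
            raise SchemaVersionError(f"{path}: not a scemsort trajectory")
        meta = json.loads(header[len("# scemsort-trajectory "):])
        if meta.get("schema") != SCHEMA_VERSION:
            raise SchemaVersionError(
                f"{path}: schema {meta.get('schema')} != {SCHEMA_VERSION}")
        table = pd.read_csv(fh, float_precision="round_trip")
    snapshots = []
    for _, sub in table.groupby("snapshot", sort=True):
        cell_ids = sub["cell"].to_numpy()
        n_cells = cell_ids.max() + 1 if len(cell_ids) else 0
        cell_types = np.ones(n_cells, dtype=np.int8)
        cell_types[cell_ids] = sub["cell_type"].to_numpy()
        agg = Aggregate(sub[["x", "y", "z"]].to_numpy(), cell_ids,
                        cell_types, sub["etype"].to_numpy(),
                        time=float(sub["t"].iloc[0]))
        snapshots.append(agg)
    return snapshots, meta["config"]


def export_off(path, agg: Aggregate) -> None:
    """Export the current cortical meshes of all cells as one OFF file."""
    if agg.network is None:
        raise RuntimeError("no tension network to export; refresh first")
    facets = [m.facets for m in agg.network.meshes.values()]
    facets = (np.concatenate(facets) if facets
              else np.empty((0, 3), dtype=int))
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{agg.n_elements} {len(facets)} 0\n")
        for p in agg.positions:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        for f in facets:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
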