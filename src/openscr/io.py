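"""File formats and reproducibility plumbing.

Traps travel as a CSV with columns ``trap_id,x,y`` plus either a single
``K`` column (uniform effort) or ``K_t1..K_tT`` columns (per-period
effort, which accommodates expanding camera-trap designs).  Detections
use a long/tidy CSV ``individual_id,trap_id,period,count`` with 1-based
periods, which stays diff-friendly and supports ragged trap deployment.
Posterior draws and summaries are plain CSV; manifests are JSON and carry
everything needed to replay a run bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import EncounterData, StateSpace, TrapArray
from .simulate import SimulatedDataset

__all__ = [
    "read_traps",
    "read_detections",
    "write_traps",
    "write_detections",
    "write_dataset",
    "RunManifest",
]


class ParseError(ValueError):
    pass


def read_traps(path, T: int | None = None) -> TrapArray:
    """Read a trap-deployment CSV into a :class:`TrapArray`.

    Accepts a ``K`` column (constant effort across periods; requires
    ``T``) or ``K_t1..K_tT`` columns.  Traps whose effort is zero in every
    period are kept (they contribute no likelihood) but reported.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("trap_id", "x", "y"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    if df["trap_id"].duplicated().any():
        line = int(df.index[df["trap_id"].duplicated()][0]) + 2
        raise ParseError(f"{path}:{line}: duplicate trap_id")
    for col in ("x", "y"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            line = int(df.index[bad][0]) + 2
            raise ParseError(f"{path}:{line}: non-numeric {col}")
    kcols = [c for c in df.columns if c.startswith("K_t")]
    if kcols:
        kcols = sorted(kcols, key=lambda c: int(c[3:]))
        expected = [f"K_t{t}" for t in range(1, len(kcols) + 1)]
        if kcols != expected:
            raise ParseError(f"{path}: effort columns must be K_t1..K_tT, "
                             f"got {kcols}")
        if T is not None and len(kcols) != T:
            raise ParseError(
                f"{path}: {len(kcols)} effort columns but T={T} periods")
        effort = df[kcols].to_numpy()
    elif "K" in df.columns:
        if T is None:
            raise ParseError(f"{path}: constant-K file needs the number of "
                             "periods T")
        effort = np.repeat(df[["K"]].to_numpy(), T, axis=1)
    else:
        raise ParseError(f"{path}: need a K column or K_t1..K_tT columns")
    neg = np.asarray(effort < 0)
    if neg.any():
        line = int(np.argwhere(neg)[0, 0]) + 2
        raise ParseError(f"{path}:{line}: negative effort")
    return TrapArray(trap_id=df["trap_id"].to_numpy(),
                     x=df["x"].to_numpy(dtype=float),
                     y=df["y"].to_numpy(dtype=float),
                     effort=effort.astype(np.int64))


def write_traps(traps: TrapArray, path) -> None:
    cols = {"trap_id": traps.trap_id, "x": traps.x, "y": traps.y}
    for t in range(traps.n_periods):
        cols[f"K_t{t + 1}"] = traps.effort[:, t]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_detections(path, traps: TrapArray, T: int, M: int | None = None
                    ) -> EncounterData:
    """Read a long-format detections CSV into an :class:`EncounterData`.

    Counts are validated against the trap effort (``y <= K[j, t]``: at
    most one record per trap-day).  An empty file yields zero observed
    individuals.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = ["individual_id", "trap_id", "period", "count"]
    for col in required:
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    trap_index = {tid: j for j, tid in enumerate(traps.trap_id.tolist())}
    individuals = list(dict.fromkeys(df["individual_id"].tolist()))
    y = np.zeros((len(individuals), traps.n_traps, T), dtype=np.int64)
    ind_index = {ind: i for i, ind in enumerate(individuals)}
    for row in df.itertuples():
        line = row.Index + 2
        if row.trap_id not in trap_index:
            raise ParseError(f"{path}:{line}: unknown trap_id {row.trap_id!r}")
        if not 1 <= int(row.period) <= T:
            raise ParseError(f"{path}:{line}: period {row.period} outside 1..{T}")
        j = trap_index[row.trap_id]
        t = int(row.period) - 1
        c = int(row.count)
        if c < 0 or c > traps.effort[j, t]:
            raise ParseError(
                f"{path}:{line}: count {c} exceeds effort K={traps.effort[j, t]}")
        y[ind_index[row.individual_id], j, t] += c
    keep = y.sum(axis=(1, 2)) > 0
    data = EncounterData(
        y=y[keep], M=M if M is not None else int(keep.sum()),
        individual_id=np.asarray(individuals, dtype=object)[keep])
    data.validate_against(traps)
    return data


def write_detections(data: EncounterData, traps: TrapArray, path) -> None:
    rows = []
    for i in range(data.n_observed):
        for j, t in zip(*np.nonzero(data.y[i])):
            rows.append((data.individual_id[i], traps.trap_id[j], t + 1,
                         data.y[i, j, t]))
    pd.DataFrame(rows, columns=["individual_id", "trap_id", "period",
                                "count"]).to_csv(path, index=False)


def write_dataset(sim: SimulatedDataset, out_dir) -> dict[str, Path]:
    """Export one simulated dataset (traps, detections, truth) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"traps": out / "traps.csv", "detections": out / "detections.csv",
             "truth": out / "truth.json"}
    write_traps(sim.traps, paths["traps"])
    write_detections(sim.data, sim.traps, paths["detections"])
    truth = {
        "phi": sim.config.phi, "lambda0": sim.config.lambda0,
        "sigma_p": sim.config.sigma_p, "sigma_s": sim.config.sigma_s,
        "movement_model": str(sim.config.movement_model.value),
        "gamma": sim.params.gamma.tolist(),
        "N": sim.N.tolist(), "D": sim.D.tolist(),
        "state_space": dataclasses.asdict(sim.state_space),
        "n_observed": int(sim.data.n_observed),
        "seed": sim.config.seed,
    }
    paths["truth"].write_text(json.dumps(truth, indent=2))
    return paths


@dataclass
class RunManifest:
    """Everything needed to replay a run bit-identically."""

    command: str
    config: dict
    master_seed: int
    package_version: str = ""
    replicate_seeds: list = field(default_factory=list)
    convergence_flags: dict = field(default_factory=dict)
    timestamp: str = field(
        default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         default=str))

    @classmethod
    def load(cls, path) -> "RunManifest":
        payload = json.loads(Path(path).read_text())
        return cls(**payload)


def state_space_from_dict(d: dict) -> StateSpace:
    return StateSpace(xmin=d["xmin"], xmax=d["xmax"], ymin=d["ymin"],
                      ymax=d["ymax"], buffer=d.get("buffer"))
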