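"""Inbreeding-aware adjustment of effective-population-size trajectories.

High selfing/inbreeding shortens the effective generation interval seen by
sequential coalescent methods; comparing populations with very different
inbreeding therefore requires rescaling one trajectory's time axis (e.g. by
a factor of 3 for a highly inbred population) before the split time can be
read off the matched trajectories.  "Matched" is formalised here as uniform
agreement of log Ne into the past on a common log-spaced time grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


@dataclass
class NeTrajectory:
    """A piecewise-constant Ne history: (years before present, Ne) points."""

    population: str
    times: np.ndarray         # strictly increasing, years before present
    ne: np.ndarray            # > 0
    generation_time_years: float = 1.0
    mutation_rate: float | None = None
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.ne = np.asarray(self.ne, dtype=float)
        if len(self.times) < 2:
            raise ValueError("trajectory needs at least two points")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.ne <= 0):
            raise ValueError("Ne must be positive")

    @classmethod
    def read_tsv(cls, path, population: str = "pop") -> "NeTrajectory":
        df = pd.read_csv(path, sep="\t")
        return cls(population=population, times=df.iloc[:, 0].to_numpy(), ne=df.iloc[:, 1].to_numpy())

    def write_tsv(self, path) -> None:
        pd.DataFrame({"time_years": self.times, "Ne": self.ne}).to_csv(path, sep="\t", index=False)

    def at(self, t) -> np.ndarray:
        """Step-function (piecewise-constant, left-continuous) interpolation."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right") - 1
        idx = np.clip(idx, 0, len(self.ne) - 1)
        return self.ne[idx]


def rescale_generation_time(traj: NeTrajectory, factor: float) -> NeTrajectory:
    """Multiply every time coordinate by ``factor``; Ne values unchanged.

    The factor is recorded in the trajectory's provenance, so successive
    rescalings compose multiplicatively.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    return replace(
        traj,
        times=traj.times * factor,
        ne=traj.ne.copy(),
        provenance=traj.provenance + [("rescale_generation_time", factor)],
    )


def match_split_time(
    traj_a: NeTrajectory,
    traj_b: NeTrajectory,
    tol_log: float = 0.1,
    n_grid: int = 400,
) -> float | None:
    """Most recent time from which the two trajectories agree into the past.

    Both trajectories are resampled onto a common log-spaced grid over the
    overlap of their time ranges (step-function interpolation); the split
    time is the smallest grid time tau such that
    |ln Ne_A(t) - ln Ne_B(t)| <= tol_log for every grid time t >= tau.
    None when the trajectories never match (or do not overlap in time).
    """
    lo = max(traj_a.times[0], traj_b.times[0])
    hi = min(traj_a.times[-1], traj_b.times[-1])
    if hi <= lo or lo <= 0:
        lo = max(lo, min(traj_a.times[traj_a.times > 0].min(), traj_b.times[traj_b.times > 0].min()))
    if hi <= lo:
        return None
    grid = np.geomspace(lo, hi, n_grid)
    # keep the original breakpoints on the grid so constructed step pairs
    # are recovered exactly
    breaks = np.concatenate([traj_a.times, traj_b.times])
    breaks = breaks[(breaks >= lo) & (breaks <= hi)]
    grid = np.unique(np.concatenate([grid, breaks]))
    diff = np.abs(np.log(traj_a.at(grid)) - np.log(traj_b.at(grid)))
    ok = diff <= tol_log
    if not ok[-1]:
        return None
    # scan from the past toward the present for the last time matching holds
    idx = len(ok) - 1
    while idx > 0 and ok[idx - 1]:
        idx -= 1
    return float(grid[idx])
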