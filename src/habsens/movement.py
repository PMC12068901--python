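"""Stepping-stone movement simulation with known selection coefficients.

The simulated animal lives on the landscape raster.  At every raw time step
it leaves its current cell with probability ``p_move`` (independent of the
local covariates); conditional on moving, it picks one of the four von
Neumann neighbours j with probability proportional to

    exp(omega_elev * elev_j + omega_hab * hab_j + omega_cent * dist_j),

i.e. an exponential habitat-selection function with known coefficients.
``omega_cent < 0`` on the distance-to-center covariate produces a homing
(central-place) tendency; ``omega_cent = 0`` disables it.  Neighbours outside
the grid are removed from the choice set and the move distribution is
renormalised over the remaining neighbours (P(stay) stays ``1 - p_move``);
with homing at full scale the boundary is effectively never reached.

Tracks are rarefied during simulation (only every ``keep_every``-th raw
position is retained), then optionally thinned by a further factor k and
truncated to the first ``n_max`` relocations, emulating a telemetry device
with a fixed battery budget at different fix intervals.

The raw-step loop is compiled with numba (~1e7 steps/s on one core); the
sequential update semantics above are normative, the compilation is only an
acceleration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from numba import njit

from .landscape import LandscapeSet, center_of
from .seeding import child_seed, substream

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionParams",
    "Track",
    "neighbor_distribution",
    "simulate_track",
    "thin_track",
    "truncate_track",
    "true_choice_strata",
    "write_track_csv",
    "read_track_csv",
]

# von Neumann neighbour offsets, fixed order N, E, S, W (y increases "north")
_OFFSETS = ((0, 1), (1, 0), (0, -1), (-1, 0))


@dataclasses.dataclass
class SelectionParams:
    """Known selection coefficients and the per-step leave probability."""

    omega_elev: float = 2.0
    omega_hab: float = -2.0
    omega_cent: float = 0.0  # 0 disables homing
    p_move: float = 0.3

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_move <= 1.0):
            raise ValueError("p_move must be in [0, 1]")

    @property
    def homing(self) -> bool:
        return self.omega_cent != 0.0


@dataclasses.dataclass
class Track:
    """An ordered sequence of relocations for one simulated animal.

    ``times`` are integer time indices in units of retained fixes of the
    coarsest upstream rarefaction; after thinning by k they are multiples of
    k.  ``meta`` records simulation parameters, seeds and the thinning
    factor.
    """

    animal_id: str
    times: np.ndarray
    xs: np.ndarray
    ys: np.ndarray
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.int64)
        self.xs = np.asarray(self.xs, dtype=np.int64)
        self.ys = np.asarray(self.ys, dtype=np.int64)
        if not (len(self.xs) == len(self.ys) == len(self.times)):
            raise ValueError("times, xs, ys must have equal length")
        if len(self.times) < 2:
            raise ValueError("a track needs at least 2 relocations")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


def _weights_at(landscape: LandscapeSet, params: SelectionParams,
                x: int, y: int) -> float:
    lsc = landscape
    return float(np.exp(
        params.omega_elev * lsc.elev.values[y, x]
        + params.omega_hab * lsc.hab.values[y, x]
        + params.omega_cent * lsc.dist_center.values[y, x]
    ))


def neighbor_distribution(cell, landscape: LandscapeSet,
                          params: SelectionParams) -> np.ndarray:
    """Single-step choice probabilities over (stay, N, E, S, W).

    Out-of-grid neighbours get probability 0 and the conditional move
    distribution is renormalised over the in-grid ones.
    """
    x, y = int(cell[0]), int(cell[1])
    size = landscape.size
    if not (0 <= x < size and 0 <= y < size):
        raise IndexError(f"cell {cell} outside the {size}x{size} grid")
    probs = np.zeros(5)
    probs[0] = 1.0 - params.p_move
    w = np.zeros(4)
    for j, (dx, dy) in enumerate(_OFFSETS):
        nx, ny = x + dx, y + dy
        if 0 <= nx < size and 0 <= ny < size:
            w[j] = _weights_at(landscape, params, nx, ny)
    if w.sum() == 0.0:  # pragma: no cover - 1x1 grid is rejected upstream
        probs[0] = 1.0
        return probs
    probs[1:] = params.p_move * w / w.sum()
    return probs


@njit(cache=True)
def _sim_kernel(elev, hab, dist, w_elev, w_hab, w_cent, p_move,
                n_raw_steps, keep_every, x0, y0, seed):  # pragma: no cover
    np.random.seed(seed)
    size = elev.shape[0]
    n_keep = n_raw_steps // keep_every
    xs = np.empty(n_keep, np.int64)
    ys = np.empty(n_keep, np.int64)
    x, y = x0, y0
    wx = np.empty(4)
    cx = np.empty(4, np.int64)
    cy = np.empty(4, np.int64)
    k = 0
    for t in range(n_raw_steps):
        if np.random.random() < p_move:
            n_in = 0
            wsum = 0.0
            for d in range(4):
                if d == 0:
                    nx, ny = x, y + 1
                elif d == 1:
                    nx, ny = x + 1, y
                elif d == 2:
                    nx, ny = x, y - 1
                else:
                    nx, ny = x - 1, y
                if 0 <= nx < size and 0 <= ny < size:
                    w = np.exp(w_elev * elev[ny, nx] + w_hab * hab[ny, nx]
                               + w_cent * dist[ny, nx])
                    wx[n_in] = w
                    cx[n_in] = nx
                    cy[n_in] = ny
                    wsum += w
                    n_in += 1
            u = np.random.random() * wsum
            acc = 0.0
            for j in range(n_in):
                acc += wx[j]
                if u <= acc:
                    x = cx[j]
                    y = cy[j]
                    break
        if (t + 1) % keep_every == 0:
            xs[k] = x
            ys[k] = y
            k += 1
    return xs, ys


def _draw_start(landscape: LandscapeSet, rng: np.random.Generator) -> tuple[int, int]:
    # uniform over the central square with 20% of the side length
    # ([800, 1200]^2 on a 2000-cell grid)
    size = landscape.size
    cx, cy = center_of(size)
    half = size * 0.1
    x = int(np.floor(rng.uniform(cx - half, cx + half) + 0.5))
    y = int(np.floor(rng.uniform(cy - half, cy + half) + 0.5))
    return x, y


def simulate_track(
    landscape: LandscapeSet,
    params: SelectionParams,
    n_raw_steps: int,
    keep_every: int = 100,
    start: Optional[tuple[int, int]] = None,
    seed: int = 0,
    animal_id: str = "sim",
) -> Track:
    """Simulate one track and rarefy it during simulation.

    Returns every ``keep_every``-th raw position (``n_raw_steps //
    keep_every`` relocations, time index incrementing by 1 per retained
    position).  Fully deterministic for a fixed seed.
    """
    if keep_every < 1:
        raise ValueError("keep_every must be >= 1")
    if n_raw_steps < keep_every:
        raise ValueError("n_raw_steps must be >= keep_every")
    size = landscape.size
    if start is None:
        start = _draw_start(landscape, substream(seed, "start", animal_id))
    x0, y0 = int(start[0]), int(start[1])
    if not (0 <= x0 < size and 0 <= y0 < size):
        raise IndexError(f"start {start} outside the {size}x{size} grid")
    kernel_seed = child_seed(seed, "steps", animal_id)
    xs, ys = _sim_kernel(
        landscape.elev.values, landscape.hab.values,
        landscape.dist_center.values,
        float(params.omega_elev), float(params.omega_hab),
        float(params.omega_cent), float(params.p_move),
        int(n_raw_steps), int(keep_every), x0, y0, kernel_seed,
    )
    meta = {
        "params": dataclasses.asdict(params),
        "seed": int(seed),
        "keep_every": int(keep_every),
        "n_raw_steps": int(n_raw_steps),
        "start": [x0, y0],
        "landscape_replicate": landscape.replicate_id,
        "thin": 1,
    }
    return Track(animal_id=animal_id, times=np.arange(1, len(xs) + 1),
                 xs=xs, ys=ys, meta=meta)


def thin_track(track: Track, k: int) -> Track:
    """Retain every k-th relocation, starting at the first; time indices
    become multiples of k (k=1 is the identity)."""
    if k < 1:
        raise ValueError("thinning factor must be >= 1")
    if k == 1:
        return track
    meta = dict(track.meta)
    meta["thin"] = meta.get("thin", 1) * k
    return Track(animal_id=track.animal_id, times=track.times[::k],
                 xs=track.xs[::k], ys=track.ys[::k], meta=meta)


def truncate_track(track: Track, n_max: int = 1000) -> Track:
    """Keep the first min(n_max, length) relocations (battery-lifetime cap).

    Pipeline convention: thin first, then truncate, so every sampling
    interval ends up with the same number of data points.
    """
    if len(track) <= n_max:
        return track
    meta = dict(track.meta)
    meta["n_max"] = int(n_max)
    return Track(animal_id=track.animal_id, times=track.times[:n_max],
                 xs=track.xs[:n_max], ys=track.ys[:n_max], meta=meta)


def true_choice_strata(track: Track, landscape: LandscapeSet,
                       include_center: bool = False) -> pd.DataFrame:
    """Exact per-move choice sets of the simulator, as conditional-logit data.

    Requires a track retained at every raw step (``keep_every=1``).  Each raw
    step on which the animal moved becomes one stratum whose alternatives
    are the in-grid von Neumann neighbours of the previous cell, with the
    chosen neighbour marked as used.  Conditional on moving, the simulator's
    choice probability is exactly softmax(omega . z), so conditional logistic
    regression on these strata is consistent for the omegas — the
    gold-standard internal consistency check between simulator and
    estimator.  (Stay decisions carry no covariate information because the
    leave probability is covariate-independent, so they are not strata.)
    """
    if track.meta.get("keep_every", 1) != 1 or track.meta.get("thin", 1) != 1:
        raise ValueError("true_choice_strata needs an unthinned keep_every=1 track")
    size = landscape.size
    moved = (np.diff(track.xs) != 0) | (np.diff(track.ys) != 0)
    idx = np.nonzero(moved)[0]  # step i: from position i to i+1
    px, py = track.xs[idx], track.ys[idx]
    chosen_x, chosen_y = track.xs[idx + 1], track.ys[idx + 1]
    rows = []
    for s, (x0, y0, x1, y1) in enumerate(zip(px, py, chosen_x, chosen_y)):
        for dx, dy in _OFFSETS:
            nx, ny = x0 + dx, y0 + dy
            if 0 <= nx < size and 0 <= ny < size:
                rows.append((s, int(nx == x1 and ny == y1), nx, ny))
    df = pd.DataFrame(rows, columns=["stratum_id", "case", "x", "y"])
    cov = {"elev": landscape.elev.values[df["y"], df["x"]],
           "hab": landscape.hab.values[df["y"], df["x"]]}
    if include_center:
        cov["dist_center"] = landscape.dist_center.values[df["y"], df["x"]]
    for name, vals in cov.items():
        df[name] = vals
    return df


# ---------------------------------------------------------------------------
# track I/O
# ---------------------------------------------------------------------------

def write_track_csv(track: Track, path) -> None:
    """CSV with columns animal_id, t, x, y plus a JSON metadata sidecar."""
    path = Path(path)
    pd.DataFrame({"animal_id": track.animal_id, "t": track.times,
                  "x": track.xs, "y": track.ys}).to_csv(path, index=False)
    Path(str(path) + ".meta.json").write_text(json.dumps(track.meta, indent=1))


def read_track_csv(path) -> Track:
    """Read a track CSV; extra columns are tolerated and ignored."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = {"animal_id", "t", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"track CSV missing columns: {sorted(missing)}")
    meta_path = Path(str(path) + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    animal_id = str(df["animal_id"].iloc[0])
    return Track(animal_id=animal_id, times=df["t"].to_numpy(),
                 xs=df["x"].to_numpy(), ys=df["y"].to_numpy(), meta=meta)
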