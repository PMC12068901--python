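"""Steps, movement kernels and available-step sampling for iSSA.

A step is the directed segment between two consecutive relocations; the
turning angle of a step needs the bearing of the previous step, so the first
step of a track has no defined turning angle and is excluded from strata.
The empirical movement kernel is a gamma distribution for step lengths and a
von Mises distribution for turning angles, both fitted to the observed
steps.  Each observed (used) step is then matched with ``n_avail`` available
steps drawn from the fitted kernel, starting at the same location, with
covariates extracted at the step end cell; one used step plus its available
steps forms a stratum for the conditional logistic regression.

Zero-length steps (the discrete-space animal can return to its cell within
one sampling interval) are given a floor displacement of half a cell width
before gamma fitting and their turning angle is treated as missing; the
floor is configurable via ``ZERO_STEP_SL``.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .landscape import LandscapeSet, extract_covariates
from .movement import Track
from .seeding import substream

logger = logging.getLogger(__name__)

__all__ = [
    "Step",
    "MovementKernel",
    "build_steps",
    "fit_gamma_sl",
    "fit_vonmises_ta",
    "fit_kernel",
    "sample_available_steps",
    "steps_to_csv",
    "steps_from_csv",
]

#: displacement (cell widths) substituted for zero-length steps
ZERO_STEP_SL = 0.5
#: cap on the fitted von Mises concentration (degenerate all-equal angles)
KAPPA_MAX = 500.0
#: attempts to redraw an available step whose end point falls off the grid
MAX_REDRAWS = 100

#: tidy per-row schema of serialized strata
STEP_COLUMNS = ["stratum_id", "case", "x1", "y1", "x2", "y2", "sl", "ta",
                "elev", "hab", "dist_center"]

# Step rows are carried as a pandas DataFrame with the STEP_COLUMNS schema;
# the dataclass documents the row contract.


@dataclasses.dataclass
class Step:
    """One used or available step (``case`` 1=used, 0=available)."""

    stratum_id: int
    case: int
    x1: float
    y1: float
    x2: float
    y2: float
    sl: float
    ta: float
    elev: float
    hab: float
    dist_center: float


@dataclasses.dataclass
class MovementKernel:
    """Fitted selection-free movement kernel (gamma SL, von Mises TA)."""

    gamma_shape: float
    gamma_scale: float
    vm_kappa: float
    vm_mu: float = 0.0

    def __post_init__(self) -> None:
        if self.gamma_shape <= 0 or self.gamma_scale <= 0:
            raise ValueError("gamma parameters must be positive")
        if self.vm_kappa < 0:
            raise ValueError("vm_kappa must be nonnegative")


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    return np.pi - np.mod(np.pi - a, 2 * np.pi)


def build_steps(track: Track) -> pd.DataFrame:
    """Observed (used) steps of a track.

    m relocations give m-1 steps with columns step_id, t1, x1, y1, x2, y2,
    dt, sl, bearing, ta.  Bearings are measured counterclockwise from +x;
    the turning angle is the signed difference between successive step
    bearings wrapped to (-pi, pi], undefined (NaN) for the first step and
    wherever a zero-length step leaves a bearing undefined.
    """
    if len(track) < 3:
        raise ValueError("need at least 3 relocations to form turning angles")
    x = track.xs.astype(float)
    y = track.ys.astype(float)
    dx, dy = np.diff(x), np.diff(y)
    sl = np.hypot(dx, dy)
    bearing = np.where(sl > 0, np.arctan2(dy, dx), np.nan)
    ta = np.full(len(sl), np.nan)
    ta[1:] = _wrap_angle(bearing[1:] - bearing[:-1])
    return pd.DataFrame({
        "step_id": np.arange(len(sl)),
        "t1": track.times[:-1],
        "x1": x[:-1], "y1": y[:-1], "x2": x[1:], "y2": y[1:],
        "dt": np.diff(track.times),
        "sl": sl, "bearing": bearing, "ta": ta,
    })


def fit_gamma_sl(step_lengths) -> tuple[float, float]:
    """Maximum-likelihood gamma fit (shape, scale) of step lengths.

    Zero lengths are floored at ``ZERO_STEP_SL`` first; negative lengths are
    rejected, as are degenerate (constant) samples.
    """
    sl = np.asarray(step_lengths, dtype=float)
    sl = sl[np.isfinite(sl)]
    if np.any(sl < 0):
        raise ValueError("step lengths must be nonnegative")
    sl = np.where(sl == 0.0, ZERO_STEP_SL, sl)
    if len(sl) < 10:
        raise ValueError("need at least 10 step lengths to fit a gamma")
    if np.ptp(sl) == 0.0:
        raise ValueError("constant step lengths: gamma fit is degenerate")
    shape, _, scale = stats.gamma.fit(sl, floc=0.0)
    return float(shape), float(scale)


def _vm_mean_resultant(kappa: float) -> float:
    # A(kappa) = I1(kappa)/I0(kappa), exponentially scaled for stability
    return special.i1e(kappa) / special.i0e(kappa)


def fit_vonmises_ta(turning_angles) -> tuple[float, float]:
    """Maximum-likelihood von Mises fit (kappa, mu) of turning angles.

    mu is the circular mean; kappa solves A(kappa) = mean resultant length,
    capped at ``KAPPA_MAX`` for degenerate (all-equal) samples.
    """
    ta = np.asarray(turning_angles, dtype=float)
    ta = ta[np.isfinite(ta)]
    if len(ta) < 10:
        raise ValueError("need at least 10 turning angles to fit a von Mises")
    c, s = np.cos(ta).mean(), np.sin(ta).mean()
    mu = float(np.arctan2(s, c))
    rbar = float(np.hypot(c, s))
    if rbar <= 0.0:
        return 0.0, mu
    if rbar >= _vm_mean_resultant(KAPPA_MAX):
        return float(KAPPA_MAX), mu
    kappa = optimize.brentq(lambda k: _vm_mean_resultant(k) - rbar,
                            1e-12, KAPPA_MAX)
    return float(kappa), mu


def fit_kernel(steps: pd.DataFrame) -> MovementKernel:
    """Fit the movement kernel to observed steps."""
    shape, scale = fit_gamma_sl(steps["sl"].to_numpy())
    kappa, mu = fit_vonmises_ta(steps["ta"].to_numpy())
    return MovementKernel(gamma_shape=shape, gamma_scale=scale,
                          vm_kappa=kappa, vm_mu=mu)


def sample_available_steps(
    steps: pd.DataFrame,
    kernel: MovementKernel,
    landscape: LandscapeSet,
    n_avail: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Build iSSA strata: each usable observed step plus ``n_avail``
    available steps drawn from the fitted kernel.

    Usable steps are those with a defined previous bearing (turning angles
    of zero-length previous steps are drawn uniformly, per the zero-step
    policy).  Available steps start at the used step's start location; their
    length comes from the fitted gamma, their turning angle from the fitted
    von Mises applied to the previous bearing.  End points falling outside
    the grid are redrawn (up to ``MAX_REDRAWS``), then clamped with a
    warning.  Covariates are extracted at the end cell.
    """
    if n_avail < 1:
        raise ValueError("n_avail must be >= 1")
    rng = substream(seed, "available-steps")
    prev_bearing = np.roll(steps["bearing"].to_numpy(), 1)
    prev_bearing[0] = np.nan
    usable = np.isfinite(prev_bearing)
    used = steps.loc[usable].reset_index(drop=True)
    pb = prev_bearing[usable]
    n = len(used)
    if n == 0:
        raise ValueError("no usable steps (no defined previous bearing)")

    size = landscape.size
    strata = np.repeat(np.arange(n), n_avail)
    x1 = np.repeat(used["x1"].to_numpy(), n_avail)
    y1 = np.repeat(used["y1"].to_numpy(), n_avail)
    base_bearing = np.repeat(pb, n_avail)

    def draw(count):
        sl = rng.gamma(kernel.gamma_shape, kernel.gamma_scale, size=count)
        if kernel.vm_kappa > 0:
            ta = stats.vonmises.rvs(kernel.vm_kappa, loc=kernel.vm_mu,
                                    size=count, random_state=rng)
        else:
            ta = rng.uniform(-np.pi, np.pi, size=count)
        return sl, _wrap_angle(ta)

    sl, ta = draw(n * n_avail)
    x2 = x1 + sl * np.cos(base_bearing + ta)
    y2 = y1 + sl * np.sin(base_bearing + ta)
    out = (x2 < -0.5) | (x2 >= size - 0.5) | (y2 < -0.5) | (y2 >= size - 0.5)
    attempts = 0
    while out.any() and attempts < MAX_REDRAWS:
        idx = np.nonzero(out)[0]
        nsl, nta = draw(len(idx))
        sl[idx], ta[idx] = nsl, nta
        x2[idx] = x1[idx] + nsl * np.cos(base_bearing[idx] + nta)
        y2[idx] = y1[idx] + nsl * np.sin(base_bearing[idx] + nta)
        out[idx] = ((x2[idx] < -0.5) | (x2[idx] >= size - 0.5)
                    | (y2[idx] < -0.5) | (y2[idx] >= size - 0.5))
        attempts += 1
    if out.any():
        logger.warning("clamping %d available end points to the grid", out.sum())
        x2 = np.clip(x2, 0, size - 1)
        y2 = np.clip(y2, 0, size - 1)
        sl = np.hypot(x2 - x1, y2 - y1)

    # used rows: observed geometry; missing turning angle (after a
    # zero-length previous step) treated as missing, not imputed
    used_ta = used["ta"].to_numpy()
    used_rows = pd.DataFrame({
        "stratum_id": np.arange(n), "case": 1,
        "x1": used["x1"], "y1": used["y1"],
        "x2": used["x2"], "y2": used["y2"],
        "sl": used["sl"], "ta": used_ta,
    })
    avail_rows = pd.DataFrame({
        "stratum_id": strata, "case": 0,
        "x1": x1, "y1": y1, "x2": x2, "y2": y2, "sl": sl, "ta": ta,
    })
    df = pd.concat([used_rows, avail_rows], ignore_index=True)
    df.sort_values(["stratum_id", "case"], ascending=[True, False],
                   inplace=True, kind="stable")
    df.reset_index(drop=True, inplace=True)
    cov = extract_covariates(landscape, df["x2"].to_numpy(), df["y2"].to_numpy())
    for name, vals in cov.items():
        df[name] = vals
    return df[STEP_COLUMNS]


def steps_to_csv(strata: pd.DataFrame, path) -> None:
    strata[STEP_COLUMNS].to_csv(path, index=False)


def steps_from_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(STEP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"step CSV missing columns: {sorted(missing)}")
    return df
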