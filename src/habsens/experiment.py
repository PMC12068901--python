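"""Factorial sensitivity experiment: landscapes x tracks x intervals x methods.

One experiment cell is a landscape replicate at a given pair of fractional
dimensions plus one simulated track; for each thinning factor the track is
thinned, truncated to the battery budget and analysed with every requested
method and covariate set.  The grid is a pure function of (config, master
seed): each cell derives its own named substream, so any single cell is
reproducible in isolation, and cells already written to the output
directory are skipped on resume.

Summaries follow the headline read-outs of this kind of sensitivity study:
the spread (SD, quantiles) of estimated selection coefficients across
replicates and the fraction of coefficients whose 95% Wald interval
excludes zero, per (method x covariate x landscape autocorrelation x
sampling interval).  Non-convergent fits are excluded from both numerator
and denominator of the significance fraction (the exclusion count is
reported).
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import time
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import estimators
from .landscape import make_landscape_set
from .movement import SelectionParams, simulate_track, thin_track, truncate_track
from .seeding import child_seed, substream

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "run_replicate",
    "run_grid",
    "summarize",
    "make_gps_fixture",
    "read_gps_csv",
    "resample_gps",
]


@dataclasses.dataclass
class ExperimentConfig:
    """The factorial design and all simulation/estimation settings.

    Defaults are the desk-scale study conditions: 256-cell landscapes, 1e7
    raw steps rarefied to every 100th position (so that even after thinning
    by 100 a track still yields the full 1000-fix battery budget), 2
    landscape replicates x 5 tracks.  ``paper_scale`` raises the landscape
    and replication to the full design (2000-cell grids, 10 landscapes x 20
    tracks) — a compute-cluster-sized job.
    """

    size: int = 256
    n_landscapes: int = 2
    n_tracks: int = 5
    # (fract_dim_elev, fract_dim_hab) per landscape scenario; equal values
    # give the single-autocorrelation scenarios, unequal the mixed ones
    fract_dims: Sequence[tuple[float, float]] = (
        (0.01, 0.01), (0.1, 0.1), (1.0, 1.0))
    thins: Sequence[int] = (1, 10, 100)
    methods: Sequence[str] = ("rsa", "wrsa", "issa")
    covariate_sets: Sequence[Sequence[str]] = (("elev", "hab"),)
    homing: bool = True
    omega_elev: float = 2.0
    omega_hab: float = -2.0
    omega_cent: float = -0.01
    p_move: float = 0.3
    n_raw_steps: int = 10_000_000
    keep_every: int = 100
    n_max: int = 1000
    ratio: int = 20
    n_avail: int = 20
    domain: str = "mcp"
    movement_adjust: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.fract_dims = tuple(tuple(float(v) for v in pair)
                                for pair in self.fract_dims)
        self.covariate_sets = tuple(tuple(cs) for cs in self.covariate_sets)
        self.thins = tuple(int(t) for t in self.thins)
        self.methods = tuple(self.methods)
        unknown = set(self.methods) - {"rsa", "wrsa", "issa"}
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")

    @property
    def n_cells(self) -> int:
        return (len(self.fract_dims) * self.n_landscapes * self.n_tracks)

    @property
    def selection_params(self) -> SelectionParams:
        return SelectionParams(
            omega_elev=self.omega_elev, omega_hab=self.omega_hab,
            omega_cent=self.omega_cent if self.homing else 0.0,
            p_move=self.p_move)

    @classmethod
    def paper_scale(cls, **overrides) -> "ExperimentConfig":
        logger.warning("paper-scale configuration: expect a very long run")
        defaults = dict(size=2000, n_landscapes=10, n_tracks=20)
        defaults.update(overrides)
        return cls(**defaults)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["fract_dims"] = [list(p) for p in self.fract_dims]
        d["covariate_sets"] = [list(c) for c in self.covariate_sets]
        d["thins"] = list(self.thins)
        d["methods"] = list(self.methods)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError("experiment config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _cell_seed(config: ExperimentConfig, fd_pair, landscape_id: int,
               track_id: int) -> int:
    return child_seed(config.seed, "cell", fd_pair[0], fd_pair[1],
                      landscape_id, track_id)


def run_replicate(config: ExperimentConfig, landscape, fd_pair,
                  landscape_id: int, track_id: int) -> pd.DataFrame:
    """Simulate one track and fit every (method x thin x covariate set).

    Returns tidy coefficient rows (only the habitat covariates of each set;
    intercepts and movement-adjustment terms are estimation detail).
    Deterministic given the config master seed.
    """
    seed = _cell_seed(config, fd_pair, landscape_id, track_id)
    params = config.selection_params
    track = simulate_track(landscape, params, config.n_raw_steps,
                           keep_every=config.keep_every, seed=seed,
                           animal_id=f"l{landscape_id}t{track_id}")
    fits = []
    for thin, covset in itertools.product(config.thins, config.covariate_sets):
        sample = truncate_track(thin_track(track, thin), config.n_max)
        fit_seed = child_seed(seed, "fit", thin)
        for method in config.methods:
            if method == "rsa":
                fit = estimators.fit_rsa(sample, landscape, covset,
                                         ratio=config.ratio,
                                         domain=config.domain, seed=fit_seed)
            elif method == "wrsa":
                fit = estimators.fit_wrsa(sample, landscape, covset,
                                          ratio=config.ratio,
                                          domain=config.domain, seed=fit_seed)
            else:
                fit = estimators.fit_issa(
                    sample, landscape, covset, n_avail=config.n_avail,
                    seed=fit_seed, movement_adjust=config.movement_adjust)
            fit.meta.update(fract_dim_elev=fd_pair[0], fract_dim_hab=fd_pair[1],
                            thin=thin, homing=config.homing,
                            landscape_id=landscape_id, track_id=track_id,
                            seed=seed)
            fit.table = fit.table.loc[[c for c in covset if c in fit.table.index]]
            fits.append(fit)
    return estimators.results_to_tidy(fits)


def run_grid(config: ExperimentConfig, out_dir=None,
             resume: bool = True) -> pd.DataFrame:
    """Run the full factorial grid and return the tidy results table.

    With ``out_dir`` each cell's rows are written to their own CSV as soon
    as they are computed; on resume, cells whose file already exists are
    loaded instead of recomputed, so an interrupted grid can be restarted
    and yields an identical table.
    """
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
    frames = []
    cells = list(itertools.product(config.fract_dims,
                                   range(config.n_landscapes)))
    for fd_pair, lid in cells:
        landscape = make_landscape_set(
            config.size, fd_pair[0], fd_pair[1], replicate_id=lid,
            seed=child_seed(config.seed, "landscape", fd_pair[0],
                            fd_pair[1], lid))
        for tid in range(config.n_tracks):
            tag = (f"cell_fd{fd_pair[0]:g}-{fd_pair[1]:g}_l{lid}_t{tid}")
            path = out_dir / f"{tag}.csv" if out_dir is not None else None
            if path is not None and resume and path.exists():
                logger.info("resume: skipping %s", tag)
                frames.append(pd.read_csv(path))
                continue
            t0 = time.perf_counter()
            rows = run_replicate(config, landscape, fd_pair, lid, tid)
            logger.info("%s: %d rows in %.1fs", tag, len(rows),
                        time.perf_counter() - t0)
            if path is not None:
                rows.to_csv(path, index=False)
                rows = pd.read_csv(path)  # byte-identical with resumed runs
            frames.append(rows)
    if not frames:
        return pd.DataFrame(columns=estimators.TIDY_COLUMNS)
    return pd.concat(frames, ignore_index=True)


SUMMARY_KEYS = ["method", "covariate", "fract_dim_elev", "fract_dim_hab",
                "thin"]


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Aggregate tidy results per (method x covariate x scenario x thin).

    Reports replicate counts, the spread of converged estimates (sample SD,
    n-1 denominator; 5/50/95% quantiles) and the fraction of converged fits
    whose 95% CI excludes zero.  Groups without any converged fit are
    omitted (with a log note).
    """
    missing = set(SUMMARY_KEYS + ["estimate", "significant", "converged"]) \
        - set(results.columns)
    if missing:
        raise ValueError(f"results table missing columns: {sorted(missing)}")
    if results.empty:
        return pd.DataFrame(columns=SUMMARY_KEYS)
    rows = []
    for keys, grp in results.groupby(SUMMARY_KEYS, dropna=False, sort=True):
        conv = grp[grp["converged"].astype(bool)]
        if conv.empty:
            logger.info("summary group %s: no converged fits, omitted", keys)
            continue
        est = conv["estimate"].to_numpy(dtype=float)
        rows.append(dict(zip(SUMMARY_KEYS, keys)) | {
            "n_fits": len(grp),
            "n_converged": len(conv),
            "n_excluded": len(grp) - len(conv),
            "mean": est.mean(),
            "sd": est.std(ddof=1) if len(est) > 1 else np.nan,
            "q05": np.quantile(est, 0.05),
            "q50": np.quantile(est, 0.50),
            "q95": np.quantile(est, 0.95),
            "fraction_significant": conv["significant"].astype(bool).mean(),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GPS-like fixture (irregular timestamps) for I/O and resampling tests
# ---------------------------------------------------------------------------

def make_gps_fixture(n_fixes: int, interval_minutes: float = 60.0,
                     jitter_minutes: float = 2.0, seed: int = 0,
                     path=None) -> pd.DataFrame:
    """A synthetic GPS-style track with irregular timestamps.

    Emulates the structure of empirical telemetry exports (ISO timestamps
    at a nominal fix interval with jitter, float coordinates) for testing
    readers and time-based resampling; it carries no habitat-selection
    signal.
    """
    rng = substream(seed, "gps-fixture")
    gaps = np.maximum(interval_minutes
                      + rng.normal(0.0, jitter_minutes, size=n_fixes - 1), 1.0)
    minutes = np.concatenate([[0.0], np.cumsum(gaps)])
    t0 = pd.Timestamp("2024-01-01 00:00:00")
    ts = t0 + pd.to_timedelta(minutes, unit="min")
    xy = np.cumsum(rng.normal(0.0, 50.0, size=(n_fixes, 2)), axis=0)
    df = pd.DataFrame({"animal_id": "gps0",
                       "timestamp": ts.strftime("%Y-%m-%dT%H:%M:%S"),
                       "x": 1000 + xy[:, 0], "y": 1000 + xy[:, 1]})
    if path is not None:
        df.to_csv(path, index=False)
    return df


def read_gps_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"animal_id", "timestamp", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"GPS CSV missing columns: {sorted(missing)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def resample_gps(df: pd.DataFrame, interval_minutes: float) -> pd.DataFrame:
    """Greedy time-based subsampling: keep each fix at least
    ``interval_minutes`` after the last kept fix."""
    ts = pd.to_datetime(df["timestamp"]).to_numpy()
    keep = [0]
    last = ts[0]
    delta = np.timedelta64(int(interval_minutes * 60), "s")
    for i in range(1, len(ts)):
        if ts[i] - last >= delta:
            keep.append(i)
            last = ts[i]
    return df.iloc[keep].reset_index(drop=True)
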