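"""Habitat-selection estimators: RSA, weighted RSA and iSSA.

All three methods estimate the coefficients beta of an exponential
habitat-selection function w(z) = exp(beta_1 z_1 + ... + beta_m z_m) by
contrasting used with available locations; they differ in how availability
is defined and whether temporal autocorrelation is modelled:

* RSA — logistic regression of used relocations against ``ratio`` times as
  many points sampled uniformly from an availability domain (by default the
  100% minimum convex polygon of the used points); assumes independent
  relocations.
* wRSA — the same design, but each used relocation is down-weighted by the
  effective sample size of the track: a first-order autoregressive (discrete
  Ornstein-Uhlenbeck) model fitted to the position series gives the
  per-interval correlation rho, the track of n fixes is worth
  n_eff = n (1 - rho) / (1 + rho) independent points, and every used row
  enters the weighted likelihood with weight n_eff / n.  This captures the
  mechanism by which temporal autocorrelation deflates the information
  content of high-resolution tracks.
* iSSA — conditional logistic regression on step strata (one observed step
  vs. available steps drawn from the fitted movement kernel), optionally
  with the movement-adjustment terms log(step length) and cos(turning
  angle) as extra covariates.

Estimates, Wald standard errors, 95% confidence intervals and a
CI-excludes-zero significance flag are reported per covariate; fit failures
are recorded (``converged=False``), never raised, so a large experiment grid
is robust to individual pathological replicates.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import shapely
import statsmodels.api as sm
from scipy import stats

from .landscape import LandscapeSet, extract_covariates
from .movement import Track
from .seeding import substream
from .steps import ZERO_STEP_SL, build_steps, fit_kernel, sample_available_steps

logger = logging.getLogger(__name__)

__all__ = [
    "FitResult",
    "AcwWeights",
    "UAPointDesign",
    "wald_ci",
    "sample_available_uniform",
    "fit_logistic",
    "fit_rsa",
    "estimate_acw",
    "fit_wrsa",
    "conditional_logit_fit",
    "fit_issa",
    "results_to_tidy",
    "TIDY_COLUMNS",
]

#: conditional-logit Newton optimizer settings (fixed for reproducibility)
MAX_ITER = 100
GRAD_TOL = 1e-8
LL_RELTOL = 1e-10

Z975 = float(stats.norm.ppf(0.975))

TIDY_COLUMNS = ["method", "covariate", "estimate", "se", "lo", "hi",
                "significant", "converged", "n_used", "fract_dim_elev",
                "fract_dim_hab", "thin", "homing", "landscape_id",
                "track_id", "seed"]


def wald_ci(estimate: float, se: float, level: float = 0.95):
    """Wald interval estimate +/- z * se and a CI-excludes-zero flag."""
    if se < 0:
        raise ValueError("standard error must be nonnegative")
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    lo, hi = estimate - z * se, estimate + z * se
    return lo, hi, bool(lo > 0 or hi < 0)


@dataclasses.dataclass
class FitResult:
    """Per-covariate estimates of one fitted model.

    ``table`` is indexed by covariate name with columns estimate, se, lo,
    hi, significant.  ``meta`` carries scenario metadata (fract_dim levels,
    thinning factor, replicate ids, seeds, availability domain ...).
    """

    method: str
    table: pd.DataFrame
    converged: bool
    n_used: int
    meta: dict = dataclasses.field(default_factory=dict)

    def coef(self, name: str) -> pd.Series:
        return self.table.loc[name]

    def __getitem__(self, name: str) -> float:
        return float(self.table.loc[name, "estimate"])


def _result_table(names: Sequence[str], est: np.ndarray, se: np.ndarray,
                  level: float = 0.95) -> pd.DataFrame:
    rows = {}
    for name, b, s in zip(names, est, se):
        if np.isfinite(b) and np.isfinite(s):
            lo, hi, sig = wald_ci(float(b), float(s), level)
        else:
            lo, hi, sig = -np.inf, np.inf, False
        rows[name] = (b, s, lo, hi, sig)
    return pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["estimate", "se", "lo", "hi", "significant"])


@dataclasses.dataclass
class AcwWeights:
    """Autocorrelation-informed effective-sample-size weights."""

    tau: float      # position autocorrelation timescale, time units
    rho: float      # per-interval correlation exp(-dt/tau)
    n: int          # relocations in the track
    n_eff: float    # n (1-rho)/(1+rho)

    @property
    def weight(self) -> float:
        """Uniform per-used-point weight n_eff / n."""
        return self.n_eff / self.n


@dataclasses.dataclass
class UAPointDesign:
    """Used/available point design for (w)RSA.

    ``points`` has one row per location with columns case (1=used,
    0=available), weight, x, y and the covariates; ``domain`` is the
    availability region the available points were drawn from.
    """

    points: pd.DataFrame
    domain: shapely.Geometry
    domain_kind: str
    ratio: int

    @property
    def n_used(self) -> int:
        return int((self.points["case"] == 1).sum())


# ---------------------------------------------------------------------------
# RSA design
# ---------------------------------------------------------------------------

def _availability_domain(x, y, kind: str, size: int):
    if kind == "full":
        return shapely.box(-0.5, -0.5, size - 0.5, size - 0.5), "full"
    if kind == "bbox":
        return _bbox(x, y), "bbox"
    if kind == "mcp":
        hull = shapely.MultiPoint(np.column_stack([x, y])).convex_hull
        if hull.area > 0:
            return hull, "mcp"
        logger.warning("degenerate convex hull; falling back to bounding box")
        return _bbox(x, y), "bbox"
    raise ValueError(f"unknown availability domain {kind!r}")


def _bbox(x, y):
    x0, x1 = float(np.min(x)), float(np.max(x))
    y0, y1 = float(np.min(y)), float(np.max(y))
    if x1 - x0 <= 0:
        x0, x1 = x0 - 0.5, x1 + 0.5
    if y1 - y0 <= 0:
        y0, y1 = y0 - 0.5, y1 + 0.5
    return shapely.box(x0, y0, x1, y1)


def sample_available_uniform(
    track: Track,
    landscape: LandscapeSet,
    ratio: int = 20,
    domain: str = "mcp",
    seed: int = 0,
) -> UAPointDesign:
    """Build the RSA design: used relocations plus ``ratio`` times as many
    available points sampled uniformly over the availability domain
    (100% minimum convex polygon of the used points by default)."""
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    rng = substream(seed, "available-points")
    ux = track.xs.astype(float)
    uy = track.ys.astype(float)
    poly, kind = _availability_domain(ux, uy, domain, landscape.size)
    n_avail = ratio * len(ux)
    x0, y0, x1, y1 = poly.bounds
    ax = np.empty(0)
    ay = np.empty(0)
    while len(ax) < n_avail:
        m = max(int((n_avail - len(ax)) * 2), 1000)
        cx = rng.uniform(x0, x1, size=m)
        cy = rng.uniform(y0, y1, size=m)
        keep = shapely.contains_xy(poly, cx, cy)
        ax = np.concatenate([ax, cx[keep]])
        ay = np.concatenate([ay, cy[keep]])
    ax, ay = ax[:n_avail], ay[:n_avail]
    df = pd.DataFrame({
        "case": np.concatenate([np.ones(len(ux), dtype=int),
                                np.zeros(n_avail, dtype=int)]),
        "weight": 1.0,
        "x": np.concatenate([ux, ax]),
        "y": np.concatenate([uy, ay]),
    })
    for name, vals in extract_covariates(landscape, df["x"].to_numpy(),
                                         df["y"].to_numpy()).items():
        df[name] = vals
    return UAPointDesign(points=df, domain=poly, domain_kind=kind, ratio=ratio)


# ---------------------------------------------------------------------------
# (weighted) logistic regression
# ---------------------------------------------------------------------------

def fit_logistic(design, covariates: Sequence[str],
                 method: str = "RSA") -> FitResult:
    """Weighted binomial GLM (logit link) of used vs available points.

    Per-row weights enter the likelihood (not the point count); standard
    errors come from the weighted observed information.  Covariates without
    variation are reported with estimate 0 and infinite SE (unidentifiable);
    non-convergence or separation is flagged, never raised.
    """
    df = design.points if isinstance(design, UAPointDesign) else design
    covariates = list(covariates)
    y = df["case"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("design must contain both used and available rows")
    w = df["weight"].to_numpy(dtype=float) if "weight" in df else np.ones(len(df))
    identifiable = [c for c in covariates if np.ptp(df[c].to_numpy()) > 0]
    dropped = [c for c in covariates if c not in identifiable]
    est = {c: (0.0, np.inf) for c in dropped}
    converged = True
    if identifiable:
        X = sm.add_constant(df[identifiable].to_numpy(dtype=float))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(y, X, family=sm.families.Binomial(),
                             var_weights=w).fit(maxiter=200, tol=1e-10)
            converged = bool(res.converged) and np.all(np.isfinite(res.bse))
            est["intercept"] = (float(res.params[0]), float(res.bse[0]))
            for i, c in enumerate(identifiable, start=1):
                est[c] = (float(res.params[i]), float(res.bse[i]))
        except Exception as exc:  # separation, singular design, ...
            logger.warning("logistic fit failed: %s", exc)
            converged = False
            est["intercept"] = (np.nan, np.nan)
            for c in identifiable:
                est[c] = (np.nan, np.nan)
    names = ["intercept"] + covariates if identifiable else covariates
    table = _result_table(names,
                          np.array([est[c][0] for c in names]),
                          np.array([est[c][1] for c in names]))
    meta = {"unidentifiable": dropped}
    if isinstance(design, UAPointDesign):
        meta.update(domain=design.domain_kind, ratio=design.ratio)
    return FitResult(method=method, table=table, converged=converged,
                     n_used=int((y == 1).sum()), meta=meta)


def _rsa_meta(track: Track, covariates, seed) -> dict:
    params = track.meta.get("params", {})
    return {
        "covariates": list(covariates),
        "thin": track.meta.get("thin", 1),
        "homing": params.get("omega_cent", 0.0) != 0.0,
        "track_seed": track.meta.get("seed"),
        "seed": seed,
    }


def fit_rsa(track: Track, landscape: LandscapeSet,
            covariates: Sequence[str] = ("elev", "hab"), ratio: int = 20,
            domain: str = "mcp", seed: int = 0) -> FitResult:
    """Classic RSA: uniform available sampling + unweighted logistic fit.

    By default the homing covariate dist_center is not offered to the model
    even when the track was simulated with homing; pass it in ``covariates``
    explicitly to override.
    """
    design = sample_available_uniform(track, landscape, ratio=ratio,
                                      domain=domain, seed=seed)
    fit = fit_logistic(design, covariates, method="RSA")
    fit.meta.update(_rsa_meta(track, covariates, seed))
    return fit


# ---------------------------------------------------------------------------
# autocorrelation-informed weighting
# ---------------------------------------------------------------------------

def estimate_acw(track: Track) -> AcwWeights:
    """Effective sample size of a regularly sampled track.

    A first-order autoregressive (discrete OU) position model is fitted by
    conditional maximum likelihood, pooling the x and y coordinate series:
    rho is the pooled lag-1 regression coefficient of the demeaned
    positions, tau = -dt / log(rho).  White-noise tracks (rho <= 0) get
    rho = 0 and n_eff = n.
    """
    n = len(track)
    if n < 50:
        raise ValueError("need at least 50 relocations to estimate autocorrelation")
    dt = float(np.median(np.diff(track.times)))
    num = den = 0.0
    for z in (track.xs.astype(float), track.ys.astype(float)):
        z = z - z.mean()
        num += float(z[:-1] @ z[1:])
        den += float(z[:-1] @ z[:-1])
    rho = num / den if den > 0 else 0.0
    rho = float(np.clip(rho, 0.0, 1.0 - 1e-9))
    tau = np.inf if rho == 0.0 else -dt / np.log(rho)
    n_eff = n * (1.0 - rho) / (1.0 + rho)
    return AcwWeights(tau=float(tau), rho=rho, n=n, n_eff=float(n_eff))


def fit_wrsa(track: Track, landscape: LandscapeSet,
             covariates: Sequence[str] = ("elev", "hab"), ratio: int = 20,
             domain: str = "mcp", seed: int = 0,
             acw: Optional[AcwWeights] = None) -> FitResult:
    """Autocorrelation-weighted RSA.

    Identical to :func:`fit_rsa` except that every used row carries the
    uniform weight n_eff / n from :func:`estimate_acw` (available rows keep
    weight 1); with rho = 0 the two fits coincide exactly.
    """
    if acw is None:
        acw = estimate_acw(track)
    design = sample_available_uniform(track, landscape, ratio=ratio,
                                      domain=domain, seed=seed)
    pts = design.points
    pts.loc[pts["case"] == 1, "weight"] = acw.weight
    fit = fit_logistic(design, covariates, method="wRSA")
    fit.meta.update(_rsa_meta(track, covariates, seed))
    fit.meta.update(rho=acw.rho, tau=acw.tau, n_eff=acw.n_eff)
    return fit


# ---------------------------------------------------------------------------
# conditional logistic regression (iSSA core)
# ---------------------------------------------------------------------------

def _clogit_ll(X, y, starts, stratum_of, beta):
    eta = X @ beta
    mx = np.maximum.reduceat(eta, starts)
    w = np.exp(eta - mx[stratum_of])
    denom = np.add.reduceat(w, starts)
    ll = float(eta[y == 1].sum() - (np.log(denom) + mx).sum())
    p = w / denom[stratum_of]
    return ll, p


def conditional_logit_fit(strata: pd.DataFrame,
                          covariates: Sequence[str]) -> FitResult:
    """Conditional logistic regression on used/available strata.

    Maximises the conditional log-likelihood
    sum_s [eta_used(s) - log sum_j exp(eta_j(s))] by Newton iteration with
    analytic gradient and Hessian (any intercept is absorbed by the strata,
    so none is fitted).  Covariates with no within-stratum variation
    anywhere are unidentifiable and reported with estimate 0 / infinite SE.
    """
    covariates = list(covariates)
    df = strata.sort_values("stratum_id", kind="stable")
    sid = df["stratum_id"].to_numpy()
    y = df["case"].to_numpy(dtype=int)
    uniq, stratum_of, counts = np.unique(sid, return_inverse=True,
                                         return_counts=True)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    used_per = np.add.reduceat(y, starts)
    if np.any(used_per != 1):
        raise ValueError("every stratum must contain exactly one used row")
    if np.any(counts < 2):
        raise ValueError("every stratum needs at least one available row")

    Xall = df[covariates].to_numpy(dtype=float)
    # within-stratum centering detects unidentifiable covariates
    means = np.add.reduceat(Xall, starts, axis=0) / counts[:, None]
    centered = Xall - means[stratum_of]
    keep = [i for i in range(len(covariates))
            if np.abs(centered[:, i]).max() > 0]
    dropped = [covariates[i] for i in range(len(covariates)) if i not in keep]
    n_strata = len(uniq)

    est = {c: (0.0, np.inf) for c in dropped}
    converged = True
    if keep:
        X = Xall[:, keep]
        p_dim = X.shape[1]
        beta = np.zeros(p_dim)
        ll, p = _clogit_ll(X, y, starts, stratum_of, beta)
        converged = False
        for _ in range(MAX_ITER):
            grad = X[y == 1].sum(axis=0) - X.T @ p
            ex = np.add.reduceat(p[:, None] * X, starts, axis=0)
            hess = -(X.T @ (p[:, None] * X) - ex.T @ ex)
            if np.abs(grad).max() < GRAD_TOL:
                converged = True
                break
            try:
                step = np.linalg.solve(-hess, grad)
            except np.linalg.LinAlgError:
                logger.warning("singular Hessian in conditional logit")
                break
            # step halving keeps the iteration ascending
            new_ll, new_p = _clogit_ll(X, y, starts, stratum_of, beta + step)
            halvings = 0
            while not np.isfinite(new_ll) or new_ll < ll:
                step *= 0.5
                halvings += 1
                if halvings > 50:
                    break
                new_ll, new_p = _clogit_ll(X, y, starts, stratum_of,
                                           beta + step)
            if halvings > 50:
                break
            rel = abs(new_ll - ll) / (abs(ll) + 1e-300)
            beta, ll, p = beta + step, new_ll, new_p
            if rel < LL_RELTOL:
                converged = True
                break
        grad = X[y == 1].sum(axis=0) - X.T @ p
        ex = np.add.reduceat(p[:, None] * X, starts, axis=0)
        hess = -(X.T @ (p[:, None] * X) - ex.T @ ex)
        try:
            cov = np.linalg.inv(-hess)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(p_dim, np.nan)
            converged = False
        for i, ci in enumerate(keep):
            est[covariates[ci]] = (float(beta[i]), float(se[i]))
    table = _result_table(covariates,
                          np.array([est[c][0] for c in covariates]),
                          np.array([est[c][1] for c in covariates]))
    return FitResult(method="iSSA", table=table, converged=converged,
                     n_used=n_strata, meta={"unidentifiable": dropped})


def fit_issa(track: Track, landscape: LandscapeSet,
             covariates: Sequence[str] = ("elev", "hab"), n_avail: int = 20,
             seed: int = 0, movement_adjust: bool = True) -> FitResult:
    """Integrated step-selection analysis on one track.

    Pipeline: observed steps -> fitted gamma/von Mises movement kernel ->
    ``n_avail`` available steps per stratum -> conditional logistic
    regression.  With ``movement_adjust`` the kernel-correction terms
    log(sl) and cos(ta) are estimated alongside the habitat covariates
    (reported in the same table under ``log_sl`` / ``cos_ta``).
    """
    if len(track) < 50:
        raise ValueError("need at least 50 relocations for iSSA")
    covariates = list(covariates)
    try:
        used = build_steps(track)
        kernel = fit_kernel(used)
        strata = sample_available_steps(used, kernel, landscape,
                                        n_avail=n_avail, seed=seed)
        model_covs = list(covariates)
        if movement_adjust:
            sl = strata["sl"].to_numpy(dtype=float)
            ta = strata["ta"].to_numpy(dtype=float)
            missing = ~np.isfinite(ta)
            if missing.any():  # zero-length used steps: angle drawn uniform
                rng = substream(seed, "missing-ta")
                ta = ta.copy()
                ta[missing] = rng.uniform(-np.pi, np.pi, size=missing.sum())
            strata = strata.assign(
                log_sl=np.log(np.maximum(sl, ZERO_STEP_SL)),
                cos_ta=np.cos(ta),
            )
            model_covs += ["log_sl", "cos_ta"]
        fit = conditional_logit_fit(strata, model_covs)
    except (ValueError, RuntimeError) as exc:
        logger.warning("iSSA fit failed: %s", exc)
        table = _result_table(covariates,
                              np.full(len(covariates), np.nan),
                              np.full(len(covariates), np.nan))
        fit = FitResult(method="iSSA", table=table, converged=False,
                        n_used=0, meta={"error": str(exc)})
        kernel = None
    fit.meta.update(_rsa_meta(track, covariates, seed))
    fit.meta.update(n_avail=n_avail, movement_adjust=movement_adjust,
                    kernel=dataclasses.asdict(kernel) if kernel else None)
    return fit


# ---------------------------------------------------------------------------
# tidy export
# ---------------------------------------------------------------------------

def results_to_tidy(fits) -> pd.DataFrame:
    """One row per (fit x covariate), with scenario metadata columns."""
    rows = []
    for fit in fits:
        for cov, r in fit.table.iterrows():
            rows.append({
                "method": fit.method, "covariate": cov,
                "estimate": r["estimate"], "se": r["se"],
                "lo": r["lo"], "hi": r["hi"],
                "significant": bool(r["significant"]),
                "converged": fit.converged, "n_used": fit.n_used,
                "fract_dim_elev": fit.meta.get("fract_dim_elev", np.nan),
                "fract_dim_hab": fit.meta.get("fract_dim_hab", np.nan),
                "thin": fit.meta.get("thin", np.nan),
                "homing": fit.meta.get("homing", None),
                "landscape_id": fit.meta.get("landscape_id", None),
                "track_id": fit.meta.get("track_id", None),
                "seed": fit.meta.get("seed", None),
            })
    return pd.DataFrame(rows, columns=TIDY_COLUMNS)
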