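import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st, assume
from scipy import stats

import habsens as h
from habsens.estimators import AcwWeights

# ---------------------------------------------------------------------------
# independent conditional-likelihood oracle: dense grid refinement
# ---------------------------------------------------------------------------


def _grid_ll(df, covs, betas):
    """Conditional log-likelihood at many beta values, straight from the
    definition sum_s [eta_used - log sum_j exp(eta_j)]."""
    d = df.sort_values("stratum_id", kind="stable")
    X = d[covs].to_numpy(float)
    y = d["case"].to_numpy(int)
    sid = d["stratum_id"].to_numpy()
    _, counts = np.unique(sid, return_counts=True)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    which = np.repeat(np.arange(len(counts)), counts)
    E = X @ np.asarray(betas).T
    M = np.maximum.reduceat(E, starts, axis=0)
    D = np.add.reduceat(np.exp(E - M[which]), starts, axis=0)
    return E[y == 1].sum(axis=0) - (np.log(D) + M).sum(axis=0)


def grid_oracle(df, covs, half_width=8.0, rounds=6, n_grid=41):
    """Argmax of the conditional likelihood by iterative grid refinement.

    Returns (beta, hit_boundary): hit_boundary means the coarse grid argmax
    touched the search box, i.e. the MLE is effectively infinite
    (separation) and no finite comparison is meaningful.
    """
    p = len(covs)
    center = np.zeros(p)
    width = half_width
    hit_boundary = False
    for r in range(rounds):
        axes = [np.linspace(c - width, c + width, n_grid) for c in center]
        mesh = np.meshgrid(*axes, indexing="ij")
        cand = np.column_stack([g.ravel() for g in mesh])
        best = cand[_grid_ll(df, covs, cand).argmax()]
        if r == 0 and np.any(np.abs(best) >= half_width - 1e-9):
            hit_boundary = True
        spacing = 2 * width / (n_grid - 1)
        center, width = best, 2 * spacing
    return center, hit_boundary


def random_clogit_instance(rng, n_strata, n_alt, beta):
    """Per-stratum multinomial choices under a known conditional model."""
    beta = np.asarray(beta, float)
    rows = []
    for s in range(n_strata):
        X = rng.normal(0.0, 1.0, size=(n_alt, len(beta)))
        p = np.exp(X @ beta)
        p /= p.sum()
        choice = rng.choice(n_alt, p=p)
        for j in range(n_alt):
            rows.append((s, int(j == choice), *X[j]))
    cols = ["stratum_id", "case"] + [f"z{i}" for i in range(len(beta))]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# inference utilities
# ---------------------------------------------------------------------------


def test_wald_ci_arithmetic():
    lo, hi, sig = h.wald_ci(2.0, 0.5)
    assert (lo, hi) == (pytest.approx(1.02, abs=0.001),
                        pytest.approx(2.98, abs=0.001))
    assert sig
    lo, hi, sig = h.wald_ci(0.5, 0.5)
    assert lo < 0 < hi and not sig
    lo, hi, sig = h.wald_ci(1.5, 0.0)
    assert lo == hi == 1.5 and sig
    with pytest.raises(ValueError):
        h.wald_ci(1.0, -0.1)


# ---------------------------------------------------------------------------
# RSA design
# ---------------------------------------------------------------------------


def test_available_sampling_counts_and_domain(track_mid, landscape_low):
    track = h.truncate_track(track_mid, 1000)
    design = h.sample_available_uniform(track, landscape_low, ratio=20, seed=1)
    pts = design.points
    assert (pts["case"] == 0).sum() == 20 * 1000
    assert design.n_used == 1000
    import shapely
    avail = pts[pts["case"] == 0]
    assert shapely.contains_xy(design.domain.buffer(1e-9),
                               avail["x"].to_numpy(),
                               avail["y"].to_numpy()).all()


def test_available_sampling_is_uniform(track_mid, landscape_low):
    """Chi-square uniformity over a 4x4 partition of the domain's bounding
    box, with expected counts proportional to in-domain area."""
    import shapely

    track = h.truncate_track(track_mid, 1000)
    design = h.sample_available_uniform(track, landscape_low, ratio=20, seed=2)
    avail = design.points[design.points["case"] == 0]
    x0, y0, x1, y1 = design.domain.bounds
    xe = np.linspace(x0, x1, 5)
    ye = np.linspace(y0, y1, 5)
    obs, exp = [], []
    for i in range(4):
        for j in range(4):
            cell = shapely.box(xe[i], ye[j], xe[i + 1], ye[j + 1])
            area = cell.intersection(design.domain).area
            if area <= 1e-9:
                continue
            inside = ((avail["x"] >= xe[i]) & (avail["x"] < xe[i + 1])
                      & (avail["y"] >= ye[j]) & (avail["y"] < ye[j + 1]))
            obs.append(inside.sum())
            exp.append(area)
    exp = np.array(exp) / sum(exp) * sum(obs)
    assert stats.chisquare(obs, exp).pvalue > 0.01


def test_degenerate_hull_falls_back_to_bbox(landscape_low, caplog):
    track = h.Track("line", times=np.arange(1, 61),
                    xs=np.arange(10, 70), ys=np.full(60, 20))  # collinear
    design = h.sample_available_uniform(track, landscape_low, ratio=5, seed=0)
    assert design.domain_kind == "bbox"
    assert (design.points["case"] == 0).sum() == 5 * 60


# ---------------------------------------------------------------------------
# (weighted) logistic regression
# ---------------------------------------------------------------------------


def _rsf_design(landscape, n_used, rng, beta_elev=2.0, beta_hab=-2.0,
                ratio=20):
    """Used/available points drawn exactly from the exponential RSF."""
    elev = landscape.elev.values.ravel()
    hab = landscape.hab.values.ravel()
    w = np.exp(beta_elev * elev + beta_hab * hab)
    used = rng.choice(len(elev), size=n_used, p=w / w.sum())
    avail = rng.integers(0, len(elev), size=ratio * n_used)
    idx = np.concatenate([used, avail])
    return pd.DataFrame({
        "case": np.r_[np.ones(n_used, int), np.zeros(ratio * n_used, int)],
        "weight": 1.0, "elev": elev[idx], "hab": hab[idx]})


def test_logistic_recovers_rsf_coefficients(landscape_low):
    """Used points sampled from w(z)=exp(2 elev - 2 hab) over an
    uncorrelated landscape: both coefficients within 2 SE of truth in >=90%
    of replicates."""
    rng = np.random.default_rng(20)
    hits = 0
    for _ in range(50):
        fit = h.fit_logistic(_rsf_design(landscape_low, 1000, rng),
                             ["elev", "hab"])
        assert fit.converged
        ok = (abs(fit["elev"] - 2.0) <= 2 * fit.coef("elev")["se"]
              and abs(fit["hab"] + 2.0) <= 2 * fit.coef("hab")["se"])
        hits += ok
    assert hits >= 45


def test_logistic_zero_covariate_unidentifiable(landscape_low):
    rng = np.random.default_rng(21)
    df = _rsf_design(landscape_low, 200, rng)
    df["dead"] = 0.0
    fit = h.fit_logistic(df, ["elev", "hab", "dead"])
    assert fit["dead"] == 0.0
    assert np.isinf(fit.coef("dead")["se"])
    assert "dead" in fit.meta["unidentifiable"]
    assert not fit.coef("dead")["significant"]


def test_logistic_weights_enter_likelihood_not_count(landscape_low):
    """Weights act through the likelihood: duplicating available rows with
    halved weights changes nothing (exact identity), and doubling available
    weights only shifts the intercept by ~ -log 2 (exact in the rare-events
    limit of a 20:1 design)."""
    rng = np.random.default_rng(22)
    df = _rsf_design(landscape_low, 500, rng)
    base = h.fit_logistic(df, ["elev", "hab"])
    avail = df[df["case"] == 0].assign(weight=0.5)
    dup = pd.concat([df[df["case"] == 1], avail, avail], ignore_index=True)
    same = h.fit_logistic(dup, ["elev", "hab"])
    for cov in ("intercept", "elev", "hab"):
        assert same[cov] == pytest.approx(base[cov], abs=1e-6)
    df2 = df.copy()
    df2.loc[df2["case"] == 0, "weight"] = 2.0
    doubled = h.fit_logistic(df2, ["elev", "hab"])
    for cov in ("elev", "hab"):
        assert doubled[cov] == pytest.approx(base[cov], abs=5e-3)
    assert doubled["intercept"] == pytest.approx(base["intercept"] - np.log(2),
                                                 abs=1e-2)


def test_logistic_requires_both_classes(landscape_low):
    df = _rsf_design(landscape_low, 50, np.random.default_rng(0))
    with pytest.raises(ValueError):
        h.fit_logistic(df[df["case"] == 0], ["elev"])


# ---------------------------------------------------------------------------
# autocorrelation weighting
# ---------------------------------------------------------------------------


def _ar1_track(rho, n, seed, scale=200.0):
    rng = np.random.default_rng(seed)
    z = np.empty((n, 2))
    z[0] = rng.normal(0, 1, 2)
    for t in range(1, n):
        z[t] = rho * z[t - 1] + rng.normal(0, np.sqrt(1 - rho**2), 2)
    xy = np.rint(z * scale).astype(int) + 5000
    return h.Track("ar1", times=np.arange(1, n + 1), xs=xy[:, 0], ys=xy[:, 1])


def test_acw_iid_limit():
    rng = np.random.default_rng(30)
    track = h.Track("iid", times=np.arange(1, 2001),
                    xs=rng.integers(0, 500, 2000),
                    ys=rng.integers(0, 500, 2000))
    acw = h.estimate_acw(track)
    assert acw.rho < 0.05
    assert acw.weight > 0.9


def test_acw_ar1_effective_sample_size():
    acw = h.estimate_acw(_ar1_track(0.9, 4000, seed=31))
    assert acw.rho == pytest.approx(0.9, abs=0.02)
    # closed form: n_eff/n = (1-rho)/(1+rho) ~ 0.0526
    assert acw.weight == pytest.approx((1 - 0.9) / (1 + 0.9), abs=0.02)
    assert np.isfinite(acw.tau) and acw.tau > 0


def test_acw_thinning_increases_relative_information():
    track = _ar1_track(0.9, 6000, seed=32)
    full = h.estimate_acw(track)
    thinned = h.estimate_acw(h.thin_track(track, 5))
    assert thinned.weight > full.weight  # rho^k < rho


def test_wrsa_equals_rsa_at_rho_zero(track_mid, landscape_low):
    track = h.truncate_track(track_mid, 500)
    rsa = h.fit_rsa(track, landscape_low, seed=3)
    acw = AcwWeights(tau=np.inf, rho=0.0, n=len(track), n_eff=len(track))
    wrsa = h.fit_wrsa(track, landscape_low, seed=3, acw=acw)
    pd.testing.assert_frame_equal(rsa.table, wrsa.table)


def test_wrsa_downweights_autocorrelated_tracks(track_mid, landscape_low):
    """On an autocorrelated track, wRSA inflates the standard errors
    relative to RSA for the same design."""
    track = h.truncate_track(track_mid, 1000)
    rsa = h.fit_rsa(track, landscape_low, seed=4)
    wrsa = h.fit_wrsa(track, landscape_low, seed=4)
    assert wrsa.meta["rho"] > 0.5
    assert wrsa.coef("elev")["se"] > 2 * rsa.coef("elev")["se"]


# ---------------------------------------------------------------------------
# conditional logistic regression
# ---------------------------------------------------------------------------


def test_clogit_matches_grid_oracle_fixed_instance():
    df = random_clogit_instance(np.random.default_rng(40), 5, 3, (1.0, -1.0))
    fit = h.conditional_logit_fit(df, ["z0", "z1"])
    oracle, boundary = grid_oracle(df, ["z0", "z1"])
    assert not boundary and fit.converged
    np.testing.assert_allclose([fit["z0"], fit["z1"]], oracle, atol=1e-3)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(n_strata=st.integers(2, 10), n_alt=st.integers(2, 5),
       p=st.integers(1, 2), seed=st.integers(0, 10_000))
def test_clogit_grid_oracle_property(n_strata, n_alt, p, seed):
    """Newton optimum equals the dense-grid likelihood argmax on small
    random instances (<=10 strata, <=5 alternatives, <=2 covariates)."""
    rng = np.random.default_rng(seed)
    df = random_clogit_instance(rng, n_strata, n_alt, [1.0, -1.0][:p])
    covs = [f"z{i}" for i in range(p)]
    oracle, boundary = grid_oracle(df, covs)
    assume(not boundary)  # separation: MLE not finite
    fit = h.conditional_logit_fit(df, covs)
    assume(fit.converged)
    est = np.array([fit[c] for c in covs])
    np.testing.assert_allclose(est, oracle, atol=1e-3)


def test_clogit_matches_statsmodels():
    from statsmodels.discrete.conditional_models import ConditionalLogit

    df = random_clogit_instance(np.random.default_rng(41), 200, 4,
                                (1.5, -0.5))
    fit = h.conditional_logit_fit(df, ["z0", "z1"])
    res = ConditionalLogit(df["case"], df[["z0", "z1"]],
                           groups=df["stratum_id"]).fit(disp=0)
    # statsmodels optimises by BFGS with a looser gradient tolerance than
    # the Newton iteration here, so agreement is at its precision
    np.testing.assert_allclose([fit["z0"], fit["z1"]], res.params, atol=2e-4)
    np.testing.assert_allclose([fit.coef("z0")["se"], fit.coef("z1")["se"]],
                               res.bse, atol=1e-3)


def test_clogit_invariant_to_per_stratum_shift():
    rng = np.random.default_rng(42)
    df = random_clogit_instance(rng, 50, 4, (1.0, -1.0))
    fit = h.conditional_logit_fit(df, ["z0", "z1"])
    shifted = df.copy()
    shifts = rng.normal(0, 5, size=shifted["stratum_id"].nunique())
    shifted["z0"] = shifted["z0"] + shifts[shifted["stratum_id"]]
    fit2 = h.conditional_logit_fit(shifted, ["z0", "z1"])
    assert fit2["z0"] == pytest.approx(fit["z0"], abs=1e-6)
    assert fit2["z1"] == pytest.approx(fit["z1"], abs=1e-6)


def test_clogit_parameter_recovery():
    """Per-stratum multinomial data with beta=(2,-2): recovery within 2 SE
    in >=90% of replicates."""
    hits = 0
    for rep in range(50):
        rng = np.random.default_rng(1000 + rep)
        df = random_clogit_instance(rng, 500, 5, (2.0, -2.0))
        fit = h.conditional_logit_fit(df, ["z0", "z1"])
        assert fit.converged
        ok = (abs(fit["z0"] - 2.0) <= 2 * fit.coef("z0")["se"]
              and abs(fit["z1"] + 2.0) <= 2 * fit.coef("z1")["se"])
        hits += ok
    assert hits >= 45


def test_clogit_unidentifiable_covariate():
    df = random_clogit_instance(np.random.default_rng(43), 20, 3, (1.0,))
    df["const_in_stratum"] = df["stratum_id"] * 2.0  # varies only across strata
    fit = h.conditional_logit_fit(df, ["z0", "const_in_stratum"])
    assert fit["const_in_stratum"] == 0.0
    assert np.isinf(fit.coef("const_in_stratum")["se"])
    assert "const_in_stratum" in fit.meta["unidentifiable"]


def test_clogit_validates_strata():
    df = random_clogit_instance(np.random.default_rng(44), 5, 3, (1.0,))
    bad = df.copy()
    bad.loc[bad["stratum_id"] == 0, "case"] = 0
    with pytest.raises(ValueError):
        h.conditional_logit_fit(bad, ["z0"])


# ---------------------------------------------------------------------------
# estimator-simulator consistency and iSSA
# ---------------------------------------------------------------------------


def test_true_choice_sets_recover_omegas():
    """Conditional logit on the simulator's exact move choice sets recovers
    the simulation coefficients (smoke version; the full 50-replicate run
    lives in the acceptance suite)."""
    params = h.SelectionParams(omega_elev=2.0, omega_hab=-2.0)
    hits = 0
    for rep in range(3):
        lset = h.make_landscape_set(128, 0.01, 0.01, replicate_id=rep,
                                    seed=rep)
        raw = h.simulate_track(lset, params, 100_000, keep_every=1,
                               seed=5000 + rep)
        strata = h.true_choice_strata(raw, lset)
        fit = h.conditional_logit_fit(strata, ["elev", "hab"])
        assert fit.converged
        ok = (abs(fit["elev"] - 2.0) <= 2 * fit.coef("elev")["se"]
              and abs(fit["hab"] + 2.0) <= 2 * fit.coef("hab")["se"])
        hits += ok
    assert hits >= 2


def test_issa_deterministic_and_sign_recovery(track_mid, landscape_low):
    track = h.truncate_track(track_mid, 1000)
    fit = h.fit_issa(track, landscape_low, seed=5)
    again = h.fit_issa(track, landscape_low, seed=5)
    pd.testing.assert_frame_equal(fit.table, again.table)
    assert fit.converged
    assert fit["elev"] > 0 and fit["hab"] < 0
    assert {"log_sl", "cos_ta"} <= set(fit.table.index)
    plain = h.fit_issa(track, landscape_low, seed=5, movement_adjust=False)
    assert {"log_sl", "cos_ta"}.isdisjoint(plain.table.index)
    assert plain["elev"] > 0


def test_issa_failure_recorded_not_raised(landscape_low):
    # constant-position track: degenerate step lengths, fit cannot proceed
    track = h.Track("still", times=np.arange(1, 61),
                    xs=np.full(60, 10), ys=np.full(60, 10))
    fit = h.fit_issa(track, landscape_low, seed=0)
    assert not fit.converged
    assert "error" in fit.meta


def test_more_available_points_reduce_sampling_variance(track_mid,
                                                        landscape_low):
    """Monte-Carlo variance of beta-hat across availability resamples
    shrinks as the available:used ratio grows."""
    track = h.truncate_track(track_mid, 300)
    ests = {r: [] for r in (5, 50)}
    for r in ests:
        for s in range(12):
            fit = h.fit_rsa(track, landscape_low, ratio=r, seed=200 + s)
            ests[r].append(fit["elev"])
    assert np.var(ests[50]) < np.var(ests[5])


def test_results_to_tidy_schema(track_mid, landscape_low):
    fit = h.fit_rsa(h.truncate_track(track_mid, 200), landscape_low, seed=1)
    fit.meta.update(fract_dim_elev=0.01, fract_dim_hab=0.01,
                    landscape_id=0, track_id=0)
    tidy = h.results_to_tidy([fit])
    assert list(tidy.columns) == h.estimators.TIDY_COLUMNS
    assert set(tidy["covariate"]) == {"intercept", "elev", "hab"}
    assert (tidy["n_used"] == 200).all()
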