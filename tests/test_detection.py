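import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from birdradar.detection import (BEYOND_DATA, FitError, blip_scan_ratio,
                                 clutter_contrast, crossing_range,
                                 detection_range_at, fit_detection_glmm,
                                 glmm_loglik, DetectionFit)

from conftest import make_glmm_data


def trapezoid_loglik(beta, sigma, X, y, groups, width=10.0, n=40001):
    """Brute-force numerical integration of the marginal likelihood."""
    u = np.linspace(-width, width, n)
    total = 0.0
    for g in np.unique(groups):
        sel = groups == g
        e = X[sel] @ beta
        e = e[:, None] + sigma * u[None, :]
        ll = np.sum(y[sel][:, None] * e - np.logaddexp(0.0, e), axis=0)
        dens = np.exp(ll - u ** 2 / 2.0) / np.sqrt(2.0 * np.pi)
        total += np.log(np.trapezoid(dens, u))
    return total


def toy_instance(seed):
    rng = np.random.default_rng(seed)
    n = 18
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    groups = np.repeat([0, 1, 2], 6)
    beta = np.array([0.3, -0.9])
    sigma = 0.8
    y = (rng.random(n) < expit(X @ beta + sigma * rng.normal(size=3)[groups])
         ).astype(float)
    return X, y, groups


@pytest.mark.parametrize("seed", [0, 1, 2])
@pytest.mark.parametrize("sigma", [0.0, 0.4, 1.2])
def test_quadrature_matches_numerical_integration(seed, sigma):
    """Adaptive quadrature log-likelihood equals fine-grid integration."""
    X, y, groups = toy_instance(seed)
    beta = np.array([0.2, -0.7])
    agq = glmm_loglik(beta, sigma, X, y, groups)
    ref = trapezoid_loglik(beta, sigma, X, y, groups)
    assert agq == pytest.approx(ref, abs=1e-4)


def test_fit_recovers_generating_parameters():
    df = make_glmm_data(3, n_tracks=10, per_track=400, beta0=3.0,
                        beta_range=-0.00134, beta_clutter=-0.6,
                        beta_orientation=-0.3, beta_tortuosity=-0.8,
                        sigma=0.5)
    fit = fit_detection_glmm(df, covariates=("range", "in_clutter",
                                             "orientation", "tortuosity"))
    assert fit.converged
    for name, truth in [("intercept", 3.0), ("range", -0.00134),
                        ("in_clutter", -0.6), ("orientation", -0.3)]:
        est, se = fit.coefficients[name], fit.se[name]
        assert abs(est - truth) < 4.0 * se, name
    assert 0.1 < fit.sigma_track < 1.2


def test_fit_matches_lme4_reference(tmp_path):
    """Independent oracle: R lme4 glmer with 15-node adaptive quadrature."""
    if shutil.which("Rscript") is None:
        pytest.fail("Rscript not available for the lme4 cross-check")
    df = make_glmm_data(7, n_tracks=8, per_track=120, beta0=3.0,
                        beta_range=-0.0013, beta_orientation=-0.4,
                        beta_tortuosity=-0.8, sigma=0.6)
    fit = fit_detection_glmm(df)
    csv = str(tmp_path / "d.csv")
    out = df.copy()
    out["across"] = (out["orientation"] == "across").astype(int)
    out["det"] = out["detected"].astype(int)
    out.to_csv(csv, index=False)
    script = textwrap.dedent(f"""
        suppressMessages(library(lme4))
        d <- read.csv('{csv}')
        m <- glmer(det ~ range + across + tortuosity + (1|track_id),
                   data=d, family=binomial, nAGQ=15)
        b <- fixef(m)
        cat(b[1], b[2], b[3], b[4], sqrt(unlist(VarCorr(m))),
            as.numeric(logLik(m)), sep='\\n')
    """)
    res = subprocess.run(["Rscript", "-e", script], capture_output=True,
                         text=True, timeout=300)
    vals = [float(v) for v in res.stdout.strip().split("\n")]
    b0, brange, bacross, btort, sigma_r, ll_r = vals
    assert fit.coefficients["intercept"] == pytest.approx(b0, abs=2e-3)
    assert fit.coefficients["range"] == pytest.approx(brange, rel=2e-3)
    assert fit.coefficients["orientation"] == pytest.approx(bacross, abs=2e-3)
    assert fit.coefficients["tortuosity"] == pytest.approx(btort, abs=5e-3)
    assert fit.sigma_track == pytest.approx(sigma_r, abs=5e-3)
    assert fit.loglik == pytest.approx(ll_r, abs=1e-3)


def test_all_same_outcome_raises():
    df = make_glmm_data(0)
    df["detected"] = True
    with pytest.raises(FitError):
        fit_detection_glmm(df)


def test_single_track_pins_random_effect():
    df = make_glmm_data(1, n_tracks=1, per_track=200, beta0=1.0,
                        beta_range=-0.0005)
    with pytest.warns(UserWarning):
        fit = fit_detection_glmm(df, covariates=("range",))
    assert fit.sigma_track == 0.0


def fixed_fit(coeffs, cov=None, names=None):
    names = names or list(coeffs)
    k = len(names)
    return DetectionFit(coefficients=coeffs, cov=cov if cov is not None
                        else np.zeros((k, k)), names=names, sigma_track=0.0,
                        n_obs=0, n_tracks=0, converged=True, loglik=0.0,
                        mean_range=1000.0)


def test_detection_range_closed_form():
    fit = fixed_fit({"intercept": 2.34, "range": -0.001})
    res = detection_range_at(fit, 0.5)
    assert res.range_at_pd == pytest.approx(2340.0)
    res0 = detection_range_at(fixed_fit({"intercept": 0.0, "range": -0.001}), 0.5)
    assert res0.range_at_pd == pytest.approx(0.0)


def test_detection_range_requires_negative_slope():
    with pytest.raises(FitError):
        detection_range_at(fixed_fit({"intercept": 1.0, "range": 0.001}), 0.5)


def test_detection_range_unit_equivariance():
    """Expressing range in different units rescales the solved range exactly."""
    cov = np.array([[0.04, -1e-5], [-1e-5, 4e-8]])
    fit_m = fixed_fit({"intercept": 3.0, "range": -0.0013}, cov=cov)
    cov_km = cov * np.array([[1.0, 1e3], [1e3, 1e6]])
    fit_km = fixed_fit({"intercept": 3.0, "range": -1.3}, cov=cov_km)
    rm = detection_range_at(fit_m, 0.5)
    rkm = detection_range_at(fit_km, 0.5)
    assert rm.range_at_pd == pytest.approx(rkm.range_at_pd * 1000.0)
    assert rm.ci_low == pytest.approx(rkm.ci_low * 1000.0)
    assert rm.ci_high == pytest.approx(rkm.ci_high * 1000.0)


def test_clutter_contrast_zero_coefficient():
    fit = fixed_fit({"intercept": 0.3, "range": -0.001, "in_clutter": 0.0})
    c = clutter_contrast(fit, at_range=1000.0)
    assert c.reduction == pytest.approx(0.0)
    assert c.pd_outside == pytest.approx(c.pd_inside)


def test_clutter_contrast_recovers_simulated_reduction():
    df = make_glmm_data(11, n_tracks=8, per_track=300, beta0=0.04,
                        beta_clutter=-0.615, sigma=0.3)
    fit = fit_detection_glmm(df, covariates=("range", "in_clutter"))
    c = clutter_contrast(fit, at_range=0.0)
    # truth: Pd 0.51 -> 0.36, a 28% reduction
    true_red = 1.0 - expit(0.04 - 0.615) / expit(0.04)
    assert c.ci_reduction[0] <= true_red <= c.ci_reduction[1]
    assert c.reduction == pytest.approx(true_red, abs=0.12)


def test_blip_scan_counts_and_conservation():
    obs = pd.DataFrame({
        "range": [110.0, 112.0, 120.0, 124.0, 300.0, 310.0],
        "detected": [True, True, True, False, True, False],
    })
    t = blip_scan_ratio(obs, bin_width=25.0)
    row = t[t["bin_left"] == 100.0].iloc[0]
    assert row["n_opportunities"] == 4 and row["pd"] == pytest.approx(0.75)
    # pooled conservation: total detections / total opportunities
    assert (t["n_detections"].sum() / t["n_opportunities"].sum()
            == pytest.approx(obs["detected"].mean()))
    assert t["pd"].between(0, 1).all()


def test_blip_scan_all_detected():
    obs = pd.DataFrame({"range": np.linspace(0, 500, 40),
                        "detected": np.ones(40, bool)})
    t = blip_scan_ratio(obs)
    assert (t["pd"] == 1.0).all()


def test_crossing_range_step_and_sentinel():
    bins = np.arange(0.0, 1000.0, 25.0)
    table = pd.DataFrame({"bin_left": bins, "bin_width": 25.0,
                          "n_opportunities": 10, "n_detections": 10,
                          "pd": np.where(bins < 500.0, 1.0, 0.0)})
    # 5-bin centered moving average first dips below 0.5 at the step bin
    assert crossing_range(table, 0.5) == pytest.approx(512.5, abs=25.0)
    table_hi = table.assign(pd=1.0)
    assert crossing_range(table_hi, 0.5) == BEYOND_DATA


def test_crossing_range_logistic_decay():
    """On the expected (noise-free) blip/scan curve of a logistic decay with
    Pd = 0.5 at 2,340 m, the automated read lands within two bins."""
    bins = np.arange(0.0, 3500.0, 25.0)
    centers = bins + 12.5
    p_true = expit(3.136 - 0.00134 * centers)
    table = pd.DataFrame({"bin_left": bins, "bin_width": 25.0,
                          "n_opportunities": 100,
                          "n_detections": 100 * p_true, "pd": p_true})
    cr = crossing_range(table, 0.5)
    assert abs(cr - 2340.0) <= 2 * 25.0


def test_crossing_matches_model_range_at_scale():
    """Binned and modelled detection ranges agree on simulated data.

    With ~25 opportunities per 25-m bin the moving-average read of the
    binned curve carries ~±130 m binomial jitter, so agreement is asserted
    at that scale (the noise-free accuracy of the read is two bins, checked
    separately above)."""
    df = make_glmm_data(31, n_tracks=5, per_track=600, beta0=3.136,
                        beta_range=-0.00134, sigma=0.2)
    fit = fit_detection_glmm(df, covariates=("range",))
    modeled = detection_range_at(fit, 0.5).range_at_pd
    crossed = crossing_range(blip_scan_ratio(df), 0.5)
    assert abs(modeled - crossed) <= 150.0
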