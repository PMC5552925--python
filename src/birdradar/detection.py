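"""Binomial random-intercept models of radar detection, and derived ranges.

Per-scan detection outcomes (detected / nondetected) are modelled as

    logit(Pd_ij) = x_ij' beta + u_j,     u_j ~ Normal(0, sigma²)

with a random intercept u_j per flight track absorbing inter-track
dependence (weather, aspect, battery state — anything shared within a
flight). Fixed effects are range from the radar (metres, linear on the
logit scale), clutter membership, orientation relative to the beam
(along/across) and tortuosity. The marginal likelihood integrates the
random intercept out per track with adaptive Gauss–Hermite quadrature
(default 15 nodes, recentred and rescaled at the per-track mode), and is
maximized by quasi-Newton iteration; Wald covariance comes from the
numerically differentiated observed information at the optimum.

From the fitted model, the calibrated detection range is the range at
which Pd crosses a threshold (default 0.5, the tracker's tolerance: a
track survives when every other detection is lost) at reference covariate
levels (along-beam, straight flight, outside clutter), with a delta-method
confidence interval. The empirical counterpart, the blip/scan ratio, bins
detections against opportunities in 25-m range rings.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit, roots_hermite

__all__ = [
    "DetectionFit",
    "DetectionRangeResult",
    "ClutterContrast",
    "glmm_loglik",
    "fit_detection_glmm",
    "detection_range_at",
    "clutter_contrast",
    "blip_scan_ratio",
    "crossing_range",
    "BEYOND_DATA",
]

#: Sentinel returned by crossing_range when Pd never falls below threshold.
BEYOND_DATA = float("inf")

_Z95 = 1.959963984540054


class FitError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# marginal likelihood

def _cluster_loglik(eta_fixed, y, sigma, nodes, weights):
    """Adaptive GH quadrature log-likelihood of one track.

    Integrand: prod_i Bernoulli(y_i | expit(eta_i + sigma z)) * phi(z).
    The mode of the log-integrand is found by Newton iteration; nodes are
    recentred there and scaled by the Laplace curvature.
    """
    def h_parts(z):
        eta = eta_fixed + sigma * z
        # log Bernoulli: y*eta - log1p(exp(eta)), stable form
        ll = y * eta - np.logaddexp(0.0, eta)
        return ll.sum() - 0.5 * z * z - 0.5 * math.log(2.0 * math.pi)

    # Newton for the mode
    z = 0.0
    for _ in range(100):
        p = expit(eta_fixed + sigma * z)
        g = sigma * np.sum(y - p) - z
        hpp = -(sigma * sigma) * np.sum(p * (1.0 - p)) - 1.0
        step = g / hpp
        z_new = z - step
        if abs(z_new - z) < 1e-12:
            z = z_new
            break
        z = z_new
    p = expit(eta_fixed + sigma * z)
    hpp = -(sigma * sigma) * np.sum(p * (1.0 - p)) - 1.0
    tau = 1.0 / math.sqrt(-hpp)

    zk = z + math.sqrt(2.0) * tau * nodes
    eta = eta_fixed[:, None] + sigma * zk[None, :]
    ll = np.sum(y[:, None] * eta - np.logaddexp(0.0, eta), axis=0)
    logint = ll - 0.5 * zk * zk - 0.5 * math.log(2.0 * math.pi)
    terms = np.log(weights) + nodes * nodes + logint
    m = terms.max()
    return math.log(math.sqrt(2.0) * tau) + m + math.log(np.sum(np.exp(terms - m)))


def glmm_loglik(beta, sigma, X, y, groups, n_nodes: int = 15) -> float:
    """Marginal log-likelihood of the binomial random-intercept model.

    Parameters are on the natural scale: ``beta`` matches the columns of
    ``X`` (first column is typically the intercept), ``sigma >= 0`` is the
    random-intercept SD, ``groups`` labels the track of each row.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    eta = X @ np.asarray(beta, dtype=float)
    nodes, weights = roots_hermite(n_nodes)
    total = 0.0
    for g in np.unique(groups):
        sel = groups == g
        total += _cluster_loglik(eta[sel], y[sel], float(sigma), nodes, weights)
    return total


# ---------------------------------------------------------------------------
# model fitting

_COVARIATE_BUILDERS = {
    "range": lambda df: df["range"].to_numpy(dtype=float),
    "in_clutter": lambda df: df["in_clutter"].to_numpy(dtype=float),
    "orientation": lambda df: (df["orientation"].to_numpy() == "across").astype(float),
    "tortuosity": lambda df: np.nan_to_num(df["tortuosity"].to_numpy(dtype=float)),
}


@dataclass
class DetectionFit:
    """Fitted binomial random-intercept detection model."""

    coefficients: dict                 # name -> fixed effect on the logit scale
    cov: np.ndarray                    # fixed-effect covariance, same order
    names: list
    sigma_track: float
    n_obs: int
    n_tracks: int
    converged: bool
    loglik: float
    mean_range: float = float("nan")   # mean observed range of the fit data
    se: dict = field(default_factory=dict)

    def eta(self, values: dict) -> float:
        """Linear predictor at the given covariate values (missing -> 0)."""
        return float(sum(b * (1.0 if n == "intercept" else values.get(n, 0.0))
                         for n, b in self.coefficients.items()))

    def summary(self) -> pd.DataFrame:
        b = np.array([self.coefficients[n] for n in self.names])
        se = np.sqrt(np.clip(np.diag(self.cov), 0, None))
        z = np.divide(b, se, out=np.full_like(b, np.nan), where=se > 0)
        from scipy.stats import norm
        return pd.DataFrame({"coef": b, "se": se, "z": z,
                             "p": 2 * norm.sf(np.abs(z))}, index=self.names)


def fit_detection_glmm(obs: pd.DataFrame,
                       covariates=("range", "orientation", "tortuosity"),
                       n_nodes: int = 15,
                       gtol: float = 1e-6) -> DetectionFit:
    """Fit the detection GLMM on a paired-observation table.

    ``obs`` needs columns ``detected``, ``track_id`` and one column per
    requested covariate (``orientation`` is coded across=1 vs along=0;
    undefined tortuosity enters as 0, i.e. straight flight). At least two
    tracks are required for the random intercept; with a single track the
    random effect is pinned to zero and a warning issued.
    """
    covariates = list(covariates)
    y = obs["detected"].to_numpy(dtype=float)
    groups = obs["track_id"].to_numpy()
    n_tracks = len(np.unique(groups))
    if y.sum() == 0 or y.sum() == y.size:
        raise FitError("need at least one detection and one nondetection")
    cols = [np.ones(len(obs))]
    for c in covariates:
        cols.append(_COVARIATE_BUILDERS[c](obs))
    X = np.column_stack(cols)
    names = ["intercept"] + covariates

    # column scaling for conditioning (range is O(1000) m)
    scales = np.array([max(np.abs(col).max(), 1e-12) if i > 0 else 1.0
                       for i, col in enumerate(X.T)])
    Xs = X / scales

    single_track = n_tracks < 2
    if single_track:
        warnings.warn("single track: random-intercept SD pinned to 0")

    # starting values: plain logistic regression via a few IRLS steps
    beta0 = np.zeros(X.shape[1])
    beta0[0] = logit(np.clip(y.mean(), 1e-3, 1 - 1e-3))
    b = beta0.copy()
    for _ in range(25):
        p = expit(Xs @ b)
        w = np.clip(p * (1 - p), 1e-10, None)
        zresp = Xs @ b + (y - p) / w
        WX = Xs * w[:, None]
        try:
            b_new = np.linalg.solve(Xs.T @ WX, WX.T @ zresp)
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(b_new - b)) < 1e-8:
            b = b_new
            break
        b = np.clip(b_new, -30, 30)

    nodes, weights = roots_hermite(n_nodes)

    def negll(theta):
        beta = theta[:-1]
        sigma = 0.0 if single_track else math.exp(min(theta[-1], 5.0))
        eta = Xs @ beta
        total = 0.0
        for g in np.unique(groups):
            sel = groups == g
            total += _cluster_loglik(eta[sel], y[sel], sigma, nodes, weights)
        return -total

    theta0 = np.concatenate([b, [math.log(0.5)]])
    res = minimize(negll, theta0, method="BFGS",
                   options={"gtol": gtol, "maxiter": 500})
    theta = res.x
    gnorm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
    converged = bool(res.success or gnorm < 1e-3) and np.all(np.abs(theta[:-1]) < 50)

    sigma = 0.0 if single_track else math.exp(theta[-1])
    beta = theta[:-1] / scales[: len(theta) - 1]

    # observed information by central differences on the full parameter
    k = len(theta)
    H = np.zeros((k, k))
    h = 1e-4
    f0 = negll(theta)
    for i in range(k):
        for j in range(i, k):
            ei = np.eye(k)[i] * h
            ej = np.eye(k)[j] * h
            if i == j:
                H[i, i] = (negll(theta + ei) - 2 * f0 + negll(theta - ei)) / h ** 2
            else:
                H[i, j] = H[j, i] = (negll(theta + ei + ej) - negll(theta + ei - ej)
                                     - negll(theta - ei + ej) + negll(theta - ei - ej)) / (4 * h ** 2)
    try:
        cov_full = np.linalg.pinv(H)
    except np.linalg.LinAlgError:
        cov_full = np.full((k, k), np.nan)
        converged = False
    p = len(beta)
    cov_beta = cov_full[:p, :p] / np.outer(scales[:p], scales[:p])
    cov_beta = 0.5 * (cov_beta + cov_beta.T)
    if np.any(np.diag(cov_beta) < 0):
        converged = False

    coeffs = dict(zip(names, beta))
    se = dict(zip(names, np.sqrt(np.clip(np.diag(cov_beta), 0, None))))
    rng_col = obs["range"].to_numpy(dtype=float) if "range" in obs else np.array([np.nan])
    return DetectionFit(coefficients=coeffs, cov=cov_beta, names=names,
                        sigma_track=float(sigma), n_obs=len(obs),
                        n_tracks=int(n_tracks), converged=converged,
                        loglik=float(-res.fun),
                        mean_range=float(np.nanmean(rng_col)), se=se)


# ---------------------------------------------------------------------------
# derived quantities

@dataclass(frozen=True)
class DetectionRangeResult:
    """Range at which modelled Pd crosses the threshold, with Wald CI (m)."""

    range_at_pd: float
    ci_low: float
    ci_high: float
    pd_threshold: float = 0.5


def detection_range_at(fit: DetectionFit, pd_threshold: float = 0.5,
                       reference: dict | None = None) -> DetectionRangeResult:
    """Solve beta0 + beta_range·R = logit(pd) for R at reference covariates.

    Reference levels default to along-beam orientation, zero tortuosity and
    outside clutter (all non-range covariates at 0); pass ``reference`` to
    override. The CI is by the delta method on
    R = (logit(pd) − eta0) / beta_range using the fixed-effect covariance.
    """
    if "range" not in fit.coefficients:
        raise FitError("model has no range coefficient")
    br = fit.coefficients["range"]
    if br >= 0:
        raise FitError("non-negative range slope: no finite detection range")
    reference = dict(reference or {})
    reference["range"] = 0.0
    eta0 = fit.eta(reference)
    target = float(logit(pd_threshold))
    R = (target - eta0) / br
    grad = np.array([
        (-(1.0 if n == "intercept" else reference.get(n, 0.0)) / br)
        if n != "range" else (-(R) / br)
        for n in fit.names
    ])
    var = float(grad @ fit.cov @ grad)
    se = math.sqrt(max(var, 0.0))
    lo = max(0.0, R - _Z95 * se)
    hi = R + _Z95 * se
    R = max(R, 0.0)
    return DetectionRangeResult(range_at_pd=R, ci_low=min(lo, R),
                                ci_high=max(hi, R), pd_threshold=pd_threshold)


@dataclass(frozen=True)
class ClutterContrast:
    """Detection probability outside vs inside clutter at a reference range."""

    pd_outside: float
    pd_inside: float
    reduction: float                 # 1 - pd_inside/pd_outside
    ci_outside: tuple
    ci_inside: tuple
    ci_reduction: tuple
    at_range: float


def clutter_contrast(fit: DetectionFit, at_range: float | None = None,
                     reference: dict | None = None) -> ClutterContrast:
    """Effect of clutter membership on Pd, as a proportional reduction.

    Evaluated at ``at_range`` metres (default: the mean observed range of
    the fitted data) and reference levels of the other covariates. Point
    CIs are logit-scale Wald intervals mapped through the inverse logit;
    the reduction CI is a delta-method interval on the log-ratio
    log(pd_inside / pd_outside).
    """
    if "in_clutter" not in fit.coefficients:
        raise FitError("model has no in_clutter term")
    if at_range is None:
        at_range = fit.mean_range if np.isfinite(fit.mean_range) else 0.0
    ref = dict(reference or {})
    ref["range"] = float(at_range)

    def xvec(clut):
        vals = dict(ref, in_clutter=clut)
        return np.array([1.0 if n == "intercept" else vals.get(n, 0.0)
                         for n in fit.names])

    x_out, x_in = xvec(0.0), xvec(1.0)
    b = np.array([fit.coefficients[n] for n in fit.names])
    eta_out, eta_in = float(x_out @ b), float(x_in @ b)
    p_out, p_in = float(expit(eta_out)), float(expit(eta_in))

    def eta_ci(x, eta):
        se = math.sqrt(max(float(x @ fit.cov @ x), 0.0))
        return (float(expit(eta - _Z95 * se)), float(expit(eta + _Z95 * se)))

    # log-ratio: d/d beta of [log expit(eta_in) - log expit(eta_out)]
    g = (1.0 - p_in) * x_in - (1.0 - p_out) * x_out
    se_rho = math.sqrt(max(float(g @ fit.cov @ g), 0.0))
    rho = math.log(p_in / p_out)
    red_lo = 1.0 - math.exp(rho + _Z95 * se_rho)
    red_hi = 1.0 - math.exp(rho - _Z95 * se_rho)
    return ClutterContrast(
        pd_outside=p_out, pd_inside=p_in, reduction=1.0 - p_in / p_out,
        ci_outside=eta_ci(x_out, eta_out), ci_inside=eta_ci(x_in, eta_in),
        ci_reduction=(red_lo, red_hi), at_range=float(at_range),
    )


# ---------------------------------------------------------------------------
# blip/scan ratio

def blip_scan_ratio(obs: pd.DataFrame, bin_width: float = 25.0) -> pd.DataFrame:
    """Empirical Pd in left-closed range bins: detections / opportunities.

    Returns a DataFrame with ``bin_left, bin_width, n_opportunities,
    n_detections, pd``; empty bins are omitted.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    rng = obs["range"].to_numpy(dtype=float)
    det = obs["detected"].to_numpy(dtype=bool)
    idx = np.floor(rng / bin_width).astype(int)
    table = (pd.DataFrame({"bin": idx, "det": det.astype(int)})
             .groupby("bin").agg(n_opportunities=("det", "size"),
                                 n_detections=("det", "sum"))
             .reset_index())
    table["bin_left"] = table.pop("bin") * bin_width
    table["bin_width"] = bin_width
    table["pd"] = table["n_detections"] / table["n_opportunities"]
    return table[["bin_left", "bin_width", "n_opportunities",
                  "n_detections", "pd"]].sort_values("bin_left",
                                                     ignore_index=True)


def crossing_range(table: pd.DataFrame, pd_threshold: float = 0.5,
                   window: int = 5, persistence: int = 3) -> float:
    """Automated read of the blip/scan curve's threshold crossing.

    Returns the midpoint of the first bin at which a ``window``-bin moving
    average of Pd falls below the threshold and stays below for
    ``persistence`` consecutive bins; ``BEYOND_DATA`` (inf) if it never
    does.
    """
    if len(table) == 0:
        raise ValueError("empty blip/scan table")
    t = table.sort_values("bin_left")
    ma = t["pd"].rolling(window, min_periods=1, center=True).mean().to_numpy()
    below = ma < pd_threshold
    run = 0
    for i, flag in enumerate(below):
        run = run + 1 if flag else 0
        if run >= persistence:
            j = i - persistence + 1
            return float(t["bin_left"].iloc[j] + t["bin_width"].iloc[j] / 2.0)
    # allow a terminal run shorter than persistence only if it reaches the end
    if run > 0:
        j = len(below) - run
        return float(t["bin_left"].iloc[j] + t["bin_width"].iloc[j] / 2.0)
    return BEYOND_DATA
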