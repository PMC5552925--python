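"""Data-quality screening: segmented-regression thresholds and exclusions.

Detection opportunities at very low altitude (UAV take-off/landing, where
terrain obscures the target) and at very high tortuosity (sharp turns that
track-while-scan algorithms handle poorly) are screened out before the
detection models are fitted. The thresholds are found by segmented
regression on binned detection rates: observations are ranked on the
covariate into equal-count bins, per-bin detection rates are computed, and
for every candidate breakpoint a two-segment piecewise-constant model (mean
rate below, mean rate above) is scored by its total sum of squared
residuals; the breakpoint minimizing the SSR is the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ThresholdFit", "segmented_threshold", "apply_exclusions",
           "ScreeningError"]


class ScreeningError(ValueError):
    pass


@dataclass
class ThresholdFit:
    breakpoint: float
    ssr_total: float
    side: str                      # "lower": keep covariate >= breakpoint
    candidates_evaluated: int
    degenerate: bool = False
    diagnostics: pd.DataFrame = field(default=None, repr=False)


def _bin_rates(covariate, detected, n_bins):
    """Equal-count binning on the covariate; per-bin detection rates.

    Returns (left_edges, centers, rates, counts) over OCCUPIED bins only;
    heavy ties can reduce the effective bin count below ``n_bins``.
    ``left_edges[s]`` is the covariate value at which bin ``s`` begins, i.e.
    the candidate breakpoint that puts bins ``s, s+1, ...`` above the split.
    """
    q = np.linspace(0.0, 1.0, n_bins + 1)
    edges = np.unique(np.quantile(covariate, q))
    if edges.size < 3:
        raise ScreeningError("covariate has too few distinct values to bin")
    idx = np.clip(np.searchsorted(edges, covariate, side="right") - 1,
                  0, edges.size - 2)
    k = edges.size - 1
    counts = np.bincount(idx, minlength=k)
    sums = np.bincount(idx, weights=detected.astype(float), minlength=k)
    occupied = counts > 0
    rates = np.full(k, np.nan)
    rates[occupied] = sums[occupied] / counts[occupied]
    centers = 0.5 * (edges[:-1] + edges[1:])
    return (edges[:-1][occupied], centers[occupied], rates[occupied],
            counts[occupied])


def _two_segment_ssr(rates, split):
    """SSR of mean-below / mean-above model splitting after bin ``split``."""
    below = rates[:split]
    above = rates[split:]
    ssr = 0.0
    for seg in (below, above):
        if seg.size:
            ssr += float(np.sum((seg - seg.mean()) ** 2))
    return ssr


def segmented_threshold(covariate, detected, side: str, n_bins: int = 50,
                        min_obs: int = 20) -> ThresholdFit:
    """Breakpoint on a covariate that best splits detection rates in two.

    Parameters
    ----------
    covariate : array-like
        Screening variable (altitude AGL in metres, or tortuosity).
    detected : array-like of bool
        Detection outcome per observation.
    side : {"lower", "upper"}
        "lower": the threshold is a minimum (data below it will be
        excluded, e.g. altitude); "upper": a maximum (tortuosity).
    n_bins : int
        Equal-count bins on the covariate (default 50).

    The cumulative standard deviation of the binned rates (used in the
    companion visual check) is returned in ``diagnostics`` for plotting; it
    plays no part in the automated selection.
    """
    if side not in ("lower", "upper"):
        raise ValueError("side must be 'lower' or 'upper'")
    covariate = np.asarray(covariate, dtype=float)
    detected = np.asarray(detected, dtype=bool)
    ok = np.isfinite(covariate)
    covariate, detected = covariate[ok], detected[ok]
    if covariate.size < min_obs:
        raise ScreeningError(f"need >= {min_obs} observations")
    if np.ptp(covariate) == 0:
        raise ScreeningError("covariate is constant")

    left_edges, centers, rates, counts = _bin_rates(covariate, detected, n_bins)
    diag = pd.DataFrame({"bin_center": centers, "rate": rates,
                         "n": counts,
                         "cum_sd": pd.Series(rates).expanding().std()})

    degenerate = bool(np.ptp(rates) < 1e-12)
    if degenerate:
        bp = float(covariate.min() if side == "lower" else covariate.max())
        return ThresholdFit(breakpoint=bp, ssr_total=_two_segment_ssr(rates, 0),
                            side=side, candidates_evaluated=0, degenerate=True,
                            diagnostics=diag)

    # candidate breakpoints: interior (occupied) bin edges; split s puts
    # bins s.. above the breakpoint
    best = None
    best_fit = None
    k = rates.size
    for s in range(1, k):
        ssr = _two_segment_ssr(rates, s)
        bp = float(left_edges[s])
        retained = float(np.mean(covariate >= bp)) if side == "lower" \
            else float(np.mean(covariate <= bp))
        cand = (round(ssr, 12), -retained, bp)
        if best is None or cand < best:
            best = cand
            best_fit = ThresholdFit(breakpoint=bp, ssr_total=ssr, side=side,
                                    candidates_evaluated=k - 1,
                                    diagnostics=diag)
    return best_fit


def apply_exclusions(obs: pd.DataFrame, alt_min: float, tort_max: float):
    """Drop observations below the altitude threshold or above the
    tortuosity threshold.

    Undefined tortuosity (track ends) and undefined altitude are retained —
    only positive evidence of a screening violation excludes a point.
    Returns ``(retained, report)`` where the report gives per-rule counts
    and the overall excluded fraction.
    """
    if np.isnan(alt_min) or np.isnan(tort_max):
        raise ValueError("thresholds must not be NaN (use -inf/+inf to disable)")
    alt = obs["alt"].to_numpy(dtype=float)
    tort = obs["tortuosity"].to_numpy(dtype=float)
    low_alt = np.isfinite(alt) & (alt < alt_min)
    high_tort = np.isfinite(tort) & (tort > tort_max)
    drop = low_alt | high_tort
    n = len(obs)
    report = {
        "n_input": n,
        "n_excluded_altitude": int(low_alt.sum()),
        "n_excluded_tortuosity": int(high_tort.sum()),
        "n_excluded": int(drop.sum()),
        "excluded_fraction": float(drop.sum() / n) if n else 0.0,
        "alt_min": float(alt_min),
        "tort_max": float(tort_max),
    }
    return obs.loc[~drop].reset_index(drop=True), report
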