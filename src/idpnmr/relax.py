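"""15N relaxation-rate analysis.

Longitudinal (R1) and transverse (R2) rates are obtained by fitting
peak-height decays to a two-parameter single exponential

    I(t) = I0 * exp(-R * t)

with no offset term.  Experimental errors come from duplicate measurements
at a subset of the relaxation delays: the pooled replicate standard
deviation is converted into a fractional intensity error applied to all
points.  The steady-state heteronuclear NOE is the ratio of peak heights
with and without proton presaturation, noe = I_sat / I_unsat; for a
flexible chain it falls well below the rigid-limit value (~0.75 at 600 MHz)
and can be negative.  Slow proline cis/trans isomerization produces a
duplicate minor peak set whose relative intensity estimates the cis
population fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit


@dataclass
class DecaySeries:
    """Peak-height decay for one residue.

    delays are in seconds; replicate_ids distinguish repeated measurements
    at the same delay (0 for the primary pass, 1.. for repeats).
    """

    residue: int
    delays: np.ndarray
    heights: np.ndarray
    replicate_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        if self.replicate_ids is None:
            self.replicate_ids = np.zeros(len(self.delays), dtype=int)
        else:
            self.replicate_ids = np.asarray(self.replicate_ids, dtype=int)
        if not (len(self.delays) == len(self.heights) == len(self.replicate_ids)):
            raise ValueError("delays, heights and replicate_ids must align")
        if np.any(self.delays < 0):
            raise ValueError("negative relaxation delay")

    @property
    def n_distinct_delays(self) -> int:
        return len(np.unique(self.delays))


@dataclass
class RateEstimate:
    """Fitted decay rate with uncertainty and residual statistics."""

    residue: int
    rate: float
    i0: float
    sigma_rate: float
    sigma_i0: float
    rss: float
    n_points: int
    converged: bool = True
    flags: list[str] = field(default_factory=list)

    @property
    def unreliable(self) -> bool:
        return "unreliable" in self.flags or not self.converged


@dataclass
class HetNoePair:
    residue: int
    i_sat: float
    i_unsat: float
    noe: float
    sigma: float
    valid: bool = True


def _exp_model(t: np.ndarray, i0: float, rate: float) -> np.ndarray:
    return i0 * np.exp(-rate * t)


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    # log-linear regression on the positive heights; robust enough as a seed
    pos = y > 0
    if pos.sum() >= 2 and len(np.unique(t[pos])) >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
        return float(np.exp(intercept)), float(max(-slope, 0.0))
    return float(y[np.argmin(t)]) if len(y) else 1.0, 1.0


def fit_exponential(
    series: DecaySeries,
    weights: np.ndarray | None = None,
    error_method: str = "cov",
    n_mc: int = 1000,
    seed: int | None = None,
    allow_offset: bool = False,
) -> RateEstimate:
    """Fit I(t) = I0*exp(-R*t) to one decay series.

    Parameters
    ----------
    weights : per-point standard deviations (same units as heights); used
        both in the weighted least squares and in the reported covariance.
    error_method : "cov" for covariance-based sigma(R) (default) or "mc"
        for Monte Carlo residual resampling with ``n_mc`` draws.
    allow_offset : adds a constant baseline parameter; intended for QC
        only — the reported model has no offset term.

    Replicate points enter as independent observations.  Fewer than three
    distinct delays is rejected; a non-converging fit returns a flagged
    estimate rather than raising.
    """
    if series.n_distinct_delays < 3:
        raise ValueError(
            f"residue {series.residue}: need >= 3 distinct delays, "
            f"got {series.n_distinct_delays}"
        )
    t, y = series.delays, series.heights
    sigma = None if weights is None else np.asarray(weights, dtype=float)
    i0_init, r_init = _initial_guess(t, y)

    if allow_offset:
        model = lambda tt, i0, r, c: i0 * np.exp(-r * tt) + c  # noqa: E731
        p0 = [i0_init, r_init, 0.0]
        bounds = ([-np.inf, 0.0, -np.inf], [np.inf, np.inf, np.inf])
    else:
        model = _exp_model
        p0 = [i0_init, r_init]
        bounds = ([-np.inf, 0.0], [np.inf, np.inf])

    try:
        popt, pcov = curve_fit(
            model, t, y, p0=p0, sigma=sigma, absolute_sigma=sigma is not None,
            bounds=bounds, maxfev=10000,
        )
    except (RuntimeError, ValueError):
        return RateEstimate(
            series.residue, np.nan, np.nan, np.nan, np.nan, np.nan,
            len(y), converged=False, flags=["non-convergence"],
        )

    yhat = model(t, *popt)
    rss = float(np.sum((y - yhat) ** 2))
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))

    if error_method == "mc":
        rng = np.random.default_rng(seed)
        resid = y - yhat
        draws = []
        for _ in range(n_mc):
            y_star = yhat + rng.choice(resid, size=len(resid), replace=True)
            try:
                p_star, _ = curve_fit(
                    model, t, y_star, p0=popt, bounds=bounds, maxfev=5000
                )
                draws.append(p_star)
            except (RuntimeError, ValueError):
                continue
        if len(draws) >= max(10, n_mc // 10):
            spread = np.std(np.asarray(draws), axis=0, ddof=1)
            perr = spread
    elif error_method != "cov":
        raise ValueError(f"unknown error_method {error_method!r}")

    est = RateEstimate(
        series.residue,
        rate=float(popt[1]),
        i0=float(popt[0]),
        sigma_rate=float(perr[1]),
        sigma_i0=float(perr[0]),
        rss=rss,
        n_points=len(y),
    )
    if est.rate > 0 and est.sigma_rate / est.rate > 0.5:
        est.flags.append("unreliable")
    return est


def replicate_error(series: DecaySeries) -> np.ndarray:
    """Per-point intensity sigmas from replicate measurements.

    Pools the standard deviation over all delays carrying >= 2 replicates,
    expresses it as a fractional error relative to the mean replicate
    intensity, and applies that fraction to every point of the series.
    """
    frac = fractional_replicate_error(series)
    return frac * np.abs(series.heights)


def fractional_replicate_error(series: DecaySeries) -> float:
    """Pooled fractional intensity error from replicated delays."""
    t = series.delays
    groups = [series.heights[t == d] for d in np.unique(t)]
    reps = [g for g in groups if len(g) >= 2]
    if not reps:
        raise ValueError(
            "no replicated delays; supply per-point sigmas explicitly"
        )
    ss = sum(float(np.sum((g - g.mean()) ** 2)) for g in reps)
    dof = sum(len(g) - 1 for g in reps)
    pooled = np.sqrt(ss / dof)
    scale = float(np.mean([np.abs(g).mean() for g in reps]))
    if scale == 0:
        return 0.0
    return pooled / scale


def compute_hetnoe(
    sat: dict[int, float],
    unsat: dict[int, float],
    sigma_sat: dict[int, float] | None = None,
    sigma_unsat: dict[int, float] | None = None,
    invert_ratio: bool = False,
) -> list[HetNoePair]:
    """Steady-state heteronuclear NOE per residue.

    noe = I_sat / I_unsat (saturated over reference).  ``invert_ratio``
    computes the reciprocal for cross-checking against conventions that
    divide the other way.  Residues with I_unsat = 0 are returned masked.
    Uncertainties propagate in quadrature from the supplied intensity
    errors (zero if none given).
    """
    sigma_sat = sigma_sat or {}
    sigma_unsat = sigma_unsat or {}
    out: list[HetNoePair] = []
    for res in sorted(set(sat) & set(unsat)):
        i_s, i_u = float(sat[res]), float(unsat[res])
        denom = i_s if invert_ratio else i_u
        if denom == 0:
            out.append(HetNoePair(res, i_s, i_u, np.nan, np.nan, valid=False))
            continue
        noe = i_u / i_s if invert_ratio else i_s / i_u
        ss, su = sigma_sat.get(res, 0.0), sigma_unsat.get(res, 0.0)
        rel = 0.0
        if i_s != 0:
            rel += (ss / i_s) ** 2
        if i_u != 0:
            rel += (su / i_u) ** 2
        out.append(HetNoePair(res, i_s, i_u, noe, abs(noe) * np.sqrt(rel)))
    return out


def isomer_fraction(
    major_heights: dict[int, float], minor_heights: dict[int, float]
) -> tuple[float, float, dict[int, float]]:
    """Minor-species population from duplicate peak sets.

    For slow cis/trans proline isomerization the minor (cis) fraction at
    each doubled residue is minor/(minor+major); the summary is the mean
    and standard deviation across residues.

    Returns (mean_fraction, sd_fraction, per_residue_fraction).
    """
    common = sorted(set(major_heights) & set(minor_heights))
    fracs: dict[int, float] = {}
    for res in common:
        ma, mi = float(major_heights[res]), float(minor_heights[res])
        if ma < 0 or mi < 0:
            raise ValueError(f"negative peak height at residue {res}")
        if ma + mi == 0:
            continue
        fracs[res] = mi / (ma + mi)
    if not fracs:
        raise ValueError("no residue with quantifiable major+minor peaks")
    vals = np.array(list(fracs.values()))
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return float(vals.mean()), sd, fracs


def r2_over_r1(
    r1: RateEstimate, r2: RateEstimate
) -> tuple[float, float]:
    """Elementwise R2/R1 with quadrature error propagation."""
    if r1.rate == 0:
        raise ZeroDivisionError("R1 = 0")
    ratio = r2.rate / r1.rate
    sig = abs(ratio) * np.sqrt(
        (r1.sigma_rate / r1.rate) ** 2 + (r2.sigma_rate / r2.rate) ** 2
        if r2.rate != 0
        else (r1.sigma_rate / r1.rate) ** 2
    )
    return ratio, sig
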