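"""Pulsed-field-gradient diffusion fitting and hydrodynamic radii.

Signal attenuation versus gradient strength follows the Stejskal-Tanner
relation

    I(g) = I0 * exp(-D * (gamma * g * delta)^2 * (Delta - delta/3) * s)

with gradient duration delta (s), diffusion delay Delta (s), the observed
nucleus' gyromagnetic ratio gamma, and a pulse-shape factor s (1 for the
classic rectangular gradients; sine-shaped gradients scale the effective
area).  The fitted translational diffusion coefficient D converts to a
hydrodynamic (Stokes) radius either against an internal reference
molecule of known R_H (R_H = D_ref/D * R_H,ref — the recommended route,
since it cancels the unknown solvent viscosity) or via Stokes-Einstein
R_H = kB*T / (6 pi eta D).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.constants import k as K_B
from scipy.optimize import curve_fit

from .core import GAMMA_H


@dataclass
class GradientSeries:
    """Relative intensities versus gradient strength for one species."""

    gradients: np.ndarray  # T/m
    intensities: np.ndarray
    delta: float  # gradient pulse duration, s
    big_delta: float  # diffusion delay, s
    gamma: float = GAMMA_H
    shape_factor: float = 1.0

    def __post_init__(self) -> None:
        self.gradients = np.asarray(self.gradients, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.gradients) != len(self.intensities):
            raise ValueError("gradients and intensities must align")
        if len(self.gradients) < 4:
            raise ValueError("need >= 4 gradient points")
        if np.any(self.gradients < 0):
            raise ValueError("negative gradient strength")
        if self.delta <= 0 or self.big_delta <= self.delta / 3:
            raise ValueError("invalid pulse timing")

    @property
    def b_values(self) -> np.ndarray:
        """Stejskal-Tanner exponent prefactor b(g) = (gamma g delta)^2 (Delta - delta/3) s."""
        return (
            (self.gamma * self.gradients * self.delta) ** 2
            * (self.big_delta - self.delta / 3.0)
            * self.shape_factor
        )


@dataclass
class DiffusionFit:
    d: float  # m^2/s
    i0: float
    sigma_d: float
    rss: float
    converged: bool = True
    flags: list | None = None


@dataclass
class HydroResult:
    d: float
    sigma_d: float
    rh: float  # Angstrom
    sigma_rh: float
    method: str


def fit_diffusion(series: GradientSeries) -> DiffusionFit:
    """Least-squares fit of (I0, D) to a gradient decay.

    The fit is invariant to overall intensity scaling (only I0 changes).
    A noiseless non-monotone profile triggers a warning; a flat profile
    yields D = 0 flagged as nonphysical.
    """
    b = series.b_values
    y = series.intensities
    order = np.argsort(b)
    if np.any(np.diff(y[order]) > 1e-9 * np.max(np.abs(y))):
        warnings.warn("non-monotone intensity profile", stacklevel=2)
    if np.ptp(y) == 0:
        return DiffusionFit(0.0, float(y[0]), 0.0, 0.0,
                            flags=["nonphysical: D = 0"])
    pos = y > 0
    if pos.sum() >= 2 and np.ptp(b[pos]) > 0:
        slope, intercept = np.polyfit(b[pos], np.log(y[pos]), 1)
        p0 = [float(np.exp(intercept)), float(max(-slope, 0.0))]
    else:
        p0 = [float(y.max()), 1e-10]
    try:
        popt, pcov = curve_fit(
            lambda bb, i0, d: i0 * np.exp(-d * bb), b, y, p0=p0,
            bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10000,
        )
    except (RuntimeError, ValueError):
        return DiffusionFit(np.nan, np.nan, np.nan, np.nan, False,
                            ["non-convergence"])
    rss = float(np.sum((y - popt[0] * np.exp(-popt[1] * b)) ** 2))
    sigma_d = float(np.sqrt(max(pcov[1, 1], 0.0)))
    flags = []
    if popt[1] == 0:
        flags.append("nonphysical: D = 0")
    return DiffusionFit(float(popt[1]), float(popt[0]), sigma_d, rss,
                        flags=flags or None)


def hydrodynamic_radius(
    d: float,
    sigma_d: float = 0.0,
    reference: tuple[float, float] | None = None,
    solvent: tuple[float, float] | None = None,
) -> HydroResult:
    """Hydrodynamic radius from a diffusion coefficient.

    Exactly one of ``reference`` = (D_ref in m^2/s, R_H,ref in Angstrom)
    or ``solvent`` = (T in K, viscosity in Pa*s) must be given.
    """
    if (reference is None) == (solvent is None):
        raise ValueError("supply exactly one of reference= or solvent=")
    if d <= 0:
        raise ValueError("diffusion coefficient must be positive")
    if reference is not None:
        d_ref, rh_ref = reference
        rh = (d_ref / d) * rh_ref
        method = "reference"
    else:
        temp, eta = solvent
        rh = K_B * temp / (6.0 * np.pi * eta * d) * 1e10  # m -> Angstrom
        method = "stokes-einstein"
    sigma_rh = rh * sigma_d / d
    return HydroResult(d, sigma_d, rh, sigma_rh, method)
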