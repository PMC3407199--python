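"""Reduced spectral density mapping.

The (R1, R2, NOE) triple of a backbone amide 15N is converted into the
spectral density of the N-H bond-vector motion at three frequencies,
J(0), J(omega_N) and J(0.87*omega_H), under the standard single
high-frequency reduction: J(omega) is assumed flat around the proton
frequency, so the three proton-frequency terms collapse onto an effective
frequency 0.87*omega_H.  The mapping is then an exact linear solve:

    sigma_NH     = R1 * (NOE - 1) * gammaN/gammaH
    J(0.87wH)    = (4/5) * sigma_NH / d^2
    J(wN)        = [R1 - (7 d^2/4) J(0.87wH)] / (3 d^2/4 + c^2)
    J(0)         = [R2 - (13 d^2/8) J(0.87wH) - (3 d^2/8 + c^2/2) J(wN)]
                   / (d^2/2 + 2 c^2/3)

with the dipolar constant d = (mu0/4pi) hbar gammaH gammaN / rNH^3 and the
CSA constant c = wN * delta_sigma / sqrt(3).  gammaN is negative, so an
NOE < 1 yields sigma_NH < 0 via the signed ratio and J(0.87wH) > 0.
Chemical exchange is assumed absent: any Rex broadening is absorbed into
J(0).  The exact algebraic inverse :func:`forward_rates` doubles as the
test oracle for the mapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.constants import hbar, mu_0

from .core import GAMMA_H, GAMMA_N, SpectrometerContext


@dataclass(frozen=True)
class InteractionConstants:
    """Dipolar and CSA interaction constants for an amide 15N-1H pair."""

    r_nh: float  # m
    delta_sigma: float  # ppm
    gamma_h: float
    gamma_n: float
    omega_h: float  # rad/s
    omega_n: float  # rad/s
    d: float  # rad/s, dipolar (magnitude)
    c: float  # rad/s, CSA (magnitude)


def make_constants(
    ctx: SpectrometerContext,
    r_nh: float = 1.02e-10,
    delta_sigma: float = 172.0,
) -> InteractionConstants:
    """Interaction constants from field context, bond length and CSA.

    Defaults: rNH = 1.02 Angstrom and delta_sigma = 172 ppm.  d and c are
    computed from CODATA physical constants; doubling rNH divides d by 8
    (r^-3 scaling) and a zero CSA gives c = 0.
    """
    if r_nh <= 0:
        raise ValueError("NH bond length must be positive")
    d = (mu_0 / (4 * np.pi)) * hbar * abs(GAMMA_H * GAMMA_N) / r_nh**3
    c = ctx.omega_n * abs(delta_sigma) * 1e-6 / np.sqrt(3.0)
    return InteractionConstants(
        r_nh=r_nh,
        delta_sigma=delta_sigma,
        gamma_h=GAMMA_H,
        gamma_n=GAMMA_N,
        omega_h=ctx.omega_h,
        omega_n=ctx.omega_n,
        d=d,
        c=c,
    )


def forward_rates(
    j0: float | np.ndarray,
    jwn: float | np.ndarray,
    jwh087: float | np.ndarray,
    k: InteractionConstants,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(R1, R2, NOE) from a spectral-density triple (algebraic inverse).

    R1  = (d^2/4)(3 JwN + 7 JwH) + c^2 JwN
    R2  = (d^2/8)(4 J0 + 3 JwN + 13 JwH) + (c^2/6)(4 J0 + 3 JwN)
    NOE = 1 + (gammaH/gammaN)(d^2/4) * 5 JwH / R1

    Raises if R1 = 0 anywhere (NOE undefined).
    """
    j0 = np.asarray(j0, dtype=float)
    jwn = np.asarray(jwn, dtype=float)
    jwh = np.asarray(jwh087, dtype=float)
    d2, c2 = k.d**2, k.c**2
    r1 = (d2 / 4.0) * (3.0 * jwn + 7.0 * jwh) + c2 * jwn
    r2 = (d2 / 8.0) * (4.0 * j0 + 3.0 * jwn + 13.0 * jwh) + (c2 / 6.0) * (
        4.0 * j0 + 3.0 * jwn
    )
    if np.any(r1 == 0):
        raise ZeroDivisionError("R1 = 0: NOE undefined")
    noe = 1.0 + (k.gamma_h / k.gamma_n) * (d2 / 4.0) * 5.0 * jwh / r1
    return r1, r2, noe


def reduced_jmap(
    r1: float,
    r2: float,
    noe: float,
    k: InteractionConstants,
    sigma_r1: float = 0.0,
    sigma_r2: float = 0.0,
    sigma_noe: float = 0.0,
    n_mc: int = 1000,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Map one (R1, R2, NOE) triple to (J0, JwN, JwH087) with MC errors.

    Returns (j_triple, sigma_triple), both length-3 arrays in s*rad^-1.
    Uncertainties are propagated by Monte Carlo over Gaussian draws of the
    inputs; with all input sigmas zero the sigma triple is zero.  Noise
    can push a mapped J(0) negative; values are reported as computed (the
    caller masks, never clips).
    """
    if r1 <= 0:
        raise ValueError("R1 must be positive")
    j = _map_triple(r1, r2, noe, k)
    if sigma_r1 == sigma_r2 == sigma_noe == 0.0:
        return j, np.zeros(3)
    rng = np.random.default_rng(seed)
    r1s = rng.normal(r1, sigma_r1, n_mc)
    r2s = rng.normal(r2, sigma_r2, n_mc)
    noes = rng.normal(noe, sigma_noe, n_mc)
    ok = r1s > 0
    draws = _map_triple(r1s[ok], r2s[ok], noes[ok], k)
    return j, np.std(draws, axis=-1, ddof=1)


def _map_triple(r1, r2, noe, k: InteractionConstants):
    d2, c2 = k.d**2, k.c**2
    sigma_nh = r1 * (noe - 1.0) * (k.gamma_n / k.gamma_h)
    jwh = (4.0 / 5.0) * sigma_nh / d2
    jwn = (r1 - (7.0 * d2 / 4.0) * jwh) / (3.0 * d2 / 4.0 + c2)
    j0 = (
        r2 - (13.0 * d2 / 8.0) * jwh - (3.0 * d2 / 8.0 + c2 / 2.0) * jwn
    ) / (d2 / 2.0 + 2.0 * c2 / 3.0)
    return np.array([j0, jwn, jwh])


def lorentzian_j(omega: float | np.ndarray, tau: float) -> np.ndarray:
    """Single-Lorentzian spectral density J(w) = (2/5) tau / (1 + (w tau)^2).

    The isotropic rigid-rotor form; in the extreme-narrowing limit
    (w*tau << 1) all sampled J values approach (2/5) tau.
    """
    omega = np.asarray(omega, dtype=float)
    return 0.4 * tau / (1.0 + (omega * tau) ** 2)
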