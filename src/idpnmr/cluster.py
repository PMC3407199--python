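"""Sequence-dependent transverse-relaxation (R2) cluster model.

For a denatured or intrinsically disordered chain the R2 profile is
modelled as an intrinsic segmental-motion baseline plus Gaussian cluster
terms:

    R2(i) = A * sum_j w_j * exp(-|i-j| / lambda0)
          + sum_c R2c * exp(-(i - xc)^2 / (2 Delta^2))

The first term says that the influence of residue j's local motion on
residue i decays exponentially with sequence separation, with persistence
length lambda0 (in residues).  The per-residue weight w_j is a proxy for
the intrinsic correlation time: in the size-weighted variant w = 1 for
glycine and alanine and w = 7 for all other residues (small residues allow
greater backbone flexibility); in the uniform variant every residue
contributes w = 1.  Each cluster of transiently interacting side chains
adds a Gaussian bump of amplitude R2c (s^-1) centred at residue xc with
half-width Delta.

``width_convention`` selects between Delta acting as a Gaussian sigma
(exp(-(i-xc)^2/(2 Delta^2)), the default) and as a plain Gaussian decay
length (exp(-((i-xc)/Delta)^2)).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .core import PeptideSequence, ResidueTable

SMALL_RESIDUES = set("GA")  # weight 1; everything else weight 7
LAMBDA0_BOUNDS = (0.1, 20.0)


@dataclass
class ClusterComponent:
    """One Gaussian cluster term: amplitude (s^-1), centre, half-width."""

    r2c: float
    xc: float
    delta: float

    def __post_init__(self) -> None:
        if self.r2c < 0:
            raise ValueError("cluster amplitude must be >= 0")
        if self.delta <= 0:
            raise ValueError("cluster half-width must be > 0")


@dataclass
class ClusterModelParams:
    a: float
    lambda0: float
    weights: np.ndarray
    components: list[ClusterComponent] = field(default_factory=list)
    variant: str = "size_weighted"
    width_convention: str = "sigma"

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError("scaling constant A must be >= 0")
        if self.lambda0 <= 0:
            raise ValueError("persistence length must be > 0")
        self.weights = np.asarray(self.weights, dtype=float)


@dataclass
class ClusterFitResult:
    params: ClusterModelParams
    predicted: np.ndarray
    baseline: np.ndarray
    residuals: np.ndarray
    chi2: float
    aicc: float
    n_points: int
    converged: bool = True
    message: str = ""
    param_sigmas: dict[str, float] = field(default_factory=dict)

    @property
    def rss(self) -> float:
        return float(np.sum(self.residuals**2))


def residue_weights(seq: PeptideSequence, variant: str = "size_weighted") -> np.ndarray:
    """Per-residue weight vector for the intrinsic term.

    size_weighted: 1 for Gly/Ala, 7 otherwise.  uniform: all ones.
    """
    if variant == "uniform":
        return np.ones(len(seq))
    if variant == "size_weighted":
        return np.array(
            [1.0 if aa in SMALL_RESIDUES else 7.0 for aa in seq.residues]
        )
    raise ValueError(f"unknown variant {variant!r}")


def _gauss(i: np.ndarray, comp: ClusterComponent, convention: str) -> np.ndarray:
    z = (i - comp.xc) / comp.delta
    if convention == "sigma":
        return comp.r2c * np.exp(-0.5 * z**2)
    if convention == "decay":
        return comp.r2c * np.exp(-(z**2))
    raise ValueError(f"unknown width convention {convention!r}")


def intrinsic_r2(
    a: float, lambda0: float, weights: np.ndarray, indices: np.ndarray
) -> np.ndarray:
    """First (baseline) term, vectorized over the |i-j| kernel matrix."""
    idx = np.asarray(indices, dtype=float)
    kernel = np.exp(-np.abs(idx[:, None] - idx[None, :]) / lambda0)
    return a * kernel @ np.asarray(weights, dtype=float)


def model_r2(params: ClusterModelParams, seq: PeptideSequence) -> np.ndarray:
    """Predicted R2 profile over all residues of the sequence."""
    idx = seq.indices.astype(float)
    if len(params.weights) != len(seq):
        raise ValueError("weight vector does not match sequence length")
    out = intrinsic_r2(params.a, params.lambda0, params.weights, idx)
    for comp in params.components:
        out = out + _gauss(idx, comp, params.width_convention)
    return out


def _pack(a, lam, comps):
    return np.concatenate([[a, lam], np.ravel([[c.r2c, c.xc, c.delta] for c in comps])]) \
        if comps else np.array([a, lam])


def _unpack(theta, k):
    comps = [
        ClusterComponent(theta[2 + 3 * c], theta[3 + 3 * c], theta[4 + 3 * c])
        for c in range(k)
    ]
    return float(theta[0]), float(theta[1]), comps


def _aicc(rss: float, n: int, p: int) -> float:
    if n <= p + 1:
        return np.inf
    return n * np.log(max(rss, 1e-300) / n) + 2 * p + 2 * p * (p + 1) / (n - p - 1)


def fit_cluster_model(
    profile: ResidueTable,
    seq: PeptideSequence,
    n_clusters: int = 1,
    variant: str = "size_weighted",
    width_convention: str = "sigma",
    fix_lambda0: float | None = None,
    n_bootstrap: int = 0,
    seed: int | None = None,
) -> ClusterFitResult:
    """Weighted nonlinear least-squares fit of the cluster model.

    Free parameters are (A, lambda0) plus (R2c, xc, Delta) per cluster;
    ``fix_lambda0`` pins the persistence length to a given value instead of
    optimizing it.  Cluster centres are multistarted at the local maxima of
    (data - cluster-free prefit baseline); ties break on lowest chi^2.
    Parameter uncertainties come from a bootstrap over residues
    (``n_bootstrap`` refits on residue resamples).
    """
    k = int(n_clusters)
    n_ok = int(profile.mask.sum())
    if n_ok == 0:
        raise ValueError("all residues masked")
    if n_ok < 3 * k + 2:
        raise ValueError(
            f"{n_ok} unmasked residues cannot identify {k} cluster(s): "
            f"need >= {3 * k + 2}"
        )
    weights_all = residue_weights(seq, variant)
    if not np.all(np.isin(profile.indices, seq.indices)):
        raise ValueError("profile indices outside sequence range")

    idx_all = seq.indices.astype(float)
    obs_pos = np.searchsorted(seq.indices, profile.valid_indices)
    y = profile.valid_values
    sig = profile.valid_sigmas
    w_ls = np.where(sig > 0, 1.0 / np.where(sig > 0, sig, 1.0), 1.0)

    lam_lo, lam_hi = LAMBDA0_BOUNDS
    first, last = seq.first_index, seq.last_index

    def predict(theta: np.ndarray) -> np.ndarray:
        a, lam, comps = _unpack(theta, k)
        lam = fix_lambda0 if fix_lambda0 is not None else lam
        out = intrinsic_r2(a, lam, weights_all, idx_all)
        for comp in comps:
            out = out + _gauss(idx_all, comp, width_convention)
        return out

    def resid(theta: np.ndarray) -> np.ndarray:
        return (predict(theta)[obs_pos] - y) * w_ls

    # cluster-free prefit for the baseline and the multistart candidates
    kernel_scale = intrinsic_r2(1.0, 2.0, weights_all, idx_all)[obs_pos].mean()
    a0 = max(float(y.mean()) / kernel_scale, 1e-6)
    lo2 = [0.0, lam_lo]
    hi2 = [np.inf, lam_hi]
    pre = least_squares(
        lambda th: (intrinsic_r2(th[0], fix_lambda0 or th[1], weights_all, idx_all)[obs_pos] - y) * w_ls,
        x0=[a0, 2.0], bounds=(lo2, hi2),
    )
    base_resid = y - intrinsic_r2(
        pre.x[0], fix_lambda0 or pre.x[1], weights_all, idx_all
    )[obs_pos]

    if k == 0:
        theta_best, best = pre.x, pre
    else:
        centers = _candidate_centers(profile.valid_indices, base_resid)
        amp0 = max(float(base_resid.max()), 0.1)
        lo = lo2 + [0.0, first - 2.0, 0.5] * k
        hi = hi2 + [np.inf, last + 2.0, float(len(seq))] * k
        best = None
        theta_best = None
        for combo in itertools.islice(itertools.combinations(centers, k), 12):
            x0 = np.concatenate(
                [pre.x, np.ravel([[amp0, c, 2.0] for c in combo])]
            )
            try:
                sol = least_squares(resid, x0=x0, bounds=(lo, hi))
            except ValueError:
                continue
            if sol.success and (best is None or sol.cost < best.cost):
                best, theta_best = sol, sol.x
        if best is None:
            params = ClusterModelParams(
                pre.x[0], fix_lambda0 or pre.x[1], weights_all, [], variant,
                width_convention,
            )
            nanrow = np.full(len(seq), np.nan)
            return ClusterFitResult(
                params, nanrow, nanrow, np.full(n_ok, np.nan), np.nan, np.nan,
                n_ok, converged=False, message="no multistart converged",
            )

    a_fit, lam_fit, comps = _unpack(theta_best, k)
    lam_fit = fix_lambda0 if fix_lambda0 is not None else lam_fit
    params = ClusterModelParams(
        a_fit, lam_fit, weights_all, comps, variant, width_convention
    )
    predicted = model_r2(params, seq)
    baseline = intrinsic_r2(a_fit, lam_fit, weights_all, idx_all)
    residuals = y - predicted[obs_pos]
    chi2 = float(np.sum((residuals * w_ls) ** 2))
    p = len(theta_best) - (1 if fix_lambda0 is not None else 0)
    result = ClusterFitResult(
        params, predicted, baseline, residuals, chi2,
        _aicc(float(np.sum(residuals**2)), n_ok, p), n_ok,
    )
    if n_bootstrap > 0:
        result.param_sigmas = _bootstrap_sigmas(
            profile, seq, theta_best, k, variant, width_convention,
            fix_lambda0, n_bootstrap, seed,
        )
    return result


def _candidate_centers(indices: np.ndarray, resid: np.ndarray) -> list[float]:
    """Local maxima of the baseline-subtracted profile, best first."""
    cands = []
    for p in range(len(resid)):
        left = resid[p - 1] if p > 0 else -np.inf
        right = resid[p + 1] if p < len(resid) - 1 else -np.inf
        if resid[p] >= left and resid[p] >= right:
            cands.append((resid[p], float(indices[p])))
    cands.sort(reverse=True)
    out = [c for _, c in cands]
    top = float(indices[np.argmax(resid)])
    if top not in out:
        out.insert(0, top)
    return out


def _bootstrap_sigmas(
    profile, seq, theta_hat, k, variant, width_convention, fix_lambda0,
    n_bootstrap, seed,
) -> dict[str, float]:
    rng = np.random.default_rng(seed)
    ok = np.flatnonzero(profile.mask)
    draws = []
    for _ in range(n_bootstrap):
        pick = rng.choice(ok, size=len(ok), replace=True)
        # collapse duplicate residues to unique picks to keep indices unique
        pick = np.unique(pick)
        if len(pick) < 3 * k + 2:
            continue
        sub = ResidueTable(
            profile.indices[pick], profile.values[pick], profile.sigmas[pick]
        )
        try:
            fit = _refit_from(sub, seq, theta_hat, k, variant,
                              width_convention, fix_lambda0)
        except Exception:
            continue
        if fit is not None:
            draws.append(fit)
    names = ["a", "lambda0"] + [
        f"{p}{c + 1}" for c in range(k) for p in ("r2c", "xc", "delta")
    ]
    if len(draws) < 5:
        return {n: np.nan for n in names}
    arr = np.asarray(draws)
    return {n: float(s) for n, s in zip(names, arr.std(axis=0, ddof=1))}


def _refit_from(profile, seq, theta0, k, variant, width_convention, fix_lambda0):
    weights_all = residue_weights(seq, variant)
    idx_all = seq.indices.astype(float)
    obs_pos = np.searchsorted(seq.indices, profile.valid_indices)
    y = profile.valid_values
    sig = profile.valid_sigmas
    w_ls = np.where(sig > 0, 1.0 / np.where(sig > 0, sig, 1.0), 1.0)
    lam_lo, lam_hi = LAMBDA0_BOUNDS
    first, last = seq.first_index, seq.last_index
    lo = [0.0, lam_lo] + [0.0, first - 2.0, 0.5] * k
    hi = [np.inf, lam_hi] + [np.inf, last + 2.0, float(len(seq))] * k

    def resid(theta):
        a, lam, comps = _unpack(theta, k)
        lam = fix_lambda0 if fix_lambda0 is not None else lam
        out = intrinsic_r2(a, lam, weights_all, idx_all)
        for comp in comps:
            out = out + _gauss(idx_all, comp, width_convention)
        return (out[obs_pos] - y) * w_ls

    x0 = np.clip(theta0, np.asarray(lo) + 1e-9, np.asarray(hi) - 1e-9)
    sol = least_squares(resid, x0=x0, bounds=(lo, hi))
    return sol.x if sol.success else None


def select_n_clusters(
    profile: ResidueTable,
    seq: PeptideSequence,
    candidates: tuple[int, ...] = (0, 1, 2),
    **kwargs,
) -> tuple[int, dict[int, ClusterFitResult]]:
    """Small-sample-corrected information-criterion choice of K."""
    fits: dict[int, ClusterFitResult] = {}
    for k in candidates:
        try:
            fits[k] = fit_cluster_model(profile, seq, n_clusters=k, **kwargs)
        except ValueError:
            continue
    ok = {k: f for k, f in fits.items() if f.converged}
    if not ok:
        raise RuntimeError("no candidate K converged")
    best = min(ok, key=lambda k: ok[k].aicc)
    return best, fits


def compare_variants(
    profile: ResidueTable,
    seq: PeptideSequence,
    n_clusters: int = 1,
    **kwargs,
) -> dict[str, ClusterFitResult]:
    """Fit size-weighted and uniform variants side by side.

    Returns a dict keyed by variant; cluster centres, widths and AICc can
    be read off the two :class:`ClusterFitResult` objects.  Deterministic
    given the seed passed through ``kwargs``.
    """
    return {
        variant: fit_cluster_model(
            profile, seq, n_clusters=n_clusters, variant=variant, **kwargs
        )
        for variant in ("size_weighted", "uniform")
    }
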