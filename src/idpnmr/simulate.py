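"""Synthetic spectrometer-level data with known ground truth.

Every generator returns a (truth, data) pair and is a deterministic
function of (config, seed), so each downstream fit has a parameter-
recovery test keyed to the truth.  The defaults emulate the study
conditions of a denatured 20-residue Trp-cage peptide at 600 MHz:

* peak-height decays at ten relaxation delays (10-1200 ms for R1,
  15.6-469.4 ms for R2) with 2% multiplicative intensity noise and
  duplicate measurements at exactly two delays per series;
* R2 profiles from the segmental-motion cluster model with one Gaussian
  cluster (amplitude 2 s^-1 at residue 8, half-width 3) on the
  size-weighted baseline (A = 0.05, lambda0 = 2), 0.1 s^-1 additive noise;
* a cluster-free "random-coil control" preset whose intrinsic amplitude
  is anchored so the profile tops out near 3.2 s^-1, emulating a
  Trp-deleted variant that relaxes like a statistical coil;
* relaxation triples from a single-Lorentzian spectral density at the
  60.25 MHz 15N field;
* shift tables = packaged random-coil references + a localized Gaussian
  secondary-shift bump (helix-like signs: +CA, +C', -CB), 0.02 ppm noise;
* Stejskal-Tanner gradient decays.

Prolines carry no backbone HN; the paper-like preset masks them for all
HN-detected observables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .cluster import ClusterComponent, ClusterModelParams, model_r2, residue_weights
from .core import DEFAULT_CONTEXT, PeptideSequence, ResidueTable, TC5B_SEQUENCE, write_fasta
from .jmap import InteractionConstants, forward_rates, lorentzian_j, make_constants
from .diffusion import GradientSeries
from .relax import DecaySeries
from .shifts import ShiftRecord, corrected_random_coil, load_coil_table

R1_DELAYS_MS = (10.0, 20.0, 40.0, 80.0, 150.0, 250.0, 400.0, 600.0, 900.0, 1200.0)
R2_DELAYS_MS = (15.6, 31.3, 62.6, 93.9, 125.2, 187.7, 250.3, 312.9, 391.1, 469.4)


@dataclass
class SimulationConfig:
    """Truth parameters and noise levels for the synthetic study."""

    seed: int = 0
    sequence: str = TC5B_SEQUENCE
    r1_delays_ms: tuple = R1_DELAYS_MS
    r2_delays_ms: tuple = R2_DELAYS_MS
    fractional_noise: float = 0.02  # multiplicative intensity noise
    replicate_delay_positions: tuple = (1, 5)  # duplicate these delay indices
    r2_profile_noise: float = 0.1  # s^-1, additive
    shift_noise_ppm: float = 0.02
    # cluster-model truth (size-weighted variant)
    cluster_a: float = 0.05
    cluster_lambda0: float = 2.0
    cluster_components: tuple = ((2.0, 8.0, 3.0),)  # (R2c, xc, Delta)
    # cluster-free control: intrinsic amplitude anchored to a coil-like
    # profile peaking near 3.2 s^-1
    null_a: float = 0.12
    # shift-perturbation truth
    shift_bump_amplitude: float = 0.5  # ppm, applied +CA/+C and -CB
    shift_bump_center: float = 6.0
    shift_bump_width: float = 2.5
    # diffusion truth
    diffusion_d: float = 1.5e-10  # m^2/s
    gradient_max: float = 0.5  # T/m
    n_gradients: int = 16
    pfg_delta: float = 0.004  # s
    pfg_big_delta: float = 0.1  # s
    # cis/trans isomer truth
    cis_fraction: float = 0.2
    isomer_noise: float = 0.1
    n_isomer_residues: int = 8

    def __post_init__(self) -> None:
        for name in ("fractional_noise", "r2_profile_noise", "shift_noise_ppm",
                     "isomer_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for sched in (self.r1_delays_ms, self.r2_delays_ms):
            if np.any(np.diff(sched) <= 0):
                raise ValueError("delay schedules must be strictly increasing")

    @property
    def peptide(self) -> PeptideSequence:
        return PeptideSequence(self.sequence)

    def truth_cluster_params(self, null: bool = False) -> ClusterModelParams:
        seq = self.peptide
        w = residue_weights(seq, "size_weighted")
        if null:
            return ClusterModelParams(self.null_a, self.cluster_lambda0, w, [])
        comps = [ClusterComponent(*c) for c in self.cluster_components]
        return ClusterModelParams(self.cluster_a, self.cluster_lambda0, w, comps)


def _rng(cfg: SimulationConfig, offset: int = 0) -> np.random.Generator:
    return np.random.default_rng(cfg.seed + offset)


def simulate_r2_profile(
    cfg: SimulationConfig, null: bool = False
) -> tuple[ClusterModelParams, ResidueTable]:
    """Noisy per-residue R2 profile from the cluster model.

    With ``null=True`` the cluster terms are dropped and the coil-control
    intrinsic amplitude is used.  Returns (truth parameters, data); zero
    noise reproduces the forward model exactly.
    """
    seq = cfg.peptide
    truth = cfg.truth_cluster_params(null=null)
    clean = model_r2(truth, seq)
    rng = _rng(cfg, 1)
    noisy = clean + rng.normal(0.0, cfg.r2_profile_noise, len(clean))
    sig = np.full(len(clean), cfg.r2_profile_noise)
    return truth, ResidueTable(seq.indices, noisy, sig)


def simulate_decays(
    rates: ResidueTable, cfg: SimulationConfig, schedule: str = "r2",
    i0: float = 100.0,
) -> dict[int, DecaySeries]:
    """Exponential peak-height decays for a table of true rates.

    Gaussian multiplicative noise at ``cfg.fractional_noise``; the delays
    at ``cfg.replicate_delay_positions`` carry one duplicate measurement
    each (two replicated mixing times per series).
    """
    delays_ms = cfg.r1_delays_ms if schedule == "r1" else cfg.r2_delays_ms
    t = np.asarray(delays_ms) * 1e-3
    rng = _rng(cfg, 2)
    out: dict[int, DecaySeries] = {}
    for res, rate, _, ok in rates:
        if not ok:
            continue
        if rate <= 0:
            raise ValueError(f"non-positive rate at residue {res}")
        tt = list(t)
        kk = [0] * len(t)
        for p in cfg.replicate_delay_positions:
            tt.append(t[p])
            kk.append(1)
        tt = np.asarray(tt)
        clean = i0 * np.exp(-rate * tt)
        noisy = clean * (1.0 + rng.normal(0.0, cfg.fractional_noise, len(tt)))
        out[int(res)] = DecaySeries(int(res), tt, noisy, np.asarray(kk))
    return out


def simulate_rates_from_lorentzian(
    tau_c: ResidueTable,
    constants: InteractionConstants | None = None,
    cfg: SimulationConfig | None = None,
    fractional_noise: float = 0.0,
):
    """(R1, R2, NOE) per residue from single-Lorentzian spectral densities.

    J(w) = (2/5) tau / (1 + (w tau)^2) is evaluated at the three reduced
    frequencies (0, wN, 0.87 wH) and pushed through the forward rate
    equations, so the reduced mapping recovers exactly these J values.
    Optional fractional Gaussian noise applies to all three observables.
    """
    k = constants or make_constants(DEFAULT_CONTEXT)
    cfg = cfg or SimulationConfig()
    rng = _rng(cfg, 3)
    rows = {}
    for res, tau, _, ok in tau_c:
        if not ok:
            continue
        if tau <= 0:
            raise ValueError(f"non-positive correlation time at residue {res}")
        j0 = float(lorentzian_j(0.0, tau))
        jwn = float(lorentzian_j(k.omega_n, tau))
        jwh = float(lorentzian_j(0.87 * k.omega_h, tau))
        r1, r2, noe = forward_rates(j0, jwn, jwh, k)
        vals = np.array([float(r1), float(r2), float(noe)])
        if fractional_noise > 0:
            vals = vals * (1.0 + rng.normal(0.0, fractional_noise, 3))
        rows[int(res)] = tuple(vals)
    return rows


def simulate_shift_table(
    cfg: SimulationConfig,
) -> tuple[dict[tuple[int, str], float], list[ShiftRecord]]:
    """Shift table = random-coil references + a localized Gaussian bump.

    The bump emulates residual helix-like structure: +amplitude on CA and
    C', -amplitude on CB, centred at ``shift_bump_center`` with width
    ``shift_bump_width`` (residues).  Returns (truth ddelta per
    (residue, nucleus), observed records).
    """
    seq = cfg.peptide
    table = load_coil_table("urea8m")
    reference = corrected_random_coil(seq, table)
    rng = _rng(cfg, 4)
    truth: dict[tuple[int, str], float] = {}
    records: list[ShiftRecord] = []
    for (res, nuc), ref in sorted(reference.items()):
        bump = cfg.shift_bump_amplitude * np.exp(
            -((res - cfg.shift_bump_center) ** 2)
            / (2.0 * cfg.shift_bump_width**2)
        )
        dd = -bump if nuc == "CB" else bump
        truth[(res, nuc)] = dd
        obs = ref + dd + rng.normal(0.0, cfg.shift_noise_ppm)
        records.append(ShiftRecord(res, nuc, float(obs)))
    return truth, records


def simulate_diffusion(
    cfg: SimulationConfig, d: float | None = None, noise: float | None = None
) -> tuple[float, GradientSeries]:
    """Stejskal-Tanner gradient decay for a known diffusion coefficient."""
    d = cfg.diffusion_d if d is None else d
    if d <= 0:
        raise ValueError("diffusion coefficient must be positive")
    noise = cfg.fractional_noise if noise is None else noise
    g = np.linspace(0.01, cfg.gradient_max, cfg.n_gradients)
    series = GradientSeries(
        g, np.ones_like(g), cfg.pfg_delta, cfg.pfg_big_delta
    )
    clean = np.exp(-d * series.b_values)
    rng = _rng(cfg, 5)
    y = clean * (1.0 + rng.normal(0.0, noise, len(g))) if noise > 0 else clean
    return d, GradientSeries(g, y, cfg.pfg_delta, cfg.pfg_big_delta)


def simulate_isomer_peaks(
    cfg: SimulationConfig,
) -> tuple[float, dict[int, float], dict[int, float]]:
    """Major/minor duplicate peak sets for a slow two-state isomer exchange.

    Returns (true minor fraction, major heights, minor heights) for
    ``n_isomer_residues`` doubled residues with multiplicative intensity
    noise on both peak sets.
    """
    f = cfg.cis_fraction
    rng = _rng(cfg, 6)
    major, minor = {}, {}
    for res in range(1, cfg.n_isomer_residues + 1):
        total = rng.uniform(50.0, 150.0)
        major[res] = total * (1 - f) * (1.0 + rng.normal(0.0, cfg.isomer_noise))
        minor[res] = total * f * (1.0 + rng.normal(0.0, cfg.isomer_noise))
    return f, major, minor


def proline_positions(seq: PeptideSequence) -> list[int]:
    return seq.positions_of("P")


def paper_like_fixture(outdir: str | Path, cfg: SimulationConfig | None = None) -> dict:
    """Write a complete synthetic fixture directory.

    Contents: sequence FASTA, R1/R2 decay TSVs, saturated/reference
    hetNOE peak tables, shift TSV, the packaged contact transcription,
    gradient TSV and a truth YAML.  Prolines are masked for all
    HN-detected observables.  Returns the truth dictionary.
    """
    from . import io as iom

    cfg = cfg or SimulationConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seq = cfg.peptide
    pro = proline_positions(seq)

    write_fasta(seq, outdir / "sequence.fasta", name="peptide")

    # R2 truth from the cluster model; R1 roughly uniform along the chain
    truth_params, r2_table = simulate_r2_profile(cfg)
    r2_table = r2_table.masked_at(pro)
    r1_clean = ResidueTable(seq.indices, np.full(len(seq), 1.6)).masked_at(pro)
    r2_clean = ResidueTable(
        seq.indices, model_r2(truth_params, seq)
    ).masked_at(pro)
    iom.write_decay_table(
        simulate_decays(r1_clean, cfg, "r1"), outdir / "decays_r1.tsv"
    )
    iom.write_decay_table(
        simulate_decays(r2_clean, cfg, "r2"), outdir / "decays_r2.tsv"
    )

    # hetNOE pairs from a Lorentzian tau profile shaped like the cluster
    k = make_constants(DEFAULT_CONTEXT)
    tau = ResidueTable(
        seq.indices, 0.4e-9 + 0.2e-9 * (model_r2(truth_params, seq) / 3.0)
    ).masked_at(pro)
    rates = simulate_rates_from_lorentzian(tau, k, cfg)
    rng = _rng(cfg, 7)
    with open(outdir / "hetnoe_sat.tsv", "w") as fs, \
            open(outdir / "hetnoe_unsat.tsv", "w") as fu:
        fs.write("# columns: residue\theight\n")
        fu.write("# columns: residue\theight\n")
        for res, (r1, r2, noe) in sorted(rates.items()):
            unsat = 100.0 * (1.0 + rng.normal(0.0, cfg.fractional_noise))
            sat = 100.0 * noe * (1.0 + rng.normal(0.0, cfg.fractional_noise))
            fu.write(f"{res}\t{unsat:.6g}\n")
            fs.write(f"{res}\t{sat:.6g}\n")

    shift_truth, shift_records = simulate_shift_table(cfg)
    iom.write_shift_table(shift_records, outdir / "shifts.tsv")

    contacts = iom.read_contact_table(iom.packaged_contacts_path())
    iom.write_contact_table(contacts, outdir / "contacts.tsv")

    d_true, grad = simulate_diffusion(cfg)
    iom.write_gradient_table(grad, outdir / "gradients.tsv")

    truth = {
        "seed": cfg.seed,
        "sequence": cfg.sequence,
        "proline_masked": [int(p) for p in pro],
        "cluster": {
            "a": cfg.cluster_a,
            "lambda0": cfg.cluster_lambda0,
            "components": [list(c) for c in cfg.cluster_components],
        },
        "r1_true": 1.6,
        "diffusion_d": d_true,
        "shift_bump": {
            "amplitude": cfg.shift_bump_amplitude,
            "center": cfg.shift_bump_center,
            "width": cfg.shift_bump_width,
        },
    }
    with open(outdir / "truth.yaml", "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=False)
    return truth
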