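"""Secondary chemical shifts, consensus CSI and Karplus phi angles.

A secondary shift is the observed shift minus a sequence-corrected
random-coil reference, ddelta = delta_obs - delta_rc(i), where the
reference for residue i is the residue-type base value plus neighbour
corrections from positions i-2..i+2.  Systematic ddelta deviations flag
residual structure; the consensus chemical shift index (CSI) thresholds
the CA, CB and C' secondary shifts (CB with inverted sign), takes a
majority vote per residue and suppresses runs shorter than three residues.
When the reference table was recorded at a different pH, titrating
residue types (Asp/Glu, optionally His) are excluded from the analysis.

3J(HN,HA) couplings constrain the backbone dihedral phi through the
Karplus relation J = A cos^2(phi - 60) + B cos(phi - 60) + C; the curve is
solved exactly for all branches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .core import PeptideSequence

#: Classic consensus-CSI thresholds, ppm.
CSI_THRESHOLDS = {"CA": 0.7, "C": 0.5, "CB": 0.5}
#: Default deviance thresholds for flagging residual structure, ppm.
DEVIANT_THRESHOLDS = {"CA": 0.3, "C": 0.3, "CB": 0.5}
#: Residue types whose 13C shifts titrate between pH 2.5 and ~3.5.
PH_SENSITIVE = frozenset("DE")

#: HNHA-calibrated Karplus coefficients, Hz.
KARPLUS_HNHA = (6.51, -1.76, 1.60)

#: (residue type, nucleus) pairs that legitimately do not exist.
NUCLEUS_ABSENT = {("G", "CB")}


@dataclass
class ShiftRecord:
    residue: int
    nucleus: str
    shift_ppm: float


@dataclass
class SecondaryShiftRecord:
    residue: int
    nucleus: str
    d_obs: float
    d_ref: float
    ddelta: float
    excluded: bool = False
    exclusion_reason: str = ""
    deviant: bool = False


@dataclass
class RandomCoilTable:
    """Base random-coil shifts plus neighbour-correction increments.

    ``base`` maps (residue_type, nucleus) -> ppm.  ``corrections`` maps
    (neighbor_type, offset, nucleus) -> ppm, where the increment is added
    to the reference of residue i when ``neighbor_type`` occupies
    position i + offset (offset in {-2, -1, +1, +2}); corrections default
    to zero when absent.  ``provenance`` labels the measurement condition.
    """

    base: dict[tuple[str, str], float]
    corrections: dict[tuple[str, int, str], float] = field(default_factory=dict)
    provenance: str = ""

    def base_shift(self, residue_type: str, nucleus: str) -> float:
        try:
            return self.base[(residue_type, nucleus)]
        except KeyError:
            raise KeyError(
                f"no random-coil base value for residue type {residue_type!r}, "
                f"nucleus {nucleus!r} ({self.provenance})"
            ) from None

    def has(self, residue_type: str, nucleus: str) -> bool:
        return (residue_type, nucleus) in self.base

    def correction(self, neighbor_type: str, offset: int, nucleus: str) -> float:
        return self.corrections.get((neighbor_type, offset, nucleus), 0.0)

    @property
    def nuclei(self) -> list[str]:
        return sorted({nuc for _, nuc in self.base})


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", header=None)


def load_coil_table(
    name_or_path: str | Path = "urea8m",
    corrections: str | Path | None = "default",
) -> RandomCoilTable:
    """Load a packaged or user-supplied random-coil table.

    Packaged sets: ``"urea8m"`` (8 M urea, pH 2.5 — the denatured-state
    reference) and ``"wishart1995"`` (aqueous near-neutral coil set).
    ``corrections="default"`` attaches the packaged preceding-proline
    increments to the urea set; pass None for no corrections or a path to
    a full correction table.
    """
    packaged = {"urea8m": "random_coil_urea8m.tsv",
                "wishart1995": "random_coil_wishart1995.tsv"}
    datadir = resources.files("idpnmr") / "data"
    if str(name_or_path) in packaged:
        df = _read_tsv(datadir / packaged[str(name_or_path)])
        provenance = ("8 M urea, pH 2.5" if name_or_path == "urea8m"
                      else "aqueous, pH ~5 (1995 coil set)")
    else:
        df = _read_tsv(name_or_path)
        provenance = str(name_or_path)
    base = {(str(r[0]).upper(), str(r[1]).upper()): float(r[2])
            for r in df.itertuples(index=False)}
    corr: dict[tuple[str, int, str], float] = {}
    if corrections == "default":
        cdf = _read_tsv(datadir / "coil_corrections_urea8m.tsv")
        corr = {(str(r[0]).upper(), int(r[1]), str(r[2]).upper()): float(r[3])
                for r in cdf.itertuples(index=False)}
    elif corrections is not None:
        cdf = _read_tsv(corrections)
        corr = {(str(r[0]).upper(), int(r[1]), str(r[2]).upper()): float(r[3])
                for r in cdf.itertuples(index=False)}
    return RandomCoilTable(base, corr, provenance)


def corrected_random_coil(
    seq: PeptideSequence,
    table: RandomCoilTable,
    nuclei: list[str] | None = None,
) -> dict[tuple[int, str], float]:
    """Sequence-corrected reference shifts for every residue and nucleus.

    reference(i) = base(type_i) + sum over existing neighbours at offsets
    {-2,-1,+1,+2} of correction(type_{i+k}, k).  Chain ends simply lack
    the out-of-range neighbours.  Raises KeyError if a residue type has no
    base value for a requested nucleus that exists for its type.
    """
    nuclei = nuclei or table.nuclei
    out: dict[tuple[int, str], float] = {}
    for i in seq.indices:
        aa = seq[int(i)]
        for nuc in nuclei:
            if (aa, nuc) in NUCLEUS_ABSENT:
                continue  # e.g. glycine has no CB
            ref = table.base_shift(aa, nuc)  # raises with context if missing
            for k in (-2, -1, 1, 2):
                j = int(i) + k
                if seq.first_index <= j <= seq.last_index:
                    ref += table.correction(seq[j], k, nuc)
            out[(int(i), nuc)] = ref
    return out


def secondary_shifts(
    observed: list[ShiftRecord],
    reference: dict[tuple[int, str], float],
    seq: PeptideSequence | None = None,
    exclude_ph_sensitive: bool = False,
    exclude_types: frozenset[str] = PH_SENSITIVE,
) -> list[SecondaryShiftRecord]:
    """ddelta = observed - sequence-corrected reference, per (residue, nucleus).

    Observed records without a matching reference are skipped (masked).
    With ``exclude_ph_sensitive`` the titrating residue types (default
    Asp/Glu) are flagged excluded regardless of their ddelta.
    """
    out: list[SecondaryShiftRecord] = []
    for rec in observed:
        key = (rec.residue, rec.nucleus)
        if key not in reference:
            continue
        ref = reference[key]
        r = SecondaryShiftRecord(
            rec.residue, rec.nucleus, rec.shift_ppm, ref, rec.shift_ppm - ref
        )
        if exclude_ph_sensitive and seq is not None:
            aa = seq[rec.residue]
            if aa in exclude_types:
                r.excluded = True
                r.exclusion_reason = f"pH-sensitive residue type {aa}"
        out.append(r)
    return out


@dataclass
class CsiResult:
    """Per-nucleus CSI indices and the per-residue consensus call."""

    indices: dict[tuple[int, str], int]
    consensus: dict[int, str]  # helix | coil | strand


def consensus_csi(
    records: list[SecondaryShiftRecord],
    thresholds: dict[str, float] | None = None,
    min_run: int = 3,
) -> CsiResult:
    """Consensus chemical shift index from CA/CB/C secondary shifts.

    Per nucleus: index +1 if ddelta > threshold, -1 if < -threshold, else
    0.  Helix votes are +index for CA and C' and -index for CB (the CSI
    sign inversion); the per-residue consensus is the majority vote (ties
    -> coil) and any helix/strand run shorter than ``min_run`` residues is
    reset to coil.
    """
    thresholds = thresholds or CSI_THRESHOLDS
    indices: dict[tuple[int, str], int] = {}
    votes: dict[int, int] = {}
    for rec in records:
        if rec.excluded or rec.nucleus not in thresholds:
            continue
        thr = thresholds[rec.nucleus]
        idx = 1 if rec.ddelta > thr else (-1 if rec.ddelta < -thr else 0)
        indices[(rec.residue, rec.nucleus)] = idx
        vote = -idx if rec.nucleus == "CB" else idx
        votes[rec.residue] = votes.get(rec.residue, 0) + vote
    raw = {
        res: ("helix" if v > 0 else "strand" if v < 0 else "coil")
        for res, v in votes.items()
    }
    consensus = _suppress_short_runs(raw, min_run)
    return CsiResult(indices, consensus)


def _suppress_short_runs(calls: dict[int, str], min_run: int) -> dict[int, str]:
    out = dict(calls)
    residues = sorted(calls)
    run: list[int] = []
    prev_state = None

    def flush():
        if prev_state in ("helix", "strand") and 0 < len(run) < min_run:
            for r in run:
                out[r] = "coil"

    for res in residues:
        state = calls[res]
        contiguous = run and res == run[-1] + 1
        if state == prev_state and contiguous:
            run.append(res)
        else:
            flush()
            run = [res]
            prev_state = state
    flush()
    return out


def flag_deviant(
    records: list[SecondaryShiftRecord],
    thresholds: dict[str, float] | None = None,
) -> list[SecondaryShiftRecord]:
    """Flag records with \\|ddelta\\| above the per-nucleus threshold.

    Excluded records are never flagged.  Flags are monotone in the
    threshold: raising it can only remove flags.  Returns the flagged
    records (the flag is also set in place).
    """
    thresholds = thresholds or DEVIANT_THRESHOLDS
    flagged = []
    for rec in records:
        thr = thresholds.get(rec.nucleus)
        rec.deviant = (
            thr is not None and not rec.excluded and abs(rec.ddelta) > thr
        )
        if rec.deviant:
            flagged.append(rec)
    return flagged


@dataclass
class PhiEstimate:
    """Solutions of the Karplus equation for one 3J(HN,HA) coupling."""

    residue: int
    j3: float
    solutions: list[float]  # degrees, in (-180, 180]
    chosen: float | None = None  # preferred branch, if selected


def karplus_phi(
    j3: float,
    coefficients: tuple[float, float, float] = KARPLUS_HNHA,
    residue: int = 0,
    prefer_negative: bool = True,
) -> PhiEstimate:
    """All backbone phi angles consistent with a 3J(HN,HA) coupling.

    Solves A cos^2(theta) + B cos(theta) + C = J with theta = phi - 60 deg
    exactly: the quadratic in cos(theta) gives up to two cosines, each
    with a +/-theta branch, hence up to four phi solutions in (-180, 180].
    An empty solution list means J lies outside the curve's range.  With
    ``prefer_negative`` the chosen branch is the solution closest to the
    sterically common negative-phi region (phi ~ -120 deg).
    """
    if j3 < 0:
        raise ValueError("coupling constant must be >= 0")
    a, b, c = coefficients
    disc = b * b - 4.0 * a * (c - j3)
    solutions: list[float] = []
    if disc >= 0:
        for u in ((-b + math.sqrt(disc)) / (2 * a), (-b - math.sqrt(disc)) / (2 * a)):
            if -1.0 <= u <= 1.0:
                theta = math.degrees(math.acos(u))
                for phi in (theta + 60.0, -theta + 60.0):
                    phi = ((phi + 180.0) % 360.0) - 180.0
                    if phi == -180.0:
                        phi = 180.0
                    solutions.append(phi)
    solutions = sorted(set(round(s, 6) for s in solutions))
    chosen = None
    if solutions:
        target = -120.0 if prefer_negative else solutions[0]
        chosen = min(solutions, key=lambda s: abs(s - target))
    return PhiEstimate(residue, j3, solutions, chosen)


def karplus_j(phi_deg: float, coefficients=KARPLUS_HNHA) -> float:
    """Forward Karplus curve: J(phi) in Hz (the root-finding oracle)."""
    a, b, c = coefficients
    u = math.cos(math.radians(phi_deg - 60.0))
    return a * u * u + b * u + c
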