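"""NOE connectivity classification and hydrophobicity (AABUF) profiles.

Assigned proton-proton NOE contacts are typed by the atom classes of the
two protons (backbone HN, backbone HA, or side chain) and the sequence
separation |j - i|: sequential and medium-range HN-HN and HA-HN classes
(dNN, daN) diagnose secondary structure, while side-chain-side-chain
contacts at larger separations diagnose hydrophobic clustering.
Classification is symmetric in the two partners; contacts are
canonicalized to res_i <= res_j and duplicates (same atom pair seen in
several peaks or mixing times) collapse with a multiplicity count.

The AABUF profile (average area buried upon folding) is a per-residue
hydrophobicity scale proportional to the hydrophobic contribution to the
conformational free energy; a sliding-window mean smooths it and min-max
normalization maps it onto [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .core import PeptideSequence, ResidueTable

HN_NAMES = {"HN", "H"}
HA_NAMES = {"HA", "HA2", "HA3"}


class AtomNameError(ValueError):
    pass


def atom_class(name: str) -> str:
    """Map a proton name to {HN, HA, sc}; rejects non-proton names."""
    up = name.strip().upper()
    if not up or up[0] not in "HQ":  # Q* = pseudoatom protons
        raise AtomNameError(f"not a proton name: {name!r}")
    if up in HN_NAMES:
        return "HN"
    if up in HA_NAMES:
        return "HA"
    return "sc"


@dataclass(frozen=True)
class NoeContact:
    """One assigned cross-peak between two protons.

    Stored canonically with res_i <= res_j (swapped on construction via
    :func:`make_contact`).
    """

    res_i: int
    atom_i: str
    res_j: int
    atom_j: str
    peak_id: str | None = None
    mixing_time_ms: float | None = None

    @property
    def separation(self) -> int:
        return abs(self.res_j - self.res_i)

    def swapped(self) -> "NoeContact":
        return NoeContact(
            self.res_j, self.atom_j, self.res_i, self.atom_i,
            self.peak_id, self.mixing_time_ms,
        )


def make_contact(
    res_i: int, atom_i: str, res_j: int, atom_j: str,
    peak_id: str | None = None, mixing_time_ms: float | None = None,
) -> NoeContact:
    """Build a contact in canonical order (lower residue first)."""
    atom_class(atom_i), atom_class(atom_j)  # validate early
    if res_j < res_i:
        res_i, atom_i, res_j, atom_j = res_j, atom_j, res_i, atom_i
    return NoeContact(res_i, atom_i.upper(), res_j, atom_j.upper(),
                      peak_id, mixing_time_ms)


#: Canonical classes reported (and explicitly reported when absent) by
#: :func:`connectivity_map`; anything else falls into a descriptive label.
CANONICAL_CLASSES = (
    "intra",
    "dNN(i,i+1)", "dNN(i,i+2)",
    "daN(i,i+1)", "daN(i,i+2)", "daN(i,i+3)",
    "dscN(i,i+2)", "dscN(i,i+3)",
    "sc-sc(|d|=1)", "sc-sc(2<=|d|<=4)", "sc-sc(|d|>=5)",
)


def classify_contact(c: NoeContact) -> str:
    """Deterministic class label from atom classes and separation only.

    The label is symmetric under swapping the two partners, so e.g. an
    HA(4)-HN(6) and an HN(6)-HA(4) entry both classify as daN(i,i+2).
    """
    ci, cj = atom_class(c.atom_i), atom_class(c.atom_j)
    k = c.separation
    if k == 0:
        return "intra"
    pair = frozenset((ci, cj)) if ci != cj else frozenset((ci,))
    if pair == frozenset(("HN",)):
        return f"dNN(i,i+{k})"
    if pair == frozenset(("HA", "HN")):
        return f"daN(i,i+{k})"
    if pair == frozenset(("HA",)):
        return f"daa(i,i+{k})"
    if pair == frozenset(("sc", "HN")):
        return f"dscN(i,i+{k})"
    if pair == frozenset(("sc", "HA")):
        return f"dscA(i,i+{k})"
    # side chain - side chain, bucketed by separation
    if k == 1:
        return "sc-sc(|d|=1)"
    if k <= 4:
        return "sc-sc(2<=|d|<=4)"
    return "sc-sc(|d|>=5)"


@dataclass
class ConnectivityMap:
    """Residue-by-class presence matrix with per-class counts."""

    matrix: pd.DataFrame  # bool, index = residue of the lower partner
    counts: dict[str, int]
    absent_classes: list[str]
    multiplicities: dict[tuple[int, str, int, str], int]

    def count(self, label: str) -> int:
        return self.counts.get(label, 0)


def connectivity_map(contacts: list[NoeContact]) -> ConnectivityMap:
    """Classify a contact list into a connectivity matrix and class counts.

    Duplicate contacts (identical canonical atom pairs) collapse to a
    single entry and contribute once to the counts; their multiplicity is
    retained.  Counts are invariant to input order.  Classes from the
    canonical list with zero count are reported in ``absent_classes``.
    """
    seen: dict[tuple[int, str, int, str], int] = {}
    uniques: list[NoeContact] = []
    for c in contacts:
        c = make_contact(c.res_i, c.atom_i, c.res_j, c.atom_j,
                         c.peak_id, c.mixing_time_ms)
        key = (c.res_i, c.atom_i, c.res_j, c.atom_j)
        if key in seen:
            seen[key] += 1
        else:
            seen[key] = 1
            uniques.append(c)
    labels = [classify_contact(c) for c in uniques]
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    residues = sorted({c.res_i for c in uniques} | {c.res_j for c in uniques})
    cols = list(dict.fromkeys(list(CANONICAL_CLASSES) + sorted(set(labels))))
    mat = pd.DataFrame(False, index=residues, columns=cols)
    for c, lab in zip(uniques, labels):
        mat.loc[c.res_i, lab] = True
    absent = [lab for lab in CANONICAL_CLASSES if counts.get(lab, 0) == 0]
    return ConnectivityMap(mat, counts, absent, seen)


def sidechain_contact_table(
    contacts: list[NoeContact], focus: int
) -> pd.DataFrame:
    """Side-chain contact map around one residue.

    Rows are the side-chain protons of the focus residue, columns the
    partner residues, cells the partner atoms with peak ids, e.g.
    ``"HD2 (8)/HD3 (8)"``.  Only side-chain-to-side-chain contacts enter;
    backbone HN/HA contacts belong to the connectivity map instead.
    """
    cells: dict[tuple[str, int], list[str]] = {}
    for c in contacts:
        for this, other in ((c, c.swapped()), (c.swapped(), c)):
            if this.res_i != focus or other.res_i == focus:
                continue
            if atom_class(this.atom_i) != "sc" or atom_class(other.atom_i) != "sc":
                continue
            entry = other.atom_i
            if c.peak_id not in (None, "", "."):
                entry += f" ({c.peak_id})"
            cells.setdefault((this.atom_i, other.res_i), []).append(entry)
    if not cells:
        return pd.DataFrame()
    rows = sorted({a for a, _ in cells})
    partners = sorted({r for _, r in cells})
    table = pd.DataFrame("", index=rows, columns=partners)
    for (atom, res), entries in cells.items():
        table.loc[atom, res] = "/".join(sorted(set(entries)))
    return table


@dataclass
class AabufProfile:
    residues: np.ndarray
    raw: np.ndarray
    windowed: np.ndarray
    normalized: np.ndarray | None
    window: int
    constant: bool = False


def load_residue_scale(path: str | Path | None = None) -> dict[str, float]:
    """Residue hydrophobicity scale; default is the packaged AABUF set."""
    src = path or resources.files("idpnmr") / "data" / "aabuf_rose1985.tsv"
    df = pd.read_csv(src, sep="\t", comment="#", header=None)
    return {str(r[0]).upper(): float(r[1]) for r in df.itertuples(index=False)}


def aabuf_profile(
    seq: PeptideSequence,
    scale: dict[str, float] | None = None,
    window: int = 5,
) -> AabufProfile:
    """Windowed, min-max-normalized AABUF profile of a sequence.

    The sliding window (odd length, uniform weighting) is truncated at the
    chain ends.  A constant windowed profile cannot be normalized; it is
    returned flagged with ``normalized = None``.
    """
    if window % 2 == 0 or window < 1 or window > len(seq):
        raise ValueError("window must be odd and <= sequence length")
    scale = scale or load_residue_scale()
    raw = np.array([scale[aa] for aa in seq.residues])
    half = window // 2
    win = np.array([
        raw[max(0, p - half): p + half + 1].mean() for p in range(len(raw))
    ])
    span = win.max() - win.min()
    if span == 0:
        return AabufProfile(seq.indices, raw, win, None, window, constant=True)
    norm = (win - win.min()) / span
    return AabufProfile(seq.indices, raw, win, norm, window)


def read_helix_propensity(
    path: str | Path, seq: PeptideSequence | None = None
) -> ResidueTable:
    """Read per-residue helix propensities (%) from external predictor output.

    Expects two tab- or whitespace-separated columns (residue number,
    propensity in 0..100); '#' lines are comments.  With a sequence given,
    residues missing from the file appear masked.
    """
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None)
    if df.shape[1] < 2:
        raise ValueError("expected two columns: residue, propensity")
    res = df.iloc[:, 0].astype(int).to_numpy()
    prop = df.iloc[:, 1].astype(float).to_numpy()
    bad = (prop < 0) | (prop > 100)
    if bad.any():
        raise ValueError(
            f"propensity out of range 0..100 at residue {int(res[bad][0])}"
        )
    if seq is None:
        return ResidueTable(res, prop)
    values = np.zeros(len(seq))
    mask = np.zeros(len(seq), dtype=bool)
    for r, p in zip(res, prop):
        pos = r - seq.first_index
        if 0 <= pos < len(seq):
            values[pos] = p
            mask[pos] = True
    return ResidueTable(seq.indices, values, mask=mask)
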