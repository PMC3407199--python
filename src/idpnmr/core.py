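"""Core domain types shared by every pipeline stage.

Units at rest throughout the package: delays in s, rates in s^-1, chemical
shifts in ppm, gradients in T·m^-1, spectral densities in s·rad^-1.
Residue numbering is 1-based by default (configurable first-residue offset).
Missing per-residue values are represented by the mask of
:class:`ResidueTable`, never by sentinel numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
from Bio import SeqIO

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: Gyromagnetic ratios in rad s^-1 T^-1.  The 15N ratio is negative; sign
#: conventions in the spectral-density mapping rely on the signed value.
GAMMA_H = 2.6752218744e8
GAMMA_N = -2.7126180e7

#: TC5b, the 20-residue Trp-cage mini-protein studied throughout the docs.
TC5B_SEQUENCE = "NLYIQWLKDGGPSSGRPPPS"


class SequenceError(ValueError):
    """Raised for empty or non-amino-acid sequence input."""


@dataclass(frozen=True)
class PeptideSequence:
    """An ordered one-letter amino-acid sequence with 1-based numbering.

    Parameters
    ----------
    residues : str
        Upper-case one-letter codes.
    first_index : int
        Number of the first residue (default 1); supports fragments.
    """

    residues: str
    first_index: int = 1

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise SequenceError("empty sequence")
        for pos, aa in enumerate(self.residues):
            if aa not in AMINO_ACIDS:
                raise SequenceError(
                    f"illegal residue code {aa!r} at position {pos + 1}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def indices(self) -> np.ndarray:
        """1-based (or offset) residue numbers as an int array."""
        return np.arange(self.first_index, self.first_index + len(self))

    @property
    def last_index(self) -> int:
        return self.first_index + len(self) - 1

    def __getitem__(self, index: int) -> str:
        """One-letter code of the residue with the given *number*."""
        off = index - self.first_index
        if not 0 <= off < len(self.residues):
            raise IndexError(
                f"residue {index} outside [{self.first_index}, {self.last_index}]"
            )
        return self.residues[off]

    def positions_of(self, aa: str) -> list[int]:
        """Residue numbers at which amino acid *aa* occurs."""
        aa = aa.upper()
        return [int(i) for i in self.indices if self[int(i)] == aa]

    def renumbered(self, first_index: int) -> "PeptideSequence":
        return PeptideSequence(self.residues, first_index)


def load_sequence(source: str | Path, first_index: int = 1) -> PeptideSequence:
    """Read a peptide sequence from a FASTA file or a raw one-letter string.

    Whitespace and line breaks are ignored and case is normalized, so the
    printed form ``"NLYIQ WLKDG GPSSG RPPPS"`` parses directly.
    """
    try:
        is_file = Path(source).is_file()
    except (OSError, ValueError):
        is_file = False
    if isinstance(source, Path) or is_file:
        records = list(SeqIO.parse(str(source), "fasta"))
        if not records:
            raise SequenceError(f"no FASTA records in {source}")
        text = str(records[0].seq)
    else:
        text = str(source)
    cleaned = "".join(text.split()).upper()
    if not cleaned:
        raise SequenceError("empty sequence")
    return PeptideSequence(cleaned, first_index)


def write_fasta(seq: PeptideSequence, path: str | Path, name: str = "peptide") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq.residues), 60):
            fh.write(seq.residues[i : i + 60] + "\n")


@dataclass(frozen=True)
class SpectrometerContext:
    """Static field parameters of the spectrometer.

    ``proton_frequency`` and ``nitrogen_frequency`` are Larmor frequencies in
    MHz (magnitudes); angular frequencies are derived as 2π·ν.  The ratio of
    the two frequencies must agree with \\|γN/γH\\| to within 2%, which guards
    against swapped or mistyped fields.
    """

    proton_frequency: float
    nitrogen_frequency: float
    temperature: float = 298.0

    def __post_init__(self) -> None:
        if self.proton_frequency <= 0 or self.nitrogen_frequency <= 0:
            raise ValueError("spectrometer frequencies must be positive")
        ratio = self.nitrogen_frequency / self.proton_frequency
        expected = abs(GAMMA_N / GAMMA_H)
        if abs(ratio - expected) / expected > 0.02:
            raise ValueError(
                f"15N/1H frequency ratio {ratio:.5f} deviates more than 2% "
                f"from |gammaN/gammaH| = {expected:.5f}"
            )

    @property
    def omega_h(self) -> float:
        """1H angular frequency, rad s^-1."""
        return 2.0 * math.pi * self.proton_frequency * 1e6

    @property
    def omega_n(self) -> float:
        """15N angular frequency (magnitude), rad s^-1."""
        return 2.0 * math.pi * self.nitrogen_frequency * 1e6


#: Field context used throughout the worked examples: 599.92 MHz 1H,
#: 60.25 MHz 15N.
DEFAULT_CONTEXT = SpectrometerContext(599.92, 60.25)


class ResidueTable:
    """Per-residue values with uncertainties and a missing-data mask.

    A thin container over parallel numpy arrays keyed by residue number.
    Entries are stored for an explicit set of residue indices (a subset of a
    sequence's range); anything can be masked afterwards, e.g. prolines for
    HN-detected observables.
    """

    def __init__(
        self,
        indices: Sequence[int],
        values: Sequence[float],
        sigmas: Sequence[float] | None = None,
        mask: Sequence[bool] | None = None,
    ) -> None:
        self.indices = np.asarray(indices, dtype=int)
        self.values = np.asarray(values, dtype=float)
        if self.indices.shape != self.values.shape:
            raise ValueError("indices and values must have equal length")
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("duplicate residue indices")
        self.sigmas = (
            np.zeros_like(self.values)
            if sigmas is None
            else np.asarray(sigmas, dtype=float)
        )
        if np.any(self.sigmas < 0):
            raise ValueError("uncertainties must be >= 0")
        # mask True == value present / usable
        self.mask = (
            np.ones(len(self.values), dtype=bool)
            if mask is None
            else np.asarray(mask, dtype=bool)
        )

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self) -> Iterator[tuple[int, float, float, bool]]:
        yield from zip(self.indices, self.values, self.sigmas, self.mask)

    def get(self, index: int) -> float:
        pos = np.flatnonzero(self.indices == index)
        if len(pos) == 0:
            raise KeyError(index)
        return float(self.values[pos[0]])

    def masked_at(self, indices: Sequence[int]) -> "ResidueTable":
        """Copy with the given residue numbers additionally masked out."""
        drop = np.isin(self.indices, np.asarray(list(indices), dtype=int))
        return ResidueTable(self.indices, self.values, self.sigmas, self.mask & ~drop)

    @property
    def valid_indices(self) -> np.ndarray:
        return self.indices[self.mask]

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    @property
    def valid_sigmas(self) -> np.ndarray:
        return self.sigmas[self.mask]

    @classmethod
    def from_mapping(
        cls, mapping: Mapping[int, float], sigmas: Mapping[int, float] | None = None
    ) -> "ResidueTable":
        idx = sorted(mapping)
        sig = None if sigmas is None else [sigmas.get(i, 0.0) for i in idx]
        return cls(idx, [mapping[i] for i in idx], sig)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "residue": self.indices,
                "value": self.values,
                "sigma": self.sigmas,
                "valid": self.mask,
            }
        )
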