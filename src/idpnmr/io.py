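"""File readers and writers shared by all pipeline stages.

TSV dialect: tab-separated columns, '#'-prefixed comment/header lines,
'.' for missing values.  Delays are stored in ms in decay files (declared
by the column name) and converted to seconds at parse time; everything
in memory uses SI-at-rest units (s, s^-1, ppm, T/m).

Chemical-shift tables are accepted either as TSV (residue, nucleus,
shift_ppm) or as an NMR-STAR 3.1 assigned-chemical-shift loop (read
only); nucleus names are normalized to CA/CB/C/HA/HB/HN/N and unknown
labels are skipped with a warning.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .contacts import NoeContact, make_contact
from .diffusion import GradientSeries
from .relax import DecaySeries
from .shifts import ShiftRecord

logger = logging.getLogger("idpnmr")

MISSING = "."

NUCLEUS_ALIASES = {
    "CA": "CA", "C-ALPHA": "CA", "CALPHA": "CA",
    "CB": "CB", "C-BETA": "CB", "CBETA": "CB",
    "C": "C", "CO": "C", "C'": "C", "CPRIME": "C",
    "HA": "HA", "HA2": "HA2", "HA3": "HA3",
    "HB": "HB", "HN": "HN", "H": "HN",
    "N": "N", "NH": "N",
}


def normalize_nucleus(label: str) -> str | None:
    """Canonical nucleus name, or None for labels outside the vocabulary."""
    return NUCLEUS_ALIASES.get(label.strip().upper().replace("Δ", ""))


def _read_table(path: str | Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=columns,
        na_values=[MISSING], dtype=str, skip_blank_lines=True,
    )
    return df


# ---------------------------------------------------------------- decays

def read_decay_table(path: str | Path) -> dict[int, DecaySeries]:
    """Read a peak-height decay TSV into per-residue series.

    Columns: residue, delay_ms, height, replicate_id.  Delays convert
    ms -> s; replicate rows are preserved as independent points.  A
    duplicated (residue, delay, replicate_id) triple is an error.
    """
    df = _read_table(path, ["residue", "delay_ms", "height", "replicate_id"])
    if df.isna().all(axis=None) or df.shape[1] < 4:
        raise ValueError(f"{path}: expected 4 columns")
    try:
        residue = df["residue"].astype(int)
        delay = df["delay_ms"].astype(float)
        height = df["height"].astype(float)
        replicate = df["replicate_id"].astype(int)
    except (TypeError, ValueError) as err:
        raise ValueError(f"{path}: non-numeric field ({err})") from None
    dup = pd.DataFrame({"r": residue, "d": delay, "k": replicate}).duplicated()
    if dup.any():
        row = df[dup.to_numpy()].iloc[0]
        raise ValueError(
            f"{path}: duplicate (residue, delay, replicate) triple "
            f"({row['residue']}, {row['delay_ms']} ms, {row['replicate_id']})"
        )
    out: dict[int, DecaySeries] = {}
    for res, grp in pd.DataFrame(
        {"res": residue, "t": delay * 1e-3, "y": height, "k": replicate}
    ).groupby("res"):
        out[int(res)] = DecaySeries(
            int(res), grp["t"].to_numpy(), grp["y"].to_numpy(),
            grp["k"].to_numpy(),
        )
    return out


def write_decay_table(series: dict[int, DecaySeries], path: str | Path) -> None:
    """Canonical decay TSV (sorted by residue, delay, replicate)."""
    with open(path, "w") as fh:
        fh.write("# columns: residue\tdelay_ms\theight\treplicate_id\n")
        for res in sorted(series):
            s = series[res]
            order = np.lexsort((s.replicate_ids, s.delays))
            for p in order:
                fh.write(
                    f"{res}\t{s.delays[p] * 1e3:.6g}\t"
                    f"{s.heights[p]:.10g}\t{int(s.replicate_ids[p])}\n"
                )


# ---------------------------------------------------------------- shifts

def read_shift_table(path: str | Path) -> list[ShiftRecord]:
    """Read chemical shifts from TSV or an NMR-STAR 3.1 file.

    Dispatches on content: files containing a ``loop_`` token are parsed
    as NMR-STAR (assigned-chemical-shift loop only); otherwise TSV with
    columns residue, nucleus, shift_ppm.  Unknown nucleus labels are
    skipped with a logged warning.
    """
    text = Path(path).read_text()
    if "loop_" in text and "_Atom_chem_shift" in text:
        return _read_star_shifts(text, str(path))
    records: list[ShiftRecord] = []
    df = _read_table(path, ["residue", "nucleus", "shift_ppm"])
    for row in df.itertuples(index=False):
        if pd.isna(row.residue) or pd.isna(row.shift_ppm):
            continue
        nuc = normalize_nucleus(str(row.nucleus))
        if nuc is None:
            logger.warning("skipping unknown nucleus label %r", row.nucleus)
            warnings.warn(f"unknown nucleus label {row.nucleus!r}; skipped",
                          stacklevel=2)
            continue
        records.append(ShiftRecord(int(row.residue), nuc, float(row.shift_ppm)))
    if not records and len(df):
        raise ValueError(f"{path}: no parseable shift rows")
    return records


def _star_tokens(text: str):
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        pos = 0
        while pos < len(line):
            if line[pos].isspace():
                pos += 1
                continue
            if line[pos] in "'\"":
                q = line[pos]
                end = line.find(q, pos + 1)
                end = len(line) if end == -1 else end
                yield line[pos + 1: end]
                pos = end + 1
            else:
                end = pos
                while end < len(line) and not line[end].isspace():
                    end += 1
                yield line[pos:end]
                pos = end


def _read_star_shifts(text: str, name: str) -> list[ShiftRecord]:
    """Minimal NMR-STAR 3.1 reader scoped to the Atom_chem_shift loop."""
    tokens = list(_star_tokens(text))
    records: list[ShiftRecord] = []
    pos = 0
    while pos < len(tokens):
        if tokens[pos].lower() != "loop_":
            pos += 1
            continue
        pos += 1
        tags = []
        while pos < len(tokens) and tokens[pos].startswith("_"):
            tags.append(tokens[pos])
            pos += 1
        values = []
        while pos < len(tokens) and tokens[pos].lower() not in ("stop_", "loop_") \
                and not tokens[pos].startswith("_") \
                and not tokens[pos].lower().startswith("save_"):
            values.append(tokens[pos])
            pos += 1
        if not any(t.startswith("_Atom_chem_shift") for t in tags):
            continue

        def col(*names):
            for n in names:
                full = f"_Atom_chem_shift.{n}"
                if full in tags:
                    return tags.index(full)
            return None

        i_seq = col("Seq_ID", "Comp_index_ID")
        i_atom = col("Atom_ID")
        i_val = col("Val")
        if None in (i_seq, i_atom, i_val):
            raise ValueError(f"{name}: incomplete Atom_chem_shift loop")
        ncol = len(tags)
        if ncol == 0 or len(values) % ncol:
            raise ValueError(f"{name}: ragged Atom_chem_shift loop")
        for row_start in range(0, len(values), ncol):
            row = values[row_start: row_start + ncol]
            if row[i_val] in (MISSING, "?"):
                continue
            nuc = normalize_nucleus(row[i_atom])
            if nuc is None:
                logger.warning("skipping unknown nucleus label %r", row[i_atom])
                continue
            records.append(
                ShiftRecord(int(row[i_seq]), nuc, float(row[i_val]))
            )
    if not records:
        raise ValueError(f"{name}: no assigned chemical shifts found")
    return records


def write_shift_table(records: list[ShiftRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# columns: residue\tnucleus\tshift_ppm\n")
        for rec in sorted(records, key=lambda r: (r.residue, r.nucleus)):
            fh.write(f"{rec.residue}\t{rec.nucleus}\t{rec.shift_ppm:.4f}\n")


# -------------------------------------------------------------- contacts

def read_contact_table(path: str | Path) -> list[NoeContact]:
    """Contact TSV: res_i, atom_i, res_j, atom_j, peak_id, mixing_time_ms."""
    df = _read_table(
        path, ["res_i", "atom_i", "res_j", "atom_j", "peak_id", "mixing_time_ms"]
    )
    out = []
    for row in df.itertuples(index=False):
        if pd.isna(row.res_i):
            continue
        peak = None if pd.isna(row.peak_id) else str(row.peak_id)
        mix = None if pd.isna(row.mixing_time_ms) else float(row.mixing_time_ms)
        out.append(
            make_contact(int(row.res_i), str(row.atom_i),
                         int(row.res_j), str(row.atom_j), peak, mix)
        )
    return out


def write_contact_table(contacts: list[NoeContact], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "# columns: res_i\tatom_i\tres_j\tatom_j\tpeak_id\tmixing_time_ms\n"
        )
        for c in contacts:
            peak = c.peak_id if c.peak_id not in (None, "") else MISSING
            mix = f"{c.mixing_time_ms:g}" if c.mixing_time_ms is not None else MISSING
            fh.write(f"{c.res_i}\t{c.atom_i}\t{c.res_j}\t{c.atom_j}\t{peak}\t{mix}\n")


# -------------------------------------------------------------- gradients

def read_gradient_table(
    path: str | Path, delta: float, big_delta: float,
    gamma: float | None = None, shape_factor: float = 1.0,
) -> GradientSeries:
    """Gradient TSV (g in T/m, relative intensity) plus pulse parameters."""
    from .core import GAMMA_H

    df = _read_table(path, ["gradient", "intensity"])
    g = df["gradient"].astype(float).to_numpy()
    y = df["intensity"].astype(float).to_numpy()
    return GradientSeries(g, y, delta, big_delta, gamma or GAMMA_H, shape_factor)


def write_gradient_table(series: GradientSeries, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# delta_s: {series.delta}\n# big_delta_s: {series.big_delta}\n")
        fh.write("# columns: gradient_T_per_m\tintensity\n")
        for g, y in zip(series.gradients, series.intensities):
            fh.write(f"{g:.6g}\t{y:.10g}\n")


# ------------------------------------------------------- relaxation table

def write_relaxation_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write the combined relaxation TSV (residue, R1, sR1, R2, sR2, noe,
    snoe, r2_over_r1); missing values as '.'."""
    cols = ["residue", "R1", "sR1", "R2", "sR2", "noe", "snoe", "r2_over_r1"]
    with open(path, "w") as fh:
        fh.write("# columns: " + "\t".join(cols) + "\n")
        for _, row in df.iterrows():
            cells = []
            for c in cols:
                v = row.get(c)
                if v is None or (isinstance(v, float) and np.isnan(v)):
                    cells.append(MISSING)
                elif c == "residue":
                    cells.append(str(int(v)))
                else:
                    cells.append(f"{v:.6g}")
            fh.write("\t".join(cells) + "\n")


def read_relaxation_table(path: str | Path) -> pd.DataFrame:
    cols = ["residue", "R1", "sR1", "R2", "sR2", "noe", "snoe", "r2_over_r1"]
    df = _read_table(path, cols)
    df = df.dropna(how="all")
    df["residue"] = df["residue"].astype(int)
    for c in cols[1:]:
        df[c] = df[c].astype(float)
    return df.reset_index(drop=True)


def packaged_contacts_path() -> Path:
    """Path of the packaged TC5b contact transcription."""
    from importlib import resources

    return Path(str(resources.files("idpnmr") / "data" / "tc5b_noe_contacts.tsv"))
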