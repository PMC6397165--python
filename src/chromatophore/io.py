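"""Readers and writers for the plain-text formats the pipeline consumes.

FASTA goes through Biopython; tabular data through pandas. Count tables are
CSV/TSV with the protein id in the first column and one column per sample.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from chromatophore.digest import ProteinRecord

#: BLAST tabular (-outfmt 6) default columns
BLAST6_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from a (possibly multi-line-wrapped) FASTA file."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            ProteinRecord(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                description=rec.description,
            )
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description or "")
        for r in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read a spectral-count table (rows: proteins, columns: samples)."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.shape[1] < 1:
        raise ValueError(f"{path}: no sample columns found")
    return df


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep=_sep_for(path), index=index)


def read_category_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV/CSV: protein id, category label."""
    df = pd.read_csv(path, sep=_sep_for(path), header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (id, category)")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def read_blast_tabular(path: str | Path, qcovs: bool = False) -> pd.DataFrame:
    """Read BLAST tabular output (-outfmt 6 dialect, optional qcovs column)."""
    cols = BLAST6_COLUMNS + (["qcovs"] if qcovs else [])
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] not in (len(BLAST6_COLUMNS), len(BLAST6_COLUMNS) + 1):
        raise ValueError(
            f"{path}: expected 12 or 13 tab-separated columns, "
            f"got {df.shape[1]}"
        )
    df.columns = cols[: df.shape[1]]
    if df.shape[1] == 13 and not qcovs:
        df = df.rename(columns={df.columns[-1]: "qcovs"})
    return df


def read_measurements(path: str | Path) -> list[float]:
    """Layer measurements: one value (nm) per line, or a one-column CSV."""
    values: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            values.append(float(line.split(",")[0]))
    return values


def read_line_list(path: str | Path) -> tuple[list[float], list[float]]:
    """Excited-state line list: two-column CSV (wavelength nm, osc. strength)."""
    df = pd.read_csv(path, header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (nm, strength)")
    # tolerate a header row of labels
    if not pd.api.types.is_numeric_dtype(df.iloc[:, 0]):
        df = df.iloc[1:].astype(float)
    return df.iloc[:, 0].astype(float).tolist(), df.iloc[:, 1].astype(float).tolist()


def write_trace(trace, path: str | Path) -> None:
    """Write an ROI trace as CSV (time_s, R, G, B)."""
    df = pd.DataFrame(
        {"time_s": trace.time_s, "R": trace.r, "G": trace.g, "B": trace.b}
    )
    df.to_csv(path, index=False)


def write_spectrum(wavelengths: Sequence[float], values: Sequence[float],
                   path: str | Path, value_name: str = "reflectance") -> None:
    pd.DataFrame({"wavelength_nm": wavelengths, value_name: values}).to_csv(
        path, index=False
    )
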