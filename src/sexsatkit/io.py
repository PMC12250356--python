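"""Shared file I/O: FASTA/FASTQ catalogs and reads, genotype CSVs, report TSVs.

All coordinates written to reports are 1-based inclusive, following the
convention of FASTA-facing tools. The genotype CSV dialect is the collapsed
single-row DArT one: one row per locus, one column per individual, codes
0 (homozygous reference), 1 (homozygous alternate), 2 (heterozygous) and
``-`` for a missing call. A sidecar sex-map CSV carries ``individual,sex``
with sex in {M, F}.
"""

from __future__ import annotations

import json
import os
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_GENOTYPE_CODES = {"0", "1", "2", "-"}
MISSING = -1  # internal sentinel for a missing genotype call


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(name, sequence), ...]`` (uppercased)."""
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    for name, seq in records:
        if not seq:
            raise FormatError(f"empty sequence for FASTA record {name!r}")
    return records


def write_fasta(path: str | os.PathLike, records: Iterable[tuple[str, str]]) -> None:
    """Write ``(name, sequence)`` pairs as FASTA, wrapped at 60 columns."""
    seqrecs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(seqrecs, str(path), "fasta")


def read_fastq(path: str | os.PathLike) -> list[str]:
    """Read a FASTQ file, returning the read sequences (uppercased)."""
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(path: str | os.PathLike, reads: Sequence[str], prefix: str = "read") -> None:
    """Write reads as FASTQ with a fixed quality string (no error model)."""
    with open(path, "w") as fh:
        for i, seq in enumerate(reads, start=1):
            fh.write(f"@{prefix}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# Genotype matrices


def read_genotype_csv(path: str | os.PathLike) -> pd.DataFrame:
    """Read a genotype CSV into a loci x individuals integer DataFrame.

    First column holds locus IDs, the header row individual IDs. Codes are
    validated; a missing call ``-`` (or empty cell) becomes ``MISSING``.
    Raises :class:`FormatError` naming the offending locus and column.
    """
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    if df.empty or df.shape[1] == 0:
        raise FormatError(f"genotype matrix {path} has no data")

    def decode(value: str, locus: str, indiv: str) -> int:
        v = value.strip()
        if v == "" or v == "-":
            return MISSING
        if v not in {"0", "1", "2"}:
            raise FormatError(
                f"invalid genotype code {value!r} at locus {locus!r}, individual {indiv!r}"
            )
        return int(v)

    data = {
        indiv: [decode(df.at[locus, indiv], str(locus), str(indiv)) for locus in df.index]
        for indiv in df.columns
    }
    out = pd.DataFrame(data, index=df.index.astype(str))
    out.index.name = "locus"
    return out


def write_genotype_csv(path: str | os.PathLike, matrix: pd.DataFrame) -> None:
    """Write a loci x individuals genotype matrix; MISSING becomes ``-``."""
    display = matrix.astype(object).where(matrix != MISSING, "-")
    display.index.name = "locus"
    display.to_csv(path)


def read_sex_map(path: str | os.PathLike) -> dict[str, str]:
    """Read the sidecar sex-map CSV (``individual,sex`` with sex in {M, F})."""
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"sex map {path} needs two columns (individual, sex)")
    sexes = {}
    for _, row in df.iterrows():
        indiv, sex = str(row.iloc[0]), str(row.iloc[1]).strip().upper()
        if sex not in {"M", "F"}:
            raise FormatError(f"invalid sex {row.iloc[1]!r} for individual {indiv!r}")
        sexes[indiv] = sex
    return sexes


def write_sex_map(path: str | os.PathLike, sexes: Mapping[str, str]) -> None:
    pd.DataFrame(
        {"individual": list(sexes), "sex": [sexes[k] for k in sexes]}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Reports


def write_tsv(path: str | os.PathLike, frame: pd.DataFrame, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)


def write_json(path: str | os.PathLike, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
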