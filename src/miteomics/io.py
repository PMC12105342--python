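"""Readers and writers for the plain-text interchange formats.

All tables are tab-separated. The count matrix carries gene ids in the first
column; the sample sheet maps sample ids to stage/sex groups; gene lengths are
in nucleotides. Protein annotation tables carry domain accessions and the
secretion/localization calls as plain columns, so upstream predictors are
consumed rather than re-run.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PathLike = Union[str, Path]

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_counts(path: PathLike) -> pd.DataFrame:
    """Read a gene x sample count matrix (first column gene_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    return df


def write_counts(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_sheet(path: PathLike) -> pd.Series:
    """Read the sample sheet; returns a sample_id -> group Series."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "group"} <= set(df.columns):
        raise ValueError("sample sheet needs columns sample_id, group")
    return df.set_index("sample_id")["group"]


def write_sample_sheet(groups: pd.Series, path: PathLike) -> None:
    df = groups.rename("group").rename_axis("sample_id").reset_index()
    df.to_csv(path, sep="\t", index=False)


def read_gene_lengths(path: PathLike) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "length_nt"} <= set(df.columns):
        raise ValueError("gene length table needs columns gene_id, length_nt")
    return df.set_index("gene_id")["length_nt"].astype(int)


def write_gene_lengths(lengths: pd.Series, path: PathLike) -> None:
    df = lengths.rename("length_nt").rename_axis("gene_id").reset_index()
    df.to_csv(path, sep="\t", index=False)


def read_annotations(path: PathLike) -> pd.DataFrame:
    """Read the protein annotation table.

    Columns: gene_id, domain_accessions (semicolon list, may repeat an
    accession), go_flag, ko_flag, inhouse_flags (semicolon list),
    signal_peptide (0/1), sp_cleavage_pos (1-based, 0 = none),
    extracellular (0/1).
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str}, keep_default_na=False)
    for col in ("go_flag", "ko_flag", "signal_peptide", "extracellular",
                "sp_cleavage_pos"):
        df[col] = df[col].astype(int)
    return df.set_index("gene_id")


def write_annotations(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_fasta(path: PathLike) -> dict[str, str]:
    """Read a protein FASTA into an id -> sequence dict (order preserved)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: PathLike) -> None:
    records = [SeqRecord(Seq(s), id=gid, description="") for gid, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_tpm(path: PathLike) -> pd.DataFrame:
    return read_counts(path)


def write_tpm(df: pd.DataFrame, path: PathLike) -> None:
    write_counts(df, path)


def parse_blast_tab(source: PathLike | _io.TextIOBase, taxon_group: str) -> pd.DataFrame:
    """Parse a BLAST outfmt-6 tabular file for one taxon-group database.

    Accepts >= 12 tab-separated columns per row (extra columns ignored).
    Malformed rows (wrong column count, non-numeric bitscore) raise a
    ValueError naming the offending line number. An empty file yields an
    empty, correctly-typed table.
    """
    if isinstance(source, (str, Path)):
        handle = open(source)
        close = True
    else:
        handle, close = source, False
    rows = []
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"line {lineno}: expected >=12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ValueError(
                    f"line {lineno}: non-numeric bitscore {fields[11]!r}"
                ) from exc
            rows.append((fields[0], fields[1], bitscore))
    finally:
        if close:
            handle.close()
    df = pd.DataFrame(rows, columns=["qseqid", "sseqid", "bitscore"])
    if df.empty:
        df = pd.DataFrame({"qseqid": pd.Series(dtype=str),
                           "sseqid": pd.Series(dtype=str),
                           "bitscore": pd.Series(dtype=float)})
    df.attrs["taxon_group"] = taxon_group
    return df
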