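"""Readers and writers for the plain-text formats every stage touches.

Count tables, score tables and half-life tables are tab-separated text with
fixed headers; sequences travel as FASTA.  DNA input (T) is converted to the
internal RNA alphabet (U) at ingest.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._alphabet import to_rna, validate_rna

COUNT_COLUMNS = ["variant_id", "n50", "pre_count", "post_count"]
SCORE_COLUMNS = ["variant_id", "n50", "enr"]


class SchemaError(ValueError):
    """A table does not match its documented dialect."""


def read_fasta(path) -> list[tuple[str, str]]:
    """Parse FASTA into (id, RNA sequence) pairs; T is converted to U."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = to_rna(str(rec.seq))
        validate_rna(seq)
        records.append((rec.id, seq))
    if not records:
        import logging

        logging.getLogger(__name__).warning("no FASTA records in %s", path)
    return records


def write_fasta(path, records) -> None:
    """Write (id, sequence) pairs or a library DataFrame as FASTA."""
    if isinstance(records, pd.DataFrame):
        records = list(zip(records["variant_id"], records["n50"]))
    SeqIO.write(
        (SeqRecord(Seq(s), id=str(i), description="") for i, s in records),
        str(path),
        "fasta",
    )


def read_counts(path, sequences: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a count table TSV; optionally join sequences from a FASTA dict.

    Validates the header, integer non-negative counts and unique variant ids;
    errors cite the offending row.
    """
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "n50": str})
    missing = [c for c in COUNT_COLUMNS if c not in df.columns and c != "n50"]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    for col in ("pre_count", "post_count"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round()) | (vals < 0)
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, counting the header line
            raise SchemaError(f"{path}: invalid {col} at line {row}")
        df[col] = vals.astype(int)
    if df["variant_id"].duplicated().any():
        dup = df["variant_id"][df["variant_id"].duplicated()].iloc[0]
        raise SchemaError(f"{path}: duplicate variant_id {dup!r}")
    if "n50" not in df.columns:
        if sequences is None:
            raise SchemaError(f"{path}: no n50 column and no FASTA sequences given")
        df["n50"] = df["variant_id"].map(sequences)
        if df["n50"].isna().any():
            missing_id = df.loc[df["n50"].isna(), "variant_id"].iloc[0]
            raise SchemaError(f"{path}: no sequence for variant {missing_id!r}")
    df["n50"] = df["n50"].map(to_rna)
    for s in df["n50"]:
        validate_rna(s)
    return df[COUNT_COLUMNS]


def write_counts(path, counts: pd.DataFrame) -> None:
    counts[COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def write_scores(path, variants: pd.DataFrame) -> None:
    variants[SCORE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_halflife(path) -> pd.DataFrame:
    from .halflife import HALFLIFE_COLUMNS

    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "isoform_utr_seq": str})
    missing = [c for c in HALFLIFE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    df["isoform_utr_seq"] = df["isoform_utr_seq"].map(to_rna)
    return df[HALFLIFE_COLUMNS]


def write_halflife(path, records: pd.DataFrame) -> None:
    from .halflife import HALFLIFE_COLUMNS

    records[HALFLIFE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_motif_list(path) -> list[str]:
    """One IUPAC motif per line; '#' starts a comment."""
    motifs = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            seq = to_rna(line)
            validate_rna(seq, allow_iupac=True)
            motifs.append(seq)
    return motifs
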