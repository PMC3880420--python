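"""Readers and writers for the plain-text formats used by the pipeline.

Count tables and key tables are TSV with a header row; sequences travel as
FASTA/FASTQ via Biopython. Tag sequences are always written as the 17-base
form without the shared CATG anchor.
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InvalidConfigError
from .matrix import LibraryKey, TagCountMatrix

#: Constant FASTQ quality character for simulated reads.
FASTQ_QUALITY = "I"


# -- count matrices -----------------------------------------------------------

def write_count_matrix(matrix: TagCountMatrix, path) -> None:
    df = matrix.counts.copy()
    df.insert(0, "sequence", matrix.sequences)
    df.index.name = "tag_id"
    df.to_csv(path, sep="\t")


def read_count_matrix(path, libraries: list[LibraryKey], state: str = "raw") -> TagCountMatrix:
    df = pd.read_csv(path, sep="\t", index_col="tag_id")
    sequences = df.pop("sequence").astype(str)
    lib_ids = [lk.library_id for lk in libraries]
    missing = [c for c in lib_ids if c not in df.columns]
    if missing:
        raise InvalidConfigError(f"count table lacks library columns {missing}")
    counts = df[lib_ids].astype(float)
    if state == "raw":
        counts = counts.round().astype(int)
    return TagCountMatrix(counts=counts, sequences=sequences,
                          libraries=list(libraries), state=state)


# -- library key tables -------------------------------------------------------

def write_key_table(libraries: Iterable[LibraryKey], path) -> None:
    df = pd.DataFrame(
        [(lk.key, lk.library_id, lk.section) for lk in libraries],
        columns=["key", "library_id", "section"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_key_table(path) -> list[LibraryKey]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"key", "library_id", "section"}
    if not required <= set(df.columns):
        raise InvalidConfigError(f"key table needs columns {sorted(required)}")
    return [LibraryKey(r.key, r.library_id, r.section) for r in df.itertuples()]


# -- reads --------------------------------------------------------------------

def write_reads(reads: Iterable[str], path, fmt: str = "fastq") -> None:
    """Write simulated reads as FASTQ (constant quality) or one per line."""
    if fmt == "txt":
        with open(path, "w") as fh:
            for read in reads:
                fh.write(read + "\n")
        return
    if fmt != "fastq":
        raise InvalidConfigError(f"unknown read format {fmt!r}")
    records = []
    for i, read in enumerate(reads):
        rec = SeqRecord(Seq(read), id=f"read{i}", description="")
        rec.letter_annotations["phred_quality"] = [ord(FASTQ_QUALITY) - 33] * len(read)
        records.append(rec)
    SeqIO.write(records, path, "fastq")


def read_reads(path, fmt: str | None = None) -> list[str]:
    """Load reads from FASTQ or plain one-sequence-per-line text.

    Format is inferred from the extension when ``fmt`` is None; qualities are
    discarded.
    """
    if fmt is None:
        ext = os.path.splitext(str(path))[1].lower()
        fmt = "fastq" if ext in (".fastq", ".fq") else "txt"
    if fmt == "fastq":
        return [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


# -- FASTA --------------------------------------------------------------------

def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    """Write (id, sequence) pairs; a two-part id ``(id, description)`` may be
    given as ``id`` separated by a space."""
    seq_records = []
    for rid, seq in records:
        parts = rid.split(None, 1)
        seq_records.append(
            SeqRecord(Seq(seq), id=parts[0],
                      description=parts[1] if len(parts) > 1 else "")
        )
    SeqIO.write(seq_records, path, "fasta")


def read_fasta(path) -> list[tuple[str, str, str]]:
    """Return (id, description, sequence) triples."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        out.append((rec.id, desc, str(rec.seq)))
    return out
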