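"""Readers/writers for the plain-text formats the pipeline exchanges.

TSV for design / count / truth / target / histopathology tables, FASTA for
the mature-miRNA reference, FASTQ (Sanger Phred+33) for reads, GMT for
gene-set collections, JSON for QC stats and summaries.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="mirna_id")


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="mirna_id")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: Iterable[tuple[str, str, Sequence[int]]], path: str | Path) -> None:
    """Write (name, sequence, phred_qualities) tuples as Sanger FASTQ."""
    with open(path, "w") as fh:
        for name, seq, quals in reads:
            if len(seq) != len(quals):
                raise ValueError(f"read {name!r}: sequence/quality length mismatch")
            qline = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{name}\n{seq}\n+\n{qline}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str, list[int]]]:
    """Parse Sanger FASTQ into (name, sequence, phred_qualities) tuples."""
    out = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
        quals = rec.letter_annotations.get("phred_quality")
        if quals is None or len(quals) != len(rec.seq):
            raise ValueError(f"malformed FASTQ record at index {i}")
        out.append((rec.id, str(rec.seq), list(quals)))
    return out


def write_gmt(collection: Mapping[str, Iterable[str]], path: str | Path) -> None:
    """One gene set per line: name, description, members (tab-separated)."""
    with open(path, "w") as fh:
        for name in collection:
            genes = sorted(collection[name])
            fh.write("\t".join([name, "synthetic"] + genes) + "\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    collection: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line {lineno}")
            collection[parts[0]] = set(parts[2:])
    return collection


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
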