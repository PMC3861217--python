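"""Small sequence utilities shared across the pipeline.

Nucleotide alphabets, IUPAC ambiguity handling and minimal GFF3/FASTA helpers.
Coordinates are 1-based inclusive throughout (GenBank convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"

# two-base IUPAC ambiguity codes, unordered
IUPAC2 = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}
IUPAC2_INV = {code: pair for pair, code in IUPAC2.items()}

AMBIGUOUS = set(IUPAC2.values()) | {"N", "B", "D", "H", "V"}

_COMPLEMENT = str.maketrans("ACGTRYSWKMN-", "TGCAYRSWMKN-")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_code(bases: Iterable[str]) -> str:
    """IUPAC code for a set of two bases; N for anything else."""
    key = frozenset(bases)
    if len(key) == 1:
        return next(iter(key))
    return IUPAC2.get(key, "N")


def is_ambiguous(allele: str) -> bool:
    return allele not in BASES


@dataclass(frozen=True)
class GeneFeature:
    """A CDS (or pseudogene) interval, 1-based inclusive."""

    gene_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    feature_type: str = "CDS"
    pseudo: bool = False

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad interval {self.start}-{self.end} for {self.gene_id}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


def write_fasta(path: str | Path, records: Mapping[str, str]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        str(path),
        "fasta",
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(path: str | Path, features: Iterable[GeneFeature], seqid: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.gene_id}"
            if f.pseudo:
                attrs += ";pseudo=true"
            fh.write(
                f"{seqid}\tsymbiovar\t{f.feature_type}\t{f.start}\t{f.end}\t.\t{f.strand}\t0\t{attrs}\n"
            )


def read_gff3(path: str | Path) -> list[GeneFeature]:
    feats = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
            feats.append(
                GeneFeature(
                    gene_id=attrs.get("ID", cols[2]),
                    start=int(cols[3]),
                    end=int(cols[4]),
                    strand=cols[6],
                    feature_type=cols[2],
                    pseudo=attrs.get("pseudo", "false") == "true",
                )
            )
    return feats


def features_frame(features: Iterable[GeneFeature]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": f.gene_id,
                "start": f.start,
                "end": f.end,
                "strand": f.strand,
                "feature_type": f.feature_type,
                "pseudo": f.pseudo,
            }
            for f in features
        ]
    )
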