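"""Reference sequences and feature annotation.

A :class:`Genome` bundles replicon sequences (DNA, upper case) with a flat
list of :class:`Feature` records (tRNA and CDS genes).  Coordinates are
1-based and inclusive throughout, matching SAM and GFF3 conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["Feature", "Genome", "reverse_complement"]


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved by Biopython)."""
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class Feature:
    """One annotated gene on a replicon (1-based, inclusive coordinates)."""

    seqid: str
    start: int
    end: int
    strand: str
    gene_id: str
    biotype: str  # "tRNA" or "CDS"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad coordinates for {self.gene_id}: {self.start}-{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass
class Genome:
    """Replicon sequences plus gene annotation."""

    sequences: dict[str, str] = field(default_factory=dict)
    features: list[Feature] = field(default_factory=list)

    # -- access ---------------------------------------------------------

    @property
    def replicons(self) -> list[str]:
        return list(self.sequences)

    def length(self, seqid: str) -> int:
        return len(self.sequences[seqid])

    def slice(self, seqid: str, start: int, end: int) -> str:
        """Sequence of [start, end] (1-based, inclusive), clipped to bounds."""
        seq = self.sequences[seqid]
        return seq[max(start, 1) - 1 : min(end, len(seq))]

    def feature_sequence(self, feature: Feature) -> str:
        """Transcript-orientation sequence of a feature (5'->3')."""
        s = self.slice(feature.seqid, feature.start, feature.end)
        return reverse_complement(s) if feature.strand == "-" else s

    def features_at(self, seqid: str, position: int, strand: str | None = None) -> list[Feature]:
        hits = [f for f in self.features if f.seqid == seqid and f.contains(position)]
        if strand is not None:
            hits = [f for f in hits if f.strand == strand]
        return hits

    def write_into(self, seqid: str, start: int, text: str) -> None:
        """Overwrite genome sequence at [start, start+len-1] (1-based)."""
        seq = self.sequences[seqid]
        if start < 1 or start + len(text) - 1 > len(seq):
            raise ValueError(f"write outside {seqid} bounds at {start}")
        self.sequences[seqid] = seq[: start - 1] + text + seq[start - 1 + len(text) :]

    # -- FASTA ----------------------------------------------------------

    def to_fasta(self, path: str | Path) -> None:
        records = [SeqRecord(Seq(s), id=name, description="") for name, s in self.sequences.items()]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        sequences = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        return cls(sequences=sequences)

    # -- GFF3 -----------------------------------------------------------
    # Writing GFF3 is a fixed nine-column text layout; read back with the
    # same minimal column split (only gene_id/biotype attributes are used).

    def to_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for name, seq in self.sequences.items():
                fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
            for f in sorted(self.features, key=lambda f: (f.seqid, f.start)):
                attrs = f"ID={f.gene_id};gene_id={f.gene_id};biotype={f.biotype}"
                fh.write(
                    f"{f.seqid}\tendocut\tgene\t{f.start}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
                )

    def load_gff3(self, path: str | Path) -> None:
        self.features = list(read_gff3_features(path))

    @classmethod
    def from_files(cls, fasta: str | Path, gff3: str | Path | None = None) -> "Genome":
        genome = cls.from_fasta(fasta)
        if gff3 is not None:
            genome.load_gff3(gff3)
        return genome


def read_gff3_features(path: str | Path) -> Iterable[Feature]:
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            yield Feature(
                seqid=cols[0],
                start=int(cols[3]),
                end=int(cols[4]),
                strand=cols[6],
                gene_id=attrs.get("gene_id", attrs.get("ID", "unknown")),
                biotype=attrs.get("biotype", cols[2]),
            )
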