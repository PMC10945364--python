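"""Alignment ingestion: filtering and strand-aware 5'-end counting.

Converts alignment records into fractional per-position 5'-end count
tracks.  Reads with a mismatch within their first 30 aligned bases
(counted from the read's 5' end) are removed, as are reads antisense to
the gene overlapping their 5' end.  A read reported at x equally good
locations contributes 1/x at each location, so each retained read carries
total mass 1.
"""

from __future__ import annotations

import re
import statistics
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam
from intervaltree import IntervalTree

from .genome import Feature, Genome, reverse_complement

__all__ = [
    "AlignmentRecord",
    "EndCountTrack",
    "SummaryTrack",
    "filter_reads",
    "count_five_prime_ends",
    "summarize_replicates",
    "read_sam",
    "write_sam",
    "read_alignment_tsv",
    "write_alignment_tsv",
    "write_bedgraph",
    "track_to_frame",
]

CLEAN_PREFIX = 30  # 5'-most bases that must align without mismatch


@dataclass(frozen=True, slots=True)
class AlignmentRecord:
    """One reported placement of a read.

    ``mismatch_offsets`` are 0-based offsets from the read's 5' end;
    ``n_best_hits`` is x, the number of equally good placements of the
    read in the genome.
    """

    read_id: str
    replicon: str
    leftmost: int  # 1-based leftmost reference coordinate
    strand: str  # '+' or '-'
    aligned_length: int
    mismatch_offsets: tuple[int, ...] = ()
    n_best_hits: int = 1

    def __post_init__(self) -> None:
        if self.leftmost < 1:
            raise ValueError(f"{self.read_id}: leftmost must be >= 1")
        if self.n_best_hits < 1:
            raise ValueError(f"{self.read_id}: n_best_hits must be >= 1")
        if any(o < 0 or o >= self.aligned_length for o in self.mismatch_offsets):
            raise ValueError(f"{self.read_id}: mismatch offset outside aligned length")

    @property
    def five_prime_position(self) -> int:
        """Genomic coordinate of the read's 5' end (rightmost base on -)."""
        if self.strand == "+":
            return self.leftmost
        return self.leftmost + self.aligned_length - 1


@dataclass
class EndCountTrack:
    """Fractional 5'-end start counts for one replicate of one condition."""

    condition: str
    replicate: str
    counts: dict[tuple[str, str, int], float] = field(default_factory=dict)

    def total_mass(self) -> float:
        return sum(self.counts.values())


@dataclass
class SummaryTrack:
    """Per-position median of replicate 5'-end counts for one condition."""

    condition: str
    counts: dict[tuple[str, str, int], float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# filtering


def _feature_trees(features: Sequence[Feature]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for f in features:
        trees[f.seqid].addi(f.start, f.end + 1, f)  # half-open
    return dict(trees)


def filter_reads(
    records: Sequence[AlignmentRecord],
    annotation: Genome | Sequence[Feature],
    *,
    clean_prefix: int = CLEAN_PREFIX,
    keep_unannotated: bool = True,
) -> list[AlignmentRecord]:
    """Apply the mismatch and orientation filters.

    Drops records with any mismatch at 5'-end offsets 0..clean_prefix-1,
    and records whose strand disagrees with every gene overlapping their
    5' end.  Records overlapping no gene are kept when
    ``keep_unannotated`` (default).  Records naming a replicon absent
    from the annotation raise ``ValueError``.
    """
    if isinstance(annotation, Genome):
        features = annotation.features
        known = set(annotation.sequences) | {f.seqid for f in features}
    else:
        features = list(annotation)
        known = {f.seqid for f in features}
    trees = _feature_trees(features)

    kept: list[AlignmentRecord] = []
    for rec in records:
        if known and rec.replicon not in known:
            raise ValueError(f"record {rec.read_id} maps to unknown replicon {rec.replicon!r}")
        if rec.mismatch_offsets and min(rec.mismatch_offsets) < clean_prefix:
            continue
        tree = trees.get(rec.replicon)
        overlapping = [iv.data for iv in tree[rec.five_prime_position]] if tree else []
        if overlapping:
            if not any(f.strand == rec.strand for f in overlapping):
                continue
        elif not keep_unannotated:
            continue
        kept.append(rec)
    return kept


# ---------------------------------------------------------------------------
# counting


def count_five_prime_ends(
    records: Iterable[AlignmentRecord],
    condition: str = "na",
    replicate: str = "na",
) -> EndCountTrack:
    """Fractional 5'-end counting: each placement adds 1/x at its 5' end."""
    track = EndCountTrack(condition=condition, replicate=replicate)
    counts = track.counts
    for rec in records:
        key = (rec.replicon, rec.strand, rec.five_prime_position)
        counts[key] = counts.get(key, 0.0) + 1.0 / rec.n_best_hits
    return track


def summarize_replicates(tracks: Sequence[EndCountTrack]) -> SummaryTrack:
    """Per-position median across replicate tracks (absent position = 0).

    With two replicates the median equals the arithmetic mean.
    """
    if len(tracks) < 2:
        raise ValueError("need at least 2 replicate tracks")
    conditions = {t.condition for t in tracks}
    if len(conditions) != 1:
        raise ValueError(f"mixed conditions in replicate summary: {sorted(conditions)}")
    n = len(tracks)
    keys: set[tuple[str, str, int]] = set()
    for t in tracks:
        keys.update(t.counts)
    summary = SummaryTrack(condition=tracks[0].condition)
    for key in keys:
        values = [t.counts.get(key, 0.0) for t in tracks]
        summary.counts[key] = float(statistics.median(values))
    return summary


# ---------------------------------------------------------------------------
# SAM dialect

_MD_TOKEN = re.compile(r"(\d+)|(\^[A-Za-z]+)|([A-Za-z])")


def _md_mismatch_offsets(md: str) -> list[int]:
    """Alignment-column offsets (reference orientation) of substitutions."""
    offsets, col = [], 0
    for num, deletion, sub in _MD_TOKEN.findall(md):
        if num:
            col += int(num)
        elif deletion:
            continue  # deleted reference bases occupy no read column
        else:
            offsets.append(col)
            col += 1
    return offsets


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    """Load mapped records from SAM.

    Mismatch offsets come from the MD tag (converted to 5'-end offsets
    for reverse-strand reads).  The number of equally good placements is
    taken from the NH tag; records without NH are assigned x = number of
    occurrences of their read name in the file.
    """
    raw = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            raw.append(
                (
                    aln.query_name,
                    aln.reference_name,
                    aln.reference_start + 1,
                    "-" if aln.is_reverse else "+",
                    aln.query_alignment_length,
                    aln.get_tag("MD") if aln.has_tag("MD") else None,
                    aln.get_tag("NH") if aln.has_tag("NH") else None,
                )
            )
    name_counts = Counter(name for name, *_ in raw)
    records = []
    for name, replicon, leftmost, strand, alen, md, nh in raw:
        offsets: tuple[int, ...] = ()
        if md is not None:
            cols = _md_mismatch_offsets(md)
            if strand == "-":
                offsets = tuple(sorted(alen - 1 - c for c in cols))
            else:
                offsets = tuple(cols)
        records.append(
            AlignmentRecord(
                read_id=name,
                replicon=replicon,
                leftmost=leftmost,
                strand=strand,
                aligned_length=alen,
                mismatch_offsets=offsets,
                n_best_hits=int(nh) if nh is not None else name_counts[name],
            )
        )
    return records


def _make_md(ref: str, seq: str) -> str:
    """MD tag for an ungapped alignment of seq against ref."""
    out, run = [], 0
    for r, s in zip(ref, seq):
        if r == s:
            run += 1
        else:
            out.append(str(run))
            out.append(r)
            run = 0
    out.append(str(run))
    return "".join(out)


def write_sam(
    records: Sequence[AlignmentRecord],
    path: str | Path,
    genome: Genome,
) -> None:
    """Serialize records as SAM with NM, MD and NH tags.

    Read sequences are reconstructed from the reference with the stored
    mismatch offsets substituted, so MD/NM round-trip exactly.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in genome.sequences.items()],
    }
    refs = list(genome.sequences)
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for rec in records:
            ref = genome.slice(rec.replicon, rec.leftmost, rec.leftmost + rec.aligned_length - 1)
            seq = list(ref)
            for off in rec.mismatch_offsets:
                # convert 5'-end offset to reference-orientation column
                col = rec.aligned_length - 1 - off if rec.strand == "-" else off
                seq[col] = {"A": "C", "C": "G", "G": "T", "T": "A"}.get(seq[col], "A")
            seq_str = "".join(seq)
            aln = pysam.AlignedSegment()
            aln.query_name = rec.read_id
            aln.flag = 16 if rec.strand == "-" else 0
            aln.reference_id = refs.index(rec.replicon)
            aln.reference_start = rec.leftmost - 1
            aln.mapping_quality = 255
            aln.cigarstring = f"{rec.aligned_length}M"
            aln.query_sequence = seq_str
            aln.set_tags(
                [
                    ("NM", len(rec.mismatch_offsets)),
                    ("MD", _make_md(ref, seq_str)),
                    ("NH", rec.n_best_hits),
                ]
            )
            fh.write(aln)


# ---------------------------------------------------------------------------
# tabular dialect

_TSV_COLUMNS = [
    "read_id",
    "replicon",
    "leftmost",
    "strand",
    "aligned_length",
    "mismatch_offsets",
    "n_best_hits",
]


def write_alignment_tsv(records: Sequence[AlignmentRecord], path: str | Path) -> None:
    rows = [
        (
            r.read_id,
            r.replicon,
            r.leftmost,
            r.strand,
            r.aligned_length,
            ",".join(map(str, r.mismatch_offsets)),
            r.n_best_hits,
        )
        for r in records
    ]
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_alignment_tsv(path: str | Path) -> list[AlignmentRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"mismatch_offsets": str}, keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        offsets = tuple(int(x) for x in str(row.mismatch_offsets).split(",") if x != "")
        records.append(
            AlignmentRecord(
                read_id=str(row.read_id),
                replicon=str(row.replicon),
                leftmost=int(row.leftmost),
                strand=str(row.strand),
                aligned_length=int(row.aligned_length),
                mismatch_offsets=offsets,
                n_best_hits=int(row.n_best_hits),
            )
        )
    return records


# ---------------------------------------------------------------------------
# track output


def track_to_frame(track: EndCountTrack | SummaryTrack) -> pd.DataFrame:
    rows = [
        (replicon, strand, pos, count)
        for (replicon, strand, pos), count in sorted(track.counts.items())
    ]
    return pd.DataFrame(rows, columns=["replicon", "strand", "position", "count"])


def write_bedgraph(track: EndCountTrack | SummaryTrack, prefix: str | Path) -> list[Path]:
    """One bedGraph per strand (positions are 1-length intervals)."""
    paths = []
    df = track_to_frame(track)
    for strand, tag in (("+", "fwd"), ("-", "rev")):
        path = Path(f"{prefix}.{tag}.bedgraph")
        sub = df[df["strand"] == strand]
        with open(path, "w") as fh:
            for row in sub.itertuples(index=False):
                fh.write(f"{row.replicon}\t{row.position - 1}\t{row.position}\t{row.count:g}\n")
        paths.append(path)
    return paths
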