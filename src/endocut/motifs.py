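"""Consensus motifs around cleavage sites and anticodon-loop scanning.

A :class:`ConsensusMotif` is an IUPAC-degenerate RNA pattern with an
internal cut offset: the cut falls 5' of ``pattern[cut_offset]``, so a
hit starting at 1-based position s places the first nucleotide of the 3'
cleavage product at s + cut_offset.  The consensus derived from a tRNase
cleaving serine-tRNA anticodon loops is CUKGAA with the cut between G
and AA (written CU(U/G)G^AA); its minimal form is G^AA.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "IUPAC",
    "ConsensusMotif",
    "MotifHit",
    "StructuredRNA",
    "LoopInterval",
    "build_consensus",
    "scan_motif",
    "locate_anticodon_loop",
    "classify_targets",
    "exclude_lacking_motif",
    "MINIMAL_MOTIF",
]

# IUPAC nucleotide codes over the RNA alphabet
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "U": frozenset("U"),
    "R": frozenset("AG"),
    "Y": frozenset("CU"),
    "S": frozenset("CG"),
    "W": frozenset("AU"),
    "K": frozenset("GU"),
    "M": frozenset("AC"),
    "B": frozenset("CGU"),
    "D": frozenset("AGU"),
    "H": frozenset("ACU"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGU"),
}
_SET_TO_CODE = {bases: code for code, bases in IUPAC.items()}


def _rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class ConsensusMotif:
    """Degenerate pattern with a cut 5' of ``pattern[cut_offset]``."""

    pattern: str
    cut_offset: int

    def __post_init__(self) -> None:
        pat = _rna(self.pattern)
        if pat != self.pattern:
            object.__setattr__(self, "pattern", pat)
        if any(b not in IUPAC for b in pat):
            raise ValueError(f"non-IUPAC character in pattern {self.pattern!r}")
        if not (0 < self.cut_offset < len(pat)):
            raise ValueError("cut_offset must be internal to the pattern")

    def regex(self) -> re.Pattern[str]:
        parts = []
        for code in self.pattern:
            bases = IUPAC[code]
            parts.append(next(iter(bases)) if len(bases) == 1 else f"[{''.join(sorted(bases))}]")
        return re.compile("".join(parts))

    def display(self) -> str:
        """Pattern with the cut marked, e.g. CUKG^AA."""
        return self.pattern[: self.cut_offset] + "^" + self.pattern[self.cut_offset :]


MINIMAL_MOTIF = ConsensusMotif("GAA", 1)  # G^AA


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    start: int  # 1-based start of the pattern match
    cut_position: int  # 1-based first nucleotide of the 3' product
    in_loop: bool | None = None


@dataclass(frozen=True)
class LoopInterval:
    start: int
    end: int  # 1-based, inclusive
    method: str  # "structure" or "heuristic"

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class StructuredRNA:
    sequence_id: str
    sequence: str
    structure: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _rna(self.sequence))
        if self.structure is not None:
            if len(self.structure) != len(self.sequence):
                raise ValueError(f"{self.sequence_id}: structure/sequence length mismatch")
            depth = 0
            for ch in self.structure:
                depth += {"(": 1, ")": -1}.get(ch, 0)
                if depth < 0:
                    raise ValueError(f"{self.sequence_id}: unbalanced brackets")
            if depth != 0:
                raise ValueError(f"{self.sequence_id}: unbalanced brackets")


# ---------------------------------------------------------------------------


def build_consensus(
    windows: Sequence[str],
    cut_offset: int,
    min_fraction: float = 1.0,
) -> ConsensusMotif:
    """Column-wise IUPAC generalization of aligned cut windows.

    Each column becomes the smallest IUPAC code covering every base seen
    in at least ``min_fraction`` of the windows (1.0 keeps all observed
    bases).  Flanking fully-degenerate (N) columns are trimmed, shifting
    the cut offset accordingly.
    """
    if len(windows) < 1:
        raise ValueError("need at least one window")
    seqs = [_rna(w) for w in windows]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"windows have unequal lengths: {sorted(lengths)}")
    (width,) = lengths
    if not 0 < cut_offset < width:
        raise ValueError("cut_offset must be internal to the windows")

    n = len(seqs)
    codes = []
    for col in range(width):
        counts: dict[str, int] = {}
        for s in seqs:
            counts[s[col]] = counts.get(s[col], 0) + 1
        kept = frozenset(b for b, c in counts.items() if c / n >= min_fraction)
        if not kept:  # threshold excludes everything: fall back to all observed
            kept = frozenset(counts)
        codes.append(_SET_TO_CODE[kept])

    left = 0
    while left < width and codes[left] == "N":
        left += 1
    right = width
    while right > left and codes[right - 1] == "N":
        right -= 1
    if left == right:
        raise ValueError("no informative columns in consensus windows")
    if not (left < cut_offset < right):
        raise ValueError("cut falls outside the informative consensus columns")
    return ConsensusMotif("".join(codes[left:right]), cut_offset - left)


def scan_motif(
    motif: ConsensusMotif,
    targets: Sequence[StructuredRNA | tuple[str, str]],
) -> list[MotifHit]:
    """All (overlapping) IUPAC matches of the motif in each target.

    Targets with a dot-bracket structure, or of plausible tRNA length,
    get an ``in_loop`` verdict from :func:`locate_anticodon_loop`; other
    hits carry ``in_loop=None`` (unknown).
    """
    rx = re.compile(rf"(?=({motif.regex().pattern}))")
    hits: list[MotifHit] = []
    for target in targets:
        if isinstance(target, tuple):
            target = StructuredRNA(*target)
        loop = locate_anticodon_loop(target)
        for m in rx.finditer(target.sequence):
            start = m.start() + 1
            cut = start + motif.cut_offset
            hits.append(
                MotifHit(
                    sequence_id=target.sequence_id,
                    start=start,
                    cut_position=cut,
                    in_loop=loop.contains(cut) if loop is not None else None,
                )
            )
    return hits


def _hairpin_loops(structure: str) -> list[tuple[int, int]]:
    """1-based (start, end) of unpaired runs directly closed by a pair."""
    pairs: dict[int, int] = {}
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            j = stack.pop()
            pairs[j] = i
            pairs[i] = j
    loops = []
    i = 0
    n = len(structure)
    while i < n:
        if structure[i] == ".":
            j = i
            while j + 1 < n and structure[j + 1] == ".":
                j += 1
            if i > 0 and j + 1 < n and structure[i - 1] == "(" and structure[j + 1] == ")":
                if pairs.get(i - 1) == j + 1:
                    loops.append((i + 1, j + 1))
            i = j + 1
        else:
            i += 1
    return loops


def locate_anticodon_loop(rna: StructuredRNA) -> LoopInterval | None:
    """Anticodon-loop interval of a tRNA.

    With a dot-bracket structure: the unpaired interval enclosed by the
    second of the three cloverleaf hairpin stems; any other hairpin count
    returns None (unknown).  Without structure, a sequence of tRNA length
    (60-95 nt) gets the standard-numbering heuristic interval 32-38.
    """
    if rna.structure is not None:
        loops = _hairpin_loops(rna.structure)
        if len(loops) != 3:
            return None
        start, end = loops[1]
        return LoopInterval(start, end, "structure")
    if 60 <= len(rna.sequence) <= 95:
        return LoopInterval(32, 38, "heuristic")
    return None


def classify_targets(
    hits: Sequence[MotifHit],
    biotypes: dict[str, str],
) -> pd.DataFrame:
    """Tabulate hits per biotype and loop status.

    Returns one row per (biotype, loop status) with hit and sequence
    counts; loop status is "in_loop", "outside_loop" or "unknown".
    """
    rows = []
    for h in hits:
        status = {True: "in_loop", False: "outside_loop", None: "unknown"}[h.in_loop]
        rows.append((biotypes.get(h.sequence_id, "unknown"), status, h.sequence_id))
    if not rows:
        return pd.DataFrame(columns=["biotype", "loop_status", "n_hits", "n_sequences"])
    df = pd.DataFrame(rows, columns=["biotype", "loop_status", "sequence_id"])
    out = (
        df.groupby(["biotype", "loop_status"])
        .agg(n_hits=("sequence_id", "size"), n_sequences=("sequence_id", "nunique"))
        .reset_index()
    )
    return out


def exclude_lacking_motif(
    candidates: Iterable[StructuredRNA | tuple[str, str]],
    motif: ConsensusMotif = MINIMAL_MOTIF,
) -> list[StructuredRNA]:
    """Drop candidate sequences with no occurrence of the (minimal) motif.

    Used to rule out homologs that cannot be physiological targets
    because they lack even the minimal cut site.
    """
    kept = []
    rx = motif.regex()
    for target in candidates:
        if isinstance(target, tuple):
            target = StructuredRNA(*target)
        if rx.search(target.sequence):
            kept.append(target)
    return kept
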