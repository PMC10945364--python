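"""Cleavage-site calling from 5'-end count tracks.

The local peak score at position i is

    score_i = (m_i + 0.5) / (sum_{k in W(i)} m_k + 10 * 0.5)

where m is the per-position replicate median of 5'-end counts and W(i)
is the 10-position window immediately upstream of i in transcript
orientation (i-1..i-10 on '+', i+1..i+10 on '-').  All counts carry a
+0.5 pseudocount so the score is strictly positive.  A position is
called a cleavage site when the toxin/control score ratio strictly
exceeds the threshold (default 60).  Scores are undefined where the
upstream window runs off the replicon; such positions are skipped, not
padded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import Genome, reverse_complement
from .ingest import SummaryTrack

__all__ = [
    "PSEUDOCOUNT",
    "WINDOW",
    "ScoreTrack",
    "CleavageSite",
    "local_peak_score",
    "cleavage_ratio",
    "score_arrays",
    "ratio_arrays",
    "call_sites",
    "annotate_sites",
    "sites_to_frame",
    "write_bed6",
]

PSEUDOCOUNT = 0.5
WINDOW = 10


@dataclass
class ScoreTrack:
    """Dense per-position local peak scores; NaN where undefined."""

    condition: str
    scores: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    # arrays are 0-indexed: scores[key][i-1] is the score at 1-based position i


@dataclass(frozen=True)
class CleavageSite:
    """A called position: first nucleotide of the 3' cleavage product."""

    replicon: str
    position: int
    strand: str
    ratio: float
    toxin_score: float
    control_score: float
    feature: str = "intergenic"
    biotype: str = "intergenic"
    context: str = ""


def _dense_counts(
    track: SummaryTrack, replicon: str, strand: str, length: int
) -> np.ndarray:
    m = np.zeros(length)
    for (rep, st, pos), count in track.counts.items():
        if rep == replicon and st == strand and 1 <= pos <= length:
            m[pos - 1] = count
    return m


def local_peak_score(
    track: SummaryTrack,
    replicon: str,
    strand: str,
    position: int,
    *,
    length: int | None = None,
    pseudocount: float = PSEUDOCOUNT,
) -> float:
    """Score at one position, computed directly from the track mapping.

    Raises ``ValueError`` when the 10-position upstream window (or the
    position itself) lies off the replicon — callers skip such positions.
    """
    step = -1 if strand == "+" else 1
    window = [position + step * k for k in range(1, WINDOW + 1)]
    for p in [position, *window]:
        if p < 1 or (length is not None and p > length):
            raise ValueError(
                f"score undefined at {replicon}:{strand}{position}: window off replicon"
            )
    get = track.counts.get
    m_i = get((replicon, strand, position), 0.0)
    denom = sum(get((replicon, strand, p), 0.0) for p in window) + WINDOW * pseudocount
    return (m_i + pseudocount) / denom


def cleavage_ratio(
    toxin: SummaryTrack,
    control: SummaryTrack,
    replicon: str,
    strand: str,
    position: int,
    *,
    length: int | None = None,
) -> float:
    """Toxin/control score ratio at one position."""
    t = local_peak_score(toxin, replicon, strand, position, length=length)
    c = local_peak_score(control, replicon, strand, position, length=length)
    return t / c


def score_arrays(
    track: SummaryTrack,
    replicon_lengths: dict[str, int],
    *,
    pseudocount: float = PSEUDOCOUNT,
) -> ScoreTrack:
    """Vectorized scores for every (replicon, strand); NaN off-window."""
    out = ScoreTrack(condition=track.condition)
    for replicon, length in replicon_lengths.items():
        for strand in "+-":
            m = _dense_counts(track, replicon, strand, length)
            scores = np.full(length, np.nan)
            if length > WINDOW:
                # upstream window sum via cumulative sums
                csum = np.concatenate([[0.0], np.cumsum(m)])
                if strand == "+":
                    # W(i) = i-10..i-1  ->  csum[i-1] - csum[i-11]  (1-based i >= 11)
                    idx = np.arange(WINDOW + 1, length + 1)
                    wsum = csum[idx - 1] - csum[idx - 1 - WINDOW]
                else:
                    # W(i) = i+1..i+10  (1-based i <= length-10)
                    idx = np.arange(1, length - WINDOW + 1)
                    wsum = csum[idx + WINDOW] - csum[idx]
                scores[idx - 1] = (m[idx - 1] + pseudocount) / (
                    wsum + WINDOW * pseudocount
                )
            out.scores[(replicon, strand)] = scores
    return out


def ratio_arrays(
    toxin: ScoreTrack, control: ScoreTrack
) -> dict[tuple[str, str], np.ndarray]:
    """Per-position ratio arrays; NaN where either score is undefined."""
    ratios = {}
    for key in toxin.scores:
        t, c = toxin.scores[key], control.scores[key]
        with np.errstate(invalid="ignore"):
            ratios[key] = t / c
    return ratios


def call_sites(
    toxin: SummaryTrack,
    control: SummaryTrack,
    genome: Genome,
    *,
    threshold: float = 60.0,
    min_median: float = 0.0,
) -> list[CleavageSite]:
    """Call every position whose cleavage ratio strictly exceeds threshold.

    ``min_median`` optionally requires the toxin replicate-median count at
    the position to reach a floor (off by default).  Sites are annotated
    with the overlapping same-strand gene and +-10 nt sequence context,
    and sorted by (replicon, position, strand).
    """
    lengths = {name: len(seq) for name, seq in genome.sequences.items()}
    t_scores = score_arrays(toxin, lengths)
    c_scores = score_arrays(control, lengths)
    ratios = ratio_arrays(t_scores, c_scores)
    sites: list[CleavageSite] = []
    for (replicon, strand), r in ratios.items():
        with np.errstate(invalid="ignore"):
            hits = np.nonzero(r > threshold)[0]
        for i0 in hits:
            position = int(i0) + 1
            if min_median > 0.0:
                if toxin.counts.get((replicon, strand, position), 0.0) < min_median:
                    continue
            sites.append(
                CleavageSite(
                    replicon=replicon,
                    position=position,
                    strand=strand,
                    ratio=float(r[i0]),
                    toxin_score=float(t_scores.scores[(replicon, strand)][i0]),
                    control_score=float(c_scores.scores[(replicon, strand)][i0]),
                )
            )
    sites.sort(key=lambda s: (s.replicon, s.position, s.strand))
    return annotate_sites(sites, genome)


def annotate_sites(
    sites: Sequence[CleavageSite], genome: Genome, flank: int = 10
) -> list[CleavageSite]:
    """Fill gene overlap and transcript-orientation sequence context."""
    annotated = []
    for site in sites:
        overlapping = genome.features_at(site.replicon, site.position, site.strand)
        if overlapping:
            feature, biotype = overlapping[0].gene_id, overlapping[0].biotype
        else:
            feature, biotype = "intergenic", "intergenic"
        raw = genome.slice(site.replicon, site.position - flank, site.position + flank)
        if site.strand == "-":
            raw = reverse_complement(raw)
        context = raw.replace("T", "U")
        annotated.append(replace(site, feature=feature, biotype=biotype, context=context))
    return annotated


def sites_to_frame(sites: Sequence[CleavageSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                s.replicon,
                s.position,
                s.strand,
                s.ratio,
                s.toxin_score,
                s.control_score,
                s.feature,
                s.biotype,
                s.context,
            )
            for s in sites
        ],
        columns=[
            "replicon",
            "position",
            "strand",
            "ratio",
            "toxin_score",
            "control_score",
            "feature",
            "biotype",
            "context",
        ],
    )


def write_bed6(sites: Sequence[CleavageSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            score = min(1000, round(s.ratio))
            fh.write(
                f"{s.replicon}\t{s.position - 1}\t{s.position}\t{s.feature}\t{score}\t{s.strand}\n"
            )
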