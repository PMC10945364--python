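"""Synthetic genomes, aligned reads and zone-expression tables.

Every downstream stage of the pipeline is testable against planted
ground truth: genomes carry annotated tRNA/CDS genes (optionally with
identical duplicated tRNA pairs, emulating multi-copy isoacceptor
genes), cleavage motifs are written into chosen features with a recorded
cut coordinate, 5'-end read starts are drawn from per-position Poisson
intensities with the planted positions enriched in the toxin condition
only, and zone-expression tables realize per-gene serine-codon
compositions with known list memberships.

All generators are deterministic under their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genome import Feature, Genome, reverse_complement
from .ingest import AlignmentRecord
from .motifs import IUPAC, ConsensusMotif
from .codons import SERINE_CODONS, CodingRecord

__all__ = [
    "SyntheticGenomeSpec",
    "PlantedSite",
    "ReadSimParams",
    "ZoneExpressionSpec",
    "ZoneExpressionResult",
    "simulate_genome",
    "plant_motif_sites",
    "simulate_reads",
    "simulate_zone_expression",
    "write_ground_truth",
    "find_duplicate_pairs",
]

_TRNA_LENGTH = 85
_DUP_MIN_GAP = 1000  # duplicated tRNA copies sit >= 1 kb apart
_DEFAULT_REPLICON_NAMES = ("chromosome", "pSymA", "pSymB")


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Layout of a synthetic multi-replicon genome."""

    n_replicons: int = 1
    replicon_lengths: tuple[int, ...] = (20000,)
    n_trna_genes: int = 4
    n_duplicate_trna_pairs: int = 0
    n_cds_genes: int = 4
    gc_content: float = 0.62
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_replicons <= 3:
            raise ValueError("n_replicons must be in 1..3")
        if len(self.replicon_lengths) != self.n_replicons:
            raise ValueError("replicon_lengths must match n_replicons")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must lie in [0, 1]")
        if 2 * self.n_duplicate_trna_pairs > self.n_trna_genes:
            raise ValueError("duplicate pairs exceed tRNA gene count")


@dataclass(frozen=True)
class PlantedSite:
    """Ground-truth cleavage site written into a synthetic genome."""

    replicon: str
    position: int  # first nucleotide of the 3' cleavage product
    strand: str
    enrichment: float
    context: str  # realized motif, RNA alphabet, transcript orientation

    def __post_init__(self) -> None:
        if self.enrichment <= 1:
            raise ValueError("enrichment must exceed 1")


@dataclass(frozen=True)
class ReadSimParams:
    """Single-end 5'-end read simulation parameters.

    ``background_start_rate`` is the mean number of read 5' starts per
    genomic position per strand (Poisson).  With ``reads_per_replicate``
    set, exactly that many reads are drawn with the same per-position
    intensities conditioned on the total (multinomial); with None the
    per-position counts are i.i.d. Poisson.
    """

    reads_per_replicate: int | None = None
    replicates_per_condition: int = 2
    read_length: int = 150
    background_start_rate: float = 2.0
    mismatch_rate: float = 0.05
    multimap_fraction: float | None = None
    capture_probability: float = 1.0
    replicate_scaling: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mismatch_rate", "capture_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.multimap_fraction is not None and not 0.0 <= self.multimap_fraction < 1.0:
            raise ValueError("multimap_fraction must lie in [0, 1)")
        if self.background_start_rate < 0:
            raise ValueError("background_start_rate must be nonnegative")
        if self.replicates_per_condition < 1 or self.read_length < 1:
            raise ValueError("counts must be positive")
        if self.reads_per_replicate is not None and self.reads_per_replicate < 1:
            raise ValueError("reads_per_replicate must be positive")


# ---------------------------------------------------------------------------
# genome


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


def simulate_genome(spec: SyntheticGenomeSpec) -> Genome:
    """Random replicons with non-overlapping tRNA and CDS genes.

    Duplicated tRNA pairs are bit-identical in transcript orientation
    and placed on the same replicon at least 1 kb apart.  Raises a
    sizing error naming the replicon when its features do not fit.
    """
    rng = np.random.default_rng(spec.seed)
    names = _DEFAULT_REPLICON_NAMES[: spec.n_replicons]
    genome = Genome(
        sequences={
            name: _random_sequence(rng, length, spec.gc_content)
            for name, length in zip(names, spec.replicon_lengths)
        }
    )

    # feature demand per replicon, round-robin; duplicate pairs stay together
    demands: dict[str, list[tuple[str, int, str | None]]] = {n: [] for n in names}
    pair_seqs: dict[str, str] = {}
    trna_idx = 0
    for p in range(spec.n_duplicate_trna_pairs):
        rep = names[p % len(names)]
        pair_id = f"pair{p}"
        pair_seqs[pair_id] = _random_sequence(rng, _TRNA_LENGTH, spec.gc_content)
        for _ in range(2):
            demands[rep].append((f"trna{trna_idx:03d}", _TRNA_LENGTH, pair_id))
            trna_idx += 1
    extra = spec.n_trna_genes - 2 * spec.n_duplicate_trna_pairs
    for i in range(extra):
        rep = names[(spec.n_duplicate_trna_pairs + i) % len(names)]
        demands[rep].append((f"trna{trna_idx:03d}", _TRNA_LENGTH, None))
        trna_idx += 1
    for i in range(spec.n_cds_genes):
        rep = names[i % len(names)]
        n_codons = int(rng.integers(100, 301))
        demands[rep].append((f"cds{i:03d}", 3 * n_codons, None))

    for rep in names:
        cursor = 200
        length = genome.length(rep)
        prev_pair: str | None = None
        for gene_id, span, pair_id in demands[rep]:
            if pair_id is not None and pair_id == prev_pair:
                gap = int(rng.integers(_DUP_MIN_GAP, _DUP_MIN_GAP + 500))
            else:
                gap = int(rng.integers(100, 400))
            prev_pair = pair_id
            start = cursor + gap
            end = start + span - 1
            if end > length - 100:
                raise ValueError(
                    f"replicon {rep} too short ({length} nt) for its features"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            biotype = "tRNA" if gene_id.startswith("trna") else "CDS"
            if pair_id is not None:
                transcript = pair_seqs[pair_id]
                genome.write_into(
                    rep,
                    start,
                    transcript if strand == "+" else reverse_complement(transcript),
                )
            genome.features.append(
                Feature(seqid=rep, start=start, end=end, strand=strand,
                        gene_id=gene_id, biotype=biotype)
            )
            cursor = end
    return genome


def find_duplicate_pairs(genome: Genome) -> list[tuple[Feature, Feature]]:
    """Feature pairs with identical transcript-orientation sequences."""
    by_seq: dict[str, list[Feature]] = {}
    for f in genome.features:
        by_seq.setdefault(genome.feature_sequence(f), []).append(f)
    return [(fs[0], fs[1]) for fs in by_seq.values() if len(fs) == 2]


# ---------------------------------------------------------------------------
# motif planting


def _realize_motif(rng: np.random.Generator, motif: ConsensusMotif) -> str:
    """One concrete RNA sequence drawn from the motif's language."""
    return "".join(
        sorted(IUPAC[code])[int(rng.integers(len(IUPAC[code])))] for code in motif.pattern
    )


def plant_motif_sites(
    genome: Genome,
    n_sites: int,
    motif: ConsensusMotif,
    seed: int = 0,
    *,
    enrichment: float = 300.0,
    features: Sequence[Feature] | None = None,
    max_attempts: int = 200,
) -> list[PlantedSite]:
    """Write the motif into ``n_sites`` distinct annotated features.

    The motif is written in transcript orientation (reverse-complemented
    on '-' features) and the recorded cut position is the genomic
    coordinate of the first transcript nucleotide 3' of the cut.  When
    the chosen feature is one of an identical duplicated pair, the motif
    is written into both copies at the same transcript offset, so the
    pair stays indistinguishable to an aligner; the site is recorded for
    the chosen copy.  Mutates ``genome`` in place.
    """
    pool = list(features if features is not None else genome.features)
    if n_sites > len(pool):
        raise ValueError(f"{n_sites} sites requested but only {len(pool)} features")
    if n_sites == 0:
        return []
    twin_of: dict[str, Feature] = {}
    for f1, f2 in find_duplicate_pairs(genome):
        twin_of[f1.gene_id] = f2
        twin_of[f2.gene_id] = f1
    rng = np.random.default_rng(seed)
    width = len(motif.pattern)
    chosen = [pool[i] for i in rng.choice(len(pool), size=n_sites, replace=False)]
    occupied: dict[str, list[tuple[int, int]]] = {}

    def transcript_write_coords(feat: Feature, t_off: int) -> int:
        """Genomic start of a width-long motif at transcript offset t_off."""
        if feat.strand == "+":
            return feat.start + t_off
        return feat.end - t_off - width + 1

    # keep planted intervals (and their duplicated-gene mirrors) separated
    # by more than the 10-nt scoring window, so one site's peak cannot sit
    # in another site's upstream window
    margin = 12

    def clashes(seqid: str, interval: tuple[int, int]) -> bool:
        return any(
            not (interval[1] + margin < a or interval[0] - margin > b)
            for a, b in occupied.get(seqid, [])
        )

    sites: list[PlantedSite] = []
    for feat in chosen:
        if feat.length <= width:
            raise ValueError(f"feature {feat.gene_id} shorter than the motif")
        twin = twin_of.get(feat.gene_id)
        placed = False
        for _ in range(max_attempts):
            t_off = int(rng.integers(0, feat.length - width + 1))
            start = transcript_write_coords(feat, t_off)
            interval = (start, start + width - 1)
            if clashes(feat.seqid, interval):
                continue
            if twin is not None:
                t_start = transcript_write_coords(twin, t_off)
                t_interval = (t_start, t_start + width - 1)
                if clashes(twin.seqid, t_interval):
                    continue
            realized = _realize_motif(rng, motif)
            dna = realized.replace("U", "T")
            for f, s_g in ([(feat, start)] if twin is None else [(feat, start), (twin, transcript_write_coords(twin, t_off))]):
                genome.write_into(
                    f.seqid, s_g, dna if f.strand == "+" else reverse_complement(dna)
                )
                occupied.setdefault(f.seqid, []).append((s_g, s_g + width - 1))
            if feat.strand == "+":
                position = start + motif.cut_offset
            else:
                position = start + width - 1 - motif.cut_offset
            sites.append(
                PlantedSite(
                    replicon=feat.seqid,
                    position=position,
                    strand=feat.strand,
                    enrichment=enrichment,
                    context=realized,
                )
            )
            placed = True
            break
        if not placed:
            raise RuntimeError(f"could not place a site in {feat.gene_id} without collision")
    return sites


def expected_signal_positions(
    genome: Genome, sites: Sequence["PlantedSite"]
) -> set[tuple[str, str, int]]:
    """All (replicon, strand, position) triples where cleavage signal must
    appear: the planted cuts plus, for cuts inside a duplicated gene, the
    homologous position in the twin copy (multi-mapped reads put half of
    the enriched mass there)."""
    homolog = _homolog_position_maps(genome)
    expected = set()
    for s in sites:
        key = (s.replicon, s.strand, s.position)
        expected.add(key)
        if key in homolog:
            expected.add(homolog[key])
    return expected


# ---------------------------------------------------------------------------
# read simulation


def _homolog_position_maps(
    genome: Genome,
) -> dict[tuple[str, str, int], tuple[str, str, int]]:
    """Map each position of a duplicated gene to its twin's homologous
    position (transcript offset preserved), on the twin's strand."""
    mapping: dict[tuple[str, str, int], tuple[str, str, int]] = {}
    for f1, f2 in find_duplicate_pairs(genome):
        for a, b in ((f1, f2), (f2, f1)):
            for off in range(a.length):
                pos_a = a.start + off if a.strand == "+" else a.end - off
                pos_b = b.start + off if b.strand == "+" else b.end - off
                mapping[(a.seqid, a.strand, pos_a)] = (b.seqid, b.strand, pos_b)
    return mapping


def simulate_reads(
    genome: Genome,
    sites: Sequence[PlantedSite],
    params: ReadSimParams,
) -> dict[tuple[str, str], list[AlignmentRecord]]:
    """Draw 5'-end reads per condition x replicate.

    Background starts are Poisson per position per strand on every
    replicon; in the toxin condition the intensity at each planted
    position is multiplied by its enrichment (thinned by the capture
    probability).  Reads starting inside a duplicated gene are reported
    at both homologous placements with x = 2.  A ``mismatch_rate``
    fraction of reads carry one mismatch within their first 30 aligned
    bases.  Returns {(condition, replicate): records}.
    """
    for name, seq in genome.sequences.items():
        if len(seq) == 0:
            raise ValueError(f"zero-length replicon {name}")
    for s in sites:
        if not 1 <= s.position <= genome.length(s.replicon):
            raise ValueError(f"planted site off replicon: {s}")
        if params.background_start_rate * s.enrichment > 1e9:
            raise ValueError("enrichment would overflow per-position counts")

    rng = np.random.default_rng(params.seed)
    keys = [
        (replicon, strand)
        for replicon in genome.sequences
        for strand in "+-"
    ]
    site_lookup: dict[tuple[str, str], dict[int, float]] = {}
    for s in sites:
        site_lookup.setdefault((s.replicon, s.strand), {})[s.position] = s.enrichment

    homolog = _homolog_position_maps(genome)
    dup_positions = set(homolog)

    scaling = params.replicate_scaling or tuple(
        1.0 for _ in range(params.replicates_per_condition)
    )
    if len(scaling) != params.replicates_per_condition:
        raise ValueError("replicate_scaling length must equal replicates_per_condition")

    out: dict[tuple[str, str], list[AlignmentRecord]] = {}
    for condition in ("toxin", "control"):
        for r in range(params.replicates_per_condition):
            label = f"R{r + 1}"
            lam_parts = []
            for replicon, strand in keys:
                length = genome.length(replicon)
                lam = np.full(length, params.background_start_rate * scaling[r])
                if condition == "toxin":
                    for pos, enr in site_lookup.get((replicon, strand), {}).items():
                        lam[pos - 1] *= 1.0 + (enr - 1.0) * params.capture_probability
                if params.multimap_fraction is not None:
                    mask = np.zeros(length, dtype=bool)
                    for (rep2, st2, pos2) in dup_positions:
                        if rep2 == replicon and st2 == strand:
                            mask[pos2 - 1] = True
                    lam_d, lam_r = lam[mask].sum(), lam[~mask].sum()
                    f = params.multimap_fraction
                    if lam_d > 0:
                        lam[mask] *= (f * lam_r) / ((1.0 - f) * lam_d) if f > 0 else 0.0
                lam_parts.append(lam)
            flat = np.concatenate(lam_parts)
            if params.reads_per_replicate is None:
                counts_flat = rng.poisson(flat)
            else:
                total = flat.sum()
                if total <= 0:
                    raise ValueError("all start intensities are zero")
                counts_flat = rng.multinomial(params.reads_per_replicate, flat / total)

            records: list[AlignmentRecord] = []
            idx = 0
            offset = 0
            for (replicon, strand), lam in zip(keys, lam_parts):
                length = genome.length(replicon)
                counts = counts_flat[offset : offset + length]
                offset += length
                positions = np.repeat(np.arange(1, length + 1), counts)
                if positions.size == 0:
                    continue
                has_mm = rng.random(positions.size) < params.mismatch_rate
                mm_off = rng.integers(0, 30, size=positions.size)
                for pos, mm, off in zip(positions, has_mm, mm_off):
                    pos = int(pos)
                    if strand == "+":
                        alen = min(params.read_length, length - pos + 1)
                        leftmost = pos
                    else:
                        leftmost = max(1, pos - params.read_length + 1)
                        alen = pos - leftmost + 1
                    placements = [(replicon, strand, pos, leftmost, alen)]
                    key3 = (replicon, strand, pos)
                    if key3 in homolog:
                        rep_b, st_b, pos_b = homolog[key3]
                        len_b = genome.length(rep_b)
                        if st_b == "+":
                            alen_b = min(params.read_length, len_b - pos_b + 1)
                            left_b = pos_b
                        else:
                            left_b = max(1, pos_b - params.read_length + 1)
                            alen_b = pos_b - left_b + 1
                        placements.append((rep_b, st_b, pos_b, left_b, alen_b))
                    x = len(placements)
                    # one shared mismatch offset valid in every placement
                    min_alen = min(p[4] for p in placements)
                    offsets = (int(min(off, min_alen - 1)),) if mm else ()
                    read_id = f"{condition}_{label}_r{idx:07d}"
                    idx += 1
                    for rep_p, st_p, _pos_p, left_p, alen_p in placements:
                        records.append(
                            AlignmentRecord(
                                read_id=read_id,
                                replicon=rep_p,
                                leftmost=left_p,
                                strand=st_p,
                                aligned_length=alen_p,
                                mismatch_offsets=offsets,
                                n_best_hits=x,
                            )
                        )
                del positions
            out[(condition, label)] = records
    return out


# ---------------------------------------------------------------------------
# zone expression


_ALL_CODONS = tuple(
    a + b + c for a in "ACGU" for b in "ACGU" for c in "ACGU"
)
_NONSERINE_CODONS = tuple(c for c in _ALL_CODONS if c not in SERINE_CODONS)

# serine-codon mix of a GC-rich genome: frequent UCC/UCG/AGC, rare UCU/UCA/AGU
_DEFAULT_SERINE_MIX = {
    "UCU": 0.08,
    "UCC": 0.30,
    "UCA": 0.06,
    "UCG": 0.28,
    "AGU": 0.05,
    "AGC": 0.23,
}
_DEFAULT_REPLICON_PROBS = {"chromosome": 0.55, "pSymA": 0.22, "pSymB": 0.23}
_RARE_SERINE = ("UCU", "UCA", "AGU")


@dataclass(frozen=True)
class ZoneExpressionSpec:
    """Parameters of the synthetic zone-specific transcriptome.

    Defaults scale the real setting (2209 zone-specific genes among
    8933) by ~10x down; expression is log-normal so a realistic
    minority of zone genes clears the 1500-read high-expression cut.
    """

    n_genes_universe: int = 900
    n_zone_specific: int = 220
    expression_mu: float = 6.2  # log normalized reads, zone-specific genes
    expression_sigma: float = 1.5
    background_mu: float = 4.0  # non-zone genes
    serine_codon_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_SERINE_MIX)
    )
    serine_fraction: float = 0.06
    mean_codons: int = 250
    length_sigma: float = 0.45
    min_codons: int = 60
    replicon_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_REPLICON_PROBS)
    )
    rare_bias_replicon: str | None = None
    rare_bias_factor: float = 5.0
    plant_boundary_genes: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_zone_specific > self.n_genes_universe:
            raise ValueError("zone-specific genes must be a subset of the universe")
        mix = dict(self.serine_codon_mix)
        if set(mix) != set(SERINE_CODONS):
            raise ValueError("serine_codon_mix must cover exactly the six serine codons")
        if any(v < 0 for v in mix.values()) or sum(mix.values()) <= 0:
            raise ValueError("serine_codon_mix must be a nonnegative distribution")
        if any(v < 0 for v in self.replicon_probs.values()):
            raise ValueError("replicon probabilities must be nonnegative")
        if not 0 <= self.serine_fraction <= 1:
            raise ValueError("serine_fraction must lie in [0, 1]")


@dataclass
class ZoneExpressionResult:
    records: list[CodingRecord]
    zone_ids: set[str]
    truth: dict[str, set[str]]  # planted list memberships over the zone universe


def _count_triplets(cds_rna: str) -> dict[str, int]:
    # independent in-frame tally used only for ground-truth labels
    counts = dict.fromkeys(SERINE_CODONS, 0)
    for i in range(0, len(cds_rna), 3):
        codon = cds_rna[i : i + 3]
        if codon in counts:
            counts[codon] += 1
    return counts


def _exact_count_cds(n_codons: int, planted: Mapping[str, int], rng: np.random.Generator) -> str:
    """CDS with exactly the planted serine-codon counts, no other serines."""
    total_planted = sum(planted.values())
    if total_planted > n_codons:
        raise ValueError("planted codons exceed gene length")
    codons = list(
        rng.choice(_NONSERINE_CODONS, size=n_codons - total_planted)
    )
    for codon, k in planted.items():
        codons.extend([codon] * k)
    order = rng.permutation(len(codons))
    return "".join(codons[i] for i in order)


def simulate_zone_expression(spec: ZoneExpressionSpec) -> ZoneExpressionResult:
    """Realize the gene universe, CDS sequences and zone expression.

    Ground-truth list labels (which genes clear each codon/expression
    threshold, evaluated over the zone-specific universe) are computed
    from the realized sequences by an independent triplet tally and
    returned alongside the records.
    """
    rng = np.random.default_rng(spec.seed)
    replicons = list(spec.replicon_probs)
    probs = np.array(list(spec.replicon_probs.values()), dtype=float)
    probs /= probs.sum()
    mix_base = np.array([spec.serine_codon_mix[c] for c in SERINE_CODONS], dtype=float)
    mix_base /= mix_base.sum()

    order = rng.permutation(spec.n_genes_universe)
    zone_flags = np.zeros(spec.n_genes_universe, dtype=bool)
    zone_flags[order[: spec.n_zone_specific]] = True

    records: list[CodingRecord] = []
    zone_ids: set[str] = set()
    for g in range(spec.n_genes_universe):
        gene_id = f"gene{g:05d}"
        replicon = replicons[int(rng.choice(len(replicons), p=probs))]
        n_codons = max(
            spec.min_codons,
            int(np.exp(rng.normal(np.log(spec.mean_codons), spec.length_sigma))),
        )
        mix = mix_base.copy()
        if spec.rare_bias_replicon == replicon:
            for i, codon in enumerate(SERINE_CODONS):
                if codon in _RARE_SERINE:
                    mix[i] *= spec.rare_bias_factor
            mix /= mix.sum()
        is_ser = rng.random(n_codons) < spec.serine_fraction
        ser_draw = rng.choice(len(SERINE_CODONS), size=n_codons, p=mix)
        non_draw = rng.choice(len(_NONSERINE_CODONS), size=n_codons)
        codons = [
            SERINE_CODONS[ser_draw[i]] if is_ser[i] else _NONSERINE_CODONS[non_draw[i]]
            for i in range(n_codons)
        ]
        mu = spec.expression_mu if zone_flags[g] else spec.background_mu
        reads = float(np.exp(rng.normal(mu, spec.expression_sigma)))
        cds_rna = "".join(codons)
        records.append(
            CodingRecord(
                gene_id=gene_id,
                replicon=replicon,
                cds=cds_rna.replace("U", "T"),
                zone_reads=reads,
            )
        )
        if zone_flags[g]:
            zone_ids.add(gene_id)

    if spec.plant_boundary_genes and spec.n_zone_specific >= 6:
        # overwrite six zone genes with exact boundary compositions
        boundary = sorted(zone_ids)[:6]
        plans = [
            ({"UCU": 3}, None),
            ({"UCU": 4}, None),
            ({"UCC": 11}, None),
            ({"UCC": 12}, None),
            ({}, 1499.0),
            ({}, 1500.0),
        ]
        by_id = {r.gene_id: i for i, r in enumerate(records)}
        for gene_id, (planted, reads) in zip(boundary, plans):
            i = by_id[gene_id]
            old = records[i]
            cds_rna = _exact_count_cds(max(60, sum(planted.values())), planted, rng)
            records[i] = CodingRecord(
                gene_id=old.gene_id,
                replicon=old.replicon,
                cds=cds_rna.replace("U", "T"),
                zone_reads=old.zone_reads if reads is None else reads,
            )

    truth: dict[str, set[str]] = {
        "zone_specific": set(zone_ids),
        "ZIII+": set(),
        "serT": set(),
        "rare-serX": set(),
        "serX": set(),
        "serU": set(),
        "serV": set(),
    }
    by_id_rec = {r.gene_id: r for r in records}
    for gene_id in zone_ids:
        rec = by_id_rec[gene_id]
        counts = _count_triplets(rec.cds.replace("T", "U"))
        if rec.zone_reads >= 1500:
            truth["ZIII+"].add(gene_id)
        if counts["UCA"] >= 4:
            truth["serT"].add(gene_id)
        if counts["UCU"] >= 4:
            truth["rare-serX"].add(gene_id)
        if counts["UCU"] >= 4 or counts["UCC"] >= 12:
            truth["serX"].add(gene_id)
        if counts["UCG"] >= 12:
            truth["serU"].add(gene_id)
        if counts["AGU"] >= 4 or counts["AGC"] >= 12:
            truth["serV"].add(gene_id)
    return ZoneExpressionResult(records=records, zone_ids=zone_ids, truth=truth)


# ---------------------------------------------------------------------------
# ground-truth serialization


def write_ground_truth(
    path: str | Path,
    sites: Sequence[PlantedSite] = (),
    truth: Mapping[str, set[str]] | None = None,
) -> None:
    payload = {
        "planted_sites": [
            {
                "replicon": s.replicon,
                "position": s.position,
                "strand": s.strand,
                "enrichment": s.enrichment,
                "context": s.context,
            }
            for s in sites
        ],
        "list_labels": {k: sorted(v) for k, v in (truth or {}).items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
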