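"""Serine-codon composition and translation-target prediction.

Given a universe of coding genes with zone-specific expression, build
threshold-defined gene lists (highly expressed in the nitrogen-fixation
zone; rich in codons decoded by each serine-tRNA isoacceptor), intersect
them, and test for replicon bias in rare-codon-rich genes.

Thresholds follow the asymmetric rare/frequent convention: a gene is
"rich" in a rare codon from 4 occurrences (UCU, UCA, AGU) and in a
frequent codon from 12 (UCC, UCG, AGC); absolute counts, not
proportions, are used to limit length bias.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

__all__ = [
    "SERINE_CODONS",
    "CodingRecord",
    "GeneListSet",
    "VennResult",
    "count_serine_codons",
    "relative_codon_usage",
    "build_lists",
    "venn",
    "replicon_bias",
    "subset_representativeness",
    "records_from_table",
    "records_to_table",
]

SERINE_CODONS = ("UCU", "UCC", "UCA", "UCG", "AGU", "AGC")

# list name -> (codon, minimum count) alternatives; a gene joins a list
# when ANY alternative is satisfied
DEFAULT_LIST_RULES: dict[str, tuple[tuple[str, int], ...]] = {
    "serT": (("UCA", 4),),
    "rare-serX": (("UCU", 4),),
    "serX": (("UCU", 4), ("UCC", 12)),
    "serU": (("UCG", 12),),
    "serV": (("AGU", 4), ("AGC", 12)),
}


def count_serine_codons(cds: str) -> dict[str, int]:
    """In-frame counts of the six serine codons in a coding sequence."""
    seq = cds.upper().replace("T", "U")
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} is not a multiple of 3")
    counts = dict.fromkeys(SERINE_CODONS, 0)
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if codon in counts:
            counts[codon] += 1
    return counts


@dataclass(frozen=True)
class CodingRecord:
    """One gene: CDS, replicon, fixation-zone expression, serine counts."""

    gene_id: str
    replicon: str
    cds: str
    zone_reads: float
    serine_counts: Mapping[str, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.zone_reads < 0:
            raise ValueError(f"{self.gene_id}: zone_reads must be nonnegative")
        counts = count_serine_codons(self.cds)
        if self.serine_counts is None:
            object.__setattr__(self, "serine_counts", counts)
        elif dict(self.serine_counts) != counts:
            raise ValueError(f"{self.gene_id}: serine_counts inconsistent with cds")

    @property
    def n_codons(self) -> int:
        return len(self.cds) // 3


@dataclass
class GeneListSet:
    """Named threshold-defined gene lists over a common universe."""

    lists: dict[str, set[str]]
    universe: set[str]

    def __getitem__(self, name: str) -> set[str]:
        return self.lists[name]


@dataclass
class VennResult:
    """Exclusive region memberships for 2-4 gene lists.

    Region keys are frozensets of list names; a gene sits in exactly one
    region, the one keyed by the full set of lists containing it.
    """

    list_names: tuple[str, ...]
    region_members: dict[frozenset[str], set[str]]

    @property
    def region_counts(self) -> dict[frozenset[str], int]:
        return {k: len(v) for k, v in self.region_members.items()}

    def region(self, *names: str) -> set[str]:
        return self.region_members.get(frozenset(names), set())

    def intersection(self, *names: str) -> set[str]:
        """All genes in every named list (union of enclosing regions)."""
        want = frozenset(names)
        out: set[str] = set()
        for sig, members in self.region_members.items():
            if want <= sig:
                out |= members
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("&".join(sorted(sig)), len(members), ";".join(sorted(members)))
            for sig, members in sorted(
                self.region_members.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
            )
        ]
        return pd.DataFrame(rows, columns=["region", "count", "members"])


# ---------------------------------------------------------------------------


def relative_codon_usage(records: Sequence[CodingRecord]) -> dict[str, float]:
    """Fraction of all serine codons (pooled over records) per codon."""
    totals = dict.fromkeys(SERINE_CODONS, 0)
    for rec in records:
        for codon in SERINE_CODONS:
            totals[codon] += rec.serine_counts[codon]
    grand = sum(totals.values())
    if grand == 0:
        raise ValueError("no serine codons in the supplied records")
    return {codon: totals[codon] / grand for codon in SERINE_CODONS}


def build_lists(
    records: Sequence[CodingRecord],
    zone_threshold: float = 1500,
    rules: Mapping[str, tuple[tuple[str, int], ...]] | None = None,
    *,
    zone_strict: bool = False,
) -> GeneListSet:
    """Build the expression and codon-richness gene lists.

    ZIII+ holds genes whose fixation-zone expression reaches
    ``zone_threshold`` (>= by default; ``zone_strict`` switches to >).
    Codon lists follow ``rules`` (default: serT UCA>=4; rare-serX UCU>=4;
    serX UCU>=4 or UCC>=12; serU UCG>=12; serV AGU>=4 or AGC>=12),
    evaluated on the supplied universe.
    """
    rules = dict(DEFAULT_LIST_RULES if rules is None else rules)
    for name, alts in rules.items():
        for codon, minimum in alts:
            if minimum < 0:
                raise ValueError(f"list {name}: negative threshold for {codon}")
            if codon not in SERINE_CODONS:
                raise ValueError(f"list {name}: {codon} is not a serine codon")
    universe = {r.gene_id for r in records}
    lists: dict[str, set[str]] = {"ZIII+": set()}
    for name in rules:
        lists[name] = set()
    for rec in records:
        above = rec.zone_reads > zone_threshold if zone_strict else rec.zone_reads >= zone_threshold
        if above:
            lists["ZIII+"].add(rec.gene_id)
        for name, alts in rules.items():
            if any(rec.serine_counts[codon] >= minimum for codon, minimum in alts):
                lists[name].add(rec.gene_id)
    return GeneListSet(lists=lists, universe=universe)


def venn(lists: Mapping[str, set[str]]) -> VennResult:
    """Exclusive Venn regions of 2-4 named gene lists."""
    if not 2 <= len(lists) <= 4:
        raise ValueError("venn requires between 2 and 4 lists")
    names = tuple(lists)
    regions: dict[frozenset[str], set[str]] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            regions[frozenset(combo)] = set()
    for gene in set().union(*lists.values()):
        sig = frozenset(n for n in names if gene in lists[n])
        regions[sig].add(gene)
    return VennResult(list_names=names, region_members=regions)


def replicon_bias(
    records: Sequence[CodingRecord],
    gene_lists: Mapping[str, set[str]],
    *,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-replicon membership counts and pairwise proportion tests.

    For each list and each ordered replicon pair, a two-sided Fisher
    exact test on the 2x2 table (member vs not, replicon A vs B) with
    Bonferroni correction over the pairs of that list.  Replicons with
    zero genes are excluded with a warning.  With a single replicon only
    the count table is returned.
    """
    by_replicon: dict[str, list[CodingRecord]] = {}
    for rec in records:
        by_replicon.setdefault(rec.replicon, []).append(rec)
    empty = [r for r, recs in by_replicon.items() if not recs]
    for r in empty:
        warnings.warn(f"replicon {r} has no genes; excluded from bias test")
        del by_replicon[r]
    replicons = sorted(by_replicon)

    count_rows = []
    for name, members in gene_lists.items():
        for rep in replicons:
            genes = {g.gene_id for g in by_replicon[rep]}
            n_mem = len(genes & members)
            count_rows.append((name, rep, len(genes), n_mem, n_mem / len(genes)))
    counts = pd.DataFrame(
        count_rows, columns=["list", "replicon", "n_genes", "n_members", "fraction"]
    )

    test_rows = []
    pairs = list(itertools.combinations(replicons, 2))
    for name, members in gene_lists.items():
        for rep_a, rep_b in pairs:
            a_genes = {g.gene_id for g in by_replicon[rep_a]}
            b_genes = {g.gene_id for g in by_replicon[rep_b]}
            table = [
                [len(a_genes & members), len(a_genes - members)],
                [len(b_genes & members), len(b_genes - members)],
            ]
            odds, p = stats.fisher_exact(table, alternative="two-sided")
            p_adj = min(1.0, p * len(pairs))
            test_rows.append(
                (name, rep_a, rep_b, odds, p, p_adj, p_adj < alpha)
            )
    tests = pd.DataFrame(
        test_rows,
        columns=["list", "replicon_a", "replicon_b", "odds_ratio", "p_value", "p_bonferroni", "significant"],
    )
    return counts, tests


def subset_representativeness(
    universe: Sequence[CodingRecord],
    subset_ids: set[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compare a gene subset's length and serine-codon-frequency
    distributions with the full universe (two-sample KS tests).

    Returns (tests, quantiles); a descriptive report, not a gate.
    """
    if not subset_ids:
        raise ValueError("subset is empty")
    ids = {r.gene_id for r in universe}
    missing = subset_ids - ids
    if missing:
        raise ValueError(f"subset ids not in universe: {sorted(missing)[:5]}")
    subset = [r for r in universe if r.gene_id in subset_ids]

    def metrics(recs: Sequence[CodingRecord]) -> dict[str, list[float]]:
        out = {"length_codons": [float(r.n_codons) for r in recs]}
        out["serine_frequency"] = [
            sum(r.serine_counts.values()) / r.n_codons for r in recs
        ]
        for codon in SERINE_CODONS:
            out[f"freq_{codon}"] = [r.serine_counts[codon] / r.n_codons for r in recs]
        return out

    uni_m, sub_m = metrics(universe), metrics(subset)
    test_rows, quant_rows = [], []
    for metric in uni_m:
        stat, p = stats.ks_2samp(uni_m[metric], sub_m[metric])
        test_rows.append((metric, stat, p))
        qs = pd.Series(uni_m[metric]).quantile([0.25, 0.5, 0.75]).tolist()
        qs_sub = pd.Series(sub_m[metric]).quantile([0.25, 0.5, 0.75]).tolist()
        quant_rows.append((metric, *qs, *qs_sub))
    tests = pd.DataFrame(test_rows, columns=["metric", "ks_statistic", "p_value"])
    quantiles = pd.DataFrame(
        quant_rows,
        columns=[
            "metric",
            "universe_q25",
            "universe_q50",
            "universe_q75",
            "subset_q25",
            "subset_q50",
            "subset_q75",
        ],
    )
    return tests, quantiles


# ---------------------------------------------------------------------------
# tabular I/O


def records_to_table(records: Sequence[CodingRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.gene_id, r.replicon, r.zone_reads, r.cds) for r in records],
        columns=["gene_id", "replicon", "zone_reads", "cds_sequence"],
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def records_from_table(path: str | Path) -> list[CodingRecord]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        CodingRecord(
            gene_id=str(row.gene_id),
            replicon=str(row.replicon),
            cds=str(row.cds_sequence),
            zone_reads=float(row.zone_reads),
        )
        for row in df.itertuples(index=False)
    ]
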