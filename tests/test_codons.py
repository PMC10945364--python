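"""Serine-codon counting, gene lists, Venn regions, replicon bias."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endocut.codons import (
    SERINE_CODONS,
    CodingRecord,
    build_lists,
    count_serine_codons,
    records_from_table,
    records_to_table,
    relative_codon_usage,
    replicon_bias,
    subset_representativeness,
    venn,
)
from endocut.synthetic import ZoneExpressionSpec, simulate_zone_expression


def make_record(gene_id="g", replicon="chromosome", counts=None, zone_reads=100.0, pad=0):
    """Record whose CDS realizes exactly the requested serine counts."""
    counts = counts or {}
    codons = []
    for codon, k in counts.items():
        codons.extend([codon] * k)
    codons.extend(["GCC"] * pad)  # alanine filler
    cds = "".join(codons).replace("U", "T") or "GCC"
    return CodingRecord(gene_id=gene_id, replicon=replicon, cds=cds, zone_reads=zone_reads)


class TestCounting:
    def test_direct_read_off(self):
        counts = count_serine_codons("UCUUCAUCCAGC")
        assert counts == {"UCU": 1, "UCA": 1, "UCC": 1, "AGC": 1, "UCG": 0, "AGU": 0}

    def test_frame_discipline_no_overlapping_count(self):
        # AUC UCA: the embedded UCU spanning a codon boundary is not counted
        assert count_serine_codons("AUCUCA") == {
            "UCU": 0, "UCC": 0, "UCA": 1, "UCG": 0, "AGU": 0, "AGC": 0,
        }

    def test_frame_error(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            count_serine_codons("UCUU")

    def test_random_cds_matches_sliding_oracle(self):
        rng = np.random.default_rng(0)
        cds = "".join(rng.choice(list("ACGT"), size=3000))
        counts = count_serine_codons(cds)
        rna = cds.replace("T", "U")
        for codon in SERINE_CODONS:
            oracle = sum(rna[i : i + 3] == codon for i in range(0, 3000, 3))
            assert counts[codon] == oracle

    def test_serine_counts_always_recomputable(self):
        rec = make_record(counts={"UCA": 5, "AGC": 2}, pad=10)
        assert rec.serine_counts == count_serine_codons(rec.cds)

    def test_inconsistent_supplied_counts_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            CodingRecord(
                gene_id="g", replicon="chromosome", cds="TCTTCT", zone_reads=1.0,
                serine_counts={"UCU": 1, "UCC": 0, "UCA": 0, "UCG": 0, "AGU": 0, "AGC": 0},
            )


class TestUsage:
    def test_uniform_counts_give_equal_fractions(self):
        rec = make_record(counts={c: 1 for c in SERINE_CODONS})
        usage = relative_codon_usage([rec])
        assert all(f == pytest.approx(1 / 6) for f in usage.values())

    def test_single_codon_dominates(self):
        rec = make_record(counts={"UCC": 7})
        assert relative_codon_usage([rec])["UCC"] == 1.0

    def test_pooling_equals_concatenation(self):
        a = make_record("a", counts={"UCU": 3, "AGC": 1})
        b = make_record("b", counts={"UCC": 2, "UCU": 1})
        pooled = relative_codon_usage([a, b])
        merged = make_record("ab", counts={"UCU": 4, "AGC": 1, "UCC": 2})
        assert pooled == relative_codon_usage([merged])
        assert sum(pooled.values()) == pytest.approx(1.0, abs=1e-12)

    def test_no_serine_codons_is_explicit_error(self):
        with pytest.raises(ValueError, match="no serine"):
            relative_codon_usage([make_record(counts={})])


class TestLists:
    @pytest.mark.parametrize(
        "counts,reads,expected",
        [
            ({"UCU": 4}, 0, {"rare-serX", "serX"}),
            ({"UCU": 3}, 0, set()),
            ({"UCU": 3, "UCC": 12}, 0, {"serX"}),
            ({"UCC": 11}, 0, set()),
            ({"UCA": 4}, 0, {"serT"}),
            ({"UCA": 3}, 0, set()),
            ({"UCG": 12}, 0, {"serU"}),
            ({"AGU": 4}, 0, {"serV"}),
            ({"AGC": 12}, 0, {"serV"}),
            ({"AGC": 11, "AGU": 3}, 0, set()),
            ({}, 1500, {"ZIII+"}),
            ({}, 1499, set()),
        ],
    )
    def test_threshold_boundaries(self, counts, reads, expected):
        rec = make_record(counts=counts, zone_reads=float(reads))
        lists = build_lists([rec])
        member_of = {name for name, genes in lists.lists.items() if "g" in genes}
        assert member_of == expected

    def test_rare_serx_always_subset_of_serx(self):
        res = simulate_zone_expression(ZoneExpressionSpec(seed=3))
        zone = [r for r in res.records if r.gene_id in res.zone_ids]
        lists = build_lists(zone)
        assert lists["rare-serX"] <= lists["serX"]

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 8), st.integers(0, 15))
    def test_raising_thresholds_never_adds_members(self, ucu_min, ucc_min):
        recs = [
            make_record(f"g{i}", counts={"UCU": i % 6, "UCC": (i * 3) % 14})
            for i in range(30)
        ]
        base = build_lists(recs, rules={"serX": (("UCU", ucu_min), ("UCC", ucc_min))})
        tighter = build_lists(
            recs, rules={"serX": (("UCU", ucu_min + 1), ("UCC", ucc_min + 2))}
        )
        assert tighter["serX"] <= base["serX"]

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            build_lists([make_record()], rules={"serT": (("UCA", -1),)})

    def test_ground_truth_labels_reproduced_exactly(self):
        res = simulate_zone_expression(ZoneExpressionSpec(seed=4))
        zone = [r for r in res.records if r.gene_id in res.zone_ids]
        lists = build_lists(zone)
        for name in ("ZIII+", "serT", "serX", "rare-serX", "serU", "serV"):
            assert lists[name] == res.truth[name], name


class TestVenn:
    def test_two_list_enumeration(self):
        result = venn({"A": {"1", "2"}, "B": {"2", "3"}})
        assert result.region("A") == {"1"}
        assert result.region("B") == {"3"}
        assert result.region("A", "B") == {"2"}

    def test_disjoint_lists_have_empty_intersections(self):
        result = venn({"A": {"1"}, "B": {"2"}, "C": {"3"}})
        assert result.region("A", "B") == set()
        assert result.region("A", "B", "C") == set()

    def test_region_counts_partition_the_union(self):
        rng = np.random.default_rng(5)
        lists = {
            name: set(map(str, rng.choice(100, size=30, replace=False)))
            for name in ("X", "Y", "Z")
        }
        result = venn(lists)
        union = set().union(*lists.values())
        assert sum(result.region_counts.values()) == len(union)
        # every gene in exactly one region
        seen = [g for members in result.region_members.values() for g in members]
        assert len(seen) == len(set(seen))

    def test_planted_headline_intersection_recovered(self):
        """Seven genes planted to satisfy high zone expression AND
        richness in a targeted-tRNA codon are exactly the genes in the
        relevant overlap regions."""
        planted = {f"nif{i}" for i in range(7)}
        records = [
            make_record(g, counts={"UCA": 4} if i % 2 else {"UCU": 4}, zone_reads=2000.0, pad=50)
            for i, g in enumerate(sorted(planted))
        ]
        # background: expressed but codon-poor, or codon-rich but weakly expressed
        records += [make_record(f"bg{i}", counts={}, zone_reads=3000.0, pad=50) for i in range(20)]
        records += [make_record(f"lo{i}", counts={"UCA": 9}, zone_reads=10.0, pad=50) for i in range(20)]
        lists = build_lists(records)
        result = venn({"ZIII+": lists["ZIII+"], "serT": lists["serT"], "serX": lists["serX"]})
        recovered = result.intersection("ZIII+", "serT") | result.intersection("ZIII+", "serX")
        assert recovered == planted

    def test_list_count_bounds(self):
        with pytest.raises(ValueError):
            venn({"A": {"1"}})


class TestRepliconBias:
    def test_single_replicon_counts_only(self):
        recs = [make_record(f"g{i}", counts={"UCU": 4}) for i in range(5)]
        counts, tests = replicon_bias(recs, {"rare-serX": {r.gene_id for r in recs}})
        assert len(counts) == 1
        assert tests.empty

    def test_enriched_replicon_detected(self):
        """A 5x rare-codon-biased replicon has the top fraction and its
        pairwise tests reject at alpha=0.01."""
        res = simulate_zone_expression(
            ZoneExpressionSpec(
                seed=6,
                n_genes_universe=900,
                rare_bias_replicon="pSymA",
                rare_bias_factor=5.0,
                plant_boundary_genes=False,
            )
        )
        lists = build_lists(res.records)  # full universe, proteome-wide style
        counts, tests = replicon_bias(res.records, {"rare-serX": lists["rare-serX"]})
        frac = counts.set_index("replicon")["fraction"]
        assert frac.idxmax() == "pSymA"
        psyma_rows = tests[(tests.replicon_a == "pSymA") | (tests.replicon_b == "pSymA")]
        assert (psyma_rows.p_bonferroni < 0.01).all()

    def test_uniform_membership_rarely_rejects(self):
        """Without planted bias, pairwise tests reject at about the
        nominal rate or below (Fisher's test is conservative)."""
        n_reject = 0
        n_seeds = 30
        for seed in range(n_seeds):
            res = simulate_zone_expression(
                ZoneExpressionSpec(seed=seed + 100, n_genes_universe=300, plant_boundary_genes=False)
            )
            lists = build_lists(res.records)
            _, tests = replicon_bias(res.records, {"rare-serX": lists["rare-serX"]})
            if (tests.p_value < 0.05).any():
                n_reject += 1
        assert n_reject / n_seeds <= 0.15


class TestRepresentativeness:
    def _universe(self, seed=7, n=300):
        res = simulate_zone_expression(
            ZoneExpressionSpec(
                seed=seed,
                n_genes_universe=n,
                n_zone_specific=n // 4,
                plant_boundary_genes=False,
            )
        )
        return res.records

    def test_identity_subset_is_null_minimum(self):
        universe = self._universe()
        tests, quantiles = subset_representativeness(universe, {r.gene_id for r in universe})
        assert (tests.ks_statistic == 0).all()
        assert (tests.p_value == 1.0).all()
        assert (quantiles.universe_q50 == quantiles.subset_q50).all()

    def test_shortest_decile_rejects_on_length(self):
        universe = self._universe(seed=8, n=2000)
        by_len = sorted(universe, key=lambda r: r.n_codons)
        subset = {r.gene_id for r in by_len[:200]}
        tests, _ = subset_representativeness(universe, subset)
        row = tests.set_index("metric").loc["length_codons"]
        assert row.p_value < 0.01

    def test_random_quarter_usually_passes(self):
        rng = np.random.default_rng(9)
        n_reject = 0
        n_seeds = 20
        for seed in range(n_seeds):
            universe = self._universe(seed=seed + 200, n=200)
            ids = [r.gene_id for r in universe]
            subset = set(rng.choice(ids, size=50, replace=False))
            tests, _ = subset_representativeness(universe, subset)
            row = tests.set_index("metric").loc["length_codons"]
            if row.p_value < 0.05:
                n_reject += 1
        assert n_reject / n_seeds <= 0.10

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            subset_representativeness(self._universe(), set())


def test_expression_table_round_trip(tmp_path):
    res = simulate_zone_expression(
        ZoneExpressionSpec(seed=10, n_genes_universe=40, n_zone_specific=10)
    )
    path = tmp_path / "expr.tsv"
    records_to_table(res.records, path)
    assert records_from_table(path) == res.records
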