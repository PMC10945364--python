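import pytest

from endocut import ingest
from endocut.motifs import ConsensusMotif
from endocut.synthetic import (
    ReadSimParams,
    SyntheticGenomeSpec,
    plant_motif_sites,
    simulate_genome,
    simulate_reads,
)

CONSENSUS = ConsensusMotif("CUKGAA", 4)


def make_genome(seed=1, length=20000, n_replicons=1, n_dup_pairs=1, n_trna=6, n_cds=6):
    spec = SyntheticGenomeSpec(
        n_replicons=n_replicons,
        replicon_lengths=tuple([length] * n_replicons),
        n_trna_genes=n_trna,
        n_duplicate_trna_pairs=n_dup_pairs,
        n_cds_genes=n_cds,
        seed=seed,
    )
    return simulate_genome(spec)


def run_pipeline(seed, n_sites=8, enrichment=300.0, background=2.0, length=20000):
    """Full simulate -> filter -> count -> summarize run for one seed."""
    genome = make_genome(seed=seed, length=length)
    sites = plant_motif_sites(
        genome, n_sites, CONSENSUS, seed=seed + 1000, enrichment=enrichment
    )
    params = ReadSimParams(
        seed=seed + 2000, background_start_rate=background, mismatch_rate=0.05
    )
    read_sets = simulate_reads(genome, sites, params)
    summaries = {}
    for condition in ("toxin", "control"):
        tracks = [
            ingest.count_five_prime_ends(
                ingest.filter_reads(read_sets[(condition, rep)], genome),
                condition,
                rep,
            )
            for rep in ("R1", "R2")
        ]
        summaries[condition] = ingest.summarize_replicates(tracks)
    return genome, sites, read_sets, summaries


@pytest.fixture(scope="session")
def pipeline_run():
    return run_pipeline(seed=1)
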