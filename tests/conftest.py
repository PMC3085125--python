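import numpy as np
import pytest

from popdiff import MicrosatDataset, SeqAlignment


def make_micro(pop_genotypes, loci=None):
    """Build a MicrosatDataset from {pop: [((a, b), (c, d), ...), ...]}.

    Each individual is a tuple of per-locus allele pairs; (0, 0) = missing.
    """
    ids, pops, rows = [], [], []
    for pop, individuals in pop_genotypes.items():
        for k, geno in enumerate(individuals):
            ids.append(f"{pop}_{k}")
            pops.append(pop)
            rows.append(geno)
    n_loci = len(rows[0])
    return MicrosatDataset(
        ids=ids,
        populations=pops,
        loci=loci or [f"L{j + 1}" for j in range(n_loci)],
        genotypes=np.array(rows, dtype=np.int64),
    )


def make_alignment(pop_seqs):
    """Build a SeqAlignment from {pop: [seq, ...]}."""
    ids, pops, seqs = [], [], []
    for pop, ss in pop_seqs.items():
        for k, s in enumerate(ss):
            ids.append(f"{pop}_{k}")
            pops.append(pop)
            seqs.append(s)
    return SeqAlignment(ids=ids, populations=pops, seqs=seqs)


@pytest.fixture
def two_pop_dataset():
    # pop A carries alleles {a=101, b=103}, pop B carries {c=105, d=107}
    return make_micro(
        {"A": [((101, 101),), ((103, 103),)], "B": [((105, 105),), ((107, 107),)]}
    )


@pytest.fixture
def toy_haploid():
    # {a,a} vs {b,b}: the exhaustively enumerable toy dataset
    return make_alignment({"A": ["AAAA", "AAAA"], "B": ["TTTT", "TTTT"]})


@pytest.fixture(scope="session")
def sim_dataset():
    """A moderately structured simulated microsatellite dataset."""
    from popdiff import IslandModelParams, simulate_microsats

    params = IslandModelParams(
        K=4, N_deme=40, m=0.01, mu=0.005, marker_model="stepwise",
        sample_n=15, seed=1234,
    )
    return simulate_microsats(params, 5)


@pytest.fixture(scope="session")
def sim_alignment():
    """A structured simulated alignment (4 demes, 1305 bp)."""
    from popdiff import IslandModelParams, simulate_sequences

    params = IslandModelParams(
        K=4, N_deme=60, m=0.004, mu=2e-5, marker_model="finite_sites",
        L=1305, sample_n=12, seed=99,
    )
    return simulate_sequences(params)
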