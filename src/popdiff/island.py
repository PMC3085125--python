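"""Forward-time finite-island-model simulator.

K demes of equal size exchange migrants at a uniform rate m (destination
uniform over the other demes); within each deme, reproduction is
Wright-Fisher.  The simulator provides microsatellite genotypes
(stepwise or infinite-alleles mutation) and haploid sequence alignments
(finite sites), so that every statistic in the package can be exercised
on data with known mutation and migration parameters.  Unlinked loci are
simulated independently, which is equivalent to free recombination under
random mating.

The mitochondrial emulation uses N_deme/2 haploid copies per deme: with
equal sex ratio, the maternally inherited haploid locus has a 4-fold
smaller population size than a nuclear diploid locus (2N copies).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    MISSING,
    MicrosatDataset,
    PopulationTable,
    SeqAlignment,
    write_alignment,
    write_genotype_table,
    write_population_table,
)

_MARKER_MODELS = ("stepwise", "infinite_alleles", "finite_sites")
_BASES = "ACGT"


@dataclass
class IslandModelParams:
    """Parameters of the finite-island Wright-Fisher simulation.

    m is the per-generation emigration probability per lineage; mu the
    per-allele (microsatellites) or per-site (sequences) mutation rate
    per generation.  burn_in defaults to 10 * N_deme * K generations from
    a monomorphic start, enough to reach mutation-migration-drift
    quasi-equilibrium at desk scales.
    """

    K: int
    N_deme: int
    m: float
    mu: float
    marker_model: str = "stepwise"
    L: int | None = None
    sample_n: int = 20
    burn_in: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.N_deme < 1:
            raise ValueError("N_deme must be >= 1")
        if not 0 <= self.m <= 1:
            raise ValueError("m must lie in [0, 1]")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.marker_model not in _MARKER_MODELS:
            raise ValueError(f"marker_model must be one of {_MARKER_MODELS}")
        if self.marker_model == "finite_sites" and (self.L is None or self.L < 1):
            raise ValueError("finite_sites model needs L >= 1")
        if self.sample_n > self.N_deme:
            raise ValueError("sample_n cannot exceed N_deme")

    @property
    def generations(self) -> int:
        return self.burn_in if self.burn_in is not None else 10 * self.N_deme * self.K


def _migration_sources(rng, K: int, m: float, shape) -> np.ndarray:
    """Source deme for every new lineage: own deme w.p. 1-m, else uniform
    over the K-1 others."""
    own = np.broadcast_to(np.arange(K).reshape((1, K, 1)), shape).copy()
    if K == 1 or m == 0:
        return own
    migrate = rng.random(shape) < m
    offset = rng.integers(1, K, size=shape)
    own[migrate] = (own[migrate] + offset[migrate]) % K
    return own


def simulate_microsats(params: IslandModelParams, n_loci: int) -> MicrosatDataset:
    """Forward Wright-Fisher island-model microsatellites.

    Stepwise mutation shifts the allele label by +-1 repeat with equal
    probability; the infinite-alleles model assigns a fresh label to
    every mutant.  Diploid individuals are formed by pairing consecutive
    pool copies (random mating makes the pairing exchangeable); sample_n
    individuals per deme are returned.
    """
    if params.marker_model not in ("stepwise", "infinite_alleles"):
        raise ValueError("microsatellite simulation needs stepwise or "
                         "infinite_alleles marker_model")
    rng = np.random.default_rng(params.seed)
    K, N = params.K, params.N_deme
    ncopies = 2 * N
    shape = (n_loci, K, ncopies)
    start_label = 100 if params.marker_model == "stepwise" else 1
    pool = np.full(shape, start_label, dtype=np.int64)
    next_allele = start_label + 1
    locus_idx = np.broadcast_to(
        np.arange(n_loci).reshape((n_loci, 1, 1)), shape
    )
    for _ in range(params.generations):
        src = _migration_sources(rng, K, params.m, shape)
        parent = rng.integers(0, ncopies, size=shape)
        pool = pool[locus_idx, src, parent]
        if params.mu > 0:
            mut = rng.random(shape) < params.mu
            n_mut = int(mut.sum())
            if n_mut:
                if params.marker_model == "stepwise":
                    pool[mut] += rng.choice((-1, 1), size=n_mut)
                else:
                    pool[mut] = np.arange(next_allele, next_allele + n_mut)
                    next_allele += n_mut
    if pool.min() < 1:  # stepwise walk strayed below 1: shift all labels
        pool += 1 - pool.min()

    ids, pops, genos = [], [], []
    for d in range(K):
        chosen = rng.choice(N, size=params.sample_n, replace=False)
        pop = f"pop{d + 1}"
        for c in sorted(chosen):
            ids.append(f"{pop}_ind{c + 1}")
            pops.append(pop)
            genos.append(pool[:, d, [2 * c, 2 * c + 1]])
    return MicrosatDataset(
        ids=ids,
        populations=pops,
        loci=[f"L{j + 1}" for j in range(n_loci)],
        genotypes=np.stack(genos),
    )


def simulate_sequences(params: IslandModelParams) -> SeqAlignment:
    """Forward island-model haploid sequences of length L.

    Per-deme copy number is N_deme/2 (rounded, >= 2), emulating maternal
    haploid transmission at one quarter of the nuclear copy number; each
    site mutates to a uniformly chosen different base at rate mu.
    """
    if params.marker_model != "finite_sites":
        raise ValueError("sequence simulation needs the finite_sites marker_model")
    rng = np.random.default_rng(params.seed)
    K, L = params.K, int(params.L)
    n_hap = max(2, round(params.N_deme / 2))
    pool = np.zeros((K, n_hap, L), dtype=np.uint8)
    flat_shape = (K, n_hap)
    for _ in range(params.generations):
        src = _migration_sources(rng, K, params.m, (1,) + flat_shape)[0]
        parent = rng.integers(0, n_hap, size=flat_shape)
        flat = pool.reshape(K * n_hap, L)
        pool = flat[(src * n_hap + parent).ravel()].reshape(K, n_hap, L).copy()
        if params.mu > 0:
            n_mut = rng.poisson(K * n_hap * L * params.mu)
            if n_mut:
                pos = rng.integers(0, K * n_hap * L, size=n_mut)
                flat = pool.reshape(-1)
                flat[pos] = (flat[pos] + rng.integers(1, 4, size=n_mut)) % 4

    sample = min(params.sample_n, n_hap)
    ids, pops, seqs = [], [], []
    for d in range(K):
        chosen = rng.choice(n_hap, size=sample, replace=False)
        pop = f"pop{d + 1}"
        for c in sorted(chosen):
            ids.append(f"{pop}_seq{c + 1}")
            pops.append(pop)
            seqs.append("".join(_BASES[b] for b in pool[d, c]))
    return SeqAlignment(ids=ids, populations=pops, seqs=seqs, length=L)


def inject_null_alleles(
    dataset: MicrosatDataset, null_freq: float, seed: int | None = None
) -> MicrosatDataset:
    """Degrade genotypes with null (non-amplifying) alleles.

    Each allele copy independently fails to amplify with probability
    null_freq (equivalent, under random mating, to a null allele class
    of that frequency).  A (visible, null) heterozygote becomes an
    apparent homozygote for the visible allele; (null, null) becomes a
    missing genotype.
    """
    if not 0 <= null_freq < 1:
        raise ValueError("null_freq must lie in [0, 1)")
    geno = dataset.genotypes.copy()
    if null_freq > 0:
        rng = np.random.default_rng(seed)
        null = rng.random(geno.shape) < null_freq
        null &= geno != MISSING
        a_null, b_null = null[..., 0], null[..., 1]
        only_a = a_null & ~b_null
        only_b = b_null & ~a_null
        both = a_null & b_null
        geno[..., 0][only_a] = geno[..., 1][only_a]
        geno[..., 1][only_b] = geno[..., 0][only_b]
        geno[..., 0][both] = MISSING
        geno[..., 1][both] = MISSING
    return MicrosatDataset(
        ids=list(dataset.ids),
        populations=list(dataset.populations),
        loci=list(dataset.loci),
        genotypes=geno,
    )


# ---------------------------------------------------------------------------
# species-shaped fixtures


@dataclass
class SpeciesProfile:
    K: int
    sample_sizes: tuple[int, ...]
    n_loci: int
    locus_mu: tuple[float, ...]
    m: float
    N_deme: int
    seq_samples: tuple[int, ...]
    seq_mu: float
    seq_m: float
    L: int = 1305

    def __post_init__(self) -> None:
        assert len(self.sample_sizes) == self.K
        assert len(self.locus_mu) == self.n_loci


# Sample sizes follow the shape of a multi-site field survey (6-9 sites,
# 10-50 colonies each, one worker per colony); per-locus mutation rates
# span two orders of magnitude so that within-population effective allele
# numbers cover roughly the 2-22 range seen for real microsatellites.
PROFILES: dict[str, SpeciesProfile] = {
    "host_primary": SpeciesProfile(
        K=6, sample_sizes=(50, 50, 50, 33, 32, 50), n_loci=8,
        locus_mu=(0.02, 0.03, 0.01, 0.005, 0.001, 0.025, 0.001, 0.0003),
        m=0.02, N_deme=60,
        seq_samples=(6, 7, 4, 3, 9, 7), seq_mu=2e-5, seq_m=0.002,
    ),
    "host_secondary": SpeciesProfile(
        K=8, sample_sizes=(48, 42, 48, 50, 46, 10, 44, 50), n_loci=8,
        locus_mu=(0.004, 0.05, 0.008, 0.02, 0.004, 0.03, 0.012, 0.0008),
        m=0.01, N_deme=60,
        seq_samples=(6, 5, 3, 3, 15, 4, 2, 2), seq_mu=1e-5, seq_m=0.002,
    ),
    "parasite": SpeciesProfile(
        K=6, sample_sizes=(10, 50, 50, 12, 16, 49), n_loci=6,
        locus_mu=(0.02, 0.04, 0.02, 0.03, 0.002, 0.02),
        m=0.008, N_deme=60,
        seq_samples=(10, 9, 14, 20, 4, 16), seq_mu=1.5e-5, seq_m=0.004,
    ),
}

# bounding box of the sampled range (northeastern US / southern Canada);
# longitudes stored as negative degrees east
_LAT_RANGE = (38.1, 45.5)
_LON_RANGE = (-88.9, -71.2)


def make_paperlike_fixture(
    species_profile: str, seed: int | None = None
) -> tuple[MicrosatDataset, SeqAlignment, PopulationTable]:
    """A full species-shaped bundle: genotypes, alignment, site table.

    Returns microsatellite genotypes at 6 or 8 loci for 6-9 sites of
    10-50 individuals, a 1305 bp haploid alignment with a handful of
    sequences per site, and site coordinates drawn inside the survey
    bounding box.  Deterministic under ``seed``.
    """
    if species_profile not in PROFILES:
        raise ValueError(
            f"unknown profile {species_profile!r}; choose from {sorted(PROFILES)}"
        )
    prof = PROFILES[species_profile]
    seeds = np.random.SeedSequence(seed).spawn(prof.n_loci + 2)
    max_n = max(prof.sample_sizes)

    # each locus has its own mutation rate: simulate loci one at a time
    per_locus = []
    for j in range(prof.n_loci):
        p = IslandModelParams(
            K=prof.K, N_deme=prof.N_deme, m=prof.m, mu=prof.locus_mu[j],
            marker_model="stepwise", sample_n=max_n,
            seed=int(seeds[j].generate_state(1)[0] % (2**31)),
        )
        per_locus.append(simulate_microsats(p, 1))
    base = per_locus[0]
    geno = np.concatenate([d.genotypes for d in per_locus], axis=1)
    full = MicrosatDataset(
        ids=list(base.ids), populations=list(base.populations),
        loci=[f"L{j + 1}" for j in range(prof.n_loci)], genotypes=geno,
    )
    # truncate each deme to its profile sample size
    idx = []
    seen: dict[str, int] = {}
    for i, pop in enumerate(full.populations):
        d = int(pop[3:]) - 1
        seen[pop] = seen.get(pop, 0) + 1
        if seen[pop] <= prof.sample_sizes[d]:
            idx.append(i)
    micro = full.subset(idx)

    seq_params = IslandModelParams(
        K=prof.K, N_deme=prof.N_deme, m=prof.seq_m, mu=prof.seq_mu,
        marker_model="finite_sites", L=prof.L,
        sample_n=max(prof.seq_samples),
        seed=int(seeds[prof.n_loci].generate_state(1)[0] % (2**31)),
    )
    aln_full = simulate_sequences(seq_params)
    idx = []
    seen = {}
    for i, pop in enumerate(aln_full.populations):
        d = int(pop[3:]) - 1
        seen[pop] = seen.get(pop, 0) + 1
        if seen[pop] <= prof.seq_samples[d]:
            idx.append(i)
    aln = aln_full.subset(idx)

    coord_rng = np.random.default_rng(
        int(seeds[prof.n_loci + 1].generate_state(1)[0] % (2**31))
    )
    pops = [f"pop{d + 1}" for d in range(prof.K)]
    table = pd.DataFrame(
        {
            "latitude": np.round(coord_rng.uniform(*_LAT_RANGE, size=prof.K), 2),
            "longitude": np.round(coord_rng.uniform(*_LON_RANGE, size=prof.K), 2),
            "n_microsat": list(prof.sample_sizes),
            "n_seq": list(prof.seq_samples),
        },
        index=pd.Index(pops, name="population"),
    )
    return micro, aln, PopulationTable(table)


def write_fixture_bundle(
    species_profile: str, outdir: str | Path, seed: int | None = None
) -> dict[str, str]:
    """Write a fixture to disk (genotype TSV, FASTA + popmap, site TSV)
    with a JSON sidecar echoing all generation parameters."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    micro, aln, sites = make_paperlike_fixture(species_profile, seed)
    paths = {
        "genotypes": str(outdir / "genotypes.tsv"),
        "fasta": str(outdir / "alignment.fasta"),
        "popmap": str(outdir / "popmap.tsv"),
        "sites": str(outdir / "sites.tsv"),
        "params": str(outdir / "params.json"),
    }
    write_genotype_table(micro, paths["genotypes"])
    write_alignment(aln, paths["fasta"], paths["popmap"])
    write_population_table(sites, paths["sites"])
    with open(paths["params"], "w") as fh:
        json.dump(
            {"species_profile": species_profile, "seed": seed,
             "profile": asdict(PROFILES[species_profile])},
            fh, indent=1,
        )
        fh.write("\n")
    return paths
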