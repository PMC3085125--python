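"""Within-population diversity statistics.

The central quantity is the effective number of alleles

    n_e = 1 / J,    J = sum_i p_i**2  (homozygosity),

the number of equally frequent alleles that would give the observed
homozygosity.  Unlike heterozygosity H = 1 - J, which saturates near 1
for highly variable markers, n_e scales linearly with diversity: a
population going from 4 to 2 to 1 equally frequent alleles has
H = 0.75, 0.5, 0 but n_e = 4, 2, 1.

H_S and H_T can be computed either as plain frequency plug-ins or with
the Nei & Chesser (1983) sample-size corrections (the default for real
data; the plug-in mode keeps small worked examples exact).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, MicrosatDataset, SeqAlignment

_ACGT = frozenset("ACGT")


@dataclass
class AlleleFreqs:
    """Per-population allele relative frequencies at one locus.

    ``freqs`` has shape ``(K, A)`` over a shared allele index ``alleles``;
    ``n`` counts non-missing diploid individuals (or haploid sequences);
    ``h_obs`` is the observed heterozygosity per population (diploid data
    only).  Populations with no usable data at the locus are excluded and
    listed in ``excluded``.
    """

    locus: str
    populations: list[str]
    alleles: np.ndarray
    freqs: np.ndarray
    n: np.ndarray
    ploidy: int = 2
    h_obs: np.ndarray | None = None
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        sums = self.freqs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("allele frequencies must sum to 1 per population")
        if (self.freqs < -1e-12).any() or (self.freqs > 1 + 1e-12).any():
            raise ValueError("frequencies outside [0, 1]")
        if (self.n < 1).any():
            raise ValueError("each retained population needs n >= 1")

    @property
    def n_populations(self) -> int:
        return len(self.populations)


def allele_frequencies(dataset: MicrosatDataset, locus: str) -> AlleleFreqs:
    """Allele frequencies per population at one microsatellite locus.

    Individuals missing at the locus are dropped locus-wise; populations
    left with no individuals are excluded (with a warning) rather than
    carried as empty vectors.
    """
    try:
        j = dataset.loci.index(locus)
    except ValueError:
        raise KeyError(f"unknown locus {locus!r}") from None
    geno = dataset.genotypes[:, j, :]  # (n, 2)
    labels = np.asarray(dataset.populations)
    pops = list(dict.fromkeys(dataset.populations))  # stable order
    present = geno[:, 0] != MISSING
    alleles = np.unique(geno[present])
    if alleles.size == 0:
        raise ValueError(f"no non-missing data at locus {locus!r}")
    index = {a: i for i, a in enumerate(alleles)}

    kept, freqs, ns, hobs, excluded = [], [], [], [], []
    for pop in pops:
        sel = (labels == pop) & present
        n = int(sel.sum())
        if n == 0:
            excluded.append(pop)
            continue
        g = geno[sel]
        counts = np.zeros(alleles.size)
        for a in g.ravel():
            counts[index[a]] += 1
        kept.append(pop)
        freqs.append(counts / (2 * n))
        ns.append(n)
        hobs.append(float((g[:, 0] != g[:, 1]).mean()))
    if excluded:
        warnings.warn(
            f"locus {locus!r}: populations with no data excluded: {excluded}",
            stacklevel=2,
        )
    return AlleleFreqs(
        locus=locus,
        populations=kept,
        alleles=alleles,
        freqs=np.array(freqs),
        n=np.array(ns),
        ploidy=2,
        h_obs=np.array(hobs),
        excluded=excluded,
    )


def haplotype_alleles(alignment: SeqAlignment) -> np.ndarray:
    """Map each sequence to an integer allele id by full-sequence identity.

    Two sequences are the same allele iff they are identical over all
    sites (after uppercasing at input); 'N' and '-' count as ordinary
    characters here, so ambiguity conservatively creates new alleles.
    Ids are assigned in order of first appearance, starting at 1.
    """
    seen: dict[str, int] = {}
    out = np.empty(alignment.n_sequences, dtype=np.int64)
    for i, s in enumerate(alignment.seqs):
        out[i] = seen.setdefault(s, len(seen) + 1)
    return out


def haplotype_frequencies(alignment: SeqAlignment) -> AlleleFreqs:
    """Treat the alignment as one haploid locus of full-sequence alleles."""
    ids = haplotype_alleles(alignment)
    labels = np.asarray(alignment.populations)
    pops = list(dict.fromkeys(alignment.populations))
    alleles = np.unique(ids)
    kept, freqs, ns = [], [], []
    for pop in pops:
        sel = labels == pop
        n = int(sel.sum())
        counts = np.bincount(ids[sel], minlength=alleles.max() + 1)[alleles]
        kept.append(pop)
        freqs.append(counts / n)
        ns.append(n)
    return AlleleFreqs(
        locus="sequence",
        populations=kept,
        alleles=alleles,
        freqs=np.array(freqs, dtype=float),
        n=np.array(ns),
        ploidy=1,
    )


def homozygosity(p: Sequence[float]) -> float:
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty frequency vector")
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError("frequencies must sum to 1")
    return float((p**2).sum())


def effective_alleles(p: Sequence[float]) -> float:
    """Effective number of alleles n_e = 1 / sum(p_i^2)."""
    return 1.0 / homozygosity(p)


def heterozygosity_equal_alleles(k: int) -> float:
    """Expected heterozygosity of k equally frequent alleles, 1 - 1/k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return 1.0 - 1.0 / k


@dataclass
class HsHt:
    H_S: float
    H_T: float
    H_o: float | None
    n_tilde: float | None
    mode: str
    n_populations: int


def hs_ht(freqs: AlleleFreqs, mode: str = "nei_chesser") -> HsHt:
    """Within- and total-sample expected heterozygosity over K populations.

    plain mode:
        H_S = (1/K) sum_s (1 - sum_i p_si^2)
        H_T = 1 - sum_i pbar_i^2,  pbar_i the unweighted mean of p_si.

    nei_chesser mode (default): Nei & Chesser (1983) estimators with the
    harmonic-mean sample size ntilde; for diploid data

        Hs_hat = ntilde/(ntilde-1) * [ (1/K) sum_s (1 - sum_i p_si^2)
                                        - Ho_bar / (2 ntilde) ]
        Ht_hat = 1 - sum_i pbar_i^2 + Hs_hat/(ntilde K) - Ho_bar/(2 ntilde K)

    Haploid data drop the Ho terms and use haploid sample sizes.
    """
    K = freqs.n_populations
    if K < 2:
        raise ValueError("need at least 2 populations")
    within = 1.0 - (freqs.freqs**2).sum(axis=1)  # per-population 1 - sum p^2
    pbar = freqs.freqs.mean(axis=0)
    hs_plain = float(within.mean())
    ht_plain = float(1.0 - (pbar**2).sum())
    if mode == "plain":
        ho = float(freqs.h_obs.mean()) if freqs.h_obs is not None else None
        return HsHt(hs_plain, ht_plain, ho, None, mode, K)
    if mode != "nei_chesser":
        raise ValueError(f"unknown mode {mode!r}")
    if (freqs.n <= 1).any():
        raise ValueError("sample-size correction undefined: some n_s = 1")
    n_tilde = float(stats.hmean(freqs.n))
    if freqs.ploidy == 2:
        if freqs.h_obs is None:
            raise ValueError("diploid nei_chesser mode needs observed heterozygosity")
        ho_bar = float(freqs.h_obs.mean())
        hs = n_tilde / (n_tilde - 1.0) * (hs_plain - ho_bar / (2.0 * n_tilde))
        ht = ht_plain + hs / (n_tilde * K) - ho_bar / (2.0 * n_tilde * K)
        return HsHt(float(hs), float(ht), ho_bar, n_tilde, mode, K)
    hs = n_tilde / (n_tilde - 1.0) * hs_plain
    ht = ht_plain + hs / (n_tilde * K)
    return HsHt(float(hs), float(ht), None, n_tilde, mode, K)


def _seq_matrix(seqs: Sequence[str]) -> np.ndarray:
    return np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), -1)


def nucleotide_diversity(alignment: SeqAlignment, population: str) -> float:
    """Mean pairwise differences per nucleotide (pi) within one population.

    A site enters a pair's comparison only if both characters are in
    {A, C, G, T}; each pair contributes differences / comparable sites.
    """
    idx = [i for i, p in enumerate(alignment.populations) if p == population]
    if len(idx) < 2:
        raise ValueError(f"need >= 2 sequences in population {population!r}")
    mat = _seq_matrix([alignment.seqs[i] for i in idx])
    valid = np.isin(mat, [b"A", b"C", b"G", b"T"])
    vals = []
    for i in range(len(idx)):
        for j in range(i + 1, len(idx)):
            comp = valid[i] & valid[j]
            n_comp = int(comp.sum())
            if n_comp == 0:
                warnings.warn(
                    f"pair with no comparable sites in {population!r}; skipped",
                    stacklevel=2,
                )
                continue
            vals.append((mat[i][comp] != mat[j][comp]).sum() / n_comp)
    if not vals:
        raise ValueError("no comparable pairs")
    return float(np.mean(vals))


def null_allele_proportion(h_exp: float, h_o: float) -> float:
    """Chakraborty et al. (1992) null-allele proportion estimate.

    r = (H_exp - H_o) / (H_exp + H_o), attributing the entire
    heterozygote deficit to alleles that fail to amplify; floored at 0.
    Returns NaN when both heterozygosities are 0 (uninformative).
    """
    if not (0 <= h_exp <= 1 and 0 <= h_o <= 1):
        raise ValueError("heterozygosities must lie in [0, 1]")
    if h_exp == 0 and h_o == 0:
        return float("nan")
    return max(0.0, (h_exp - h_o) / (h_exp + h_o))


def null_allele_table(dataset: MicrosatDataset, *, unbiased: bool = True) -> pd.DataFrame:
    """Per locus x population null-allele estimates plus per-locus means.

    The across-population average per locus (column of the returned
    frame's ``mean`` rows) is the upper-limit summary used when
    heterozygote deficiency is attributed entirely to null alleles.
    """
    rows = []
    for locus in dataset.loci:
        freqs = allele_frequencies(dataset, locus)
        per_pop = []
        for k, pop in enumerate(freqs.populations):
            n = freqs.n[k]
            he = 1.0 - float((freqs.freqs[k] ** 2).sum())
            if unbiased and n > 1:
                he *= 2 * n / (2 * n - 1.0)
            r = null_allele_proportion(min(he, 1.0), float(freqs.h_obs[k]))
            per_pop.append(r)
            rows.append({"locus": locus, "population": pop, "null_proportion": r})
        finite = [r for r in per_pop if np.isfinite(r)]
        rows.append(
            {
                "locus": locus,
                "population": "mean",
                "null_proportion": float(np.mean(finite)) if finite else float("nan"),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ExpansionTestResult:
    """Sign aggregation of per-locus expansion statistics.

    The per-locus k statistic itself is pluggable (negative values signal
    population expansion); here only the cross-locus sign count and its
    exact two-sided binomial probability are computed.
    """

    k_values: list[float]
    n_negative: int
    n_loci: int
    p_value: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "n_negative": self.n_negative,
                    "n_loci": self.n_loci,
                    "p_value": self.p_value,
                }
            ]
        )


def expansion_sign_test(
    k_values: Sequence[float],
    statistic: Callable[[Sequence[float]], float] | None = None,
) -> ExpansionTestResult:
    """Exact two-sided binomial test on the count of negative k values.

    ``k_values`` may instead be raw per-locus inputs if ``statistic`` is
    supplied; zeros count as non-negative (conservative toward the
    expansion hypothesis).  p = min(1, 2 * min(P(X <= n_neg), P(X >= n_neg)))
    with X ~ Binomial(n_loci, 1/2).
    """
    if statistic is not None:
        k_values = [statistic(v) for v in k_values]
    ks = [float(v) for v in k_values]
    if not ks or not all(np.isfinite(ks)):
        raise ValueError("need >= 1 finite k value")
    n = len(ks)
    n_neg = sum(1 for v in ks if v < 0)
    lo = float(stats.binom.cdf(n_neg, n, 0.5))
    hi = float(stats.binom.sf(n_neg - 1, n, 0.5))
    p = min(1.0, 2.0 * min(lo, hi))
    return ExpansionTestResult(ks, n_neg, n, p)


@dataclass
class DiversitySummary:
    """Per locus x population diversity table with marginal means."""

    table: pd.DataFrame  # columns: locus, population, n, J, n_e, H_o, H_exp
    pi: pd.DataFrame | None = None  # columns: population, n, pi

    def to_frame(self) -> pd.DataFrame:
        return self.table

    def locus_means(self) -> pd.DataFrame:
        t = self.table[self.table["population"] != "mean"]
        return t.groupby("locus", sort=False)[["n_e", "H_exp", "H_o"]].mean().reset_index()


def diversity_summary(
    dataset: MicrosatDataset | None = None,
    alignment: SeqAlignment | None = None,
    *,
    unbiased: bool = True,
) -> DiversitySummary:
    """Within-population J, n_e, H_o and H_exp per locus (and pi per
    population for sequence data), each averaged over populations.

    H_exp uses Nei's small-sample correction 2n/(2n-1) (n/(n-1) for
    haploid data) when ``unbiased``; n_e is always the plug-in 1/J so
    that n_e * J = 1 holds exactly.
    """
    rows = []
    if dataset is not None:
        for locus in dataset.loci:
            freqs = allele_frequencies(dataset, locus)
            for k, pop in enumerate(freqs.populations):
                p = freqs.freqs[k]
                n = int(freqs.n[k])
                J = float((p**2).sum())
                he = 1.0 - J
                if unbiased and n > 1:
                    he = min(1.0, he * 2 * n / (2 * n - 1.0))
                rows.append(
                    {
                        "locus": locus,
                        "population": pop,
                        "n": n,
                        "J": J,
                        "n_e": 1.0 / J,
                        "H_o": float(freqs.h_obs[k]),
                        "H_exp": he,
                    }
                )
    if alignment is not None:
        freqs = haplotype_frequencies(alignment)
        for k, pop in enumerate(freqs.populations):
            p = freqs.freqs[k]
            n = int(freqs.n[k])
            J = float((p**2).sum())
            he = 1.0 - J
            if unbiased and n > 1:
                he = min(1.0, he * n / (n - 1.0))
            rows.append(
                {
                    "locus": "sequence",
                    "population": pop,
                    "n": n,
                    "J": J,
                    "n_e": 1.0 / J,
                    "H_o": float("nan"),
                    "H_exp": he,
                }
            )
    if not rows:
        raise ValueError("need a dataset and/or an alignment")
    table = pd.DataFrame(rows)
    means = (
        table.groupby("locus", sort=False)[["J", "n_e", "H_o", "H_exp"]]
        .mean()
        .reset_index()
    )
    means.insert(1, "population", "mean")
    means.insert(2, "n", table.groupby("locus", sort=False)["n"].sum().to_numpy())
    table = pd.concat([table, means], ignore_index=True)

    pi_frame = None
    if alignment is not None:
        pi_rows = []
        sizes = alignment.population_sizes()
        for pop in dict.fromkeys(alignment.populations):
            if sizes[pop] >= 2:
                pi_rows.append(
                    {
                        "population": pop,
                        "n": sizes[pop],
                        "pi": nucleotide_diversity(alignment, pop),
                    }
                )
        if pi_rows:
            pi_frame = pd.DataFrame(pi_rows)
            pi_frame.loc[len(pi_frame)] = {
                "population": "mean",
                "n": int(pi_frame["n"].sum()),
                "pi": float(pi_frame["pi"].mean()),
            }
    return DiversitySummary(table=table, pi=pi_frame)
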