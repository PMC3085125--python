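"""Between-population differentiation: G_ST, Jost D, gamma_ST.

G_ST = (H_T - H_S) / H_T is bounded by 1 - H_S, so for highly variable
markers (microsatellites with H_S near 0.9) it is pushed toward 0 even
when subpopulations share no alleles.  Jost's D,

    D = [N/(N-1)] * (H_T - H_S) / (1 - H_S)
      = [N/(N-1)] * (1 - n_eS / n_eT),

depends only on the ratio of effective allele numbers and is independent
of within-population diversity, which makes it the statistic of choice
for comparing structure across markers of similar mutation rate.

For sequence data, gamma_ST applies the G_ST ratio to per-nucleotide
heterozygosities averaged over all sites (monomorphic ones included),
which folds genetic distance between haplotypes into the statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .diversity import AlleleFreqs, haplotype_alleles, hs_ht
from .io import MISSING, MicrosatDataset, SeqAlignment
from .resampling import LabelStatistic, PermutationConfig, permutation_test


def gst(H_T: float, H_S: float) -> float:
    """(H_T - H_S)/H_T; NaN (undefined, not an error) when H_T = 0."""
    if not (0 <= H_S <= 1 and 0 <= H_T <= 1):
        raise ValueError("heterozygosities must lie in [0, 1]")
    if H_T == 0:
        return float("nan")
    return (H_T - H_S) / H_T


def jost_d(H_T: float, H_S: float, N: int) -> float:
    """D = [N/(N-1)] (H_T - H_S)/(1 - H_S) over N sampled subpopulations."""
    if N < 2:
        raise ValueError("need N >= 2 subpopulations")
    if H_S >= 1:
        raise ValueError("degenerate: within-population diversity saturated")
    return (N / (N - 1.0)) * (H_T - H_S) / (1.0 - H_S)


def jost_d_from_ne(n_eS: float, n_eT: float, N: int) -> float:
    """Equivalent formulation D = [N/(N-1)] (1 - n_eS/n_eT)."""
    if N < 2:
        raise ValueError("need N >= 2 subpopulations")
    if n_eS < 1 or n_eT < 1:
        raise ValueError("effective allele numbers must be >= 1")
    return (N / (N - 1.0)) * (1.0 - n_eS / n_eT)


@dataclass
class LocusDifferentiation:
    locus: str
    D: float
    G_ST: float
    H_S: float
    H_T: float
    n_eS: float
    n_eT: float
    N: int
    p_value: float = float("nan")
    note: str = ""

    def as_dict(self) -> dict:
        return {
            "locus": self.locus, "D": self.D, "G_ST": self.G_ST,
            "H_S": self.H_S, "H_T": self.H_T, "n_eS": self.n_eS,
            "n_eT": self.n_eT, "N": self.N, "p_value": self.p_value,
            "note": self.note,
        }


def _row_from_hsht(locus: str, res) -> LocusDifferentiation:
    hs, ht, N = res.H_S, res.H_T, res.n_populations
    note = ""
    if hs >= 1.0:
        return LocusDifferentiation(locus, float("nan"), gst(ht, min(hs, 1.0)),
                                    hs, ht, float("inf"), float("inf"), N,
                                    note="H_S saturated")
    d = jost_d(ht, hs, N)
    g = gst(min(max(ht, 0.0), 1.0), min(max(hs, 0.0), 1.0)) if 0 <= hs <= 1 and 0 <= ht <= 1 else (
        (ht - hs) / ht if ht > 0 else float("nan"))
    if (np.isfinite(d) and d < 0) or (np.isfinite(g) and g < 0):
        note = "negative estimate (estimator noise)"
    n_es = 1.0 / (1.0 - hs)
    n_et = 1.0 / (1.0 - ht) if ht < 1 else float("inf")
    return LocusDifferentiation(locus, d, g, hs, ht, n_es, n_et, N, note=note)


def locus_differentiation(
    dataset: MicrosatDataset, locus: str, mode: str = "nei_chesser"
) -> LocusDifferentiation:
    """Per-locus D and G_ST from H_S/H_T; N = populations usable at the locus."""
    from .diversity import allele_frequencies

    freqs = allele_frequencies(dataset, locus)
    if freqs.n_populations < 2:
        return LocusDifferentiation(locus, *[float("nan")] * 6,
                                    N=freqs.n_populations,
                                    note="fewer than 2 usable populations")
    return _row_from_hsht(locus, hs_ht(freqs, mode))


def multilocus_mean(values: Sequence[float]) -> float:
    """Unweighted arithmetic mean over loci, missing (NaN) loci excluded."""
    arr = np.asarray(list(values), dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size == 0:
        raise ValueError("all per-locus values are missing")
    return float(finite.mean())


@dataclass
class DifferentiationResult:
    rows: list[LocusDifferentiation]
    mode: str = "nei_chesser"

    @property
    def mean_D(self) -> float:
        return multilocus_mean([r.D for r in self.rows])

    @property
    def mean_GST(self) -> float:
        return multilocus_mean([r.G_ST for r in self.rows])

    def to_frame(self) -> pd.DataFrame:
        recs = [r.as_dict() for r in self.rows]
        mean = {
            "locus": "mean", "D": self.mean_D, "G_ST": self.mean_GST,
            "H_S": float("nan"), "H_T": float("nan"), "n_eS": float("nan"),
            "n_eT": float("nan"), "N": max(r.N for r in self.rows),
            "p_value": float("nan"), "note": "unweighted mean over loci",
        }
        return pd.DataFrame(recs + [mean])


def differentiation_table(
    dataset: MicrosatDataset, mode: str = "nei_chesser"
) -> DifferentiationResult:
    rows = [locus_differentiation(dataset, locus, mode) for locus in dataset.loci]
    return DifferentiationResult(rows, mode)


# ---------------------------------------------------------------------------
# label-statistic bundles (shared permutation stream for D and G_ST)


def _freqs_from_counts(locus, pops, alleles, freqs, ns, ploidy, hobs):
    return AlleleFreqs(
        locus=locus, populations=pops, alleles=alleles,
        freqs=np.asarray(freqs), n=np.asarray(ns), ploidy=ploidy,
        h_obs=None if hobs is None else np.asarray(hobs),
    )


class MultilocusDGST(LabelStatistic):
    """Mean-over-loci D and G_ST as a function of the population labels.

    Allele labels are compacted per locus at construction; each call only
    re-bins counts by the supplied labels, which keeps permutation tests
    cheap.
    """

    def __init__(self, dataset: MicrosatDataset, mode: str = "nei_chesser",
                 loci: Sequence[str] | None = None):
        self.mode = mode
        self.loci = list(loci) if loci is not None else list(dataset.loci)
        self._per_locus = []
        for locus in self.loci:
            j = dataset.loci.index(locus)
            geno = dataset.genotypes[:, j, :]
            present = geno[:, 0] != MISSING
            alleles, inv = np.unique(geno[present], return_inverse=True)
            comp = np.full(geno.shape, -1, dtype=np.int64)
            comp[present] = inv.reshape(-1, 2)
            het = (geno[:, 0] != geno[:, 1]) & present
            self._per_locus.append((locus, comp, present, het, alleles))

    def __call__(self, labels: np.ndarray) -> dict[str, float]:
        labels = np.asarray(labels)
        pops = pd.unique(labels)
        ds, gs = [], []
        for locus, comp, present, het, alleles_ in self._per_locus:
            A = alleles_.size
            kept, fr, ns, ho = [], [], [], []
            for pop in pops:
                sel = (labels == pop) & present
                n = int(sel.sum())
                if n == 0:
                    continue
                counts = np.bincount(comp[sel].ravel(), minlength=A)
                kept.append(str(pop))
                fr.append(counts / (2.0 * n))
                ns.append(n)
                ho.append(het[sel].mean())
            if len(kept) < 2:
                ds.append(float("nan"))
                gs.append(float("nan"))
                continue
            freqs = _freqs_from_counts(locus, kept, alleles_, fr, ns, 2, ho)
            row = _row_from_hsht(locus, hs_ht(freqs, self.mode))
            ds.append(row.D)
            gs.append(row.G_ST)
        d = multilocus_mean(ds) if np.isfinite(ds).any() else float("nan")
        g = multilocus_mean(gs) if np.isfinite(gs).any() else float("nan")
        return {"D": d, "G_ST": g}


class SequenceDGST(LabelStatistic):
    """D and G_ST of an alignment treated as one haploid locus.

    Distinct full-length sequences are the alleles (identity includes
    'N' and '-').
    """

    def __init__(self, alignment: SeqAlignment, mode: str = "nei_chesser"):
        self.mode = mode
        ids = haplotype_alleles(alignment)
        self._alleles, self._comp = np.unique(ids, return_inverse=True)

    def __call__(self, labels: np.ndarray) -> dict[str, float]:
        labels = np.asarray(labels)
        pops = pd.unique(labels)
        A = self._alleles.size
        kept, fr, ns = [], [], []
        for pop in pops:
            sel = labels == pop
            n = int(sel.sum())
            if n == 0:
                continue
            counts = np.bincount(self._comp[sel], minlength=A)
            kept.append(str(pop))
            fr.append(counts / n)
            ns.append(n)
        if len(kept) < 2:
            return {"D": float("nan"), "G_ST": float("nan")}
        freqs = _freqs_from_counts("sequence", kept, self._alleles, fr, ns, 1, None)
        row = _row_from_hsht("sequence", hs_ht(freqs, self.mode))
        return {"D": row.D, "G_ST": row.G_ST}


def sequence_differentiation(
    alignment: SeqAlignment, mode: str = "nei_chesser"
) -> LocusDifferentiation:
    """D and G_ST for an alignment collapsed to full-sequence alleles.

    With no sequence variation at all, G_ST is undefined (NaN marker)
    and D is reported as 0 (no differentiation is detectable).
    """
    stat = SequenceDGST(alignment, mode)
    vals = stat(np.asarray(alignment.populations))
    from .diversity import haplotype_frequencies

    freqs = haplotype_frequencies(alignment)
    res = hs_ht(freqs, mode)
    row = _row_from_hsht("sequence", res)
    if res.H_T == 0:  # monomorphic alignment
        row = LocusDifferentiation("sequence", 0.0, float("nan"), res.H_S,
                                   res.H_T, 1.0, 1.0, res.n_populations,
                                   note="no variation")
    assert np.isnan(row.D) or np.isnan(vals["D"]) or abs(row.D - vals["D"]) < 1e-9
    return row


# ---------------------------------------------------------------------------
# gamma_ST


_BASE_CODE = {b"A": 0, b"C": 1, b"G": 2, b"T": 3}


class GammaSTStatistic(LabelStatistic):
    """Per-nucleotide H_S/H_T averaged over all sites, as a label statistic."""

    def __init__(self, alignment: SeqAlignment):
        mat = np.frombuffer("".join(alignment.seqs).encode(), dtype="S1")
        mat = mat.reshape(alignment.n_sequences, alignment.length)
        code = np.full(mat.shape, -1, dtype=np.int8)
        for b, c in _BASE_CODE.items():
            code[mat == b] = c
        self._onehot = np.stack([(code == c) for c in range(4)], axis=1)  # (n,4,L)
        self.length = alignment.length

    def components(self, labels: np.ndarray) -> tuple[float, float]:
        labels = np.asarray(labels)
        pops = pd.unique(labels)
        L = self.length
        hs_sum = np.zeros(L)
        hs_npop = np.zeros(L)
        pbar_sum = np.zeros((4, L))
        for pop in pops:
            counts = self._onehot[labels == pop].sum(axis=0).astype(float)  # (4,L)
            n_valid = counts.sum(axis=0)
            usable = n_valid > 0
            f = np.zeros_like(counts)
            f[:, usable] = counts[:, usable] / n_valid[usable]
            h = 1.0 - (f**2).sum(axis=0)
            hs_sum[usable] += h[usable]
            hs_npop[usable] += 1
            pbar_sum[:, usable] += f[:, usable]
        ok = hs_npop > 0
        hs_site = np.zeros(L)
        ht_site = np.zeros(L)
        hs_site[ok] = hs_sum[ok] / hs_npop[ok]
        pbar = np.zeros((4, L))
        pbar[:, ok] = pbar_sum[:, ok] / hs_npop[ok]
        ht_site[ok] = 1.0 - (pbar[:, ok] ** 2).sum(axis=0)
        # sites with no usable data in any population count as monomorphic (H = 0)
        return float(hs_site.mean()), float(ht_site.mean())

    def __call__(self, labels: np.ndarray) -> dict[str, float]:
        hs, ht = self.components(labels)
        g = (ht - hs) / ht if ht > 0 else float("nan")
        return {"gamma_ST": g}


@dataclass
class GammaSTResult:
    H_Snuc: float
    H_Tnuc: float
    gamma_ST: float
    p_value: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"H_Snuc": self.H_Snuc, "H_Tnuc": self.H_Tnuc,
              "gamma_ST": self.gamma_ST, "p_value": self.p_value}]
        )


def gamma_st(alignment: SeqAlignment) -> GammaSTResult:
    """gamma_ST = (H_Tnuc - H_Snuc)/H_Tnuc from per-site heterozygosities.

    Sites where a sequence carries N or '-' simply exclude that sequence
    at that site; monomorphic sites stay in the average (they dilute both
    numerator terms equally, matching a whole-sequence average).
    """
    pops = set(alignment.populations)
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    sizes = alignment.population_sizes()
    if min(sizes.values()) < 2:
        raise ValueError("need >= 2 sequences per population")
    stat = GammaSTStatistic(alignment)
    hs, ht = stat.components(np.asarray(alignment.populations))
    g = (ht - hs) / ht if ht > 0 else float("nan")
    return GammaSTResult(H_Snuc=hs, H_Tnuc=ht, gamma_ST=g)


# ---------------------------------------------------------------------------
# pairwise D, sequence distances


@dataclass
class PairwiseD:
    matrix: pd.DataFrame
    flagged_pairs: list[tuple[str, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return self.matrix.reset_index(names="population")


def pairwise_d(dataset: MicrosatDataset, mode: str = "nei_chesser") -> PairwiseD:
    """Pairwise-population D, averaged over loci, with N fixed at 2.

    Cells where no locus is usable for a pair are NaN and flagged.
    """
    pops = list(dict.fromkeys(dataset.populations))
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    K = len(pops)
    out = np.zeros((K, K))
    flagged = []
    for i in range(K):
        for j in range(i + 1, K):
            sub = dataset.restrict_to_populations([pops[i], pops[j]])
            vals = []
            for locus in sub.loci:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    row = locus_differentiation(sub, locus, mode)
                if row.N == 2 and np.isfinite(row.D):
                    vals.append(row.D)
            if vals:
                out[i, j] = out[j, i] = float(np.mean(vals))
            else:
                out[i, j] = out[j, i] = float("nan")
                flagged.append((pops[i], pops[j]))
    return PairwiseD(pd.DataFrame(out, index=pops, columns=pops), flagged)


def pairwise_sequence_distance(alignment: SeqAlignment) -> pd.DataFrame:
    """Mean pairwise sequence differences per nucleotide between populations.

    Off-diagonal cells average over all cross-population sequence pairs
    (sites compared only where both characters are A/C/G/T); used as the
    genetic distance input to isolation-by-distance tests.
    """
    from .diversity import _seq_matrix

    pops = list(dict.fromkeys(alignment.populations))
    labels = np.asarray(alignment.populations)
    mat = _seq_matrix(alignment.seqs)
    valid = np.isin(mat, [b"A", b"C", b"G", b"T"])
    K = len(pops)
    out = np.zeros((K, K))
    for i in range(K):
        for j in range(i + 1, K):
            rows_i = np.where(labels == pops[i])[0]
            rows_j = np.where(labels == pops[j])[0]
            vals = []
            for a in rows_i:
                comp = valid[a] & valid[rows_j]
                n_comp = comp.sum(axis=1)
                diffs = ((mat[a] != mat[rows_j]) & comp).sum(axis=1)
                ok = n_comp > 0
                vals.extend(diffs[ok] / n_comp[ok])
            out[i, j] = out[j, i] = float(np.mean(vals)) if vals else float("nan")
    return pd.DataFrame(out, index=pops, columns=pops)


# ---------------------------------------------------------------------------
# fragment-length analysis


@dataclass
class FragmentAnalysisResult:
    records: pd.DataFrame  # length, replicate, start, D, G_ST, p_value
    summary: pd.DataFrame  # length, mean_D, mean_GST, power
    n_frag: int
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return self.summary


def fragment_length_analysis(
    alignment: SeqAlignment,
    lengths: Sequence[int] = (100, 300, 500, 700, 900, 1100),
    n_frag: int = 20,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    mode: str = "nei_chesser",
) -> FragmentAnalysisResult:
    """How sequence length drives D, G_ST and the power to detect structure.

    For each fragment length L, ``n_frag`` windows are cut at uniformly
    random start positions (with replacement across draws, no wrap),
    each analysed as a haploid locus with a permutation p-value; power is
    the fraction of windows with p < alpha.  Longer fragments carry more
    mutations, so D rises with L while G_ST sinks as haplotype
    heterozygosity saturates.
    """
    if max(lengths) > alignment.length:
        raise ValueError(
            f"fragment length {max(lengths)} exceeds alignment length "
            f"{alignment.length}"
        )
    rng = np.random.default_rng(seed)
    labels = np.asarray(alignment.populations)
    records = []
    for L in lengths:
        for rep in range(n_frag):
            start = int(rng.integers(0, alignment.length - L + 1))
            win = alignment.window(start, L)
            stat = SequenceDGST(win, mode)
            obs = stat(labels)
            if not np.isfinite(obs["D"]) or not np.isfinite(obs["G_ST"]):
                records.append({"length": L, "replicate": rep, "start": start,
                                "D": obs["D"], "G_ST": obs["G_ST"],
                                "p_value": float("nan")})
                continue
            cfg = PermutationConfig(n_perm=n_perm,
                                    seed=int(rng.integers(2**31)), alpha=alpha)
            out = permutation_test(win, stat, cfg)
            records.append({"length": L, "replicate": rep, "start": start,
                            "D": obs["D"], "G_ST": obs["G_ST"],
                            "p_value": out.p_D})
    rec = pd.DataFrame(records)
    rows = []
    for L in lengths:
        sub = rec[rec["length"] == L]
        power = float((sub["p_value"] < alpha).sum()) / n_frag  # NaN p => not significant
        rows.append({"length": L,
                     "mean_D": float(sub["D"].mean(skipna=True)) if sub["D"].notna().any() else float("nan"),
                     "mean_GST": float(sub["G_ST"].mean(skipna=True)) if sub["G_ST"].notna().any() else float("nan"),
                     "power": power})
    return FragmentAnalysisResult(rec, pd.DataFrame(rows), n_frag, alpha)
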