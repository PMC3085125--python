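"""Permutation significance machinery and the Mantel test.

The permutation null is panmixia: individuals are redistributed over the
subpopulations without replacement, so sample sizes are preserved and an
individual's full multilocus genotype moves as one unit.  D and G_ST are
evaluated on the *same* randomized datasets, and the p-value is the
fraction of permuted statistics greater than or equal to the observed
one (it can therefore be exactly 0; an optional add-one correction is
available but off by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd


class LabelStatistic:
    """Base class for statistics evaluated on a permuted label vector.

    Subclasses precompute whatever is label-invariant (allele ids,
    per-site base counts, ...) at construction and implement
    ``__call__(labels) -> dict of named statistics``.  ``permutation_test``
    also accepts a plain callable taking the full dataset.
    """

    def __call__(self, labels: np.ndarray) -> Mapping[str, float]:  # pragma: no cover
        raise NotImplementedError


@dataclass
class PermutationConfig:
    n_perm: int = 1000
    seed: int | None = None
    alpha: float = 0.05
    add_one: bool = False
    unit: str = "individual"

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.unit != "individual":
            raise ValueError("only individual-level permutation is supported")


@dataclass
class PermutationOutcome:
    observed: dict[str, float]
    p_values: dict[str, float]
    null_quantiles: dict[str, dict[str, float]]
    n_perm: int
    null_values: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    @property
    def observed_D(self) -> float:
        return self.observed.get("D", float("nan"))

    @property
    def observed_GST(self) -> float:
        return self.observed.get("G_ST", float("nan"))

    @property
    def p_D(self) -> float:
        return self.p_values.get("D", float("nan"))

    @property
    def p_GST(self) -> float:
        return self.p_values.get("G_ST", float("nan"))


def permute_individuals(data, rng: np.random.Generator):
    """One random redistribution of individuals over populations.

    The multiset of population labels is preserved exactly; genotypes
    travel with their individual.
    """
    labels = np.asarray(data.populations)
    return data.with_populations(rng.permutation(labels).tolist())


_QUANTS = {"min": 0.0, "q05": 0.05, "q25": 0.25, "median": 0.5,
           "q75": 0.75, "q95": 0.95, "max": 1.0}


def permutation_test(data, statistic_bundle, config: PermutationConfig) -> PermutationOutcome:
    """Monte-Carlo permutation test with a shared permutation stream.

    Every named statistic in the bundle (typically D and G_ST) is
    recomputed on the identical sequence of randomized label vectors, so
    their p-values are directly comparable.  p = #(stat_perm >= stat_obs)
    / n_perm; permuted values that are undefined (NaN) never count as
    exceeding.
    """
    labels = np.asarray(data.populations)
    if isinstance(statistic_bundle, LabelStatistic):
        evaluate = statistic_bundle
    else:
        evaluate = lambda lab: statistic_bundle(data.with_populations(lab.tolist()))
    observed = dict(evaluate(labels))
    bad = [k for k, v in observed.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"statistic undefined on observed data: {bad}")

    rng = np.random.default_rng(config.seed)
    null: dict[str, list[float]] = {k: [] for k in observed}
    for _ in range(config.n_perm):
        perm = rng.permutation(labels)
        stats = evaluate(perm)
        for k in null:
            null[k].append(float(stats[k]))

    p_values, quantiles, null_arrays = {}, {}, {}
    for k, vals in null.items():
        arr = np.asarray(vals)
        count = int(np.nansum(arr >= observed[k] - 1e-12))
        if config.add_one:
            p_values[k] = (count + 1) / (config.n_perm + 1)
        else:
            p_values[k] = count / config.n_perm
        finite = arr[np.isfinite(arr)]
        quantiles[k] = (
            {name: float(np.quantile(finite, q)) for name, q in _QUANTS.items()}
            if finite.size
            else {name: float("nan") for name in _QUANTS}
        )
        null_arrays[k] = arr
    return PermutationOutcome(observed, p_values, quantiles, config.n_perm, null_arrays)


def _enumerate_assignments(indices: list[int], sizes: list[int]):
    """All ordered assignments of distinct indices into labeled groups."""
    if len(sizes) == 1:
        yield [tuple(indices)]
        return
    for first in combinations(indices, sizes[0]):
        rest = [i for i in indices if i not in set(first)]
        for tail in _enumerate_assignments(rest, sizes[1:]):
            yield [tuple(first)] + tail


def exact_permutation_pvalue(data, statistic, *, key: str | None = None,
                             max_n: int = 12) -> float:
    """Exact permutation p-value by exhaustive enumeration (test oracle).

    Enumerates every assignment of the (distinct) individuals to the
    labeled populations that preserves sample sizes and returns
    P(stat >= observed).  ``statistic`` is either a :class:`LabelStatistic`
    (pick one named statistic via ``key``) or a callable on the dataset
    returning a float.  Refuses more than ``max_n`` individuals.
    """
    labels = list(data.populations)
    n = len(labels)
    if n > max_n:
        raise ValueError(
            f"{n} individuals exceed the enumeration bound {max_n}; "
            "use the Monte-Carlo permutation_test instead"
        )
    if isinstance(statistic, LabelStatistic):
        if key is None:
            raise ValueError("key required for a LabelStatistic bundle")
        stat_fn = lambda lab: float(statistic(np.asarray(lab))[key])
    else:
        stat_fn = lambda lab: float(statistic(data.with_populations(list(lab))))
    pops = list(dict.fromkeys(labels))
    sizes = [labels.count(p) for p in pops]
    observed = stat_fn(labels)
    total = 0
    hits = 0
    for groups in _enumerate_assignments(list(range(n)), sizes):
        lab = [None] * n
        for pop, members in zip(pops, groups):
            for i in members:
                lab[i] = pop
        total += 1
        val = stat_fn(lab)
        if np.isfinite(val) and val >= observed - 1e-12:
            hits += 1
    return hits / total


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_perm: int
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"r": self.r, "p_value": self.p_value, "n_perm": self.n_perm,
              "n_populations": self.n}]
        )


def _as_matrix(m) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(m, pd.DataFrame):
        return m.to_numpy(dtype=float), [str(c) for c in m.columns]
    return np.asarray(m, dtype=float), None


def mantel_test(matrix_a, matrix_b, n_perm: int = 1000,
                seed: int | None = None) -> MantelResult:
    """Mantel permutation test of matrix correlation (two-sided on |r|).

    Both inputs must be symmetric with zero diagonal over the same
    population labels; r is the Pearson correlation over the strictly
    lower triangle and p the fraction of joint row/column permutations of
    the second matrix with |r_perm| >= |r_obs|.
    """
    A, la = _as_matrix(matrix_a)
    B, lb = _as_matrix(matrix_b)
    if A.shape != B.shape or A.shape[0] != A.shape[1]:
        raise ValueError("matrices must be square and of equal dimension")
    if la is not None and lb is not None and la != lb:
        raise ValueError(f"label mismatch: {la} vs {lb}")
    K = A.shape[0]
    if K < 3:
        raise ValueError("need >= 3 populations")
    for M, name in ((A, "matrix_a"), (B, "matrix_b")):
        if not np.allclose(M, M.T, equal_nan=True):
            raise ValueError(f"{name} is not symmetric")
        if not np.allclose(np.diag(M), 0):
            raise ValueError(f"{name} has a non-zero diagonal")
    tril = np.tril_indices(K, -1)
    a = A[tril]

    def corr(bm: np.ndarray) -> float:
        b = bm[tril]
        if np.std(a) == 0 or np.std(b) == 0:
            return float("nan")
        return float(np.corrcoef(a, b)[0, 1])

    r_obs = corr(B)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(K)
        r_perm = corr(B[np.ix_(perm, perm)])
        if np.isfinite(r_perm) and abs(r_perm) >= abs(r_obs) - 1e-12:
            hits += 1
    return MantelResult(r=r_obs, p_value=hits / n_perm, n_perm=n_perm, n=K)


EARTH_RADIUS_KM = 6371.0088


def great_circle_km(lat1, lon1, lat2, lon2) -> float:
    """Haversine great-circle distance in km between decimal-degree points."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def geographic_distance_matrix(poptable) -> pd.DataFrame:
    """Great-circle distance matrix (km) from a PopulationTable."""
    t = poptable.table
    labels = list(t.index)
    K = len(labels)
    out = np.zeros((K, K))
    for i in range(K):
        for j in range(i + 1, K):
            d = great_circle_km(
                t["latitude"].iloc[i], t["longitude"].iloc[i],
                t["latitude"].iloc[j], t["longitude"].iloc[j],
            )
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=labels, columns=labels)


def child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-analysis child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]
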