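# Methods

## Estimators

**Allele frequencies and diversity.** For each locus and population,
allele frequencies are computed from non-missing genotypes (two copies
per diploid individual, one per haploid sequence). A microsatellite
genotype is missing only as a whole pair; individuals missing at a locus
are dropped locus-wise, and a population with no usable individuals at a
locus is excluded from that locus (with a warning) rather than imputed.
Homozygosity J = Σp², effective number of alleles n_e = 1/J (so
n_e·J = 1 holds exactly), observed heterozygosity H_o is the fraction of
heterozygous individuals, and the single-population expected
heterozygosity uses Nei's small-sample factor 2n/(2n−1) (n/(n−1)
haploid).

**H_S and H_T.** Two modes are exposed. `plain` is the frequency
plug-in: H_S = (1/K)Σ_s(1−Σ_i p_si²), H_T = 1−Σ_i p̄_i² with p̄ the
*unweighted* mean frequency across populations (the Nei–Chesser
convention; weighting by sample size would re-introduce sampling design
into a population parameter). `nei_chesser` (default for data analysis)
applies the Nei & Chesser (1983) corrections with the harmonic mean
sample size ñ:

    Ĥ_S = ñ/(ñ−1) [ (1/K)Σ_s(1−Σ_i p_si²) − H̄_o/(2ñ) ]
    Ĥ_T = 1 − Σ_i p̄_i² + Ĥ_S/(ñK) − H̄_o/(2ñK)

Haploid data drop the H̄_o terms. The correction is undefined for any
n_s = 1 and raises. The plug-in mode exists because the algebraic
identities (D from heterozygosities ≡ D from effective allele numbers;
D = 1 for disjoint equal-size samples; H_T ≥ H_S) are exact only without
corrections, which keeps worked examples and the permutation-invariance
argument (pooled frequencies, hence plain H_T, are invariant under label
permutation) transparent.

**D and G_ST.** D = [N/(N−1)](H_T−H_S)/(1−H_S) with N the number of
populations actually usable at the locus; G_ST = (H_T−H_S)/H_T, returned
as a NaN marker (not an exception) when H_T = 0. Negative
estimator-noise values are reported as computed and flagged, never
clamped. The across-locus summary is the unweighted arithmetic mean of
per-locus values (missing loci excluded) — not D recomputed from
averaged heterozygosities; the mean of printed per-locus values in the
motivating study's tables reproduces its printed means only under this
convention. Pairwise-population D fixes N = 2 per pair and averages over
loci.

**Sequences.** An alignment is treated as one haploid locus whose
alleles are distinct full-length sequences; identity is exact string
equality after uppercasing, with `N` and `-` acting as ordinary
characters (conservative: ambiguity splits rather than merges
haplotypes). Sites containing non-ACGT characters are excluded pairwise
only where single sites are compared: in nucleotide diversity π (mean
pairwise differences per comparable site) and in γ_ST, where each site's
plain H_S/H_T is computed over the sequences readable at that site.
γ_ST averages per-site heterozygosities over **all** sites, monomorphic
ones included, so its value reflects diversity per nucleotide of the
whole fragment. Sites readable in fewer than one population contribute
zero (monomorphic-equivalent).

**Null alleles.** r = (H_e − H_o)/(H_e + H_o), floored at 0, NaN when
both are 0; per locus × population, with the across-population mean per
locus as the upper-limit summary. Flooring at zero is a choice (the
source estimator's behaviour for negative estimates is unstated); it
biases per-locus means upward slightly when the true rate is 0.

**Expansion sign test.** The per-locus k statistic is pluggable (its
formula lives in literature the package does not reproduce); the package
ships the aggregation: count negative values (zeros count as
non-negative, conservative toward expansion) and compute the exact
two-sided binomial probability min(1, 2·min(P(X≤k), P(X≥k))),
X ~ Bin(n_loci, ½).

## Permutation machinery

The unit of permutation is the individual (its whole multilocus genotype
moves), because genotypes deviating from Hardy–Weinberg make
allele-level shuffling anti-conservative. Sample sizes are preserved
exactly; D and G_ST are evaluated on identical randomized label vectors,
so their p-values come from the same null stream. p = #(perm ≥ obs)/n_perm
and may be exactly 0; an add-one variant ((count+1)/(n_perm+1)) is
available behind a flag, default off. Statistics are implemented as
"label bundles" that precompute label-invariant structure (compact
allele ids, per-site base indicators) once, making 10³–10⁴ permutations
cheap. An exhaustive-enumeration oracle (≤ 12 individuals) provides
exact p-values for testing the Monte-Carlo path.

The Mantel test correlates the strictly-lower-triangle entries of two
symmetric zero-diagonal matrices and permutes row/column labels jointly;
significance is two-sided on |r|, since both negative and positive
isolation-by-distance correlations are substantive findings. Geographic
distances are haversine great-circle distances (km) from decimal-degree
coordinates; longitude is stored as negative degrees east.

Randomness: one master seed; per-analysis child seeds are derived with
`numpy.random.SeedSequence.spawn`, so adding an analysis never shifts
earlier results, and all derived seeds stay below 2³¹.

## The island-model generator

A forward-time Wright–Fisher finite-island model: K demes of N_deme
diploids (2N allele copies); each new copy draws its source deme (stay
with probability 1−m, otherwise uniform over the other K−1 demes) and a
uniform parent copy, then mutates. Marker models: stepwise (±1 repeat,
equal probability, unbounded), infinite alleles (fresh label per
mutation), and finite sites for sequences (per-site rate, mutation to a
uniformly chosen different base). Unlinked loci are simulated
independently — equivalent to free recombination under random mating.
The mtDNA emulation uses N_deme/2 haploid copies per deme (≥ 2): with an
even sex ratio a maternally inherited haploid locus has one quarter the
copy number of a nuclear diploid locus. Burn-in defaults to
10·N_deme·K generations from a monomorphic start, which reaches
mutation–migration–drift quasi-equilibrium at the desk scales used here
(K ≤ 10, N_deme ≤ 500); a coalescent backend would be faster at larger
scales but was not needed.

The null-allele injector marks each allele copy unamplifiable
independently with probability r — under random mating this is exactly a
null allele class of frequency r, the model the Chakraborty estimator
assumes (algebraically, apparent H_o = H_e(1−r)/(1+r), so the estimator
recovers r exactly in expectation). A (visible, null) heterozygote
becomes an apparent homozygote; (null, null) becomes missing.

`make_paperlike_fixture` emulates one species of a multi-site survey:
6–9 sites of 10–50 individuals, 6 or 8 microsatellite loci whose
per-locus mutation rates span ~3×10⁻⁴–5×10⁻², giving within-population
n_e from ~2 to ~10 and heterozygosities 0.4–0.9, plus a 1305 bp haploid
alignment with π of order 10⁻³–10⁻² and site coordinates inside the
survey's bounding box (lat 38–45.5 N, lon 71–89 W). What the generator
does **not** emulate: allele binning error, genotyping dropout other
than null alleles, linkage disequilibrium between loci, selection,
spatially structured (non-island) migration, or population size change —
so a green simulation-based test establishes correct behaviour under the
island model's assumptions, not robustness to their violation.

## Numerical and design choices

- Default sample-size filter: populations with fewer than 5 individuals
  are removed whole (small samples sap differentiation-test power);
  filtering is idempotent and never touches surviving genotypes.
- Fragment analysis draws window starts uniformly with replacement (the
  replication scheme across windows is a free choice); windows with no
  variation get NaN statistics and count as non-significant for power.
- NJ trees: Saitou–Nei agglomeration with Studier–Keppler branch
  lengths; a negative branch is clamped to 0 with the deficit moved to
  its sister so the joined pair's distance is preserved; ties in the
  Q-matrix resolve to the lexicographically smallest index pair. Output
  is an unrooted newick (trifurcating root for ≥ 3 taxa); additive
  metrics are recovered exactly.
- Human-readable pipeline TSVs round to 2 decimals; `report.json` keeps
  full precision. Reruns with the same seed are byte-identical (the
  output directory is excluded from the report echo for this reason).
- Results writers emit 6 significant digits in both TSV and JSON so the
  two formats carry identical values.

## Known limitations

- The Nei–Chesser Ĥ_T can marginally exceed 1 or undercut Ĥ_S by
  estimator noise; downstream D/G_ST are flagged, not clamped.
- `exact_permutation_pvalue` enumerates ordered assignments of distinct
  individuals, so its cost grows multinomially; it refuses > 12
  individuals by design.
- The forward simulator's stepwise model is unbounded (no allele-size
  ceiling), and the fixture's effective allele numbers top out near 10
  rather than the low 20s seen for the most variable real loci — raising
  per-locus mutation rates further would get there at the cost of
  slower equilibration.
- γ_ST assumes sites are exchangeable (no rate heterogeneity model).
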