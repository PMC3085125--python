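"""Input/output for genotype tables, sequence alignments and result files.

Genotype tables use a wide TSV dialect: columns ``id``, ``population``,
then two columns per locus named ``<locus>.1`` and ``<locus>.2``.  Missing
genotypes are coded by a configurable token (default ``0`` or ``NA``) and
are only ever missing as a whole pair — a half-missing genotype is a
format error.

Alignments are plain FASTA plus a two-column TSV population map
(sequence id, population label).  Longitude in population tables is
stored as negative degrees east (i.e. ``77.23`` W becomes ``-77.23``).
"""

from __future__ import annotations

import copy
import json
import math
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MISSING = 0  # sentinel allele label for a missing genotype slot
SEQ_ALPHABET = frozenset("ACGTN-")


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


@dataclass
class MicrosatDataset:
    """Diploid multilocus genotypes with population labels.

    ``genotypes`` has shape ``(n_individuals, n_loci, 2)``; allele labels
    are positive integers (binned fragment or repeat lengths); a missing
    genotype is the pair ``(0, 0)``.
    """

    ids: list[str]
    populations: list[str]
    loci: list[str]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        n = len(self.ids)
        if len(self.populations) != n:
            raise ValueError("ids and populations differ in length")
        if self.genotypes.shape != (n, len(self.loci), 2):
            raise ValueError(
                f"genotype array shape {self.genotypes.shape} does not match "
                f"{n} individuals x {len(self.loci)} loci x 2"
            )
        if len(set(self.ids)) != n:
            dupes = [k for k, c in Counter(self.ids).items() if c > 1]
            raise FormatError(f"duplicate individual id(s): {dupes}")
        if any(not p for p in self.populations):
            raise ValueError("empty population label")
        if (self.genotypes < 0).any():
            raise ValueError("allele labels must be positive integers (0 = missing)")
        half = (self.genotypes == MISSING).sum(axis=2) == 1
        if half.any():
            i, j = np.argwhere(half)[0]
            raise FormatError(
                f"half-missing genotype for individual {self.ids[i]!r} "
                f"at locus {self.loci[j]!r}"
            )

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    def population_sizes(self) -> dict[str, int]:
        return dict(Counter(self.populations))

    def subset(self, indices: Sequence[int]) -> "MicrosatDataset":
        idx = list(indices)
        return MicrosatDataset(
            ids=[self.ids[i] for i in idx],
            populations=[self.populations[i] for i in idx],
            loci=list(self.loci),
            genotypes=self.genotypes[idx].copy(),
        )

    def restrict_to_populations(self, keep: Iterable[str]) -> "MicrosatDataset":
        keep = set(keep)
        return self.subset([i for i, p in enumerate(self.populations) if p in keep])

    def with_populations(self, labels: Sequence[str]) -> "MicrosatDataset":
        """Copy with relabelled populations (genotypes shared, not copied)."""
        out = copy.copy(self)
        out.populations = list(labels)
        return out


@dataclass
class SeqAlignment:
    """Equal-length haploid sequences with population labels."""

    ids: list[str]
    populations: list[str]
    seqs: list[str]
    length: int = field(default=0)

    def __post_init__(self) -> None:
        if self.seqs and not self.length:
            self.length = len(self.seqs[0])
        self.validate()

    def validate(self) -> None:
        n = len(self.ids)
        if len(self.populations) != n or len(self.seqs) != n:
            raise ValueError("ids, populations and seqs differ in length")
        if self.length < 1:
            raise ValueError("alignment length must be >= 1")
        for sid, s in zip(self.ids, self.seqs):
            if len(s) != self.length:
                raise FormatError(
                    f"sequence {sid!r} has length {len(s)}, expected {self.length}"
                )
            bad = next((i for i, c in enumerate(s) if c not in SEQ_ALPHABET), None)
            if bad is not None:
                raise FormatError(
                    f"illegal character {s[bad]!r} at position {bad} in {sid!r}"
                )
        if any(not p for p in self.populations):
            raise ValueError("empty population label")
        if len(set(self.ids)) != n:
            raise FormatError("duplicate sequence ids")

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    def population_sizes(self) -> dict[str, int]:
        return dict(Counter(self.populations))

    def subset(self, indices: Sequence[int]) -> "SeqAlignment":
        idx = list(indices)
        return SeqAlignment(
            ids=[self.ids[i] for i in idx],
            populations=[self.populations[i] for i in idx],
            seqs=[self.seqs[i] for i in idx],
            length=self.length,
        )

    def restrict_to_populations(self, keep: Iterable[str]) -> "SeqAlignment":
        keep = set(keep)
        return self.subset([i for i, p in enumerate(self.populations) if p in keep])

    def window(self, start: int, length: int) -> "SeqAlignment":
        """Contiguous sub-alignment ``[start, start + length)``."""
        if start < 0 or start + length > self.length:
            raise ValueError("window outside alignment")
        return SeqAlignment(
            ids=list(self.ids),
            populations=list(self.populations),
            seqs=[s[start : start + length] for s in self.seqs],
            length=length,
        )

    def with_populations(self, labels: Sequence[str]) -> "SeqAlignment":
        out = copy.copy(self)
        out.populations = list(labels)
        return out


@dataclass
class PopulationTable:
    """Per-population metadata: coordinates and sample sizes.

    ``table`` is indexed by population label with at least columns
    ``latitude`` (decimal degrees north) and ``longitude`` (negative
    decimal degrees east, so a site reported as 77.23 W is -77.23).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("duplicate population labels")
        for col in ("latitude", "longitude"):
            if col not in self.table.columns:
                raise ValueError(f"population table lacks column {col!r}")
            if not np.isfinite(self.table[col].to_numpy(dtype=float)).all():
                raise ValueError(f"non-finite values in {col!r}")

    @property
    def labels(self) -> list[str]:
        return list(self.table.index)


# ---------------------------------------------------------------------------
# genotype tables


def read_genotype_table(
    path: str | Path,
    *,
    missing_tokens: Sequence[str] = ("0", "NA"),
    sep: str = "\t",
) -> MicrosatDataset:
    """Read the wide genotype TSV dialect (two columns per locus)."""
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if len(cols) < 4 or cols[0] != "id" or cols[1] != "population":
        raise FormatError("expected columns: id, population, <locus>.1, <locus>.2, ...")
    allele_cols = cols[2:]
    if len(allele_cols) % 2 != 0:
        raise FormatError(f"odd number of allele columns ({len(allele_cols)})")
    loci: list[str] = []
    for a, b in zip(allele_cols[::2], allele_cols[1::2]):
        if not (a.endswith(".1") and b.endswith(".2") and a[:-2] == b[:-2]):
            raise FormatError(f"allele columns {a!r}/{b!r} are not a <locus>.1/.2 pair")
        loci.append(a[:-2])

    missing = set(missing_tokens)
    n = len(df)
    geno = np.zeros((n, len(loci), 2), dtype=np.int64)
    for j, locus in enumerate(loci):
        for k in range(2):
            col = f"{locus}.{k + 1}"
            for i, tok in enumerate(df[col]):
                tok = tok.strip()
                if tok in missing or tok == "":
                    geno[i, j, k] = MISSING
                    continue
                try:
                    val = int(tok)
                except ValueError as exc:
                    raise FormatError(
                        f"non-integer allele {tok!r} in row {i + 1}, column {col!r}"
                    ) from exc
                if val <= 0:
                    raise FormatError(
                        f"non-positive allele {val} in row {i + 1}, column {col!r}"
                    )
                geno[i, j, k] = val
    return MicrosatDataset(
        ids=list(df["id"]),
        populations=list(df["population"]),
        loci=loci,
        genotypes=geno,
    )


def write_genotype_table(
    dataset: MicrosatDataset, path: str | Path, *, missing_token: str = "0"
) -> None:
    cols: dict[str, list] = {
        "id": dataset.ids,
        "population": dataset.populations,
    }
    for j, locus in enumerate(dataset.loci):
        for k in range(2):
            vals = dataset.genotypes[:, j, k]
            cols[f"{locus}.{k + 1}"] = [
                missing_token if v == MISSING else str(v) for v in vals
            ]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# alignments


def read_alignment(fasta_path: str | Path, popmap_path: str | Path) -> SeqAlignment:
    """Read a FASTA alignment and attach population labels from a popmap TSV."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise FormatError(f"no sequences in {fasta_path}")
    popmap = pd.read_csv(
        popmap_path, sep="\t", header=None, names=["id", "population"], dtype=str
    )
    mapping = dict(zip(popmap["id"], popmap["population"]))
    ids = [r.id for r in records]
    unmapped = [i for i in ids if i not in mapping]
    if unmapped:
        raise FormatError(f"ids missing from popmap: {unmapped}")
    seqs = [str(r.seq).upper() for r in records]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise FormatError(f"unequal sequence lengths: {sorted(lengths)}")
    return SeqAlignment(
        ids=ids,
        populations=[mapping[i] for i in ids],
        seqs=seqs,
        length=lengths.pop(),
    )


def write_alignment(
    alignment: SeqAlignment, fasta_path: str | Path, popmap_path: str | Path
) -> None:
    records = [
        SeqRecord(Seq(s), id=sid, description="")
        for sid, s in zip(alignment.ids, alignment.seqs)
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(popmap_path, "w") as fh:
        for sid, pop in zip(alignment.ids, alignment.populations):
            fh.write(f"{sid}\t{pop}\n")


# ---------------------------------------------------------------------------
# population tables


def read_population_table(path: str | Path) -> PopulationTable:
    df = pd.read_csv(path, sep="\t", dtype={"population": str})
    if "population" not in df.columns:
        raise FormatError("population table needs a 'population' column")
    return PopulationTable(df.set_index("population"))


def write_population_table(table: PopulationTable, path: str | Path) -> None:
    table.table.to_csv(path, sep="\t", index_label="population")


# ---------------------------------------------------------------------------
# sample-size filter


def filter_small_samples(dataset, min_n: int = 5):
    """Drop whole populations sampled with fewer than ``min_n`` individuals.

    Small samples sap the power of differentiation tests, so populations
    below the threshold are removed entirely.  Returns ``(filtered,
    removed_labels)``; the input is left unmodified and surviving
    individuals keep their genotypes untouched.
    """
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    sizes = dataset.population_sizes()
    removed = sorted(p for p, c in sizes.items() if c < min_n)
    kept = [p for p in sizes if p not in removed]
    if not kept:
        raise ValueError("no populations survive filter")
    return dataset.restrict_to_populations(kept), removed


# ---------------------------------------------------------------------------
# result files


def _format_sig(x, sig: int) -> object:
    if isinstance(x, float):
        if math.isnan(x):
            return float("nan")
        return float(f"{x:.{sig}g}")
    return x


def write_results(result, path: str | Path, format: str = "tsv", *, sig: int = 6) -> None:
    """Write any result object exposing ``to_frame()`` as TSV or JSON.

    Column order is the frame's order (deterministic); floats are written
    with ``sig`` significant digits in both formats so that a TSV and a
    JSON export of the same result carry identical values.
    """
    frame = result.to_frame() if hasattr(result, "to_frame") else pd.DataFrame(result)
    format = format.lower()
    if format == "tsv":
        frame.to_csv(path, sep="\t", index=False, float_format=f"%.{sig}g")
    elif format == "json":
        records = [
            {k: _format_sig(v, sig) for k, v in row.items()}
            for row in frame.to_dict(orient="records")
        ]
        with open(path, "w") as fh:
            json.dump({"columns": list(frame.columns), "data": records}, fh, indent=1,
                      allow_nan=True)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {format!r} (use 'tsv' or 'json')")
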