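"""Report assembly: neighbour-joining trees from pairwise D, and the
end-to-end pipeline that turns a genotype table plus an alignment into
the standard set of diversity/differentiation tables.

There is deliberately no command-line layer: `run_pipeline` is the
orchestration entry point and the example scripts show typical calls.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .differentiation import (
    GammaSTStatistic,
    MultilocusDGST,
    SequenceDGST,
    differentiation_table,
    fragment_length_analysis,
    gamma_st,
    pairwise_d,
    pairwise_sequence_distance,
    sequence_differentiation,
)
from .diversity import diversity_summary
from .io import (
    MicrosatDataset,
    PopulationTable,
    SeqAlignment,
    filter_small_samples,
    read_alignment,
    read_genotype_table,
    read_population_table,
)
from .resampling import (
    PermutationConfig,
    child_seeds,
    geographic_distance_matrix,
    mantel_test,
    permutation_test,
)

log = logging.getLogger("popdiff")


# ---------------------------------------------------------------------------
# neighbour joining


def _fmt(x: float) -> str:
    return f"{x:.10g}"


def nj_tree(matrix) -> str:
    """Neighbour-joining tree from a distance matrix, as a newick string.

    Standard Saitou-Nei agglomeration with Studier-Keppler branch
    lengths; a negative branch length is clamped to 0 and its deficit
    moved to the sister branch, so the pair's summed length (their
    distance) is preserved.  The tree is unrooted (final node is a
    trifurcation for >= 3 taxa).
    """
    if isinstance(matrix, pd.DataFrame):
        labels = [str(c) for c in matrix.columns]
        D = matrix.to_numpy(dtype=float)
    else:
        D = np.asarray(matrix, dtype=float)
        labels = [f"t{i + 1}" for i in range(D.shape[0])]
    n = D.shape[0]
    if D.shape != (n, n) or n < 2:
        raise ValueError("need a square matrix over >= 2 taxa")
    off = ~np.eye(n, dtype=bool)
    if np.isnan(D[off]).any():
        raise ValueError("matrix has missing cells; imputation is unsupported")
    if not np.allclose(D, D.T):
        raise ValueError("matrix is not symmetric")

    nodes = list(labels)
    D = D.copy()
    if n == 2:
        h = D[0, 1] / 2.0
        return f"({nodes[0]}:{_fmt(h)},{nodes[1]}:{_fmt(h)});"

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        elif lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(nodes) > 3:
        nn = len(nodes)
        r = D.sum(axis=1)
        Q = (nn - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)
        if i > j:
            i, j = j, i
        li = D[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (nn - 2))
        lj = D[i, j] - li
        li, lj = clamp(li, lj)
        new = f"({nodes[i]}:{_fmt(li)},{nodes[j]}:{_fmt(lj)})"
        du = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(nn) if k not in (i, j)]
        D2 = np.zeros((nn - 1, nn - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = du[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [new]

    a, b, c = 0, 1, 2
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    return (
        f"({nodes[0]}:{_fmt(la)},{nodes[1]}:{_fmt(lb)},{nodes[2]}:{_fmt(lc)});"
    )


# ---------------------------------------------------------------------------
# pipeline


class PipelineStageError(RuntimeError):
    """Raised when a pipeline stage fails; carries a machine-readable record."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage
        self.record = {"stage": stage, "error": message}


@dataclass
class AnalysisConfig:
    """Configuration of `run_pipeline`.

    Inputs may be paths (read via the io module) or in-memory objects.
    ``seed`` is mandatory: every stochastic stage draws a deterministic
    child seed from it, so adding a stage never shifts earlier results.
    """

    outdir: str | Path
    seed: int
    genotypes: str | Path | MicrosatDataset | None = None
    fasta: str | Path | None = None
    popmap: str | Path | None = None
    alignment: SeqAlignment | None = None
    sites: str | Path | PopulationTable | None = None
    mode: str = "nei_chesser"
    min_n: int = 5
    n_perm: int = 1000
    fragment_lengths: tuple[int, ...] = (100, 300, 500, 700, 900, 1100)
    n_frag: int = 20
    alpha: float = 0.05
    report_decimals: int = 2

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for p in (self.genotypes, self.fasta, self.popmap, self.sites):
            if isinstance(p, (str, Path)) and not Path(p).exists():
                raise FileNotFoundError(p)


def _write_table(frame: pd.DataFrame, path: Path, decimals: int) -> None:
    out = frame.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].round(decimals)
    out.to_csv(path, sep="\t", index=False)


def run_pipeline(config: AnalysisConfig) -> dict:
    """Filter -> diversity -> differentiation (+ permutation p-values) ->
    gamma_ST -> pairwise D + NJ -> Mantel -> fragment analysis.

    Writes rounded human-readable TSVs, newick files and a full-precision
    JSON report plus a manifest into ``config.outdir``; returns the
    report as a dict.  Any stage failure raises
    :class:`PipelineStageError` naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dec = config.report_decimals
    seeds = child_seeds(config.seed, 8)
    # outdir is deliberately left out of the echo so that two runs with
    # the same seed produce byte-identical reports in different directories
    report: dict = {"config": {
        k: str(v) if isinstance(v, Path) else v
        for k, v in asdict(config).items()
        if k != "outdir"
        and isinstance(v, (str, int, float, tuple, list, Path, type(None)))
    }}
    manifest: list[dict] = []

    def stage(name):
        def deco(fn):
            def run(*a, **kw):
                log.info("stage %s", name)
                try:
                    return fn(*a, **kw)
                except PipelineStageError:
                    raise
                except Exception as exc:
                    raise PipelineStageError(name, str(exc)) from exc
            return run
        return deco

    @stage("load")
    def load():
        micro = config.genotypes
        if isinstance(micro, (str, Path)):
            micro = read_genotype_table(micro)
        aln = config.alignment
        if aln is None and config.fasta is not None:
            aln = read_alignment(config.fasta, config.popmap)
        sites = config.sites
        if isinstance(sites, (str, Path)):
            sites = read_population_table(sites)
        if micro is None and aln is None:
            raise ValueError("no inputs: need genotypes and/or an alignment")
        return micro, aln, sites

    micro, aln, sites = load()

    @stage("filter")
    def filt():
        out = {}
        if micro is not None:
            kept, removed = filter_small_samples(micro, config.min_n)
            log.info("microsatellites: kept %d populations, removed %s",
                     len(set(kept.populations)), removed or "none")
            out["micro"] = kept
            out["micro_removed"] = removed
        if aln is not None:
            kept, removed = filter_small_samples(aln, config.min_n)
            log.info("sequences: kept %d populations, removed %s",
                     len(set(kept.populations)), removed or "none")
            out["aln"] = kept
            out["aln_removed"] = removed
        return out

    filtered = filt()
    fmicro = filtered.get("micro")
    faln = filtered.get("aln")
    report["filter"] = {
        "min_n": config.min_n,
        "removed_microsat": filtered.get("micro_removed", []),
        "removed_sequences": filtered.get("aln_removed", []),
    }

    @stage("diversity")
    def diversity():
        summary = diversity_summary(dataset=fmicro, alignment=faln)
        path = outdir / "diversity.tsv"
        _write_table(summary.table, path, dec)
        manifest.append({"stage": "diversity", "file": path.name,
                         "columns": list(summary.table.columns)})
        report["diversity"] = summary.table.to_dict(orient="records")
        if summary.pi is not None:
            ppath = outdir / "nucleotide_diversity.tsv"
            _write_table(summary.pi, ppath, max(dec, 3))
            manifest.append({"stage": "diversity", "file": ppath.name,
                             "columns": list(summary.pi.columns)})
            report["pi"] = summary.pi.to_dict(orient="records")
        return summary

    diversity()

    @stage("differentiation")
    def diff():
        out = {}
        if fmicro is not None:
            table = differentiation_table(fmicro, config.mode)
            locus_seeds = child_seeds(seeds[0], len(table.rows))
            for row, s in zip(table.rows, locus_seeds):
                if not np.isfinite(row.D):
                    continue
                bundle = MultilocusDGST(fmicro, config.mode, loci=[row.locus])
                cfg = PermutationConfig(n_perm=config.n_perm, seed=s,
                                        alpha=config.alpha)
                row.p_value = permutation_test(fmicro, bundle, cfg).p_D
            frame = table.to_frame()
            path = outdir / "differentiation_microsat.tsv"
            _write_table(frame.drop(columns="note"), path, dec)
            manifest.append({"stage": "differentiation", "file": path.name,
                             "columns": list(frame.columns)})
            report["differentiation_microsat"] = frame.to_dict(orient="records")
            out["micro"] = table
        if faln is not None:
            row = sequence_differentiation(faln, config.mode)
            if np.isfinite(row.D) and np.isfinite(row.G_ST):
                bundle = SequenceDGST(faln, config.mode)
                cfg = PermutationConfig(n_perm=config.n_perm, seed=seeds[1],
                                        alpha=config.alpha)
                row.p_value = permutation_test(faln, bundle, cfg).p_D
            frame = pd.DataFrame([row.as_dict()])
            path = outdir / "differentiation_sequence.tsv"
            _write_table(frame.drop(columns="note"), path, dec)
            manifest.append({"stage": "differentiation", "file": path.name,
                             "columns": list(frame.columns)})
            report["differentiation_sequence"] = frame.to_dict(orient="records")
            out["seq"] = row
        return out

    diff()

    if faln is not None:
        @stage("gamma_st")
        def gamma():
            res = gamma_st(faln)
            if np.isfinite(res.gamma_ST):
                cfg = PermutationConfig(n_perm=config.n_perm, seed=seeds[2],
                                        alpha=config.alpha)
                res.p_value = permutation_test(
                    faln, GammaSTStatistic(faln), cfg
                ).p_values["gamma_ST"]
            path = outdir / "gamma_st.tsv"
            _write_table(res.to_frame(), path, dec)
            manifest.append({"stage": "gamma_st", "file": path.name,
                             "columns": list(res.to_frame().columns)})
            report["gamma_st"] = res.to_frame().to_dict(orient="records")[0]
            return res

        gamma()

    pw = None
    if fmicro is not None:
        @stage("pairwise_nj")
        def pairwise():
            res = pairwise_d(fmicro, config.mode)
            path = outdir / "pairwise_d.tsv"
            res.matrix.round(dec).to_csv(path, sep="\t", index_label="population")
            manifest.append({"stage": "pairwise_nj", "file": path.name,
                             "columns": list(res.matrix.columns)})
            report["pairwise_d"] = res.matrix.to_dict()
            if not res.flagged_pairs and len(res.matrix) >= 2:
                newick = nj_tree(res.matrix)
                tpath = outdir / "nj_pairwise_d.nwk"
                tpath.write_text(newick + "\n")
                manifest.append({"stage": "pairwise_nj", "file": tpath.name,
                                 "columns": None})
                report["nj_newick"] = newick
            return res

        pw = pairwise()

    if sites is not None:
        @stage("mantel")
        def mantel():
            geo = geographic_distance_matrix(sites)
            rows = []
            if pw is not None and len(pw.matrix) >= 3 and not pw.flagged_pairs:
                labels = list(pw.matrix.columns)
                g = geo.loc[labels, labels]
                res = mantel_test(g, pw.matrix, n_perm=config.n_perm,
                                  seed=seeds[3])
                rows.append({"data": "microsatellite_pairwise_D",
                             "r": res.r, "p_value": res.p_value, "n": res.n})
            if faln is not None:
                seq_d = pairwise_sequence_distance(faln)
                if len(seq_d) >= 3 and not seq_d.isna().any().any():
                    labels = [p for p in seq_d.columns if p in geo.index]
                    if len(labels) >= 3:
                        res = mantel_test(geo.loc[labels, labels],
                                          seq_d.loc[labels, labels],
                                          n_perm=config.n_perm, seed=seeds[4])
                        rows.append({"data": "sequence_mean_differences",
                                     "r": res.r, "p_value": res.p_value,
                                     "n": res.n})
            if rows:
                frame = pd.DataFrame(rows)
                path = outdir / "mantel.tsv"
                _write_table(frame, path, max(dec, 3))
                manifest.append({"stage": "mantel", "file": path.name,
                                 "columns": list(frame.columns)})
                report["mantel"] = rows

        mantel()

    if faln is not None and max(config.fragment_lengths) <= faln.length:
        @stage("fragments")
        def fragments():
            res = fragment_length_analysis(
                faln, lengths=config.fragment_lengths, n_frag=config.n_frag,
                n_perm=config.n_perm, alpha=config.alpha, seed=seeds[5],
                mode=config.mode,
            )
            spath = outdir / "fragments_summary.tsv"
            rpath = outdir / "fragments_records.tsv"
            _write_table(res.summary, spath, max(dec, 3))
            _write_table(res.records, rpath, max(dec, 3))
            manifest.append({"stage": "fragments", "file": spath.name,
                             "columns": list(res.summary.columns)})
            manifest.append({"stage": "fragments", "file": rpath.name,
                             "columns": list(res.records.columns)})
            report["fragments"] = res.summary.to_dict(orient="records")
            return res

        fragments()

    report["manifest"] = manifest
    report["versions"] = {"popdiff": __version__, "numpy": np.__version__,
                          "pandas": pd.__version__}
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str, allow_nan=True)
        fh.write("\n")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump({"seed": config.seed, "stages": manifest,
                   "versions": report["versions"]}, fh, indent=1)
        fh.write("\n")
    return report
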