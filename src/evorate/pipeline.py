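"""End-to-end orchestration: one config in, a directory of artifacts out.

Stages: read (or simulate) per-locus alignments -> ordered concatenation ->
pairwise distance matrix -> time-normalized pair table, clade summaries and
ANOVA -> NJ tree with bootstrap support -> heatmaps and violin plots ->
manifest.  All randomness flows through the single configured seed, which
the manifest records together with the full configuration, so every numeric
artifact on disk is re-derivable from the manifest alone.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import __version__, ratecomp, seqio, treebuild
from .distance import DistanceMatrix, clip_for_display, distance_matrix
from .errors import ConfigError
from .motifscan import DEFAULT_CTERM_WINDOW, scan_alignment_members
from .ratecomp import build_pair_table, interclade_anova, interclade_distribution
from .seqio import CladeMap, TimeTree

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated run configuration (one YAML file)."""

    loci_fastas: dict[str, str]  # locus name -> FASTA path
    timetree: str
    clademap: str
    order: list[str] = field(default_factory=list)
    missing_policy: str = "drop_taxon"
    model: str = "p_distance"
    deletion: str = "pairwise"
    gamma_shape: float | None = None
    display_cap: float = 0.6
    bootstrap_replicates: int = 500
    seed: int = 0
    anova_groups: list[list[str]] = field(default_factory=list)
    anova_which: str = "normalized"
    cterm_window: int = DEFAULT_CTERM_WINDOW
    outdir: str = "evorate_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            cfg = cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"bad run config: {exc}") from exc
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.bootstrap_replicates < 1:
            raise ConfigError("bootstrap_replicates must be >= 1")
        for path in [self.timetree, self.clademap, *self.loci_fastas.values()]:
            if not Path(path).exists():
                raise ConfigError(f"configured path does not exist: {path}")

    def to_dict(self) -> dict:
        return {
            "loci_fastas": dict(self.loci_fastas),
            "timetree": self.timetree,
            "clademap": self.clademap,
            "order": list(self.order),
            "missing_policy": self.missing_policy,
            "model": self.model,
            "deletion": self.deletion,
            "gamma_shape": self.gamma_shape,
            "display_cap": self.display_cap,
            "bootstrap_replicates": self.bootstrap_replicates,
            "seed": self.seed,
            "anova_groups": [list(g) for g in self.anova_groups],
            "anova_which": self.anova_which,
            "cterm_window": self.cterm_window,
            "outdir": self.outdir,
        }


def render_heatmap(matrix: DistanceMatrix, path, cap: float | None = None) -> None:
    """Heatmap of a distance matrix; values above ``cap`` share the top colour."""
    if matrix.n_taxa == 0:
        raise ValueError("empty distance matrix")
    shown = clip_for_display(matrix, cap) if cap else matrix
    fig, ax = plt.subplots(
        figsize=(max(4, 0.4 * matrix.n_taxa), max(3.5, 0.4 * matrix.n_taxa))
    )
    vmax = cap if cap else None
    im = ax.imshow(shown.values, cmap="turbo", vmin=0.0, vmax=vmax)
    ax.set_xticks(range(matrix.n_taxa), matrix.taxa, rotation=90, fontsize=6)
    ax.set_yticks(range(matrix.n_taxa), matrix.taxa, fontsize=6)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def render_violin(
    distributions: dict[str, np.ndarray], path, ylabel: str = "pairwise distance"
) -> None:
    """Violin plot per group; solid line = median, dotted = quartiles."""
    if not distributions:
        raise ValueError("no distributions to plot")
    labels = list(distributions)
    data = [np.asarray(distributions[k], dtype=float) for k in labels]
    fig, ax = plt.subplots(figsize=(max(4, 1.2 * len(labels)), 4))
    parts = ax.violinplot(data, showextrema=False)
    for body in parts["bodies"]:
        body.set_alpha(0.6)
    for idx, values in enumerate(data, start=1):
        q1, med, q3 = np.percentile(values, [25, 50, 75])
        ax.hlines(med, idx - 0.2, idx + 0.2, linestyles="solid", color="black")
        ax.hlines([q1, q3], idx - 0.15, idx + 0.15, linestyles="dotted", color="black")
    ax.set_xticks(range(1, len(labels) + 1), labels, rotation=45, ha="right")
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _stage(name: str, started: float) -> None:
    log.info("stage %-12s done in %.2f s", name, time.perf_counter() - started)


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and write all artifacts into the output directory.

    Returns the run directory.  Any stage error aborts with the stage name
    in the log and the underlying exception naming the offending taxa/loci.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    loci = [
        seqio.read_fasta(path, locus=name)
        for name, path in config.loci_fastas.items()
    ]
    tree: TimeTree = seqio.read_timetree(config.timetree)
    clades: CladeMap = seqio.read_clademap(config.clademap)
    order = config.order or [a.locus for a in loci]
    concat = seqio.concatenate(loci, order, config.missing_policy)
    log.info(
        "concatenated %d loci, %d taxa, %d columns",
        len(order),
        len(concat.taxa),
        concat.length,
    )
    seqio.write_fasta(concat, outdir / "concatenated.fasta")
    _stage("read+concat", t0)

    t0 = time.perf_counter()
    dm = distance_matrix(concat, config.model, config.deletion, config.gamma_shape)
    dm.write_tsv(outdir / "distances_raw.tsv")
    _stage("distances", t0)

    t0 = time.perf_counter()
    table = build_pair_table(dm, tree, clades)
    seqio.write_tsv(table, outdir / "pair_table.tsv")

    clade_labels = clades.clades
    summary_rows = []
    raw_dists: dict[str, np.ndarray] = {}
    norm_dists: dict[str, np.ndarray] = {}
    for ca, cb in itertools.combinations_with_replacement(clade_labels, 2):
        label = ratecomp.clade_pair_label(ca, cb)
        if not (table["clade_pair"] == label).any():
            continue
        for which, store in (("raw", raw_dists), ("normalized", norm_dists)):
            values, summ = interclade_distribution(table, ca, cb, which)
            store[label] = values
            summary_rows.append(
                {
                    "clade_pair": label,
                    "which": which,
                    "n_pairs": summ.n,
                    "mean": summ.mean,
                    "sd": summ.sd,
                    "median": summ.median,
                    "q1": summ.q1,
                    "q3": summ.q3,
                }
            )
    seqio.write_tsv(pd.DataFrame(summary_rows), outdir / "clade_summary.tsv")

    if config.anova_groups:
        pairs = [tuple(g) for g in config.anova_groups]
    else:
        # default: every between-clade pair group present in the table
        pairs = [
            (ca, cb)
            for ca, cb in itertools.combinations(clade_labels, 2)
            if (table["clade_pair"] == ratecomp.clade_pair_label(ca, cb)).any()
        ]
    anova = interclade_anova(table, pairs, config.anova_which)
    report = anova.to_dataframe()
    seqio.write_tsv(report, outdir / "anova_tukey.tsv")
    with open(outdir / "anova.txt", "w") as fh:
        fh.write(
            f"one-way ANOVA on {config.anova_which} distances: "
            f"F({anova.df_between},{anova.df_within}) = {anova.F:.6g}, "
            f"p = {anova.p_value:.6g}\n"
        )
    _stage("rates+anova", t0)

    t0 = time.perf_counter()
    nj = treebuild.bootstrap_support(
        concat,
        model=config.model,
        deletion=config.deletion,
        b_replicates=config.bootstrap_replicates,
        seed=config.seed,
    )
    with open(outdir / "nj_tree.nwk", "w") as fh:
        fh.write(nj.newick(with_support=True) + "\n")
    _stage("nj+bootstrap", t0)

    t0 = time.perf_counter()
    render_heatmap(dm, outdir / "heatmap_raw.png", cap=config.display_cap)
    norm_values = dm.values.copy()
    for i, a in enumerate(dm.taxa):
        for j in range(i + 1, len(dm.taxa)):
            t = ratecomp.divergence_time(tree, a, dm.taxa[j])
            norm_values[i, j] = norm_values[j, i] = (
                dm.values[i, j] / (t / 100.0) if t > 0 else np.nan
            )
    norm_dm = DistanceMatrix(
        taxa=list(dm.taxa),
        values=norm_values,
        model=dm.model,
        deletion=dm.deletion,
        sites_used=dm.sites_used.copy(),
    )
    render_heatmap(norm_dm, outdir / "heatmap_normalized.png", cap=config.display_cap)
    render_violin(raw_dists, outdir / "violin_raw.png", "raw pairwise distance")
    render_violin(
        norm_dists,
        outdir / "violin_normalized.png",
        "normalized pairwise distance (100 MY = 1)",
    )
    _stage("plots", t0)

    t0 = time.perf_counter()
    motif_table = scan_alignment_members(concat.rows, config.cterm_window)
    seqio.write_tsv(motif_table, outdir / "iq_motifs.tsv")
    _stage("motifs", t0)

    manifest = {
        "evorate_version": __version__,
        "config": config.to_dict(),
        "n_taxa": len(concat.taxa),
        "n_columns": concat.length,
        "order_hash": hashlib.sha256("|".join(order).encode()).hexdigest()[:12],
        "partitions": [[name, start, end] for name, start, end in concat.partitions],
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return outdir
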