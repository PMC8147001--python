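"""Divergence-time normalization of pairwise distances and clade comparison.

The central statistic: a raw pairwise distance D between two species is
divided by their divergence time T (age of their most recent common
ancestor, MYA) scaled so that 100 MY = 1, i.e. D_norm = D / (T/100) —
a per-100-MY rate proxy.  Lineages that diverged long ago but accumulated
few substitutions (slowly evolving clades) have large raw but small
normalized distances; recently diverged, fast-evolving clades show the
opposite, so ranking species by raw vs normalized distance can reverse.

Clade-pair distributions of either quantity are summarised
(mean/SD/median/quartiles) and compared by classical one-way ANOVA with the
Tukey(-Kramer) HSD post hoc test.  Note pairwise distances sharing a taxon
are not independent, so the ANOVA p-values are approximate; a taxon-level
jackknife is provided as a sensitivity check.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .distance import DistanceMatrix
from .errors import (
    CoverageError,
    DegreesOfFreedomError,
    EmptyGroupError,
    NormalizationError,
)
from .seqio import CladeMap, TimeTree

log = logging.getLogger(__name__)

NORMALIZATION_SCALE = 100.0  # MY corresponding to D_norm == D_raw


def divergence_time(tree: TimeTree, a: str, b: str) -> float:
    """Divergence time of two species = age of their MRCA, in MYA."""
    return tree.mrca_age(a, b)


def normalize_distance(d_raw: float, t_mya: float) -> float:
    """Normalize a raw distance by divergence time (100 MYA = 1)."""
    if t_mya <= 0:
        raise NormalizationError(f"divergence time must be positive, got {t_mya}")
    return d_raw / (t_mya / NORMALIZATION_SCALE)


def clade_pair_label(clade_a: str, clade_b: str) -> str:
    """Canonical unordered label for a clade pair."""
    return "|".join(sorted((clade_a, clade_b)))


def build_pair_table(
    matrix: DistanceMatrix, tree: TimeTree, clades: CladeMap
) -> pd.DataFrame:
    """One record per unordered species pair: raw distance, divergence time,
    normalized distance and clade-pair label.

    Pairs with a missing distance are excluded with a logged count.  Taxa in
    the matrix missing from the tree or the clade map raise
    :class:`CoverageError` naming the offenders.
    """
    leaf_set = set(tree.leaves)
    missing_tree = [t for t in matrix.taxa if t not in leaf_set]
    missing_clade = [t for t in matrix.taxa if t not in clades]
    if missing_tree or missing_clade:
        raise CoverageError(
            f"taxa missing from tree: {missing_tree}; from clade map: {missing_clade}"
        )
    records = []
    n_dropped = 0
    for i, j in itertools.combinations(range(matrix.n_taxa), 2):
        d_raw = float(matrix.values[i, j])
        if math.isnan(d_raw):
            n_dropped += 1
            continue
        a, b = matrix.taxa[i], matrix.taxa[j]
        t = divergence_time(tree, a, b)
        ca, cb = clades.clade_of(a), clades.clade_of(b)
        records.append(
            {
                "taxon_a": a,
                "taxon_b": b,
                "clade_a": ca,
                "clade_b": cb,
                "clade_pair": clade_pair_label(ca, cb),
                "d_raw": d_raw,
                "t_mya": t,
                "d_norm": normalize_distance(d_raw, t),
            }
        )
    if n_dropped:
        log.warning("%d pair(s) excluded from the table (missing distance)", n_dropped)
    return pd.DataFrame.from_records(
        records,
        columns=[
            "taxon_a",
            "taxon_b",
            "clade_a",
            "clade_b",
            "clade_pair",
            "d_raw",
            "t_mya",
            "d_norm",
        ],
    )


@dataclass
class GroupSummary:
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    n: int


def interclade_distribution(
    table: pd.DataFrame, clade_a: str, clade_b: str, which: str = "raw"
) -> tuple[np.ndarray, GroupSummary]:
    """Pairwise values for one clade pair plus a violin-style summary.

    ``which`` selects raw or normalized distances.  ``clade_a == clade_b``
    selects within-clade pairs (both members in that clade).  The summary's
    median/quartiles follow the violin-annotation convention (solid median,
    dotted quartile lines); SD uses the n-1 (sample) denominator.
    """
    col = {"raw": "d_raw", "normalized": "d_norm"}.get(which)
    if col is None:
        raise ValueError(f"which must be 'raw' or 'normalized', got {which!r}")
    label = clade_pair_label(clade_a, clade_b)
    values = table.loc[table["clade_pair"] == label, col].to_numpy(dtype=float)
    if values.size == 0:
        raise EmptyGroupError(f"no pairs with clade-pair label {label!r}")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return values, GroupSummary(
        mean=float(np.mean(values)),
        sd=sd,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        n=int(values.size),
    )


def significance_stars(p: float) -> str:
    """Convention: * p<0.05, ** p<0.01, *** p<0.001, else 'ns'."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class TukeyComparison:
    group_a: str
    group_b: str
    mean_diff: float
    p_adj: float
    stars: str


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p_value: float
    tukey: list[TukeyComparison]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "group_a": c.group_a,
                    "group_b": c.group_b,
                    "mean_diff": c.mean_diff,
                    "p_adj": c.p_adj,
                    "stars": c.stars,
                }
                for c in self.tukey
            ]
        )


def anova_tukey(
    groups: list[np.ndarray | list[float]], labels: list[str] | None = None
) -> AnovaResult:
    """One-way ANOVA with the Tukey HSD post hoc test.

    F and p from the classical between/within sums of squares; adjusted
    pairwise p-values from the studentized-range distribution using the
    Tukey-Kramer standard error, which is exact-Tukey for equal group sizes
    and the standard conservative extension for unequal sizes.
    """
    if len(groups) < 2:
        raise DegreesOfFreedomError("ANOVA needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for idx, g in enumerate(arrays):
        if g.size < 2:
            raise DegreesOfFreedomError(f"group {idx} has fewer than 2 values")
    if labels is None:
        labels = [f"group{idx}" for idx in range(len(arrays))]

    k = len(arrays)
    ns = np.array([g.size for g in arrays])
    n_total = int(ns.sum())
    means = np.array([g.mean() for g in arrays])
    grand = float(np.concatenate(arrays).mean())

    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(arrays, means)))
    df_between = k - 1
    df_within = n_total - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0.0:
        F = 0.0 if ms_between == 0.0 else math.inf
    else:
        F = ms_between / ms_within
    p_value = float(stats.f.sf(F, df_between, df_within)) if math.isfinite(F) else 0.0

    comparisons = []
    for i, j in itertools.combinations(range(k), 2):
        diff = float(means[i] - means[j])
        se = math.sqrt(ms_within / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        if se == 0.0:
            p_adj = 1.0 if diff == 0.0 else 0.0
        else:
            q_obs = abs(diff) / se
            p_adj = float(stats.studentized_range.sf(q_obs, k, df_within))
        comparisons.append(
            TukeyComparison(
                group_a=labels[i],
                group_b=labels[j],
                mean_diff=diff,
                p_adj=p_adj,
                stars=significance_stars(p_adj),
            )
        )
    return AnovaResult(
        F=F,
        df_between=df_between,
        df_within=df_within,
        p_value=p_value,
        tukey=comparisons,
    )


def interclade_anova(
    table: pd.DataFrame,
    clade_pairs: list[tuple[str, str]],
    which: str = "normalized",
) -> AnovaResult:
    """ANOVA across selected clade-pair groups of the pair table."""
    groups, labels = [], []
    for ca, cb in clade_pairs:
        values, _ = interclade_distribution(table, ca, cb, which)
        groups.append(values)
        labels.append(clade_pair_label(ca, cb))
    return anova_tukey(groups, labels)


def jackknife_anova(
    table: pd.DataFrame,
    clade_pairs: list[tuple[str, str]],
    which: str = "normalized",
) -> pd.DataFrame:
    """Taxon-level jackknife sensitivity for the interclade ANOVA.

    Pairwise distances sharing a species are correlated; dropping one taxon
    at a time and re-running the ANOVA shows whether the conclusion hinges
    on any single species.  Taxa whose removal empties a group are skipped.
    """
    taxa = sorted(set(table["taxon_a"]) | set(table["taxon_b"]))
    rows = []
    for taxon in taxa:
        sub = table[(table["taxon_a"] != taxon) & (table["taxon_b"] != taxon)]
        try:
            res = interclade_anova(sub, clade_pairs, which)
        except (EmptyGroupError, DegreesOfFreedomError):
            continue
        rows.append({"dropped_taxon": taxon, "F": res.F, "p_value": res.p_value})
    return pd.DataFrame(rows, columns=["dropped_taxon", "F", "p_value"])
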