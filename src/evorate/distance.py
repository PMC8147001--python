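"""Pairwise amino-acid distance estimation on protein alignments.

Implements the proportion-of-differences estimator (p-distance), the Poisson
multiple-hit correction d = -ln(1-p) and its gamma-rates generalisation
d = a((1-p)^(-1/a) - 1), with either pairwise or complete deletion of
gap/unknown columns.  The default — p-distance with pairwise deletion —
matches the convention of distance heatmaps on a [0, 1] proportion scale.

Missing (incomparable) pairs propagate as explicit NaN entries, never as
silent zeros; tree building refuses matrices containing them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import IncomparablePairError, IncompleteMatrixError, SaturationError
from .seqio import AMINO_ACIDS, ConcatenatedAlignment, LocusAlignment

log = logging.getLogger(__name__)

_STANDARD = frozenset(AMINO_ACIDS)

MODELS = ("p_distance", "poisson", "gamma")
DELETIONS = ("pairwise", "complete")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


_STANDARD_CODES = np.zeros(256, dtype=bool)
for _aa in AMINO_ACIDS:
    _STANDARD_CODES[ord(_aa)] = True


def p_distance(row_a: str, row_b: str, deletion: str = "pairwise") -> tuple[float, int]:
    """Proportion of differing residues among comparable columns.

    With pairwise deletion a column is comparable when both residues are
    standard amino acids ('-' and 'X' excluded).  Complete deletion expects
    the caller to have pre-masked columns containing any gap in any taxon
    (see :func:`complete_deletion_mask`); per-pair behaviour is identical.
    Returns ``(p, n_sites)``; zero comparable sites raise
    :class:`IncomparablePairError` so the pair is reported missing, not 0.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows have different lengths")
    if deletion not in DELETIONS:
        raise ValueError(f"unknown deletion scheme {deletion!r}")
    a = _encode(row_a)
    b = _encode(row_b)
    comparable = _STANDARD_CODES[a] & _STANDARD_CODES[b]
    n_sites = int(comparable.sum())
    if n_sites == 0:
        raise IncomparablePairError("no comparable sites between the pair")
    mismatches = int(((a != b) & comparable).sum())
    return mismatches / n_sites, n_sites


def poisson_distance(p: float) -> float:
    """Poisson-corrected amino-acid distance d = -ln(1-p)."""
    if not 0.0 <= p < 1.0:
        raise SaturationError(f"p-distance {p} outside [0, 1): distance undefined")
    return -math.log1p(-p)


def gamma_distance(p: float, shape: float) -> float:
    """Gamma-rates corrected distance d = a((1-p)^(-1/a) - 1).

    Converges to the Poisson correction as the shape parameter a grows.
    """
    if shape <= 0:
        raise ValueError("gamma shape must be positive")
    if not 0.0 <= p < 1.0:
        raise SaturationError(f"p-distance {p} outside [0, 1): distance undefined")
    return shape * ((1.0 - p) ** (-1.0 / shape) - 1.0)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix tagged with its settings.

    ``values`` holds NaN for pairs flagged missing (no comparable sites or
    saturated correction); ``sites_used`` holds the per-pair comparable-site
    count (0 where missing).
    """

    taxa: list[str]
    values: np.ndarray
    model: str
    deletion: str
    sites_used: np.ndarray
    gamma_shape: float | None = None

    def __post_init__(self) -> None:
        n = len(self.taxa)
        assert self.values.shape == (n, n)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def has_missing(self) -> bool:
        off = ~np.eye(self.n_taxa, dtype=bool)
        return bool(np.isnan(self.values[off]).any())

    def value(self, a: str, b: str) -> float:
        i, j = self.taxa.index(a), self.taxa.index(b)
        return float(self.values[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxa, columns=self.taxa)

    def write_tsv(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = "taxon"
        df.to_csv(path, sep="\t", float_format="%.10g")

    def require_complete(self) -> None:
        if self.has_missing:
            raise IncompleteMatrixError(
                "distance matrix has missing pairs; cannot proceed"
            )


def complete_deletion_mask(rows: list[str]) -> np.ndarray:
    """Boolean mask of columns where every taxon has a standard residue."""
    mat = np.vstack([_encode(r) for r in rows])
    return _STANDARD_CODES[mat].all(axis=0)


def _correct(p: float, model: str, gamma_shape: float | None) -> float:
    if model == "p_distance":
        return p
    if model == "poisson":
        return poisson_distance(p)
    if model == "gamma":
        if gamma_shape is None:
            raise ValueError("gamma model requires gamma_shape")
        return gamma_distance(p, gamma_shape)
    raise ValueError(f"unknown distance model {model!r}")


def encode_alignment(
    aln: LocusAlignment | ConcatenatedAlignment,
) -> tuple[list[str], np.ndarray]:
    """Taxon list and (n_taxa, n_columns) uint8 residue matrix."""
    rows_map = aln.members if isinstance(aln, LocusAlignment) else aln.rows
    taxa = list(rows_map)
    return taxa, np.vstack([_encode(rows_map[t]) for t in taxa])


def distance_matrix(
    aln: LocusAlignment | ConcatenatedAlignment,
    model: str = "p_distance",
    deletion: str = "pairwise",
    gamma_shape: float | None = None,
) -> DistanceMatrix:
    """All-pairs distance matrix on an alignment.

    Each unordered pair is computed once (symmetry is exact by
    construction).  Incomparable or saturated pairs are recorded as NaN with
    a warning rather than silently zero.
    """
    taxa, mat = encode_alignment(aln)
    return distance_matrix_from_array(mat, taxa, model, deletion, gamma_shape)


def distance_matrix_from_array(
    mat: np.ndarray,
    taxa: list[str],
    model: str = "p_distance",
    deletion: str = "pairwise",
    gamma_shape: float | None = None,
) -> DistanceMatrix:
    """Distance matrix from an encoded residue matrix (rows = taxa)."""
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa")
    if deletion not in DELETIONS:
        raise ValueError(f"unknown deletion scheme {deletion!r}")
    standard = _STANDARD_CODES[mat]
    if deletion == "complete":
        keep = standard.all(axis=0)
        mat = mat[:, keep]
        standard = standard[:, keep]

    n = len(taxa)
    values = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=int)
    n_missing = 0
    for i in range(n):
        sites[i, i] = int(standard[i].sum())
        for j in range(i + 1, n):
            comparable = standard[i] & standard[j]
            ns = int(comparable.sum())
            if ns == 0:
                values[i, j] = values[j, i] = np.nan
                n_missing += 1
                continue
            p = float(((mat[i] != mat[j]) & comparable).sum()) / ns
            try:
                d = _correct(p, model, gamma_shape)
            except SaturationError:
                d = np.nan
                n_missing += 1
            values[i, j] = values[j, i] = d
            sites[i, j] = sites[j, i] = ns
    if n_missing:
        log.warning("%d pair(s) recorded as missing (no sites or saturated)", n_missing)
    return DistanceMatrix(
        taxa=taxa,
        values=values,
        model=model,
        deletion=deletion,
        sites_used=sites,
        gamma_shape=gamma_shape,
    )


def clip_for_display(matrix: DistanceMatrix, cap: float = 0.6) -> DistanceMatrix:
    """Copy of the matrix with entries above ``cap`` set to ``cap``.

    Display-only convention for heatmap rendering (values above the cap all
    map to the top colour); never used for statistics or tree building.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    clipped = np.where(matrix.values > cap, cap, matrix.values)
    return replace(matrix, values=clipped, sites_used=matrix.sites_used.copy())


def read_distance_tsv(path) -> DistanceMatrix:
    """Read a square TSV distance matrix written by ``write_tsv``."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    taxa = [str(t) for t in df.index]
    return DistanceMatrix(
        taxa=taxa,
        values=df.to_numpy(dtype=float),
        model="p_distance",
        deletion="pairwise",
        sites_used=np.zeros((len(taxa), len(taxa)), dtype=int),
    )
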