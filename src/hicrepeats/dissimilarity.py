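"""Physicochemical dissimilarity between repeat variants.

The dissimilarity of two variants is the sum, over the seven signature
positions, of an amino-acid physicochemical distance.  The packaged
default is the Grantham (1974) distance, recomputed from the original
composition/polarity/volume properties (d = rho * sqrt(1.833*dc^2 +
0.1018*dp^2 + 0.000399*dv^2), rho scaled so the mean over all pairs is
100, rounded to integers); any 20x20 symmetric zero-diagonal table in
the same TSV layout can be swapped in.

Also provides the repeat-level Hamming distance and the one-hot
nucleotide encoding used for repeat-space PCA.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import VariantCatalog

__all__ = [
    "AADistanceMatrix",
    "load_aa_matrix",
    "grantham_matrix",
    "variant_distance",
    "distance_matrix",
    "repeat_hamming",
    "one_hot_pca_encode",
]


class AADistanceMatrix:
    """Symmetric amino-acid distance table with a provenance name."""

    def __init__(self, table: pd.DataFrame, name: str = "custom"):
        table = table.astype(float)
        if list(table.index) != list(table.columns):
            raise ValueError("row and column labels differ")
        vals = table.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError("non-finite distances")
        if (vals < 0).any():
            raise ValueError("negative distances")
        if not np.allclose(vals, vals.T):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(vals), 0):
            raise ValueError("diagonal not zero")
        self.table = table
        self.name = name
        self._mean_offdiag = float(
            vals[~np.eye(len(table), dtype=bool)].mean()
        )

    def __call__(self, a: str, b: str) -> float:
        if a == "X" or b == "X":
            # unknown residue (partial repeat): unbiased placeholder
            return self._mean_offdiag
        try:
            return float(self.table.at[a, b])
        except KeyError:
            raise KeyError(f"residue pair ({a}, {b}) outside the matrix alphabet")

    @property
    def mean_offdiagonal(self) -> float:
        return self._mean_offdiag


def load_aa_matrix(path: str | Path, name: str | None = None) -> AADistanceMatrix:
    table = pd.read_csv(path, sep="\t", index_col=0)
    return AADistanceMatrix(table, name=name or Path(path).stem)


def grantham_matrix() -> AADistanceMatrix:
    """The packaged Grantham-type physicochemical distance table."""
    ref = resources.files("hicrepeats").joinpath("data/grantham.tsv")
    with resources.as_file(ref) as path:
        return load_aa_matrix(path, name="grantham")


def variant_distance(a: str, b: str, m: AADistanceMatrix) -> float:
    """Sum of per-position physicochemical distances between two
    signatures; X positions contribute the matrix's mean off-diagonal."""
    if len(a) != len(b):
        raise ValueError(f"signature length mismatch: {len(a)} vs {len(b)}")
    return sum(m(x, y) if x != y else 0.0 for x, y in zip(a, b))


def distance_matrix(catalog: VariantCatalog, m: AADistanceMatrix) -> pd.DataFrame:
    """All-pairs variant dissimilarities, indexed by variant ID."""
    if len(catalog) == 0:
        raise ValueError("empty catalog")
    ids = sorted(catalog.entries.values())
    sigs = {vid: sig for sig, vid in catalog.entries.items()}
    n = len(ids)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = variant_distance(sigs[ids[i]], sigs[ids[j]], m)
            vals[i, j] = vals[j, i] = d
    return pd.DataFrame(vals, index=ids, columns=ids)


def repeat_hamming(a: str, b: str) -> int:
    """Number of differing positions between two equal-length repeats."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def one_hot_pca_encode(seqs: list[str]) -> tuple[np.ndarray, list[tuple[int, str]]]:
    """One-hot encode aligned nucleotide sequences for PCA.

    One indicator column per (0-based position, observed state); gap
    characters count as a state.  Returns the 0/1 matrix (rows in input
    order) and the column key.
    """
    if not seqs:
        raise ValueError("no sequences")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("sequences are not aligned (unequal lengths)")
    columns: list[tuple[int, str]] = []
    for p in range(length):
        for state in sorted({s[p] for s in seqs}):
            columns.append((p, state))
    col_index = {c: i for i, c in enumerate(columns)}
    mat = np.zeros((len(seqs), len(columns)), dtype=np.int8)
    for r, s in enumerate(seqs):
        for p, ch in enumerate(s):
            mat[r, col_index[(p, ch)]] = 1
    return mat, columns
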