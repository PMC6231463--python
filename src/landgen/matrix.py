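"""Labelled symmetric distance matrices.

The :class:`DistanceMatrix` is the common currency of the package: genetic
distances, Euclidean distances and circuit-theory resistance distances all
travel through the Mantel machinery and the MLPE models in this form.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

__all__ = ["DistanceMatrix"]

_SYM_TOL = 1e-12


class DistanceMatrix:
    """A labelled, symmetric, zero-diagonal, non-negative matrix.

    Parameters
    ----------
    values : (n, n) array_like
        Symmetric matrix with zero diagonal.
    labels : sequence of str
        Unique identifiers for the n objects, in matrix order.
    """

    def __init__(self, values, labels: Sequence[str]):
        values = np.asarray(values, dtype=float)
        labels = [str(x) for x in labels]
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError(f"values must be square, got shape {values.shape}")
        if len(labels) != values.shape[0]:
            raise ValueError(
                f"{len(labels)} labels for a {values.shape[0]}x{values.shape[0]} matrix"
            )
        if len(set(labels)) != len(labels):
            raise ValueError("labels must be unique")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")
        if np.max(np.abs(values - values.T), initial=0.0) > _SYM_TOL:
            raise ValueError("matrix is not symmetric")
        if np.any(np.diag(values) != 0.0):
            raise ValueError("diagonal must be exactly zero")
        # enforce exact symmetry so downstream vectorization is consistent
        self.values = (values + values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)
        self.labels = list(labels)

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.labels)

    def __len__(self) -> int:
        return self.n

    def __repr__(self) -> str:  # pragma: no cover
        return f"<DistanceMatrix n={self.n}>"

    def condensed(self) -> np.ndarray:
        """Upper-triangle (i < j) entries as a flat vector of length n(n-1)/2."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        """Return a copy with rows/columns in the given label order."""
        idx = [self.labels.index(str(l)) for l in labels]
        return DistanceMatrix(self.values[np.ix_(idx, idx)], [self.labels[i] for i in idx])

    def subset(self, labels: Sequence[str]) -> "DistanceMatrix":
        return self.reorder(labels)

    # ------------------------------------------------------------------
    @classmethod
    def from_condensed(cls, condensed, labels: Sequence[str]) -> "DistanceMatrix":
        n = len(labels)
        condensed = np.asarray(condensed, dtype=float)
        if condensed.size != n * (n - 1) // 2:
            raise ValueError("condensed length does not match label count")
        values = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        values[iu] = condensed
        values += values.T
        return cls(values, labels)

    @classmethod
    def read_csv(cls, path) -> "DistanceMatrix":
        """Read a square labelled matrix (ids as header row and first column)."""
        df = pd.read_csv(path, index_col=0)
        if list(df.index.astype(str)) != list(df.columns.astype(str)):
            raise ValueError("row and column labels differ")
        return cls(df.to_numpy(dtype=float), list(df.columns.astype(str)))

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)


def check_same_labels(*matrices: DistanceMatrix) -> None:
    """Raise if the matrices do not share an identical label ordering."""
    first = matrices[0].labels
    for m in matrices[1:]:
        if m.labels != first:
            missing = set(first) ^ set(m.labels)
            raise ValueError(
                "distance matrices have mismatched labels"
                + (f" (symmetric difference: {sorted(missing)[:5]}...)" if missing else " (order differs)")
            )
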