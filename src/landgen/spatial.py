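"""Mantel tests, partial Mantel tests and spatial autocorrelograms.

The permutation machinery underlying the isolation-by-distance and
isolation-by-resistance hypothesis tests. Tests are one-tailed (positive
association) by default, matching the directional hypotheses of
resistance modelling; permutations relabel individuals, i.e. permute rows
and columns of one matrix simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import DistanceMatrix, check_same_labels

__all__ = [
    "MantelResult",
    "CorrelogramResult",
    "euclidean_matrix",
    "mantel",
    "partial_mantel",
    "autocorrelogram",
    "sex_stratified_correlograms",
]

_CHUNK = 256  # permutations per fancy-indexing batch (bounds memory)


@dataclass
class MantelResult:
    """Correlation, one-tailed permutation p-value and reproducibility info."""

    r: float
    p: float
    n_perm: int
    seed: int
    tail: str = "greater"

    def __post_init__(self):
        if not -1.0 - 1e-9 <= self.r <= 1.0 + 1e-9:
            raise ValueError("r outside [-1, 1]")
        if not 0.0 < self.p <= 1.0:
            raise ValueError("p outside (0, 1]")


def euclidean_matrix(points, labels=None) -> DistanceMatrix:
    """Straight-line distances (metres) between projected points."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if not np.all(np.isfinite(pts)):
        raise ValueError("coordinates must be finite")
    if labels is None:
        labels = [str(i) for i in range(len(pts))]
    diff = pts[:, None, :] - pts[None, :, :]
    return DistanceMatrix(np.hypot(diff[..., 0], diff[..., 1]), labels)


def _condensed(m: DistanceMatrix) -> np.ndarray:
    return m.condensed()


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        raise ValueError("zero-variance distance matrix in correlation")
    return float((a @ b) / denom)


def _perm_corrs(
    values: np.ndarray, other_vec: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Correlations of row/column-permuted ``values`` with a fixed vector."""
    n = values.shape[0]
    iu0, iu1 = np.triu_indices(n, k=1)
    b = other_vec - other_vec.mean()
    nb = np.sqrt(b @ b)
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        k = min(_CHUNK, n_perm - done)
        perms = np.empty((k, n), dtype=int)
        for t in range(k):
            perms[t] = rng.permutation(n)
        av = values[perms[:, iu0], perms[:, iu1]]  # (k, m)
        av = av - av.mean(axis=1, keepdims=True)
        na = np.sqrt(np.einsum("ij,ij->i", av, av))
        out[done : done + k] = (av @ b) / (na * nb)
        done += k
    return out


def _tail_p(r_obs: float, r_perm: np.ndarray, tail: str) -> float:
    n_perm = len(r_perm)
    eps = 1e-12  # floating ties (e.g. the identity permutation) count
    if tail == "greater":
        count = int(np.sum(r_perm >= r_obs - eps))
    elif tail == "two-sided":
        count = int(np.sum(np.abs(r_perm) >= abs(r_obs) - eps))
    else:
        raise ValueError("tail must be 'greater' or 'two-sided'")
    return (1 + count) / (n_perm + 1)


def mantel(
    A: DistanceMatrix,
    B: DistanceMatrix,
    n_perm: int = 9999,
    seed: int = 0,
    tail: str = "greater",
) -> MantelResult:
    """Mantel test: Pearson correlation of two distance matrices.

    ``r`` is computed over the n(n-1)/2 unordered pairs; the permutation
    null permutes rows and columns of ``B`` simultaneously. ``p`` is
    (1 + #{r_perm >= r_obs}) / (n_perm + 1) for the default positive tail.
    """
    check_same_labels(A, B)
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    a, b = _condensed(A), _condensed(B)
    r_obs = _corr(a, b)
    rng = np.random.default_rng(seed)
    r_perm = _perm_corrs(B.values, a, n_perm, rng)
    return MantelResult(r_obs, _tail_p(r_obs, r_perm, tail), n_perm, seed, tail)


def _ols_residuals(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    x = x - x.mean()
    xx = x @ x
    if xx == 0:  # constant conditioner: no information to remove
        return y - y.mean()
    beta = (x @ (y - y.mean())) / xx
    return y - y.mean() - beta * x


def partial_mantel(
    A: DistanceMatrix,
    B: DistanceMatrix,
    C: DistanceMatrix,
    n_perm: int = 9999,
    seed: int = 0,
    tail: str = "greater",
) -> MantelResult:
    """Partial Mantel test of A ~ B controlling C (residual permutation).

    The statistic is the partial correlation
    ``(r_AB - r_AC r_BC) / sqrt((1 - r_AC^2)(1 - r_BC^2))``, identical to
    the correlation of the OLS residuals of A|C and B|C. The null permutes
    the residual matrix of A on C (rows and columns together) and
    recomputes the statistic, the Legendre "residuals of A" scheme.
    """
    check_same_labels(A, B, C)
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    a, b, c = _condensed(A), _condensed(B), _condensed(C)
    if np.ptp(c) == 0:
        # constant off-diagonal conditioner carries no information: the
        # partial test degenerates to the simple Mantel test
        r_ac = r_bc = 0.0
    else:
        r_ac, r_bc = _corr(a, c), _corr(b, c)
    if abs(r_ac) >= 1 - 1e-12 or abs(r_bc) >= 1 - 1e-12:
        raise ValueError(
            f"degenerate conditioning: |r_AC|={abs(r_ac):.6f}, |r_BC|={abs(r_bc):.6f}"
        )
    res_a = _ols_residuals(a, c)
    res_b = _ols_residuals(b, c)
    r_obs = _corr(res_a, res_b)

    n = A.n
    RA = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    RA[iu] = res_a
    RA += RA.T
    rng = np.random.default_rng(seed)
    r_perm = _perm_corrs(RA, res_b, n_perm, rng)
    return MantelResult(r_obs, _tail_p(r_obs, r_perm, tail), n_perm, seed, tail)


# ----------------------------------------------------------------------
@dataclass
class CorrelogramResult:
    """Multilocus spatial autocorrelogram over geographic distance classes.

    ``r[h]`` is the genetic autocorrelation of pairs whose separation falls
    in class ``h`` (edges ``class_edges[h]..class_edges[h+1]``), with a
    permutation 95% null envelope and a bootstrap 95% CI around r.
    Classes with no pairs report ``nan`` and ``n_pairs = 0``.
    """

    class_edges: np.ndarray
    r: np.ndarray
    null_low: np.ndarray
    null_high: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_pairs: np.ndarray
    n_perm: int
    n_boot: int
    seed: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "lower_m": self.class_edges[:-1],
                "upper_m": self.class_edges[1:],
                "r": self.r,
                "null_low": self.null_low,
                "null_high": self.null_high,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "n_pairs": self.n_pairs,
            }
        )

    def plot(self, ax=None, label=None):
        """Correlogram with null envelope (dashed) and bootstrap error bars."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        mid = (self.class_edges[:-1] + self.class_edges[1:]) / 2.0
        ax.errorbar(
            mid, self.r,
            yerr=[self.r - self.ci_low, self.ci_high - self.r],
            fmt="o-", capsize=3, label=label,
        )
        ax.plot(mid, self.null_low, "k--", lw=0.8)
        ax.plot(mid, self.null_high, "k--", lw=0.8)
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_xlabel("distance class midpoint (m)")
        ax.set_ylabel("autocorrelation r")
        return ax


def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    d2 = d * d
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * (J @ d2 @ J)


def _class_r(C: np.ndarray, I: np.ndarray, J: np.ndarray, parts: np.ndarray) -> float:
    """Mean pair covariance in the class over the mean self-covariance of
    the participating individuals (a correlation-like ratio in [-1, 1];
    its null expectation is -1/(n-1), near zero)."""
    den = C[parts, parts].mean()
    if den == 0:
        return np.nan
    return C[I, J].mean() / den


def autocorrelogram(
    gd: DistanceMatrix,
    points,
    class_width: float = 1900.0,
    n_classes: int = 15,
    n_perm: int = 999,
    n_boot: int = 999,
    seed: int = 0,
) -> CorrelogramResult:
    """Multivariate spatial autocorrelogram (Smouse-Peakall r).

    The genetic covariance matrix is the Gower-centered element-wise
    squared genetic distance matrix C. For class h,
    ``r_h = 2 * sum_{i<j in h} c_ij / sum_{i in pairs of h} c_ii``.
    The null envelope permutes individual locations; the CI bootstraps
    pairs within class. The default 1900 m class width is the radius of a
    typical giant-panda home range, the scale at which local genetic
    structure is expected.
    """
    if class_width <= 0:
        raise ValueError("class_width must be > 0")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) != gd.n:
        raise ValueError("points and genetic matrix sizes differ")
    n = gd.n
    C = _gower_center(gd.values)
    geo = euclidean_matrix(pts, gd.labels).values
    edges = np.arange(n_classes + 1) * class_width

    iu0, iu1 = np.triu_indices(n, k=1)
    pair_class = np.floor(geo[iu0, iu1] / class_width).astype(int)
    classes = []
    for h in range(n_classes):  # pairs beyond the last edge are dropped
        sel = pair_class == h
        I, J = iu0[sel], iu1[sel]
        parts = np.unique(np.r_[I, J])
        classes.append((I, J, parts))

    r = np.array([_class_r(C, I, J, p) if len(I) else np.nan for I, J, p in classes])
    n_pairs = np.array([len(I) for I, J, p in classes])

    rng = np.random.default_rng(seed)
    diag = np.diag(C)
    null = np.full((n_perm, n_classes), np.nan)
    for t in range(n_perm):
        perm = rng.permutation(n)
        for h, (I, J, parts) in enumerate(classes):
            if len(I) == 0:
                continue
            den = diag[perm[parts]].mean()
            null[t, h] = C[perm[I], perm[J]].mean() / den if den else np.nan
    with np.errstate(all="ignore"):
        null_low = np.nanpercentile(null, 2.5, axis=0)
        null_high = np.nanpercentile(null, 97.5, axis=0)

    ci_low = np.full(n_classes, np.nan)
    ci_high = np.full(n_classes, np.nan)
    for h, (I, J, parts) in enumerate(classes):
        m = len(I)
        if m < 2:
            continue
        boots = np.empty(n_boot)
        for t in range(n_boot):
            idx = rng.integers(0, m, m)
            bi, bj = I[idx], J[idx]
            bparts = np.unique(np.r_[bi, bj])
            den = diag[bparts].mean()
            boots[t] = C[bi, bj].mean() / den if den else np.nan
        ci_low[h] = np.nanpercentile(boots, 2.5)
        ci_high[h] = np.nanpercentile(boots, 97.5)

    return CorrelogramResult(
        edges, r, null_low, null_high, ci_low, ci_high, n_pairs, n_perm, n_boot, seed
    )


def sex_stratified_correlograms(table, gd: DistanceMatrix | None = None, **kwargs):
    """Run the autocorrelogram separately for females and males.

    ``table`` is a :class:`~landgen.genotypes.GenotypeTable`; ``gd``
    defaults to its Dps distance. Individuals of unknown sex are excluded.
    A sex with no individuals maps to ``None`` (absent); a sex with fewer
    than 3 individuals is an error (no meaningful autocorrelation).
    """
    from .genotypes import dps_distance

    if gd is None:
        gd = dps_distance(table)
    out = {}
    for sex in ("F", "M"):
        sub = table.subset_sex(sex)
        if sub.n == 0:
            out[sex] = None
            continue
        if sub.n < 3:
            raise ValueError(f"sex {sex!r} has only {sub.n} individuals (<3)")
        sub_gd = gd.subset(sub.sample_id)
        out[sex] = autocorrelogram(sub_gd, sub.xy, **kwargs)
    return out
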