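"""Multilocus microsatellite genotypes from noninvasive sampling.

Reads diploid genotype tables, filters samples by typing success, collapses
repeat samples of the same individual, and computes the summary statistics
that establish marker discrimination power and diversity: allele
frequencies, observed/expected heterozygosity, the probability of identity
P(ID) and its full-sib variant, and the proportion-of-shared-alleles
genetic distance Dps = 1 - PSA.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import DistanceMatrix

__all__ = [
    "GenotypeTable",
    "AlleleFrequencies",
    "DiversitySummary",
    "read_genotypes",
    "filter_by_loci",
    "collapse_individuals",
    "allele_frequencies",
    "diversity_summary",
    "probability_of_identity",
    "dps_distance",
]

log = logging.getLogger(__name__)

#: internal sentinel for a missing allele call (both alleles of a locus
#: are either present or set to this value)
MISSING = 0


@dataclass
class GenotypeTable:
    """Individuals x loci diploid allele calls with coordinates and sex.

    Attributes
    ----------
    sample_id : list of str
        Unique sample identifiers, input order preserved.
    sex : list of str
        "F", "M" or "unknown" per sample.
    xy : (n, 2) float array
        Projected map coordinates in metres.
    calls : (n, n_loci, 2) int array
        Allele sizes; ``0`` encodes a missing call (both alleles of a
        missing locus are 0).
    locus_names : list of str
    """

    sample_id: list
    sex: list
    xy: np.ndarray
    calls: np.ndarray
    locus_names: list = field(default_factory=list)

    def __post_init__(self):
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        self.calls = np.asarray(self.calls, dtype=int)
        if self.calls.ndim != 3 or self.calls.shape[2] != 2:
            raise ValueError("calls must have shape (n, n_loci, 2)")
        if len(self.sample_id) != len(set(self.sample_id)):
            dupes = {s for s in self.sample_id if self.sample_id.count(s) > 1}
            raise ValueError(f"duplicate sample_id: {sorted(dupes)}")
        if self.xy.size and not np.all(np.isfinite(self.xy)):
            raise ValueError("coordinates must be finite")
        half = (self.calls == MISSING).sum(axis=2) == 1
        if np.any(half):
            raise ValueError("half-missing locus calls; coerce before constructing")

    @property
    def n(self) -> int:
        return len(self.sample_id)

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    def typed(self) -> np.ndarray:
        """(n, n_loci) boolean mask of non-missing locus calls."""
        return self.calls[:, :, 0] != MISSING

    def n_typed(self) -> np.ndarray:
        """Number of successfully typed loci per sample."""
        return self.typed().sum(axis=1)

    def take(self, idx) -> "GenotypeTable":
        idx = np.asarray(idx, dtype=int)
        return GenotypeTable(
            [self.sample_id[i] for i in idx],
            [self.sex[i] for i in idx],
            self.xy[idx],
            self.calls[idx],
            list(self.locus_names),
        )

    def subset_sex(self, sex: str) -> "GenotypeTable":
        return self.take([i for i, s in enumerate(self.sex) if s == sex])

    def to_csv(self, path, missing_code: int = 0) -> None:
        cols = {"sample": self.sample_id, "sex": self.sex,
                "x": self.xy[:, 0], "y": self.xy[:, 1]}
        calls = np.where(self.calls == MISSING, missing_code, self.calls)
        for j, loc in enumerate(self.locus_names):
            cols[f"{loc}_1"] = calls[:, j, 0]
            cols[f"{loc}_2"] = calls[:, j, 1]
        pd.DataFrame(cols).to_csv(path, index=False)


@dataclass
class AlleleFrequencies:
    """Per-locus allele relative frequencies and gene-copy counts."""

    freqs: list          # list (per locus) of dict allele -> frequency
    n_genes: np.ndarray  # non-missing gene copies per locus
    locus_names: list

    def __post_init__(self):
        for loc, f in zip(self.locus_names, self.freqs):
            total = sum(f.values())
            if abs(total - 1.0) > 1e-12:
                raise ValueError(f"frequencies at {loc} sum to {total}")
            if any(not (0 < p <= 1) for p in f.values()):
                raise ValueError(f"frequencies at {loc} outside (0, 1]")


@dataclass
class DiversitySummary:
    """Allele counts and heterozygosities, per locus and averaged."""

    per_locus: pd.DataFrame  # index locus, columns A, H_O, H_E
    mean_a: float
    mean_ho: float
    mean_he: float


# ----------------------------------------------------------------------
def read_genotypes(path, missing_code: int = 0) -> GenotypeTable:
    """Read a delimited genotype table.

    Expected header: ``sample,sex,x,y,<locus>_1,<locus>_2,...`` with two
    allele columns per locus. Half-missing calls (one allele equal to
    ``missing_code``) are coerced to fully missing with a warning.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    base = [c for c in ("sample", "sex", "x", "y") if c in df.columns]
    if "sample" not in base or "x" not in base or "y" not in base:
        raise ValueError("header must contain sample, x, y columns")
    allele_cols = [c for c in df.columns if c not in ("sample", "sex", "x", "y")]
    if len(allele_cols) % 2:
        raise ValueError(
            f"odd number of allele columns ({len(allele_cols)}): two per locus required"
        )
    locus_names = []
    for c1, c2 in zip(allele_cols[::2], allele_cols[1::2]):
        root1 = c1.rsplit("_", 1)[0]
        root2 = c2.rsplit("_", 1)[0]
        if root1 != root2:
            raise ValueError(f"allele columns {c1!r}/{c2!r} do not pair up")
        locus_names.append(root1)

    ids = [str(s) for s in df["sample"]]
    if len(ids) != len(set(ids)):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ValueError(f"duplicate sample_id: {dupes}")
    sex = (
        [str(s) if str(s) in ("F", "M") else "unknown" for s in df["sex"]]
        if "sex" in df.columns
        else ["unknown"] * len(ids)
    )
    calls = df[allele_cols].to_numpy(dtype=int).reshape(len(ids), -1, 2)
    calls = np.where(calls == missing_code, MISSING, calls)
    half = (calls == MISSING).sum(axis=2) == 1
    if np.any(half):
        log.warning("coercing %d half-missing locus calls to missing", int(half.sum()))
        calls[half] = MISSING
    return GenotypeTable(ids, sex, df[["x", "y"]].to_numpy(float), calls, locus_names)


def filter_by_loci(table: GenotypeTable, min_loci: int) -> GenotypeTable:
    """Retain samples typed at >= ``min_loci`` loci (order preserved).

    The study-grade default is 9 of 12 loci, the reliability threshold for
    noninvasive faecal genotyping.
    """
    if not 0 <= min_loci <= table.n_loci:
        raise ValueError(f"min_loci must be in [0, {table.n_loci}]")
    keep = np.flatnonzero(table.n_typed() >= min_loci)
    return table.take(keep)


def _pair_mismatches(calls: np.ndarray, i: int, j: int) -> tuple[int, int]:
    """(mismatching co-typed loci, co-typed loci) between samples i and j."""
    ti = calls[i, :, 0] != MISSING
    tj = calls[j, :, 0] != MISSING
    both = ti & tj
    if not both.any():
        return 0, 0
    a, b = calls[i][both], calls[j][both]
    same = ((a[:, 0] == b[:, 0]) & (a[:, 1] == b[:, 1])) | (
        (a[:, 0] == b[:, 1]) & (a[:, 1] == b[:, 0])
    )
    return int((~same).sum()), int(both.sum())


def collapse_individuals(
    table: GenotypeTable, max_mismatch: int = 0
) -> tuple[GenotypeTable, dict]:
    """Collapse repeat samples into unique individuals.

    Two samples match when their genotypes disagree at no more than
    ``max_mismatch`` co-typed loci (missing loci are never mismatches).
    Groups are the transitive closure of pairwise matches. Each group keeps
    the sample with the most typed loci (ties: first in input order) and is
    assigned that sample's id as individual id.

    Returns the collapsed table and a mapping sample_id -> individual_id.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    n = table.n
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            mism, _ = _pair_mismatches(table.calls, i, j)
            if mism <= max_mismatch:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    n_typed = table.n_typed()
    reps, mapping = [], {}
    for root in sorted(groups):
        members = groups[root]
        rep = max(members, key=lambda i: (n_typed[i], -i))
        reps.append(rep)
        for i in members:
            mapping[table.sample_id[i]] = table.sample_id[rep]
    reps.sort()
    return table.take(reps), mapping


def allele_frequencies(table: GenotypeTable) -> AlleleFrequencies:
    """Count gene copies (2 per typed individual per locus) and normalize."""
    freqs, n_genes = [], []
    for j, loc in enumerate(table.locus_names):
        typed = table.calls[:, j, 0] != MISSING
        if not typed.any():
            raise ValueError(f"locus {loc!r} has no typed individuals")
        alleles = table.calls[typed, j, :].ravel()
        vals, counts = np.unique(alleles, return_counts=True)
        total = counts.sum()
        freqs.append({int(a): c / total for a, c in zip(vals, counts)})
        n_genes.append(total)
    return AlleleFrequencies(freqs, np.array(n_genes), list(table.locus_names))


def diversity_summary(table: GenotypeTable, unbiased: bool = True) -> DiversitySummary:
    """Per-locus allele count A, observed and expected heterozygosity.

    H_E uses Nei's small-sample unbiased gene diversity
    ``(2n/(2n-1)) * (1 - sum p_i^2)`` by default; pass ``unbiased=False``
    for the plain ``1 - sum p_i^2``.
    """
    af = allele_frequencies(table)
    rows = []
    for j, loc in enumerate(table.locus_names):
        typed = table.calls[:, j, 0] != MISSING
        n = int(typed.sum())
        calls = table.calls[typed, j, :]
        ho = float(np.mean(calls[:, 0] != calls[:, 1])) if n else np.nan
        sum_p2 = sum(p * p for p in af.freqs[j].values())
        he = 1.0 - sum_p2
        if unbiased:
            he *= 2 * n / (2 * n - 1) if n > 0 else np.nan
        rows.append({"locus": loc, "A": len(af.freqs[j]), "H_O": ho, "H_E": he})
    per_locus = pd.DataFrame(rows).set_index("locus")
    return DiversitySummary(
        per_locus,
        float(per_locus["A"].mean()),
        float(per_locus["H_O"].mean()),
        float(per_locus["H_E"].mean()),
    )


def probability_of_identity(freqs: AlleleFrequencies) -> tuple[float, float]:
    """Multilocus P(ID) for unrelated pairs and for full sibs.

    Per locus, with allele frequencies p_i:

    ``PID     = sum_i p_i^4 + sum_{i<j} (2 p_i p_j)^2``
    ``PIDsib  = 0.25 + 0.5*sum p_i^2 + 0.5*(sum p_i^2)^2 - 0.25*sum p_i^4``

    Multilocus values are products over loci (independence assumed).
    """
    pid, pid_sib = 1.0, 1.0
    for f in freqs.freqs:
        p = np.array(list(f.values()))
        s2, s4 = float(np.sum(p**2)), float(np.sum(p**4))
        het = 0.0
        for i in range(len(p)):
            for j in range(i + 1, len(p)):
                het += (2 * p[i] * p[j]) ** 2
        pid *= s4 + het
        pid_sib *= 0.25 + 0.5 * s2 + 0.5 * s2 * s2 - 0.25 * s4
    return pid, pid_sib


def dps_distance(table: GenotypeTable) -> DistanceMatrix:
    """Genetic distance 1 - PSA (proportion of shared alleles).

    For each pair, PSA is the mean over co-typed loci of
    (shared alleles counting multiplicity, 0..2) / 2. Pairs with no
    co-typed locus are an error.
    """
    n, L = table.n, table.n_loci
    a1 = table.calls[:, :, 0]  # (n, L)
    a2 = table.calls[:, :, 1]
    typed = a1 != MISSING

    # per-locus shares averaged over co-typed loci (not pooled counts)
    psa_sum = np.zeros((n, n))
    co = np.zeros((n, n))
    for j in range(L):
        t = typed[:, j]
        both = np.outer(t, t)
        x1, x2 = a1[:, j], a2[:, j]
        m1 = (x1[:, None] == x1[None, :]).astype(int) + (x2[:, None] == x2[None, :])
        m2 = (x1[:, None] == x2[None, :]).astype(int) + (x2[:, None] == x1[None, :])
        s = np.maximum(m1, m2) / 2.0
        psa_sum += np.where(both, s, 0.0)
        co += both

    iu = np.triu_indices(n, k=1)
    bad = co[iu] == 0
    if np.any(bad):
        k = int(np.argmax(bad))
        pair = (table.sample_id[iu[0][k]], table.sample_id[iu[1][k]])
        raise ValueError(f"pair {pair} shares no co-typed locus")

    np.fill_diagonal(co, 1)  # diagonal forced to 0 below
    psa = psa_sum / co
    d = 1.0 - psa
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, table.sample_id)
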