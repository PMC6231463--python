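"""Causal-modelling selection among isolation hypotheses.

Competes landscape-resistance (IBR) hypotheses against the uniform-surface
IBD null and against reduced models, using reciprocal partial Mantel tests:

(a) GD ~ LR | IBD must be significant,
(b) GD ~ IBD | LR must not be,

and, between a full landscape model LM and a reduced model RM,

(c) GD ~ LM | RM must be significant,
(d) GD ~ RM | LM must not be.

Relative support between two models is the difference of the reciprocal
partial correlations, ``RS_1|2 = r(GD~LR1|LR2) - r(GD~LR2|LR1)``.

The multivariate search is a coordinate-wise ascent over per-variable
parameter grids, maximizing r(GD ~ combined | IBD), adding ranked
variables one at a time and keeping each addition only if the enlarged
model passes the reduced-model criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circuit import resistance_matrix
from .matrix import DistanceMatrix
from .raster import Raster
from .resistance import ResistanceParams, build_surface, combine_surfaces
from .spatial import MantelResult, mantel, partial_mantel

__all__ = [
    "CausalModelRecord",
    "relative_support",
    "support_vs_ibd",
    "reduced_model_test",
    "univariate_scan",
    "optimize_multivariate",
    "CausalAnalysis",
]


def relative_support(r_1_given_2: float, r_2_given_1: float) -> float:
    """RS of model 1 over model 2 from their reciprocal partial correlations.

    Antisymmetric by construction: RS_1|2 = -RS_2|1. Positive values mean
    model 1 explains genetic distance beyond what model 2 captures.
    """
    for r in (r_1_given_2, r_2_given_1):
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"correlation {r} outside [-1, 1]")
    return r_1_given_2 - r_2_given_1


@dataclass
class CausalModelRecord:
    """One resistance hypothesis with its causal-modelling evidence."""

    variables: list  # list of ResistanceParams
    r_lr_given_ibd: float
    p_lr_given_ibd: float
    r_ibd_given_lr: float
    p_ibd_given_lr: float
    mantel_r: float = np.nan
    mantel_p: float = np.nan
    excluded: bool = False
    reduced_tests: dict = field(default_factory=dict)
    supported: bool = False
    alpha: float = 0.05

    @property
    def rs_ibd(self) -> float:
        return relative_support(self.r_lr_given_ibd, self.r_ibd_given_lr)

    @property
    def name(self) -> str:
        return "+".join(p.variable for p in self.variables)

    def label(self) -> str:
        return " + ".join(p.label() for p in self.variables)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<CausalModelRecord {self.name} r(GD~LR|IBD)={self.r_lr_given_ibd:.4f} "
            f"RS={self.rs_ibd:.4f} supported={self.supported}>"
        )


def support_vs_ibd(
    gd: DistanceMatrix,
    lr: DistanceMatrix,
    ibd: DistanceMatrix,
    variables=None,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
) -> CausalModelRecord:
    """Criteria (a) and (b): is the landscape model supported over IBD?"""
    a = partial_mantel(gd, lr, ibd, n_perm=n_perm, seed=seed)
    b = partial_mantel(gd, ibd, lr, n_perm=n_perm, seed=seed)
    rec = CausalModelRecord(
        variables=list(variables) if variables is not None else [],
        r_lr_given_ibd=a.r,
        p_lr_given_ibd=a.p,
        r_ibd_given_lr=b.r,
        p_ibd_given_lr=b.p,
        alpha=alpha,
    )
    rec.supported = (a.p < alpha) and (b.p >= alpha)
    return rec


def reduced_model_test(
    gd: DistanceMatrix,
    full_matrix: DistanceMatrix,
    reduced_matrix: DistanceMatrix,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[MantelResult, MantelResult, bool]:
    """Criteria (c) and (d): does the full model beat a reduced model?"""
    c = partial_mantel(gd, full_matrix, reduced_matrix, n_perm=n_perm, seed=seed)
    d = partial_mantel(gd, reduced_matrix, full_matrix, n_perm=n_perm, seed=seed)
    passes = (c.p < alpha) and (d.p >= alpha)
    return c, d, passes


# ----------------------------------------------------------------------
class _MatrixCache:
    """Resistance matrices keyed by the parameter set that produced them."""

    def __init__(self, surface_stack, points, labels, neighbourhood=8,
                 combine: str = "surface"):
        self.stack = surface_stack
        self.points = points
        self.labels = labels
        self.neighbourhood = neighbourhood
        if combine not in ("surface", "matrix"):
            raise ValueError("combine must be 'surface' or 'matrix'")
        self.combine = combine
        self._surfaces: dict[str, Raster] = {}
        self._matrices: dict[tuple, DistanceMatrix] = {}

    def surface(self, p: ResistanceParams) -> Raster:
        key = p.label()
        if key not in self._surfaces:
            if p.variable not in self.stack:
                raise KeyError(f"no raster for variable {p.variable!r}")
            self._surfaces[key] = build_surface(self.stack[p.variable], p)
        return self._surfaces[key]

    def matrix(self, params: list[ResistanceParams]) -> DistanceMatrix:
        key = tuple(sorted(p.label() for p in params))
        if key in self._matrices:
            return self._matrices[key]
        if self.combine == "matrix" and len(params) > 1:
            # literal matrix-sum reading: sum of univariate resistance matrices
            total = sum(self.matrix([p]).values for p in params)
            out = DistanceMatrix(total, list(self.labels))
        else:
            surf = (
                self.surface(params[0])
                if len(params) == 1
                else combine_surfaces([self.surface(p) for p in params])
            )
            out = resistance_matrix(
                surf, self.points, labels=self.labels, neighbourhood=self.neighbourhood
            )
        self._matrices[key] = out
        return out


def univariate_scan(
    gd: DistanceMatrix,
    ibd: DistanceMatrix,
    variable_grids: dict,
    surface_stack: dict,
    points,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
    cache: _MatrixCache | None = None,
    exclusion: str = "simple",
) -> list[CausalModelRecord]:
    """Scan all (variable, parameter) hypotheses against the IBD null.

    Models whose Mantel correlation with genetic distance is not
    significant are flagged ``excluded`` (by the simple Mantel test by
    default; ``exclusion='partial'`` uses GD~LR|IBD instead). The rest are
    ranked by r(GD~LR|IBD) descending, ties broken by fewer parameters
    then grid order.
    """
    if not variable_grids or any(len(g) == 0 for g in variable_grids.values()):
        raise ValueError("variable_grids must be non-empty")
    if cache is None:
        cache = _MatrixCache(surface_stack, points, gd.labels)
    records = []
    order = {}
    k = 0
    for var, grid in variable_grids.items():
        for p in grid:
            lr = cache.matrix([p])
            rec = support_vs_ibd(gd, lr, ibd, [p], alpha, n_perm, seed)
            m = mantel(gd, lr, n_perm=n_perm, seed=seed)
            rec.mantel_r, rec.mantel_p = m.r, m.p
            if exclusion == "simple":
                rec.excluded = m.p >= alpha
            else:
                rec.excluded = rec.p_lr_given_ibd >= alpha
            records.append(rec)
            order[id(rec)] = k
            k += 1

    def sort_key(rec):
        return (rec.excluded, -rec.r_lr_given_ibd, len(rec.variables), order[id(rec)])

    return sorted(records, key=sort_key)


def best_per_variable(records: list[CausalModelRecord]) -> dict:
    """First (best-ranked) record per variable, from a ranked scan."""
    out = {}
    for rec in records:
        out.setdefault(rec.name, rec)
    return out


def _partial_r(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Closed-form partial correlation of condensed matrices (no test)."""
    from .spatial import _corr

    r_ab, r_ac, r_bc = _corr(a, b), _corr(a, c), _corr(b, c)
    den = np.sqrt((1 - r_ac**2) * (1 - r_bc**2))
    if den == 0:
        raise ValueError("degenerate partial correlation")
    return (r_ab - r_ac * r_bc) / den


def rs_select_per_variable(
    gd: DistanceMatrix,
    records: list[CausalModelRecord],
    cache: "_MatrixCache",
) -> dict:
    """Per variable, the candidate winning the relative-support round robin.

    Among a variable's non-excluded parameterizations, each pair of
    candidates is compared by RS_1|2 = r(GD~M1|M2) - r(GD~M2|M1); the
    winner is the candidate whose worst pairwise RS is largest (a
    candidate with positive RS against every rival beats all of them).
    Ties fall back to scan rank. Variables with only excluded candidates
    are omitted.
    """
    gd_v = gd.condensed()
    by_var: dict[str, list[CausalModelRecord]] = {}
    for rec in records:
        if not rec.excluded:
            by_var.setdefault(rec.name, []).append(rec)
    out = {}
    for var, cands in by_var.items():
        # the winning candidate must also pass the support criteria, so
        # the round robin runs among supported candidates when any exist
        pool = [c for c in cands if c.supported] or cands
        if len(pool) == 1:
            out[var] = pool[0]
            continue
        vecs = [cache.matrix(rec.variables).condensed() for rec in pool]
        worst = []
        for i, vi in enumerate(vecs):
            rs_i = [
                _partial_r(gd_v, vi, vj) - _partial_r(gd_v, vj, vi)
                for j, vj in enumerate(vecs)
                if j != i
            ]
            worst.append(min(rs_i))
        out[var] = pool[int(np.argmax(worst))]
    return out


def optimize_multivariate(
    gd: DistanceMatrix,
    ibd: DistanceMatrix,
    top_variables: list[str],
    variable_grids: dict,
    surface_stack: dict,
    points,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
    max_sweeps: int = 10,
    cache: _MatrixCache | None = None,
) -> CausalModelRecord:
    """Coordinate-wise multivariate optimization over parameter grids.

    Starts from the top-ranked variable's best parameters, sweeps each
    included variable's grid in turn to maximize r(GD ~ combined | IBD)
    (first-in-grid wins ties), and adds the remaining ``top_variables``
    one at a time; an addition is kept only if the enlarged model passes
    the reduced-model criteria (c)/(d) against the model without it.
    Terminates when a full sweep changes no parameter.
    """
    if cache is None:
        cache = _MatrixCache(surface_stack, points, gd.labels)

    def obj(params: list[ResistanceParams]) -> float:
        lr = cache.matrix(params)
        return partial_mantel(gd, lr, ibd, n_perm=n_perm, seed=seed).r

    def sweep(current: dict) -> tuple[dict, bool]:
        """One pass over all included variables; returns (params, changed)."""
        changed = False
        for var in list(current):
            best_p, best_r = current[var], -np.inf
            for p in variable_grids[var]:
                trial = [p if v == var else current[v] for v in current]
                r = obj(trial)
                if r > best_r + 1e-12:
                    best_r, best_p = r, p
            if best_p.label() != current[var].label():
                current[var] = best_p
                changed = True
        return current, changed

    def converge(current: dict) -> dict:
        for _ in range(max_sweeps):
            current, changed = sweep(current)
            if not changed:
                return current
        raise RuntimeError(
            f"coordinate optimization did not converge in {max_sweeps} sweeps; "
            f"last state: {[p.label() for p in current.values()]}"
        )

    def univariate_best(var: str) -> ResistanceParams:
        """Best single-variable parameters by the same objective (the
        coordinate ascent starts each variable from here, not from an
        arbitrary grid corner, to avoid poor local optima)."""
        return max(variable_grids[var], key=lambda p: (obj([p]),))

    first = top_variables[0]
    current = {first: univariate_best(first)}
    reduced_tests = {}
    if len(top_variables) > 1:
        for var in top_variables[1:]:
            # optimize the enlarged model, then test it against its own
            # nested reduction (same parameters for the shared variables,
            # so the test isolates the candidate's contribution)
            trial = dict(current)
            trial[var] = univariate_best(var)
            trial = converge(trial)
            full_m = cache.matrix(list(trial.values()))
            red_m = cache.matrix([p for v, p in trial.items() if v != var])
            c, d, passes = reduced_model_test(
                gd, full_m, red_m, alpha=alpha, n_perm=n_perm, seed=seed
            )
            # an accepted addition must also raise the objective over the
            # current model - the coordinate search is an ascent, and a
            # re-converged enlarged model at a worse optimum must not
            # have its lack-of-fit credited to the new variable
            improved = obj(list(trial.values())) > obj(list(current.values())) + 1e-12
            reduced_tests[var] = {"c": c, "d": d, "passes": passes and improved}
            if passes and improved:
                current = trial

    lr = cache.matrix(list(current.values()))
    rec = support_vs_ibd(gd, lr, ibd, list(current.values()), alpha, n_perm, seed)
    rec.reduced_tests = reduced_tests
    if not rec.supported:
        raise RuntimeError(
            f"optimized model {rec.name} fails support criteria vs IBD "
            f"(p_a={rec.p_lr_given_ibd:.4f}, p_b={rec.p_ibd_given_lr:.4f}); "
            "restrict top_variables to supported candidates"
        )
    return rec


# ----------------------------------------------------------------------
class CausalAnalysis:
    """Convenience front-end bundling the scan and the multivariate search.

    Parameters
    ----------
    gd : DistanceMatrix
        Pairwise genetic distances (e.g. Dps).
    surface_stack : dict of str -> Raster
        One raster per candidate landscape variable.
    points : (n, 2) array
        Individual locations, ordered as ``gd.labels``.
    variable_grids : dict of str -> list of ResistanceParams
        The hypothesis space per variable.
    """

    def __init__(self, gd, surface_stack, points, variable_grids,
                 alpha=0.05, n_perm=999, seed=0, neighbourhood=8,
                 combine="surface"):
        from .resistance import ibd_surface

        self.gd = gd
        self.points = np.asarray(points, dtype=float)
        self.variable_grids = variable_grids
        self.alpha, self.n_perm, self.seed = alpha, n_perm, seed
        # the IBD null needs the full study extent: prefer a raster
        # without nodata holes (e.g. a derived aspect layer flags flat
        # cells as nodata and would punch holes in the uniform surface)
        template = next(
            (r for r in surface_stack.values() if r.valid().all()),
            next(iter(surface_stack.values())),
        )
        self.cache = _MatrixCache(surface_stack, points, gd.labels,
                                  neighbourhood, combine)
        self.ibd = resistance_matrix(
            ibd_surface(template), points, labels=gd.labels,
            neighbourhood=neighbourhood,
        )
        self.records_: list[CausalModelRecord] | None = None
        self.best_: CausalModelRecord | None = None

    def scan(self) -> list[CausalModelRecord]:
        self.records_ = univariate_scan(
            self.gd, self.ibd, self.variable_grids, self.cache.stack,
            self.points, self.alpha, self.n_perm, self.seed, cache=self.cache,
        )
        return self.records_

    def selected_univariate(self) -> dict:
        """RS-optimized best model per variable (scan first if needed)."""
        if self.records_ is None:
            self.scan()
        return rs_select_per_variable(self.gd, self.records_, self.cache)

    def optimize(self) -> CausalModelRecord:
        """Scan (if needed), then run the multivariate search.

        Candidate variables enter in univariate rank order (all
        non-excluded variables: additions are gated by the reduced-model
        criteria (c)/(d), and the final model must pass the support
        criteria (a)/(b) against IBD). If the multivariate model fails
        the final support check, the search falls back to the best
        supported univariate model; if none exists either, raises.
        """
        best = self.selected_univariate()
        ranked = list(best)  # scan-rank order
        supported = [name for name in ranked if best[name].supported]
        # variables that pass the univariate criteria define the
        # multivariate hypothesis space. With one or none supported
        # (under a multi-factor truth each univariate test is
        # contaminated by the other factors' residual, so univariate
        # support becomes rare exactly when power is high), the search
        # proceeds anchored on the top-ranked variable: admission then
        # rests on the reduced-model criteria and the final model must
        # still pass the support criteria against IBD
        if supported:
            candidates = supported + [n for n in ranked if n not in supported]
        else:
            candidates = ranked
        if len(candidates) > 1:
            try:
                self.best_ = optimize_multivariate(
                    self.gd, self.ibd, candidates, self.variable_grids,
                    self.cache.stack, self.points, self.alpha, self.n_perm,
                    self.seed, cache=self.cache,
                )
                return self.best_
            except RuntimeError:
                pass
        if supported:
            self.best_ = best[supported[0]]
            return self.best_
        raise RuntimeError("no supported model (univariate or multivariate)")

    def summary(self):
        """Ranked scan table in the shape of the univariate results table."""
        import pandas as pd

        if self.records_ is None:
            raise RuntimeError("run scan() first")
        rows = [
            {
                "model": rec.label(),
                "r_GD~LR|IBD": rec.r_lr_given_ibd,
                "p_GD~LR|IBD": rec.p_lr_given_ibd,
                "r_GD~IBD|LR": rec.r_ibd_given_lr,
                "p_GD~IBD|LR": rec.p_ibd_given_lr,
                "RS_IBD": rec.rs_ibd,
                "mantel_p": rec.mantel_p,
                "excluded": rec.excluded,
                "supported": rec.supported,
            }
            for rec in self.records_
        ]
        return pd.DataFrame(rows)
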