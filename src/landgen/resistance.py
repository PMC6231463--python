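"""Parameterized transforms from landscape variables to resistance surfaces.

Each transform maps a raster variable to movement resistance >= 1, with a
variable-specific optimum at resistance 1 and a ceiling R_max:

* ``aspect``     — circular deviation from an optimal bearing, power-shaped:
                   ``R = 1 + (R_max - 1) * (delta/180)^x``
* ``gaussian``   — suitability peaked at an optimal value (elevation):
                   ``R = 1 + (R_max - 1) * (1 - exp(-(E - opt)^2 / (2 SD^2)))``
* ``power``      — min-max rescaled continuous variable (TC, slope):
                   ``R = 1 + (R_max - 1) * v^x``
* ``categorical``— class -> resistance lookup (vegetation, rivers, roads,
                   disturbance).

The contrast exponent ``x`` sharpens (>1) or flattens (<1) the response;
``R_max`` sets its magnitude. Transforms are registered by name so
parameter grids in config files can drive univariate model scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np

from .raster import Raster, check_aligned

__all__ = [
    "ResistanceParams",
    "aspect_resistance",
    "gaussian_resistance",
    "power_resistance",
    "categorical_resistance",
    "combine_surfaces",
    "ibd_surface",
    "build_surface",
    "category_permutations",
    "TRANSFORMS",
]


@dataclass
class ResistanceParams:
    """Parameters of one resistance hypothesis for one landscape variable.

    ``optimum`` is in the variable's units (degrees for aspect, metres for
    elevation); ``x`` and ``R_max`` are dimensionless; ``SD`` (metres) only
    applies to the Gaussian transform; ``category_map`` only to categorical
    variables.
    """

    variable: str
    transform: str
    optimum: float | None = None
    x: float | None = None
    r_max: float | None = None
    sd: float | None = None
    category_map: dict | None = field(default=None)

    def __post_init__(self):
        if self.r_max is not None and self.r_max < 1:
            raise ValueError("R_max must be >= 1")
        if self.x is not None and self.x <= 0:
            raise ValueError("x must be > 0")
        if self.sd is not None and self.sd <= 0:
            raise ValueError("SD must be > 0")

    def label(self) -> str:
        bits = [self.variable]
        if self.optimum is not None:
            bits.append(f"opt={self.optimum:g}")
        if self.x is not None:
            bits.append(f"x={self.x:g}")
        if self.r_max is not None:
            bits.append(f"Rmax={self.r_max:g}")
        if self.sd is not None:
            bits.append(f"SD={self.sd:g}")
        if self.category_map is not None:
            bits.append("map=" + ",".join(f"{k}:{v:g}" for k, v in sorted(self.category_map.items())))
        return "(" + " ".join(bits) + ")"


def _finish(template: Raster, r: np.ndarray, valid: np.ndarray) -> Raster:
    out = np.where(valid, r, template.nodata)
    return template.like(out)


def aspect_resistance(aspect: Raster, p: ResistanceParams) -> Raster:
    """Resistance from circular deviation of aspect from the optimum bearing.

    Flat cells (aspect nodata) take the surface's median resistance, since
    a level cell carries no directional information.
    """
    if p.optimum is None or not (0 <= p.optimum < 360):
        raise ValueError("aspect optimum must be in [0, 360)")
    v = aspect.valid()
    a = aspect.values
    delta = np.abs((a - p.optimum + 180.0) % 360.0 - 180.0)  # circular distance, [0, 180]
    r = 1.0 + (p.r_max - 1.0) * (delta / 180.0) ** p.x
    if v.any():
        med = float(np.median(r[v]))
    else:
        raise ValueError("aspect raster has no valid cells")
    full = np.where(v, r, med)
    # flat/nodata cells become valid cells at the median resistance
    return aspect.like(np.where(np.isfinite(full), full, med), nodata=aspect.nodata)


def gaussian_resistance(dem: Raster, p: ResistanceParams) -> Raster:
    """Gaussian suitability in elevation: resistance 1 at the optimum."""
    if p.sd is None:
        raise ValueError("gaussian transform requires SD")
    v = dem.valid()
    e = dem.values
    r = 1.0 + (p.r_max - 1.0) * (1.0 - np.exp(-((e - p.optimum) ** 2) / (2 * p.sd**2)))
    return _finish(dem, r, v)


def power_resistance(variable: Raster, p: ResistanceParams) -> Raster:
    """Power transform of a min-max rescaled continuous variable."""
    v = variable.valid()
    vals = variable.values[v]
    lo, hi = float(vals.min()), float(vals.max())
    if hi - lo == 0:
        raise ValueError(f"constant raster for {p.variable!r}: min-max rescale degenerate")
    scaled = np.zeros_like(variable.values)
    scaled[v] = (variable.values[v] - lo) / (hi - lo)
    r = 1.0 + (p.r_max - 1.0) * scaled**p.x
    return _finish(variable, r, v)


def categorical_resistance(classes: Raster, p: ResistanceParams) -> Raster:
    """Cell-wise class -> resistance lookup (vegetation, linear features)."""
    if not p.category_map:
        raise ValueError("categorical transform requires category_map")
    v = classes.valid()
    present = np.unique(classes.values[v]).astype(int)
    unmapped = [int(c) for c in present if int(c) not in p.category_map]
    if unmapped:
        raise ValueError(f"classes without mapped resistance: {unmapped}")
    if any(r < 1 for r in p.category_map.values()):
        raise ValueError("mapped resistances must be >= 1")
    r = np.full_like(classes.values, classes.nodata)
    for cls, res in p.category_map.items():
        r[v & (classes.values.astype(int) == int(cls))] = res
    return classes.like(r)


def category_permutations(classes: list, ranks: list[float]) -> list[dict]:
    """All class->resistance assignments from permuting rank values.

    Used by the univariate scan for vegetation-style variables, where the
    hypothesis space is the set of orderings of the classes.
    """
    if len(ranks) != len(classes):
        raise ValueError("need one rank value per class")
    return [dict(zip(classes, perm)) for perm in permutations(ranks)]


def combine_surfaces(surfaces: list[Raster]) -> Raster:
    """Cell-wise sum of aligned resistance surfaces, floored at 1.

    Nodata in any layer propagates. The floor keeps the combined surface a
    valid resistance surface (>= 1) while preserving cell ranking.
    """
    if not surfaces:
        raise ValueError("no surfaces to combine")
    check_aligned(*surfaces)
    first = surfaces[0]
    valid = np.ones(first.values.shape, dtype=bool)
    total = np.zeros(first.values.shape)
    for s in surfaces:
        v = s.valid()
        valid &= v
        total += np.where(v, s.values, 0.0)
    total = np.maximum(total, 1.0)
    return _finish(first, total, valid)


def ibd_surface(template: Raster) -> Raster:
    """The uniform "model IBD" null: resistance 1 on every valid cell.

    Resistance distances on this surface depend only on geometry, so it
    carries the pure distance effect against which landscape hypotheses
    are competed.
    """
    v = template.valid()
    return _finish(template, np.ones_like(template.values), v)


TRANSFORMS = {
    "aspect": aspect_resistance,
    "gaussian": gaussian_resistance,
    "power": power_resistance,
    "categorical": categorical_resistance,
}


def build_surface(variable: Raster, p: ResistanceParams) -> Raster:
    """Dispatch to the registered transform named by ``p.transform``."""
    try:
        fn = TRANSFORMS[p.transform]
    except KeyError:
        raise ValueError(
            f"unknown transform {p.transform!r}; known: {sorted(TRANSFORMS)}"
        ) from None
    return fn(variable, p)
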