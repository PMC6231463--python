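# landgen

Landscape-genetic inference for continuous populations: from multilocus
microsatellite genotypes and landscape rasters, through resistance
surfaces and circuit-theory resistance distances, to causal-modelling
selection among competing isolation hypotheses, MLPE model competition,
current-density mapping and corridor design.

The package is built around the workflow used in fine-scale studies of
elusive mammals sampled noninvasively — the motivating system is the
giant panda (*Ailuropoda melanoleuca*) population of the Qinling
Mountains, genotyped at 12 microsatellite loci from faecal DNA — but
every stage is generic: any diploid genotype table, any raster stack.

## What it computes

**Isolation hypotheses.** Genetic distance between individuals
(D<sub>ps</sub> = 1 − proportion of shared alleles) is tested against
three spatial models: isolation by distance (IBD), by barriers, and by
resistance (IBR). Under IBR, each landscape variable *v* is transformed
into a resistance surface with an optimum at resistance 1 and a ceiling
*R*<sub>max</sub> — e.g. for slope aspect with easterly optimum,

&nbsp;&nbsp;&nbsp;&nbsp;*R* = 1 + (*R*<sub>max</sub> − 1) · (Δ/180°)^*x*,

where Δ is the circular deviation from the optimal bearing and *x* is a
contrast exponent. The landscape becomes a resistor network (8-neighbour
cells, edge resistance = mean of the two cell resistances, ×√2 on
diagonals), and the IBR distance between two individuals is the
effective resistance between their cells, obtained from sparse
graph-Laplacian solves.

**Causal modelling.** A resistance model LR is supported over the
uniform-surface IBD null when the partial Mantel test GD ~ LR | IBD is
significant **and** GD ~ IBD | LR is not; competing models are compared
by relative support, RS<sub>1|2</sub> = r(GD~LR₁|LR₂) − r(GD~LR₂|LR₁).
A multivariate model is assembled by coordinate-wise search over
per-variable parameter grids, admitting a variable only if the enlarged
model beats its nested reduction (GD ~ full | reduced significant,
GD ~ reduced | full not).

**MLPE regression.** Pairwise distances are not independent, so fixed
effects are estimated with maximum-likelihood population effects: one
random effect per individual, shared by all of its pairs, fitted by
REML/ML via the Woodbury identity and compared across predictor subsets
with AICc, Akaike weights, VIF screening and the R²<sub>β</sub> effect
size.

**Corridors.** From the best-supported surface, a current-density map
(unit currents between all focal pairs) and least-cost candidate paths
between habitat components, selected under three siting criteria:
overlap with low-resistance/high-current terrain, reconnection across
major roads, and avoidance of farmland by 1 km and residences by 2 km.

**Synthetic data.** A first-class generator produces landscapes
(ridge-structured elevation, topographic-complexity zones, vegetation,
roads, disturbance), survey-style individual placement, and genotypes
whose expected D<sub>ps</sub> increases linearly with true resistance
distance — so the whole pipeline can be validated end to end by
parameter recovery, without any field data.

## Worked example

Simulate a small world whose true resistance model is easterly aspect +
topographic complexity (TC), then let the pipeline find it:

```python
from landgen import (SimulationConfig, simulate_landscape, place_individuals,
                     simulate_genotypes, resistance_matrix, dps_distance,
                     diversity_summary, probability_of_identity,
                     allele_frequencies, build_surface, combine_surfaces,
                     ibd_surface, CausalAnalysis)
from landgen.simulate import default_true_model, individual_ids, reduced_scan_grids

cfg = SimulationConfig(seed=1, grid_size=32, n_individuals=40)
stack = simulate_landscape(cfg)
true = combine_surfaces([build_surface(stack[p.variable], p)
                         for p in default_true_model()])
points, sexes = place_individuals(cfg, ibd_surface(stack["dem"]))
R = resistance_matrix(true, points, labels=individual_ids(40))
table = simulate_genotypes(cfg, R, points, sexes)

div = diversity_summary(table)
pid, pid_sib = probability_of_identity(allele_frequencies(table))
print(f"mean A = {div.mean_a:.2f}   H_O = {div.mean_ho:.3f}   H_E = {div.mean_he:.3f}")
print(f"P(ID) = {pid:.3g}   P(ID)sib = {pid_sib:.3g}")

gd = dps_distance(table)
analysis = CausalAnalysis(gd, {v: stack[v] for v in reduced_scan_grids()},
                          points, reduced_scan_grids(), n_perm=499, seed=1)
best = analysis.optimize()
print(f"best model: {best.label()}")
print(f"RS vs IBD = {best.rs_ibd:.4f}   supported = {best.supported}")
```

Output:

```
mean A = 4.58   H_O = 0.417   H_E = 0.496
P(ID) = 5.5e-07   P(ID)sib = 0.00141
best model: (aspect opt=90 x=2 Rmax=500) + (tc x=10 Rmax=500)
RS vs IBD = 0.6749   supported = True
```

The marker panel distinguishes individuals (a random pair matches with
probability 5.5 × 10⁻⁷; full sibs 1.4 × 10⁻³), diversity is in the range
typical of mammalian microsatellites, and the causal-modelling search
selects exactly the generating variable pair — aspect and TC — with the
combined model strongly supported over the pure-distance null
(RS = 0.67). `analysis.summary()` prints the full ranked scan in the
shape of a univariate results table.

A command-line interface mirrors the stages
(`landgen genotypes | circuit | stats | causal | mlpe | corridors | synth`);
run `landgen --help`.

## Layout

| module | contents |
|---|---|
| `landgen.genotypes` | genotype I/O, filtering, individual collapsing, diversity, P(ID), D<sub>ps</sub> |
| `landgen.raster` | ESRI ASCII grids, slope/aspect/TC terrain derivatives |
| `landgen.resistance` | parameterized resistance transforms and surface algebra |
| `landgen.circuit` | raster→graph, effective resistance, current maps |
| `landgen.spatial` | Mantel, partial Mantel, spatial autocorrelograms |
| `landgen.causal` | causal-modelling criteria, RS, univariate scan, multivariate search |
| `landgen.mlpe` | MLPE Model/Results, VIF, AICc competition, R²<sub>β</sub> |
| `landgen.corridors` | disturbance buffers, candidate paths, corridor selection |
| `landgen.simulate` | synthetic landscapes, genotypes and the recovery benchmark |

See `docs/methods.md` for the statistical methods, modelling assumptions
and numerical choices.
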