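# Methods

## Model and assumptions

The package represents the nutrient-regulation assessment as a discrete
Bayesian belief network over 14 variables. Every variable has a small
ordered state set; grid cells are treated as exchangeable rows (no
spatial autocorrelation enters the probabilistic model — coordinates are
carried through only so results can be mapped). The graph encodes the
causal reading of the system: landscape type (Hügelland / Geest /
Marsch) drives the site conditions (soil texture, slope), which drive
water retention (field capacity), fertility (natural nutrient
availability), loss pathways (nitrate leaching, wind and water erosion),
while the land-cover-derived 0–5 ES-matrix score enters as the
"preliminary" potential. The nutrient-regulation potential node combines
these; its low/medium/high reclassification is compared against demand
(the cell's nitrogen surplus class) to yield a binary
sustainable/unsustainable budget. The exact arc set is a modelling
choice, not a data product, and can be overridden when building the
network (`build_network(arcs=...)`).

## Inference

Posteriors are computed exactly by variable elimination with a min-fill
elimination order; correctness is independent of the order (tested
directly against full-joint enumeration and against permuted orders).
Probabilities stay in linear space: with at most fourteen factors of
magnitude ≤ 1, the product is nowhere near underflow and the final
normalization removes the evidence mass. Evidence with probability zero
raises `ImpossibleEvidenceError` rather than returning NaNs. MAP
queries break posterior ties by declared state order (first state wins),
which keeps per-cell class maps deterministic.

## Discretization

The default class limits, with explicit boundary ownership so every
value lands in exactly one class:

| variable | low | medium | high |
|---|---|---|---|
| field capacity (mm) | [0, 200) | [200, 300] | (300, ∞) |
| nutrient availability (kmol_c/ha) | [0, 300) | [300, 600] | (600, ∞) |
| nitrogen surplus (kg N/ha) | (−∞, 40] | (40, 60] | (60, ∞) |
| slope (°) | [0, 0.2039] | (0.2039, 0.6581] | (0.6581, ∞) |

The printed "200–300"-style ranges own both endpoints; the surplus and
slope bands are closed on the right. Negative nitrogen surplus (net
removal) is legal input and maps to demand `low`. Slope classes are a
quantile classification; `quantile_breaks` recomputes breaks as the
⌈k·n/3⌉-th order statistics when a user wants data-driven bands, and the
shipped defaults are the breaks above. The ES matrix (land-cover class →
0–5 score) ships empty and must be supplied via config; the synthetic
generator carries its own table for its synthetic land-cover vocabulary.

## Learned and expert parameters

Ten observed nodes are estimated by maximum likelihood with a Dirichlet
pseudocount α per cell: `(count + α) / (parent count + α·K)`. The
pipeline default is α = 1 (Laplace), which keeps strata that a study
area lacks entirely — e.g. Marsch at the local scale — well defined;
α = 0 gives the plain MLE and deliberately refuses unobserved parent
combinations. Missing values are handled complete-case (the intended
input tables are complete); EM is out of scope.

Four nodes cannot be learned from the grid columns and carry generated
expert-style CPTs:

- **erosion** — the ordinal maximum of wind and water erosion folded to
  low/medium/high, with 0.7 mass on that class and 0.15 on each
  neighbour (clipped at the scale ends, renormalized);
- **potential** — the preliminary potential shifted −1/0/+1 steps
  according to a favourability score (ranks of field capacity + nutrient
  availability − leaching − erosion, range −4…+4; shift down at ≤ −2, up
  at ≥ +2), with 0.5 mass on the shifted state and 0.25 on each
  neighbour. The peak mass is deliberately < 1 so conditioning broadens
  rather than replaces the matrix score; expected potential rank is
  non-decreasing in the score (tested);
- **reclassified potential** and **budget** — deterministic point-mass
  encodings of the reclassification map ({P_no, P_1}→low, {P_2, P_3}→
  medium, {P_4, P_5}→high) and the budget rule (sustainable iff
  potential rank ≥ demand rank; the tie is configurable and defaults to
  sustainable, since a balance is not a deficit).

All four heuristics and the expert node set itself are configuration
(`ExpertCPTParams`), because which nodes are expert-elicited and how is
a judgement call, not a data product.

## Sensitivity analysis

For a target node and evidence e, the analysis differentiates every
target-state posterior with respect to every CPT entry θ under
proportional covariation (the rest of θ's column is rescaled to keep it
normalized; if the remaining mass is zero it is spread uniformly). Both
the unnormalized posterior N_s(t) = P(target = s, e) and the normalizer
D(t) = P(e) are affine in t under this perturbation, so two exact
inference evaluations (t = 0 and t = 1) determine the derivative of the
ratio in closed form — no step-size error. A central finite-difference
routine is provided as an independent cross-check. Parameters of nodes
that cannot influence the target (their auxiliary parameter-parent is
d-separated from the target given the evidence) are exactly zero by
construction. Per-node influence is aggregated as the maximum absolute
derivative over the node's parameters and ranked descending.

Arc strength is the mutual information I(parent; child) in bits under
the network joint — symmetric, nonnegative, zero exactly at
independence.

## Cross-validation

`kfold_cv` shuffles records with a seed, splits them into k near-equal
folds, learns CPTs on k−1 folds, and predicts the held-out node per
record as the MAP state given all other observed variables; it reports
per-fold accuracy and mean log-loss plus their averages. Posterior
probabilities are floored at 1e-300 in the log-loss only, to keep a
zero-probability outlier from collapsing the whole fold score to
infinity. Identical seeds give identical folds and scores.

## Synthetic generator

The generator emulates the statistical structure the analysis assumes:
landscape type conditions texture, slope class, land cover and surplus
class; texture conditions field capacity, nutrient availability,
leaching and wind erosion; slope conditions water erosion. Continuous
values are drawn uniformly inside per-class emission ranges that are
nested in the discretization intervals, so discretizing a generated
record returns exactly the sampled classes — downstream computations see
only the classes, so richer within-class shape would change nothing.
The default tables encode the qualitative regional contrasts (Geest
sandy, wind-exposed, leaching-prone, higher demand; Marsch flat;
Hügelland hilly with silt/clay soils; the local Bornhöved-style region
has no Marsch and demand peaking at medium) at plausible magnitudes.
They are fixtures chosen once for realism, **not** calibrated to any
published probabilities — so passing tests demonstrate that the
machinery recovers and propagates whatever structure the data contain,
not that these numbers describe the real region. Real-data features the
generator does not emulate: spatial autocorrelation, polygon geometry,
measurement error, and missing values.

## Problem sizes and numerical choices

Default runs use 2,000-cell grids (pipeline), 4,000–10,000 cells for
distributional tests, and 50,000 cells for parameter recovery — at
50,000 cells every well-supported conditional (expected parent count
≥ 200) is recovered within ±0.02 by plain MLE. CPT columns must sum to
1 within 1e-9; posteriors normalize within 1e-9; inference agrees with
enumeration to better than 1e-10. The min-fill tie-break is
alphabetical, making elimination orders (and hence run times)
reproducible.

## Known limitations

The budget node is a coarse ordinal comparison, not a mass balance; the
nitrogen surplus is an input, not computed from fertilization and yield
terms. The expert CPT heuristics are transparent stand-ins for elicited
tables — any real application should replace them via configuration.
Only complete-case data are supported, and only a single nutrient
(nitrogen) is modelled.
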