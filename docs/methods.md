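# Methods

## The problem

Clinical users of variant pathogenicity predictors must choose one tool
among many, and the right choice depends on the deployment context: how bad
is a missed pathogenic variant, how bad is a false alarm, and — for tools
that abstain on low-confidence variants — how costly is it to come away
with no computational evidence at all.  `costspace` answers the question
"which classifier is cheapest *where*?" exactly, for every possible cost
context at once.

## Cost models

A predictor is summarised by its sensitivity `se`, specificity `sp` and
coverage `alpha` (1 − rejection rate), all estimated on a labeled benchmark
set.  The population context enters through `rho`, the frequency of
pathogenic variants among those tested.

**MISC** (no rejection term) prices a deployment as

    c = rho (1 − se) c0 + (1 − rho) (1 − sp) c1,

with `c0` the cost of annotating a pathogenic variant benign and `c1` the
converse.  Normalising by `cT = c0 + c1` gives `rc = rc(rc1)`, a *line* in
the normalised false-positive cost `rc1 = c1/cT`.  The clinical space is
the open interval `I = (0, 1)` of `rc1` values.

**MISC+REJ** adds the rejection cost `c2`:

    c = alpha rho (1 − se) c0 + alpha (1 − rho) (1 − sp) c1 + (1 − alpha) c2.

After normalising by `cT = c0 + c1 + c2` and eliminating
`rc2 = 1 − rc0 − rc1`, the normalised cost is an affine function of
`(rc0, rc1)` on the triangle `T` with vertices (0,0), (1,0), (0,1).  Each
point of `T` is a clinical scenario; the corner (0,0) is the scenario where
only rejection costs anything, and the hypotenuse `rc0 + rc1 = 1` is the
no-rejection-cost edge on which MISC+REJ with `alpha = 1` reduces exactly
to MISC.

Error rates are **conditional on acceptance**: `se = TP/Np` and
`sp = TN/Nb` are computed over covered variants only, while
`alpha = N/Ntot` counts the rejections.  The model multiplies the error
terms by `alpha` itself; putting rejections into the denominators of
`se`/`sp` as well would double-count abstention.

## Partitioning the clinical space

*MISC.*  Pairwise cost lines cross at most once.  All in-range crossings
are collected, deduplicated and sorted; between consecutive crossings no
ordering change can occur, so the predictor with minimal cost at the
interval midpoint is minimal on the whole open sub-interval.  Adjacent
intervals with the same winner are merged.  Interval lengths are the
fractions of clinical scenarios each predictor wins.

*MISC+REJ.*  Every pair of predictors defines an equal-cost line in the
`(rc0, rc1)` plane.  The lines crossing `T` carve it into convex faces; no
cost-plane crossing occurs inside a face, so the winner at the face's
vertex-average point wins the whole face.  The pipeline is:

1. **Boundary lines** — exact coefficients from the difference of the two
   cost planes; pairs with identical `(se, sp, alpha)` have coincident
   planes (flagged, no line), pairs whose difference is a nonzero constant
   have an empty locus (one predictor dominates everywhere).
2. **Arrangement** — duplicates of other lines or of the triangle sides are
   removed by canonicalised-coefficient comparison; lines meeting the
   closed triangle in at most a point are dropped.  Vertices are all
   pairwise intersections inside the closed triangle (concurrent lines —
   e.g. the always-concurrent triple `l_ij, l_jk, l_ik` — share a single
   vertex because coordinates are exact); edges are maximal segments
   between consecutive vertices along each line and each side.
3. **Face extraction** — half-edge traversal: outgoing edges at each vertex
   are sorted by exact angle (quadrant + cross-product comparator, no
   trigonometry), and following the clockwise successor of each reverse
   edge traces every bounded face counter-clockwise.  The single clockwise
   cycle is the outer face and is discarded.  The traversal is accepted
   only if the shoelace areas of the bounded faces sum to exactly 1/2.
4. **Assignment and merging** — cheapest predictor at the vertex average of
   each face (exact comparison, ties broken by input order and recorded),
   then faces are merged per winner.  Region areas over 1/2 are the
   fractions of clinical scenarios won.

**Grouped driver.**  For large predictor sets the partition can also be
computed in groups: partition each group of at most `group_size`
predictors, keep the survivors (nonzero area), and repeat until one direct
run remains.  A predictor dominated within its group is dominated in the
full set, so survivors-only merging is safe.  With exact arithmetic the
direct run is itself robust; the driver is kept because it reproduces the
recommended workflow for big tool collections and is faster for
`N` near 17.

## Numerical policy

All geometry and cost comparison runs on `fractions.Fraction`.  Float
inputs are converted through their shortest decimal representation, so a
table entry `0.92` is the rational 23/25, not its binary approximation.
Consequences:

- faces tile the triangle *exactly* (area sum equals 1/2 as a rational);
- coincident lines and concurrent intersection points are detected by
  equality, not tolerance — there is no vertex-merge radius and no sliver
  threshold to tune, and degenerate inputs (duplicate predictors,
  `alpha = 0`, `rho = 0.001`) need no special casing;
- results are bit-reproducible across runs and platforms.

Public cost-evaluation functions return floats for convenience; the
`1e-12`/`1e-10` tolerances quoted in tests cover only that final
float conversion.

Scenario endpoints (`rc1 ∈ {0, 1}`, triangle edges) are accepted for cost
evaluation; partitions are defined on the open interior, and crossings
landing exactly on 0 or 1 are discarded.

## Synthetic study conditions

`generate_profiles` draws `se, sp ~ U(0.5, 1)` and `alpha ~ U(0.4, 1)`,
rounded to 3 decimals — the plausible operating range of published
pathogenicity predictors (the 17-tool collection this framework was built
around spans coverages 0.43–1.0), at the precision performance tables are
printed with.  `generate_labeled_table` emulates a benchmark set's
statistical structure only: class labels Bernoulli(`rho`), acceptance
Bernoulli(`alpha`), correctness among accepted calls Bernoulli(`se` or
`sp`).  It deliberately does not model predictor score distributions,
inter-tool correlation, or variant biology, so passing tests demonstrate
correctness of the cost framework's machinery, not the field performance
of any real tool.

The Monte-Carlo oracle samples `rc1 ~ U(0,1)` (MISC) or `(rc0, rc1)`
uniform on `T` (MISC+REJ, via the square fold: reflect samples with
`rc0 + rc1 > 1`), counts winners with the same first-in-input-order
tie-break as the partitions, and is the independent check that exact
interval lengths and region areas are winning *fractions*.

## Problem sizes

The verification suite compares exact partitions with 10^6-point
Monte-Carlo counts over 52 random predictor sets (sizes cycling 2–17) at
`rho ∈ {0.001, 0.01, 0.1, 0.5}`, for both models — roughly two hundred
partition/oracle pairs.  With 10^6 samples the binomial standard error of
a fraction is at most 5·10⁻⁴, so the ±0.005 agreement bound is a ten-sigma
check.  Parameter recovery uses 10^4-variant tables, where 3 binomial
standard errors separate recovery failure from sampling noise.

## Defaults

- `rho = 0.5` — the headline comparisons treat the tested population as
  strongly enriched for pathogenic variants; sweeps over
  `rho ∈ [0.001, 0.5]` are one CLI flag away.
- `group_size = 8` in the grouped driver (middle of the recommended 5–10
  working range).
- Plug-in band endpoints are *accepted* (a score exactly at a threshold is
  called): the rejection band is the open interval between the thresholds.
  `inclusive=False` flips this.

## Known limitations

- Estimation offers plain binomial standard errors only; no confidence
  intervals on region areas are propagated from the uncertainty of
  `(se, sp, alpha)`.
- Costs are assumed constant across a deployment; scenario-weighted
  (prior-integrated) expected cost over regions is out of scope.
- The exact-arithmetic pipeline expects decimal inputs of modest precision
  (performance tables); pathological rationals with enormous denominators
  will slow it down, though never make it wrong.
- `rho` is a single scalar per analysis; gene- or panel-specific mixtures
  of prevalences must be run as separate analyses.
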