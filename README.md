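# costspace

Cost-optimal comparison of binary classifiers with a reject option, across
**all** possible deployment cost scenarios at once.

Variant pathogenicity predictors (REVEL, CADD, PON-P2, ...) classify
missense variants as pathogenic or benign, and many abstain on
low-confidence variants.  Picking a tool by AUC or MCC ignores the clinical
context: the relative costs of a missed pathogenic variant (`c0`), a false
alarm (`c1`), and a rejected prediction (`c2`) differ between screening,
diagnostics, and guideline settings.  `costspace` treats each predictor as
an operating point `(se, sp, alpha)` — sensitivity, specificity, coverage —
and computes, exactly, *where* in cost space each tool has the lowest
expected normalised cost:

- **MISC** (misclassification only):
  `rc = [(1−ρ)(1−sp) − ρ(1−se)]·rc1 + ρ(1−se)` — a line in the normalised
  false-positive cost `rc1 ∈ (0,1)`.  The clinical interval is split
  exactly at the pairwise line crossings.
- **MISC+REJ** (with rejection):
  `rc = [αρ(1−se)+α−1]·rc0 + [α(1−ρ)(1−sp)+α−1]·rc1 + 1−α` over the
  triangle `T = {rc0, rc1 ≥ 0, rc0+rc1 ≤ 1}`.  Pairwise equal-cost lines
  carve `T` into convex faces; faces are assigned to their cheapest
  predictor and merged into regions whose area fractions are the fractions
  of clinical scenarios each tool wins.

All geometry runs in exact rational arithmetic: faces tile the triangle
with area summing to exactly 1/2, and degenerate inputs (coincident
predictors, concurrent boundary lines, zero coverage, prevalence 0.001)
need no tolerances.  A Monte-Carlo winner-counting oracle provides
independent verification, and estimation utilities derive `(se, sp, alpha)`
from labeled prediction tables, including plug-in rejection bands on
continuous scores (e.g. reject REVEL scores between 0.249 and 0.733).

## Worked example

Compare a full-coverage ensemble predictor with a more accurate but
heavily-abstaining one (coverage 0.46, i.e. a 54% rejection rate; the
specificities shown are illustrative), at pathogenic-variant frequency
ρ = 0.5:

```python
from costspace import PredictorProfile, partition_interval, partition_triangle
from costspace import interval_fractions

revel = PredictorProfile("REVEL", se=0.92, sp=0.94, alpha=1.0)
ponp2 = PredictorProfile("PON-P2", se=0.96, sp=0.95, alpha=0.46)

print(interval_fractions(partition_interval([revel, ponp2], rho=0.5)))
for region in partition_triangle([revel, ponp2], rho=0.5).regions:
    print(region.predictor, float(region.area_fraction))
```

prints

```
{'PON-P2': 1.0}
REVEL 0.9147035776955367
PON-P2 0.08529642230446328
```

Ignoring rejection (MISC), PON-P2's better sensitivity *and* specificity
make it optimal in every scenario.  Accounting for its 54% rejection rate
(MISC+REJ) reverses the picture: REVEL is cheaper in ~91% of clinical
scenarios, and PON-P2 survives only near the hypotenuse `rc0 + rc1 = 1`,
where rejection is almost free.  This is exactly the kind of
context-dependent reversal that performance metrics alone cannot show.

The same analysis from the shell:

```
costspace partition --model miscrej --profiles profiles.tsv --rho 0.5 --out report.json
costspace estimate  --table variants.tsv --rules rules.json --out profiles.tsv
costspace oracle    --profiles profiles.tsv --model miscrej --rho 0.5 --n 1000000 --seed 1
costspace sweep     --profiles profiles.tsv --rho 0.001 --rho 0.01 --rho 0.1 --rho 0.5
costspace simulate  --n-predictors 17 --profiles-out synthetic.tsv
```

Profile tables are CSV/TSV with header
`name,sensitivity,specificity,coverage`; labeled prediction tables have
`variant_id,label` plus one `<name>_call` or `<name>_score` column per
predictor.

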