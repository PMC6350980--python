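# pbfaudit

Audit targeting for performance-based financing (PBF) verification.

PBF programs pay health facilities fee-for-service bonuses for reported
service volumes, which creates an incentive to over-report. Programs
counter this with independent verification (audits that reconcile reported
counts against facility registers), but auditing every facility every
quarter is expensive. `pbfaudit` is a toolkit for program analysts and
health economists who want to study **which facilities to audit**: it
compares random-sampling audit designs against adaptive (prior-offender)
and classifier-ranked targeting, and prices the difference with a linear
verification cost model.

## What it implements

**The over-reporting label.** For each facility-quarter, the bonus is
computed twice — once from reported counts, once from verified counts —
as the price-weighted sum over the nine incentivized indicators,
B = Σᵢ qᵢ·pᵢ. A quarter is flagged as over-reporting when

```
B_reported ≥ (1 + τ) · B_verified,   τ = 0.10
```

(10% or more, inclusive; a positive report against zero verified services
is also flagged).

**Audit strategies.** Simple random sampling (SRS) of 50% of facilities;
SRS stratified by district; a mixed design (half the 28-facility sample
from the previous quarter's offenders, half from the rest); an
offenders-first design (fill with prior offenders, then top up at
random); and top-k selection by classifier risk score.

**Classifiers.** Naive Bayes (normal / kernel / supervised-discretized
densities), logistic regression (ridge 0–10⁻²), SVM (linear, polynomial
2–3, radial width 10⁻³–1), and random forest (50–500 trees, 1–9 features
per split), each exposing calibrated-in-[0,1] risk scores, evaluated by
10-fold cross-validation and by a train-on-Q1 / predict-Q2–Q4 protocol.

**The cost model.** Auditing n facilities of which a share p are detected
over-reporters costs

```
tc = n[p(mc − s) + (1 − p)mc] + fc = n(mc − p·s) + fc
```

with marginal cost mc per audit, sanction s recovered per detection, and
fixed cost fc; per facility, `mc − p·s + afc`. Better targeting raises p
and lowers cost linearly with slope −s.

**The panel generator.** Because operational verification data are not
public, a calibrated simulator produces facility-quarter panels with the
structure such data exhibit: 140 facilities in 18 districts (10 PBF, 8
non-PBF), 15–23% quarterly over-reporting prevalence, strong
quarter-to-quarter persistence (≈0.58), and a heavy never-offending mass
(≈58% of facilities). See `docs/methods.md` for the generative model.

## Worked example

```python
from pbfaudit import (SimConfig, generate_panel, label_panel,
                      offender_distribution, sampling_yield, srs,
                      offenders_first, per_facility_cost, relative_savings)

panel = generate_panel(SimConfig(seed=1))
labels = label_panel(panel)
print(offender_distribution(labels))

ids = sorted(labels["facility_id"].unique())
flagged_q2 = set(labels.query("quarter == 2 and over_report == 1")["facility_id"])
prior = labels.query("quarter == 1 and over_report == 1")["facility_id"].tolist()
y_srs = sampling_yield(lambda s: srs(ids, 0.5, s), flagged_q2, reps=1000, seed=0)
y_off = sampling_yield(lambda s: offenders_first(ids, prior, 28, s),
                       flagged_q2, reps=1000, seed=0)
print(f"Q2 detection yield: SRS {y_srs:.1%}, offenders-first {y_off:.1%}")
print(f"per-facility cost: ${per_facility_cost(y_srs, 800, 1900, 1600):,.0f} -> "
      f"${per_facility_cost(y_off, 800, 1900, 1600):,.0f} "
      f"({relative_savings(y_srs, y_off, 800, 1900, 1600):.0%} saved)")
```

Output:

```
                    n_facilities    percent
n_quarters_flagged
0                             81  57.857143
1                             32  22.857143
2                             12   8.571429
3                              9   6.428571
4                              6   4.285714

Q2 detection yield: SRS 23.5%, offenders-first 55.4%
per-facility cost: $1,954 -> $1,348 (31% saved)
```

Reading it: 81 of the 140 simulated facilities (57.9%) never over-report
while 6 (4.3%) game all four quarters. Auditing 28 facilities chosen from
the first quarter's offenders catches over-reporters at more than twice
the rate of a 70-facility random sample (55.4% vs 23.5% of audited
facilities), and feeding those detection rates into the cost model (mc =
$800, s = $1,900, afc = $1,600) cuts the average verification cost per
facility by about a third.

A `pbfaudit` console script orchestrates the same pipeline from the shell
(`pbfaudit simulate | label | plan | fit | evaluate | cost | full`) with a
YAML run configuration and a single master seed; every artifact is written
with a manifest recording the config hash.

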