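# Methods

## Exposure model

A well is an exposure source during its **activity window**: the closed
interval from its earliest recorded activity date to the same calendar date
30 years later (`lifespan_years` configurable; a Feb 29 anniversary falls
back to Feb 28). The earliest activity date is the minimum over the spud,
completion, and first-production dates — the conservative, earliest-start
reading. Records missing coordinates or all three dates are excluded before
harmonization and tallied by reason (a record missing both is tallied under
missing coordinates). Date supplements from secondary sources fill missing
dates only; a supplement never overwrites a present date, and conflicting
dates are logged and discarded. Wells are keyed by `source_name:source_id`;
cross-source duplicates are deliberately not collapsed, since no defensible
national dedup rule exists without richer attributes.

A school is **exposed at radius r** during a school year (July 1–June 30)
when at least one well whose activity window overlaps the year (closed
intervals on both sides) lies at geodesic distance ≤ r — boundary inclusive,
so a well active on any single day of the year at exactly r meters counts.
Buffers default to 800 m, 1 km, 1.6 km, 5 km, and 10 km.

### Distance and the spatial index

Distance is the haversine great-circle distance on a sphere of mean radius
6,371,008.8 m. At buffer scales of 0.8–10 km the relative error versus an
ellipsoidal geodesic is below 0.6%, which is immaterial against the coarse
buffer radii themselves; the sphere radius is a parameter for anyone who
wants a different convention.

The production path indexes active wells with a k-d tree on unit-sphere 3-D
coordinates. Chord length is strictly monotone in central angle, so a
chord-radius ball inflated by a relative 10⁻⁹ (10⁻⁶ for nearest-neighbor
ties) is a guaranteed superset of the true candidates; candidates are then
refined with the *same* vectorized haversine comparison the exhaustive scan
uses. Results are therefore bit-identical to brute force, which the test
suite verifies over 100 random scenes. Exact-distance ties (e.g., co-located
wells) break to the lexicographically smallest well id in both paths.

### Prevalence summaries

Percent-exposed values are rounded half-up to one decimal. The denominator is
an explicit parameter: `full_roster` divides by every school on the roster,
`analysis_sample` by schools with positive enrollment. The two conventions
differ in published national tallies, so neither is hard-coded.

## School characteristics

Race/ethnicity categories are modeled as mutually exclusive (Hispanic of any
race vs. non-Hispanic groups); free/reduced-lunch eligibility is an
income proxy independent of them. Proportions divide category counts by total
enrollment; schools with missing or zero enrollment are excluded (zero makes
the proportions undefined), and a missing category count with enrollment
present is treated as zero and flagged rather than excluded. Predominance is
strict: share > threshold, so a school at exactly 50% is *not* predominant.
The 40%/60% thresholds are computed alongside 50% for sensitivity use, and
nest by construction (60% flags ⊆ 50% flags ⊆ 40% flags). RUCA codes 1–3/
4–6/7–10 collapse to Metropolitan/Micropolitan/Rural; a ZIP absent from the
RUCA table yields a missing code and a Rural class.

## Association estimators

The primary estimator is bivariable logistic regression with stratum fixed
effects: one intercept per state (or county), no grand intercept, plus the
exposure indicator. The fit is Newton–Raphson with step-halving on the
binomial log-likelihood of counts collapsed to (stratum × exposure) cells —
algebraically identical to the individual-level likelihood and orders of
magnitude faster. Convergence requires max |score| < 10⁻⁸ or relative
log-likelihood change < 10⁻¹⁰ within 100 iterations; non-convergence raises
with the iteration trace. Strata whose outcome never varies are dropped
before fitting (their intercepts diverge and they carry no information about
β) and reported in `n_strata_dropped`; |β̂| > 30 is treated as separation and
raised. Wald 95% CIs use the inverse observed information. The test suite
cross-checks the fit against an independent maximum-likelihood implementation
on dummy-encoded designs.

The Mantel–Haenszel pooled OR, Σaᵢdᵢ/nᵢ ÷ Σbᵢcᵢ/nᵢ with the
Robins–Breslow–Greenland variance, is implemented as a verification oracle
over the same stratified tables. Zero cells drop out natively (no continuity
correction); a zero pooled numerator or denominator flags the result
inestimable rather than raising. Empty subset cells in the association grid
are likewise flagged, not raised.

The suite lays results out as a grid of buffer × characteristic ×
subset: pooled (state or county FE), per-urbanicity (state FE within class),
per-state (unadjusted within-state bivariable fits — a fixed effect would be
degenerate), and a top-producing-states subset (AK, CO, LA, ND, NM, OK, PA,
TX, WV). No multiple-testing adjustment is applied; results are meant to be
read for magnitude, direction, and precision. Descriptive summaries report
mean, median, and IQR of student-body percentages per exposure class, with
quantiles interpolated linearly at rank 1 + (n−1)p.

## Synthetic data

The generator emulates the *structure* of a national well registry and school
roster, not real geography. Wells follow a Thomas-like clustered process
(uniform cluster centers inside rectangular pseudo-states, Gaussian scatter,
default 80 clusters / 4,000 wells, spread 2 km) with spud/completion/
first-production dates over 1950–2023 and exact-count missingness: stated
fractions of records (5% dates, 2% coordinates, on disjoint record sets) are
blanked deterministically so fixtures hit printed totals exactly. A
supplement file restores dates for half of the date-blanked wells and appends
a few registry-absent wells, exercising the merge semantics.

Schools are placed by an urbanicity mix of 0.746/0.112/0.142
(Metro/Micro/Rural — the observed national mix) around per-state settlement
cores, 60% of which are anchored near well fields; towns and drilling regions
co-occur, and this anchoring gives the generated population a 10 km exposure
prevalence near the ~29% observed nationally (≈3% at 800 m, ≈8% at 1.6 km at
the defaults). True exposure is computed *by the exposure engine itself* on
the harmonized wells, so the emitted truth file is consistent with
recomputation from the emitted CSVs by construction, and the tests verify it.

Each predominance flag is drawn from
logit p = baseline<sub>state</sub> + β·exposed, with state baselines jittered
(SD 0.3) around logits of the observed national predominance rates
(0.486/0.185/0.507) and planted β defaulting to the observed 10 km
associations (OR 1.37/0.92/1.14). One structural constraint matters:
predominantly-White and predominantly-Hispanic cannot both hold, since two
shares cannot both exceed one half. The White flag is drawn first from its
exact logit model; the Hispanic flag is drawn from its logit model *among
schools not flagged White*; FRL is independent and exact. Consequently the
marginal Hispanic OR recovered by the pipeline is attenuated below the
planted conditional value — parameter-recovery and CI-coverage checks
therefore use the FRL characteristic, whose generative model is exactly the
fitted one. Demographic counts are then drawn uniformly inside the
flag-consistent share region with a 0.02 margin around the 50% threshold;
with enrollment ≥ 60 the rounding error of count/enrollment (≤ 1/120) cannot
flip a flag, so roster-derived flags equal the drawn truth flags exactly.
Enrollment is uniform on 60–1,500, and an exact count of schools
(default fraction 1,671/101,390) has enrollment blanked to exercise the
roster exclusion.

What the generator does **not** emulate: real U.S. geography and spatial
autocorrelation beyond simple clustering, correlation between urbanicity and
demographics, production volumes, well abandonment records, or registry
field-name quirks beyond a configurable column mapping. Passing tests
demonstrate the pipeline's arithmetic and estimators, not claims about any
real population.

### Worked fixtures

For exact-arithmetic checks the worked fixture places schools on a ~25 km
grid and gives each school designated exposed exactly one active well — at
the school itself for the tightest radius class, otherwise offset east to the
midpoint of its radius band — with no well within 10 km of any other school.
Requested per-radius exposed counts and per-class student-enrollment totals
are therefore reproduced exactly by the engine, at any scale up to ~400,000
schools. Infeasible requests (counts exceeding the roster, non-nested counts,
radii above 10 km) raise at construction.

## Problem sizes and numerical choices

Defaults were chosen so a full desktop run is comfortable: the national-scale
worked fixture (101,390 schools, 29,649 wells) runs the indexed engine in a
few seconds; synthetic disparity scenes use 20,000 schools × 4,000 wells
(50,000 for null-calibration checks); oracle-equivalence tests use 100 scenes
of 30–180 schools × 60–420 wells; CI coverage uses 500 replicates at
n = 20,000 with 10 strata. Randomness flows through named, fixed substreams
of a single seed, so adding one entity type never perturbs another and
identical (config, seed) pairs produce byte-identical files.

## Known limitations

- Exposure is a distance surrogate: no production volume, flaring, wind, or
  plume modeling, and no conventional/unconventional distinction.
- The haversine sphere slightly distorts distances versus an ellipsoid
  (< 0.6% relative); at these buffer radii this cannot change conclusions,
  but the radius is configurable rather than the geodesic model.
- Fixed-effects logistic drops outcome-invariant strata; software that
  retains them via penalization would differ slightly.
- The generator's planted Hispanic effect is conditional, not marginal (see
  above); only the FRL channel is an exact logit simulation.
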