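# schoolwells

Proximity-based exposure assessment of schools to oil and gas development
(OGD), with a sociodemographic disparity analysis. The package asks two
questions about a roster of schools and a registry of wells:

1. **Who is exposed?** For each school, the geodesic distance to the nearest
   well that was *active* during a school year, and the number of active wells
   within circular buffers (800 m, 1 km, 1.6 km, 5 km, 10 km). A well is
   treated as active from its earliest recorded activity date (minimum of
   spud, completion, and first-production dates) until 30 years later; a
   school year runs July 1–June 30.
2. **Is exposure patterned by who attends the school?** Schools are
   dichotomized as "predominantly" non-Hispanic White, Hispanic, or
   free/reduced-lunch (FRL) eligible when the category share of enrollment
   strictly exceeds a threshold (50%, with 40%/60% sensitivity settings), and
   the exposure–predominance association is estimated by bivariable logistic
   regression with state (or county) fixed effects:

   logit P(predominant = 1) = α<sub>state</sub> + β · exposed<sub>r</sub>, OR = e<sup>β</sup>

   with Wald 95% CIs, overall and stratified by RUCA urbanicity
   (Metropolitan 1–3, Micropolitan 4–6, Rural 7–10; unassigned ZIPs default
   to Rural). A Mantel–Haenszel pooled OR (Robins–Breslow–Greenland variance)
   over the same stratified 2×2 tables serves as an independent cross-check.

It is aimed at environmental-epidemiology and environmental-justice analysts
who work with well registries (OGIM-style) and school rosters (NCES-style).
Because those national datasets are large downloads, the package ships a
synthetic-data generator that emulates their structure — clustered well
fields with realistic date missingness, rosters with demographic counts and a
*planted* exposure–predominance log-odds association, and a ZIP→RUCA map — so
every stage runs and is testable offline.

## Worked example

```bash
# generate a synthetic scene (wells + supplement + schools + RUCA + truth)
cat > scenario.yaml <<EOF
seed: 7
n_schools: 20000
n_wells: 4000
EOF
schoolwells simulate --config scenario.yaml --out scene/

# run every stage end to end
cat > run.yaml <<EOF
wells_path: scene/wells.csv
supplements_path: scene/supplement.csv
schools_path: scene/schools.csv
ruca_path: scene/ruca.csv
out_dir: out/
EOF
schoolwells run-all --config run.yaml
```

or in Python:

```python
import schoolwells as sw
from schoolwells.roster import make_ruca_table

cfg = sw.ScenarioConfig(seed=7, n_schools=20000, n_wells=4000)
bundle = sw.generate_scenario(cfg)
wells = sw.harmonize(sw.merge_date_supplements(bundle.wells, bundle.supplement)[0])
exposure = sw.build_exposure_profiles(bundle.schools, wells)
kept, _ = sw.exclude_missing_enrollment(bundle.schools)
profiles = sw.build_school_profiles(kept, make_ruca_table(bundle.ruca))
res = sw.run_association_suite(exposure, profiles,
                               sw.AssociationSpec(buffers=(10000.0,), subsets=("all",)))
print(res[["characteristic", "odds_ratio", "ci95_low", "ci95_high"]])
```

prints

```
  characteristic  odds_ratio  ci95_low  ci95_high
0       nh_white    1.330448  1.252985   1.412700
1       hispanic    0.806018  0.725767   0.895142
2            frl    1.110625  1.045998   1.179245
```

The scene plants odds ratios of 1.37 / 0.92 / 1.14 (at the 10 km truth
buffer) for the three characteristics; the fitted state-fixed-effects ORs
recover the White and FRL effects within their CIs. The Hispanic estimate is
attenuated by design: predominantly-White and predominantly-Hispanic are
mutually exclusive (both shares cannot exceed one half), so the generator
draws the Hispanic flag conditionally among non-White-predominant schools and
its *marginal* OR sits below the planted conditional value (see
`docs/methods.md`).

## Layout

- `schoolwells.registry` — raw well ingestion (CSV/GeoJSON), date-supplement
  merging, usability filter, activity windows.
- `schoolwells.roster` — school ingestion, enrollment exclusion, proportions,
  predominance flags, RUCA urbanicity.
- `schoolwells.exposure` — haversine distances, k-d-tree spatial index with a
  brute-force oracle mode, exposure profiles, prevalence summaries.
- `schoolwells.associations` — stratified 2×2 tabulation, fixed-effects
  logistic (Newton–Raphson), Mantel–Haenszel oracle, the Tables-style
  association suite, descriptive (mean/median/IQR) summaries.
- `schoolwells.synthetic` — scenario generator and worked fixtures.
- `schoolwells.pipeline` / `schoolwells.cli` — end-to-end orchestration with
  a manifest, and the `schoolwells` command-line interface.
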