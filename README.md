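# mpikit — harmonised multidimensional poverty measurement

`mpikit` implements the production pipeline behind harmonised
multidimensional poverty statistics of the kind published for the global
MPI: ten household-level deprivation indicators in three dimensions
(health, education, living standards), the Alkire–Foster counting measures
over them, design-based survey estimation with Taylor-linearised standard
errors, cross-wave harmonisation of indicators for comparability over time,
and annualised changes between survey pairs. It is aimed at researchers in
poverty measurement and survey statistics who want a tested, transparent
re-implementation of these methods that can be exercised end to end —
the real inputs (DHS/MICS recode microdata) are restricted, so the package
ships a synthetic household-survey generator with known census truth in
their place.

## The measures

With deprivation indicators d_ij ∈ {0,1}, weights w_j (Σ w_j = 1,
equal-nested: each dimension 1/3, indicators equal within a dimension) and
poverty cutoff k = 1/3:

- deprivation score: c_i = Σ_j w_j d_ij; poor_i = 1{c_i ≥ k}
- incidence H = share of people who are poor; intensity A = mean of c among
  the poor; adjusted headcount ratio **M0 = H × A**
- uncensored / censored headcounts: hd_j = share deprived in j,
  hdk_j = share poor *and* deprived in j, with the dimensional breakdown
  **M0 = Σ_j w_j · hdk_j**
- vulnerability = share with 0.2 ≤ c < 1/3; severity = share with c ≥ 0.5

Indicators are built at the household level under the published policies:
only usual members count, households with no eligible members are
non-deprived, partial information is resolved toward non-deprivation
(lower-bound estimates), two-thirds rules govern schooling and attendance
missingness, and observations that still lack an indicator are dropped
(case-wise deletion) with the sample drop monitored and — above 15%
nationally / 25% regionally — used to suppress subnational rows.

## Worked example

The numbered scripts under `analysis/` run a two-wave synthetic country
whose second wave lacks adult anthropometry, child death dates, the water
round-trip time, the shared-toilet flag, wall materials and the computer
asset item — so all six harmonisation variant rules fire. From
`analysis/03_estimate_levels.py` and `analysis/04_changes_over_time.py`:

```
national estimates (design-based 95% CIs):
     year measure       b     se      ll      ul
     2010       A 43.1971 1.6284 39.6491 46.7451
     2010       H 31.3251 2.6777 25.4909 37.1593
     2010      M0  0.1353 0.0112  0.1110  0.1597
2014-2016       A 40.6846 1.5207 37.3713 43.9978
2014-2016       H 17.3133 2.3289 12.2391 22.3875
2014-2016      M0  0.0704 0.0099  0.0489  0.0920

national changes 2010 -> 2014-2016 (dt = 5.0 years):
measure  ctype  ann        b     se    tval
      H      1    1  -2.8024 0.7098 -3.9483
     M0      1    1  -0.0130 0.0030 -4.3459
     M0      2    1 -12.2408 2.8603 -4.2796
```

Read: about 31% of people were multidimensionally poor in 2010 and 17% in
the 2014–2016 survey; incidence fell by 2.8 percentage points per year, and
M0 by 12.2% per year in relative terms (ctype 2), both highly significant.
The multi-year survey label enters through its reference year
(2014–2016 → 2015). `analysis/01_simulate_microdata.py` records the census
truth these estimates chase, and `analysis/05_validate.py` certifies the
emitted files (schema, 0/1 coding, M0 = H×A and breakdown identities,
subgroup aggregation).

Result files follow the released-database layout: one row per estimate with
a nucleus (`b`, `se`, `ll`, `ul`, `tval`) and metadata (`ccty`, `year`,
`loa` ∈ {nat, region, area, agec2, agec4}, `measure`, `indicator`, `k`,
`wgts`, `misind`; change files add `t0`, `t1`, `year0`, `year1`, `ann`),
plus `_lab` label companions.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's main end-to-end computation from scratch: it
generates the two-wave synthetic country, injects item missingness,
harmonises, builds indicators, estimates all measures with survey standard
errors, computes changes over time, applies the suppression policy,
certifies both result files, prints the national estimates, and writes the
JSON summary to `--out`.
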