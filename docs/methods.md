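# Methods

This note documents the statistical content of `mpikit`: the measurement
model, the indicator-construction policies, the survey-estimation
machinery, the synthetic-data generator that stands in for restricted
DHS/MICS microdata, and the numerical and design choices that were
genuinely open.

## 1. Counting measures

The Alkire–Foster "dual cutoff" approach identifies a person as poor when
their weighted deprivation score c_i = Σ_j w_j d_ij reaches the poverty
cutoff k (weak inequality, default k = 1/3, reported under the label
`33`). All measures are weighted by the member-level sampling weight
(household weight attached to every member). Reporting scales follow the
released database: H, A, hd, hdk, sev, vuln, popsh, pctb and the
missingness shares in percent; M0 and actb on the 0–1 scale of M.

Identities maintained (and certified on every emitted file):
M0 = H·A/10⁴, M0 = Σ_j w_j·hdk_j/100, hdk_j ≤ hd_j, H(k=0.5) = sev,
H(k=0.2) − H(k=1/3) = vuln, Σ_j pctb_j = 100 when M0 > 0, and subgroup
aggregation Σ_l popsh_l·X_l = X for X ∈ {H, M0, hd_j, …}.

**Conventions.** With zero poor people A is a mean over an empty set and is
reported missing (not 0); M0 is then 0 and the M0 = H·A identity is
vacuous. Identification uses c ≥ k − 10⁻¹⁰ so that scores assembled from
float weights (e.g. 1/6 + 1/6 vs 1/3) compare as intended.

**Weights.** Equal-nested: health and education indicators carry 1/6,
living-standard indicators 1/18. When a survey cannot support an indicator,
the remaining indicators of the affected dimension share its 1/3 equally
(`reweight_for_missing`); at least one health and one education indicator
must remain, mirroring the inclusion policy. Estimates from such surveys
carry the `misind` flag.

## 2. Indicator construction

Householdness: all ten indicators are household-level; every member of a
household shares its value. Construction uses usual members only.
Eligibility forcing: a household with no eligible members for an indicator
is non-deprived in it (the single exception: no reproductive-age woman
*and* no male mortality report leaves child mortality missing).

Thresholds are strict as published: z-scores < −2, adult BMI < 18.5 kg/m²
(ages 20–70, months 229–840; 5–19-year-olds by BMI-for-age z; under-5s by
height-for-age or weight-for-age z), fewer than six completed years of
schooling among members aged 10+, any school-age child (entry age to entry
age + 8, entry age configurable) out of school, water round trip ≥ 30
minutes, at most one small asset and no car. Housing is deprived on a
natural floor or natural/rudimentary roof or walls.

Missing-value policies (lower-bound logic — published headcounts can only
rise if unobserved cases turn out deprived):

- nutrition: deprived if any measured eligible member is undernourished;
  non-deprived if none is and at least one was measured; missing only when
  eligible members exist and none has valid anthropometry;
- child mortality: deprived on any qualifying reported death; non-deprived
  when all eligible women reported none, or when no woman information
  exists but a male report says no death; otherwise missing;
- schooling / attendance: missing only under the two-thirds rules (≥ 2/3 of
  eligible members unreported while the reported remainder gives no
  decisive evidence);
- water / sanitation: an improved source or facility with a missing
  round-trip time or shared flag is non-deprived by source/type; a ≥ 30
  minute fetch or a shared facility deprives even when the other item is
  unknown;
- assets: enough observed assets (or a car) settle non-deprivation
  regardless of gaps; deprivation requires the complete item set.

Missingness accounting (`mv_uw`, `mv_w`) is computed at the member level,
weighted by the household sampling weight — the paper-level unit is not
stated; member level matches the person-based measures. Case-wise deletion
then drops members with any missing included indicator, design variable or
disaggregator. Region-level results are suppressed when the weighted
sample drop strictly exceeds 15% nationally or 25% for the region.

## 3. Harmonisation

A country's waves are restricted to their common domain: the intersection
of eligible populations and collected items. The six named variant rules
are derived automatically from wave inventories: child-only (or
women-and-children) nutrition, any-death child mortality (no dates),
source-only water, type-only sanitation, housing from the materials present
everywhere, assets from the consistently collected items. A plan can also
be supplied declaratively, and region codes are mapped through a per-wave
correspondence table; codes mapped to `EXCLUDE` keep their members in the
sample (national, area, age rows unaffected) but get no region rows.

Application and construction commute: building from a plan-masked wave
under the restricted specs equals building from the raw wave under the
restricted specs, exactly — the restricted specs never consult
out-of-domain data. This is the tested comparability guarantee: harmonised
indicators depend only on the common domain.

## 4. Survey estimation

Point estimates are ratio means R̂ = Σ w y / Σ w (or ratios of totals for
A and pctb). Variances use first-order Taylor linearisation with the
stratified between-PSU (ultimate cluster) formula on PSU totals of the
member scores w_i u_i, where u_i = (y_i − R̂)/Ŵ for means and
u_i = (x_i − R̂ y_i)/Ŷ for ratios:

    var = Σ_h n_h/(n_h−1) Σ_c (z_hc − z̄_h)²

Domains (subgroups) zero the scores outside the domain and keep the full
design, so all PSUs contribute. Degrees of freedom are #PSUs − #strata;
intervals use Student-t quantiles at the configured level (default 95%).
Strata with a single PSU contribute the squared deviation of their PSU
total from the grand mean of all PSU totals — the "centered" singleton
rule, isolated in one code path for auditability. No finite-population
correction is applied (sampling fractions of real surveys are unknown), so
variances are mildly conservative when PSU-stage fractions are not small.
Estimates are not truncated to [0, 100]; intervals may cross logical
bounds. A Rao–Wu PSU bootstrap (m_h = n_h − 1 with weight rescaling)
exists as a test oracle only.

Full-design degrees of freedom are used for domain estimates (the exact
domain-df convention of the reference system is not documented).

## 5. Changes over time

Surveys are independent cross-sections, so var(b₁ − b₀) = se₀² + se₁².
Forms: raw absolute b₁ − b₀; raw relative (b₁ − b₀)/b₀ × 100; annualised
absolute (b₁ − b₀)/Δt; annualised relative ((b₁/b₀)^{1/Δt} − 1) × 100,
where Δt is the difference of reference years (a survey spanning years
takes the mean of the span's endpoints, e.g. "2005-2006" → 2005.5).
Relative and annualised forms get first-order delta-method variances, e.g.
for the annualised relative change with r = b₁/b₀ and
g_r = 100/Δt · r^{1/Δt − 1}: var = (g_r b₁/b₀²)² se₀² + (g_r/b₀)² se₁².
Relative changes from a zero baseline are reported missing. Pairing is
consecutive (t, t+1) by default with an explicit-pairs override;
sample-size and missingness bookkeeping rows are never differenced.

## 6. Synthetic microdata generator

The generator emulates the structure the pipeline assumes, with defaults
describing one high-poverty country (chosen once; they are the stated
world, not tuning knobs):

- households: sizes 1–12 (mean ≈ 4.6), ages drawn from five bands over
  0–95 with an adult head forced; sex ~ Bernoulli(0.5); months recorded;
  3% non-usual members; 4000 households by default;
- deprivation: household j-deprivation is latent — Φ(ρ z_h + √(1−ρ²) e_hj)
  < p_j with one standard-normal factor z_h per household (loading ρ = 0.5)
  — so deprivations cluster within households while the household-level
  marginal probability equals the configured propensity p_j (defaults
  between 0.08 for child mortality and 0.65 for cooking fuel). Raw
  variables (z-scores, BMI, schooling years, attendance, item categories
  from documented synthetic code lists) are then filled consistently with
  the latent statuses; anthropometry is generated directly as z-scores/BMI
  because growth-standard conversion is out of scope;
- eligibility forcing makes realised census truth differ from the
  propensities (e.g. a household without school-age children cannot be
  attendance-deprived); truth therefore comes from `compute_truth`, a
  person-by-person plain-Python enumeration in exact rational arithmetic,
  independent of the vectorised measurement path;
- sampling: stratified two-stage — PSUs without replacement within strata,
  households without replacement within PSUs, all members of sampled
  households — with weight = inverse inclusion probability times a mean-one
  lognormal perturbation of configurable CV (0.15 default; the weight
  construction of real surveys is undocumented, any positive
  inverse-probability scheme qualifies);
- waves: a pair of independent populations with a propensity drift
  (default −0.05, poverty declining) and per-wave item inventories;
  missingness is injected MCAR per member or per household — MCAR suffices
  because the policies are deterministic in the observed pattern.

What a green test does *not* establish: the generator has no real
demographic calibration (no fertility/mortality processes, no
informative non-response, no intra-PSU spatial correlation beyond the
household factor, no measurement error in anthropometry), so passing
checks validate the measurement and inference machinery, not the realism
of any particular country's microdata. Male mortality reports are present
by default wherever a household exists (rate 1.0) so that complete data
yield a complete indicator; lowering the rate exercises the missing-report
policy.

Validation designs in the test-suite use 24–40 PSUs with PSU-stage
sampling fractions below ~10%, the regime where the no-FPC linearised
variance is near-nominal and normal approximations hold for the rarest
indicator (child mortality, hd ≈ 7%).

## 7. Result files

Two files, one row per estimate: level (`ctype` 0) and change (`ctype` 1
absolute / 2 relative, `ann` 0/1), with the documented column sets and
`_lab` label companions. `loa` uses the code `nat` (the example-data
spelling). Age bands: agec2 = {0–17, 18+}; agec4 = {0–9, 10–17, 18–59,
60+} — the variables are named in the source scheme but the bands are not,
so these follow the child/adult narrative and are recorded in the column
dictionary. `pctb` is emitted alongside `actb` as its relative twin (an
extension of the published measure list, flagged as such). Writing is
byte-stable: fixed column order, six-decimal numeric formatting, missing
values as empty fields, and a machine-readable column dictionary next to
each file. `certify` re-checks schema, coding and the measure identities
on every emitted file and is a release gate in `run_pipeline`.

## 8. Known limitations

- Real DHS/MICS recode parsing, WHO growth-standard z-score computation,
  country-specific school-entry ages and region-boundary harmonisation are
  out of scope; the synthetic dialect stands in for all of them.
- M1/M2 (poverty-gap members of the AF family), replication-weight
  variance methods and multiple imputation are not implemented.
- Plans are versionable but there is no revision logic for growing survey
  sequences; pair selection beyond consecutive/explicit pairs is not
  offered.
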