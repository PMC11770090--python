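"""Generator properties: determinism, propensity calibration, census truth,
two-stage sampling, design-unbiasedness, missingness injection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mpikit.afcore import dcol, equal_nested_weights
from mpikit.indicators import assemble_matrix, missingness_report
from mpikit.specs import INDICATORS, default_specs
from mpikit.synthetic import (
    GeneratorConfig,
    compute_truth,
    draw_sample,
    generate_population,
    inject_missingness,
)

from conftest import small_generator_config


def as_selfweighted_wave(pop) -> pd.DataFrame:
    df = pop.data.copy()
    df["weight"] = 1.0
    return df


class TestDeterminism:
    def test_population_byte_identical_under_seed(self):
        cfg = small_generator_config(seed=77, n_households=200)
        p1 = generate_population(cfg)
        p2 = generate_population(cfg)
        pd.testing.assert_frame_equal(p1.data, p2.data)

    def test_sample_and_injection_deterministic(self):
        cfg = small_generator_config(seed=78, n_households=400)
        pop = generate_population(cfg)
        w1 = draw_sample(pop, cfg, seed=5)
        w2 = draw_sample(pop, cfg, seed=5)
        pd.testing.assert_frame_equal(w1.data, w2.data)
        m1 = inject_missingness(w1, {"yschool": 0.2}, seed=3)
        m2 = inject_missingness(w2, {"yschool": 0.2}, seed=3)
        pd.testing.assert_frame_equal(m1.data, m2.data)

    def test_different_seed_different_draw(self):
        cfg = small_generator_config(seed=79, n_households=200)
        p1 = generate_population(cfg, seed=1)
        p2 = generate_population(cfg, seed=2)
        assert not p1.data.equals(p2.data)


class TestPropensityExtremes:
    def test_all_zero_propensities_no_poverty_at_any_cutoff(self, scheme):
        cfg = small_generator_config(
            seed=101, n_households=300,
            indicator_propensities={j: 0.0 for j in INDICATORS},
        )
        truth = compute_truth(generate_population(cfg), k=min(scheme.weights.values()))
        assert truth.h == 0.0
        assert all(v == 0.0 for v in truth.hd.values())

    def test_all_one_propensities_saturate_headcount(self):
        """With every propensity 1, the six always-eligible living-standard
        indicators alone give c >= 1/3, so H = 100; indicators whose
        eligibility is guaranteed (adult head present) also saturate."""
        cfg = small_generator_config(
            seed=102, n_households=300,
            indicator_propensities={j: 1.0 for j in INDICATORS},
        )
        truth = compute_truth(generate_population(cfg))
        assert truth.h == pytest.approx(100.0)
        for j in ("ckfl", "sani", "wtr", "elct", "hsg", "asst", "educ", "nutr"):
            assert truth.hd[j] == pytest.approx(100.0), j

    def test_household_level_rate_within_exact_binomial_bounds(self, scheme):
        """Cooking-fuel deprivation is always realisable, so the share of
        deprived households is Binomial(n, p): the census rate must fall in
        the exact central 99% interval."""
        cfg = small_generator_config(
            seed=103, n_households=5000,
            indicator_propensities={**{j: 0.2 for j in INDICATORS}, "ckfl": 0.30},
        )
        pop = generate_population(cfg)
        matrix = assemble_matrix(as_selfweighted_wave(pop), default_specs(), scheme)
        hh_rate = matrix.drop_duplicates("hh_id")[dcol("ckfl")].mean()
        lo, hi = stats.binom.ppf([0.005, 0.995], 5000, 0.30) / 5000
        assert lo <= hh_rate <= hi


class TestTruth:
    def test_fixture_a_truth_by_enumeration(self, fixture_a_population):
        truth = compute_truth(fixture_a_population)
        assert truth.h == pytest.approx(50.0)
        assert truth.a == pytest.approx(1300 / 36)
        assert truth.m0 == pytest.approx(13 / 72)
        assert truth.vuln == pytest.approx(25.0)
        assert truth.hdk["nutr"] == pytest.approx(50.0)

    def test_union_identification_equates_censored_and_uncensored(self, scheme):
        cfg = small_generator_config(seed=104, n_households=250)
        truth = compute_truth(generate_population(cfg), k=min(scheme.weights.values()))
        for j in scheme.indicators:
            assert truth.hdk[j] == pytest.approx(truth.hd[j], abs=1e-12)

    def test_truth_identities(self):
        cfg = small_generator_config(seed=105, n_households=400)
        truth = compute_truth(generate_population(cfg))
        scheme = equal_nested_weights()
        assert abs(truth.m0 - truth.h * truth.a / 1e4) < 1e-12
        breakdown = sum(scheme.weights[j] * truth.hdk[j] / 100.0 for j in scheme.indicators)
        assert abs(truth.m0 - breakdown) < 1e-12

    def test_truth_equals_vectorised_measures_on_census(self, scheme):
        from mpikit.afcore import compute_measures

        cfg = small_generator_config(seed=106, n_households=350)
        pop = generate_population(cfg)
        truth = compute_truth(pop)
        ms = compute_measures(
            assemble_matrix(as_selfweighted_wave(pop), default_specs(), scheme), scheme
        )
        assert ms.h == pytest.approx(truth.h, abs=1e-9)
        assert ms.m0 == pytest.approx(truth.m0, abs=1e-12)
        assert ms.hd == pytest.approx(truth.hd, abs=1e-9)


def takeall_config(seed=110, n_households=400):
    return small_generator_config(
        seed=seed, n_households=n_households, pop_psu_size=50,
        design={"n_strata": 2, "psus_per_stratum": 4, "households_per_psu": 50,
                "weight_cv": 0.0},
    )


class TestSampling:
    def test_takeall_design_is_a_census(self, scheme):
        cfg = takeall_config()
        pop = generate_population(cfg)
        wave = draw_sample(pop, cfg, seed=1)
        assert (wave.data["weight"] == 1.0).all()
        hh_w = wave.data.drop_duplicates("hh_id")["weight"].sum()
        assert abs(hh_w - cfg.n_households) <= 1.0
        truth = compute_truth(pop)
        from mpikit.afcore import compute_measures

        ms = compute_measures(assemble_matrix(wave.data, default_specs(), scheme), scheme)
        assert ms.h == pytest.approx(truth.h, abs=1e-9)
        assert ms.m0 == pytest.approx(truth.m0, abs=1e-12)

    def test_insufficient_psus_rejected(self):
        cfg = small_generator_config(
            seed=111, n_households=200, pop_psu_size=50,
            design={"n_strata": 2, "psus_per_stratum": 10, "households_per_psu": 5,
                    "weight_cv": 0.0},
        )
        pop = generate_population(cfg)
        with pytest.raises(ValueError, match="fewer than"):
            draw_sample(pop, cfg)

    def test_design_unbiasedness_over_replicates(self, scheme):
        """Replicate mean of the weighted estimators tracks census truth
        within 3 Monte-Carlo standard errors (500 replicates)."""
        cfg = small_generator_config(
            seed=112, n_households=2000, pop_psu_size=25,
            design={"n_strata": 4, "psus_per_stratum": 4, "households_per_psu": 10,
                    "weight_cv": 0.1},
        )
        pop = generate_population(cfg)
        truth = compute_truth(pop)
        # household-level indicators survive row subsetting: attach them once
        matrix = assemble_matrix(as_selfweighted_wave(pop), default_specs(), scheme)
        cols = [dcol(j) for j in scheme.indicators] + ["c"]
        enriched = pop.data.join(matrix.set_index(["hh_id", "person_id"])[cols],
                                 on=["hh_id", "person_id"])
        enriched_pop = type(pop)(data=enriched, n_households=pop.n_households)

        reps = 500
        h_vals = np.empty(reps)
        m0_vals = np.empty(reps)
        hd_vals = {j: np.empty(reps) for j in ("ckfl", "nutr", "cm")}
        for r in range(reps):
            s = draw_sample(enriched_pop, cfg, seed=10_000 + r).data
            s = s[s["usual_member"] == 1]  # visitors never enter estimation
            w = s["weight"].to_numpy()
            poor = (s["c"].to_numpy() >= 1 / 3 - 1e-10).astype(float)
            W = w.sum()
            h_vals[r] = np.dot(w, poor) / W * 100.0
            m0_vals[r] = np.dot(w, s["c"].to_numpy() * poor) / W
            for j in hd_vals:
                hd_vals[j][r] = np.dot(w, s[dcol(j)].to_numpy()) / W * 100.0

        for vals, target in [(h_vals, truth.h), (m0_vals, truth.m0)] + [
            (hd_vals[j], truth.hd[j]) for j in hd_vals
        ]:
            mcse = vals.std(ddof=1) / np.sqrt(reps)
            assert abs(vals.mean() - target) <= 3.0 * mcse, (vals.mean(), target, mcse)


class TestInjectMissingness:
    def test_rate_zero_is_identity(self):
        cfg = small_generator_config(seed=120, n_households=400, pop_psu_size=20)
        wave = draw_sample(generate_population(cfg), cfg, seed=2)
        out = inject_missingness(wave, {"yschool": 0.0, "fuel": 0.0}, seed=1)
        pd.testing.assert_frame_equal(out.data, wave.data)

    def test_total_birth_history_loss_blanks_child_mortality(self, scheme):
        # without male reports every household depends on the birth history
        cfg = small_generator_config(
            seed=121, n_households=400, pop_psu_size=20, male_report_rate=0.0
        )
        wave = draw_sample(generate_population(cfg), cfg, seed=2)
        out = inject_missingness(wave, {"birth_history": 1.0}, seed=1)
        matrix = assemble_matrix(out.data, default_specs(), scheme)
        rep = missingness_report(matrix, scheme)
        assert rep.mv_uw["cm"] == pytest.approx(100.0)

    def test_household_item_rate_within_binomial_bounds(self):
        cfg = small_generator_config(seed=122, n_households=4000)
        wave = draw_sample(
            generate_population(cfg),
            small_generator_config(
                seed=122, n_households=4000, pop_psu_size=50,
                design={"n_strata": 4, "psus_per_stratum": 20,
                        "households_per_psu": 50, "weight_cv": 0.0},
            ),
            seed=2,
        )
        out = inject_missingness(wave, {"toilet_shared": 0.10}, seed=9)
        hh = out.data.drop_duplicates("hh_id")
        share = hh["toilet_shared"].isna().mean()
        n = len(hh)
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.10) / n
        assert lo <= share <= hi

    def test_unknown_item_rejected(self):
        cfg = small_generator_config(seed=123, n_households=400, pop_psu_size=20)
        wave = draw_sample(generate_population(cfg), cfg, seed=2)
        with pytest.raises(ValueError, match="unknown raw item"):
            inject_missingness(wave, {"horoscope": 0.5}, seed=1)

    def test_invalid_rate_rejected(self):
        cfg = small_generator_config(seed=124, n_households=400, pop_psu_size=20)
        wave = draw_sample(generate_population(cfg), cfg, seed=2)
        with pytest.raises(ValueError, match="outside"):
            inject_missingness(wave, {"yschool": 1.2}, seed=1)
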