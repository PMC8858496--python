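"""Synthetic-population generator: frequencies, effects, test days, designs."""

import numpy as np
import pandas as pd
import pytest

from heatgp.errors import ConfigError, DataError
from heatgp.simdata import (
    MIXTURE_CLASS_SCALARS,
    Population,
    make_study_design,
    check_design_invariants,
    scaled_thi,
    sigma_v2_for_target_variance,
    simulate_effects,
    simulate_genotypes,
    simulate_population,
    simulate_test_days,
)

SMALL_MAP = {"n_chrom": 2, "chrom_length_bp": 1_000_000,
             "n_array_snps": 200, "n_sequence_snps": 1000}


class TestSimulateGenotypes:
    def test_no_divergence_has_zero_mean_frequency_difference(self):
        g = simulate_genotypes({"A": 400, "B": 400}, SMALL_MAP, fst=0.0, seed=3)
        fa = g.dosages[g.breed == "A"].mean(axis=0) / 2
        fb = g.dosages[g.breed == "B"].mean(axis=0) / 2
        # both breeds sample the same frequency: difference is binomial noise
        assert abs(np.mean(fa - fb)) < 0.01
        assert np.std(fa - fb) < 0.05

    def test_empty_population_rejected(self):
        with pytest.raises(ConfigError, match="empty population"):
            simulate_genotypes({"A": 0, "B": 0, "cross": 0}, SMALL_MAP)

    def test_fst_recovered_by_hudson_estimator(self):
        target = 0.1
        g = simulate_genotypes({"A": 500, "B": 500},
                               {**SMALL_MAP, "n_sequence_snps": 2000,
                                "n_array_snps": 200},
                               fst=target, seed=5)
        n1 = n2 = 500
        p1 = g.dosages[g.breed == "A"].mean(axis=0) / 2
        p2 = g.dosages[g.breed == "B"].mean(axis=0) / 2
        num = ((p1 - p2) ** 2
               - p1 * (1 - p1) / (2 * n1 - 1) - p2 * (1 - p2) / (2 * n2 - 1))
        den = p1 * (1 - p2) + p2 * (1 - p1)
        fst_hat = num.sum() / den.sum()
        assert abs(fst_hat - target) / target < 0.2

    def test_maf_floor_enforced_and_deterministic(self):
        g1 = simulate_genotypes({"A": 300}, SMALL_MAP, fst=0.05, seed=9, maf_floor=0.01)
        g2 = simulate_genotypes({"A": 300}, SMALL_MAP, fst=0.05, seed=9, maf_floor=0.01)
        assert (g1.maf() > 0.01).all()
        assert np.array_equal(g1.dosages, g2.dosages)
        assert g1.snp_map.equals(g2.snp_map)

    def test_invalid_fst_rejected(self):
        with pytest.raises(ConfigError):
            simulate_genotypes({"A": 10}, SMALL_MAP, fst=1.5)

    def test_crossbreds_intermediate_frequency(self):
        g = simulate_genotypes({"A": 400, "B": 400, "cross": 400},
                               SMALL_MAP, fst=0.3, seed=21)
        fa = g.dosages[g.breed == "A"].mean(axis=0) / 2
        fb = g.dosages[g.breed == "B"].mean(axis=0) / 2
        fx = g.dosages[g.breed == "cross"].mean(axis=0) / 2
        resid = fx - (fa + fb) / 2
        assert abs(resid.mean()) < 0.01


class TestSimulateEffects:
    def test_null_mixture_gives_zero_effects(self, small_genotypes):
        m = simulate_effects(small_genotypes, (1, 0, 0, 0), sigma_v2=1.0, seed=0)
        assert m.qtl_indices.size == 0
        assert not m.effects_slope.any()
        assert not m.tbv_slope.any()

    def test_qtl_count_matches_binomial_expectation(self):
        g = simulate_genotypes({"A": 50}, {**SMALL_MAP, "n_sequence_snps": 10_000,
                                           "n_array_snps": 500}, seed=1)
        pi = (0.99, 0.006, 0.003, 0.001)
        m = simulate_effects(g, pi, sigma_v2=1.0, seed=2)
        expected = 0.01 * g.n_snps
        sd = np.sqrt(g.n_snps * 0.01 * 0.99)
        assert abs(m.qtl_indices.size - expected) < 4 * sd

    def test_breeding_value_variance_matches_analytic_expectation(self):
        g = simulate_genotypes({"A": 500}, {**SMALL_MAP, "n_sequence_snps": 10_000,
                                            "n_array_snps": 500}, seed=3)
        pi = (0.95, 0.03, 0.015, 0.005)
        sv2 = 2.0
        p = g.allele_freq
        het = np.sum(2 * p * (1 - p))
        analytic = het * np.dot(pi, MIXTURE_CLASS_SCALARS) * sv2
        # Monte-Carlo over effect draws
        draws = [simulate_effects(g, pi, sv2, seed=s).tbv_slope.var() for s in range(12)]
        mc = np.mean(draws)
        assert abs(mc - analytic) / analytic < 0.25

    def test_target_variance_helper_inverts_expectation(self, small_genotypes):
        pi = (0.9, 0.05, 0.03, 0.02)
        sv2 = sigma_v2_for_target_variance(small_genotypes, pi, 0.25)
        draws = [simulate_effects(small_genotypes, pi, sv2, seed=s).tbv_slope.var()
                 for s in range(20)]
        assert abs(np.mean(draws) - 0.25) / 0.25 < 0.3

    def test_negative_proportions_rejected(self, small_genotypes):
        with pytest.raises(ConfigError):
            simulate_effects(small_genotypes, (1.2, -0.2, 0, 0), 1.0)


class TestSimulateTestDays:
    def test_noise_free_records_return_true_slope_by_ols(self, small_genotypes):
        model = simulate_effects(small_genotypes, (0.8, 0.1, 0.06, 0.04), 1.0, seed=4)
        td = simulate_test_days(model, design={
            "residual_sd": 0.0, "herd_sd": 0.0,
            "env_intercept_sd": 0.0, "env_slope_sd": 0.0,
            "parity_effects": (0.0,), "records_per_cow": 6}, seed=5)
        t = scaled_thi(td["thi"], 60.0, 85.0)
        for cow, grp in td.assign(t=t).groupby("cow_id"):
            if grp["t"].nunique() < 2:
                continue  # all records below the THI threshold: no slope info
            slope = np.polyfit(grp["t"], grp["yield"], 1)[0]
            i = np.flatnonzero(model.individual_ids == cow)[0]
            assert slope == pytest.approx(model.tbv_slope[i], abs=1e-9)

    def test_zero_slopes_give_flat_pooled_regression(self, small_genotypes):
        model = simulate_effects(small_genotypes, (1, 0, 0, 0), 1.0, seed=6)
        td = simulate_test_days(model, design={"env_slope_sd": 0.0}, seed=7)
        t = scaled_thi(td["thi"], 60.0, 85.0)
        slope = np.polyfit(t, td["yield"], 1)[0]
        assert abs(slope) < 0.05

    def test_all_thi_below_threshold_is_an_error(self, small_genotypes):
        model = simulate_effects(small_genotypes, (1, 0, 0, 0), 1.0, seed=8)
        with pytest.raises(ConfigError, match="unidentifiable"):
            simulate_test_days(model, climate={"thi_min": 40, "thi_max": 55,
                                               "threshold": 60})

    def test_each_cow_has_requested_records(self, small_genotypes):
        model = simulate_effects(small_genotypes, (1, 0, 0, 0), 1.0, seed=9)
        td = simulate_test_days(model, design={"records_per_cow": 5}, seed=10)
        assert (td.groupby("cow_id").size() == 5).all()


def _random_population(seed, n_cows=60, n_bulls=12):
    rng = np.random.default_rng(seed)
    import pandas as pd
    from tests.conftest import make_genotypes
    geno = make_genotypes(n_cows + n_bulls, 50, seed=seed)
    sex = np.array(["F"] * n_cows + ["M"] * n_bulls, dtype=object)
    bulls = geno.individual_ids[n_cows:]
    sires = np.array([rng.choice(bulls) if rng.random() < 0.6 else ""
                      for _ in range(n_cows)] + [""] * n_bulls, dtype=object)
    ind = pd.DataFrame({"individual_id": geno.individual_ids,
                        "breed": geno.breed, "sex": sex, "sire_id": sires})
    return Population(genotypes=geno, individuals=ind)


class TestStudyDesign:
    @pytest.mark.parametrize("seed", range(5))
    def test_invariants_hold_on_randomized_pedigrees(self, seed):
        pop = _random_population(seed)
        design = make_study_design(pop, scenario=1, seed=seed, discovery_fraction=0.5)
        check_design_invariants(design, pop)  # raises on violation

    def test_no_sire_links_all_bulls_admissible(self):
        pop = _random_population(3)
        pop.individuals["sire_id"] = ""
        design = make_study_design(pop, scenario=1, seed=0, discovery_fraction=0.5)
        n_bulls = (pop.individuals["sex"] == "M").sum()
        assert len(design.reference_ids) == n_bulls

    def test_bull_siring_all_discovery_cows_excluded_from_reference(self):
        pop = _random_population(4)
        bull = pop.individuals.loc[pop.individuals["sex"] == "M", "individual_id"].iloc[0]
        is_cow = pop.individuals["sex"] == "F"
        pop.individuals.loc[is_cow, "sire_id"] = bull
        design = make_study_design(pop, scenario=1, seed=1, discovery_fraction=0.5)
        assert bull not in set(design.reference_ids)

    def test_same_seed_same_split(self):
        pop = _random_population(5)
        d1 = make_study_design(pop, scenario=1, seed=42)
        d2 = make_study_design(pop, scenario=1, seed=42)
        assert np.array_equal(d1.discovery_ids, d2.discovery_ids)
        assert np.array_equal(d1.reference_ids, d2.reference_ids)
        for k in d1.validation_sets:
            assert np.array_equal(d1.validation_sets[k][0], d2.validation_sets[k][0])

    def test_validation_subsets_balanced(self):
        pop = _random_population(6)
        design = make_study_design(pop, scenario=1, seed=2, discovery_fraction=0.4)
        for a, b in design.validation_sets.values():
            assert abs(len(a) - len(b)) <= 1

    def test_bad_scenario_rejected(self):
        pop = _random_population(7)
        with pytest.raises(ConfigError):
            make_study_design(pop, scenario=4)


def test_simulate_population_bundle_is_consistent():
    study = simulate_population(
        n_discovery_cows=80, n_reference_bulls=20, daughters_per_bull=5,
        n_validation_cows=40, map_config=SMALL_MAP, traits=("milk",), seed=1)
    geno = study.population.genotypes
    assert geno.n_individuals == 140
    td = study.test_days["milk"]
    # analysis cows plus 20*5 daughters have records
    assert td["cow_id"].nunique() == 140 + 100
    ped = study.daughter_pedigree
    assert set(ped["sire_id"]) <= set(geno.individual_ids)
    # daughters average half their sire's breeding value
    model = study.models["milk"]
    assert model.tbv_slope.shape == (140,)
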