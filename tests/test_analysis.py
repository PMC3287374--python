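import dataclasses
import json

import numpy as np
import pytest
from scipy import stats

from phyloplast.analysis import (
    AnalysisConfig,
    AnalysisError,
    MissingSpeciesError,
    ancova_controlling_devtime,
    case_table,
    compare_groups,
    compare_plasticity,
    plasticity_interaction,
    plasticity_vs_mean,
    run_full_analysis,
    venue_screen,
)
from phyloplast.pgls import PglsError
from phyloplast.simulate import SimParams, simulate_dataset
from phyloplast.traits import StudyCase, TreatmentSummary
from phyloplast.tree import prune_to_tips


def dataset(seed=0, **overrides):
    params = SimParams(n_species=16, seed=seed, **overrides)
    return simulate_dataset(params)


@pytest.fixture(scope="module")
def sim():
    return dataset(seed=1, n_polytomy_species=3)


class TestVenueScreen:
    def test_single_venue_skips(self):
        tree, cases, _ = dataset(
            seed=2, venue_probs={"laboratory": 1.0}
        )
        assert venue_screen(cases, tree) is None

    def test_returns_f_test(self, sim):
        tree, cases, _ = sim
        res = venue_screen(cases, tree, trait="log10_dev_rate")
        assert res is not None
        assert res.df_num == res.n_venues - 1
        assert 0 < res.p_value <= 1

    def test_null_p_uniform(self):
        pvals = []
        for seed in range(200):
            tree, cases, _ = dataset(
                seed=seed, sigma2_bm=0.0, case_noise_sd=0.2,
                venue_probs={"laboratory": 0.4, "mesocosm": 0.3, "field": 0.3},
            )
            res = venue_screen(cases, tree)
            if res is not None:
                pvals.append(res.p_value)
        _, p = stats.kstest(pvals, "uniform")
        assert p > 0.01

    def test_power_against_injected_effect(self):
        # venue effect of 3 residual SDs: detected in > 90% of simulations
        hits, total = 0, 0
        for seed in range(100):
            tree, cases, _ = dataset(
                seed=seed, sigma2_bm=0.0, case_noise_sd=0.1,
                venue_probs={"laboratory": 0.5, "mesocosm": 0.5},
                venue_effect_log10={"laboratory": 0.0, "mesocosm": 0.3},
            )
            res = venue_screen(cases, tree)
            if res is None:
                continue
            total += 1
            hits += res.p_value < 0.05
        assert total >= 80
        assert hits / total > 0.90


class TestCompareGroups:
    def test_missing_species_listed(self, sim):
        tree, cases, _ = sim
        keep = sorted(set(c.species for c in cases))[:-2]
        pruned = prune_to_tips(tree, keep)
        with pytest.raises(MissingSpeciesError, match="sp"):
            compare_groups(cases, pruned)

    def test_constant_trait_degenerate_error(self, sim):
        tree, cases, _ = sim
        flat = [
            StudyCase(
                case_id=c.case_id, species=c.species, risk_group=c.risk_group,
                venue=c.venue,
                constant=TreatmentSummary(30.0, 3.0, 10, 0.5, 0.05, 10),
            )
            for c in cases
        ]
        with pytest.raises(PglsError):
            compare_groups(flat, tree)

    def test_unknown_trait_errors(self, sim):
        tree, cases, _ = sim
        with pytest.raises(AnalysisError):
            compare_groups(cases, tree, trait="banana")

    def test_polytomy_df_used_in_tree_tests(self, sim):
        tree, cases, _ = sim
        mc = compare_groups(cases, tree)
        n = len(case_table(cases))
        assert mc.n_polytomies == 3
        for test in mc.tests_by_model["grafen"]:
            assert test.df_corrected == n - 2 - 3
        for test in mc.tests_by_model["star"]:
            assert test.df_corrected == n - 2

    def test_star_results_ignore_tree(self, sim):
        tree, cases, _ = sim
        mc1 = compare_groups(cases, tree)
        # a different (re-simulated) tree with the same tip labels
        other_tree, _, _ = dataset(seed=77, n_polytomy_species=3)
        mc2 = compare_groups(cases, other_tree)
        f1, f2 = mc1.fits["star"], mc2.fits["star"]
        np.testing.assert_allclose(f1.coefficients, f2.coefficients, atol=1e-12)
        assert f1.aic == pytest.approx(f2.aic, abs=1e-12)

    def test_case_order_invariance(self, sim):
        tree, cases, _ = sim
        mc1 = compare_groups(cases, tree)
        mc2 = compare_groups(list(reversed(cases)), tree)
        for label in ("star", "grafen"):
            np.testing.assert_allclose(
                mc1.fits[label].coefficients, mc2.fits[label].coefficients, atol=1e-9
            )
            assert mc1.fits[label].aic == pytest.approx(mc2.fits[label].aic, abs=1e-8)


class TestAncova:
    def test_risk_estimate_consistent_when_covariate_inert(self):
        # with no true covariate effect the risk estimate should match the
        # no-covariate model within Monte-Carlo error
        diffs = []
        for seed in range(30):
            tree, cases, _ = dataset(seed=seed, sigma2_bm=0.1, delta_log_mass=0.2)
            a = compare_groups(cases, tree, "log10_mass")
            b = ancova_controlling_devtime(cases, tree, "log10_mass")
            ia = a.fits["grafen"].coef_names.index("risk[High]")
            ib = b.fits["grafen"].coef_names.index("risk[High]")
            diffs.append(
                b.fits["grafen"].coefficients[ib] - a.fits["grafen"].coefficients[ia]
            )
        mean_diff = np.mean(diffs)
        mc_se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(mean_diff) < max(2 * mc_se, 0.05)

    def test_null_risk_when_trait_tracks_covariate(self):
        # trait a linear function of the covariate (small iid noise keeps
        # the fit non-degenerate), no group effect: |t| < 2 nearly always
        calm = 0
        trials = 60
        for seed in range(trials):
            tree, cases, _ = dataset(seed=seed, sigma2_bm=0.2)
            noise_rng = np.random.default_rng(seed + 10_000)
            rigged = []
            for c in cases:
                # log10 mass = 0.5*log10 rate + noise
                mass = c.constant.period_mean ** -0.5 * 10 ** noise_rng.normal(0, 0.02)
                rigged.append(
                    StudyCase(
                        case_id=c.case_id, species=c.species,
                        risk_group=c.risk_group, venue=c.venue,
                        constant=TreatmentSummary(
                            c.constant.period_mean, c.constant.period_sd, 10,
                            mass, 0.1 * mass, 10,
                        ),
                    )
                )
            mc = ancova_controlling_devtime(rigged, tree, "log10_mass")
            # the star model matches the iid noise used to rig the trait
            i = mc.fits["star"].coef_names.index("risk[High]")
            t = mc.tests_by_model["star"][i].t_statistic
            calm += abs(t) < 2
        assert calm / trials >= 0.93

    def test_collinear_design_raises_rank_error(self, sim):
        tree, cases, _ = sim
        # constant developmental time per group makes risk + covariate collinear
        rigged = []
        for c in cases:
            period = 20.0 if c.risk_group == "High" else 40.0
            rigged.append(
                StudyCase(
                    case_id=c.case_id, species=c.species, risk_group=c.risk_group,
                    venue=c.venue,
                    constant=TreatmentSummary(
                        period, 2.0, 10, c.constant.mass_mean, c.constant.mass_sd, 10
                    ),
                )
            )
        with pytest.raises(PglsError, match="rank deficient"):
            ancova_controlling_devtime(rigged, tree, "log10_mass")


class TestComparePlasticity:
    def test_all_drying_absent_skips(self):
        tree, cases, _ = dataset(seed=9, prop_paired=0.0)
        assert compare_plasticity(cases, tree) is None

    def test_too_few_paired_skips(self):
        tree, cases, _ = dataset(seed=10, prop_paired=0.15)
        assert compare_plasticity(cases, tree, min_per_group=5) is None

    def test_group_difference_recovered(self):
        # High -20%, Low -5% time plasticity: recovered within 2 MC SE
        est = []
        for seed in range(120):
            tree, cases, _ = dataset(
                seed=seed,
                time_plast_mean={"High": -20.0, "Low": -5.0},
                time_plast_sd={"High": 5.0, "Low": 5.0},
            )
            mc = compare_plasticity(cases, tree, "dev_time")
            if mc is None:  # a group drew < 3 paired cases this seed
                continue
            i = mc.fits["star"].coef_names.index("risk[High]")
            est.append(mc.fits["star"].coefficients[i])
        assert len(est) >= 100
        mean = np.mean(est)
        se = np.std(est, ddof=1) / np.sqrt(len(est))
        assert abs(mean - (-15.0)) < 2 * se + 0.5

    def test_null_rejection_rate_nominal(self):
        reject = 0
        total = 0
        trials = 200
        for seed in range(trials):
            tree, cases, _ = dataset(
                seed=seed,
                time_plast_mean={"High": -15.0, "Low": -15.0},
                time_plast_sd={"High": 8.0, "Low": 8.0},
            )
            mc = compare_plasticity(cases, tree, "dev_time")
            if mc is None:
                continue
            total += 1
            i = mc.fits["star"].coef_names.index("risk[High]")
            reject += mc.tests_by_model["star"][i].p_value < 0.05
        assert total >= 150
        rate = reject / total
        mc_se = np.sqrt(0.05 * 0.95 / total)
        assert rate <= 0.05 + 2 * mc_se


class TestPlasticityInteraction:
    def test_single_group_skips(self):
        tree, cases, _ = dataset(seed=12)
        one_group = [
            dataclasses.replace(c, risk_group="High") for c in cases
        ]
        assert plasticity_interaction(one_group, tree) is None

    def test_slopes_reported_by_group(self):
        tree, cases, _ = dataset(
            seed=13,
            case_noise_sd=0.0,
            mass_plast_slope={"High": 1.0, "Low": 0.0},
            mass_plast_sd={"High": 1.0, "Low": 1.0},
            time_plast_sd={"High": 15.0, "Low": 15.0},
        )
        mc = plasticity_interaction(cases, tree, response="mass")
        slopes = mc.extra["slopes_by_group"]
        assert slopes["High"] > slopes["Low"]
        assert slopes["High"] == pytest.approx(1.0, abs=0.35)
        assert slopes["Low"] == pytest.approx(0.0, abs=0.35)

    def test_equal_slopes_type_i_controlled(self):
        reject = 0
        total = 0
        trials = 150
        for seed in range(trials):
            tree, cases, _ = dataset(
                seed=seed,
                mass_plast_slope={"High": 0.5, "Low": 0.5},
                mass_plast_sd={"High": 5.0, "Low": 5.0},
                time_plast_sd={"High": 12.0, "Low": 12.0},
                time_plast_mean={"High": -20.0, "Low": -20.0},
            )
            mc = plasticity_interaction(cases, tree, response="mass")
            if mc is None:
                continue
            total += 1
            i = mc.fits["star"].coef_names.index("plast_dev_time:risk[High]")
            reject += mc.tests_by_model["star"][i].p_value < 0.05
        assert total >= 100
        rate = reject / total
        mc_se = np.sqrt(0.05 * 0.95 / total)
        assert rate <= 0.05 + 3 * mc_se


class TestPlasticityVsMean:
    def test_constant_mean_trait_rank_error(self, sim):
        tree, cases, _ = sim
        rigged = [
            StudyCase(
                case_id=c.case_id, species=c.species, risk_group=c.risk_group,
                venue=c.venue,
                constant=TreatmentSummary(30.0, 3.0, 10, 0.5, 0.05, 10),
                drying=c.drying,
            )
            for c in cases
        ]
        with pytest.raises(PglsError, match="rank deficient"):
            plasticity_vs_mean(rigged, tree, "dev_time", "log10_mass")

    def test_null_slope_unbiased(self):
        est = []
        for seed in range(100):
            tree, cases, _ = dataset(seed=seed, time_plast_sd={"High": 10.0, "Low": 10.0})
            mc = plasticity_vs_mean(cases, tree, "dev_time", "log10_dev_rate")
            if mc is None:
                continue
            i = mc.fits["star"].coef_names.index("log10_dev_rate")
            est.append(mc.fits["star"].coefficients[i])
        assert len(est) >= 80
        mean = np.mean(est)
        se = np.std(est, ddof=1) / np.sqrt(len(est))
        assert abs(mean) < max(2 * se, 0.5)


class TestRunFullAnalysis:
    def test_deterministic_report(self, sim, tmp_path):
        tree, cases, _ = sim
        config = AnalysisConfig(seed=5)
        r1 = run_full_analysis(config, cases, tree, out_dir=tmp_path / "a")
        r2 = run_full_analysis(config, cases, tree, out_dir=tmp_path / "b")
        blob1 = (tmp_path / "a" / "report.json").read_bytes()
        blob2 = (tmp_path / "b" / "report.json").read_bytes()
        assert blob1 == blob2
        assert r1 == r2

    def test_polytomy_count_matches_generator(self, sim):
        tree, cases, truth = sim
        report = run_full_analysis(AnalysisConfig(), cases, tree)
        assert (
            report["polytomies"]["n_soft_polytomies"]
            == truth["n_injected_polytomies"]
        )

    def test_all_stages_ok_on_clean_fixture(self, sim):
        tree, cases, _ = sim
        report = run_full_analysis(AnalysisConfig(), cases, tree)
        statuses = {entry["status"] for entry in report["stages"].values()}
        assert statuses == {"ok"}

    def test_missing_species_fails_tree_stages_only(self, sim):
        tree, cases, _ = sim
        keep = sorted(set(c.species for c in cases))[:-1]
        pruned = prune_to_tips(tree, keep)
        report = run_full_analysis(AnalysisConfig(), cases, pruned)
        stages = report["stages"]
        assert stages["compare_groups:log10_dev_rate"]["status"] == "failed"
        assert stages["venue_screen:log10_dev_rate"]["status"] == "ok"

    def test_aicw_pairs_sum_to_one(self, sim):
        tree, cases, _ = sim
        report = run_full_analysis(AnalysisConfig(), cases, tree)
        for name, entry in report["stages"].items():
            if entry["status"] != "ok" or "models" not in entry.get("result", {}):
                continue
            total = sum(m["AICw"] for m in entry["result"]["models"].values())
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_outputs_written(self, sim, tmp_path):
        tree, cases, _ = sim
        run_full_analysis(AnalysisConfig(), cases, tree, out_dir=tmp_path)
        for name in ("report.json", "derived_traits.tsv", "plasticity.tsv", "model_tables.tsv"):
            assert (tmp_path / name).exists()
        report = json.loads((tmp_path / "report.json").read_text())
        assert report["provenance"]["package"] == "phyloplast"

    def test_config_round_trip_yaml(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("seed: 9\nmin_paired_per_group: 4\n")
        config = AnalysisConfig.from_yaml(path)
        assert config.seed == 9
        assert config.min_paired_per_group == 4

    def test_config_unknown_key_errors(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("bogus: 1\n")
        with pytest.raises(AnalysisError):
            AnalysisConfig.from_yaml(path)
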