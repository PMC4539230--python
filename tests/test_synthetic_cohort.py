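"""Generator: discounting model, titration, mixture, copula, determinism."""

from dataclasses import replace

import numpy as np
import pytest

from sexdisc.curves import DDT_SCHEDULE, SDT_SCHEDULE, SEXUAL_CONDITIONS
from sexdisc.stats import spearman
from sexdisc.synthetic_cohort import (
    Agent,
    TitrationConfig,
    default_config,
    generate_cohort,
    null_config,
    pearson_to_spearman,
    sample_agent,
    simulate_ddt_titration,
    simulate_sdt_response,
    spearman_to_pearson,
)


def make_agent(k=1e-3, k_money=1e-4, floor=False, ceiling=False):
    return Agent(
        participant_id="A1",
        scenario="positive",
        gender="female",
        age=30,
        k_sex={c: k for c in SEXUAL_CONDITIONS},
        k_money=k_money,
        latent_traits={},
        is_floor=floor,
        is_ceiling=ceiling,
    )


class TestAgentResponses:
    def test_hyperbola_closed_form_half_value(self):
        curve = simulate_sdt_response(make_agent(k=1 / 720), "least_sti")
        idx = SDT_SCHEDULE.durations.index(720.0)
        assert curve.values[idx] == pytest.approx(0.5)

    def test_vanishing_rate_gives_full_curve(self):
        curve = simulate_sdt_response(make_agent(k=1e-12), "most_attractive")
        assert np.allclose(curve.values, 1.0, atol=1e-6)

    def test_extreme_rate_gives_empty_curve_beyond_zero_delay(self):
        curve = simulate_sdt_response(make_agent(k=1e6), "most_attractive")
        assert curve.values[0] == 1.0  # zero-delay trial keeps full value
        assert np.all(np.asarray(curve.values[1:]) < 0.01)

    def test_floor_and_ceiling_agents(self):
        assert np.all(np.asarray(simulate_sdt_response(make_agent(floor=True), "most_sti").values) == 0.0)
        assert np.all(np.asarray(simulate_sdt_response(make_agent(ceiling=True), "most_sti").values) == 1.0)

    def test_rates_must_be_positive(self):
        with pytest.raises(ValueError, match="> 0"):
            make_agent(k=-1.0)


class TestTitration:
    def test_patient_agent_reaches_ladder_top(self):
        # k ~ 0: always prefers the delayed $1000
        prop = simulate_ddt_titration(make_agent(k_money=1e-12), delay_hours=720.0)
        assert prop == pytest.approx(0.998046875)

    def test_impulsive_agent_reaches_ladder_bottom(self):
        prop = simulate_ddt_titration(make_agent(k_money=1e6), delay_hours=720.0)
        assert prop == pytest.approx(0.001953125)

    @pytest.mark.parametrize("k_money", [1e-4, 5e-4, 2e-3, 1e-2])
    def test_deterministic_ladder_brackets_true_indifference(self, k_money):
        cfg = TitrationConfig()
        for delay in DDT_SCHEDULE.durations:
            true_value = 1000.0 / (1 + k_money * delay)
            if not 2.0 <= true_value <= 998.0:
                continue  # outside the ladder's reachable range
            offer = simulate_ddt_titration(make_agent(k_money=k_money), delay, cfg) * 1000
            assert abs(offer - true_value) <= cfg.final_step + 1e-9


class TestCohortGeneration:
    def test_identical_seed_gives_byte_identical_files(self, tmp_path):
        cfg = default_config(seed=123, n_per_scenario=2)
        generate_cohort(cfg, out_csv=tmp_path / "a.csv")
        generate_cohort(cfg, out_csv=tmp_path / "b.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_all_floor_mixture_gives_all_zero_auc(self):
        cfg = replace(default_config(seed=1, n_per_scenario=30), p_floor=1.0, p_ceiling=0.0)
        m = generate_cohort(cfg).measures_frame()
        for cond in SEXUAL_CONDITIONS:
            assert (m[f"auc_{cond}"] == 0.0).all()

    def test_zero_spread_collapses_rates_within_cell(self):
        cfg = replace(
            default_config(seed=2, n_per_scenario=25),
            sigma_log_k=0.0,
            sigma_log_k_cond=0.0,
            sigma_vas=0.0,
            p_floor=0.0,
            p_ceiling=0.0,
            male_log_k_shift=0.0,
        )
        m = generate_cohort(cfg).measures_frame()
        for scenario in ("positive", "negative_regret"):
            sub = m.loc[m["scenario"] == scenario, "auc_most_attractive"]
            assert sub.nunique() == 1

    def test_mixture_calibration_at_large_n(self):
        cfg = default_config(seed=3, n_per_scenario=1667)  # ~5000 total
        m = generate_cohort(cfg).measures_frame()
        n = len(m)
        for cond in ("least_attractive", "most_sti"):
            frac0 = (m[f"auc_{cond}"] == 0.0).mean()
            frac1 = (m[f"auc_{cond}"] == 1.0).mean()
            assert abs(frac0 - cfg.p_floor) < 3 * np.sqrt(cfg.p_floor * 0.8 / n)
            assert abs(frac1 - cfg.p_ceiling) < 3 * np.sqrt(cfg.p_ceiling * 0.85 / n)

    def test_auc_strictly_decreasing_in_k(self):
        from sexdisc.curves import compute_auc

        aucs = []
        for k in np.logspace(-6, 0, 12):
            curve = simulate_sdt_response(make_agent(k=k), "least_attractive")
            aucs.append(compute_auc(curve).auc)
        assert np.all(np.diff(aucs) < 0)

    def test_zero_copula_targets_decorrelate_traits(self):
        cfg = replace(
            null_config(seed=4, n_per_scenario=1667),
            copula_targets={t: 0.0 for t in ("monetary", "hrbs", "ztpi", "sss", "cfc", "image_count")},
        )
        m = generate_cohort(cfg).measures_frame()
        for col in ("hrbs_score", "ztpi_score", "auc_monetary", "image_count"):
            rho = spearman(m["auc_most_attractive"], m[col]).rho
            assert abs(rho) < 0.05

    def test_copula_recovers_hrbs_target(self):
        cfg = default_config(seed=5, n_per_scenario=1667)
        m = generate_cohort(cfg).measures_frame()
        rho = spearman(m["auc_least_sti"], m["hrbs_score"]).rho
        assert rho == pytest.approx(cfg.copula_targets["hrbs"], abs=0.05)

    def test_scenario_counts_and_schema(self):
        cohort = generate_cohort(default_config(seed=6, n_per_scenario={"positive": 4, "negative": 5, "negative_regret": 6}))
        assert cohort.n_per_scenario == {"positive": 4, "negative": 5, "negative_regret": 6}
        assert (cohort.df["image_count"] >= 2).all()

    def test_exponential_model_supported(self):
        cfg = replace(default_config(seed=7, n_per_scenario=5), discount_model="exponential")
        cohort = generate_cohort(cfg)
        assert len(cohort) == 15


class TestConfigValidation:
    def test_mixture_weights_must_be_feasible(self):
        with pytest.raises(ValueError, match="mixture"):
            replace(default_config(), p_floor=0.7, p_ceiling=0.5)

    def test_copula_target_out_of_open_interval(self):
        with pytest.raises(ValueError, match=r"\(-1, 1\)"):
            replace(default_config(), copula_targets={"hrbs": 1.0})

    def test_unknown_copula_target_named(self):
        with pytest.raises(ValueError, match="unknown copula targets"):
            replace(default_config(), copula_targets={"zzz": 0.1})

    def test_spearman_pearson_conversion_round_trip(self):
        for rho in (-0.9, -0.2, 0.0, 0.4, 0.8):
            assert pearson_to_spearman(spearman_to_pearson(rho)) == pytest.approx(rho)


class TestSampleAgent:
    def test_agent_fields_valid(self):
        rng = np.random.default_rng(0)
        agent = sample_agent(default_config(seed=0), "negative", rng)
        assert agent.scenario == "negative"
        assert set(agent.k_sex) == set(SEXUAL_CONDITIONS)
        assert all(k > 0 for k in agent.k_sex.values()) and agent.k_money > 0
        assert agent.gender in ("male", "female")
        assert not (agent.is_floor and agent.is_ceiling)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            sample_agent(default_config(), "neutral", np.random.default_rng(0))
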