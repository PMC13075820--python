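"""Generator: design construction, moment matching, determinism, table IO."""

import numpy as np
import pandas as pd
import pytest

from resistqg.config import LifeHistoryConfig, SimulationConfig
from resistqg.simulate import (
    expected_binomial_noise,
    generate_design,
    simulate_family_effects,
    simulate_life_history,
    simulate_survival,
)
from resistqg.tables import (
    FamilySurvivalTable,
    LifeHistoryTable,
    SchemaError,
    read_tables,
    write_tables,
)


class TestGenerateDesign:
    def test_full_sib_design_has_35_families(self):
        cfg = SimulationConfig(n_sires=35, n_dams_per_sire=1)
        design = generate_design(cfg)
        df = design.df
        assert df["family_id"].nunique() == 35
        # each sire appears in exactly one family under full-sib pairing
        assert df.groupby("sire_id")["family_id"].nunique().eq(1).all()
        # family-matched replicates in both arms
        assert (
            df.groupby("family_id")["treatment"].nunique().eq(2).all()
        )

    def test_single_family_table(self):
        cfg = SimulationConfig(
            n_sires=1, n_dams_per_sire=1, n_blocks=1, n_plants_per_block=1,
            n_replicates_per_family=1,
        )
        df = generate_design(cfg).df
        assert len(df) == 2  # one row per treatment
        assert set(df["treatment"]) == {"control", "exposed"}

    def test_half_sib_design_counts(self):
        cfg = SimulationConfig(
            n_sires=10, n_dams_per_sire=3, n_replicates_per_family=1
        )
        df = generate_design(cfg).df
        assert df["family_id"].nunique() == 30
        # brute-force tally: each sire occurs in 3 rows per treatment
        tally = df.groupby(["sire_id", "treatment"]).size()
        assert (tally == 3).all()

    def test_determinism(self):
        cfg = SimulationConfig(seed=11)
        assert generate_design(cfg) == generate_design(cfg)


class TestFamilyEffects:
    def test_zero_genetic_variance_gives_exact_zero_effects(self):
        cfg = SimulationConfig(v_a=0.0, v_d=0.0, v_ec=0.0)
        eff = simulate_family_effects(cfg)
        assert not eff.sire.any() and not eff.dam.any()
        assert not eff.block.any() and not eff.plant.any()

    def test_sire_variance_is_half_additive(self):
        cfg = SimulationConfig(n_sires=100_000, v_a=0.8, seed=5)
        eff = simulate_family_effects(cfg)
        target = 0.4
        mc_se = target * np.sqrt(2 / (len(eff.sire) - 1))
        assert abs(np.var(eff.sire, ddof=1) - target) < 3 * mc_se

    def test_dam_variance_composition(self):
        # with the full common-environment share on the dam:
        # V_A/4 + V_D/2 + V_Ec = 0.1 + 0.1 + 0.1
        cfg = SimulationConfig(
            n_sires=100_000,
            v_a=0.4,
            v_d=0.2,
            v_ec=0.1,
            ec_dam_share=1.0,
            ec_plant_share=0.0,
            ec_block_share=0.0,
            seed=6,
        )
        eff = simulate_family_effects(cfg)
        target = 0.3
        mc_se = target * np.sqrt(2 / (len(eff.dam) - 1))
        assert abs(np.var(eff.dam, ddof=1) - target) < 3 * mc_se


class TestSimulateSurvival:
    def test_certain_survival_means_no_deaths(self):
        cfg = SimulationConfig(
            v_a=0, v_d=0, v_ec=0, v_e=0,
            baseline_survival_control=1.0, baseline_survival_exposed=1.0,
        )
        table = simulate_survival(
            generate_design(cfg), simulate_family_effects(cfg), cfg
        )
        assert table.df["n_dead_day10"].eq(0).all()

    def test_pooled_survival_matches_baselines(self):
        # no family variation: pooled survival ~ 30% exposed / 97% control
        cfg = SimulationConfig(
            n_sires=200, v_a=0, v_d=0, v_ec=0, v_e=0, seed=3
        )
        table = simulate_survival(
            generate_design(cfg), simulate_family_effects(cfg), cfg
        )
        for arm, target in (("exposed", 0.30), ("control", 0.97)):
            sub = table.subset(arm).df
            surv = 1 - sub["n_dead_day10"].sum() / sub["n_nymphs"].sum()
            assert surv == pytest.approx(target, abs=0.01)

    def test_mean_deaths_matches_binomial_expectation(self):
        cfg = SimulationConfig(
            n_sires=5000, n_replicates_per_family=1,
            nymphs_per_family_mean=20,
            v_a=0, v_d=0, v_ec=0, v_e=0,
            baseline_survival_control=0.5, baseline_survival_exposed=0.5,
            link="identity", seed=9,
        )
        table = simulate_survival(
            generate_design(cfg), simulate_family_effects(cfg), cfg
        )
        # brute-force average over 10000 family rows of binomial(n~Poisson(20), 1/2)
        assert table.df["n_dead_day10"].mean() == pytest.approx(10.0, rel=0.02)

    def test_byte_identical_tables_for_same_seed(self, tmp_path):
        cfg = SimulationConfig(seed=21)
        for sub in ("a", "b"):
            t = simulate_survival(
                generate_design(cfg), simulate_family_effects(cfg), cfg
            )
            write_tables({"survival": t}, tmp_path / sub)
        assert (tmp_path / "a" / "survival.csv").read_bytes() == (
            tmp_path / "b" / "survival.csv"
        ).read_bytes()


class TestSimulateLifeHistory:
    def test_certain_hatching(self):
        lh = LifeHistoryConfig(hatch_p_control=1.0, hatch_p_exposed=1.0,
                               hatch_overdispersion=0.0)
        cfg = SimulationConfig(seed=2, life_history=lh)
        life = simulate_life_history(cfg)
        assert (life.final_hatched() == life.df["eggs_laid"]).all()

    def test_poisson_limit_variance_mean_ratio(self):
        lh = LifeHistoryConfig(
            n_plants_per_arm=400, nb_size=1e12, pair_sd_log=0.0,
            mean_total_eggs_control=20.0, mean_total_eggs_exposed=20.0,
            disk_day_weights=(1.0, 1.0, 1.0, 1.0),
        )
        cfg = SimulationConfig(seed=4, life_history=lh)
        eggs = simulate_life_history(cfg).df["eggs_laid"]
        ratio = eggs.var(ddof=1) / eggs.mean()
        assert ratio == pytest.approx(1.0, abs=0.08)

    def test_group_means_recover_defaults(self):
        # treatment means anchored at 21.47 / 37.27 eggs over 4 disks
        lh = LifeHistoryConfig(n_plants_per_arm=600)
        cfg = SimulationConfig(seed=8, life_history=lh)
        df = simulate_life_history(cfg).df
        totals = df.groupby(["treatment", "plant_id", "replicate_id"])[
            "eggs_laid"
        ].sum()
        assert totals["exposed"].mean() == pytest.approx(21.47, rel=0.07)
        assert totals["control"].mean() == pytest.approx(37.27, rel=0.07)

    def test_cumulative_hatch_columns_monotone(self):
        life = simulate_life_history(SimulationConfig(seed=13))
        hm = life.df[life.hatch_columns(life.df)].to_numpy()
        assert (np.diff(hm, axis=1) >= 0).all()


class TestTableIO:
    def test_round_trip_identity(self, tmp_path):
        cfg = SimulationConfig(seed=31)
        surv = simulate_survival(
            generate_design(cfg), simulate_family_effects(cfg), cfg
        )
        life = simulate_life_history(cfg)
        write_tables({"survival": surv, "life_history": life}, tmp_path)
        back = read_tables(tmp_path)
        assert back["survival"] == surv
        assert back["life_history"] == life

    def test_empty_table_round_trip(self, tmp_path):
        empty = FamilySurvivalTable(
            pd.DataFrame(columns=list(FamilySurvivalTable.COLUMNS))
        )
        write_tables({"survival": empty}, tmp_path)
        assert len(read_tables(tmp_path)["survival"]) == 0

    def test_deaths_exceeding_nymphs_rejected_with_row(self):
        df = generate_design(SimulationConfig()).df.copy()
        df.loc[3, "n_dead_day10"] = df.loc[3, "n_nymphs"] + 1
        with pytest.raises(SchemaError, match="row 3"):
            FamilySurvivalTable(df)

    def test_missing_column_rejected(self):
        df = generate_design(SimulationConfig()).df.drop(columns=["dam_id"])
        with pytest.raises(SchemaError, match="dam_id"):
            FamilySurvivalTable(df)

    def test_non_integer_counts_rejected(self):
        df = generate_design(SimulationConfig()).df.copy()
        df["n_nymphs"] = df["n_nymphs"] + 0.5
        with pytest.raises(SchemaError, match="non-integer"):
            FamilySurvivalTable(df)

    def test_decreasing_hatch_counts_rejected(self):
        life = simulate_life_history(SimulationConfig(seed=1))
        df = life.df.copy()
        cols = life.hatch_columns(df)
        df.loc[0, cols[0]] = 5
        df.loc[0, cols[-1]] = 0
        with pytest.raises(SchemaError):
            LifeHistoryTable(df)


def test_expected_binomial_noise_closed_form():
    # fixed n: E[p(1-p)]/n exactly; Poisson mean 200 makes E[1/n] ~ 1/199
    val = expected_binomial_noise(0.5, 0.01, 200)
    assert val == pytest.approx((0.25 - 0.01) / 199, rel=0.02)


def test_config_validation_errors():
    with pytest.raises(ValueError):
        SimulationConfig(n_sires=0).validate()
    with pytest.raises(ValueError):
        SimulationConfig(v_a=-0.1).validate()
    with pytest.raises(ValueError):
        SimulationConfig(baseline_survival_exposed=1.3).validate()
    with pytest.raises(ValueError):
        SimulationConfig(link="probit").validate()
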