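"""Generator contracts: determinism, guild structure, gradient response,
identification and trait degradation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from recruits.inventory_io import UNRESOLVED
from recruits.synthetic_forest import (
    GUILDS,
    TRAITS,
    ScenarioConfig,
    degrade_identifications,
    degrade_traits,
    generate_species_pool,
    simulate_inventory,
)

from conftest import small_scenario


class TestSpeciesPool:
    def test_same_seed_identical(self, small_cfg):
        p1 = generate_species_pool(small_cfg, np.random.default_rng(3))
        p2 = generate_species_pool(small_cfg, np.random.default_rng(3))
        pd.testing.assert_frame_equal(p1.table, p2.table)

    def test_degenerate_mixture_all_one_guild(self):
        cfg = small_scenario(
            n_species=10, guild_proportions={"shade-tolerant": 1.0}
        )
        pool = generate_species_pool(cfg, np.random.default_rng(0))
        assert (pool.table["guild"] == "shade-tolerant").all()

    def test_invalid_guild_proportions(self):
        with pytest.raises(ValueError):
            small_scenario(guild_proportions={"pioneer": -1.0, "shade-tolerant": 2.0})

    def test_sla_wsg_tradeoff(self):
        cfg = ScenarioConfig()  # 600 species, default guild mix
        pool = generate_species_pool(cfg, np.random.default_rng(11))
        r, p = stats.pearsonr(pool.table["sla_m2_kg"], pool.table["wsg_g_cm3"])
        assert r < 0 and p < 0.05

    def test_guild_trait_syndromes(self):
        pool = generate_species_pool(ScenarioConfig(), np.random.default_rng(4))
        g = pool.table.groupby("guild")[["sla_m2_kg", "wsg_g_cm3", "leaf_toughness_n", "hmax_m"]].mean()
        assert g.loc["pioneer", "sla_m2_kg"] > g.loc["shade-tolerant", "sla_m2_kg"]
        for trait in ["wsg_g_cm3", "leaf_toughness_n", "hmax_m"]:
            assert g.loc["pioneer", trait] < g.loc["shade-tolerant", trait]

    def test_base_abundance_normalized(self, small_cfg, rng):
        pool = generate_species_pool(small_cfg, rng)
        assert pool.table["base_abundance"].sum() == pytest.approx(1.0)


class TestSimulation:
    def test_same_seed_identical_inventory(self, small_cfg):
        out1 = simulate_inventory(
            generate_species_pool(small_cfg, np.random.default_rng(5)),
            small_cfg,
            np.random.default_rng(6),
        )
        out2 = simulate_inventory(
            generate_species_pool(small_cfg, np.random.default_rng(5)),
            small_cfg,
            np.random.default_rng(6),
        )
        pd.testing.assert_frame_equal(out1[0].records, out2[0].records)
        pd.testing.assert_frame_equal(out1[2].trees, out2[2].trees)

    def test_recruitment_increases_with_disturbance(self):
        """Monte-Carlo: mean annual recruits higher in a 60%-lost plot than a 10% one."""
        cfg = small_scenario(
            n_plots=2, agb_lost_pct=(10.0, 60.0), n_species=30, stems_per_ha=20.0,
            base_recruits_per_year=5.0, horizon=16,
        )
        master = np.random.default_rng(21)
        wins = 0
        n_rep = 50
        for _ in range(n_rep):
            pool = generate_species_pool(cfg, master.spawn(1)[0])
            _, _, truth = simulate_inventory(pool, cfg, master.spawn(1)[0])
            rec = truth.trees.dropna(subset=["recruit_year"])
            per_plot = rec.groupby("plot_id").size()
            wins += per_plot.get("P02", 0) > per_plot.get("P01", 0)
        assert wins / n_rep > 0.8

    def test_pioneer_pulse_peaks_at_configured_time(self):
        """Median pioneer-share peak over replicates within +-4 y of the target."""
        cfg = small_scenario(
            n_plots=1, agb_lost_pct=(50.0,), n_species=80, stems_per_ha=20.0,
            base_recruits_per_year=30.0,
        )
        master = np.random.default_rng(31)
        peaks = []
        pool = generate_species_pool(cfg, master.spawn(1)[0])
        for _ in range(50):
            _, _, truth = simulate_inventory(pool, cfg, master.spawn(1)[0])
            rec = truth.trees.dropna(subset=["recruit_year"]).copy()
            rec["t"] = rec["recruit_year"] - cfg.disturbance_year
            share = (
                rec.assign(p=rec["guild"] == "pioneer").groupby("t")["p"].mean()
            )
            peaks.append(float(share.idxmax()))
        assert abs(np.median(peaks) - cfg.peak_time) <= 4.0

    def test_control_guild_mix_stationary(self):
        """No time trend of the recruit guild mix in an undisturbed plot."""
        cfg = small_scenario(
            n_plots=1, agb_lost_pct=(0.0,), n_species=80, stems_per_ha=20.0,
            base_recruits_per_year=30.0,
        )
        rng = np.random.default_rng(41)
        pool = generate_species_pool(cfg, rng)
        _, _, truth = simulate_inventory(pool, cfg, rng)
        rec = truth.trees.dropna(subset=["recruit_year"]).copy()
        decade = ((rec["recruit_year"] - cfg.disturbance_year - 1) // 10).astype(int)
        table = pd.crosstab(decade, rec["guild"])
        _, p, _, _ = stats.chi2_contingency(table)
        assert p > 0.01


class TestDegradeIdentifications:
    def test_no_degradation_is_identity(self, small_bundle):
        cfg, pool, inv, _, _ = small_bundle
        cfg0 = small_scenario(ambiguity_rate=0.0, id_loss_rate=0.0)
        out, assoc = degrade_identifications(inv, pool, cfg0, np.random.default_rng(0))
        assert (out.records["species"] == inv.records["species"]).all()
        # every vernacular unambiguous
        assert all(len(pairs) == 1 for pairs in assoc.mapping.values())

    def test_full_erasure_still_deterministic(self, small_bundle):
        _, pool, inv, _, _ = small_bundle
        cfg = small_scenario(ambiguity_rate=0.0, id_loss_rate=1.0)
        out, assoc = degrade_identifications(inv, pool, cfg, np.random.default_rng(0))
        assert (out.records["species"] == UNRESOLVED).all()
        lookup = {v: pairs[0][0] for v, pairs in assoc.mapping.items()}
        recovered = out.records["vernacular"].map(lookup)
        assert (recovered.to_numpy() == inv.records["species"].to_numpy()).all()

    def test_ambiguous_fraction_configured(self, small_bundle):
        _, pool, inv, _, _ = small_bundle
        cfg = small_scenario(ambiguity_rate=1.0, id_loss_rate=0.0)
        _, assoc = degrade_identifications(inv, pool, cfg, np.random.default_rng(0))
        sizes = [len(p) for p in assoc.mapping.values()]
        # families with >= 2 species must yield multi-species vernaculars
        assert sum(s >= 2 for s in sizes) > 0.5 * len(sizes)

    def test_alphas_are_renormalized_abundances(self, small_bundle):
        _, pool, inv, _, _ = small_bundle
        cfg = small_scenario(ambiguity_rate=1.0, id_loss_rate=0.0)
        _, assoc = degrade_identifications(inv, pool, cfg, np.random.default_rng(2))
        abund = pool.table.set_index("species")["base_abundance"]
        for v, pairs in assoc.mapping.items():
            sp, al = zip(*pairs)
            expected = abund.loc[list(sp)].to_numpy()
            expected = expected / expected.sum()
            assert np.allclose(al, expected, atol=1e-12)


class TestDegradeTraits:
    def test_zero_missingness_equals_truth(self, small_bundle):
        _, pool, _, _, _ = small_bundle
        cfg = small_scenario(trait_missing_species_frac=0.0, trait_unsampled_frac=0.0)
        tm = degrade_traits(pool, cfg, np.random.default_rng(0))
        pd.testing.assert_frame_equal(
            tm.traits.sort_index(), pool.true_traits().sort_index(), check_names=False
        )

    def test_drop_count_exact(self):
        cfg = small_scenario(n_species=100, trait_unsampled_frac=0.4)
        pool = generate_species_pool(cfg, np.random.default_rng(1))
        tm = degrade_traits(pool, cfg, np.random.default_rng(2))
        assert len(tm.traits) == 60
        assert len(tm.taxonomy) == 100

    def test_masked_cells_near_target_rate(self):
        cfg = small_scenario(
            n_species=200, trait_unsampled_frac=0.0, trait_missing_species_frac=0.5
        )
        pool = generate_species_pool(cfg, np.random.default_rng(1))
        tm = degrade_traits(pool, cfg, np.random.default_rng(3))
        n_masked_species = tm.traits.isna().any(axis=1).sum()
        assert n_masked_species == 100  # exact species count
        cells = tm.traits.isna().to_numpy().sum()
        # 1-3 cells per masked species, uniform -> mean 2
        assert 100 <= cells <= 300

    def test_all_dropped_errors(self, small_bundle):
        _, pool, _, _, _ = small_bundle
        cfg = small_scenario(trait_unsampled_frac=1.0)
        with pytest.raises(ValueError):
            degrade_traits(pool, cfg, np.random.default_rng(0))
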