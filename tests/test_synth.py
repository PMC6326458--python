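import numpy as np
import pandas as pd
import pytest

import reefcs as rc
from reefcs.synth import (
    StudyDesign, BenthicParams, FishCommunityParams, SpeciesParams,
    ObserverErrorParams, SSTParams, BENTHIC_CATEGORIES,
)


def small_design(**kw):
    defaults = dict(sites=("S1", "S2"), replicates_per_zone=1,
                    years=(2001, 2002), missing_fraction_by_year={})
    defaults.update(kw)
    return StudyDesign(**defaults)


class TestDesign:
    def test_default_scenario_has_51_permanent_transects(self):
        assert rc.default_design().n_permanent_transects == 51

    def test_roster_lists_every_permanent_transect_each_year(self):
        d = rc.default_design()
        roster = rc.generate_design(d, seed=0)
        assert roster.groupby("year")["transect"].count().eq(51).all()

    def test_no_missingness_means_all_sampled(self):
        roster = rc.generate_design(small_design(), seed=1)
        assert roster["sampled"].all()

    def test_missing_fraction_rounds_sampled_size(self):
        # 2 sites x 3 habitats x 1 rep = 6 transects; 0.5 missing -> 3 sampled
        d = small_design(missing_fraction_by_year={2002: 0.5})
        roster = rc.generate_design(d, seed=1)
        per_year = roster[roster["sampled"]].groupby("year").size()
        assert per_year[2001] == 6
        assert per_year[2002] == 3

    @pytest.mark.parametrize("kw", [
        dict(sites=()),
        dict(years=()),
        dict(years=(2002, 2001)),
        dict(replicates_per_zone=0),
        dict(missing_fraction_by_year={2001: 1.0}),
        dict(flat_absent_sites=frozenset({"nowhere"})),
    ])
    def test_invalid_designs_rejected(self, kw):
        with pytest.raises(ValueError):
            small_design(**kw)


class TestBenthic:
    def test_zero_noise_reproduces_trajectory_exactly(self):
        d = small_design()
        params = BenthicParams(
            initial_cover={"hard_coral": 40, "soft_coral": 15, "macroalgae": 15,
                           "rock": 10, "rubble": 10, "sand": 10},
            coral_trajectory={2001: 40.0, 2002: 20.0}, cover_noise_sd=0.0)
        roster = rc.generate_design(d, seed=0)
        benthic = rc.simulate_benthic(roster, params, seed=0)
        assert (benthic.loc[benthic["year"] == 2001, "hard_coral"] == 40.0).all()
        assert (benthic.loc[benthic["year"] == 2002, "hard_coral"] == 20.0).all()
        # coral loss moves into the abiotic categories
        assert benthic.loc[benthic["year"] == 2002, ["rock", "rubble", "sand"]].sum(axis=1).iloc[0] == pytest.approx(50.0)

    def test_covers_sum_to_100(self, default_dataset):
        sums = default_dataset["benthic"][list(BENTHIC_CATEGORIES)].sum(axis=1)
        assert np.allclose(sums, 100.0, atol=1e-9)
        assert (default_dataset["benthic"][list(BENTHIC_CATEGORIES)] >= 0).all().all()

    def test_default_trajectory_endpoints(self):
        traj = rc.default_benthic_params().coral_trajectory
        assert traj[2002] == 45.8
        assert traj[2012] == 14.0

    def test_missing_trajectory_year_errors(self):
        d = small_design()
        params = BenthicParams(
            initial_cover={"hard_coral": 40, "soft_coral": 15, "macroalgae": 15,
                           "rock": 10, "rubble": 10, "sand": 10},
            coral_trajectory={2001: 40.0})
        with pytest.raises(ValueError, match="trajectory"):
            rc.simulate_benthic(rc.generate_design(d, seed=0), params, seed=0)


class TestFishCounts:
    def _flat_benthic(self, roster, coral_by_year):
        rows = roster[roster["sampled"]].copy()
        rows["hard_coral"] = rows["year"].map(coral_by_year)
        for cat in ("soft_coral", "macroalgae", "rock", "rubble", "sand"):
            rows[cat] = (100 - rows["hard_coral"]) / 5
        return rows

    def test_total_zero_inflation_yields_no_records(self):
        d = small_design()
        roster = rc.generate_design(d, seed=0)
        benthic = self._flat_benthic(roster, {2001: 30, 2002: 30})
        params = FishCommunityParams(species=(
            SpeciesParams("allzero", "F", beta0=2.0, beta1=0.0, pi=0.999999, theta=2.0),), year_sd=0.0)
        # pi in [0,1): use pi ~ 1; all Bernoulli draws hit the structural zero
        fish = rc.simulate_fish_counts(roster, benthic, params, seed=3)
        assert fish.empty

    def test_mean_ratio_follows_coral_slope(self):
        # beta1=0.05 over a 30-point coral contrast -> mean ratio exp(1.5)
        d = StudyDesign(sites=("S",), habitats=("crest",), replicates_per_zone=400,
                        years=(2001, 2002), missing_fraction_by_year={})
        roster = rc.generate_design(d, seed=0)
        benthic = self._flat_benthic(roster, {2001: 45.0, 2002: 15.0})
        params = FishCommunityParams(species=(
            SpeciesParams("sp", "F", beta0=np.log(5) - 0.05 * 30, beta1=0.05,
                          pi=0.0, theta=2.0),), year_sd=0.0)
        fish = rc.simulate_fish_counts(roster, benthic, params, seed=5)
        full = roster[roster["sampled"]].merge(fish, on=list(roster.columns[:4]), how="left").fillna({"count": 0})
        means = full.groupby("year")["count"].mean()
        ratio = means[2001] / means[2002]
        assert ratio == pytest.approx(np.exp(0.05 * 30), rel=0.15)

    def test_nb_moments_at_zero_sigma(self):
        d = StudyDesign(sites=("S",), habitats=("crest",), replicates_per_zone=2000,
                        years=(2001, 2002), missing_fraction_by_year={})
        roster = rc.generate_design(d, seed=0)
        benthic = self._flat_benthic(roster, {2001: 30.0, 2002: 30.0})
        theta = 2.0
        mean_target = 5.0
        params = FishCommunityParams(species=(
            SpeciesParams("sp", "F", beta0=np.log(mean_target) - 0.05 * 30,
                          beta1=0.05, pi=0.0, theta=theta),), year_sd=0.0)
        fish = rc.simulate_fish_counts(roster, benthic, params, seed=7)
        full = roster[roster["sampled"]].merge(fish, on=list(roster.columns[:4]), how="left").fillna({"count": 0})
        y = full["count"].to_numpy()
        var_target = mean_target + mean_target ** 2 / theta
        se = np.sqrt(var_target / len(y))
        assert abs(y.mean() - mean_target) < 3 * se
        assert y.var() / y.mean() > 1.0  # overdispersed for finite theta

    def test_missing_benthic_row_errors(self):
        d = small_design()
        roster = rc.generate_design(d, seed=0)
        benthic = self._flat_benthic(roster, {2001: 30, 2002: 30}).iloc[:-1]
        with pytest.raises(ValueError, match="benthic row missing"):
            rc.simulate_fish_counts(roster, benthic, rc.default_fish_params(), seed=0)


class TestObserverError:
    def test_zero_rates_identity(self, default_dataset):
        fish = default_dataset["fish_true"]
        out, ledger = rc.inject_observer_error(
            fish, default_dataset["traits"],
            ObserverErrorParams(0.0, 0.0, 0.0), seed=1)
        pd.testing.assert_frame_equal(out, fish)
        assert ledger == {"phantoms": [], "misids": [], "cryptics": []}

    def test_phantoms_are_singletons_by_construction(self, default_dataset):
        fish = default_dataset["fish_observed"]
        for entry in default_dataset["ledger"]["phantoms"]:
            rows = fish[fish["species"] == entry["species"]]
            assert len(rows) == 1
            cells = rows[["site", "habitat", "transect", "year"]].drop_duplicates()
            assert len(cells) == 1

    def test_phantom_count_is_poisson_around_rate(self):
        counts = []
        for seed in range(12):
            data = rc.simulate_dataset(seed, observer_params=ObserverErrorParams(10.0, 0.0, 0.0))
            counts.append(len(data["ledger"]["phantoms"]))
        m = np.mean(counts)
        assert abs(m - 10.0) < 3 * np.sqrt(10.0 / len(counts))

    def test_misid_without_lookalikes_errors(self, default_dataset):
        traits = default_dataset["traits"]
        with pytest.raises(ValueError, match="lookalike"):
            rc.inject_observer_error(
                default_dataset["fish_true"], traits[traits["in_region"]],
                ObserverErrorParams(0.0, 0.5, 0.0), seed=1)

    def test_misids_conserve_abundance(self, default_dataset):
        assert (default_dataset["fish_observed"]["count"].sum()
                == default_dataset["fish_true"]["count"].sum()
                + sum(e["count"] for e in default_dataset["ledger"]["phantoms"])
                + sum(e["count"] for e in default_dataset["ledger"]["cryptics"]))


class TestSST:
    def test_no_anomaly_no_exceedance(self):
        params = SSTParams(climatology=tuple([28.0] * 11 + [29.9]), noise_sd=0.0)
        sst = rc.simulate_sst([2001, 2002], params, seed=0)
        assert len(sst) == 24
        assert (sst["sst_c"] <= params.threshold).all()

    def test_anomaly_year_crosses_threshold(self):
        params = SSTParams(climatology=tuple([28.0] * 11 + [29.9]),
                           anomaly_years={2002: 1.0}, noise_sd=0.0)
        sst = rc.simulate_sst([2001, 2002], params, seed=0)
        peak = sst[sst["year"] == 2002]["sst_c"].max()
        assert peak == pytest.approx(30.9)
        assert peak > params.threshold

    def test_default_threshold(self):
        assert rc.default_sst_params().threshold == 30.38


class TestReproducibility:
    def test_same_seed_identical_tables(self):
        a = rc.simulate_dataset(5)
        b = rc.simulate_dataset(5)
        for key in ("roster", "benthic", "fish_true", "fish_observed", "sst"):
            pd.testing.assert_frame_equal(a[key], b[key])
        assert a["ledger"] == b["ledger"]

    def test_different_seeds_differ(self):
        a = rc.simulate_dataset(5)
        b = rc.simulate_dataset(6)
        assert not a["fish_true"].equals(b["fish_true"])
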