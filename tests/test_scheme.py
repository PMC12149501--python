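"""Selection-round structure: preselection, final selection, mating, orchestration."""

import numpy as np
import pytest

from preselsim import scheme as sc
from preselsim import traits as tr


def full_scale_config(criterion="P", male=0.10, female=0.30, rounds=1):
    return sc.SchemeConfig(presel_male_frac=male, presel_female_frac=female,
                           criterion=criterion, n_rounds=rounds)


def desk_config(**kw):
    args = dict(chicks_per_round=600, hatches_per_round=7,
                presel_male_frac=0.10, presel_female_frac=0.30,
                criterion="G", n_sires=4, n_dams=40, mates_per_sire=10,
                chicks_per_dam_by_stage=(4, 4, 4, 3), n_rounds=2)
    args.update(kw)
    return sc.SchemeConfig(**args)


class TestPreselect:
    def test_full_scale_counts(self):
        """9000-chick 50:50 cohort at 10:30% -> 450 males, 1350 females."""
        rng = np.random.default_rng(0)
        ids = np.arange(9000)
        sex = np.zeros(9000, dtype=bool)
        sex[:4500] = True
        scores = rng.standard_normal(9000)
        keep = sc.preselect(ids, sex, scores, 0.10, 0.30)
        assert int(sex[keep].sum()) == 450
        assert int((~sex[keep]).sum()) == 1350

    def test_fraction_one_keeps_everyone(self):
        ids = np.arange(10)
        sex = np.array([True] * 5 + [False] * 5)
        keep = sc.preselect(ids, sex, np.arange(10.0), 1.0, 1.0)
        assert set(keep) == set(ids)

    def test_ties_resolved_by_ascending_id(self):
        ids = np.array([5, 3, 9, 1])
        sex = np.array([True] * 4)
        keep = sc.preselect(ids, sex, np.zeros(4), 0.5, 1.0)
        assert sorted(keep) == [1, 3]

    def test_nested_truncation_is_monotone_in_fraction(self):
        rng = np.random.default_rng(1)
        ids = np.arange(200)
        sex = rng.random(200) < 0.5
        scores = rng.standard_normal(200)
        small = set(sc.preselect(ids, sex, scores, 0.10, 0.30))
        large = set(sc.preselect(ids, sex, scores, 0.20, 0.60))
        assert small <= large

    def test_missing_scores_rejected(self):
        with pytest.raises(ValueError):
            sc.preselect(np.arange(4), np.array([True, True, False, False]),
                         np.array([1.0, np.nan, 0.0, 0.0]), 0.5, 0.5)


class TestFinalSelect:
    def test_exact_quotas(self):
        rng = np.random.default_rng(2)
        n = 1800
        ids = np.arange(n)
        sex = np.zeros(n, dtype=bool)
        sex[:450] = True
        sires, dams = sc.final_select(ids, sex, rng.standard_normal(n), 10, 150)
        assert sires.size == 10 and dams.size == 150
        assert np.all(sex[sires]) and not np.any(sex[dams])

    def test_matches_brute_force_sort(self):
        rng = np.random.default_rng(3)
        ids = np.arange(30)
        sex = rng.random(30) < 0.5
        index = rng.standard_normal(30)
        sires, dams = sc.final_select(ids, sex, index, 3, 5)
        males = ids[sex]
        want = males[np.argsort(-index[sex], kind="stable")][:3]
        assert set(sires) == set(want)

    def test_quota_equals_candidates_selects_all(self):
        ids = np.arange(6)
        sex = np.array([True] * 2 + [False] * 4)
        sires, dams = sc.final_select(ids, sex, np.arange(6.0), 2, 4)
        assert set(sires) == {0, 1} and set(dams) == {2, 3, 4, 5}

    def test_infeasible_quota_raises(self):
        with pytest.raises(ValueError, match="quota"):
            sc.final_select(np.arange(4), np.array([True] * 4),
                            np.arange(4.0), 5, 0)


class TestMatingPlan:
    def test_dam_and_sire_lifetime_offspring_counts(self):
        """One dam: 16+16+15+13 = 60 chicks; one sire (15 dams): 900."""
        config = full_scale_config()
        rng = np.random.default_rng(4)
        cohort = sc.assign_mates(np.arange(10), np.arange(10, 160), config, rng)
        # one cohort passing through all four reproductive stages contributes
        # exactly its stage litter sizes; occupy all four slots and count
        sire_arr, dam_arr, _ = sc.plan_matings([cohort] * 4, config)
        per_dam = np.bincount(dam_arr, minlength=160)
        per_sire = np.bincount(sire_arr, minlength=160)
        assert np.all(per_dam[10:] == 16 + 16 + 15 + 13)       # 60 per dam
        assert np.all(per_sire[:10] == 15 * 60)                # 900 per sire

    def test_hatch_sizes_differ_by_at_most_one_with_expected_mean(self):
        config = full_scale_config()
        rng = np.random.default_rng(5)
        cohort = sc.assign_mates(np.arange(10), np.arange(10, 160), config, rng)
        _, _, hatch = sc.plan_matings([cohort] * 4, config)
        sizes = np.bincount(hatch, minlength=7)
        assert sizes.sum() == 9000
        assert sizes.max() - sizes.min() <= 1
        assert sizes.mean() == pytest.approx(9000 / 7)   # ~1285.7, printed 1286

    def test_full_sib_families_spread_across_hatches(self):
        config = full_scale_config()
        rng = np.random.default_rng(6)
        cohort = sc.assign_mates(np.arange(10), np.arange(10, 160), config, rng)
        _, dam_arr, hatch = sc.plan_matings([cohort] * 4, config)
        first_dam = cohort.dams[0]
        assert np.unique(hatch[dam_arr == first_dam]).size == 7

    def test_exact_sex_split_in_hatched_cohort(self):
        config = desk_config()
        rng = np.random.default_rng(7)
        cohort = sc.assign_mates(np.arange(4), np.arange(4, 44), config, rng)
        chicks = sc.mate_and_hatch([cohort] * 4, config, rng)
        assert int(chicks.sex.sum()) == 300

    def test_wrong_cohort_count_rejected(self):
        config = desk_config()
        rng = np.random.default_rng(8)
        cohort = sc.assign_mates(np.arange(4), np.arange(4, 44), config, rng)
        with pytest.raises(ValueError):
            sc.plan_matings([cohort] * 3, config)


class TestSchemeConfigValidation:
    def test_mating_ratio_must_close(self):
        with pytest.raises(ValueError):
            sc.SchemeConfig(n_sires=10, n_dams=151, mates_per_sire=15)

    def test_litter_sizes_must_sum_to_round(self):
        with pytest.raises(ValueError):
            sc.SchemeConfig(chicks_per_round=9001)

    def test_unknown_criterion(self):
        with pytest.raises(ValueError):
            sc.SchemeConfig(criterion="X")


@pytest.fixture(scope="module")
def tiny_run(mini_setup):
    """Two rounds of a miniature scheme under each criterion."""
    cfg = dict(chicks_per_round=120, hatches_per_round=4,
               presel_male_frac=0.2, presel_female_frac=0.5,
               n_sires=2, n_dams=8, mates_per_sire=4,
               chicks_per_dam_by_stage=(4, 4, 4, 3), n_rounds=2)
    logs = {}
    for crit in ("P", "B", "G"):
        config = sc.SchemeConfig(criterion=crit, **cfg)
        logs[crit] = sc.run_scheme(mini_setup["base"], mini_setup["gmap"],
                                   mini_setup["params"], mini_setup["effects"],
                                   config, seed=5)
    return logs


class TestRunScheme:
    def test_log_has_all_round_artifacts(self, tiny_run):
        for crit, log in tiny_run.items():
            assert log.n_rounds == 2
            frame = log.round_frame(1)
            assert frame.shape[0] == 120
            assert frame["preselected"].sum() == 12 + 30
            assert frame["selected"].sum() == 2 + 8
            assert ("presel_index" in frame.columns) == (crit != "P")
            assert frame["final_index"].notna().all()

    def test_same_seed_reproduces_log_exactly(self, mini_setup):
        config = sc.SchemeConfig(chicks_per_round=120, hatches_per_round=4,
                                 presel_male_frac=0.2, presel_female_frac=0.5,
                                 criterion="G", n_sires=2, n_dams=8,
                                 mates_per_sire=4,
                                 chicks_per_dam_by_stage=(4, 4, 4, 3),
                                 n_rounds=2)
        args = (mini_setup["base"], mini_setup["gmap"], mini_setup["params"],
                mini_setup["effects"], config)
        a = sc.run_scheme(*args, seed=9)
        b = sc.run_scheme(*args, seed=9)
        for fa, fb in zip(a.rounds, b.rounds):
            assert fa.equals(fb)

    def test_pedigree_closed_and_parents_precede_offspring(self, tiny_run):
        log = tiny_run["G"]
        n = log.sire.size
        born = np.flatnonzero(log.sire >= 0)
        assert np.all(log.sire[born] < born)
        assert np.all(log.dam[born] < born)
        assert np.all(log.sex[log.sire[born]])
        assert not np.any(log.sex[log.dam[born]])

    def test_phenotype_and_genotype_leakage_guard(self, tiny_run):
        """Under criterion P no evaluation sees RFI/Gain data or genotypes of
        non-preselected birds: candidate counts in the log must match the
        preselection quotas exactly."""
        log = tiny_run["P"]
        for frame in log.rounds:
            assert frame.loc[~frame["preselected"], "selected"].sum() == 0
        assert log.diagnostics[-1]["n_genotyped"] == 2 * (12 + 30)

    def test_selected_subset_of_preselected(self, tiny_run):
        for log in tiny_run.values():
            for frame in log.rounds:
                assert (frame["selected"] <= frame["preselected"]).all()


def test_scaled_quota_bookkeeping_over_rounds(mini_setup):
    """Every round of a desk-style run hits its scaled quotas exactly."""
    config = sc.SchemeConfig(chicks_per_round=120, hatches_per_round=4,
                             presel_male_frac=0.2, presel_female_frac=0.5,
                             criterion="G", n_sires=2, n_dams=8,
                             mates_per_sire=4,
                             chicks_per_dam_by_stage=(4, 4, 4, 3), n_rounds=4)
    log = sc.run_scheme(mini_setup["base"], mini_setup["gmap"],
                        mini_setup["params"], mini_setup["effects"],
                        config, seed=21)
    for frame in log.rounds:
        males = frame["sex"] == "M"
        assert int((frame["preselected"] & males).sum()) == 12
        assert int((frame["preselected"] & ~males).sum()) == 30
        assert int((frame["selected"] & males).sum()) == 2
        assert int((frame["selected"] & ~males).sum()) == 8
        assert frame.groupby("hatch").size().max() - \
               frame.groupby("hatch").size().min() <= 1
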