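import numpy as np
import pytest
from scipy import stats

from clonodyn import (
    SyntheticCohortConfig,
    cmv_clonotype_count,
    derive_threshold,
    generate_cohort,
    generate_pair_with_timepoints,
    generate_repertoire,
    inverse_simpson,
)
from clonodyn.synthetic import (
    SimulationError,
    expected_richness,
    powerlaw_pmf,
    random_cdr3_keys,
)


def small_config(**kwargs):
    defaults = dict(
        n_hc=4, n_pairs=2, depth_min=2000, depth_max=2000, master_seed=7,
        n_decoys=20,
    )
    defaults.update(kwargs)
    return SyntheticCohortConfig(**defaults)


class TestConfigValidation:
    def test_rejects_bad_alpha_and_rates(self):
        with pytest.raises(SimulationError):
            small_config(alpha=0.5)
        with pytest.raises(SimulationError):
            small_config(public_rate=1.5)

    def test_rejects_infeasible_richness(self):
        with pytest.raises(SimulationError):
            small_config(richness=5000)  # > depth 2000

    def test_rejects_mismatched_timepoint_settings(self):
        with pytest.raises(SimulationError):
            small_config(n_spikes=(1, 2))


class TestGenerateRepertoire:
    def test_exact_depth_and_reproducibility(self):
        cfg = small_config()
        a = generate_repertoire(cfg, "donor", seed=11)
        b = generate_repertoire(cfg, "donor", seed=11)
        assert a.total_templates == 2000
        assert a.counts.equals(b.counts)
        assert generate_repertoire(cfg, "donor", seed=12).counts.equals(a.counts) is False

    def test_keys_are_cdr3_like(self):
        t = generate_repertoire(small_config(), "donor", seed=3)
        for k in t.counts.index[:100]:
            assert k[0] == "C" and k[-1] == "F" and 8 <= len(k) <= 20

    def test_zero_public_rate_gives_no_sharing(self):
        cfg = small_config(public_rate=0.0)
        a = generate_repertoire(cfg, "donor", seed=1)
        b = generate_repertoire(cfg, "donor", seed=2)
        assert len(set(a.counts.index) & set(b.counts.index)) == 0

    def test_large_alpha_limit_nearly_all_singletons(self):
        cfg = small_config(alpha=50.0)
        t = generate_repertoire(cfg, "donor", seed=5)
        assert (t.counts == 1).mean() > 0.999
        assert inverse_simpson(t) == pytest.approx(t.richness, rel=0.01)

    def test_size_distribution_matches_power_law(self):
        """Pooled drawn clone sizes follow the configured truncated law
        (chi-square goodness of fit at the 1% level; tail binned)."""
        cfg = small_config(depth_min=5000, depth_max=5000)
        sizes = np.concatenate(
            [
                generate_repertoire(cfg, "donor", seed=s).counts.to_numpy()
                for s in range(30)
            ]
        )
        pmf = powerlaw_pmf(cfg.alpha, cfg.max_clone_size)
        # bins 1..9 individually, 10+ pooled to keep expected counts large
        edges = list(range(1, 10))
        observed = [np.sum(sizes == k) for k in edges] + [np.sum(sizes >= 10)]
        probs = [pmf[k - 1] for k in edges] + [pmf[9:].sum()]
        expected = np.asarray(probs) * len(sizes)
        _, p = stats.chisquare(observed, expected)
        assert p > 0.01

    def test_public_pool_present_in_every_sample(self):
        cfg = small_config()
        cohort = generate_cohort(cfg)
        pool = set(cohort.ground_truth.public_keys)
        assert len(pool) > 0
        for t in cohort.all_tables():
            assert pool <= set(t.counts.index)


class TestGeneratePair:
    def test_full_carryover_recipient_within_donor(self):
        cfg = small_config(
            public_rate=0.0, carryover_fraction=1.0,
            timepoints=("d30",), richness_multipliers=(1.0,), n_spikes=(0,),
        )
        donor, _, tps, truth = generate_pair_with_timepoints(cfg, "p0")
        recipient = tps["d30"]
        assert set(recipient.counts.index) <= set(donor.counts.index)
        assert sorted(truth.carryover_keys["d30"]) == sorted(recipient.counts.index)

    def test_zero_carryover_overlap_is_public_only(self):
        cfg = small_config(carryover_fraction=0.0)
        donor, _, tps, truth = generate_pair_with_timepoints(cfg, "p0")
        shared = set(donor.counts.index) & set(tps["d30"].counts.index)
        assert shared == set(generate_cohort(cfg).ground_truth.public_keys) & shared
        assert truth.carryover_keys["d30"] == []

    def test_carryover_keys_come_from_donor_and_match_fraction(self):
        # no spikes: at a forced small depth, heavy spiking displaces de-novo
        # singletons and the realized fraction would exceed the nominal one
        cfg = small_config(
            carryover_fraction=0.05,
            richness_multipliers=(1.0, 1.0, 1.0), n_spikes=(0, 0, 0),
        )
        donor, _, tps, truth = generate_pair_with_timepoints(cfg, "p0")
        for tp, table in tps.items():
            carried = set(truth.carryover_keys[tp])
            assert carried <= set(donor.counts.index)
            assert carried <= set(table.counts.index)
            assert len(carried) / table.richness == pytest.approx(0.05, rel=0.15)

    def test_spike_clones_exceed_reference_threshold(self):
        cfg = small_config()
        cohort = generate_cohort(cfg)
        threshold = derive_threshold(cohort.reference_tables())
        for pair_id, tps in cohort.recipients.items():
            truth = cohort.ground_truth.pairs[pair_id]
            for tp, table in tps.items():
                spike_sizes = table.counts.loc[truth.spike_keys[tp]]
                assert (spike_sizes > threshold.tau).all()

    def test_gvhd_mode_adds_hyperexpanded_clones(self):
        cfg = small_config(gvhd_mode=True, n_hyper_spikes=3, depth_min=4000, depth_max=4000)
        donor, _, tps, truth = generate_pair_with_timepoints(cfg, "p0")
        last = cfg.timepoints[-1]
        assert len(truth.hyper_keys[last]) == 3
        assert (tps[last].counts.loc[truth.hyper_keys[last]] > 100).all()

    def test_shared_sizes_rank_correlated(self):
        cfg = small_config(
            carryover_fraction=0.2, carryover_rank_corr=0.9,
            depth_min=5000, depth_max=5000,
            timepoints=("d30",), richness_multipliers=(1.0,), n_spikes=(0,),
        )
        rhos = []
        for i in range(5):
            donor, _, tps, truth = generate_pair_with_timepoints(
                small_config(master_seed=i, carryover_fraction=0.2,
                             carryover_rank_corr=0.9, depth_min=5000, depth_max=5000,
                             timepoints=("d30",), richness_multipliers=(1.0,),
                             n_spikes=(0,)),
                f"p{i}",
            )
            keys = truth.carryover_keys["d30"]
            rho, _ = stats.spearmanr(
                donor.counts.loc[keys], tps["d30"].counts.loc[keys]
            )
            rhos.append(rho)
        assert np.mean(rhos) > 0.3  # positive size association by construction


class TestCohortAndLabels:
    def test_byte_reproducible(self):
        a = generate_cohort(small_config())
        b = generate_cohort(small_config())
        for ta, tb in zip(a.all_tables(), b.all_tables()):
            assert ta.sample_id == tb.sample_id
            assert ta.counts.equals(tb.counts)
        assert a.ground_truth.to_json_dict() == b.ground_truth.to_json_dict()

    def test_reference_contains_labeled_keys_plus_decoys(self):
        cohort = generate_cohort(small_config())
        truth = cohort.ground_truth
        cohort_keys = set()
        for t in cohort.all_tables():
            cohort_keys.update(t.counts.index)
        assert set(truth.labels) <= cohort_keys
        decoys = set(cohort.reference.entries) - set(truth.labels)
        assert len(decoys) == cohort.config.n_decoys
        assert decoys.isdisjoint(cohort_keys)

    def test_zero_label_rates_decoy_only_reference(self):
        cfg = small_config(
            category_label_rates={"pathogen": 0.0, "cancer": 0.0,
                                  "autoimmune": 0.0, "allergy": 0.0},
            cmv_rate=0.0,
        )
        cohort = generate_cohort(cfg)
        assert cohort.ground_truth.labels == {}
        for t in cohort.all_tables()[:2]:
            assert cmv_clonotype_count(t, cohort.reference.restrict_disease("CMV")) == 0

    def test_cmv_label_rate_binomial(self):
        rate = 0.02
        cfg = small_config(cmv_rate=rate, n_hc=6, depth_min=4000, depth_max=4000)
        cohort = generate_cohort(cfg)
        cmv_ref = cohort.reference.restrict_disease("CMV")
        counts = [cmv_clonotype_count(t, cmv_ref) for t in cohort.healthy_controls]
        richness = [t.richness for t in cohort.healthy_controls]
        observed = sum(counts) / sum(richness)
        se = np.sqrt(rate * (1 - rate) / sum(richness))
        assert abs(observed - rate) <= 4 * se


def test_expected_richness_matches_mean_size():
    pmf = powerlaw_pmf(2.5, 30)
    mean = float((np.arange(1, 31) * pmf).sum())
    assert expected_richness(6000, 2.5, 30) == round(6000 / mean)


def test_random_keys_unique_and_avoid_existing(rng):
    existing = {"CAAAAAAF"}
    keys = random_cdr3_keys(rng, 500, existing=existing)
    assert len(set(keys)) == 500
    assert "CAAAAAAF" not in keys
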