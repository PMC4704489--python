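"""The synthetic generators reproduce the generative model they claim."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from splicevar.inclusion import records_from_plate
from splicevar.synthetic import (
    SimulationConfig,
    generate_conservation_profiles,
    generate_control_plate,
    generate_posterior_inclusion,
    generate_qpcr_plate,
)


def test_invalid_configs_are_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(pi_range=(0.5, 1.5)).validate()
    with pytest.raises(ValueError):
        SimulationConfig(delta_range=(-0.1, 0.2)).validate()
    with pytest.raises(ValueError):
        SimulationConfig(n_cells_per_condition=0).validate()
    with pytest.raises(ValueError):
        SimulationConfig(technical_noise_sd=-1.0).validate()


def test_bad_expression_model_rejected():
    cfg = SimulationConfig(
        n_exons_per_group=2,
        n_cells_per_condition=2,
        expression_model={"family": "no-such-family"},
    )
    with pytest.raises(ValueError):
        generate_qpcr_plate(cfg)


def test_same_seed_gives_identical_output(small_config):
    p1, t1 = generate_qpcr_plate(small_config)
    p2, t2 = generate_qpcr_plate(small_config)
    pd.testing.assert_frame_equal(p1.wells, p2.wells)
    pd.testing.assert_frame_equal(t1.counts, t2.counts)
    p3, _ = generate_qpcr_plate(small_config.with_(seed=small_config.seed + 1))
    assert not p3.wells["Ct"].equals(p1.wells["Ct"])


def test_noise_free_plate_round_trips_to_exact_count_ratios(clean_plate):
    """With zero technical noise and no dropout, back-computed p_hat is k/n."""
    plate, truth = clean_plate
    rec = records_from_plate(plate)
    merged = rec.merge(truth.counts, on=["sample_id", "exon_id"])
    assert len(merged) == len(truth.counts)
    np.testing.assert_allclose(
        merged["p_hat"], merged["k"] / merged["n"], rtol=0, atol=1e-9
    )
    np.testing.assert_allclose(merged["n_hat"], merged["n"], rtol=1e-9)


def test_dispersed_inclusion_and_counts_respect_truth_invariants(small_config):
    _, truth = generate_qpcr_plate(small_config)
    merged = truth.counts.merge(truth.exons, on="exon_id")
    lo = np.maximum(merged["pi"] - merged["delta"], 0.0)
    hi = np.minimum(merged["pi"] + merged["delta"], 1.0)
    assert ((merged["u"] >= lo) & (merged["u"] <= hi)).all()
    assert ((merged["k"] >= 0) & (merged["k"] <= merged["n"])).all()


def test_mean_inclusion_obeys_law_of_large_numbers():
    """pi=0.3, delta=0, n=1000, 500 cells: mean k/n within 3 binomial SEs."""
    cfg = SimulationConfig(
        n_exons_per_group=1,
        n_cells_per_condition=500,
        conditions=("293T",),
        pi_range=(0.3, 0.3),
        delta_range=(0.0, 0.0),
        expression_model={"family": "fixed", "n": 1000},
        technical_noise_sd=0.0,
        seed=5,
    )
    _, truth = generate_qpcr_plate(cfg)
    p_hat = truth.counts["k"] / truth.counts["n"]
    se = np.sqrt(0.3 * 0.7 / 1000 / len(p_hat))
    assert abs(p_hat.mean() - 0.3) < 3 * se


def test_variance_of_p_hat_increases_with_dispersion():
    """Across-cell variance of k/n grows with delta at fixed pi and n."""
    variances = []
    for delta in (0.0, 0.05, 0.15):
        cfg = SimulationConfig(
            n_exons_per_group=1,
            n_cells_per_condition=2000,
            conditions=("293T",),
            pi_range=(0.5, 0.5),
            delta_range=(delta, delta),
            expression_model={"family": "fixed", "n": 500},
            seed=9,
        )
        _, truth = generate_qpcr_plate(cfg)
        variances.append((truth.counts["k"] / truth.counts["n"]).var(ddof=1))
    assert variances[0] < variances[1] < variances[2]


class TestControlPlate:
    def test_replicates_share_one_inclusion_level(self, small_config):
        _, truth = generate_control_plate(small_config)
        assert (truth.exons["delta"] == 0).all()
        per_exon = truth.counts.groupby("exon_id")["u"].nunique()
        assert (per_exon == 1).all()

    def test_high_expression_limit_has_negligible_variance(self):
        cfg = SimulationConfig(
            n_exons_per_group=2,
            n_cells_per_condition=20,
            conditions=("293T",),
            expression_model={"family": "fixed", "n": 10**6},
            pi_range=(0.3, 0.7),
            technical_noise_sd=0.0,
            seed=3,
        )
        _, truth = generate_control_plate(cfg, expression_scale=1.0)
        var = truth.counts.groupby("exon_id").apply(
            lambda g: (g["k"] / g["n"]).var(ddof=1), include_groups=False
        )
        assert (var < 1e-5).all()

    def test_replicate_variance_matches_binomial_closed_form(self):
        cfg = SimulationConfig(
            n_exons_per_group=1,
            n_cells_per_condition=10_000,
            conditions=("293T",),
            expression_model={"family": "fixed", "n": 200},
            pi_range=(0.4, 0.4),
            technical_noise_sd=0.0,
            seed=21,
        )
        _, truth = generate_control_plate(cfg, expression_scale=1.0)
        p_hat = truth.counts["k"] / truth.counts["n"]
        expected = 0.4 * 0.6 / 200
        assert p_hat.var(ddof=1) == pytest.approx(expected, rel=0.1)

    def test_diluted_control_has_lower_et_than_single_cell(self, small_config):
        single, _ = generate_qpcr_plate(small_config)
        control, _ = generate_control_plate(small_config, expression_scale=0.05)

        def mean_detected_et(plate):
            w = plate.wells
            det = w[(w["Ct"] < plate.c_max) & (w["isoform_role"] != "hkg")]
            return (plate.c_max - det["Ct"]).mean()

        assert mean_detected_et(control) < mean_detected_et(single)


class TestConservationProfiles:
    def test_distribution_of_exon_means_is_right_skewed(self):
        cfg = SimulationConfig(n_exons_per_group=1000, seed=13)
        prof = generate_conservation_profiles(cfg)
        means = prof.groupby("exon_id")["score"].mean()
        assert stats.skew(means) > 0

    def test_upstream_downstream_means_are_correlated(self):
        cfg = SimulationConfig(n_exons_per_group=300, seed=13)
        prof = generate_conservation_profiles(cfg)
        side_means = prof.pivot_table(index="exon_id", columns="side", values="score")
        r = np.corrcoef(side_means["up"], side_means["down"])[0, 1]
        assert r > 0.5
        # weaker coupling when the per-side jitter dominates
        loose = cfg.with_(
            conservation_model={**cfg.conservation_model, "side_sd": 0.5}
        )
        prof2 = generate_conservation_profiles(loose)
        sm2 = prof2.pivot_table(index="exon_id", columns="side", values="score")
        assert np.corrcoef(sm2["up"], sm2["down"])[0, 1] < r

    def test_conserved_group_occupies_the_upper_tail(self):
        cfg = SimulationConfig(n_exons_per_group=100, seed=13)
        prof = generate_conservation_profiles(cfg)
        g = prof.groupby(["exon_id", "group"])["score"].mean().reset_index()
        cons = g.loc[g["group"] == "conserved", "score"]
        non = g.loc[g["group"] == "non_conserved", "score"]
        assert cons.mean() > non.mean()

    def test_scores_in_unit_interval_and_positions_complete(self):
        cfg = SimulationConfig(n_exons_per_group=5, seed=2)
        prof = generate_conservation_profiles(cfg)
        assert prof["score"].between(0, 1).all()
        counts = prof.groupby(["exon_id", "side"])["position"].count()
        assert (counts == cfg.conservation_model.get("fir_length", 200)).all()


class TestPosteriorInclusion:
    def test_all_draws_in_unit_interval(self, small_config):
        mats = generate_posterior_inclusion(small_config)
        assert all(((m.draws >= 0) & (m.draws <= 1)).all() for m in mats)

    def test_infinite_depth_collapses_to_truth(self, small_config):
        cfg = small_config.with_(posterior_depth=1e8, posterior_draws=20)
        mats = generate_posterior_inclusion(cfg)
        for m in mats:
            np.testing.assert_allclose(
                m.draws.mean(axis=1), m.true_inclusion, atol=2e-3
            )

    def test_posterior_mean_tracks_true_inclusion(self, small_config):
        cfg = small_config.with_(posterior_depth=100.0, posterior_draws=400)
        mats = generate_posterior_inclusion(cfg)
        m = mats[0]
        # MC error of a Beta(u d, (1-u) d) mean over S draws
        u = m.true_inclusion
        mc_se = np.sqrt(u * (1 - u) / (cfg.posterior_depth + 1) / cfg.posterior_draws)
        inside = np.abs(m.draws.mean(axis=1) - u) < 2 * mc_se + 1e-12
        assert inside.mean() > 0.85  # ~95% expected, allow MC slack

    def test_deeper_posteriors_are_narrower(self, small_config):
        shallow = generate_posterior_inclusion(small_config.with_(posterior_depth=10.0))
        deep = generate_posterior_inclusion(small_config.with_(posterior_depth=1000.0))
        w_shallow = np.mean([m.draws.std(axis=1).mean() for m in shallow])
        w_deep = np.mean([m.draws.std(axis=1).mean() for m in deep])
        assert w_deep < w_shallow
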