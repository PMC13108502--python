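"""Perturbation statistics: temporal series, paired tests, ratios, nulls."""

import math

import numpy as np
import pandas as pd
import pytest

from dynconn import (
    ModularityConfig,
    MultilayerPartition,
    SyntheticStudySpec,
    ValidationError,
    bootstrap_dissimilarity,
    dissimilarity_ratio,
    flexibility,
    generate_two_condition_study,
    mean_effect_size,
    paired_node_tests,
    scramble_null_mean_t,
    temporal_metric_series,
    temporal_points,
)
from dynconn.synthetic import PlantedMultilayerSpec, generate_planted_stack


@pytest.mark.parametrize(
    "n_layers,window,overlap,expected",
    [(28, 10, 0.9, 19), (10, 10, 0.9, 1), (12, 10, 0.9, 3)],
)
def test_temporal_points(n_layers, window, overlap, expected):
    assert temporal_points(n_layers, window, overlap) == expected


def test_temporal_points_errors():
    with pytest.raises(ValidationError):
        temporal_points(5, 10, 0.9)
    with pytest.raises(ValidationError):
        temporal_points(28, 10, 1.0)


def test_temporal_series_length_and_static_zero():
    labels = np.tile(np.repeat([1, 2], 4)[:, None], (1, 28))
    part = MultilayerPartition(labels=labels)
    series = temporal_metric_series(part, "flexibility")
    assert series.n_points == 19
    assert np.all(series.values == 0.0)


def test_temporal_series_unknown_metric():
    part = MultilayerPartition(labels=np.ones((4, 28), dtype=int))
    with pytest.raises(ValidationError, match="unknown metric"):
        temporal_metric_series(part, "wibble")


def test_temporal_series_localises_planted_switch():
    """A single community switch at layer 15 produces nonzero flexibility
    exactly at the estimation points whose 10-layer window spans it."""
    for seed in range(10):
        spec = PlantedMultilayerSpec(
            n_nodes=10, n_layers=28, n_communities=2,
            switchers=frozenset({0}), switch_layers=frozenset({15}),
            noise_sd=0.0, seed=seed,
        )
        _, truth = generate_planted_stack(spec)
        series = temporal_metric_series(truth, "flexibility")
        node0 = series.values[:, 0]
        spanning = np.array(
            [s <= 14 and 15 <= s + 9 for s in series.starts]
        )
        assert np.all(node0[spanning] > 0)
        assert np.all(node0[~spanning] == 0)
        assert np.argmax(node0) in np.flatnonzero(spanning)


def test_temporal_series_from_stack_runs_detection():
    spec = PlantedMultilayerSpec(n_nodes=8, n_layers=12, n_communities=2)
    stack, _ = generate_planted_stack(spec)
    series = temporal_metric_series(
        stack, "flexibility", config=ModularityConfig(n_iter=2, seed=0)
    )
    assert series.n_points == temporal_points(12, 10, 0.9) == 3
    assert np.all(series.values <= 1.0)


def test_paired_tests_trivial_and_simulated(rng):
    pre = rng.normal(size=(17, 10))
    tests = paired_node_tests(pre, pre.copy())
    assert not np.any(np.nan_to_num(tests["p"], nan=1.0) < 0.05)
    post = pre + 1.0 + 0.1 * rng.normal(size=(17, 10))
    tests = paired_node_tests(pre, post)
    assert np.all(tests["t"] > 0)
    assert np.all(tests["p"] < 0.05)
    flipped = paired_node_tests(post, pre)
    assert np.allclose(flipped["t"], -tests["t"])


def test_paired_tests_validation(rng):
    with pytest.raises(ValidationError, match="shape"):
        paired_node_tests(rng.normal(size=(5, 3)), rng.normal(size=(5, 4)))
    with pytest.raises(ValidationError, match="subjects"):
        paired_node_tests(rng.normal(size=(1, 3)), rng.normal(size=(1, 3)))


def test_paired_tests_degenerate_variance_clamped(rng):
    pre = np.zeros((6, 2))
    post = np.zeros((6, 2))
    post[:, 0] = 1.0  # constant nonzero difference
    with pytest.warns(UserWarning, match="clamped"):
        tests = paired_node_tests(pre, post)
    assert np.isnan(tests["t"][0])
    assert tests["cohen_d"][0] == 100.0
    assert tests["cohen_d"][1] == 0.0


def _tests_frame(p_values):
    return pd.DataFrame({
        "t": np.ones(len(p_values)),
        "p": np.asarray(p_values, dtype=float),
        "cohen_d": np.ones(len(p_values)),
    })


def test_dissimilarity_ratio_counts():
    regions = np.array(["cerebellum"] * 32)
    p = np.ones(32)
    p[[1, 5, 9]] = 0.01  # 3 of 32 significant
    out = dissimilarity_ratio(_tests_frame(p), regions)
    assert out["cerebellum"] == pytest.approx(0.09375)
    assert out["whole_brain"] == pytest.approx(0.09375)
    assert dissimilarity_ratio(_tests_frame(np.ones(32)), regions)["cerebellum"] == 0.0
    assert dissimilarity_ratio(_tests_frame(np.zeros(32)), regions)["cerebellum"] == 1.0
    with pytest.warns(UserWarning, match="empty region"):
        out = dissimilarity_ratio(_tests_frame(p), regions)
    assert np.isnan(out["left"])


def test_bootstrap_enumerates_6188_subsets(rng):
    """C(17, 12) = 6188 subject subsets are exhaustively enumerated."""
    assert math.comb(17, 12) == 6188
    pre = rng.normal(size=(17, 6))
    post = pre + rng.normal(scale=0.5, size=(17, 6))
    regions = np.array(["left"] * 3 + ["right"] * 2 + ["cerebellum"])
    out = bootstrap_dissimilarity(pre, post, regions, subset_size=12)
    assert out["whole_brain"]["n_subsets"] == 6188
    assert out["whole_brain"]["enumerated"] is True
    assert out["whole_brain"]["ci_low"] <= out["whole_brain"]["ci_high"]


def test_bootstrap_degenerate_large_effect(rng):
    pre = rng.normal(size=(17, 8))
    post = pre + 5.0 + 0.01 * rng.normal(size=(17, 8))
    regions = np.array(["left"] * 8)
    out = bootstrap_dissimilarity(pre, post, regions, subset_size=12)
    assert out["whole_brain"]["ci_low"] == 1.0
    assert out["whole_brain"]["ci_high"] == 1.0


def test_bootstrap_null_ci_covers_alpha(rng):
    pre = rng.normal(size=(17, 100))
    post = rng.normal(size=(17, 100))
    regions = np.array(["left"] * 100)
    out = bootstrap_dissimilarity(pre, post, regions, subset_size=12)
    assert out["whole_brain"]["ci_low"] <= 0.05 <= out["whole_brain"]["ci_high"] + 0.05


def test_bootstrap_subset_size_error(rng):
    with pytest.raises(ValidationError):
        bootstrap_dissimilarity(
            rng.normal(size=(5, 3)), rng.normal(size=(5, 3)),
            np.array(["left"] * 3), subset_size=12,
        )


def test_mean_effect_size_recovery(rng):
    """Planted paired d = 1.0: the mean d over significant nodes recovers it
    with the expected selection inflation (200 sims)."""
    vals = []
    for _ in range(200):
        diff = rng.normal(1.0, 1.0, size=(17, 20))
        tests = paired_node_tests(np.zeros((17, 20)), diff)
        vals.append(mean_effect_size(tests))
    assert 0.8 <= float(np.nanmean(vals)) <= 1.4


def test_mean_effect_size_no_significant_nodes():
    with pytest.warns(UserWarning, match="no significant"):
        out = mean_effect_size(_tests_frame(np.ones(5)))
    assert np.isnan(out)


def _tiny_study(effect_size, seed, n_subjects=6, n_parcels=12, n_volumes=280):
    spec = SyntheticStudySpec(
        n_parcels=n_parcels, n_subjects=n_subjects, n_volumes=n_volumes,
        effect_nodes=frozenset(range(n_parcels - n_parcels // 4, n_parcels)),
        effect_size=effect_size, seed=seed,
    )
    return generate_two_condition_study(spec, output="stack"), spec


def test_scramble_null_count_and_centering():
    study, _ = _tiny_study(0.0, seed=8)
    null = scramble_null_mean_t(
        study.pre, study.post, n_null=30, seed=1, n_iter_null=2,
    )
    assert null.shape == (30,)
    assert abs(np.mean(null)) < 0.3  # centred; tighter bound needs more nulls


def test_observed_mean_t_exceeds_null_for_planted_effect():
    """A strong planted switching increase puts the observed whole-brain
    mean t above the 95th percentile of the scrambling null."""
    study, spec = _tiny_study(3.0, seed=4, n_subjects=10, n_parcels=16)
    cfg = ModularityConfig(n_iter=5, seed=0)
    from dynconn import run_ensemble

    pre = np.array([flexibility(run_ensemble(s, cfg)) for s in study.pre])
    post = np.array([flexibility(run_ensemble(s, cfg)) for s in study.post])
    observed = float(np.nanmean(paired_node_tests(pre, post)["t"]))
    null = scramble_null_mean_t(
        study.pre, study.post, n_null=20, seed=2, n_iter_null=2,
    )
    assert observed > np.percentile(null, 95)


def test_type_one_error_calibration():
    """Effect-free 17-subject studies: whole-brain dissimilarity ratio
    averages alpha = 0.05 within 0.02 over 100 simulations."""
    ratios = []
    for seed in range(100):
        spec = SyntheticStudySpec(n_parcels=32, n_subjects=17,
                                  effect_size=0.0, seed=40_000 + seed)
        study = generate_two_condition_study(spec, output="partitions")
        pre = np.array([flexibility(p) for p in study.pre])
        post = np.array([flexibility(p) for p in study.post])
        tests = paired_node_tests(pre, post)
        ratios.append(
            dissimilarity_ratio(tests, spec.region_labels)["whole_brain"]
        )
    assert abs(np.mean(ratios) - 0.05) <= 0.02


def test_power_and_directionality():
    """Planted d >= 1.2 at 10% of nodes: those nodes' median p is below
    alpha and the ratio clearly exceeds the type-I level; with the planted
    share raised to 25%, >= 90% of significant nodes have positive t."""
    ps, ratios = [], []
    for seed in range(50):
        spec = SyntheticStudySpec(
            n_parcels=40, n_subjects=17, n_volumes=560,
            effect_nodes=frozenset(range(36, 40)), effect_size=1.2,
            seed=seed,
        )
        study = generate_two_condition_study(spec, output="partitions")
        pre = np.array([flexibility(p) for p in study.pre])
        post = np.array([flexibility(p) for p in study.post])
        tests = paired_node_tests(pre, post)
        ps.append(np.median(tests["p"][36:]))
        ratios.append(dissimilarity_ratio(tests, spec.region_labels)["whole_brain"])
    assert np.median(ps) < 0.05
    assert np.mean(ratios) > 0.07  # well above the alpha = 0.05 null level

    pos, sig_total = 0, 0
    for seed in range(20):
        spec = SyntheticStudySpec(
            n_parcels=40, n_subjects=17, n_volumes=560,
            effect_nodes=frozenset(range(30, 40)), effect_size=2.0,
            seed=100 + seed,
        )
        study = generate_two_condition_study(spec, output="partitions")
        pre = np.array([flexibility(p) for p in study.pre])
        post = np.array([flexibility(p) for p in study.post])
        tests = paired_node_tests(pre, post)
        sig = np.nan_to_num(tests["p"], nan=1.0) < 0.05
        pos += int((tests["t"][sig] > 0).sum())
        sig_total += int(sig.sum())
    assert pos / sig_total >= 0.9


def test_dissimilarity_ratio_fdr_correction_is_stricter(rng):
    p = np.concatenate([np.full(5, 0.04), rng.uniform(0.2, 1.0, 45)])
    regions = np.array(["left"] * 50)
    plain = dissimilarity_ratio(_tests_frame(p), regions)["whole_brain"]
    corrected = dissimilarity_ratio(
        _tests_frame(p), regions, correction="fdr_bh"
    )["whole_brain"]
    assert plain == pytest.approx(0.1)
    assert corrected <= plain
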