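"""Normalization, LOD and detection-call behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import gmean

from evpdiet import (
    CountMatrix,
    NormalizationConfig,
    compute_lod,
    detection_calls,
    detection_rates,
    positive_control_normalize,
)


def make_matrix(endo, pos, neg, samples=None):
    endo, pos, neg = (np.atleast_2d(a) for a in (endo, pos, neg))
    values = np.vstack([endo, pos, neg])
    ids = ([f"miR-{i:03d}" for i in range(endo.shape[0])]
           + [f"POS_{i}" for i in range(pos.shape[0])]
           + [f"NEG_{i}" for i in range(neg.shape[0])])
    classes = (["Endogenous"] * endo.shape[0] + ["Positive"] * pos.shape[0]
               + ["Negative"] * neg.shape[0])
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    counts = pd.DataFrame(values, index=ids, columns=samples)
    return CountMatrix(counts, pd.Series(classes, index=ids))


def test_normalization_hand_example_geomeans_100_and_400():
    # geomeans 100 and 400 -> grand mean 250 -> factors 2.5 and 0.625
    m = make_matrix(endo=[[10.0, 10.0]],
                    pos=[[100.0, 400.0], [100.0, 400.0]],
                    neg=[[1.0, 1.0], [1.0, 1.0]])
    normalized, factors = positive_control_normalize(m)
    np.testing.assert_allclose(factors, [2.5, 0.625])
    post = gmean(normalized.positives.to_numpy(), axis=0)
    np.testing.assert_allclose(post, [250.0, 250.0])


def test_normalization_identity_when_controls_equal():
    m = make_matrix(endo=[[3.0, 5.0]], pos=[[50.0, 50.0]], neg=[[1.0, 2.0]])
    normalized, factors = positive_control_normalize(m)
    np.testing.assert_allclose(factors, [1.0, 1.0])
    pd.testing.assert_frame_equal(normalized.counts, m.counts.astype(float))


def test_normalization_is_idempotent(small_study):
    once = small_study["normalized"]
    twice, factors2 = positive_control_normalize(once)
    np.testing.assert_allclose(factors2, 1.0, atol=1e-12)
    np.testing.assert_allclose(twice.counts, once.counts)


def test_normalization_scale_equivariance(small_study):
    """Rescaling one raw sample changes nothing after renormalization.

    The grand positive-control mean moves with the rescaled sample, so
    equality holds up to one global constant shared by every entry.
    """
    raw = small_study["raw"]
    scaled = raw.copy()
    scaled.counts = scaled.counts.astype(float)
    scaled.counts.iloc[:, 0] *= 3.7
    norm_a, _ = positive_control_normalize(raw)
    norm_b, _ = positive_control_normalize(scaled)
    ratio = norm_b.counts.to_numpy() / np.where(
        norm_a.counts.to_numpy() == 0, np.nan, norm_a.counts.to_numpy())
    finite = ratio[np.isfinite(ratio)]
    np.testing.assert_allclose(finite, finite.mean(), rtol=1e-9)


def test_positive_control_geomeans_equal_after_normalization(small_study):
    post = gmean(small_study["normalized"].positives.to_numpy(), axis=0)
    np.testing.assert_allclose(post, post.mean(), rtol=1e-9)


def test_zero_positive_control_raises_unless_floored():
    m = make_matrix(endo=[[1.0, 1.0]], pos=[[0.0, 10.0]], neg=[[1.0, 1.0], [1.0, 1.0]])
    with pytest.raises(ValueError, match="positive-control"):
        positive_control_normalize(m)
    with pytest.warns(UserWarning):
        normalized, _ = positive_control_normalize(m, zero_policy="floor")
    assert np.isfinite(normalized.counts.to_numpy()).all()


@pytest.mark.parametrize("negatives,multiplier,expected", [
    ([10.0, 10.0, 10.0], 1.5, 10.0),
    ([5.0, 10.0, 15.0], 1.5, 17.5),   # sample SD = 5
    ([5.0, 10.0, 15.0], 0.0, 10.0),   # multiplier 0 -> mean
])
def test_lod_hand_values(negatives, multiplier, expected):
    m = make_matrix(endo=[[1.0]], pos=[[10.0]], neg=[[v] for v in negatives])
    lod = compute_lod(m, NormalizationConfig(lod_multiplier=multiplier))
    assert lod.iloc[0] == pytest.approx(expected)


def test_lod_monotone_in_multiplier_and_detection_shrinks(small_study):
    normalized = small_study["normalized"]
    lods = [compute_lod(normalized, NormalizationConfig(lod_multiplier=k))
            for k in (0.5, 1.5, 3.0)]
    assert (lods[0] <= lods[1]).all() and (lods[1] <= lods[2]).all()
    rates = [detection_rates(detection_calls(normalized, lod)).mean()
             for lod in lods]
    assert rates[0] >= rates[1] >= rates[2]


def test_lod_needs_two_negative_probes():
    m = make_matrix(endo=[[1.0]], pos=[[10.0]], neg=[[4.0]])
    with pytest.raises(ValueError, match="negative"):
        compute_lod(m)


def test_detection_strict_at_threshold_and_rates():
    m = make_matrix(endo=[[17.5, 20.0, 0.0]], pos=[[10.0, 10.0, 10.0]],
                    neg=[[5.0, 5.0, 5.0], [10.0, 10.0, 10.0], [15.0, 15.0, 15.0]])
    lod = compute_lod(m)  # 17.5 everywhere
    calls = detection_calls(m, lod)
    assert calls.iloc[0].tolist() == [0, 1, 0]  # equality is NOT detection
    ge = detection_calls(m, lod, NormalizationConfig(comparison="greater_equal"))
    assert ge.iloc[0].tolist() == [1, 1, 0]
    assert detection_rates(calls).iloc[0] == pytest.approx(1 / 3)


def test_detection_sample_mismatch_errors(small_study):
    lod = compute_lod(small_study["normalized"])
    with pytest.raises(ValueError):
        detection_calls(small_study["normalized"], lod.iloc[:-2].rename(index=str))


def test_scale_factor_invertibility():
    """Normalization undoes planted lot scale factors in [0.5, 2]."""
    from evpdiet import CohortConfig, generate_cohort, generate_counts
    from tests.conftest import SMALL_PANEL

    cfg = CohortConfig(n_participants=40, seed=21)
    cohort = generate_cohort(cfg)
    rng = np.random.default_rng(21)
    true_c = rng.uniform(0.5, 2.0, 40)
    raw = generate_counts(cohort, SMALL_PANEL, seed=21, scale_factors=true_c)
    _, factors = positive_control_normalize(raw)
    # recovered factor * planted factor should be a constant across samples
    product = factors.to_numpy() * true_c
    rel_err = np.abs(product / product.mean() - 1)
    assert rel_err.mean() < 0.02
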