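"""Sorting metrics: curves, standard condition, rP, AUCs, surfaces,
score standardization and unification."""

import numpy as np
import pytest

from seedsort.errors import DegenerateDataError, InputError
from seedsort.metrics import (
    ScoredBatch,
    accuracy_max,
    auc,
    curve_frame,
    fit_standardizer,
    pr_rpr_curves,
    relative_precision,
    sorting_curve,
    standard_condition,
    standard_summary,
    standardize_scores,
    successive_surface,
    unify_scores,
)
from seedsort.simulate import (
    HypotheticalModelSpec,
    simulate_hypothetical_scores,
)


def toy_batch():
    return ScoredBatch(
        scores=np.array([5.0, 4.0, 3.0, 2.0, 1.0]),
        labels=np.array([1, 1, 1, -1, -1]),
    )


def test_sorting_curve_hand_enumeration():
    curve = sorting_curve(toy_batch())
    i = int(np.flatnonzero(curve.thresholds == 3.0)[0])
    assert curve.recovery[i] == pytest.approx(0.6)
    assert curve.precision[i] == 1.0
    assert curve.recall[i] == 1.0
    assert curve.accuracy[i] == 1.0
    # lowest threshold recovers everything: P = iP, R = 1
    assert curve.recovery[-1] == 1.0
    assert curve.precision[-1] == pytest.approx(0.6)
    assert curve.recall[-1] == 1.0


def test_anticorrelated_scores_have_zero_relative_precision():
    batch = ScoredBatch(
        scores=np.array([5.0, 4.0, 3.0, 2.0, 1.0]),
        labels=np.array([-1, -1, 1, 1, 1]),
    )
    curve = sorting_curve(batch)
    above = curve.recovery <= 0.5
    assert np.all(curve.precision[above] <= curve.iP)
    assert np.all(curve.rel_precision[above] == 0.0)


def test_standard_condition_toy_and_errors():
    slst, sp, sa = standard_condition(toy_batch())
    assert (slst, sp, sa) == (3.0, 1.0, 1.0)
    with pytest.raises(DegenerateDataError):
        standard_condition(
            ScoredBatch(scores=np.arange(3.0), labels=np.array([1, 1, 1]))
        )


def test_standard_condition_ties_expand_recovery():
    batch = ScoredBatch(
        scores=np.array([4.0, 3.0, 3.0, 3.0, 1.0]),
        labels=np.array([1, 1, 1, -1, -1]),
    )
    # k = round(0.6*5) = 3 -> sLST = 3, but all ties at 3 are recovered
    slst, sp, _ = standard_condition(batch)
    assert slst == 3.0
    assert sp == pytest.approx(3 / 4)


def test_relative_precision_branches():
    assert relative_precision(0.903, 0.8) == pytest.approx(0.515)
    assert relative_precision(0.8, 0.8) == 0.0
    assert relative_precision(0.5, 0.8) == 0.0
    assert relative_precision(1.0, 0.37) == 1.0
    with pytest.raises(DegenerateDataError):
        relative_precision(0.9, 1.0)


def test_rpr_curve_is_pointwise_transform_of_pr_curve():
    curve = sorting_curve(toy_batch())
    (r, p), (r2, rp) = pr_rpr_curves(curve)
    np.testing.assert_array_equal(r, r2)
    np.testing.assert_allclose(rp, relative_precision(p, curve.iP))
    # endpoint: R = 1 -> P = iP, rP = 0
    assert p[-1] == pytest.approx(curve.iP)
    assert rp[-1] == 0.0


def test_auc_constant_and_unordered_input():
    assert auc([0.2, 0.6, 1.0], [0.7, 0.7, 0.7]) == pytest.approx(0.7)
    assert auc([1.0, 0.0, 0.5], [1.0, 1.0, 1.0]) == pytest.approx(1.0)


def test_amax_never_below_trivial_classifier(rng):
    for _ in range(20):
        n = rng.integers(5, 50)
        batch = ScoredBatch(
            scores=rng.normal(size=n), labels=rng.choice([-1, 1], n)
        )
        if abs(batch.iP - 0.5) < 1e-9 or batch.iP in (0, 1):
            continue
        curve = sorting_curve(batch)
        assert accuracy_max(curve) >= max(batch.iP, 1 - batch.iP) - 1e-12


def test_sp_equals_sr_when_k_is_integral(rng):
    """At the standard condition precision equals recall exactly."""
    for _ in range(10):
        n_ok, n_ng = int(rng.integers(5, 40)), int(rng.integers(5, 40))
        scores = rng.normal(size=n_ok + n_ng)
        labels = np.r_[np.ones(n_ok, int), -np.ones(n_ng, int)]
        batch = ScoredBatch(scores=scores, labels=labels)
        k = batch.iP * batch.n  # = n_ok, integral by construction
        assert k == pytest.approx(round(k))
        slst, sp, _ = standard_condition(batch)
        recovered = scores >= slst
        if recovered.sum() != n_ok:  # tie expansion voids the identity
            continue
        recall = (labels[recovered] == 1).sum() / n_ok
        assert sp == pytest.approx(recall)


def test_rp_below_p_and_auc_ordering(rng):
    for _ in range(10):
        n = int(rng.integers(20, 200))
        labels = np.r_[np.ones(n // 2 + 1, int), -np.ones(n - n // 2 - 1, int)]
        batch = ScoredBatch(scores=rng.normal(size=n), labels=labels)
        curve = sorting_curve(batch)
        assert np.all(curve.rel_precision <= curve.precision + 1e-12)
        (r, p), (_, rp) = pr_rpr_curves(curve)
        assert auc(r, rp) <= auc(r, p) + 1e-12


def test_metrics_invariant_under_monotone_score_transforms():
    spec = HypotheticalModelSpec("MP", 0.2, -0.2, 0.25, 300, 100)
    batch = simulate_hypothetical_scores(spec, rng=5)
    base = standard_summary(batch)
    warped = ScoredBatch(scores=np.exp(batch.scores), labels=batch.labels)
    out = standard_summary(warped)
    assert out.sp == pytest.approx(base.sp)
    assert out.auc_pr == pytest.approx(base.auc_pr)
    assert out.auc_rpr == pytest.approx(base.auc_rpr)


def test_random_scores_hug_zero_relative_precision(rng):
    labels = np.r_[np.ones(8000, int), -np.ones(2000, int)]
    batch = ScoredBatch(scores=rng.normal(size=10000), labels=labels)
    curve = sorting_curve(batch)
    assert np.median(curve.rel_precision) < 0.05


# ---------------------------------------------------------------------------
# Successive surfaces


def two_trait_batches(rng, n=300):
    t1 = rng.choice([1, -1], n, p=[0.8, 0.2])
    t2 = rng.choice([1, -1], n, p=[0.85, 0.15])
    s1 = 0.4 * t1 + rng.normal(0, 0.25, n)
    s2 = 0.4 * t2 + rng.normal(0, 0.25, n)
    joint = np.where((t1 == 1) & (t2 == 1), 1, -1)
    b1 = ScoredBatch(scores=s1, labels=t1)
    b2 = ScoredBatch(scores=s2, labels=t2)
    return b1, b2, joint


def test_surface_corner_anchor_and_marginalization(rng):
    b1, b2, joint = two_trait_batches(rng)
    surf = successive_surface(b1, b2, joint, grid=41)
    # both LSTs at the minimum: everything recovered
    assert surf.precision[-1, -1] == pytest.approx(np.mean(joint == 1))
    assert surf.recall[-1, -1] == pytest.approx(1.0)
    # LST2 at the minimum: cross-section equals single-model sorting by
    # model 1 against the joint labels
    for i, t in enumerate(surf.lst1):
        rec = b1.scores >= t
        if rec.sum() == 0:
            continue
        expected_p = np.mean(joint[rec] == 1)
        assert surf.precision[i, -1] == pytest.approx(expected_p, abs=1e-12)


def test_surface_volume_stable_under_grid_refinement(rng):
    b1, b2, joint = two_trait_batches(rng)
    coarse = successive_surface(b1, b2, joint, grid=31)
    fine = successive_surface(b1, b2, joint, grid=310)
    assert coarse.volume_rpr == pytest.approx(fine.volume_rpr, abs=0.05)
    assert coarse.volume_pr == pytest.approx(fine.volume_pr, abs=0.05)


def test_surface_rejects_misaligned_batches(rng):
    b1, b2, joint = two_trait_batches(rng)
    short = ScoredBatch(scores=b2.scores[:-1], labels=b2.labels[:-1])
    with pytest.raises(InputError):
        successive_surface(b1, short, joint)


# ---------------------------------------------------------------------------
# Standardization and unification


def test_standardize_anchors_and_affine_invariance():
    spec = HypotheticalModelSpec("MP", 0.2, -0.2, 0.25, 400, 100)
    calib = simulate_hypothetical_scores(spec, rng=11)
    scorer = fit_standardizer(calib)
    assert scorer.transform(scorer.slst_hat) == pytest.approx(0.0)
    z = standardize_scores(calib.scores, calib)
    shifted = ScoredBatch(scores=3.0 * calib.scores + 2.0, labels=calib.labels)
    z2 = standardize_scores(3.0 * calib.scores + 2.0, shifted)
    np.testing.assert_allclose(z, z2, atol=1e-9)


def test_standardized_nonnegative_fraction_approximates_ip():
    spec = HypotheticalModelSpec("MP", 0.2, -0.2, 0.25, 40000, 10000)
    batch = simulate_hypothetical_scores(spec, rng=3)
    z = standardize_scores(batch.scores, batch)
    assert np.mean(z >= 0) == pytest.approx(0.8, abs=0.01)


def test_unify_scores_min_semantics():
    z1 = np.array([0.5, -5.0, 1.0])
    z2 = np.array([0.2, 3.0, 2.0])
    np.testing.assert_array_equal(unify_scores([z1, z2]), [0.2, -5.0, 1.0])
    np.testing.assert_array_equal(unify_scores([z1]), z1)
    with pytest.raises(InputError):
        unify_scores([z1, z2[:-1]])


def test_unified_sorting_beats_single_trait_models(rng):
    """Sorting 2-trait seeds by min standardized score should match or
    beat either per-trait model on joint eligibility (median of reps)."""
    wins = []
    for rep in range(20):
        r = np.random.default_rng(100 + rep)
        b1, b2, joint = two_trait_batches(r, n=400)
        z1 = standardize_scores(b1.scores, b1)
        z2 = standardize_scores(b2.scores, b2)
        u = unify_scores([z1, z2])
        sp_u = standard_condition(ScoredBatch(scores=u, labels=joint))[1]
        sp_1 = standard_condition(ScoredBatch(scores=b1.scores, labels=joint))[1]
        sp_2 = standard_condition(ScoredBatch(scores=b2.scores, labels=joint))[1]
        wins.append(sp_u >= max(sp_1, sp_2))
    assert np.median(wins) == 1.0


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        scores=st.lists(
            st.floats(-50, 50, allow_nan=False), min_size=4, max_size=60
        ),
        seed=st.integers(0, 2**16),
    )
    def test_curve_invariants_hold_on_arbitrary_batches(scores, seed):
        """Recovery and recall grow as the threshold drops; precision
        ends at iP; rP stays within [0, 1] and below precision."""
        rng = np.random.default_rng(seed)
        labels = rng.choice([-1, 1], len(scores))
        if len(set(labels.tolist())) < 2:
            return
        curve = sorting_curve(
            ScoredBatch(scores=np.array(scores), labels=labels)
        )
        assert np.all(np.diff(curve.recovery) > 0)
        assert np.all(np.diff(curve.recall) >= 0)
        assert curve.precision[-1] == pytest.approx(curve.iP)
        assert np.all((curve.rel_precision >= 0) & (curve.rel_precision <= 1))
        assert np.all(curve.rel_precision <= curve.precision + 1e-12)

except ImportError:  # hypothesis is an optional test dependency
    pass


def test_curve_frame_columns():
    frame = curve_frame(sorting_curve(toy_batch()))
    assert list(frame.columns) == ["LST", "recovery", "P", "R", "A", "rP"]
    assert len(frame) == 5
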