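"""Migration curves, band-pattern similarity, UPGMA and partition
agreement."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from sscpkit.gel import (
    DEFAULT_TOLERANCE,
    GelLane,
    InsufficientLadder,
    LadderSpec,
    NormalizedPattern,
    PoorFit,
    band_similarity,
    compare_partitions,
    fit_migration_curve,
    normalize_gel,
    similarity_matrix,
    upgma_dendrogram,
)
from sscpkit.simulate import reference_migration_curve


def ladder_lane(curve, spec, noise_sd=0.0, rng=None, gel_id="g1"):
    pos = np.array([float(curve.distance(s)) for s in spec.fragment_sizes])
    if noise_sd:
        pos = pos + rng.normal(0, noise_sd, size=len(pos))
    return GelLane(gel_id, "L0", sorted(pos), is_ladder=True, sample_id="ladder")


# -------------------------------------------------------- migration curve


def test_noise_free_gaussian_ladder_recovers_parameters():
    true = reference_migration_curve()
    spec = LadderSpec.hundred_bp()
    fit = fit_migration_curve(ladder_lane(true, spec), spec)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
    assert fit.params == pytest.approx(true.params, abs=1e-6)


def test_noisy_ladder_still_passes_r2_threshold():
    true = reference_migration_curve()
    spec = LadderSpec.hundred_bp()
    rng = np.random.default_rng(0)
    span = float(true.distance(100) - true.distance(1000))
    lane = ladder_lane(true, spec, noise_sd=0.01 * span, rng=rng)
    fit = fit_migration_curve(lane, spec)
    assert fit.r_squared >= 0.95
    # fitted curve stays close to truth inside the calibrated range
    sizes = np.linspace(120, 950, 20)
    err = np.abs(
        np.array([fit.distance(s) for s in sizes])
        - np.array([true.distance(s) for s in sizes])
    )
    assert err.max() < 0.05 * span


def test_two_rung_ladder_insufficient():
    spec = LadderSpec([500.0, 100.0])
    lane = GelLane("g", "L0", [10.0, 60.0], is_ladder=True, sample_id="ladder")
    with pytest.raises(InsufficientLadder):
        fit_migration_curve(lane, spec)


def test_log_linear_fallback_fits_linear_ladder():
    spec = LadderSpec.hundred_bp()
    s = np.log10(np.array(spec.fragment_sizes, float))
    pos = 200.0 - 55.0 * s
    lane = GelLane("g", "L0", sorted(pos), is_ladder=True, sample_id="ladder")
    fit = fit_migration_curve(lane, spec, model="log_linear")
    assert fit.r_squared == pytest.approx(1.0)
    assert fit.params == pytest.approx((200.0, -55.0), abs=1e-9)


# ------------------------------------------------------------ normalization


def test_identity_normalization_leaves_positions_unchanged():
    curve = reference_migration_curve()
    spec = LadderSpec.hundred_bp()
    fit = fit_migration_curve(ladder_lane(curve, spec), spec)
    bands = [75.0, 95.0, 120.0]
    lane = GelLane("g1", "L1", bands, sample_id="s1")
    (pattern,) = normalize_gel([lane], fit, fit)
    assert pattern.positions == pytest.approx(bands, abs=1e-9)
    assert not pattern.extrapolated.any()


def test_affine_warp_recovered_noise_free():
    ref = reference_migration_curve()
    spec = LadderSpec.hundred_bp()
    ref_fit = fit_migration_curve(ladder_lane(ref, spec), spec)
    scale, shift = 1.07, -2.5
    warped_ladder = GelLane(
        "g2",
        "L0",
        sorted(scale * float(ref.distance(s)) + shift for s in spec.fragment_sizes),
        is_ladder=True,
        sample_id="ladder",
    )
    warped_fit = fit_migration_curve(warped_ladder, spec)
    true_bands = [75.0, 95.0, 120.0]
    lane = GelLane(
        "g2", "L1", [scale * b + shift for b in true_bands], sample_id="s1"
    )
    (pattern,) = normalize_gel([lane], warped_fit, ref_fit)
    assert pattern.positions == pytest.approx(true_bands, abs=0.5)


def test_band_beyond_ladder_flagged_as_extrapolated():
    curve = reference_migration_curve()
    spec = LadderSpec.hundred_bp()
    fit = fit_migration_curve(ladder_lane(curve, spec), spec)
    far = float(curve.distance(100)) + 10.0  # migrated past the last rung
    lane = GelLane("g1", "L1", [80.0, far], sample_id="s1")
    (pattern,) = normalize_gel([lane], fit, fit)
    assert list(pattern.extrapolated) == [False, True]


def test_poor_fit_rejected():
    curve = reference_migration_curve()
    bad = type(curve)(
        model=curve.model, params=curve.params, r_squared=0.90,
        size_range=curve.size_range,
    )
    with pytest.raises(PoorFit):
        normalize_gel([], bad, bad)


# --------------------------------------------------------- band similarity


def oracle_similarity(a, b, tol, method="dice"):
    """Exhaustive one-to-one assignment maximizing matches."""
    if not a and not b:
        return 100.0
    if not a or not b:
        return 0.0
    small, large = (a, b) if len(a) <= len(b) else (b, a)
    best = 0
    for perm in itertools.permutations(range(len(large)), len(small)):
        m = sum(1 for i, j in enumerate(perm) if abs(small[i] - large[j]) <= tol)
        best = max(best, m)
    if method == "dice":
        return 100.0 * 2 * best / (len(a) + len(b))
    return 100.0 * best / (len(a) + len(b) - best)


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ([10.0, 50.0, 90.0], [10.0, 50.0, 90.0], 100.0),
        ([10.0, 50.0, 90.0], [13.0, 50.0, 200.0], pytest.approx(200 / 3)),
        ([10.0], [100.0], 0.0),
        ([], [], 100.0),
        ([], [10.0], 0.0),
    ],
)
def test_band_similarity_known_cases(a, b, expected):
    assert band_similarity(a, b, tolerance=4) == expected


def test_band_similarity_symmetric_bounded_monotone(rng):
    for _ in range(100):
        a = sorted(rng.uniform(0, 100, size=rng.integers(0, 7)))
        b = sorted(rng.uniform(0, 100, size=rng.integers(0, 7)))
        s4 = band_similarity(a, b, 4)
        assert s4 == band_similarity(b, a, 4)
        assert 0.0 <= s4 <= 100.0
        assert s4 <= band_similarity(a, b, 8) <= band_similarity(a, b, 20)


def test_band_similarity_matches_exhaustive_oracle(rng):
    for method in ("dice", "jaccard"):
        for _ in range(100):
            a = list(rng.uniform(0, 60, size=rng.integers(0, 7)))
            b = list(rng.uniform(0, 60, size=rng.integers(0, 7)))
            tol = float(rng.uniform(1, 10))
            assert band_similarity(a, b, tol, method) == pytest.approx(
                oracle_similarity(a, b, tol, method)
            )


# ------------------------------------------------------------------ UPGMA


def upgma_oracle(dist):
    """Naive agglomeration with arithmetic-average linkage; returns the
    cophenetic (ultrametric) distance matrix."""
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    d = {
        (i, j): float(dist[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    coph = np.zeros((n, n))
    next_id = n
    while len(clusters) > 1:
        (i, j), h = min(d.items(), key=lambda kv: kv[1])
        for a in clusters[i]:
            for b in clusters[j]:
                coph[a, b] = coph[b, a] = h
        merged = clusters[i] + clusters[j]
        ni, nj = len(clusters[i]), len(clusters[j])
        del clusters[i], clusters[j]
        new_d = {}
        for (a, b), v in d.items():
            if len({a, b} & {i, j}) == 0:
                new_d[(a, b)] = v
        for k in clusters:
            dik = d[(min(i, k), max(i, k))]
            djk = d[(min(j, k), max(j, k))]
            new_d[(k, next_id)] = (ni * dik + nj * djk) / (ni + nj)
        clusters[next_id] = merged
        d = new_d
        next_id += 1
    return coph


def test_two_identical_patterns_merge_at_zero():
    sim = pd.DataFrame(
        [[100.0, 100.0], [100.0, 100.0]], index=["a", "b"], columns=["a", "b"]
    )
    tree = upgma_dendrogram(sim)
    assert tree.merge_heights == pytest.approx([0.0])


def test_hand_built_three_leaf_tree():
    # d(A,B)=10, d(A,C)=d(B,C)=40 -> ((A,B),C), heights 10 and 40
    sim = pd.DataFrame(
        100.0 - np.array([[0, 10, 40], [10, 0, 40], [40, 40, 0]], float),
        index=list("ABC"),
        columns=list("ABC"),
    )
    tree = upgma_dendrogram(sim)
    assert tree.merge_heights == pytest.approx([10.0, 40.0])
    assert tree.newick == "((A:5,B:5):15,C:20);"


def test_upgma_invariant_to_leaf_order(rng):
    n = 6
    d = np.round(rng.uniform(5, 80, size=(n, n)), 3)
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    labels = [f"s{i}" for i in range(n)]
    sim = pd.DataFrame(100.0 - d, index=labels, columns=labels)
    perm = list(rng.permutation(n))
    sim2 = sim.iloc[perm, perm]
    t1, t2 = upgma_dendrogram(sim), upgma_dendrogram(sim2)
    assert t1.newick == t2.newick


def test_upgma_matches_bruteforce_oracle(rng):
    for _ in range(30):
        n = 5
        d = rng.uniform(1, 100, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        labels = [f"s{i}" for i in range(n)]
        sim = pd.DataFrame(100.0 - d, index=labels, columns=labels)
        tree = upgma_dendrogram(sim)
        coph = hierarchy.cophenet(tree.linkage)
        from scipy.spatial.distance import squareform

        got = squareform(coph)
        expected = upgma_oracle(d)
        np.testing.assert_allclose(got, expected, atol=1e-9)


def test_asymmetric_matrix_rejected():
    sim = pd.DataFrame(
        [[100.0, 40.0], [60.0, 100.0]], index=["a", "b"], columns=["a", "b"]
    )
    with pytest.raises(ValueError):
        upgma_dendrogram(sim)


# ------------------------------------------------------ partition agreement


def test_identical_partitions_agree_perfectly():
    part = {f"s{i}": i % 3 for i in range(12)}
    table, ari = compare_partitions(part, dict(part))
    assert ari == 1.0
    assert int(table.to_numpy().sum()) == 12


def test_singletons_vs_one_cluster_not_above_chance():
    left = {f"s{i}": i for i in range(10)}
    right = {f"s{i}": 0 for i in range(10)}
    _, ari = compare_partitions(left, right)
    assert ari <= 0.0


def test_shuffled_labels_agree_at_chance_level(rng):
    ids = [f"s{i}" for i in range(40)]
    truth = {s: i % 4 for i, s in enumerate(ids)}
    labels = [truth[s] for s in ids]
    aris = []
    for _ in range(200):
        shuffled = list(rng.permutation(labels))
        aris.append(
            compare_partitions(dict(zip(ids, shuffled)), truth)[1]
        )
    assert abs(float(np.mean(aris))) < 0.02


def test_id_mismatch_lists_offenders():
    with pytest.raises(ValueError, match="s2"):
        compare_partitions({"s1": 0}, {"s1": 0, "s2": 1})
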