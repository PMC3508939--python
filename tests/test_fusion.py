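import numpy as np
import pytest

from bicar.fusion import (
    CRCMSet,
    SuperSource,
    SuperSourceGroup,
    aggregate,
    align,
    canonicalize_signs,
    compute_crcms,
)
from bicar.matching import MatchResult, abs_pearson
from bicar.unmixing import Decomposition


def scalar_pearson(x, y):
    """Brute-force scalar Pearson, independent of the package implementation."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    dx = sum((xi - mx) ** 2 for xi in x) ** 0.5
    dy = sum((yi - my) ** 2 for yi in y) ** 0.5
    return num / (dx * dy)


def make_dec(sources, k, modality="temporal", mixing=None, n_mix=6):
    sources = np.asarray(sources, dtype=float)
    if mixing is None:
        mixing = np.random.default_rng(1000 + k).normal(size=(n_mix, sources.shape[0]))
    return Decomposition(mixing, sources, k, seed=k, modality=modality)


def identity_match(n, k):
    return MatchResult(np.arange(n), np.ones(n), np.arange(n), k)


def standardized(rng, shape):
    x = rng.normal(size=shape)
    return (x - x.mean(axis=-1, keepdims=True)) / x.std(axis=-1, keepdims=True)


class TestComputeCRCMs:
    def test_identical_realizations_unit_diagonal(self, rng):
        S_T = standardized(rng, (3, 40))
        S_S = standardized(rng, (3, 50))
        t_decs = [make_dec(S_T.copy(), k) for k in range(2)]
        s_decs = [make_dec(S_S.copy(), k, "spatial") for k in range(2)]
        matches = [identity_match(3, k) for k in range(2)]
        crcms = compute_crcms(t_decs, s_decs, matches)
        np.testing.assert_allclose(np.diag(crcms.matrices[(0, 1)]), 1.0, atol=1e-12)

    def test_pure_temporal_reduces_to_raicar(self, rng):
        S_T = [standardized(rng, (3, 40)) for _ in range(2)]
        S_S = [standardized(rng, (3, 50)) for _ in range(2)]
        t_decs = [make_dec(S_T[k], k) for k in range(2)]
        s_decs = [make_dec(S_S[k], k, "spatial") for k in range(2)]
        matches = [identity_match(3, k) for k in range(2)]
        crcms = compute_crcms(t_decs, s_decs, matches, w_T=1.0, w_S=0.0)
        R = crcms.matrices[(0, 1)]
        for r in range(3):
            for c in range(3):
                direct = abs(scalar_pearson(S_T[0][r], S_T[1][c]))
                assert R[r, c] == pytest.approx(direct, abs=1e-12)

    def test_k3_brute_force_oracle_with_permutations(self, rng):
        K, n_c = 3, 2
        S_T = [standardized(rng, (n_c, 30)) for _ in range(K)]
        S_S = [standardized(rng, (n_c, 45)) for _ in range(K)]
        perms = [np.array([1, 0]), np.array([0, 1]), np.array([1, 0])]
        t_decs = [make_dec(S_T[k], k) for k in range(K)]
        s_decs = [make_dec(S_S[k], k, "spatial") for k in range(K)]
        matches = [MatchResult(perms[k], np.ones(n_c), np.arange(n_c), k) for k in range(K)]
        crcms = compute_crcms(t_decs, s_decs, matches, w_T=0.3, w_S=0.7)
        assert len(crcms.matrices) == 3
        for (i, j), R in crcms.matrices.items():
            for r in range(n_c):
                for c in range(n_c):
                    expected = 0.3 * abs(scalar_pearson(S_T[i][r], S_T[j][c])) + 0.7 * abs(
                        scalar_pearson(S_S[i][perms[i][r]], S_S[j][perms[j][c]])
                    )
                    assert R[r, c] == pytest.approx(expected, abs=1e-12)

    def test_swap_symmetry_surrogate(self, rng):
        # entry (r,c) of R^(ij) equals entry (c,r) computed with realizations swapped
        S_T = [standardized(rng, (3, 40)) for _ in range(2)]
        S_S = [standardized(rng, (3, 50)) for _ in range(2)]
        matches = [identity_match(3, k) for k in range(2)]
        fwd = compute_crcms(
            [make_dec(S_T[0], 0), make_dec(S_T[1], 1)],
            [make_dec(S_S[0], 0, "spatial"), make_dec(S_S[1], 1, "spatial")],
            matches,
        ).matrices[(0, 1)]
        rev = compute_crcms(
            [make_dec(S_T[1], 0), make_dec(S_T[0], 1)],
            [make_dec(S_S[1], 0, "spatial"), make_dec(S_S[0], 1, "spatial")],
            matches,
        ).matrices[(0, 1)]
        np.testing.assert_allclose(fwd, rev.T, atol=1e-12)

    def test_invalid_weights(self, rng):
        S = standardized(rng, (2, 20))
        decs = [make_dec(S, k) for k in range(2)]
        with pytest.raises(ValueError, match="weights"):
            compute_crcms(decs, decs, [identity_match(2, k) for k in range(2)], 0.0, 0.0)

    def test_requires_two_realizations(self, rng):
        S = standardized(rng, (2, 20))
        with pytest.raises(ValueError, match="at least 2"):
            compute_crcms([make_dec(S, 0)], [make_dec(S, 0, "spatial")], [identity_match(2, 0)])


def brute_force_align(matrices, K, n_c):
    """Independent enumeration of the seed-then-extend rule at toy scale."""
    work = {k: m.copy().astype(float) for k, m in matrices.items()}
    groups = []
    for _ in range(n_c):
        best_val, seed = -np.inf, None
        for (i, j), m in work.items():
            for r in range(n_c):
                for c in range(n_c):
                    if m[r, c] > best_val:
                        best_val, seed = m[r, c], (i, j, r, c)
        a, b, r, c = seed
        chosen = {a: r, b: c}
        for k in range(K):
            if k in chosen:
                continue
            cands = []
            for anchor, src in ((a, r), (b, c)):
                if anchor < k:
                    vec = work[(anchor, k)][src, :]
                else:
                    vec = work[(k, anchor)][:, src]
                s = int(np.argmax(vec))
                cands.append((s, vec[s]))
            (s1, v1), (s2, v2) = cands
            chosen[k] = s1 if (s1 == s2 or v1 >= v2) else s2
        for k, s in chosen.items():
            for (i, j), m in work.items():
                if i == k:
                    m[s, :] = -np.inf
                if j == k:
                    m[:, s] = -np.inf
        groups.append(chosen)
    return groups


def build_crcm_fixture(rng, K=3, n_c=2):
    S_T = [standardized(rng, (n_c, 30)) for _ in range(K)]
    S_S = [standardized(rng, (n_c, 45)) for _ in range(K)]
    t_decs = [make_dec(S_T[k], k) for k in range(K)]
    s_decs = [make_dec(S_S[k], k, "spatial") for k in range(K)]
    matches = [identity_match(n_c, k) for k in range(K)]
    crcms = compute_crcms(t_decs, s_decs, matches)
    return crcms, t_decs, s_decs, matches


class TestAlign:
    def test_identical_realizations_group_same_index(self, rng):
        n_c, K = 3, 4
        S_T = standardized(rng, (n_c, 40))
        S_S = standardized(rng, (n_c, 50))
        t_decs = [make_dec(S_T.copy(), k) for k in range(K)]
        s_decs = [make_dec(S_S.copy(), k, "spatial") for k in range(K)]
        matches = [identity_match(n_c, k) for k in range(K)]
        crcms = compute_crcms(t_decs, s_decs, matches)
        groups = align(crcms, t_decs, s_decs, matches)
        for g in groups:
            indices = {m.source_index for m in g.members}
            assert len(indices) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        crcms, t_decs, s_decs, matches = build_crcm_fixture(rng)
        groups = align(crcms, t_decs, s_decs, matches)
        oracle = brute_force_align(crcms.matrices, K=3, n_c=2)
        got = [{m.realization_index: m.source_index for m in g.members} for g in groups]
        assert got == oracle

    def test_partition_property(self, rng):
        crcms, t_decs, s_decs, matches = build_crcm_fixture(rng, K=4, n_c=3)
        groups = align(crcms, t_decs, s_decs, matches)
        used = sorted((m.realization_index, m.source_index) for g in groups for m in g.members)
        assert used == sorted((k, s) for k in range(4) for s in range(3))

    def test_one_member_per_realization(self, rng):
        crcms, t_decs, s_decs, matches = build_crcm_fixture(rng, K=5, n_c=2)
        for g in align(crcms, t_decs, s_decs, matches):
            assert sorted(m.realization_index for m in g.members) == list(range(5))


def make_group(members_spec, seed_pair=((0, 0), (1, 0))):
    """Build a group from (realization, temporal vec, spatial vec) tuples."""
    members = []
    for k, t, s in members_spec:
        members.append(
            SuperSource(
                realization_index=k,
                source_index=0,
                temporal_source=np.asarray(t, dtype=float),
                spatial_source=np.asarray(s, dtype=float),
                temporal_mixing=np.arange(4.0) + k,
                spatial_mixing=np.arange(3.0) - k,
            )
        )
    return SuperSourceGroup(members=members, seed_pair=seed_pair)


class TestCanonicalizeSigns:
    def test_alternating_signs_unified(self, rng):
        t = standardized(rng, 30)
        s = standardized(rng, 45)
        group = make_group([(k, t * (-1) ** k, s * (-1) ** k) for k in range(4)])
        canonicalize_signs(group)
        for m in group.members:
            assert abs_pearson(m.temporal_source, t) == pytest.approx(1.0)
            assert np.corrcoef(m.temporal_source, t)[0, 1] > 0
            assert np.corrcoef(m.spatial_source, s)[0, 1] > 0

    def test_reconstruction_invariant(self, rng):
        t = standardized(rng, 30)
        s = standardized(rng, 45)
        group = make_group([(k, t * (-1) ** k, s * (-1) ** k) for k in range(4)])
        before = [
            (np.outer(m.temporal_mixing, m.temporal_source), np.outer(m.spatial_mixing, m.spatial_source))
            for m in group.members
        ]
        canonicalize_signs(group)
        after = [
            (np.outer(m.temporal_mixing, m.temporal_source), np.outer(m.spatial_mixing, m.spatial_source))
            for m in group.members
        ]
        for (bt, bs), (at_, as_) in zip(before, after):
            np.testing.assert_allclose(bt, at_, atol=1e-12)
            np.testing.assert_allclose(bs, as_, atol=1e-12)

    def test_random_flip_property(self, rng):
        # canonicalizing a randomly sign-corrupted coherent group matches the
        # canonicalized uncorrupted group up to one global sign per modality
        t = standardized(rng, 30)
        s = standardized(rng, 45)
        base = make_group([(k, t + 0.01 * rng.normal(size=30), s + 0.01 * rng.normal(size=45)) for k in range(5)])
        canonicalize_signs(base)
        for trial in range(5):
            flips_t = rng.choice([-1.0, 1.0], size=5)
            flips_s = rng.choice([-1.0, 1.0], size=5)
            corrupted = make_group(
                [
                    (k, m.temporal_source * ft, m.spatial_source * fs)
                    for k, m, ft, fs in zip(range(5), base.members, flips_t, flips_s)
                ]
            )
            canonicalize_signs(corrupted)
            gt = np.sign(corrupted.members[0].temporal_source @ base.members[0].temporal_source)
            gs = np.sign(corrupted.members[0].spatial_source @ base.members[0].spatial_source)
            for mb, mc in zip(base.members, corrupted.members):
                np.testing.assert_allclose(mc.temporal_source, gt * mb.temporal_source, atol=1e-12)
                np.testing.assert_allclose(mc.spatial_source, gs * mb.spatial_source, atol=1e-12)


class TestAggregate:
    def test_identical_members_r_one(self, rng):
        t = standardized(rng, 30)
        s = standardized(rng, 45)
        group = make_group([(k, t, s) for k in range(4)])
        result = aggregate([group])
        assert result.reproducibility[0] == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(result.temporal_sources[0], t, atol=1e-12)
        np.testing.assert_allclose(result.spatial_sources[0], s, atol=1e-12)

    def test_uncorrelated_members_r_near_zero(self):
        rng = np.random.default_rng(0)
        n = 4000  # long vectors so sampling noise in Pearson is small
        group = make_group([(k, rng.normal(size=n), rng.normal(size=n)) for k in range(4)])
        result = aggregate([group])
        assert result.reproducibility[0] < 0.1

    def test_hand_computed_r_and_weights(self, rng):
        # temporal vectors built with exact pairwise Pearson {0.8, 0.6, 0.4};
        # spatial parts identical (rho 1), so with w_T = w_S = 1/2 the pair
        # similarities are {0.9, 0.8, 0.7}:
        # R = (0.9+0.8+0.7)/3 = 0.8, weights prop to {0.85, 0.80, 0.75}
        C = np.array([[1.0, 0.8, 0.6], [0.8, 1.0, 0.4], [0.6, 0.4, 1.0]])
        L = np.linalg.cholesky(C)
        n = 50
        A = rng.normal(size=(n, 3))
        A -= A.mean(axis=0)  # zero-mean columns stay zero-mean under QR
        Q, _ = np.linalg.qr(A)
        T = L @ Q.T  # rows have exactly the pairwise correlations of C
        s = standardized(rng, 60)
        group = make_group([(k, T[k], s) for k in range(3)])
        result = aggregate([group])
        assert result.reproducibility[0] == pytest.approx(0.8, abs=1e-12)
        np.testing.assert_allclose(
            group.weights, np.array([0.85, 0.80, 0.75]) / 2.4, atol=1e-12
        )

    def test_sorted_descending(self, rng):
        t = standardized(rng, 30)
        s = standardized(rng, 45)
        coherent = make_group([(k, t, s) for k in range(3)])
        noisy = make_group(
            [(k, rng.normal(size=30), rng.normal(size=45)) for k in range(3)]
        )
        result = aggregate([noisy, coherent])
        assert np.all(np.diff(result.reproducibility) <= 0)
        assert result.reproducibility[0] == pytest.approx(1.0, abs=1e-12)

    def test_k1_rejected(self, rng):
        group = make_group([(0, standardized(rng, 30), standardized(rng, 45))])
        with pytest.raises(ValueError, match="K >= 2"):
            aggregate([group])

    def test_r_in_unit_interval_random_groups(self, rng):
        for _ in range(10):
            group = make_group(
                [(k, rng.normal(size=20), rng.normal(size=25)) for k in range(3)]
            )
            result = aggregate([group])
            assert 0.0 <= result.reproducibility[0] <= 1.0

    def test_concatenated_similarity_mode(self, rng):
        t = standardized(rng, 30)
        s = standardized(rng, 45)
        group = make_group([(k, t, s) for k in range(3)])
        result = aggregate([group], similarity="concatenated")
        assert result.reproducibility[0] == pytest.approx(1.0, abs=1e-12)
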