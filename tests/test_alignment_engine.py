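import numpy as np
import pytest

from flexalign.alignment_engine import (
    Alignment,
    EngineConfig,
    align,
    alignment_gain,
    alignment_objective,
    compute_local_transforms,
    dp_align,
    evaluate_alignment,
    init_score_matrix,
    pd_score,
    rescore,
    simterm,
)
from flexalign.fragmentation import fragments_for, neighbourhoods_for
from flexalign.geometry import apply
from flexalign.structure_io import assign_sse
from flexalign.synthetic import DomainSpec, make_domain, make_hinge_pair

from oracles import brute_force_block_objective

CFG = EngineConfig()


class TestAlignmentType:
    def test_rejects_non_monotone(self):
        with pytest.raises(ValueError):
            Alignment(((0, 0), (1, 0)))
        with pytest.raises(ValueError):
            Alignment(((2, 3), (2, 4)))

    def test_runs_and_block_validation(self):
        a = Alignment(tuple((i, i) for i in range(6)))
        a.validate_blocks(6)
        b = Alignment(tuple((i, i) for i in range(5)))
        with pytest.raises(ValueError):
            b.validate_blocks(6)

    def test_mirror(self):
        a = Alignment(((0, 1), (1, 2)))
        assert a.mirror().pairs == ((1, 0), (2, 1))


class TestInitScoreMatrix:
    def test_self_diagonal_is_row_max(self, mixed_domain):
        S = init_score_matrix(mixed_domain, mixed_domain, CFG)
        assert np.all(np.diag(S) >= S.max(axis=1) - 1e-12)

    def test_identical_structures_symmetric(self, helix20):
        S = init_score_matrix(helix20, helix20, CFG)
        np.testing.assert_allclose(S, S.T, atol=1e-12)

    def test_sse_mismatch_contributes_zero(self, rng):
        coil = make_domain(DomainSpec((("loop", 12),), seed=2))
        helix = make_domain(DomainSpec((("helix", 12),), seed=3))
        S_mismatch = init_score_matrix(coil, helix, CFG)
        # rebuilding with the sse weight removed changes nothing: the match
        # indicator is uniformly zero for disjoint label sets
        cfg0 = EngineConfig(w_sse=0.0)
        np.testing.assert_allclose(
            S_mismatch, init_score_matrix(coil, helix, cfg0), atol=1e-12
        )

    def test_requires_sse(self, helix20):
        from dataclasses import replace

        bare = replace(helix20, sse=None)
        with pytest.raises(ValueError, match="assign_sse"):
            init_score_matrix(bare, helix20, CFG)


class TestDpAlign:
    def test_all_ones_full_diagonal(self):
        S = np.ones((6, 6))
        aln = dp_align(S, penalty=0.0)
        assert aln.pairs == tuple((i, i) for i in range(6))
        assert alignment_objective(S, aln, 0.0) == pytest.approx(6.0)

    def test_too_small_matrix_empty(self, rng):
        S = rng.normal(size=(5, 5))
        aln = dp_align(S, penalty=0.3)
        assert aln.pairs == ()
        assert alignment_objective(S, aln, 0.3) == pytest.approx(-0.3 * 10)

    def test_negative_matrix_empty(self, rng):
        S = np.full((8, 8), -1.0)
        assert dp_align(S, penalty=0.1).pairs == ()

    def test_matches_brute_force_small(self, rng):
        for _ in range(60):
            n1, n2 = rng.integers(6, 11, 2)
            S = rng.normal(0, 0.5, (n1, n2))
            aln = dp_align(S, 0.0622)
            aln.validate_blocks(6)
            got = alignment_objective(S, aln, 0.0622)
            exp = brute_force_block_objective(S, 0.0622)
            assert got == pytest.approx(exp, abs=1e-9)

    def test_min_block_respected(self, rng):
        for _ in range(30):
            S = rng.normal(0.2, 0.5, (15, 15))
            dp_align(S, 0.05, min_block=6).validate_blocks(6)
            dp_align(S, 0.05, min_block=4).validate_blocks(4)

    def test_objective_gain_identity(self, rng):
        # Σ S − p·(unmatched) == Σ (S + 2p) − p·(L1+L2) for any alignment
        for _ in range(100):
            n1, n2 = rng.integers(6, 14, 2)
            S = rng.normal(size=(n1, n2))
            p = float(rng.uniform(0, 0.5))
            aln = dp_align(S, p)
            lhs = alignment_objective(S, aln, p)
            rhs = alignment_gain(S, aln, p) - p * (n1 + n2)
            assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_penalty_negative_rejected(self):
        with pytest.raises(ValueError):
            dp_align(np.ones((6, 6)), -0.1)

    def test_deterministic(self, rng):
        S = rng.normal(size=(20, 20))
        assert dp_align(S, 0.0622).pairs == dp_align(S.copy(), 0.0622).pairs


class TestScoreTermCalibration:
    def test_d0_value(self):
        assert simterm(0.0) == 1.0
        assert simterm(11.5) == pytest.approx(0.5)

    def test_zero_distance_entry(self):
        # d = 0 -> S = 1 - kappa
        assert 1.0 - CFG.kappa == pytest.approx(0.7513, abs=5e-4)

    def test_break_even_at_9A(self):
        # net gain of a matched pair over two gaps vanishes exactly at 9 A
        s = simterm(81.0) - CFG.kappa
        assert s + 2 * CFG.penalty == pytest.approx(0.0, abs=1e-12)

    def test_far_limit(self):
        assert simterm(1e12) - CFG.kappa == pytest.approx(-CFG.kappa, abs=1e-9)


class TestLocalTransforms:
    def test_identity_on_self(self, mixed_domain):
        s = mixed_domain
        frags = fragments_for(s)
        nbs = neighbourhoods_for(s, frags, CFG.m)
        aln = Alignment(tuple((i, i) for i in range(len(s))))
        transforms = compute_local_transforms(s, s, aln, frags, frags, nbs, nbs)
        assert transforms
        for t in transforms.values():
            assert t is not None
            np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-8)
            np.testing.assert_allclose(t.translation, 0.0, atol=1e-8)

    def test_hinge_halves_recover_rotation(self):
        spec = DomainSpec((("helix", 20), ("loop", 4), ("helix", 20)), seed=4)
        a, b = make_hinge_pair(spec, 22, 60.0, axis_seed=7)
        cfg = EngineConfig(m=12)  # confine neighbourhoods within a half
        frags = fragments_for(a)
        nba = neighbourhoods_for(a, frags, cfg.m)
        nbb = neighbourhoods_for(b, frags, cfg.m)
        aln = Alignment(tuple((i, i) for i in range(len(a))))
        transforms = compute_local_transforms(a, b, aln, frags, frags, nba, nbb)
        # fragment pairs fully inside the fixed N-half map with identity
        for (kf, kg), t in transforms.items():
            if t is None:
                continue
            f = frags[kf]
            members = nba[kf].member_sites | nbb[kg].member_sites
            if f.end < 22 and max(members) < 22:
                np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-6)
            if f.start > 22 and min(members) > 22:
                # moved half: transform maps a-coords onto rotated b-coords
                i = f.start
                np.testing.assert_allclose(
                    apply(t, a.coords[i]), b.coords[i], atol=1e-6
                )

    def test_too_few_pairs_undefined(self, mixed_domain):
        s = mixed_domain
        frags = fragments_for(s)
        nbs = neighbourhoods_for(s, frags, 6)
        aln = Alignment(((0, 0), (1, 1)))
        transforms = compute_local_transforms(s, s, aln, frags, frags, nbs, nbs)
        assert transforms == {(0, 0): None}


class TestRescore:
    def test_self_rescore_diagonal_max(self, mixed_domain):
        s = mixed_domain
        frags = fragments_for(s)
        nbs = neighbourhoods_for(s, frags, CFG.m)
        aln = Alignment(tuple((i, i) for i in range(len(s))))
        transforms = compute_local_transforms(s, s, aln, frags, frags, nbs, nbs)
        S = rescore(s, s, aln, transforms, frags, frags, CFG)
        np.testing.assert_allclose(np.diag(S), 1.0 - CFG.kappa, atol=1e-8)
        assert S.max() <= 1.0 - CFG.kappa + 1e-8

    def test_empty_alignment_floor(self, mixed_domain):
        s = mixed_domain
        frags = fragments_for(s)
        S = rescore(s, s, Alignment(()), {}, frags, frags, CFG)
        np.testing.assert_allclose(S, -CFG.kappa)


class TestAlign:
    def test_self_alignment_perfect(self, mixed_domain):
        res = align(mixed_domain, mixed_domain)
        assert res.pd_score == pytest.approx(1.0, abs=1e-9)
        assert len(res.alignment) == len(mixed_domain)
        assert max(res.pair_distances) < 1e-8
        assert res.converged

    def test_symmetry_under_swap(self):
        a = make_domain(DomainSpec((("helix", 16), ("loop", 4), ("strand", 8)), seed=5))
        b = make_domain(
            DomainSpec((("helix", 14), ("loop", 5), ("strand", 9), ("loop", 3), ("helix", 10)), seed=6)
        )
        r1 = align(a, b)
        r2 = align(b, a)
        assert r1.pd_score == r2.pd_score
        assert r1.alignment.pairs == r2.alignment.mirror().pairs

    def test_short_structure_empty_result(self, helix20):
        tiny = make_domain(DomainSpec((("loop", 4),), seed=8))
        res = align(tiny, helix20)
        assert res.alignment.pairs == ()
        assert res.pd_score == 0.0

    def test_deterministic_repeat(self, mixed_domain, helix20):
        r1 = align(mixed_domain, helix20)
        r2 = align(mixed_domain, helix20)
        assert r1.pd_score == r2.pd_score
        assert r1.alignment.pairs == r2.alignment.pairs

    def test_pd_monotone_under_noise(self, rng):
        spec = DomainSpec((("helix", 16), ("loop", 4), ("helix", 16)), seed=9)
        clean = make_domain(spec)
        scores = []
        for sigma in (0.0, 1.0, 3.0):
            noisy = clean.with_coords(
                clean.coords + np.random.default_rng(77).normal(scale=sigma, size=clean.coords.shape)
            )
            res = align(clean, noisy)
            scores.append(res.pd_score)
        assert scores[0] > scores[1] > scores[2]


class TestPdScore:
    def test_empty_alignment_zero(self, mixed_domain):
        assert pd_score(mixed_domain, mixed_domain, Alignment(()), {}) == 0.0

    def test_partial_perfect_alignment(self):
        # L1 = L2 = 10, 6 matched pairs at distance 0 -> (2/20)*6 = 0.6
        s = make_domain(DomainSpec((("helix", 10),), seed=10))
        pairs = tuple((i, i) for i in range(6))
        frags = fragments_for(s)
        nbs = neighbourhoods_for(s, frags, CFG.m)
        aln = Alignment(pairs)
        transforms = compute_local_transforms(s, s, aln, frags, frags, nbs, nbs)
        assert pd_score(s, s, aln, transforms, frags, frags, CFG) == pytest.approx(0.6)

    def test_normalization_variants(self, mixed_domain, helix20):
        res = align(mixed_domain, helix20)
        frags_a = fragments_for(mixed_domain)
        frags_b = fragments_for(helix20)
        for norm in ("sum", "min", "geometric"):
            cfg = EngineConfig(normalization=norm)
            v = pd_score(mixed_domain, helix20, res.alignment, res.transforms, frags_a, frags_b, cfg)
            assert 0.0 <= v <= 1.0 + 1e-9


class TestEvaluateAlignment:
    def test_identity_on_copies(self, mixed_domain):
        pairs = tuple((i, i) for i in range(len(mixed_domain)))
        score, dists = evaluate_alignment(mixed_domain, mixed_domain, pairs)
        assert score == pytest.approx(1.0, abs=1e-9)
        assert np.max(dists) < 1e-8

    def test_monotone_jitter_degradation(self, mixed_domain):
        pairs = tuple((i, i) for i in range(len(mixed_domain)))
        scores = []
        for sigma in (0.0, 0.5, 5.0):
            noisy = mixed_domain.with_coords(
                mixed_domain.coords
                + np.random.default_rng(5).normal(scale=sigma, size=mixed_domain.coords.shape)
            )
            scores.append(evaluate_alignment(mixed_domain, noisy, pairs)[0])
        assert scores[0] > scores[1] > scores[2]
        assert scores[0] == pytest.approx(1.0, abs=1e-9)

    def test_consistent_with_align(self, mixed_domain, helix20):
        res = align(mixed_domain, helix20)
        if not res.alignment.pairs:
            pytest.skip("no alignment found for this fixture")
        score, _ = evaluate_alignment(mixed_domain, helix20, res.alignment.pairs)
        assert score == pytest.approx(res.pd_score, abs=1e-9)

    def test_non_monotone_errors(self, mixed_domain):
        with pytest.raises(ValueError):
            evaluate_alignment(mixed_domain, mixed_domain, ((3, 3), (2, 4)))
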