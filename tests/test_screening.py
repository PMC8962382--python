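"""Superposition, volume overlap, fitness scoring and deck-screening tests."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from mpcscreen.chem_core import Conformer, parse_structure
from mpcscreen.pharmacophore import perceive_features
from mpcscreen.screening import (
    DeckEntry,
    ScoringWeights,
    enumerate_assignments,
    fitness_score,
    hits_to_frame,
    score_conformer,
    screen_deck,
    superpose_sites,
    vector_score,
    volume_overlap,
)


def rotation_search_oracle(model, ref, n_starts=24, seed=0):
    """Best-fit RMS by generic minimization over rotation vectors —
    independent of the SVD-based superposition."""
    model = model - model.mean(axis=0)
    ref = ref - ref.mean(axis=0)

    def rms_of(rotvec):
        fitted = Rotation.from_rotvec(rotvec).apply(model)
        return np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1)))

    rng = np.random.default_rng(seed)
    best = math.inf
    for _ in range(n_starts):
        x0 = rng.uniform(-np.pi, np.pi, 3)
        res = minimize(rms_of, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
        best = min(best, res.fun)
    return best


def sphere_iou_closed_form(r, d):
    """Intersection-over-union of two equal spheres at distance d."""
    v_sphere = 4 / 3 * math.pi * r**3
    if d >= 2 * r:
        return 0.0
    lens = math.pi * (2 * r - d) ** 2 * (d + 4 * r) / 12
    return lens / (2 * v_sphere - lens)


def _single_atom_conformer(symbol, position):
    mol = parse_structure(symbol)
    return Conformer(mol, np.array([position], dtype=float))


class TestSuperposition:
    def test_identical_points(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 2, 0.5]], dtype=float)
        rot, trans, rms = superpose_sites(pts, pts)
        assert rms < 1e-12
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(trans, 0, atol=1e-10)

    def test_translated_copy(self):
        pts = np.array([[0, 0, 0], [1.5, 0, 0], [0, 2, 1]], dtype=float)
        _, _, rms = superpose_sites(pts + np.array([3.0, -2.0, 7.0]), pts)
        assert rms < 1e-12

    def test_matches_rotation_search_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(20):
            model = rng.normal(scale=3.0, size=(3, 3))
            ref = rng.normal(scale=3.0, size=(3, 3))
            _, _, rms = superpose_sites(model, ref)
            assert abs(rms - rotation_search_oracle(model, ref)) < 1e-3

    def test_collinear_points_solvable(self):
        model = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
        ref = np.array([[0, 0, 0], [0, 1, 0], [0, 2, 0]], dtype=float)
        _, _, rms = superpose_sites(model, ref)
        assert rms < 1e-10

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            superpose_sites(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_no_reflection(self):
        rng = np.random.default_rng(5)
        model = rng.normal(size=(4, 3))
        rot, _, _ = superpose_sites(model, rng.normal(size=(4, 3)))
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)


class TestVolumeOverlap:
    def test_self_is_one(self, uk_anion_conformer):
        assert volume_overlap(uk_anion_conformer, uk_anion_conformer) == 1.0

    def test_distant_is_zero(self, uk_anion_conformer):
        far = uk_anion_conformer.transformed(np.eye(3), np.array([100.0, 0, 0]))
        assert volume_overlap(uk_anion_conformer, far) == 0.0

    def test_symmetry(self, uk_anion_conformer):
        rot = Rotation.from_euler("z", 25, degrees=True).as_matrix()
        other = uk_anion_conformer.transformed(rot, np.array([1.0, 0.5, 0.0]))
        assert volume_overlap(uk_anion_conformer, other) == pytest.approx(
            volume_overlap(other, uk_anion_conformer), abs=1e-12
        )

    @pytest.mark.parametrize("distance", [0.8, 1.7, 2.5])
    def test_two_spheres_match_lens_formula(self, distance):
        # single carbon atoms: Bondi radius 1.70 Å
        a = _single_atom_conformer("C", [0, 0, 0])
        b = _single_atom_conformer("C", [distance, 0, 0])
        expected = sphere_iou_closed_form(1.70, distance)
        assert volume_overlap(a, b, grid=0.3) == pytest.approx(expected, rel=0.02)

    def test_bad_grid(self, uk_anion_conformer):
        with pytest.raises(ValueError):
            volume_overlap(uk_anion_conformer, uk_anion_conformer, grid=0.0)


class TestVectorScore:
    def test_neutral_without_vector_sites(self, hypothesis):
        # direction-less matches only -> neutral 1.0
        assert vector_score([None, None, None], hypothesis) == 1.0

    def test_perfect_alignment(self, hypothesis):
        dirs = [None if s.direction is None else s.direction for s in hypothesis.sites]
        assert vector_score(dirs, hypothesis) == pytest.approx(1.0)

    def test_orthogonal_acceptor_parallel_ring(self, hypothesis):
        n_site, a_site, ar_site = hypothesis.sites
        ortho = np.cross(a_site.direction, [0.12, 0.34, 0.91])
        ortho /= np.linalg.norm(ortho)
        dirs = [None, ortho, ar_site.direction]
        assert vector_score(dirs, hypothesis) == pytest.approx(0.5, abs=1e-9)

    def test_ring_normal_sign_invariant(self, hypothesis):
        sites = hypothesis.sites
        dirs_up = [None, sites[1].direction, sites[2].direction]
        dirs_down = [None, sites[1].direction, -sites[2].direction]
        assert vector_score(dirs_up, hypothesis) == vector_score(dirs_down, hypothesis)

    def test_negative_cosines_clamped(self, hypothesis):
        a_site = hypothesis.sites[1]
        dirs = [None, -a_site.direction, hypothesis.sites[2].direction]
        # anti-aligned acceptor earns 0, ring earns 1 -> mean 0.5
        assert vector_score(dirs, hypothesis) == pytest.approx(0.5, abs=1e-9)


class TestFitnessArithmetic:
    def test_at_cutoff_site_term_vanishes(self):
        w = ScoringWeights()
        assert fitness_score(1.2, 0.7, 0.4, w=w) == pytest.approx(0.7 + 0.4)

    @given(st.floats(0.0, 1.19), st.floats(0.0, 1.19))
    @settings(deadline=None)
    def test_strictly_decreasing_in_s_align(self, s1, s2):
        lo, hi = sorted([s1, s2])
        assume(hi - lo > 1e-9)  # below float resolution of the site term
        w = ScoringWeights()
        assert fitness_score(lo, 0.8, 0.5, w=w) > fitness_score(hi, 0.8, 0.5, w=w)

    @given(st.floats(0.0, 1.0))
    @settings(deadline=None)
    def test_s_ivol_has_no_effect_at_zero_weight(self, s_ivol):
        w = ScoringWeights()  # w_ivol = 0 by default
        assert fitness_score(0.3, 0.9, 0.6, s_ivol, w) == fitness_score(0.3, 0.9, 0.6, 0.0, w)


class TestAssignments:
    def test_uk5099_count_matches_enumeration_oracle(self, uk_anion_conformer, hypothesis):
        feats = perceive_features(uk_anion_conformer)
        assignments = enumerate_assignments(feats, hypothesis)
        # brute-force oracle: all injective tuples with matching kinds
        oracle = [
            combo
            for combo in itertools.permutations(range(len(feats)), len(hypothesis.sites))
            if all(feats[i].kind == s.kind for i, s in zip(combo, hypothesis.sites))
        ]
        assert sorted(assignments) == sorted(oracle)
        assert len(assignments) == 3  # 1 N x 1 A x 3 Ar

    def test_benzene_empty(self, hypothesis):
        from mpcscreen.chem_core import embed_conformers

        conf = embed_conformers(parse_structure("c1ccccc1"), 1, seed=1)[0]
        assert enumerate_assignments(perceive_features(conf), hypothesis) == []

    def test_ester_empty(self, hypothesis):
        from mpcscreen.chem_core import embed_conformers

        conf = embed_conformers(parse_structure("3a"), 1, seed=1)[0]
        assert enumerate_assignments(perceive_features(conf), hypothesis) == []


class TestScoreConformer:
    def test_self_match_scores_three(self, hypothesis):
        breakdown, _ = score_conformer(hypothesis.reference, hypothesis)
        assert breakdown.s_align == pytest.approx(0.0, abs=1e-9)
        assert breakdown.s_vec == pytest.approx(1.0, abs=1e-9)
        assert breakdown.s_vol == 1.0
        assert breakdown.s == pytest.approx(3.0, abs=1e-9)

    def test_no_match_returns_none(self, hypothesis):
        from mpcscreen.chem_core import embed_conformers

        conf = embed_conformers(parse_structure("c1ccccc1"), 1, seed=1)[0]
        assert score_conformer(conf, hypothesis) is None

    def test_rigid_motion_invariance(self, hypothesis):
        rot = Rotation.random(random_state=7).as_matrix()
        moved = hypothesis.reference.transformed(rot, np.array([5.0, -3.0, 2.0]))
        breakdown, _ = score_conformer(moved, hypothesis)
        assert breakdown.s == pytest.approx(3.0, abs=0.02)  # volume-grid tolerance


class TestScreenDeck:
    def test_reference_conformer_ranks_first_with_full_score(self, hypothesis, small_deck):
        deck, _ = small_deck
        deck = [DeckEntry("self", hypothesis.reference.molecule.smiles,
                          [hypothesis.reference])] + deck
        hits = screen_deck(deck, hypothesis, top_k=7)
        assert hits[0].compound_id == "self"
        assert hits[0].breakdown.s == pytest.approx(3.0, abs=1e-9)
        assert [h.rank for h in hits] == list(range(1, len(hits) + 1))
        scores = [h.breakdown.s for h in hits]
        assert scores == sorted(scores, reverse=True)

    def test_ester_negatives_never_hit(self, hypothesis, small_deck):
        deck, manifest = small_deck
        esters = set(manifest.loc[manifest["provenance"] == "ester_negative", "id"])
        hits = screen_deck(deck, hypothesis, top_k=len(deck))
        assert esters.isdisjoint({h.compound_id for h in hits})

    def test_small_hit_list_returned_whole(self, hypothesis):
        deck, _ = _mini_deck(["UK-5099", "BE1976", "BE1984"])
        hits = screen_deck(deck, hypothesis, top_k=7)
        assert len(hits) == 3

    def test_empty_deck_raises(self, hypothesis):
        with pytest.raises(ValueError):
            screen_deck([], hypothesis)

    def test_rescreen_is_bitwise_identical(self, hypothesis, small_deck):
        deck, _ = small_deck
        a = hits_to_frame(screen_deck(deck, hypothesis, top_k=7)).to_csv(index=False)
        b = hits_to_frame(screen_deck(deck, hypothesis, top_k=7)).to_csv(index=False)
        assert a == b


def _mini_deck(ids):
    from mpcscreen.chem_core import embed_conformers

    deck = []
    for i, cid in enumerate(ids):
        mol = parse_structure(cid)
        deck.append(DeckEntry(cid, mol.smiles, embed_conformers(mol, 2, seed=10 + i)))
    return deck, None
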