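"""Pharmacophore screening: site matching, superposition, and the fitness score.

A deck conformer is a hit only if it matches *all* hypothesis sites with
kind-compatible features. Each injective site->feature assignment is scored

    S = W_site * (1 - S_align / C_align) + W_vec * S_vec
        + W_vol * S_vol + W_ivol * S_ivol

where S_align is the RMS deviation of matched site points after optimal
rigid superposition, S_vec the mean cosine between matched feature
directions (ring normals compared sign-invariantly), and S_vol the
intersection-over-union of heavy-atom van der Waals volumes between the
superposed pose and the reference conformer. The site term is floored at
zero once S_align exceeds the alignment cutoff C_align; with the default
weights (1, 1, 1, 0) a perfect self-match scores S = 3.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .chem_core import Conformer
from .pharmacophore import Hypothesis, PharmacophoreFeature, perceive_features

# Bondi van der Waals radii (Å)
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
}
_DEFAULT_RADIUS = 1.70

# kinds whose features carry a direction vector entering S_vec
VECTOR_KINDS = frozenset({"A", "Ar", "D"})
# kinds whose direction sign is arbitrary (ring normals)
SIGN_INVARIANT_KINDS = frozenset({"Ar"})


@dataclass(frozen=True)
class ScoringWeights:
    w_site: float = 1.0
    w_vec: float = 1.0
    w_vol: float = 1.0
    w_ivol: float = 0.0
    c_align: float = 1.2  # alignment cutoff, Å

    def __post_init__(self) -> None:
        if min(self.w_site, self.w_vec, self.w_vol, self.w_ivol) < 0:
            raise ValueError("weights must be >= 0")
        if self.c_align <= 0:
            raise ValueError("c_align must be > 0")


@dataclass(frozen=True)
class ScoreBreakdown:
    s_align: float  # Å, RMS site-point deviation
    s_vec: float    # mean cosine, dimensionless
    s_vol: float    # overlap ratio in [0, 1]
    s_ivol: float   # included-volume ratio in [0, 1]
    s: float        # total fitness


@dataclass(frozen=True)
class ScreenHit:
    compound_id: str
    conformer_index: int
    assignment: tuple[int, ...]  # hypothesis site -> feature index
    breakdown: ScoreBreakdown
    rank: int = 0


def fitness_score(
    s_align: float,
    s_vec: float,
    s_vol: float,
    s_ivol: float = 0.0,
    w: ScoringWeights = ScoringWeights(),
) -> float:
    """Total fitness from its components; the site term is floored at zero
    once S_align exceeds the alignment cutoff."""
    site_term = max(0.0, 1.0 - s_align / w.c_align)
    return w.w_site * site_term + w.w_vec * s_vec + w.w_vol * s_vol + w.w_ivol * s_ivol


def enumerate_assignments(
    features: list[PharmacophoreFeature], h: Hypothesis
) -> list[tuple[int, ...]]:
    """All injective, kind-compatible mappings from hypothesis sites to features.

    Returns an empty list whenever any site kind has no candidate feature
    (the all-feature match rule: partial matches are not hits).
    """
    candidates = [
        [i for i, f in enumerate(features) if f.kind == site.kind]
        for site in h.sites
    ]
    if any(len(c) == 0 for c in candidates):
        return []
    out = []
    for combo in itertools.product(*candidates):
        if len(set(combo)) == len(combo):
            out.append(tuple(combo))
    return out


def superpose_sites(
    model_points: np.ndarray, reference_points: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of model onto reference points (Kabsch).

    Returns ``(rotation, translation, rms)`` such that
    ``model @ rotation.T + translation`` best fits the reference; ``rms`` is
    the post-fit RMS deviation in Å. Requires at least 3 point pairs
    (collinear triples are still solvable).
    """
    model = np.asarray(model_points, dtype=float)
    ref = np.asarray(reference_points, dtype=float)
    if model.shape != ref.shape:
        raise ValueError("point sets must have equal shapes")
    if model.shape[0] < 3:
        raise ValueError("superposition requires at least 3 points")
    mc, rc = model.mean(axis=0), ref.mean(axis=0)
    cov = (model - mc).T @ (ref - rc)
    u, _, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = rc - rotation @ mc
    fitted = model @ rotation.T + translation
    rms = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return rotation, translation, rms


def _heavy_radii(c: Conformer) -> np.ndarray:
    return np.array(
        [
            VDW_RADII.get(sym, _DEFAULT_RADIUS)
            for sym, _, _ in c.molecule.atoms
        ]
    )


def _occupancy(
    coords: np.ndarray,
    radii: np.ndarray,
    origin: np.ndarray,
    shape: tuple[int, int, int],
    spacing: float,
) -> np.ndarray:
    """Boolean occupancy of a regular grid by a union of spheres."""
    occ = np.zeros(shape, dtype=bool)
    nx, ny, nz = shape
    for (x, y, z), r in zip(coords, radii):
        lo = np.maximum(np.floor((np.array([x, y, z]) - r - origin) / spacing), 0).astype(int)
        hi = np.minimum(
            np.ceil((np.array([x, y, z]) + r - origin) / spacing).astype(int) + 1,
            [nx, ny, nz],
        )
        if np.any(lo >= hi):
            continue
        gx = origin[0] + spacing * np.arange(lo[0], hi[0])
        gy = origin[1] + spacing * np.arange(lo[1], hi[1])
        gz = origin[2] + spacing * np.arange(lo[2], hi[2])
        d2 = (
            (gx - x)[:, None, None] ** 2
            + (gy - y)[None, :, None] ** 2
            + (gz - z)[None, None, :] ** 2
        )
        occ[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= d2 <= r * r
    return occ


def volume_overlap(a: Conformer, b: Conformer, grid: float = 0.3) -> float:
    """Intersection-over-union of heavy-atom van der Waals volumes.

    Both conformers must already be in the same (post-superposition)
    frame. Volumes are evaluated on a regular grid of the given spacing
    using Bondi radii; the ratio is in [0, 1].
    """
    if grid <= 0:
        raise ValueError("grid spacing must be > 0")
    ra, rb = _heavy_radii(a), _heavy_radii(b)
    all_coords = np.vstack([a.coords, b.coords])
    all_radii = np.concatenate([ra, rb])
    lo = (all_coords - all_radii[:, None]).min(axis=0) - grid
    hi = (all_coords + all_radii[:, None]).max(axis=0) + grid
    shape = tuple(np.ceil((hi - lo) / grid).astype(int) + 1)
    # cell-centred (midpoint) sampling halves the surface-discretization bias
    origin = lo + 0.5 * grid
    occ_a = _occupancy(a.coords, ra, origin, shape, grid)
    occ_b = _occupancy(b.coords, rb, origin, shape, grid)
    union = int(np.count_nonzero(occ_a | occ_b))
    if union == 0:
        return 0.0
    inter = int(np.count_nonzero(occ_a & occ_b))
    return inter / union


def vector_score(
    aligned_directions: list[np.ndarray | None],
    h: Hypothesis,
) -> float:
    """Mean cosine between matched feature directions and hypothesis site directions.

    ``aligned_directions[i]`` is the (already rotated) direction of the
    feature matched to site i, or None for direction-less kinds. Ring
    normals are compared via |cos|; every per-site cosine is clamped at 0
    so anti-alignment earns no credit. With no vector-bearing sites the
    score is neutral (1.0).
    """
    cosines = []
    for site, d in zip(h.sites, aligned_directions):
        if site.kind not in VECTOR_KINDS or site.direction is None or d is None:
            continue
        cos = float(np.dot(d, site.direction))
        if site.kind in SIGN_INVARIANT_KINDS:
            cos = abs(cos)
        cosines.append(max(cos, 0.0))
    if not cosines:
        return 1.0
    return float(np.mean(cosines))


def score_conformer(
    c: Conformer,
    h: Hypothesis,
    w: ScoringWeights = ScoringWeights(),
    grid: float = 0.3,
    features: list[PharmacophoreFeature] | None = None,
    ionized: bool = True,
) -> tuple[ScoreBreakdown, tuple[int, ...]] | None:
    """Score a conformer against the hypothesis; None when no assignment exists.

    Every kind-compatible assignment is superposed and scored; the best
    (highest S, ties by lower S_align then assignment order) is returned.
    Volume overlap, the expensive term, is skipped for assignments whose
    site+vector part plus the maximal possible volume credit cannot beat
    the current best.
    """
    if features is None:
        features = perceive_features(c, ionized=ionized)
    assignments = enumerate_assignments(features, h)
    if not assignments:
        return None

    site_pos = h.site_positions()
    partial = []  # (upper bound, order, s_align, s_vec, transform, assignment)
    for order, assign in enumerate(assignments):
        pts = np.array([features[i].position for i in assign])
        rotation, translation, rms = superpose_sites(pts, site_pos)
        dirs = [
            None if features[i].direction is None else rotation @ features[i].direction
            for i in assign
        ]
        s_vec = vector_score(dirs, h)
        site_term = max(0.0, 1.0 - rms / w.c_align)
        base = w.w_site * site_term + w.w_vec * s_vec
        bound = base + w.w_vol * 1.0 + w.w_ivol * 1.0
        partial.append((bound, base, order, rms, s_vec, rotation, translation, assign))

    partial.sort(key=lambda t: (-t[0], t[3], t[2]))
    best: tuple[float, float, int, ScoreBreakdown, tuple[int, ...]] | None = None
    for bound, base, order, rms, s_vec, rotation, translation, assign in partial:
        if best is not None and bound < best[0] - 1e-12:
            break
        posed = c.transformed(rotation, translation)
        s_vol = volume_overlap(posed, h.reference, grid=grid)
        s_ivol = 0.0  # no included-volume spheres defined
        total = base + w.w_vol * s_vol + w.w_ivol * s_ivol
        key = (total, -rms, -order)
        if best is None or key > (best[0], -best[1], -best[2]):
            breakdown = ScoreBreakdown(rms, s_vec, s_vol, s_ivol, total)
            best = (total, rms, order, breakdown, assign)
    assert best is not None
    return best[3], best[4]


@dataclass
class DeckEntry:
    compound_id: str
    molecule_smiles: str
    conformers: list[Conformer]
    provenance: str = "unknown"
    features: list[list[PharmacophoreFeature]] = field(default_factory=list)


def screen_deck(
    deck: list[DeckEntry],
    h: Hypothesis,
    w: ScoringWeights = ScoringWeights(),
    top_k: int = 7,
    grid: float = 0.3,
    ionized: bool = True,
) -> list[ScreenHit]:
    """Score every deck compound (best conformer) and return the top-k hits.

    Compounds failing the all-feature match on every conformer are
    excluded. Survivors are sorted by S descending (ties: lower S_align,
    then compound id) and assigned 1-based ranks.
    """
    if not deck:
        raise ValueError("deck is empty")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    results = []
    for entry in deck:
        best: tuple[ScoreBreakdown, tuple[int, ...], int] | None = None
        for ci, conf in enumerate(entry.conformers):
            feats = entry.features[ci] if entry.features else None
            scored = score_conformer(conf, h, w, grid=grid, features=feats, ionized=ionized)
            if scored is None:
                continue
            breakdown, assign = scored
            if best is None or (breakdown.s, -breakdown.s_align) > (
                best[0].s, -best[0].s_align
            ):
                best = (breakdown, assign, ci)
        if best is not None:
            results.append(
                ScreenHit(entry.compound_id, best[2], best[1], best[0])
            )
    results.sort(key=lambda hit: (-hit.breakdown.s, hit.breakdown.s_align, hit.compound_id))
    return [
        ScreenHit(r.compound_id, r.conformer_index, r.assignment, r.breakdown, rank=i + 1)
        for i, r in enumerate(results[:top_k])
    ]


def hits_to_frame(hits: list[ScreenHit]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "id": hit.compound_id,
                "rank": hit.rank,
                "conformer": hit.conformer_index,
                "S": round(hit.breakdown.s, 6),
                "S_align": round(hit.breakdown.s_align, 6),
                "S_vec": round(hit.breakdown.s_vec, 6),
                "S_vol": round(hit.breakdown.s_vol, 6),
            }
            for hit in hits
        ]
    )
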