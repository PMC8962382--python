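"""Pharmacophore feature perception and hypothesis construction.

The MPC-inhibitor hypothesis is a three-feature arrangement read off a 3D
conformer of the reference inhibitor UK-5099: one negative-ionizable site
(N) on the carboxylate, one hydrogen-bond acceptor (A) on the nitrile, and
one aromatic ring (Ar) on the indole. Feature positions are centroids of
the defining atoms; A and Ar features carry unit direction vectors (the
C≡N lone-pair axis, the ring normal).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem

from .chem_core import Conformer, write_sdf

FEATURE_KINDS = ("N", "A", "Ar", "D", "H", "P")

_SMARTS = {
    "carboxylate": Chem.MolFromSmarts("[CX3](=[OX1])[OX1H0-]"),
    "carboxylic_acid": Chem.MolFromSmarts("[CX3](=[OX1])[OX2H1]"),
    "nitrile": Chem.MolFromSmarts("[CX2]#[NX1]"),
    # carbonyl O that is not part of a carboxyl group (those fold into N)
    "carbonyl": Chem.MolFromSmarts(
        "[OX1]=[CX3;!$([CX3][OX2H1]);!$([CX3][OX1-])]"
    ),
    # pyridine-type aromatic nitrogen (lone pair in plane, no substituent)
    "aromatic_n": Chem.MolFromSmarts("[nX2H0]"),
}


@dataclass(frozen=True)
class PharmacophoreFeature:
    kind: str
    position: np.ndarray  # (3,), Å
    direction: np.ndarray | None  # unit vector or None
    atom_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.direction is not None:
            d = np.asarray(self.direction, dtype=float)
            norm = np.linalg.norm(d)
            if abs(norm - 1.0) > 1e-6:
                raise ValueError(f"direction must be unit length, got |v|={norm}")
            object.__setattr__(self, "direction", d)


@dataclass(frozen=True)
class Hypothesis:
    """Ordered pharmacophore sites plus the reference conformer they came from."""

    sites: tuple[PharmacophoreFeature, ...]
    reference: Conformer
    tolerance: float = 2.0  # Å, per-site matching tolerance

    @property
    def kinds(self) -> tuple[str, ...]:
        return tuple(s.kind for s in self.sites)

    def site_positions(self) -> np.ndarray:
        return np.array([s.position for s in self.sites])


class MissingFeatureError(ValueError):
    """Raised when a reference conformer lacks a required feature kind."""


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length direction vector")
    return v / n


def _ring_plane(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit normal of the best-fit plane through ring atoms."""
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    return centroid, _unit(vt[2])


def perceive_features(c: Conformer, ionized: bool = True) -> list[PharmacophoreFeature]:
    """Perceive N/A/Ar features on a 3D conformer.

    With ``ionized=True`` neutral carboxylic acids are treated as
    negative-ionizable (the protonation state used for screening); formal
    carboxylates always are. Acceptors: nitrile N (direction along C->N),
    non-carboxyl carbonyl O (along C->O), pyridine-type aromatic N
    (outward bond bisector). One Ar feature per aromatic ring, direction =
    ring-plane normal.
    """
    mol = c.molecule.rdmol
    xyz = c.coords
    features: list[PharmacophoreFeature] = []

    # --- N: negative ionizable, centroid of both carboxyl(ate) oxygens
    acid_matches = list(mol.GetSubstructMatches(_SMARTS["carboxylate"]))
    if ionized:
        acid_matches += list(mol.GetSubstructMatches(_SMARTS["carboxylic_acid"]))
    for match in acid_matches:
        oxygens = match[1:3]
        features.append(
            PharmacophoreFeature(
                "N", xyz[list(oxygens)].mean(axis=0), None, tuple(sorted(match))
            )
        )

    # --- A: hydrogen-bond acceptors
    for cx, nx in mol.GetSubstructMatches(_SMARTS["nitrile"]):
        features.append(
            PharmacophoreFeature("A", xyz[nx], _unit(xyz[nx] - xyz[cx]), (cx, nx))
        )
    for ox, carbon in mol.GetSubstructMatches(_SMARTS["carbonyl"]):
        features.append(
            PharmacophoreFeature("A", xyz[ox], _unit(xyz[ox] - xyz[carbon]), (carbon, ox))
        )
    for (nx,) in mol.GetSubstructMatches(_SMARTS["aromatic_n"]):
        nbrs = [a.GetIdx() for a in mol.GetAtomWithIdx(nx).GetNeighbors()]
        # lone pair along the outward bisector of the two ring bonds
        bisector = sum(_unit(xyz[nx] - xyz[j]) for j in nbrs)
        features.append(
            PharmacophoreFeature("A", xyz[nx], _unit(bisector), (nx,))
        )

    # --- Ar: one feature per aromatic ring (SSSR), direction = plane normal
    for ring in mol.GetRingInfo().AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            centroid, normal = _ring_plane(xyz[list(ring)])
            features.append(
                PharmacophoreFeature("Ar", centroid, normal, tuple(sorted(ring)))
            )
    return features


def build_hypothesis(
    reference: Conformer,
    required_kinds: Sequence[str] = ("N", "A", "Ar"),
    tolerance: float = 2.0,
    ionized: bool = True,
) -> Hypothesis:
    """Build a hypothesis with one site per required kind from a reference conformer.

    Ties among candidate Ar rings are broken by picking the ring whose
    centroid is nearest the midpoint of the N and A sites (for UK-5099 this
    selects the central five-membered ring of the indole); other kinds take
    the first perceived feature.
    """
    feats = perceive_features(reference, ionized=ionized)
    by_kind: dict[str, list[PharmacophoreFeature]] = {}
    for f in feats:
        by_kind.setdefault(f.kind, []).append(f)

    missing = [k for k in required_kinds if k not in by_kind]
    if missing:
        raise MissingFeatureError(
            f"reference conformer lacks required feature kinds: {', '.join(missing)}"
        )

    chosen: dict[str, PharmacophoreFeature] = {}
    for kind in required_kinds:
        if kind != "Ar":
            chosen[kind] = by_kind[kind][0]
    if "Ar" in required_kinds:
        candidates = by_kind["Ar"]
        anchors = [chosen[k].position for k in ("N", "A") if k in chosen]
        if len(anchors) == 2:
            midpoint = (anchors[0] + anchors[1]) / 2.0
            candidates = sorted(
                candidates, key=lambda f: float(np.linalg.norm(f.position - midpoint))
            )
        chosen["Ar"] = candidates[0]

    sites = tuple(chosen[k] for k in required_kinds)
    return Hypothesis(sites=sites, reference=reference, tolerance=tolerance)


# ---------------------------------------------------------------------------
# Serialization: hypothesis as JSON, reference conformer as SDF


def save_hypothesis(h: Hypothesis, json_path: str, sdf_path: str) -> None:
    payload = {
        "tolerance": h.tolerance,
        "reference_sdf": sdf_path,
        "sites": [
            {
                "kind": s.kind,
                "position": [float(x) for x in s.position],
                "direction": None if s.direction is None else [float(x) for x in s.direction],
                "atom_indices": list(s.atom_indices),
            }
            for s in h.sites
        ],
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2)
    write_sdf([h.reference], sdf_path)


def load_hypothesis(json_path: str) -> Hypothesis:
    from .chem_core import read_sdf

    with open(json_path) as fh:
        payload = json.load(fh)
    reference = read_sdf(payload["reference_sdf"])[0]
    sites = tuple(
        PharmacophoreFeature(
            s["kind"],
            np.array(s["position"]),
            None if s["direction"] is None else np.array(s["direction"]),
            tuple(s["atom_indices"]),
        )
        for s in payload["sites"]
    )
    return Hypothesis(sites=sites, reference=reference, tolerance=payload["tolerance"])
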