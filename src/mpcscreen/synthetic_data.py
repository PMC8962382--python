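"""Synthetic inputs for the whole pipeline at desk scale.

Generates (i) a screening deck that emulates a lead-like commercial
library — the registry actives, their ester negative controls, and random
decoys decorated from a small heteroaryl scaffold pool, a configurable
fraction of which carry the cyanoacrylate warhead — and (ii) simulated
assay readouts: two-channel BRET plate reads with an injection event,
oxygraph O2 traces with piecewise-linear consumption segments, and
dose-response points with multiplicative log-normal noise.

All generators are pure functions of (spec, seed). The global seed fans
out to per-generator streams by stable hashing of the generator name, so
adding a generator never shifts another generator's draws.
"""

from __future__ import annotations

import functools
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem_core import (
    CompoundRecord,
    embed_conformers,
    load_registry,
    parse_structure,
    registry_actives,
    registry_ester_negatives,
)
from .screening import DeckEntry


def _rng(seed: int, name: str) -> np.random.Generator:
    """Per-generator stream: global seed + CRC32 of the generator name."""
    return np.random.default_rng([int(seed) % (2**31), zlib.crc32(name.encode())])


# ---------------------------------------------------------------------------
# Screening deck


@dataclass(frozen=True)
class DeckSpec:
    n_decoys: int = 100
    seed: int = 0
    conformers_per_molecule: int = 5
    include_actives: bool = True
    include_ester_negatives: bool = True
    include_reference: bool = False
    warhead_fraction: float = 0.3  # decoys carrying the cyanoacrylic acid

    def __post_init__(self) -> None:
        if self.n_decoys < 0:
            raise ValueError("n_decoys must be >= 0")
        if not 0.0 <= self.warhead_fraction <= 1.0:
            raise ValueError("warhead_fraction must be in [0, 1]")


# Aryl/heteroaryl scaffold pool; "{}" marks the decoration point. All
# fragments are valence-legal and keep decoys lead-like (< 500 Da).
_SCAFFOLDS = [
    "c1ccc({})cc1",
    "c1ccc2cc({})ccc2c1",
    "c1ccnc({})c1",
    "c1ccc({})nc1",
    "c1cncc({})c1",
    "c1ncc({})cn1",
    "c1csc({})c1",
    "c1coc({})c1",
    "c1cn(C)nc1{}",
    "c1cc2ccccc2n1{}",
    "c1ccc2sc({})nc2c1",
    "c1ccc2oc({})nc2c1",
    "c1ccc2sc({})cc2c1",
    "c1ccc2oc({})cc2c1",
    "Cn1cc({})c2ccccc21",
    "c1ccc2nc({})ccc2c1",
    "Cc1cc({})no1",
    "Cn1ccnc1{}",
]

_SUBSTITUENTS = [
    "", "C", "CC", "C(C)C", "OC", "OCC", "N", "N(C)C",
    "Cl", "F", "Br", "C(F)(F)F",
]

# warhead: Ar-CH=C(CN)-COOH (decoy stereochemistry left unspecified)
_WARHEAD = "C=C(C#N)C(=O)O"
# carboxylate-free terminal groups for plain decoys
_PLAIN_TAILS = [
    "C#N", "C(=O)N(C)C", "C(=O)OC", "CCO", "S(=O)(=O)C",
    "C(C)=O", "CNC(C)=O", "OC(C)=O",
]


@functools.lru_cache(maxsize=2)
def _enumerate_decoy_pool(warhead: bool) -> list[str]:
    """All distinct, parseable decoy SMILES of one class, in sorted order."""
    tails = [_WARHEAD] if warhead else _PLAIN_TAILS
    seen = set()
    for scaffold in _SCAFFOLDS:
        for tail in tails:
            core = scaffold.format(tail)
            for sub in _SUBSTITUENTS:
                smiles = f"{sub}{core}" if sub and core[0] == "c" else core
                mol = Chem.MolFromSmiles(smiles)
                if mol is None:
                    continue
                seen.add(Chem.MolToSmiles(mol))
    return sorted(seen)


def generate_deck(spec: DeckSpec) -> tuple[list[DeckEntry], pd.DataFrame]:
    """Build the deck (with embedded conformers) and its provenance manifest."""
    rng = _rng(spec.seed, "deck")
    records: list[tuple[str, str, str]] = []  # (id, smiles, provenance)

    if spec.include_reference:
        ref = load_registry()["UK-5099"]
        records.append((ref.id, ref.smiles, "reference"))
    if spec.include_actives:
        for rec in registry_actives():
            records.append((rec.id, rec.smiles, "active"))
    if spec.include_ester_negatives:
        for rec in registry_ester_negatives():
            records.append((rec.id, rec.smiles, "ester_negative"))

    n_warhead = int(round(spec.n_decoys * spec.warhead_fraction))
    n_plain = spec.n_decoys - n_warhead
    made = 0
    for warhead, count in ((True, n_warhead), (False, n_plain)):
        pool = _enumerate_decoy_pool(warhead)
        if count > len(pool):
            raise ValueError(
                f"requested {count} {'warhead' if warhead else 'plain'} decoys "
                f"but the scaffold pool holds only {len(pool)}"
            )
        for idx in rng.permutation(len(pool))[:count]:
            records.append((f"DEC{made:05d}", pool[idx], "decoy_warhead" if warhead else "decoy_plain"))
            made += 1

    entries = []
    for i, (cid, smi, provenance) in enumerate(records):
        mol = parse_structure(smi, mol_id=cid)
        embed_seed = (int(spec.seed) * 100003 + i * 7919) % (2**31 - 1)
        confs = embed_conformers(mol, spec.conformers_per_molecule, embed_seed)
        entries.append(DeckEntry(cid, mol.smiles, confs, provenance))

    manifest = pd.DataFrame(
        [
            {
                "id": e.compound_id,
                "smiles": e.molecule_smiles,
                "provenance": e.provenance,
                "n_conformers": len(e.conformers),
            }
            for e in entries
        ]
    )
    return entries, manifest


# ---------------------------------------------------------------------------
# Dose-response simulation


def simulate_dose_response(
    ic50: float,
    hill: float = 1.0,
    top: float = 100.0,
    bottom: float = 0.0,
    doses: Sequence[float] = (),
    reps: int = 3,
    cv: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Four-parameter log-logistic responses with multiplicative noise.

    response(d) = [bottom + (top - bottom) / (1 + (d/ic50)^hill)] * exp(eps),
    eps ~ Normal(0, cv). Doses and ic50 in nM.
    """
    if ic50 <= 0:
        raise ValueError("ic50 must be > 0")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be > 0")
    rng = _rng(seed, "dose_response")
    rows = []
    for rep in range(reps):
        clean = bottom + (top - bottom) / (1.0 + (doses / ic50) ** hill)
        noise = np.exp(rng.normal(0.0, cv, size=doses.shape)) if cv > 0 else 1.0
        for d, r in zip(doses, clean * noise):
            rows.append({"dose_nM": d, "rep": rep, "response": r})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# BRET plate simulation


@dataclass(frozen=True)
class BretSimSpec:
    treatments: Mapping[str, float] = field(
        default_factory=lambda: {"DMSO": 0.0, "UK-5099": 0.20}
    )  # treatment -> fractional post-injection ratio step
    replicates: int = 3
    donor_only_wells: int = 3
    n_readings: int = 15
    injection_index: int = 5  # first post-injection reading
    donor_level: float = 1.0e6  # counts
    base_ratio: float = 0.5  # true acceptor/donor ratio pre-injection
    bleed_through: float = 0.02  # fraction of donor counts in the acceptor channel
    noise_sd: float = 0.0  # additive channel noise, counts
    seed: int = 0


@dataclass
class PlateRead:
    """Long-format two-channel plate read plus well annotations."""

    data: pd.DataFrame  # columns: well, reading, channel (em485/em620), value
    annotations: pd.DataFrame  # columns: well, construct, treatment
    injection_index: int


def simulate_bret_plate(spec: BretSimSpec) -> PlateRead:
    rng = _rng(spec.seed, "bret_plate")
    rows, annot = [], []
    readings = np.arange(spec.n_readings)

    def emit(well: str, construct: str, treatment: str, step: float) -> None:
        annot.append({"well": well, "construct": construct, "treatment": treatment})
        for t in readings:
            donor = spec.donor_level + (rng.normal(0, spec.noise_sd) if spec.noise_sd else 0.0)
            if construct == "dimer":
                ratio = spec.base_ratio * (1.0 + (step if t >= spec.injection_index else 0.0))
            else:
                ratio = 0.0
            acceptor = donor * (ratio + spec.bleed_through)
            if spec.noise_sd:
                acceptor += rng.normal(0, spec.noise_sd)
            rows.append({"well": well, "reading": int(t), "channel": "em485", "value": donor})
            rows.append({"well": well, "reading": int(t), "channel": "em620", "value": acceptor})

    w = 0
    for treatment, step in spec.treatments.items():
        for _ in range(spec.replicates):
            emit(f"W{w:03d}", "dimer", treatment, step)
            w += 1
    for _ in range(spec.donor_only_wells):
        emit(f"W{w:03d}", "donor_only", "donor_only", 0.0)
        w += 1

    return PlateRead(pd.DataFrame(rows), pd.DataFrame(annot), spec.injection_index)


# ---------------------------------------------------------------------------
# Oxygen-trace simulation


@dataclass(frozen=True)
class O2Segment:
    label: str
    duration_s: float
    slope: float | None = None  # nmol/mL/min, <= 0 (consumption)
    residual_of_previous: float | None = None  # scale previous slope instead


@dataclass(frozen=True)
class O2SimSpec:
    segments: Sequence[O2Segment] = (
        O2Segment("baseline", 120, -2.0),
        O2Segment("state3", 120, -80.0),
        O2Segment("state4", 120, -10.0),
    )
    dt_s: float = 2.0
    o2_start: float = 200.0  # nmol/mL
    chamber_volume_ml: float = 2.0
    protein_ug: float = 50.0
    noise_sd: float = 0.0  # additive, nmol/mL
    seed: int = 0


@dataclass
class OxygenTrace:
    time_s: np.ndarray
    o2_nmol_per_ml: np.ndarray
    chamber_volume_ml: float
    protein_ug: float
    events: list[tuple[float, str]]  # (time_s, label) at each segment start

    def __post_init__(self) -> None:
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")


def simulate_o2_trace(spec: O2SimSpec) -> OxygenTrace:
    """Piecewise-linear O2 concentration with event markers and additive noise."""
    rng = _rng(spec.seed, "o2_trace")
    times, values, events = [], [], []
    t, o2 = 0.0, spec.o2_start
    prev_slope: float | None = None
    for seg in spec.segments:
        slope = seg.slope
        if slope is None:
            if seg.residual_of_previous is None or prev_slope is None:
                raise ValueError(f"segment {seg.label!r} has no slope")
            slope = prev_slope * seg.residual_of_previous
        if slope > 0:
            raise ValueError(f"segment {seg.label!r}: oxygen is consumed, slope must be <= 0")
        events.append((t, seg.label))
        n = int(round(seg.duration_s / spec.dt_s))
        for _ in range(n):
            times.append(t)
            values.append(o2)
            t += spec.dt_s
            o2 += slope * spec.dt_s / 60.0  # slope per minute
        prev_slope = slope
    values = np.asarray(values)
    if spec.noise_sd > 0:
        values = values + rng.normal(0, spec.noise_sd, size=values.shape)
    return OxygenTrace(
        np.asarray(times), values, spec.chamber_volume_ml, spec.protein_ug, events
    )


# ---------------------------------------------------------------------------
# CSV writers (long-format interchange)


def write_plate_csv(plate: PlateRead, path: str) -> None:
    merged = plate.data.merge(plate.annotations, on="well")
    merged["injection_index"] = plate.injection_index
    merged.to_csv(path, index=False)


def read_plate_csv(path: str) -> PlateRead:
    df = pd.read_csv(path)
    annotations = df[["well", "construct", "treatment"]].drop_duplicates()
    injection_index = int(df["injection_index"].iloc[0])
    data = df[["well", "reading", "channel", "value"]]
    return PlateRead(data, annotations, injection_index)


def write_trace_csv(trace: OxygenTrace, path: str) -> None:
    events = dict((round(t, 9), label) for t, label in trace.events)
    df = pd.DataFrame(
        {
            "time_s": trace.time_s,
            "o2_nmol_per_ml": trace.o2_nmol_per_ml,
            "event": [events.get(round(t, 9), "") for t in trace.time_s],
            "chamber_volume_ml": trace.chamber_volume_ml,
            "protein_ug": trace.protein_ug,
        }
    )
    df.to_csv(path, index=False)
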