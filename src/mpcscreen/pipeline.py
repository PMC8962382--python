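"""End-to-end orchestration: deck -> hypothesis -> screen -> assays -> report.

A run is fully described by a :class:`PipelineConfig` (YAML on disk,
schema-validated; unknown keys rejected). One global seed drives every
stochastic stage, so re-running an identical config reproduces identical
tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from . import __version__
from .assay_analysis import fit_dose_response, potency_report
from .chem_core import (
    deprotonate_acids,
    embed_conformers,
    lipinski_profile,
    load_registry,
    parse_structure,
)
from .pharmacophore import build_hypothesis, save_hypothesis
from .screening import ScoringWeights, hits_to_frame, screen_deck
from .synthetic_data import DeckSpec, generate_deck, simulate_dose_response

log = logging.getLogger("mpcscreen")


class ConfigError(ValueError):
    """Configuration failed schema validation."""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DeckConfig(_Strict):
    n_decoys: int = 0
    conformers_per_molecule: int = 5
    include_actives: bool = True
    include_ester_negatives: bool = True
    include_reference: bool = False
    warhead_fraction: float = 0.3


class HypothesisConfig(_Strict):
    reference_id: str = "UK-5099"
    tolerance: float = 2.0


class ScreeningConfig(_Strict):
    w_site: float = 1.0
    w_vec: float = 1.0
    w_vol: float = 1.0
    w_ivol: float = 0.0
    c_align: float = 1.2
    grid: float = 0.3
    top_k: int = 7


class AssayConfig(_Strict):
    doses_nM: list[float] = [1.0, 3.7, 13.9, 51.8, 193.1, 719.7, 2682.7, 10000.0]
    replicates: int = 3
    cv: float = 0.05
    hill: float = 1.0
    top: float = 100.0
    bottom: float = 0.0


class PipelineConfig(_Strict):
    seed: int = 17
    out_dir: str = "mpcscreen_out"
    deck: DeckConfig = DeckConfig()
    hypothesis: HypothesisConfig = HypothesisConfig()
    screening: ScreeningConfig = ScreeningConfig()
    assays: AssayConfig = AssayConfig()


def load_config(path: str) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def validate_config(raw: dict[str, Any]) -> PipelineConfig:
    try:
        return PipelineConfig.model_validate(raw)
    except ValidationError as exc:
        failing = "; ".join(
            ".".join(str(p) for p in err["loc"]) or "<root>" for err in exc.errors()
        )
        raise ConfigError(f"invalid configuration key(s): {failing}") from exc


@dataclasses.dataclass
class RunReport:
    config: dict[str, Any]
    deck_summary: dict[str, int]
    hits: pd.DataFrame
    descriptors: pd.DataFrame
    fits: pd.DataFrame
    potency: pd.DataFrame
    nanomolar_count: int
    version: str
    seed: int


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # propagate with the stage name
                raise StageError(name, exc) from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> RunReport:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    deck_spec = DeckSpec(
        n_decoys=config.deck.n_decoys,
        seed=config.seed,
        conformers_per_molecule=config.deck.conformers_per_molecule,
        include_actives=config.deck.include_actives,
        include_ester_negatives=config.deck.include_ester_negatives,
        include_reference=config.deck.include_reference,
        warhead_fraction=config.deck.warhead_fraction,
    )
    deck, manifest = _stage("deck")(generate_deck)(deck_spec)
    manifest.to_csv(out_dir / "deck_manifest.csv", index=False)
    log.info("deck: %d records", len(deck))

    @_stage("hypothesis")
    def make_hypothesis():
        # prefer the reference ligand's own library conformer so the deck
        # contains the hypothesis geometry, as in a screen whose reference
        # is part of the prepared collection
        for entry in deck:
            if entry.provenance == "reference" and entry.conformers:
                return build_hypothesis(
                    entry.conformers[0], tolerance=config.hypothesis.tolerance
                )
        reference = parse_structure(config.hypothesis.reference_id)
        anion = deprotonate_acids(reference)
        conf = embed_conformers(anion, 1, seed=config.seed)[0]
        return build_hypothesis(conf, tolerance=config.hypothesis.tolerance)

    hypothesis = make_hypothesis()
    save_hypothesis(
        hypothesis, str(out_dir / "hypothesis.json"), str(out_dir / "hypothesis_ref.sdf")
    )

    weights = ScoringWeights(
        w_site=config.screening.w_site,
        w_vec=config.screening.w_vec,
        w_vol=config.screening.w_vol,
        w_ivol=config.screening.w_ivol,
        c_align=config.screening.c_align,
    )
    hits = _stage("screen")(screen_deck)(
        deck, hypothesis, weights, top_k=config.screening.top_k, grid=config.screening.grid
    )
    hit_frame = hits_to_frame(hits)
    hit_frame.to_csv(out_dir / "hits.csv", index=False)
    log.info("screen: %d hits of %d compounds", len(hits), len(deck))

    @_stage("descriptors")
    def descriptors():
        registry = load_registry()
        rows = []
        for hit in hits:
            if hit.compound_id not in registry:
                continue
            profile = lipinski_profile(parse_structure(hit.compound_id))
            rows.append(
                {
                    "id": hit.compound_id,
                    "mw": round(profile.molecular_weight, 2),
                    "logp": round(profile.logp, 3),
                    "hbd": profile.hbd,
                    "hba": profile.hba,
                    "ro5_violations": profile.rule_of_five_violations,
                }
            )
        return pd.DataFrame(rows)

    descriptor_frame = descriptors()
    descriptor_frame.to_csv(out_dir / "descriptors.csv", index=False)

    @_stage("fit")
    def fits():
        registry = load_registry()
        rows = []
        for i, rec in enumerate(sorted(registry.values(), key=lambda r: r.id)):
            if rec.role != "active" or rec.printed_ic50_nM is None:
                continue
            points = simulate_dose_response(
                ic50=rec.printed_ic50_nM,
                hill=config.assays.hill,
                top=config.assays.top,
                bottom=config.assays.bottom,
                doses=config.assays.doses_nM,
                reps=config.assays.replicates,
                cv=config.assays.cv,
                seed=(config.seed * 131071 + i) % (2**31),
            )
            fit = fit_dose_response(points)
            rows.append(
                {
                    "id": rec.id,
                    "true_ic50_nM": rec.printed_ic50_nM,
                    "ic50_nM": round(fit.ic50_nM, 3),
                    "hill": round(fit.hill, 4),
                    "top": round(fit.top, 3),
                    "bottom": round(fit.bottom, 3),
                    "converged": fit.converged,
                }
            )
        return pd.DataFrame(rows)

    fit_frame = fits()
    fit_frame.to_csv(out_dir / "fits.csv", index=False)

    @_stage("potency")
    def potency():
        ic50s = dict(zip(fit_frame["id"], fit_frame["ic50_nM"]))
        registry = load_registry()
        ref = registry["UK-5099"]
        if ref.printed_ic50_nM is not None:
            ic50s.setdefault(ref.id, ref.printed_ic50_nM)
        return potency_report(ic50s, "UK-5099")

    report = potency()
    report.table.to_csv(out_dir / "potency.csv", index=False)

    deck_summary = manifest["provenance"].value_counts().to_dict()
    run = RunReport(
        config=config.model_dump(),
        deck_summary={k: int(v) for k, v in deck_summary.items()},
        hits=hit_frame,
        descriptors=descriptor_frame,
        fits=fit_frame,
        potency=report.table,
        nanomolar_count=report.nanomolar_count,
        version=__version__,
        seed=config.seed,
    )
    with open(out_dir / "report.json", "w") as fh:
        json.dump(
            {
                "config": run.config,
                "deck_summary": run.deck_summary,
                "n_hits": int(len(hit_frame)),
                "nanomolar_count": run.nanomolar_count,
                "version": run.version,
                "seed": run.seed,
            },
            fh,
            indent=2,
        )
    return run
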