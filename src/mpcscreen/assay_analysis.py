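"""Assay analytics: BRET normalization, oxygen consumption rates, IC50 fits.

BRET: per reading, the acceptor-channel luminescence (620 nm band) is
divided by the donor channel (485 nm); the mean ratio of donor-only wells
is subtracted at the same reading, and the corrected trace is normalized
to the readings immediately prior to compound injection, so the baseline
mean is 1 by construction.

OCR: the least-squares slope of chamber O2 concentration over a segment
window, times chamber volume, rescaled to 50 µg of mitochondrial protein
(consumption reported positive). RCR = OCR(state 3) / OCR(state 4).

IC50: four-parameter log-logistic inhibition curve fitted by bounded
least squares with multi-start initialization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .synthetic_data import OxygenTrace, PlateRead

#: acceptor-channel labels accepted interchangeably (the emission band is
#: acquired around 620-640 nm depending on filter naming)
ACCEPTOR_CHANNELS = ("em620", "em640")
DONOR_CHANNEL = "em485"

#: reference protein load the OCR is normalized to (µg)
OCR_REFERENCE_PROTEIN_UG = 50.0

#: "immediately prior to injection" = mean of this many final baseline readings
BASELINE_READINGS = 3

NANOMOLAR_CUTOFF_NM = 1000.0


@dataclass
class BretTrace:
    treatment: str
    normalized: np.ndarray  # per reading index
    injection_index: int
    post_injection_mean: float
    baseline_readings: int = BASELINE_READINGS


@dataclass
class OcrResult:
    ocr: dict[str, float]  # label -> nmol O2/min per 50 µg protein
    rcr: float | None
    chamber_volume_ml: float
    protein_ug: float


@dataclass
class DoseResponseFit:
    ic50_nM: float
    hill: float
    top: float
    bottom: float
    residual_norm: float
    converged: bool
    no_inhibition: bool = False


# ---------------------------------------------------------------------------
# BRET


def _well_ratios(plate: PlateRead) -> pd.DataFrame:
    """Per-well, per-reading acceptor/donor ratio."""
    data = plate.data
    acceptor_label = next(
        (c for c in ACCEPTOR_CHANNELS if (data["channel"] == c).any()), None
    )
    if acceptor_label is None:
        raise ValueError(f"no acceptor channel found (expected one of {ACCEPTOR_CHANNELS})")
    wide = data.pivot_table(
        index=["well", "reading"], columns="channel", values="value"
    ).reset_index()
    if (wide[DONOR_CHANNEL] <= 0).any():
        raise ValueError("donor channel contains zero or negative counts")
    wide["ratio"] = wide[acceptor_label] / wide[DONOR_CHANNEL]
    return wide[["well", "reading", "ratio"]]


def compute_bret(plate: PlateRead, baseline_readings: int = BASELINE_READINGS) -> list[BretTrace]:
    """Donor-only-corrected, baseline-normalized BRET trace per treatment.

    Donor-only wells define the per-reading background ratio (bleed-through);
    they are excluded from the treatment traces.
    """
    annotations = plate.annotations
    donor_only_wells = set(annotations.loc[annotations["construct"] == "donor_only", "well"])
    if not donor_only_wells:
        raise ValueError("plate has no donor_only wells")
    ratios = _well_ratios(plate)
    background = (
        ratios[ratios["well"].isin(donor_only_wells)]
        .groupby("reading")["ratio"]
        .mean()
    )
    corrected = ratios[~ratios["well"].isin(donor_only_wells)].copy()
    corrected["ratio"] = corrected["ratio"] - corrected["reading"].map(background)
    corrected = corrected.merge(annotations[["well", "treatment"]], on="well")

    inj = plate.injection_index
    if not 0 < inj <= corrected["reading"].max():
        raise ValueError("injection index outside the reading grid")
    lo = max(0, inj - baseline_readings)

    traces = []
    for treatment, grp in corrected.groupby("treatment", sort=True):
        mean_trace = grp.groupby("reading")["ratio"].mean().sort_index().to_numpy()
        baseline = mean_trace[lo:inj].mean()
        if baseline <= 0:
            raise ValueError(f"non-positive baseline for treatment {treatment!r}")
        normalized = mean_trace / baseline
        traces.append(
            BretTrace(
                treatment=treatment,
                normalized=normalized,
                injection_index=inj,
                post_injection_mean=float(normalized[inj:].mean()),
                baseline_readings=baseline_readings,
            )
        )
    return traces


# ---------------------------------------------------------------------------
# OCR


def compute_ocr(
    trace: OxygenTrace,
    windows: Mapping[str, tuple[float, float]],
    state3: str = "state3",
    state4: str = "state4",
) -> OcrResult:
    """Per-window oxygen consumption rates and, when available, the RCR.

    ``windows`` maps a segment label to a (t0, t1) time window in seconds;
    each window must contain at least 3 readings. OCR is reported in
    nmol O2/min per 50 µg protein.
    """
    ocr: dict[str, float] = {}
    for label, (t0, t1) in windows.items():
        mask = (trace.time_s >= t0) & (trace.time_s <= t1)
        if int(mask.sum()) < 3:
            raise ValueError(f"window {label!r} contains fewer than 3 readings")
        minutes = trace.time_s[mask] / 60.0
        slope = np.polyfit(minutes, trace.o2_nmol_per_ml[mask], 1)[0]
        rate = -slope * trace.chamber_volume_ml  # nmol/min in the chamber
        ocr[label] = float(rate * OCR_REFERENCE_PROTEIN_UG / trace.protein_ug)
    rcr = None
    if state3 in ocr and state4 in ocr and ocr[state4] != 0:
        rcr = ocr[state3] / ocr[state4]
    return OcrResult(ocr, rcr, trace.chamber_volume_ml, trace.protein_ug)


# ---------------------------------------------------------------------------
# Dose-response fitting


def _model(log10_ic50: float, hill: float, top: float, bottom: float, doses: np.ndarray):
    return bottom + (top - bottom) / (1.0 + (doses / 10.0 ** log10_ic50) ** hill)


def _fit_bounds(doses: np.ndarray, resp: np.ndarray):
    """Box bounds: IC50 within a decade of the dose grid; plateaus near the
    observed range, with the bottom floored at zero for non-negative data
    (response cannot be driven below full inhibition)."""
    log_lo, log_hi = np.log10(doses.min() / 10.0), np.log10(doses.max() * 10.0)
    r_lo, r_hi = float(resp.min()), float(resp.max())
    span = max(r_hi - r_lo, 1e-9)
    bottom_lo = min(0.0, r_lo)
    return (
        [log_lo, 0.1, r_hi - 0.5 * span, bottom_lo],
        [log_hi, 10.0, r_hi + span, r_lo + 0.5 * span],
    )


def fit_dose_response(
    points: pd.DataFrame,
    flat_epsilon: float = 5.0,
    n_starts: int = 5,
) -> DoseResponseFit:
    """Fit the four-parameter log-logistic inhibition curve.

    ``points`` needs columns ``dose_nM`` and ``response``. Multi-start
    bounded least squares: IC50 starts at quantiles of the log dose grid,
    IC50 bounded to [min dose/10, max dose*10]. A response whose dynamic
    range across doses is below ``flat_epsilon`` (response units) is
    reported as "no inhibition detected" (ic50 undefined, NaN).
    """
    doses = points["dose_nM"].to_numpy(dtype=float)
    resp = points["response"].to_numpy(dtype=float)
    if len(np.unique(doses)) < 4:
        raise ValueError("at least 4 distinct doses are required")

    per_dose = points.groupby("dose_nM")["response"].mean()
    if per_dose.max() - per_dose.min() < flat_epsilon:
        return DoseResponseFit(
            ic50_nM=math.nan, hill=math.nan, top=float(per_dose.mean()),
            bottom=float(per_dose.mean()), residual_norm=math.nan,
            converged=False, no_inhibition=True,
        )

    bounds = _fit_bounds(doses, resp)
    r_lo, r_hi = float(resp.min()), float(resp.max())

    def residuals(p):
        return _model(*p, doses) - resp

    best = None
    quantiles = np.linspace(0.1, 0.9, n_starts)
    log_doses = np.log10(np.unique(doses))
    for q in quantiles:
        x0 = [float(np.quantile(log_doses, q)), 1.0, r_hi, r_lo]
        x0 = np.clip(x0, bounds[0], bounds[1])
        try:
            sol = least_squares(residuals, x0, bounds=bounds, method="trf")
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return DoseResponseFit(math.nan, math.nan, math.nan, math.nan, math.nan, False)

    log_ic50, hill, top, bottom = best.x
    return DoseResponseFit(
        ic50_nM=float(10.0 ** log_ic50),
        hill=float(hill),
        top=float(top),
        bottom=float(bottom),
        residual_norm=float(np.linalg.norm(best.fun)),
        converged=bool(best.success),
    )


def fit_dose_response_warm(
    points: pd.DataFrame, init: DoseResponseFit
) -> DoseResponseFit:
    """Single-start refit initialized from a previous fit (bootstrap helper)."""
    doses = points["dose_nM"].to_numpy(dtype=float)
    resp = points["response"].to_numpy(dtype=float)
    bounds = _fit_bounds(doses, resp)
    x0 = np.clip(
        [np.log10(init.ic50_nM), init.hill, init.top, init.bottom],
        bounds[0], bounds[1],
    )
    sol = least_squares(lambda p: _model(*p, doses) - resp, x0, bounds=bounds, method="trf")
    log_ic50, hill, top, bottom = sol.x
    return DoseResponseFit(
        float(10.0 ** log_ic50), float(hill), float(top), float(bottom),
        float(np.linalg.norm(sol.fun)), bool(sol.success),
    )


# ---------------------------------------------------------------------------
# Potency reporting


@dataclass
class PotencyReport:
    table: pd.DataFrame
    reference_id: str
    nanomolar_count: int  # compounds with IC50 < 1 µM


def potency_report(
    ic50s: Mapping[str, float],
    reference_id: str,
    nanomolar_cutoff: float = NANOMOLAR_CUTOFF_NM,
) -> PotencyReport:
    """Fold-potency table relative to a reference compound.

    ``fold`` is IC50(compound)/IC50(reference) (> 1 means less potent than
    the reference); ``fold_nearest`` rounds to the nearest integer and
    ``fold_label`` floors ("≥18-fold" for a ratio of 18.7). The nanomolar
    filter counts compounds with IC50 below 1000 nM.
    """
    if reference_id not in ic50s:
        raise KeyError(f"reference id {reference_id!r} has no IC50")
    ref = float(ic50s[reference_id])
    rows = []
    for cid, value in ic50s.items():
        fold = float(value) / ref
        if fold >= 1:
            label = f">={math.floor(fold)}-fold" if fold >= 2 else "comparable"
        else:
            label = f"{round(1.0 / fold)}-fold more potent"
        rows.append(
            {
                "id": cid,
                "ic50_nM": float(value),
                "fold_vs_reference": fold,
                "fold_nearest": int(round(fold)),
                "fold_label": label,
                "nanomolar": bool(value < nanomolar_cutoff),
            }
        )
    table = pd.DataFrame(rows).sort_values("ic50_nM").reset_index(drop=True)
    return PotencyReport(table, reference_id, int(table["nanomolar"].sum()))
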