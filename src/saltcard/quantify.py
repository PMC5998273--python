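"""Zone signals to ppm iodine: calibration, gating, controls, verdicts.

Each reaction zone carries its own linear calibration ``signal =
intercept + slope * ppm`` valid over a stated signal range; signals outside
that range (on the background or saturation plateau of the zone's threshold
titration) carry no quantitative information and are ignored. A card is
rejected outright when the control zones misbehave, when too few fiducials
are found, when no neutral patch survives, or when no zone lands in its
linear range. The concentration reported for an accepted card is the median
over its in-range replicate zones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import stats as _stats
from .imaging import (
    DEFAULT_SCALE,
    UnreadableCardError,
    ZoneSignal,
    correct_white_balance,
    detect_fiducials,
    fit_geometric_correction,
    measure_rois,
    rectify,
)
from .layout import CardLayout

__all__ = [
    "CalibrationCurve",
    "CalibrationError",
    "ZoneReading",
    "CardResult",
    "ControlLimits",
    "fit_zone_calibration",
    "fit_calibration",
    "calibrate_from_images",
    "invert_calibration",
    "validate_controls",
    "aggregate_concentration",
    "analyze_card",
    "dilution_factor",
    "default_control_spec",
    "save_calibration",
    "load_calibration",
    "results_to_dataframe",
]

STATUS_IN_RANGE = "in_range"
STATUS_OUT_OF_RANGE = "out_of_range"
STATUS_UNREADABLE = "unreadable"

REJECTION_REASONS = (
    "controls_failed",
    "too_few_fiducials",
    "no_in_range_zones",
    "neutral_patch_saturated",
)

#: consecutive standards differing by no more than this are a plateau run
_PLATEAU_STEP = 1.0


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear map between integrated greyscale signal and ppm iodine for one
    zone, with the signal range over which the map is trusted."""

    zone_id: int
    slope: float  # signal units per ppm
    intercept: float  # signal units
    signal_range: tuple[float, float]  # [lo, hi], signal units
    source: str = ""

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise CalibrationError(f"zone {self.zone_id}: slope must be > 0")
        lo, hi = self.signal_range
        if not (0.0 <= lo < hi <= 255.0):
            raise CalibrationError(
                f"zone {self.zone_id}: signal range must satisfy 0 <= lo < hi <= 255"
            )

    def ppm(self, signal: float) -> float:
        return (signal - self.intercept) / self.slope


@dataclass(frozen=True)
class ZoneReading:
    signal: ZoneSignal
    status: str  # in_range | out_of_range | unreadable
    concentration: float | None = None  # ppm; present iff in_range
    role: str = "measurement"

    def __post_init__(self) -> None:
        if (self.status == STATUS_IN_RANGE) != (self.concentration is not None):
            raise ValueError("concentration present exactly when status is in_range")


@dataclass(frozen=True)
class ControlLimits:
    """Expected signal interval for a control zone: a negative control must
    stay at or below ``max_signal``; a positive control must reach at least
    ``min_signal``."""

    min_signal: float | None = None
    max_signal: float | None = None


@dataclass
class CardResult:
    card_id: str
    verdict: str  # accepted | rejected
    rejection_reason: str | None
    readings: list[ZoneReading]
    concentration_estimate: float | None = None  # ppm, full precision
    dispersion: float | None = None  # MAD scaled to SD, ppm
    n_used: int = 0
    survey_class: str | None = None
    qc_class: str | None = None
    process_action: str | None = None

    @property
    def accepted(self) -> bool:
        return self.verdict == "accepted"


# ---------------------------------------------------------------------------
# calibration fitting

def _trim_plateaus(ppm: np.ndarray, sig: np.ndarray) -> np.ndarray:
    """Boolean mask of standards strictly between the background and
    saturation plateaus (a plateau is a run of >= 2 extreme points whose
    consecutive signals change by <= 1 unit)."""
    n = len(sig)
    keep = np.ones(n, dtype=bool)
    i = 0
    while i + 1 < n and abs(sig[i + 1] - sig[i]) <= _PLATEAU_STEP:
        i += 1
    if i >= 1:
        keep[: i + 1] = False
    j = n - 1
    while j - 1 >= 0 and abs(sig[j] - sig[j - 1]) <= _PLATEAU_STEP:
        j -= 1
    if j <= n - 2:
        keep[j:] = False
    return keep


def fit_zone_calibration(
    zone_id: int,
    standards: Sequence[tuple[float, "ZoneSignal | float"]],
    source: str = "fit",
) -> CalibrationCurve:
    """Ordinary least-squares line through the usable standards of one zone.

    Standards sitting on the background or saturation plateau are excluded;
    at least three distinct usable concentrations are required. The linear
    signal range is the [min, max] of the fitted values at the usable
    standards.
    """
    pts = sorted(
        (float(c), float(getattr(s, "integrated_signal", s))) for c, s in standards
    )
    ppm = np.array([p for p, _ in pts])
    sig = np.array([s for _, s in pts])
    keep = _trim_plateaus(ppm, sig) if len(pts) else np.zeros(0, bool)
    ppm, sig = ppm[keep], sig[keep]
    if len(np.unique(ppm)) < 3:
        raise CalibrationError(
            f"zone {zone_id}: fewer than 3 usable standards outside the plateaus"
        )
    slope, intercept = np.polyfit(ppm, sig, 1)
    if slope <= 0:
        raise CalibrationError(f"zone {zone_id}: non-positive fitted slope")
    fitted = intercept + slope * ppm
    lo, hi = float(fitted.min()), float(fitted.max())
    return CalibrationCurve(
        zone_id=zone_id,
        slope=float(slope),
        intercept=float(intercept),
        signal_range=(max(lo, 0.0), min(hi, 255.0)),
        source=source,
    )


def fit_calibration(
    standards: Mapping[int, Sequence[tuple[float, "ZoneSignal | float"]]],
    source: str = "fit",
) -> dict[int, CalibrationCurve]:
    """Fit every zone present in ``standards``; see :func:`fit_zone_calibration`."""
    return {z: fit_zone_calibration(z, pts, source) for z, pts in standards.items()}


def calibrate_from_images(
    images: Sequence[np.ndarray],
    concentrations: Sequence[float],
    layout: CardLayout,
    scale: float = DEFAULT_SCALE,
    source: str = "standard cards",
) -> dict[int, CalibrationCurve]:
    """Fit per-zone curves from photographs of standard cards.

    Each image is carried through the measurement pipeline and its readable
    zone signals become calibration standards at the stated concentration.
    """
    if len(images) != len(concentrations):
        raise ValueError("one known concentration per standard image required")
    standards: dict[int, list[tuple[float, float]]] = {
        z.id: [] for z in layout.measurement_zones
    }
    for img, conc in zip(images, concentrations):
        detections = detect_fiducials(img, layout)
        correction = fit_geometric_correction(detections, layout)
        rect = rectify(img, correction, layout, scale=scale)
        rect, _ = correct_white_balance(rect, layout)
        for s in measure_rois(rect, layout):
            if s.zone_id in standards and not s.unreadable:
                standards[s.zone_id].append((float(conc), s.integrated_signal))
    return fit_calibration(standards, source=source)


def invert_calibration(signal: ZoneSignal, curve: CalibrationCurve, role: str = "measurement") -> ZoneReading:
    """Map one zone signal through its calibration curve.

    In-range signals yield a concentration; out-of-range signals are flagged
    and carry none; unreadable signals pass through untouched.
    """
    if signal.unreadable:
        return ZoneReading(signal, STATUS_UNREADABLE, role=role)
    lo, hi = curve.signal_range
    if lo <= signal.integrated_signal <= hi:
        return ZoneReading(
            signal, STATUS_IN_RANGE, concentration=curve.ppm(signal.integrated_signal), role=role
        )
    return ZoneReading(signal, STATUS_OUT_OF_RANGE, role=role)


# ---------------------------------------------------------------------------
# controls and aggregation

def default_control_spec(layout: CardLayout) -> dict[int, ControlLimits]:
    """Signal intervals for the layout's control zones: a negative control
    must stay near background, a positive control near saturation."""
    spec: dict[int, ControlLimits] = {}
    for z in layout.control_zones:
        if z.role == "negative_control":
            spec[z.id] = ControlLimits(max_signal=80.0)
        else:
            spec[z.id] = ControlLimits(min_signal=140.0)
    return spec


def validate_controls(
    signals: Sequence[ZoneSignal],
    layout: CardLayout,
    control_spec: Mapping[int, ControlLimits],
) -> tuple[bool, list[str]]:
    """Check every control zone against its expected signal interval.

    Returns (passed, per-control detail lines). An unreadable control zone
    is a failure: the card cannot vouch for its own chemistry.
    """
    if not layout.control_zones:
        raise ValueError("layout defines no control zones")
    by_id = {s.zone_id: s for s in signals}
    passed = True
    details: list[str] = []
    for z in layout.control_zones:
        limits = control_spec.get(z.id, ControlLimits())
        s = by_id.get(z.id)
        if s is None or s.unreadable:
            passed = False
            details.append(f"zone {z.id} ({z.role}): unreadable")
            continue
        ok = True
        if limits.max_signal is not None and s.integrated_signal > limits.max_signal:
            ok = False
            details.append(
                f"zone {z.id} ({z.role}): signal {s.integrated_signal:.1f} "
                f"above maximum {limits.max_signal:.1f}"
            )
        if limits.min_signal is not None and s.integrated_signal < limits.min_signal:
            ok = False
            details.append(
                f"zone {z.id} ({z.role}): signal {s.integrated_signal:.1f} "
                f"below minimum {limits.min_signal:.1f}"
            )
        if ok:
            details.append(f"zone {z.id} ({z.role}): ok")
        passed = passed and ok
    return passed, details


def aggregate_concentration(
    readings: Sequence[ZoneReading],
) -> tuple[float, float, int]:
    """Combine in-range measurement readings into one estimate.

    Median across replicates (robust to one mis-developed zone), with the
    median absolute deviation scaled to an SD-equivalent (x1.4826) as the
    dispersion. Ties take the mean of the middle pair (numpy convention).
    """
    conc = np.array(
        [
            r.concentration
            for r in readings
            if r.role == "measurement" and r.status == STATUS_IN_RANGE
        ]
    )
    if conc.size == 0:
        raise ValueError("no in-range measurement readings")
    est = float(np.median(conc))
    mad = float(np.median(np.abs(conc - est)))
    return est, 1.4826 * mad, int(conc.size)


# ---------------------------------------------------------------------------
# full pipeline

def _classify(result: CardResult) -> None:
    ppm = result.concentration_estimate
    result.survey_class = _stats.classify_survey(ppm)
    result.qc_class = _stats.classify_qc(ppm)
    result.process_action = _stats.process_action(ppm)


def analyze_card(
    image: np.ndarray,
    layout: CardLayout,
    curves: Mapping[int, CalibrationCurve],
    control_spec: Mapping[int, ControlLimits] | None = None,
    scale: float = DEFAULT_SCALE,
    card_id: str = "card",
) -> CardResult:
    """Run the full reading pipeline on one photograph.

    detect fiducials -> fit projective correction -> rectify -> white
    balance -> measure ROIs -> control gate -> calibration inversion ->
    replicate aggregation -> survey/QC classification. Any gate failure
    yields a rejected verdict with its reason; readings measured before the
    failure are preserved for diagnostics.
    """
    control_spec = control_spec if control_spec is not None else default_control_spec(layout)

    def rejected(reason: str, readings: list[ZoneReading] | None = None) -> CardResult:
        return CardResult(card_id, "rejected", reason, readings or [])

    detections = detect_fiducials(image, layout)
    try:
        correction = fit_geometric_correction(detections, layout)
        rect = rectify(image, correction, layout, scale=scale)
        rect, _gains = correct_white_balance(rect, layout)
    except UnreadableCardError as exc:
        return rejected(exc.reason)

    signals = measure_rois(rect, layout)
    roles = {z.id: z.role for z in layout.zones}
    readings: list[ZoneReading] = []
    for s in signals:
        role = roles[s.zone_id]
        if role != "measurement" or s.zone_id not in curves:
            status = STATUS_UNREADABLE if s.unreadable else STATUS_OUT_OF_RANGE
            readings.append(ZoneReading(s, status, role=role))
        else:
            readings.append(invert_calibration(s, curves[s.zone_id], role=role))

    ok, _details = validate_controls(signals, layout, control_spec)
    if not ok:
        return rejected("controls_failed", readings)

    try:
        est, disp, n_used = aggregate_concentration(readings)
    except ValueError:
        return rejected("no_in_range_zones", readings)

    result = CardResult(
        card_id,
        "accepted",
        None,
        readings,
        concentration_estimate=est,
        dispersion=disp,
        n_used=n_used,
    )
    _classify(result)
    return result


def dilution_factor(
    salt_mass: float, water_mass: float, solution_density: float
) -> float:
    """Factor mapping solution concentration (mg I / L) to solid-salt ppm I.

    Mass balance of the sample prep: dissolving ``salt_mass`` g of salt in
    ``water_mass`` g of water gives a solution whose iodine concentration is
    the solid's ppm divided by this factor, so

        solid ppm = factor * solution mg/L,
        factor = (salt_mass + water_mass) / (salt_mass * density).
    """
    if salt_mass <= 0 or water_mass <= 0 or solution_density <= 0:
        raise ValueError("all sample-prep quantities must be positive")
    return (salt_mass + water_mass) / (salt_mass * solution_density)


# ---------------------------------------------------------------------------
# persistence and tabulation

def save_calibration(
    curves: Mapping[int, CalibrationCurve], path: str | Path, design: str = "default"
) -> None:
    """Write per-zone curves keyed by card-design version (the stand-in for a
    QR-driven calibration lookup)."""
    doc = {
        "design": design,
        "zones": [
            {
                "id": c.zone_id,
                "slope": float(c.slope),
                "intercept": float(c.intercept),
                "signal_range": [float(c.signal_range[0]), float(c.signal_range[1])],
                "source": c.source,
            }
            for _, c in sorted(curves.items())
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_calibration(path: str | Path) -> dict[int, CalibrationCurve]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        return {
            int(z["id"]): CalibrationCurve(
                zone_id=int(z["id"]),
                slope=float(z["slope"]),
                intercept=float(z["intercept"]),
                signal_range=tuple(map(float, z["signal_range"])),
                source=str(z.get("source", "")),
            )
            for z in doc["zones"]
        }
    except (KeyError, TypeError) as exc:
        raise CalibrationError(f"malformed calibration file {path}: {exc}") from exc


def results_to_dataframe(results: Sequence[CardResult], layout: CardLayout) -> pd.DataFrame:
    """One row per card: verdict, estimate (rounded to 0.1 ppm),
    classifications, and per-zone signal/status/concentration columns."""
    rows = []
    for r in results:
        row: dict = {
            "card_id": r.card_id,
            "verdict": r.verdict,
            "rejection_reason": r.rejection_reason or "",
            "ppm": round(r.concentration_estimate, 1) if r.concentration_estimate is not None else np.nan,
            "dispersion": round(r.dispersion, 1) if r.dispersion is not None else np.nan,
            "n_used": r.n_used,
            "survey_class": r.survey_class or "",
            "qc_class": r.qc_class or "",
            "process_action": r.process_action or "",
        }
        by_id = {rd.signal.zone_id: rd for rd in r.readings}
        for z in sorted(layout.zones, key=lambda z: z.id):
            rd = by_id.get(z.id)
            row[f"z{z.id}_signal"] = round(rd.signal.integrated_signal, 2) if rd else np.nan
            row[f"z{z.id}_status"] = rd.status if rd else ""
            row[f"z{z.id}_ppm"] = (
                round(rd.concentration, 1) if rd and rd.concentration is not None else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)
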