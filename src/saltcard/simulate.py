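"""Synthetic card photographs with known ground truth.

The forward model is the exact inverse of what the reading pipeline
corrects: a card whose zone colours follow a threshold-titration response
to a known iodine concentration is projected onto the image plane
(perspective), given an illumination colour cast (diagonal RGB gain) and
i.i.d. Gaussian pixel noise, in that scene-then-camera order.

Colour development is rendered as reduced lightness: a developed (blue)
indicator circle is darker, so the measured quantity everywhere in this
package is ``signal = 255 - greyscale``, which increases with iodine.
Rendered channel values inside measured regions stay at or below 212 so
that illumination gains up to 1.2 never clip them against the 8-bit
ceiling; clipped colour is unrecoverable by any white balance. A fully
developed spot (saturation signal 175, grey 80) stays clearly lighter than
the near-black fiducial ink (grey 15), as on a printed card, so blob
detection can never confuse the two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .layout import CardLayout

__all__ = [
    "ZoneChemistry",
    "ImagingScenario",
    "TruthRecord",
    "zone_response",
    "default_chemistries",
    "make_perspective",
    "identity_scenario",
    "random_scenario",
    "render_card",
    "generate_dataset",
    "DEFAULT_IMAGING_RANGES",
]

#: greyscale of unexposed paper (slightly off-white card stock)
PAPER_GREY = 235.0
#: greyscale of the scene behind the card
SCENE_GREY = 100.0
#: greyscale of a printed fiducial disk (near-black ink)
FIDUCIAL_GREY = 15.0
#: wax barrier outline grey and width (mm)
WAX_GREY, WAX_WIDTH = 170.0, 0.8
#: colour development bleeds slightly past the indicator circle (mm), so the
#: measured interior is uniform even after resampling blur
ROI_BLEED = 0.5


@dataclass(frozen=True)
class ZoneChemistry:
    """Threshold-titration response of one reaction zone.

    Below ``threshold`` ppm the pre-loaded titrant consumes all analyte and
    the zone stays at ``background_signal``; above it the signal rises by
    ``gain`` per ppm until it saturates.
    """

    threshold: float  # ppm iodine at colour onset
    gain: float  # signal units per ppm above threshold
    background_signal: float = 45.0
    saturation_signal: float = 175.0

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if not self.background_signal < self.saturation_signal:
            raise ValueError("background_signal must be below saturation_signal")


def zone_response(concentration: float, chem: ZoneChemistry) -> float:
    """Ideal greyscale signal of a zone at a given ppm iodine.

    Piecewise linear: background below the titration threshold, linear rise
    of ``gain`` per ppm above it, clipped at saturation. Monotone
    non-decreasing in concentration.
    """
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    if concentration <= chem.threshold:
        return chem.background_signal
    s = chem.background_signal + chem.gain * (concentration - chem.threshold)
    return min(s, chem.saturation_signal)


def default_chemistries(layout: CardLayout) -> dict[int, ZoneChemistry]:
    """One chemistry per zone, derived from the layout's quantitative ranges.

    A measurement zone's threshold sits at the lower end of its range and its
    gain is chosen so the signal spans background-to-saturation across the
    range. Control zones get a nominal unit-range chemistry; their rendered
    development is fixed by their role, not by the sample (see
    :func:`render_card`).
    """
    chems: dict[int, ZoneChemistry] = {}
    for z in layout.zones:
        proto = ZoneChemistry(threshold=0.0, gain=1.0)
        span = z.quant_range[1] - z.quant_range[0]
        gain = (proto.saturation_signal - proto.background_signal) / span
        chems[z.id] = ZoneChemistry(threshold=z.quant_range[0], gain=gain)
    return chems


# ---------------------------------------------------------------------------
# imaging scenarios

@dataclass(frozen=True)
class ImagingScenario:
    """Everything the camera adds: geometry, illumination, noise."""

    true_concentration: float  # ppm iodine in the solid salt
    perspective: tuple  # 3x3 projective transform, reference mm -> image px
    illumination_gains: tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        H = np.asarray(self.perspective, dtype=float).reshape(3, 3)
        if abs(np.linalg.det(H)) < 1e-12:
            raise ValueError("perspective transform must be invertible")
        if any(g <= 0 for g in self.illumination_gains):
            raise ValueError("illumination_gains must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def matrix(self) -> np.ndarray:
        return np.asarray(self.perspective, dtype=float).reshape(3, 3)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one rendered image."""

    image_id: str
    scenario: ImagingScenario
    ideal_signals: dict[int, float]  # zone id -> noiseless signal
    fiducial_centers_px: dict[int, tuple[float, float]]  # id -> (x, y) px


def make_perspective(
    scale: float = 5.0,
    rotation_deg: float = 0.0,
    tilt_x_deg: float = 0.0,
    tilt_y_deg: float = 0.0,
    card_size: tuple[float, float] = (120.0, 90.0),
    margin_mm: float = 6.0,
) -> np.ndarray:
    """Build a mm -> px projective transform from interpretable parameters.

    ``scale`` is the nominal px/mm at the card centre, ``rotation_deg`` an
    in-plane rotation and the tilt angles produce keystoning (the projective
    foreshortening of a plane photographed off-axis). The result is
    translated so the whole card lands in positive pixel coordinates with a
    ``margin_mm`` border.
    """
    w, h = card_size
    cx, cy = w / 2.0, h / 2.0
    th = math.radians(rotation_deg)
    # centre card, rotate+scale, then add the projective row
    T = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1.0]])
    R = np.array(
        [
            [scale * math.cos(th), -scale * math.sin(th), 0],
            [scale * math.sin(th), scale * math.cos(th), 0],
            [0, 0, 1.0],
        ]
    )
    px = math.tan(math.radians(tilt_x_deg)) / (w * 2.0)
    py = math.tan(math.radians(tilt_y_deg)) / (h * 2.0)
    P = np.array([[1, 0, 0], [0, 1, 0], [px, py, 1.0]])
    H = R @ P @ T
    corners = np.array([[0, 0], [w, 0], [w, h], [0, h]], dtype=float)
    uv = _apply_h(H, corners)
    shift = margin_mm * scale - uv.min(axis=0)
    H = np.array([[1, 0, shift[0]], [0, 1, shift[1]], [0, 0, 1.0]]) @ H
    return H


def _apply_h(H: np.ndarray, pts: np.ndarray) -> np.ndarray:
    pts = np.asarray(pts, dtype=float)
    ones = np.ones((pts.shape[0], 1))
    uvw = np.hstack([pts, ones]) @ H.T
    return uvw[:, :2] / uvw[:, 2:3]


def identity_scenario(
    concentration: float, scale: float = 10.0, seed: int = 0, noise_sd: float = 0.0
) -> ImagingScenario:
    """A face-on, cast-free scenario (pure scale, no tilt or rotation)."""
    H = np.diag([scale, scale, 1.0])
    return ImagingScenario(
        true_concentration=concentration,
        perspective=tuple(map(tuple, H)),
        noise_sd=noise_sd,
        seed=seed,
    )


#: study conditions for randomly drawn scenarios: a hand-held-ish photograph
#: in a light box -- bounded tilt/rotation, mild colour cast, mild noise
DEFAULT_IMAGING_RANGES: dict[str, tuple[float, float]] = {
    "scale": (4.5, 6.0),  # px/mm
    "rotation_deg": (-8.0, 8.0),
    "tilt_x_deg": (-12.0, 12.0),
    "tilt_y_deg": (-12.0, 12.0),
    "gain": (0.85, 1.15),  # per-channel illumination
    "noise_sd": (2.0, 5.0),
}


def random_scenario(
    rng: np.random.Generator,
    concentration: float,
    ranges: Mapping[str, tuple[float, float]] | None = None,
    card_size: tuple[float, float] = (120.0, 90.0),
    seed: int | None = None,
) -> ImagingScenario:
    r = dict(DEFAULT_IMAGING_RANGES)
    if ranges:
        r.update(ranges)
    for k, (lo, hi) in r.items():
        if hi < lo:
            raise ValueError(f"empty parameter range for {k!r}")
    u = lambda key: rng.uniform(*r[key])
    H = make_perspective(
        scale=u("scale"),
        rotation_deg=u("rotation_deg"),
        tilt_x_deg=u("tilt_x_deg"),
        tilt_y_deg=u("tilt_y_deg"),
        card_size=card_size,
    )
    gains = tuple(rng.uniform(*r["gain"]) for _ in range(3))
    return ImagingScenario(
        true_concentration=concentration,
        perspective=tuple(map(tuple, H)),
        illumination_gains=gains,
        noise_sd=u("noise_sd"),
        seed=int(seed if seed is not None else rng.integers(0, 2**31 - 1)),
    )


# ---------------------------------------------------------------------------
# rendering

def _roi_color(signal: float) -> tuple[float, float, float]:
    """RGB of a developed indicator circle with mean grey = 255 - signal.

    The blue tint grows with development but is capped so no channel exceeds
    212 (see module docstring); the channel mean is exact by construction.
    """
    g = 255.0 - signal
    d = min(20.0, 0.15 * signal, max(0.0, (212.0 - g) / 2.0))
    return (g - d, g - d, g + 2.0 * d)


def _effective_concentration(role: str, concentration: float) -> float:
    if role == "negative_control":
        return 0.0  # masked: never develops
    if role == "positive_control":
        return math.inf  # pre-loaded analyte: always saturates
    return concentration


def render_card(
    layout: CardLayout,
    chemistries: Mapping[int, ZoneChemistry],
    scenario: ImagingScenario,
    zone_concentration_override: Mapping[int, float] | None = None,
    image_id: str = "card",
) -> tuple[np.ndarray, TruthRecord]:
    """Render one card photograph; return (uint8 RGB image, truth record).

    The card's analytic appearance is evaluated at every pixel centre through
    the inverse perspective, so region interiors carry exact colours.
    ``zone_concentration_override`` substitutes the analyte amount seen by
    individual zones (e.g. to simulate a failed control). Deterministic given
    ``scenario.seed``.
    """
    H = scenario.matrix
    Hinv = np.linalg.inv(H)
    w_mm, h_mm = layout.card_size

    corners = _apply_h(H, np.array([[0, 0], [w_mm, 0], [w_mm, h_mm], [0, h_mm]]))
    pad = 0.04 * (corners.max(axis=0) - corners.min(axis=0)).max() + 4
    if corners.min() < -pad:
        raise ValueError("perspective places the card outside the image")
    W = int(math.ceil(corners[:, 0].max() + pad))
    Hpx = int(math.ceil(corners[:, 1].max() + pad))
    if W * Hpx > 4_000_000:
        raise ValueError("perspective produces an unreasonably large image")

    yy, xx = np.mgrid[0:Hpx, 0:W]
    uvw = Hinv @ np.stack([xx.ravel(), yy.ravel(), np.ones(xx.size)])
    xm = (uvw[0] / uvw[2]).reshape(Hpx, W)
    ym = (uvw[1] / uvw[2]).reshape(Hpx, W)

    img = np.empty((Hpx, W, 3), dtype=float)
    img[:] = SCENE_GREY
    on_card = (xm >= 0) & (xm <= w_mm) & (ym >= 0) & (ym <= h_mm)
    img[on_card] = PAPER_GREY

    def _window(x0, y0, x1, y1):
        """Image slices covering the px footprint of an mm bounding box."""
        c = _apply_h(H, np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]]))
        j0 = max(0, int(math.floor(c[:, 0].min())) - 2)
        j1 = min(W, int(math.ceil(c[:, 0].max())) + 3)
        i0 = max(0, int(math.floor(c[:, 1].min())) - 2)
        i1 = min(Hpx, int(math.ceil(c[:, 1].max())) + 3)
        sl = (slice(i0, i1), slice(j0, j1))
        return xm[sl], ym[sl], sl

    def fill_rect(bounds, color):
        x, y, rw, rh = bounds
        xw, yw, sl = _window(x, y, x + rw, y + rh)
        m = (xw >= x) & (xw <= x + rw) & (yw >= y) & (yw <= y + rh)
        img[sl][m] = color

    def fill_disk(center, radius, color):
        cx, cy = center
        xw, yw, sl = _window(cx - radius, cy - radius, cx + radius, cy + radius)
        m = (xw - cx) ** 2 + (yw - cy) ** 2 <= radius * radius
        img[sl][m] = color

    ideal: dict[int, float] = {}
    conc = scenario.true_concentration
    for z in layout.zones:
        x, y, zw, zh = z.square
        xw, yw, sl = _window(x, y, x + zw, y + zh)
        outer = (xw >= x) & (xw <= x + zw) & (yw >= y) & (yw <= y + zh)
        inner = (
            (xw >= x + WAX_WIDTH)
            & (xw <= x + zw - WAX_WIDTH)
            & (yw >= y + WAX_WIDTH)
            & (yw <= y + zh - WAX_WIDTH)
        )
        img[sl][outer & ~inner] = WAX_GREY
        c_eff = _effective_concentration(z.role, conc)
        if zone_concentration_override and z.id in zone_concentration_override:
            c_eff = zone_concentration_override[z.id]
        s = zone_response(c_eff, chemistries[z.id])
        ideal[z.id] = s
        fill_disk(z.roi_center, z.roi_radius + ROI_BLEED, _roi_color(s))

    for p in layout.color_standards:
        fill_rect(p.bounds, tuple(255.0 * c for c in p.nominal_color))

    # QR region: a fixed mid-grey module pattern (geometry only, not decodable)
    qx, qy, qw, qh = layout.qr_region
    xw, yw, sl = _window(qx, qy, qx + qw, qy + qh)
    in_qr = (xw >= qx) & (xw <= qx + qw) & (yw >= qy) & (yw <= qy + qh)
    ix = np.floor((xw - qx) / 2.0).astype(int)
    iy = np.floor((yw - qy) / 2.0).astype(int)
    modules = ((ix * 37 + iy * 61) % 7) < 3
    img[sl][in_qr & modules] = 115.0
    img[sl][in_qr & ~modules] = 185.0

    fid_centers: dict[int, tuple[float, float]] = {}
    for f in layout.fiducials:
        fill_disk(f.center, f.radius, (FIDUCIAL_GREY,) * 3)
        u, v = _apply_h(H, np.array([f.center]))[0]
        fid_centers[f.id] = (float(u), float(v))

    img *= np.asarray(scenario.illumination_gains, dtype=float)
    if scenario.noise_sd > 0:
        rng = np.random.default_rng(scenario.seed)
        img += rng.normal(0.0, scenario.noise_sd, img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    truth = TruthRecord(
        image_id=image_id,
        scenario=scenario,
        ideal_signals=ideal,
        fiducial_centers_px=fid_centers,
    )
    return img, truth


# ---------------------------------------------------------------------------
# dataset generation

def _make_sampler(spec) -> Callable[[np.random.Generator], float]:
    """Accept ('uniform', lo, hi), ('fixed', v), or a callable rng -> ppm."""
    if callable(spec):
        return spec
    kind = spec[0]
    if kind == "uniform":
        lo, hi = float(spec[1]), float(spec[2])
        if hi < lo:
            raise ValueError("empty concentration range")
        return lambda rng: float(rng.uniform(lo, hi))
    if kind == "fixed":
        v = float(spec[1])
        return lambda rng: v
    raise ValueError(f"unknown concentration sampler spec {spec!r}")


def truth_to_frame(truths: Sequence[TruthRecord], sample_ids: Sequence[str] | None = None) -> pd.DataFrame:
    rows = []
    for i, t in enumerate(truths):
        row = {
            "image_id": t.image_id,
            "sample_id": sample_ids[i] if sample_ids else t.image_id,
            "true_concentration": t.scenario.true_concentration,
            "noise_sd": t.scenario.noise_sd,
            "seed": t.scenario.seed,
        }
        for c, g in zip("rgb", t.scenario.illumination_gains):
            row[f"gain_{c}"] = g
        for k, s in sorted(t.ideal_signals.items()):
            row[f"ideal_signal_{k}"] = s
        rows.append(row)
    return pd.DataFrame(rows)


def generate_dataset(
    layout: CardLayout,
    n: int,
    concentration_sampler=("uniform", 0.0, 50.0),
    imaging_ranges: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
    chemistries: Mapping[int, ZoneChemistry] | None = None,
    out_dir: str | Path | None = None,
    duplicates: int = 1,
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Render ``n`` samples (``duplicates`` cards each) with independent
    random scenarios; fully reproducible from ``seed``.

    If ``out_dir`` is given, images are written there as PNG together with a
    ``truth.csv`` table (one row per image).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if duplicates < 1:
        raise ValueError("duplicates must be >= 1")
    sampler = _make_sampler(concentration_sampler)
    chems = chemistries or default_chemistries(layout)
    rng = np.random.default_rng(seed)

    images: list[np.ndarray] = []
    truths: list[TruthRecord] = []
    sample_ids: list[str] = []
    k = 0
    for i in range(n):
        conc = sampler(rng)
        for _ in range(duplicates):
            scen = random_scenario(rng, conc, ranges=imaging_ranges, card_size=layout.card_size)
            img, truth = render_card(layout, chems, scen, image_id=f"card_{k:04d}")
            images.append(img)
            truths.append(truth)
            sample_ids.append(f"sample_{i:04d}")
            k += 1
    table = truth_to_frame(truths, sample_ids)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for img, t in zip(images, truths):
            Image.fromarray(img).save(out / f"{t.image_id}.png")
        table.to_csv(out / "truth.csv", index=False)
    return images, table
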