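"""Synthetic well images, plates and response surfaces with ground truth.

The scene model emulates what the assay's camera sees at low
magnification: a bright circular well on a dark surround, dark elongated
worms (rendered as smoothed random-walk tubes of roughly constant
width), optionally small round eggs, and additive Gaussian sensor noise.
A configurable subset of worms is displaced between the two frames of a
pair, to *fully disjoint* positions, so the true moving pixel fraction
is unambiguous and serves as the oracle for the FMS pipeline.

The kinetic model generates normalized dose x time response surfaces
from a two-phase mechanism — exponential paralysis onset toward a
dose-dependent depth given by a three-parameter logistic in dose,
followed by delayed exponential recovery — emulating the archetypal
paralysis/recovery time courses of cholinergic agonists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi

from .response import DoseTimeMatrix

__all__ = [
    "SceneConfig",
    "GroundTruth",
    "KineticsConfig",
    "simulate_well_pair",
    "simulate_plate",
    "simulate_response_surface",
    "logistic3_curve",
]

_PLACEMENT_MARGIN = 6  # px gap kept between objects so closing cannot merge them


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic well scene.

    Intensities are in [0, 1].  ``moving_fraction`` is the fraction of
    worms (by count) displaced between the two frames; with worms of
    near-equal size it is also approximately the true moving *pixel*
    fraction.  Moving worms are re-placed at fully disjoint positions
    ``displacement_px`` away so the ground truth is exact.
    """

    shape: tuple[int, int] = (512, 512)
    n_worms: int = 10
    worm_length_px: tuple[int, int] = (40, 60)
    worm_width_px: tuple[int, int] = (4, 6)
    moving_fraction: float = 0.5
    displacement_px: float = 25.0
    n_eggs: int = 0
    egg_radius_px: float = 3.0
    noise_sigma: float = 0.01
    well_radius_frac: float = 1.0
    background_level: float = 0.7
    worm_level: float = 0.3
    surround_level: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.moving_fraction <= 1.0:
            raise ValueError("moving_fraction must be in [0, 1]")
        if abs(self.worm_level - self.background_level) < 5 * self.noise_sigma:
            raise ValueError(
                "worm_level must differ from background_level by >= 5x noise_sigma"
            )


@dataclass
class GroundTruth:
    """Per-worm masks and the true moving fraction of a simulated pair."""

    worm_masks_f1: list[np.ndarray]
    worm_masks_f2: list[np.ndarray]
    egg_mask: np.ndarray
    moving_ids: list[int]
    true_moving_fraction: float

    @property
    def worm_mask_f1(self) -> np.ndarray:
        """Union of all frame-1 worm masks."""
        out = np.zeros_like(self.egg_mask)
        for m in self.worm_masks_f1:
            out |= m
        return out


def _worm_path(
    rng: np.random.Generator, length: int, start: np.ndarray, heading: float
) -> np.ndarray:
    """Smoothed random-walk centreline: unit steps with curvature jitter."""
    pts = np.empty((length, 2))
    pos = start.astype(float)
    for i in range(length):
        pts[i] = pos
        heading += rng.normal(0.0, 0.15)
        pos = pos + np.array([math.sin(heading), math.cos(heading)])
    return pts


def _stamp_tube(shape: tuple[int, int], pts: np.ndarray, radius: float) -> np.ndarray:
    """Rasterize a centreline into a constant-width tube mask."""
    mask = np.zeros(shape, dtype=bool)
    r = int(math.ceil(radius))
    yy, xx = np.ogrid[-r : r + 1, -r : r + 1]
    stamp = yy**2 + xx**2 <= radius**2
    rows, cols = shape
    for y, x in pts:
        iy, ix = int(round(y)), int(round(x))
        y0, y1 = iy - r, iy + r + 1
        x0, x1 = ix - r, ix + r + 1
        if y0 < 0 or x0 < 0 or y1 > rows or x1 > cols:
            continue
        mask[y0:y1, x0:x1] |= stamp
    return mask


def _disjoint(mask: np.ndarray, occupancy: np.ndarray) -> bool:
    return not (mask & occupancy).any()


def _shift_mask(mask: np.ndarray, dy: int, dx: int) -> np.ndarray:
    shifted = np.zeros_like(mask)
    rows, cols = mask.shape
    ys, xs = np.nonzero(mask)
    ys = ys + dy
    xs = xs + dx
    ok = (ys >= 0) & (ys < rows) & (xs >= 0) & (xs < cols)
    if not ok.all():
        return shifted  # marked invalid by reduced area; caller checks
    shifted[ys, xs] = True
    return shifted


def _grow(mask: np.ndarray, margin: int) -> np.ndarray:
    return ndi.binary_dilation(mask, iterations=margin)


def simulate_well_pair(
    cfg: SceneConfig,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Render the two frames of one well plus ground truth.

    Frame 2 equals frame 1 except that the chosen moving worms are
    re-rendered at displaced, non-overlapping positions and the additive
    noise is redrawn.  Deterministic for a fixed ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    rows, cols = cfg.shape
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    well_radius = cfg.well_radius_frac * min(rows, cols) / 2.0
    # Worms must sit inside the analysis circle with margin to spare.
    place_radius = 0.82 * well_radius

    yy, xx = np.ogrid[:rows, :cols]
    well = (yy - cy) ** 2 + (xx - cx) ** 2 <= well_radius**2
    base = np.full(cfg.shape, cfg.surround_level)
    base[well] = cfg.background_level

    n_moving = int(round(cfg.moving_fraction * cfg.n_worms))
    occupancy = np.zeros(cfg.shape, dtype=bool)

    def place_worm() -> np.ndarray:
        for _ in range(200):
            length = int(rng.integers(cfg.worm_length_px[0], cfg.worm_length_px[1] + 1))
            width = rng.uniform(*cfg.worm_width_px)
            ang = rng.uniform(0, 2 * math.pi)
            rad = place_radius * math.sqrt(rng.uniform(0, 1))
            start = np.array([cy + rad * math.sin(ang), cx + rad * math.cos(ang)])
            heading = rng.uniform(0, 2 * math.pi)
            pts = _worm_path(rng, length, start, heading)
            d = np.hypot(pts[:, 0] - cy, pts[:, 1] - cx)
            if (d > place_radius).any():
                continue
            mask = _stamp_tube(cfg.shape, pts, width / 2.0)
            if mask.sum() == 0:
                continue
            if _disjoint(_grow(mask, _PLACEMENT_MARGIN), occupancy):
                return mask
        raise RuntimeError(
            "could not place worm without overlap; use fewer or smaller worms"
        )

    worm_masks_f1 = []
    for _ in range(cfg.n_worms):
        m = place_worm()
        occupancy |= m
        worm_masks_f1.append(m)

    moving_ids = list(rng.choice(cfg.n_worms, size=n_moving, replace=False)) if n_moving else []
    moving_set = set(int(i) for i in moving_ids)

    # Frame-2 worm positions: stationary worms stay; moving worms are
    # shifted by displacement_px to positions disjoint from everything
    # (including their own frame-1 footprint).
    occupancy2 = occupancy.copy()  # start from full frame-1 occupancy
    worm_masks_f2: list[np.ndarray] = []
    for i, mask in enumerate(worm_masks_f1):
        if i not in moving_set:
            worm_masks_f2.append(mask)
            continue
        area = mask.sum()
        placed = None
        # crowded scenes (all worms moving) may leave no free spot at the
        # nominal displacement; escalate the magnitude rather than fail
        for scale in (1.0, 1.5, 2.0, 3.0):
            for _ in range(150):
                ang = rng.uniform(0, 2 * math.pi)
                dy = int(round(scale * cfg.displacement_px * math.sin(ang)))
                dx = int(round(scale * cfg.displacement_px * math.cos(ang)))
                cand = _shift_mask(mask, dy, dx)
                if cand.sum() != area:
                    continue
                ys, xs = np.nonzero(cand)
                if ((ys - cy) ** 2 + (xs - cx) ** 2 > place_radius**2).any():
                    continue
                if _disjoint(_grow(cand, _PLACEMENT_MARGIN), occupancy2):
                    placed = cand
                    break
            if placed is not None:
                break
        if placed is None:
            # last resort: any disjoint translation inside the well —
            # the oracle needs disjointness, not the exact displacement
            for _ in range(500):
                dy = int(rng.integers(-rows, rows))
                dx = int(rng.integers(-cols, cols))
                cand = _shift_mask(mask, dy, dx)
                if cand.sum() != area:
                    continue
                ys, xs = np.nonzero(cand)
                if ((ys - cy) ** 2 + (xs - cx) ** 2 > place_radius**2).any():
                    continue
                if _disjoint(_grow(cand, _PLACEMENT_MARGIN), occupancy2):
                    placed = cand
                    break
        if placed is None:
            raise RuntimeError(
                "could not displace worm to a disjoint position; "
                "reduce n_worms, worm size, or displacement_px"
            )
        occupancy2 |= placed
        worm_masks_f2.append(placed)

    # Eggs are placed last, from an independent RNG stream, so scenes
    # that differ only in n_eggs share identical worm layout and motion
    # (paired with/without-egg comparisons isolate the size filter).
    egg_rng = np.random.default_rng((cfg.seed, 0xE99))
    egg_mask = np.zeros(cfg.shape, dtype=bool)
    occupied_all = occupancy | occupancy2
    for _ in range(cfg.n_eggs):
        for _ in range(200):
            ang = egg_rng.uniform(0, 2 * math.pi)
            rad = place_radius * math.sqrt(egg_rng.uniform(0, 1))
            ey, ex = cy + rad * math.sin(ang), cx + rad * math.cos(ang)
            egg = (yy - ey) ** 2 + (xx - ex) ** 2 <= cfg.egg_radius_px**2
            # extra clearance: egg edge halos must never merge into one
            # component, or the size filter would see a double-size blob
            if _disjoint(_grow(egg, 2 * _PLACEMENT_MARGIN), occupied_all):
                occupied_all |= egg
                egg_mask |= egg
                break
        else:
            raise RuntimeError("could not place egg without overlap")

    worm_px_total = sum(int(m.sum()) for m in worm_masks_f1)
    moving_px = sum(int(worm_masks_f1[i].sum()) for i in moving_set)
    true_fraction = moving_px / worm_px_total if worm_px_total else 0.0

    def render(worm_masks: list[np.ndarray], noise_rng: np.random.Generator) -> np.ndarray:
        img = base.copy()
        for m in worm_masks:
            img[m] = cfg.worm_level
        img[egg_mask] = cfg.worm_level
        if cfg.noise_sigma > 0:
            img = img + noise_rng.normal(0.0, cfg.noise_sigma, size=cfg.shape)
        return np.clip(img, 0.0, 1.0)

    frame1 = render(worm_masks_f1, rng)
    frame2 = render(worm_masks_f2, rng)

    truth = GroundTruth(
        worm_masks_f1=worm_masks_f1,
        worm_masks_f2=worm_masks_f2,
        egg_mask=egg_mask,
        moving_ids=sorted(moving_set),
        true_moving_fraction=true_fraction,
    )
    return frame1, frame2, truth


def _well_ids(n_rows: int, n_cols: int) -> list[str]:
    return [
        f"{chr(ord('A') + r)}{c + 1:02d}" for r in range(n_rows) for c in range(n_cols)
    ]


def simulate_plate(
    out: str | Path,
    *,
    n_rows: int = 8,
    n_cols: int = 12,
    n_timepoints: int = 37,
    cadence_min: float = 5.0,
    scene: SceneConfig | None = None,
    moving_fraction_fn=None,
    control_cols: tuple[int, ...] = (1,),
    compound: str = "compoundX",
    doses: tuple[float, ...] | None = None,
    dose_unit: str = "mM",
    strain: str = "N2",
    stage: str = "L1",
    bit_depth: int = 8,
    seed: int = 0,
) -> Path:
    """Write a full synthetic plate in the canonical on-disk dialect.

    Produces ``t{idx:04d}/{well}_f{1,2}.tif`` image pairs, a plate-map
    CSV (``plate_map.csv``) and a ground-truth CSV (``truth.csv``) with
    the true moving fraction of every (well, timepoint).

    ``moving_fraction_fn(well_id, dose, t_min) -> fraction`` overrides
    the scene's constant moving fraction, letting a plate encode a
    dose- and time-dependent response.  Columns in ``control_cols`` are
    drug-free controls (dose 0, full mobility).
    """
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    scene = scene or SceneConfig()
    if doses is None:
        doses = tuple(2.0 ** (c - 2) for c in range(1, n_cols + 1))
    rng = np.random.default_rng(seed)

    wells = _well_ids(n_rows, n_cols)
    plate_rows = []
    for well in wells:
        col = int(well[1:])
        is_control = col in control_cols
        plate_rows.append(
            {
                "well": well,
                "compound": "none" if is_control else compound,
                "dose": 0.0 if is_control else doses[col - 1],
                "unit": dose_unit,
                "strain": strain,
                "stage": stage,
                "is_control": is_control,
            }
        )
    plate_map = pd.DataFrame(plate_rows)
    plate_map.to_csv(out / "plate_map.csv", index=False)

    dtype = np.uint8 if bit_depth == 8 else np.uint16
    scale = 255 if bit_depth == 8 else 65535

    truth_rows = []
    for t_idx in range(n_timepoints):
        tdir = out / f"t{t_idx:04d}"
        tdir.mkdir(exist_ok=True)
        t_min = t_idx * cadence_min
        for row in plate_rows:
            well = row["well"]
            if moving_fraction_fn is not None:
                frac = 1.0 if row["is_control"] else moving_fraction_fn(
                    well, row["dose"], t_min
                )
                frac = float(np.clip(frac, 0.0, 1.0))
            else:
                frac = 1.0 if row["is_control"] else scene.moving_fraction
            cfg = SceneConfig(
                shape=scene.shape,
                n_worms=scene.n_worms,
                worm_length_px=scene.worm_length_px,
                worm_width_px=scene.worm_width_px,
                moving_fraction=frac,
                displacement_px=scene.displacement_px,
                n_eggs=scene.n_eggs,
                egg_radius_px=scene.egg_radius_px,
                noise_sigma=scene.noise_sigma,
                well_radius_frac=scene.well_radius_frac,
                background_level=scene.background_level,
                worm_level=scene.worm_level,
                surround_level=scene.surround_level,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            f1, f2, truth = simulate_well_pair(cfg)
            tifffile.imwrite(
                tdir / f"{well}_f1.tif", (f1 * scale).round().astype(dtype)
            )
            tifffile.imwrite(
                tdir / f"{well}_f2.tif", (f2 * scale).round().astype(dtype)
            )
            truth_rows.append(
                {
                    "well": well,
                    "time_min": t_min,
                    "true_moving_fraction": truth.true_moving_fraction,
                }
            )
    pd.DataFrame(truth_rows).to_csv(out / "truth.csv", index=False)
    return out


def logistic3_curve(x, A: float, B: float, M: float):
    """Three-parameter logistic: 1 at low dose, ``A`` at high dose,
    midpoint ``M``, slope ``B``."""
    x = np.asarray(x, dtype=float)
    return A + (1.0 - A) / (1.0 + np.exp(-B * (M - x)))


@dataclass(frozen=True)
class KineticsConfig:
    """Two-phase paralysis/recovery kinetics with dose-dependent depth.

    The normalized mobility at dose ``x`` and time ``t`` (minutes) is

        FMS(x, t) = 1 - depth(x) * p(t) * (1 - extent * r(t))

    with depth(x) = max_paralysis_depth * (1 - L(x)) for the logistic
    L(x) with parameters (A_true, B_true, M_true), paralysis onset
    p(t) = 1 - exp(-paralysis_rate * t), and delayed recovery
    r(t) = 1 - exp(-recovery_rate * (t - recovery_onset_min)) for
    t past the onset, else 0.  With recovery off, FMS at late times
    approaches L(x) exactly, so an end-time dose column is a pure
    logistic curve.
    """

    A_true: float = 0.1
    B_true: float = 5.0
    M_true: float = 1.0
    paralysis_rate: float = 0.1
    max_paralysis_depth: float = 1.0
    recovery_onset_min: float = 60.0
    recovery_rate: float = 0.0
    recovery_extent: float = 1.0
    noise_sigma: float = 0.0
    seed: int = 0


def simulate_response_surface(
    kin: KineticsConfig,
    doses,
    times,
) -> tuple[DoseTimeMatrix, dict]:
    """Generate a normalized dose x time FMS surface from the kinetic model.

    Returns the matrix and the generating truth (logistic parameters
    and per-dose paralysis depths) for parameter-recovery tests.
    """
    doses = np.asarray(doses, dtype=float)
    times = np.asarray(times, dtype=float)
    if doses.size == 0 or times.size == 0:
        raise ValueError("doses and times must be non-empty")
    rng = np.random.default_rng(kin.seed)

    L = logistic3_curve(doses, kin.A_true, kin.B_true, kin.M_true)
    depth = kin.max_paralysis_depth * (1.0 - L)
    p = 1.0 - np.exp(-kin.paralysis_rate * times)
    r = np.where(
        times >= kin.recovery_onset_min,
        1.0 - np.exp(-kin.recovery_rate * np.maximum(times - kin.recovery_onset_min, 0.0)),
        0.0,
    )
    if kin.recovery_rate == 0:
        r = np.zeros_like(times)
    values = 1.0 - depth[:, None] * p[None, :] * (1.0 - kin.recovery_extent * r[None, :])
    if kin.noise_sigma > 0:
        values = values + rng.normal(0.0, kin.noise_sigma, size=values.shape)
    values = np.clip(values, 0.0, None)
    matrix = DoseTimeMatrix(doses=doses, times=times, values=values)
    truth = {
        "A_true": kin.A_true,
        "B_true": kin.B_true,
        "M_true": kin.M_true,
        "depth": depth,
        "logistic_end": L,
    }
    return matrix, truth
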