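"""Synthetic ultrasound frames with known ground truth.

The generator emulates the two kinds of stills the quantification pipeline
consumes, so every stage is testable without clinical data:

* **B-mode nerve cross-sections** — bright multiplicative-speckle background,
  a bright epineurium rim just inside the ROI boundary, and dark
  (hypoechogenic) elliptical fascicles whose union covers a requested
  fraction of the ROI.
* **Color-Doppler frames** — grayscale speckle background (R = G = B exactly)
  with blob overlays painted in the four palette classes (light/dark ×
  blue/red) at a requested total area fraction, fast-flow mix, and
  toward-transducer mix.

Speckle is modeled as clamped multiplicative Rayleigh noise around the tissue
mean — enough texture to stress the thresholding, with no claim to acoustic
realism. Overlay colors are idealized palette anchors with bounded per-pixel
jitter; the jitter ranges preserve every class-defining channel ordering
(light blue G>R, dark blue B>G, light red G>B, dark red R>G), and red-class
anchors are exact R↔B mirrors of the blue-class anchors so flow direction is
information-free by construction. All randomness flows through one
``numpy.random.Generator`` seeded by the ``seed`` argument; the same
arguments always produce bit-identical frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.morphology import dilation, disk as disk_footprint

from .errors import GenerationError, ValidationError
from .io_roi import BinaryMask, Frame, RoiPolygon, rasterize_roi, write_image, write_roi_json

__all__ = [
    "SyntheticTruth",
    "SiteSpec",
    "STUDY_SITE_DEFAULTS",
    "FR_SITE_DEFAULTS",
    "default_roi",
    "simulate_bmode_nerve",
    "simulate_doppler_frame",
    "simulate_cohort",
    "sample_measurement_cohort",
]

_RAYLEIGH_SCALE = math.sqrt(2.0 / math.pi)  # Rayleigh with unit mean

# Palette anchors: (suppressed, green, dominant) base values for the light
# (fast-flow) classes and (secondary, green, dominant) for the dark
# (slow-flow) classes. Light blue maps the triple to (R, G, B) =
# (suppressed, green, dominant); light red is its exact R<->B mirror, and
# likewise for the dark pair. Per-pixel jitter is a common-mode brightness
# offset added to all three channels: a Doppler overlay is a digitally
# composited palette LUT, so its per-pixel variation runs the class anchor
# along a brightness ramp rather than adding independent per-channel noise
# (the offset cancels exactly in the channel differences). The channel
# orderings that define the classes (light blue G>R, dark blue B>G, light
# red G>B, dark red R>G) hold for every draw, and slow-flow pixels never
# contribute to the fast-flow difference maps (their green channel stays
# below both the secondary and the dominant channel).
_LIGHT_BASE = (5, 190, 235)
_DARK_BASE = (45, 15, 195)
_BRIGHTNESS_SPAN = 20  # common-mode offset drawn from [0, span)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth attached to a generated frame.

    Fractions are the *achieved* values (painted pixels over ROI pixels),
    which match the requested ones to within 1-px rounding.
    """

    seed: int
    fascicle_fraction: float | None = None
    doppler_fraction: float | None = None
    high_class_fraction: float | None = None
    toward_fraction: float | None = None
    painted_masks: dict[str, BinaryMask] = field(default_factory=dict)


def default_roi(shape: tuple[int, int] = (128, 128), margin: int = 16, label: str = "nerve") -> RoiPolygon:
    """Regular-octagon ROI centered in the frame, circumradius bounded by the
    margin. The default geometry keeps the ROI inradius below the default
    background-subtraction radius so the background estimate always sees
    tissue outside any fascicle."""
    h, w = shape
    cy, cx = h / 2.0, w / 2.0
    radius = min(h, w) / 2.0 - margin
    if radius <= 2:
        raise ValidationError("frame too small for the requested margin")
    verts = []
    for k in range(8):
        ang = math.pi / 8 + k * math.pi / 4
        verts.append((cx + radius * math.cos(ang), cy + radius * math.sin(ang)))
    return RoiPolygon(tuple(verts), label=label)


def _speckle(rng: np.random.Generator, shape: tuple[int, int], scale: float) -> np.ndarray:
    ray = rng.rayleigh(scale=_RAYLEIGH_SCALE, size=shape)
    return np.clip(1.0 + scale * (ray - 1.0), 0.0, None)


def _check_fraction(name: str, value: float) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"{name} must lie in [0, 1], got {value}")
    return value


# ---------------------------------------------------------------------------
# B-mode


def simulate_bmode_nerve(
    roi: RoiPolygon,
    fascicle_fraction: float,
    speckle_scale: float = 0.02,
    n_fascicles: int = 12,
    seed: int = 0,
    shape: tuple[int, int] | None = None,
    display_noise_sd: float = 5.0,
) -> tuple[Frame, SyntheticTruth]:
    """B-mode nerve phantom with a known hypoechogenic area fraction.

    Fascicles are random ellipses inside the ROI; one global size factor is
    bisected until their union covers ``fascicle_fraction`` of the ROI within
    1% relative (or 1 px). Background mean 200, epineurium rim mean 240,
    fascicle mean 30, all modulated by the same multiplicative
    Rayleigh-speckle field; ``display_noise_sd`` adds the constant-width
    additive noise the log-compressed display leaves on every tissue class
    (without it, dark structures would be implausibly noise-free).
    """
    fascicle_fraction = _check_fraction("fascicle_fraction", fascicle_fraction)
    if shape is None:
        xs = [v[0] for v in roi.vertices]
        ys = [v[1] for v in roi.vertices]
        shape = (int(max(ys)) + 13, int(max(xs)) + 13)
    rng = np.random.default_rng(seed)
    roi_mask = rasterize_roi(roi, shape)
    roi_area = roi_mask.area_px
    if roi_area == 0:
        raise ValidationError("ROI rasterizes to zero pixels")
    target = int(round(fascicle_fraction * roi_area))
    tol = max(1, int(round(0.01 * target)))

    fasc = np.zeros(shape, dtype=bool)
    if target > 0:
        if n_fascicles < 1:
            raise GenerationError("cannot reach a positive fraction with zero fascicles")
        rows, cols = np.nonzero(roi_mask.pixels)
        idx = rng.integers(0, rows.size, size=n_fascicles)
        centers = np.column_stack([rows[idx], cols[idx]]).astype(float)
        ax_a = rng.uniform(0.6, 1.4, size=n_fascicles)
        ax_b = rng.uniform(0.6, 1.4, size=n_fascicles)
        angles = rng.uniform(0.0, math.pi, size=n_fascicles)

        def union_for(scale: float) -> np.ndarray:
            m = np.zeros(shape, dtype=bool)
            for (r0, c0), a, b, ang in zip(centers, ax_a, ax_b, angles):
                rr, cc = draw_ellipse(
                    r0, c0, max(scale * a, 0.3), max(scale * b, 0.3),
                    shape=shape, rotation=ang,
                )
                m[rr, cc] = True
            return m & roi_mask.pixels

        lo, hi = 0.0, 1.0
        for _ in range(64):
            if int(union_for(hi).sum()) >= target:
                break
            hi *= 2.0
        else:
            raise GenerationError(
                f"fascicle fraction {fascicle_fraction} unattainable with "
                f"{n_fascicles} fascicles in this ROI"
            )
        for _ in range(48):
            mid = 0.5 * (lo + hi)
            if int(union_for(mid).sum()) >= target:
                hi = mid
            else:
                lo = mid
        fasc = union_for(hi)
        if abs(int(fasc.sum()) - target) > tol:
            raise GenerationError(
                f"could not match fascicle fraction {fascicle_fraction} within "
                f"tolerance ({int(fasc.sum())} px vs target {target})"
            )

    # Epineurium: the bright ring bordering the nerve, just outside the
    # measured cross-section (the ROI traces the inner epineurium boundary).
    rim = dilation(roi_mask.pixels, disk_footprint(3)) & ~roi_mask.pixels
    base = np.full(shape, 200.0)
    base[rim] = 240.0
    base[fasc] = 30.0
    pixels = np.clip(
        np.round(
            base * _speckle(rng, shape, speckle_scale)
            + rng.normal(0.0, display_noise_sd, size=shape)
        ),
        0,
        255,
    ).astype(np.uint8)
    truth = SyntheticTruth(
        seed=seed,
        fascicle_fraction=int(fasc.sum()) / roi_area,
        painted_masks={"fascicle": BinaryMask(fasc)},
    )
    return Frame(pixels, modality="bmode"), truth


# ---------------------------------------------------------------------------
# Doppler


def _paint_blobs(
    rng: np.random.Generator,
    free: np.ndarray,
    budget: int,
    shape: tuple[int, int],
) -> np.ndarray:
    """Occupy exactly ``budget`` currently-free pixels with random disk blobs.

    Returns painted pixel coordinates (n, 2) in paint order; mutates ``free``.
    """
    painted = []
    remaining = budget
    while remaining > 0:
        rows, cols = np.nonzero(free)
        if rows.size == 0:
            raise GenerationError("overlay budget exhausted: no free ROI pixels left")
        k = rng.integers(0, rows.size)
        radius = int(rng.integers(2, 6))
        rr, cc = draw_disk((int(rows[k]), int(cols[k])), radius, shape=shape)
        sel = free[rr, cc]
        rr, cc = rr[sel], cc[sel]
        if rr.size > remaining:
            rr, cc = rr[:remaining], cc[:remaining]
        free[rr, cc] = False
        painted.append(np.column_stack([rr, cc]))
        remaining -= rr.size
    if painted:
        return np.concatenate(painted, axis=0)
    return np.empty((0, 2), dtype=int)


def simulate_doppler_frame(
    roi: RoiPolygon,
    doppler_fraction: float,
    high_class_fraction: float,
    toward_fraction: float = 0.5,
    speckle_scale: float = 0.12,
    seed: int = 0,
    shape: tuple[int, int] | None = None,
) -> tuple[Frame, SyntheticTruth]:
    """Color-Doppler phantom with known class areas.

    ``doppler_fraction`` of the ROI is painted with overlay pixels;
    ``high_class_fraction`` of those belong to the fast (light) classes;
    ``toward_fraction`` of each velocity class is painted in the red
    (toward-transducer) direction. Blob geometry and jitter draws do not
    depend on ``toward_fraction``, so frames differing only in direction
    carry identical information to a direction-independent method.
    """
    doppler_fraction = _check_fraction("doppler_fraction", doppler_fraction)
    high_class_fraction = _check_fraction("high_class_fraction", high_class_fraction)
    toward_fraction = _check_fraction("toward_fraction", toward_fraction)
    if shape is None:
        xs = [v[0] for v in roi.vertices]
        ys = [v[1] for v in roi.vertices]
        shape = (int(max(ys)) + 13, int(max(xs)) + 13)
    rng = np.random.default_rng(seed)
    roi_mask = rasterize_roi(roi, shape)
    roi_area = roi_mask.area_px
    if roi_area == 0:
        raise ValidationError("ROI rasterizes to zero pixels")

    total = int(round(doppler_fraction * roi_area))
    n_high = int(round(high_class_fraction * total))
    n_low = total - n_high

    free = roi_mask.pixels.copy()
    high_px = _paint_blobs(rng, free, n_high, shape)
    low_px = _paint_blobs(rng, free, n_low, shape)

    # Background: grayscale speckle, R = G = B exactly.
    gray = np.clip(np.round(90.0 * _speckle(rng, shape, speckle_scale)), 0, 255).astype(np.uint8)
    pixels = np.stack([gray, gray, gray], axis=-1)

    # Brightness jitter drawn per velocity class, shared by both directions
    # (role-based, so the toward/away palettes are exact channel mirrors).
    d_h = rng.integers(0, _BRIGHTNESS_SPAN, size=len(high_px))
    lo_h = _LIGHT_BASE[0] + d_h
    g_h = _LIGHT_BASE[1] + d_h
    hi_h = _LIGHT_BASE[2] + d_h
    d_l = rng.integers(0, _BRIGHTNESS_SPAN, size=len(low_px))
    sec_l = _DARK_BASE[0] + d_l
    g_l = _DARK_BASE[1] + d_l
    dom_l = _DARK_BASE[2] + d_l

    n_toward_h = int(round(toward_fraction * len(high_px)))
    n_toward_l = int(round(toward_fraction * len(low_px)))
    toward_h = np.zeros(len(high_px), dtype=bool)
    toward_h[:n_toward_h] = True
    toward_l = np.zeros(len(low_px), dtype=bool)
    toward_l[:n_toward_l] = True

    masks = {
        name: np.zeros(shape, dtype=bool)
        for name in ("light_blue", "dark_blue", "light_red", "dark_red")
    }
    if len(high_px):
        r_ch = np.where(toward_h, hi_h, lo_h)
        b_ch = np.where(toward_h, lo_h, hi_h)
        pixels[high_px[:, 0], high_px[:, 1], 0] = r_ch
        pixels[high_px[:, 0], high_px[:, 1], 1] = g_h
        pixels[high_px[:, 0], high_px[:, 1], 2] = b_ch
        masks["light_red"][high_px[toward_h, 0], high_px[toward_h, 1]] = True
        masks["light_blue"][high_px[~toward_h, 0], high_px[~toward_h, 1]] = True
    if len(low_px):
        r_ch = np.where(toward_l, dom_l, sec_l)
        b_ch = np.where(toward_l, sec_l, dom_l)
        pixels[low_px[:, 0], low_px[:, 1], 0] = r_ch
        pixels[low_px[:, 0], low_px[:, 1], 1] = g_l
        pixels[low_px[:, 0], low_px[:, 1], 2] = b_ch
        masks["dark_red"][low_px[toward_l, 0], low_px[toward_l, 1]] = True
        masks["dark_blue"][low_px[~toward_l, 0], low_px[~toward_l, 1]] = True

    truth = SyntheticTruth(
        seed=seed,
        doppler_fraction=total / roi_area,
        high_class_fraction=(len(high_px) / total) if total else 0.0,
        toward_fraction=toward_fraction,
        painted_masks={k: BinaryMask(v) for k, v in masks.items()},
    )
    return Frame(pixels, modality="doppler"), truth


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class SiteSpec:
    """Per-site truth model for cohort simulation.

    ``mean``/``sd`` parameterize the subject-level truncated normal of the
    site's area fraction (Doppler fraction for doppler sites, fascicle
    fraction for bmode sites); frames within a subject scatter around the
    subject value with SD ``frame_sd``.
    """

    n_subjects: int
    mean: float
    sd: float
    kind: str = "doppler"  # or "bmode"
    high_mean: float = 0.33
    high_sd: float = 0.05
    frame_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValidationError("each site needs n_subjects >= 2")
        if not 0 <= self.mean <= 1 or self.sd <= 0:
            raise ValidationError("site mean must lie in [0, 1] with sd > 0")
        if self.kind not in ("doppler", "bmode"):
            raise ValidationError("site kind must be 'doppler' or 'bmode'")


#: Doppler-site defaults emulating a nerve-trauma cohort: neuroma
#: hypervascularization, near-identical unaffected/healthy nerves, and a
#: perfusion drop in denervated muscle. Means are the package's clinical
#: reference values; SDs are chosen to give realistic subject scatter.
STUDY_SITE_DEFAULTS: dict[str, SiteSpec] = {
    "neuroma": SiteSpec(9, 0.4326, 0.08, high_mean=0.36, high_sd=0.15),
    "unaffected": SiteSpec(9, 0.1414, 0.04, high_mean=0.390, high_sd=0.08),
    "healthy_control": SiteSpec(4, 0.1772, 0.04, high_mean=0.328, high_sd=0.08),
    "muscle_denervated": SiteSpec(9, 0.1422, 0.05, high_mean=0.454, high_sd=0.10),
    "muscle_control": SiteSpec(9, 0.5415, 0.08, high_mean=0.875, high_sd=0.05),
}

#: B-mode fascicular-fraction defaults for the same cohort.
FR_SITE_DEFAULTS: dict[str, SiteSpec] = {
    "neuroma": SiteSpec(9, 0.8787, 0.06, kind="bmode"),
    "unaffected": SiteSpec(9, 0.5066, 0.06, kind="bmode"),
    "healthy_control": SiteSpec(4, 0.5431, 0.06, kind="bmode"),
}


def _truncnorm_sample(
    rng: np.random.Generator, mean: float, sd: float, low: float, high: float, size=None
):
    a, b = (low - mean) / sd, (high - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_cohort(
    out_dir: str | Path,
    site_specs: dict[str, SiteSpec] | None = None,
    frames_per_site: int = 6,
    seed: int = 0,
    shape: tuple[int, int] = (96, 96),
) -> pd.DataFrame:
    """Write a full synthetic cohort: frames, ROI files, and a manifest CSV.

    Every subject contributes ``frames_per_site`` stills per site (the study
    design this emulates used six). The manifest has one row per frame with
    the generating truth, so downstream measurements can be validated
    end-to-end. Returns the manifest as a DataFrame; also written to
    ``manifest.csv``.
    """
    if site_specs is None:
        site_specs = STUDY_SITE_DEFAULTS
    if not site_specs:
        raise ValidationError("cohort spec must name at least one site")
    if frames_per_site < 1:
        raise ValidationError("frames_per_site must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    roi = default_roi(shape, margin=12)
    rows = []
    for site, spec in sorted(site_specs.items()):
        for s in range(spec.n_subjects):
            subj = f"{site}_s{s:02d}"
            subj_mean = float(_truncnorm_sample(rng, spec.mean, spec.sd, 0.0, 1.0))
            subj_high = float(_truncnorm_sample(rng, spec.high_mean, spec.high_sd, 0.0, 1.0))
            for f in range(frames_per_site):
                frac = float(_truncnorm_sample(rng, subj_mean, spec.frame_sd, 0.0, 1.0))
                frame_seed = int(rng.integers(0, 2**31 - 1))
                stem = f"{subj}_f{f}"
                if spec.kind == "doppler":
                    frame, truth = simulate_doppler_frame(
                        roi, frac, subj_high, toward_fraction=0.5,
                        seed=frame_seed, shape=shape,
                    )
                    truth_fraction = truth.doppler_fraction
                    truth_high = truth.high_class_fraction
                else:
                    frame, truth = simulate_bmode_nerve(
                        roi, frac, seed=frame_seed, shape=shape,
                    )
                    truth_fraction = truth.fascicle_fraction
                    truth_high = np.nan
                write_image(out_dir / f"{stem}.png", frame)
                write_roi_json(out_dir / f"{stem}.roi.json", roi)
                rows.append(
                    {
                        "subject_id": subj,
                        "site": site,
                        "frame": f"{stem}.png",
                        "roi": f"{stem}.roi.json",
                        "kind": spec.kind,
                        "truth_fraction": truth_fraction,
                        "truth_high_fraction": truth_high,
                        "seed": frame_seed,
                    }
                )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def sample_measurement_cohort(
    group_specs: dict[str, tuple[float, float, int]],
    rng: np.random.Generator,
    frames_per_subject: int = 6,
    frame_sd: float = 2.0,
    low: float = 0.0,
    high: float = 100.0,
) -> dict[str, np.ndarray]:
    """Draw per-frame measurement values (percent scale) from the cohort
    truth model without rendering images: subject means from a truncated
    normal per group, frames scattered around each subject mean.

    ``group_specs`` maps site -> (mean, sd, n_subjects). Returns site ->
    array of shape (n_subjects, frames_per_subject). This is the value-level
    counterpart of :func:`simulate_cohort` for Monte-Carlo work on the
    statistics layer.
    """
    out = {}
    for site, (mean, sd, n) in group_specs.items():
        subj = _truncnorm_sample(rng, mean, sd, low, high, size=n)
        frames = np.empty((n, frames_per_subject))
        for i, m in enumerate(np.atleast_1d(subj)):
            frames[i] = _truncnorm_sample(rng, float(m), frame_sd, low, high, size=frames_per_subject)
        out[site] = frames
    return out
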