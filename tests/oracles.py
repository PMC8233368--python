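"""Independent reference implementations used only by the tests.

Everything here is deliberately written the slow, obvious way (python loops,
per-candidate scans) and shares no code with the package, so it can serve as
an oracle for the fast implementations.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_max_entropy(counts) -> int:
    """Exhaustive Kapur-criterion scan over all 255 candidate thresholds.

    Background = bins [0..t], foreground = bins [t+1..255]; candidates with
    an empty class are skipped; ties keep the smallest t.
    """
    counts = np.asarray(counts, dtype=float)
    p = counts / counts.sum()
    best, best_t = -math.inf, None
    for t in range(255):
        pb = p[: t + 1].sum()
        pf = p[t + 1 :].sum()
        if pb <= 0 or pf <= 0:
            continue
        hb = -sum(q / pb * math.log(q / pb) for q in p[: t + 1] if q > 0)
        hf = -sum(q / pf * math.log(q / pf) for q in p[t + 1 :] if q > 0)
        if hb + hf > best:
            best, best_t = hb + hf, t
    return best_t


def kapur_criterion(counts, t: int) -> float:
    """Kapur criterion value H_b(t) + H_f(t) for one candidate, or -inf if a
    class is empty."""
    p = np.asarray(counts, dtype=float)
    p = p / p.sum()
    pb = p[: t + 1].sum()
    pf = p[t + 1 :].sum()
    if pb <= 0 or pf <= 0:
        return -math.inf
    hb = -sum(q / pb * math.log(q / pb) for q in p[: t + 1] if q > 0)
    hf = -sum(q / pf * math.log(q / pf) for q in p[t + 1 :] if q > 0)
    return hb + hf


def assert_kapur_optimal(t_impl: int, counts, atol: float = 1e-9) -> None:
    """The implementation's threshold must achieve the brute-force criterion
    maximum (up to float noise); when the gap to the runner-up exceeds the
    tolerance this forces exact agreement, including the smallest-t tie rule."""
    t_ref = brute_force_max_entropy(counts)
    if t_impl == t_ref:
        return
    gap = kapur_criterion(counts, t_ref) - kapur_criterion(counts, t_impl)
    assert abs(gap) <= atol, (t_impl, t_ref, gap)


def point_in_polygon(x: float, y: float, vertices) -> bool:
    """Ray-casting point-in-polygon test (crossing number, half-open edges)."""
    inside = False
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_int = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_int:
                inside = not inside
    return inside


def random_star_polygon(rng: np.random.Generator, center, r_min, r_max, n_vertices):
    """Random simple polygon: vertices at sorted angles around a center
    (star-shaped, hence guaranteed non-self-intersecting)."""
    cx, cy = center
    while True:
        # Reject near-duplicate directions, and any angular gap >= pi: a
        # chord spanning more than half a turn passes the far side of the
        # center and can cross other edges, breaking simplicity.
        angles = np.sort(rng.uniform(0, 2 * math.pi, n_vertices))
        gaps = np.diff(np.concatenate([angles, [angles[0] + 2 * math.pi]]))
        if gaps.min() > 0.05 and gaps.max() < 3.0:
            break
    radii = rng.uniform(r_min, r_max, n_vertices)
    return [
        (cx + r * math.cos(a), cy + r * math.sin(a)) for a, r in zip(angles, radii)
    ]


def trace_perfusion(pixels: np.ndarray, mask: np.ndarray):
    """Slow per-pixel reimplementation of the Doppler pipeline: channel
    differences, max projections, Kapur binarization per merged map, mask
    set-difference correction, and union. Returns (high, low_corrected,
    total) pixel counts."""
    h, w, _ = pixels.shape
    high_map = np.zeros((h, w), dtype=int)
    low_map = np.zeros((h, w), dtype=int)
    for i in range(h):
        for j in range(w):
            r, g, b = (int(v) for v in pixels[i, j])
            lb, db = max(g - r, 0), max(b - g, 0)
            lr, dr = max(g - b, 0), max(r - g, 0)
            high_map[i, j] = max(lb, lr)
            low_map[i, j] = max(db, dr)

    def binarize(m):
        vals = m[mask]
        counts = np.bincount(vals, minlength=256)
        if (counts > 0).sum() < 2:
            return np.zeros((h, w), dtype=bool)
        t = brute_force_max_entropy(counts)
        return mask & (m > t)

    high = binarize(high_map)
    low = binarize(low_map)
    low_corr = low & ~high
    total = high | low_corr
    return int(high.sum()), int(low_corr.sum()), int(total.sum())
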