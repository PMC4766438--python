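"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's projection code paths: the extended
curve is discretized very finely and nearest samples are taken, so any
systematic error in the analytic/optimized implementation shows up as a
disagreement.
"""

import numpy as np

from odorfusion.curves import FittedCurve, predict

SQRT2 = np.sqrt(2.0)


def dense_curve(curve: FittedCurve, resolution: float = 1e-5, extension: float = 0.75):
    """Discretize the extended curve at roughly ``resolution`` arc spacing.

    Returns (points Nx2, arc coordinates N) with arc measured from the
    lower end of the fitted region, negative on the lower extension.
    """
    t0, t1 = curve.t_range
    # fine t grid; spacing chosen so adjacent samples are <= resolution apart
    n = 2001
    t = np.linspace(t0, t1, n)
    px, py = curve.xy(t)
    seg = np.hypot(np.diff(px), np.diff(py))
    total = float(seg.sum())
    n = max(int(np.ceil(total / resolution)) + 1, 2)
    t = np.linspace(t0, t1, n)
    px, py = curve.xy(t)
    seg = np.hypot(np.diff(px), np.diff(py))
    arc = np.concatenate([[0.0], np.cumsum(seg)])

    m = int(np.ceil(extension * SQRT2 / resolution)) + 1
    u = np.linspace(-extension, 0.0, m, endpoint=False)
    lo_x, lo_y = curve.p_lo
    hi_x, hi_y = curve.p_hi
    lower = np.column_stack([lo_x + u, lo_y + u])
    lower_arc = SQRT2 * u
    u2 = np.linspace(extension / m, extension, m)
    upper = np.column_stack([hi_x + u2, hi_y + u2])
    upper_arc = arc[-1] + SQRT2 * u2

    pts = np.vstack([lower, np.column_stack([px, py]), upper])
    arcs = np.concatenate([lower_arc, arc, upper_arc])
    return pts, arcs


def oracle_project(curve: FittedCurve, x: float, y: float, resolution: float = 1e-5):
    """Nearest dense-grid sample: (px, py, arc, distance)."""
    pts, arcs = dense_curve(curve, resolution)
    d2 = (pts[:, 0] - x) ** 2 + (pts[:, 1] - y) ** 2
    i = int(np.argmin(d2))
    return pts[i, 0], pts[i, 1], arcs[i], float(np.sqrt(d2[i]))


def oracle_md(curve: FittedCurve, xs, ys, resolution: float = 1e-5) -> float:
    pts, _ = dense_curve(curve, resolution)
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    dists = []
    for x, y in zip(xs, ys):
        d2 = (pts[:, 0] - x) ** 2 + (pts[:, 1] - y) ** 2
        dists.append(np.sqrt(d2.min()))
    return float(np.mean(dists))


def ltk_direct(values) -> float:
    """Plain-Python direct summation of the excess-kurtosis formula."""
    vals = [float(v) for v in values]
    m = len(vals)
    mean = sum(vals) / m
    var = sum((v - mean) ** 2 for v in vals) / m
    sd = var**0.5
    return sum(((v - mean) / sd) ** 4 for v in vals) / m - 3.0


def random_monotone_curve(rng: np.random.Generator) -> FittedCurve:
    """A random monotone curve instance covering all 10 family variants."""
    from odorfusion.simulate import FAMILIES, _random_transform

    family = FAMILIES[int(rng.integers(len(FAMILIES)))]
    params = _random_transform(family, rng)
    orientation = "forward" if rng.integers(2) == 0 else "inverse"
    lo = float(rng.uniform(0.0, 0.2))
    hi = float(rng.uniform(0.8, 1.0))
    return FittedCurve(
        family=family, params=params, orientation=orientation, t_range=(lo, hi)
    )
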