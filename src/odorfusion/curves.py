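"""Monotonic model families, curve fitting and orthogonal projection.

Two unit-scaled response datasets measured with different techniques are
assumed to be related by a monotone mapping: a better ligand elicits a
stronger response regardless of technique.  Five parametric families (and
their inverses, i.e. the same forms with the roles of x and y swapped) are
fitted by least squares:

* linear                y = a + b x
* exponential           y = a exp(b x) + c
* sigmoid               y = ymin + (ymax - ymin) / (1 + exp(-(x - x0)/k))
* asymptotic            y = Asym (1 - exp(-exp(lrc) x))
* asymptotic-offset     y = Asym (1 - exp(-exp(lrc) (x - c0)))

The fitted curve is used only on the range spanned by the common data
points and is extended beyond that range, on both sides, by a straight line
of slope 1.  Fit quality is the *mean distance* (MD): the mean orthogonal
Euclidean distance of the common points to the extended curve.  Fits whose
curve is not monotone non-decreasing on the overlap are rejected.

A merged response value for an odorant is the arc length of its projected
point along the extended curve, measured from the lower end of the overlap
region; arc length is monotone along the curve, so ranks are preserved, and
it is symmetric in x and y.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

FAMILY_ORDER = (
    "linear",
    "exponential",
    "sigmoid",
    "asymptotic",
    "asymptotic-offset",
)

_SQRT2 = np.sqrt(2.0)

# grid sizes: monotonicity check per the package convention (1001 points),
# arc-length table and coarse projection grid
MONO_GRID = 1001
ARC_GRID = 2001
PROJ_GRID = 513


def _clip_exp(z):
    return np.exp(np.clip(z, -700.0, 700.0))


def predict(family: str, params, x):
    """Evaluate a model family at ``x`` (vectorized)."""
    x = np.asarray(x, dtype=float)
    if family == "linear":
        a, b = params
        return a + b * x
    if family == "exponential":
        a, b, c = params
        return a * _clip_exp(b * x) + c
    if family == "sigmoid":
        ymin, ymax, x0, k = params
        return ymin + (ymax - ymin) / (1.0 + _clip_exp(-(x - x0) / k))
    if family == "asymptotic":
        asym, lrc = params
        return asym * (1.0 - _clip_exp(-np.exp(np.clip(lrc, -30, 30)) * x))
    if family == "asymptotic-offset":
        asym, lrc, c0 = params
        return asym * (1.0 - _clip_exp(-np.exp(np.clip(lrc, -30, 30)) * (x - c0)))
    raise KeyError(f"unknown model family: {family}")


def jacobian(family: str, params, x) -> np.ndarray:
    """Analytic Jacobian d f(x; p) / d p, shape (len(x), n_params)."""
    x = np.asarray(x, dtype=float)
    if family == "linear":
        return np.column_stack([np.ones_like(x), x])
    if family == "exponential":
        a, b, _ = params
        e = _clip_exp(b * x)
        return np.column_stack([e, a * x * e, np.ones_like(x)])
    if family == "sigmoid":
        ymin, ymax, x0, k = params
        sig = 1.0 / (1.0 + _clip_exp(-(x - x0) / k))
        core = (ymax - ymin) * sig * (1.0 - sig)
        return np.column_stack(
            [1.0 - sig, sig, -core / k, -core * (x - x0) / (k * k)]
        )
    if family == "asymptotic":
        asym, lrc = params
        rate = np.exp(np.clip(lrc, -30, 30))
        e = _clip_exp(-rate * x)
        return np.column_stack([1.0 - e, asym * x * rate * e])
    if family == "asymptotic-offset":
        asym, lrc, c0 = params
        rate = np.exp(np.clip(lrc, -30, 30))
        e = _clip_exp(-rate * (x - c0))
        return np.column_stack(
            [1.0 - e, asym * (x - c0) * rate * e, -asym * rate * e]
        )
    raise KeyError(f"unknown model family: {family}")


def _starts(family: str, x: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    """Eight fixed initializations per nonlinear family.

    Built from coarse data statistics only (ranges and midpoints), so they
    are deterministic for a given point set.
    """
    ylo, yhi = float(np.min(y)), float(np.max(y))
    span = max(yhi - ylo, 1e-3)
    xm = float(np.mean(x))
    if family == "exponential":
        return [
            np.array([span * s, b, ylo - span * s])
            for s in (0.5, 0.1)
            for b in (0.5, 1.0, 2.0, 4.0)
        ]
    if family == "sigmoid":
        return [
            np.array([ylo, yhi, x0, k])
            for x0 in (0.25, xm, 0.75, 0.5)
            for k in (0.1, 0.3)
        ]
    if family == "asymptotic":
        return [np.array([yhi if s else yhi + span, lrc])
                for s in (True, False)
                for lrc in (-1.0, 0.0, 1.0, 2.0)]
    if family == "asymptotic-offset":
        return [
            np.array([yhi + span * s, lrc, c0])
            for s in (0.0, 0.5)
            for lrc in (0.0, 1.0)
            for c0 in (-0.1, 0.1)
        ]
    raise KeyError(family)


def fit_family(family: str, x, y) -> np.ndarray | None:
    """Least-squares fit of one family; returns params or None.

    The linear family is solved in closed form; nonlinear families are
    fitted with Levenberg-Marquardt from the fixed start set, keeping the
    converged start with the lowest residual sum of squares.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if family == "linear":
        b, a = np.polyfit(x, y, 1)
        return np.array([a, b])

    def resid(p):
        return predict(family, p, x) - y

    def jac(p):
        return jacobian(family, p, x)

    # pre-screen the fixed starts by raw SSE and polish only the best few
    starts = sorted(_starts(family, x, y), key=lambda p: float(np.sum(resid(p) ** 2)))
    best, best_sse = None, np.inf
    for p0 in starts[:4]:
        try:
            sol = optimize.least_squares(
                resid, p0, jac=jac, method="lm", max_nfev=100
            )
        except Exception:
            continue
        if not sol.success or not np.all(np.isfinite(sol.x)):
            continue
        sse = float(np.sum(sol.fun**2))
        if sse < best_sse - 1e-12:
            best, best_sse = sol.x, sse
    return best


class NonInvertibleSegmentError(ValueError):
    """y-only projection requested at a level where the curve is flat."""


@dataclass
class FittedCurve:
    """A fitted monotone curve in the joint (x, y) response plane.

    The curve is parameterized by ``t``, the fit's input coordinate:
    forward orientation gives points ``(t, f(t))``, inverse orientation
    (roles of x and y swapped during fitting) gives ``(f(t), t)`` for
    ``t`` in ``t_range``.  Beyond both endpoints the curve continues as a
    straight line of slope 1.
    """

    family: str
    params: np.ndarray
    orientation: str  # "forward" | "inverse"
    t_range: tuple[float, float]
    _arc_t: np.ndarray = field(init=False, repr=False)
    _arc_s: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        t = np.linspace(self.t_range[0], self.t_range[1], ARC_GRID)
        px, py = self.xy(t)
        seg = np.hypot(np.diff(px), np.diff(py))
        self._arc_t = t
        self._arc_s = np.concatenate([[0.0], np.cumsum(seg)])

    # -- geometry ---------------------------------------------------------
    def xy(self, t):
        """Curve point(s) at parameter ``t`` (interior only)."""
        ft = predict(self.family, self.params, t)
        if self.orientation == "forward":
            return np.asarray(t, dtype=float), ft
        return ft, np.asarray(t, dtype=float)

    @property
    def p_lo(self) -> tuple[float, float]:
        x, y = self.xy(np.array([self.t_range[0]]))
        return float(x[0]), float(y[0])

    @property
    def p_hi(self) -> tuple[float, float]:
        x, y = self.xy(np.array([self.t_range[1]]))
        return float(x[0]), float(y[0])

    @property
    def overlap_range(self) -> tuple[float, float]:
        """Extent of the fitted region in the source-x coordinate."""
        return self.p_lo[0], self.p_hi[0]

    def is_monotone(self, n: int = MONO_GRID, tol: float = 1e-9) -> bool:
        """Non-decreasing on the overlap (checked on ``n`` equispaced points)."""
        t = np.linspace(self.t_range[0], self.t_range[1], n)
        ft = predict(self.family, self.params, t)
        return bool(np.all(np.diff(ft) >= -tol)) and bool(np.all(np.isfinite(ft)))

    # -- arc length -------------------------------------------------------
    def _arc_at_t(self, t: float) -> float:
        return float(np.interp(t, self._arc_t, self._arc_s))

    def arc_total(self) -> float:
        return float(self._arc_s[-1])

    # -- projection -------------------------------------------------------
    def _project_interior(self, x: float, y: float) -> tuple[float, float]:
        """(t*, squared distance) of the nearest interior curve point."""
        t0, t1 = self.t_range

        def d2(t):
            px, py = self.xy(np.atleast_1d(t))
            return (px - x) ** 2 + (py - y) ** 2

        tg = np.linspace(t0, t1, PROJ_GRID)
        vals = d2(tg)
        i = int(np.argmin(vals))
        lo = tg[max(i - 1, 0)]
        hi = tg[min(i + 1, PROJ_GRID - 1)]
        if hi > lo:
            res = optimize.minimize_scalar(
                lambda t: float(d2(t)[0]),
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": 1e-12},
            )
            if res.fun <= vals[i]:
                return float(res.x), float(res.fun)
        return float(tg[i]), float(vals[i])

    @staticmethod
    def _project_ray(x, y, x0, y0, sign: int) -> tuple[float, float]:
        """Project onto the slope-1 ray leaving (x0, y0).

        ``sign`` +1 for the upper extension, -1 for the lower.  Returns the
        (clipped) signed offset ``u`` along x and the squared distance.
        """
        u = ((x - x0) + (y - y0)) / 2.0
        u = max(u, 0.0) if sign > 0 else min(u, 0.0)
        dx, dy = x - (x0 + u), y - (y0 + u)
        return u, dx * dx + dy * dy

    def project(self, x: float, y: float) -> tuple[float, float, float, float]:
        """Nearest point on the extended curve.

        Returns ``(px, py, s, dist)`` where ``s`` is the arc-length
        coordinate of the projection (0 at the lower end of the overlap
        region, negative on the lower extension).
        """
        t_star, d2_int = self._project_interior(x, y)
        xl, yl = self.p_lo
        xh, yh = self.p_hi
        u_lo, d2_lo = self._project_ray(x, y, xl, yl, -1)
        u_hi, d2_hi = self._project_ray(x, y, xh, yh, +1)
        best = min(
            (d2_int, 0),
            (d2_lo, 1),
            (d2_hi, 2),
            key=lambda z: z[0],
        )
        if best[1] == 0:
            px, py = self.xy(np.atleast_1d(t_star))
            return float(px[0]), float(py[0]), self._arc_at_t(t_star), float(np.sqrt(d2_int))
        if best[1] == 1:
            return xl + u_lo, yl + u_lo, _SQRT2 * u_lo, float(np.sqrt(d2_lo))
        return (
            xh + u_hi,
            yh + u_hi,
            self.arc_total() + _SQRT2 * u_hi,
            float(np.sqrt(d2_hi)),
        )

    # -- single-coordinate evaluation ------------------------------------
    def _solve_t(self, target: float, coord: str) -> float:
        """Find t with X(t) == target (coord='x') or Y(t) == target."""
        t0, t1 = self.t_range
        tg = np.linspace(t0, t1, ARC_GRID)
        px, py = self.xy(tg)
        vals = px if coord == "x" else py
        # vals is non-decreasing for a monotone curve (up to numerics)
        j = int(np.searchsorted(vals, target))
        j = min(max(j, 1), ARC_GRID - 1)
        a, b = tg[j - 1], tg[j]
        fa = (vals[j - 1] - target)
        fb = (vals[j] - target)
        if fa == 0.0:
            return float(a)
        if fb == 0.0:
            return float(b)
        if fa * fb > 0:
            # target coincides with a flat stretch boundary; nearest end
            return float(a if abs(fa) <= abs(fb) else b)

        def g(t):
            x_, y_ = self.xy(np.atleast_1d(t))
            v = x_[0] if coord == "x" else y_[0]
            return v - target

        return float(optimize.brentq(g, a, b, xtol=1e-13))

    def y_at(self, x: float) -> float:
        """Curve height at ``x``, using the slope-1 extension outside."""
        xl, yl = self.p_lo
        xh, yh = self.p_hi
        if x < xl:
            return yl + (x - xl)
        if x > xh:
            return yh + (x - xh)
        t = self._solve_t(x, "x")
        return float(self.xy(np.atleast_1d(t))[1][0])

    def x_at(self, y: float) -> float:
        """Curve abscissa at height ``y`` (inverse evaluation)."""
        xl, yl = self.p_lo
        xh, yh = self.p_hi
        if y < yl:
            return xl + (y - yl)
        if y > yh:
            return xh + (y - yh)
        # reject inversion through a flat stretch: the level set of y must
        # not span a material x-interval
        tg = np.linspace(self.t_range[0], self.t_range[1], ARC_GRID)
        px, py = self.xy(tg)
        level = np.abs(py - y) <= 1e-9
        if level.any() and (px[level].max() - px[level].min()) > 1e-6:
            raise NonInvertibleSegmentError(
                f"curve is flat at level y={y:.6g}; x is not identified"
            )
        t = self._solve_t(y, "y")
        return float(self.xy(np.atleast_1d(t))[0][0])

    def arc_at_x(self, x: float) -> float:
        """Arc-length coordinate of the on-curve point with abscissa ``x``."""
        xl, _ = self.p_lo
        xh, _ = self.p_hi
        if x < xl:
            return _SQRT2 * (x - xl)
        if x > xh:
            return self.arc_total() + _SQRT2 * (x - xh)
        return self._arc_at_t(self._solve_t(x, "x"))

    def arc_at_y(self, y: float) -> float:
        """Arc-length coordinate of the on-curve point at height ``y``."""
        _, yl = self.p_lo
        _, yh = self.p_hi
        if y < yl:
            return _SQRT2 * (y - yl)
        if y > yh:
            return self.arc_total() + _SQRT2 * (y - yh)
        return self._arc_at_t(self._solve_t(y, "y"))


def compute_md(curve: FittedCurve, xs, ys) -> float:
    """Mean orthogonal distance of the points to the extended curve."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size == 0:
        raise ValueError("empty point set")
    return float(np.mean([curve.project(x, y)[3] for x, y in zip(xs, ys)]))


def project_onto_curve(point, curve: FittedCurve):
    """Project a fully or partially known point onto the extended curve.

    ``point`` is ``(x, y)`` with one entry possibly None.  A common odorant
    (both coordinates) goes to the nearest curve point; an odorant unique
    to the x-side goes to ``(x, f(x))``; unique to the y-side goes to
    ``(f^-1(y), y)``.  Returns ``((px, py), s)`` with ``s`` the arc-length
    coordinate along the extended curve.
    """
    x, y = point
    if x is not None and y is not None:
        px, py, s, _ = curve.project(float(x), float(y))
        return (px, py), s
    if x is not None:
        x = float(x)
        return (x, curve.y_at(x)), curve.arc_at_x(x)
    if y is not None:
        y = float(y)
        return (curve.x_at(y), y), curve.arc_at_y(y)
    raise ValueError("point must have at least one known coordinate")
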