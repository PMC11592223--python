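"""Spine-curve fitting, tangent-point detection, and curvature-type labels.

The five spine landmarks are fitted with a degree-4 polynomial by least
squares.  Photos show the spine near-vertical, so the fit is performed in a
*spine-aligned frame*: the independent variable ``t`` runs cranio-caudally
(the image ``y`` coordinate, pixels, increasing downward) and the dependent
variable ``d`` is the lateral position (the image ``x`` coordinate, pixels).
The strict top-to-bottom ordering of the landmarks guarantees distinct
abscissae, so with exactly five points the least-squares fit interpolates.

The *tangent points* of the fitted curve — apexes where the lateral slope
d'(t) changes sign — determine the coronal curvature type: one apex is a
"C" curve, two an "S" curve, more than two a multi-curve.  Apexes are found
with a sliding-window scan over a dense sample grid, kept only when their
curvature exceeds that of the non-apex samples, and merged when closer than
one window width.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, InconsistentInputError, SingularFitError
from .keypoints import BackKeypoints

DEFAULT_N_SAMPLES = 200
DEFAULT_WINDOW_FRAC = 0.1  # window = length/10 of the sampled curve
DEFAULT_STEP = 2  # sliding-window step, samples


@dataclass
class SpineCurve:
    """Degree-4 polynomial d(t) fitted to the spine landmarks.

    ``coeffs_u`` are ascending-power coefficients in the normalised
    coordinate u = (t - t_min) / (t_max - t_min); fitting on [0, 1] keeps the
    Vandermonde system well conditioned at pixel scales.  ``domain`` is the
    (t_min, t_max) span in pixels; ``residual_ss`` the sum of squared node
    residuals in pixels^2 (~0 for five distinct points, where the fit
    interpolates).
    """

    coeffs_u: np.ndarray
    domain: tuple[float, float]
    n_samples: int = DEFAULT_N_SAMPLES
    residual_ss: float = 0.0

    def __post_init__(self) -> None:
        t0, t1 = self.domain
        if not t0 < t1:
            raise DomainError(f"empty curve domain ({t0}, {t1})")
        if self.n_samples < 20:
            raise DomainError("n_samples must be >= 20")

    @property
    def length(self) -> float:
        return self.domain[1] - self.domain[0]

    def grid(self) -> np.ndarray:
        return np.linspace(self.domain[0], self.domain[1], self.n_samples)

    def coefficients(self) -> np.ndarray:
        """Ascending-power coefficients a0..a4 of d as a polynomial in raw t."""
        # expand a(u) with u = (t - t0)/L via polynomial composition
        t0, L = self.domain[0], self.length
        comp = np.polynomial.polynomial.Polynomial([-t0 / L, 1.0 / L])
        p = np.polynomial.polynomial.Polynomial([0.0])
        for c in self.coeffs_u[::-1]:
            p = p * comp + np.polynomial.polynomial.Polynomial([c])
        out = np.zeros(5)
        out[: len(p.coef)] = p.coef
        return out

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients().tolist(),
            "domain": list(self.domain),
            "n_samples": self.n_samples,
            "residual_ss": self.residual_ss,
        }


@dataclass(frozen=True)
class TangentPoint:
    """A curve apex: position t, direction of the slope sign change, and the
    (absolute) curvature there in 1/pixels."""

    t: float
    slope_change: str  # "pos_to_neg" | "neg_to_pos"
    curvature: float


@dataclass
class CurveTypeResult:
    label: str  # "C" | "S" | "multi"
    tangent_points: list[TangentPoint] = field(default_factory=list)
    window_size: int = 0
    step: int = DEFAULT_STEP
    degenerate: bool = False  # no apex at all: near-straight spine

    def to_dict(self) -> dict:
        d = {
            "label": self.label,
            "degenerate": self.degenerate,
            "tangent_points": [
                {"t": tp.t, "slope_change": tp.slope_change, "curvature": tp.curvature}
                for tp in self.tangent_points
            ],
            "window_size": self.window_size,
            "step": self.step,
        }
        return d


def fit_spine_polynomial(
    kp_or_points, n_samples: int = DEFAULT_N_SAMPLES
) -> SpineCurve:
    """Least-squares degree-4 fit of the five spine landmarks.

    Accepts a :class:`BackKeypoints` or a (5, 2) array of (x, y) pixel pairs
    ordered top to bottom.  With five distinct abscissae the fit is exact
    interpolation; ``residual_ss`` reports the residual sum of squares.
    """
    if isinstance(kp_or_points, BackKeypoints):
        xy = kp_or_points.spine_xy()
    else:
        xy = np.asarray(kp_or_points, dtype=float)
    t = xy[:, 1]
    d = xy[:, 0]
    if len(np.unique(t)) != len(t):
        raise SingularFitError("duplicate spine abscissae (equal y coordinates)")
    t0, t1 = float(t.min()), float(t.max())
    u = (t - t0) / (t1 - t0)
    V = np.vander(u, 5, increasing=True)
    coeffs, *_ = np.linalg.lstsq(V, d, rcond=None)
    resid = d - V @ coeffs
    return SpineCurve(
        coeffs_u=coeffs,
        domain=(t0, t1),
        n_samples=n_samples,
        residual_ss=float(resid @ resid),
    )


def evaluate_curve(curve: SpineCurve, t, order: int = 0):
    """Analytic value (order 0), slope d'(t) (order 1) or d''(t) (order 2).

    ``t`` may be a scalar or array inside the curve domain (a small
    floating-point tolerance is allowed at the ends).
    """
    if order not in (0, 1, 2):
        raise DomainError(f"derivative order must be 0, 1 or 2, got {order}")
    t_arr = np.asarray(t, dtype=float)
    t0, t1 = curve.domain
    tol = 1e-9 * curve.length
    if np.any(t_arr < t0 - tol) or np.any(t_arr > t1 + tol):
        raise DomainError(f"t outside curve domain [{t0}, {t1}]")
    L = curve.length
    u = (t_arr - t0) / L
    c = np.polynomial.polynomial.polyder(curve.coeffs_u, order) if order else curve.coeffs_u
    val = np.polynomial.polynomial.polyval(u, c) / L**order
    return val if np.ndim(t) else float(val)


def _curvature(curve: SpineCurve, t) -> np.ndarray:
    """Absolute plane-curve curvature |d''| / (1 + d'^2)^(3/2), 1/pixels."""
    d1 = evaluate_curve(curve, t, 1)
    d2 = evaluate_curve(curve, t, 2)
    return np.abs(d2) / (1.0 + np.asarray(d1) ** 2) ** 1.5


def detect_tangent_points(
    curve: SpineCurve,
    window_frac: float = DEFAULT_WINDOW_FRAC,
    step: int = DEFAULT_STEP,
) -> list[TangentPoint]:
    """Sliding-window apex detection on the dense sample grid.

    A window of ``round(n_samples * window_frac)`` samples slides by ``step``
    samples; inside each window the analytic slope is inspected and a sample
    where it changes sign is flagged as a candidate apex.  A candidate is
    retained only if its curvature exceeds the median curvature of the
    non-flagged samples, and retained flags closer than one window width are
    merged, keeping the one of highest curvature (lowest t on ties).

    Two geometric-consistency rules follow: a sign change at the very first
    or last grid sample is discarded (its extremum sits at or beyond the
    spine end and cannot anchor a curve segment), and of two consecutive
    retained apexes with the *same* change direction — impossible for real
    adjacent apexes, since a minimum must lie between two maxima — only the
    higher-curvature one is kept.
    """
    n = curve.n_samples
    w = max(3, int(round(n * window_frac)))
    if step < 1:
        raise DomainError("step must be >= 1")
    ts = curve.grid()
    slope = np.asarray(evaluate_curve(curve, ts, 1))
    # slopes below the float-noise floor count as zero so a numerically
    # straight spine yields no sign changes
    sgn = np.sign(np.where(np.abs(slope) <= 1e-8, 0.0, slope))

    candidates: dict[int, str] = {}
    for start in range(0, max(n - w, 0) + 1, step):
        stop = min(start + w, n)
        nz = start + np.nonzero(sgn[start:stop])[0]
        for i, j in zip(nz, nz[1:]):
            if sgn[i] * sgn[j] >= 0:
                continue
            idx = int(i + np.argmin(np.abs(slope[i : j + 1])))
            if idx in (0, n - 1):
                continue  # extremum at/beyond the spine end: not an apex
            direction = "pos_to_neg" if sgn[i] > 0 else "neg_to_pos"
            candidates.setdefault(idx, direction)

    if not candidates:
        return []

    kappa = _curvature(curve, ts)
    flagged = np.array(sorted(candidates), dtype=int)
    non_flagged = np.setdiff1d(np.arange(n), flagged)
    threshold = float(np.median(kappa[non_flagged])) if len(non_flagged) else 0.0
    kept = [i for i in flagged if kappa[i] > threshold]
    if not kept:
        return []

    # merge flags closer than one window width; highest curvature wins,
    # lowest t on exact ties
    merged: list[int] = []
    group = [kept[0]]
    for i in kept[1:]:
        if i - group[-1] < w:
            group.append(i)
        else:
            merged.append(max(group, key=lambda j: (kappa[j], -j)))
            group = [i]
    merged.append(max(group, key=lambda j: (kappa[j], -j)))

    # alternation consistency: two consecutive apexes cannot share a
    # slope-change direction; keep the stronger of such a pair
    alternating: list[int] = []
    for i in merged:
        if alternating and candidates[alternating[-1]] == candidates[i]:
            if kappa[i] > kappa[alternating[-1]]:
                alternating[-1] = i
        else:
            alternating.append(i)
    merged = alternating

    return [
        TangentPoint(t=float(ts[i]), slope_change=candidates[i], curvature=float(kappa[i]))
        for i in sorted(merged)
    ]


def classify_curve_type(
    tangent_points: list[TangentPoint],
    window_size: int = 0,
    step: int = DEFAULT_STEP,
) -> CurveTypeResult:
    """Map the apex count to the coronal curvature type.

    1 apex -> C, 2 -> S, >2 -> multi.  A curve with no apex (near-straight
    spine) has no class of its own in the clinical taxonomy; it is labeled C
    with ``degenerate=True`` so downstream grading can treat the whole domain
    as one segment.
    """
    n = len(tangent_points)
    if n == 0:
        label, degen = "C", True
    elif n == 1:
        label, degen = "C", False
    elif n == 2:
        label, degen = "S", False
    else:
        label, degen = "multi", False
    return CurveTypeResult(
        label=label,
        tangent_points=list(tangent_points),
        window_size=window_size,
        step=step,
        degenerate=degen,
    )


def analyze_curve(
    kp: BackKeypoints,
    n_samples: int = DEFAULT_N_SAMPLES,
    window_frac: float = DEFAULT_WINDOW_FRAC,
    step: int = DEFAULT_STEP,
) -> tuple[SpineCurve, CurveTypeResult]:
    """Fit + apex detection + type classification in one call."""
    curve = fit_spine_polynomial(kp, n_samples=n_samples)
    w = max(3, int(round(n_samples * window_frac)))
    tps = detect_tangent_points(curve, window_frac=window_frac, step=step)
    return curve, classify_curve_type(tps, window_size=w, step=step)


def check_type_consistency(type_result: CurveTypeResult) -> None:
    """Raise when the label contradicts the apex count."""
    n = len(type_result.tangent_points)
    ok = (
        (type_result.label == "C" and (n == 1 or (n == 0 and type_result.degenerate)))
        or (type_result.label == "S" and n == 2)
        or (type_result.label == "multi" and n > 2)
    )
    if not ok:
        raise InconsistentInputError(
            f"label {type_result.label!r} inconsistent with {n} tangent point(s)"
        )
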