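"""Coronal-plane severity: Cobb angle, scapular-triangle asymmetry, fusion.

Two photographic severity indices are computed from the seven back
landmarks and combined by a routing rule:

* **Cobb angle from the fitted curve** — the clinical Cobb angle is the
  included angle between the most-tilted vertebral endplates.  Its
  photographic analogue here takes the fitted lateral-deviation curve d(t),
  splits it at its apex, finds in each half the point of maximum absolute
  slope (the "upper" and "lower" vertebrae), and reports
  ``|atan(m_upper) - atan(m_lower)|`` in degrees.  S- and multi-curves are
  first split at the inflection points of d(t) (zero crossings of d''),
  each convex/concave part is measured by the same rule, and the per-part
  angles are accumulated.
* **Scapular-spine-triangle bottom-angle difference** — the triangle formed
  by the two scapular landmarks and the lowest spine landmark; the absolute
  difference of its two base angles (at the scapular vertices) indexes
  trunk asymmetry.

Both indices map onto the four clinical severity classes
``<10 / 10-19 / 20-44 / >=45`` (degrees Cobb), implemented as the half-open
intervals [0,10), [10,20), [20,45), [45,inf) so every real angle has a
class and ">=45" stays inclusive.  The fusion rule routes C-type curves to
the triangle index (it discriminates single lateral shifts well) and
S/multi curves to the accumulated Cobb index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DegenerateTriangleError, DomainError
from .keypoints import BackKeypoints
from .spine_curve import (
    CurveTypeResult,
    SpineCurve,
    analyze_curve,
    check_type_consistency,
    evaluate_curve,
)

COBB_CLASS_BOUNDS = (10.0, 20.0, 45.0)
CLASS_LABELS = ("<10", "10-19", "20-44", ">=45")
DEFAULT_TRIANGLE_THRESHOLDS = (2.0, 5.0, 10.0)


@dataclass
class CobbSegment:
    t_upper: float
    t_lower: float
    slope_upper: float
    slope_lower: float
    angle: float


@dataclass
class CobbResult:
    total_angle: float
    segments: list[CobbSegment]
    curve_type: str

    def to_dict(self) -> dict:
        return {
            "total_angle": self.total_angle,
            "curve_type": self.curve_type,
            "segments": [vars(s) for s in self.segments],
        }


@dataclass
class TriangleResult:
    base_angle_left: float
    base_angle_right: float
    apex_angle: float

    @property
    def abs_diff(self) -> float:
        return abs(self.base_angle_left - self.base_angle_right)


@dataclass
class SeverityGrade:
    class_index: int
    class_label: str
    method: str  # "cobb" | "triangle" | "fusion"
    score_value: float


# ------------------------------------------------------------------ Cobb


def _max_abs_slope(curve: SpineCurve, a: float, b: float, n: int = 200):
    """Grid point of maximum |d'| on [a, b] (endpoints included exactly)."""
    ts = np.linspace(a, b, n)
    slopes = np.asarray(evaluate_curve(curve, ts, 1))
    i = int(np.argmax(np.abs(slopes)))
    return float(ts[i]), float(slopes[i])


def _inflection_points(curve: SpineCurve) -> list[float]:
    """Zero crossings of d'' on the dense grid, refined by bisection.

    The quartic's second derivative is a quadratic, so there are at most two
    crossings; bisection to 1e-3 of the domain keeps this model-agnostic.
    """
    ts = curve.grid()
    d2 = np.asarray(evaluate_curve(curve, ts, 2))
    roots = []
    tol = 1e-3 * curve.length
    for i in np.nonzero(d2[:-1] * d2[1:] < 0)[0]:
        lo, hi = ts[i], ts[i + 1]
        flo = d2[i]
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            fmid = evaluate_curve(curve, mid, 2)
            if flo * fmid <= 0:
                hi = mid
            else:
                lo, flo = mid, fmid
        roots.append(0.5 * (lo + hi))
    return roots


def _segment_cobb(curve: SpineCurve, a: float, b: float, split: float) -> CobbSegment:
    t_u, m_u = _max_abs_slope(curve, a, split)
    t_l, m_l = _max_abs_slope(curve, split, b)
    angle = abs(math.degrees(math.atan(m_u) - math.atan(m_l)))
    return CobbSegment(t_u, t_l, m_u, m_l, angle)


def cobb_angle(curve: SpineCurve, type_result: CurveTypeResult) -> CobbResult:
    """Cobb angle of the fitted curve, per the segment rule described above.

    For a C curve the domain is split at the apex; for a degenerate
    (apex-free) curve at the midpoint, which yields 0 deg on a straight
    spine.  For S/multi curves each inflection-bounded part is measured by
    the C rule — splitting at the apex the part contains, or its midpoint if
    it has none — and the part angles are summed.
    """
    check_type_consistency(type_result)
    t0, t1 = curve.domain
    apexes = [tp.t for tp in type_result.tangent_points]

    if type_result.label == "C":
        split = apexes[0] if apexes else 0.5 * (t0 + t1)
        segments = [_segment_cobb(curve, t0, t1, split)]
    else:
        cuts = [r for r in _inflection_points(curve) if t0 < r < t1]
        bounds = [t0, *cuts, t1]
        segments = []
        for a, b in zip(bounds, bounds[1:]):
            inside = [x for x in apexes if a <= x <= b]
            split = inside[0] if inside else 0.5 * (a + b)
            segments.append(_segment_cobb(curve, a, b, split))

    total = float(sum(s.angle for s in segments))
    return CobbResult(total_angle=total, segments=segments, curve_type=type_result.label)


# -------------------------------------------------------------- triangle


def triangle_angle_diff(kp: BackKeypoints) -> TriangleResult:
    """Base angles of the scapular spine triangle and their absolute difference.

    Vertices: scapula_left, scapula_right and spine4 (the lowest spine
    landmark, the triangle apex).  The base angles are the interior angles
    at the two scapular vertices, from the law of cosines.
    """
    sl = kp.point("scapula_left")
    sr = kp.point("scapula_right")
    ap = kp.point("spine4")
    A = np.array([sl.x, sl.y])
    B = np.array([sr.x, sr.y])
    C = np.array([ap.x, ap.y])
    ab, ac = B - A, C - A
    area2 = abs(ab[0] * ac[1] - ab[1] * ac[0])
    base = np.linalg.norm(B - A)
    if base == 0 or area2 < 1e-9 * base**2:
        raise DegenerateTriangleError("scapular triangle vertices are collinear")

    def interior(v0, v1, v2):
        u, w = v1 - v0, v2 - v0
        c = float(u @ w / (np.linalg.norm(u) * np.linalg.norm(w)))
        return math.degrees(math.acos(max(-1.0, min(1.0, c))))

    left = interior(A, B, C)
    right = interior(B, A, C)
    return TriangleResult(
        base_angle_left=left, base_angle_right=right, apex_angle=180.0 - left - right
    )


# -------------------------------------------------------------- grading


def _grade(value: float, bounds, method: str) -> SeverityGrade:
    idx = int(np.searchsorted(np.asarray(bounds, float), value, side="right"))
    return SeverityGrade(
        class_index=idx, class_label=CLASS_LABELS[idx], method=method, score_value=value
    )


def grade_from_cobb(angle: float) -> SeverityGrade:
    """Severity class of a Cobb angle: [0,10) -> 0, [10,20) -> 1,
    [20,45) -> 2, [45,inf) -> 3."""
    if angle < 0:
        raise DomainError(f"Cobb angle must be >= 0, got {angle}")
    return _grade(angle, COBB_CLASS_BOUNDS, "cobb")


def grade_from_triangle(
    abs_diff: float, thresholds=DEFAULT_TRIANGLE_THRESHOLDS
) -> SeverityGrade:
    """Severity class of the triangle base-angle difference.

    The three ascending thresholds (degrees) bound the same four half-open
    classes as the Cobb grading; they are configuration, with defaults
    chosen so synthetic cohorts graded by either index land in comparable
    classes.
    """
    t = tuple(float(x) for x in thresholds)
    if len(t) != 3 or not (t[0] < t[1] < t[2]):
        raise ConfigError(f"triangle thresholds must be 3 ascending values, got {t}")
    if abs_diff < 0:
        raise DomainError("triangle angle difference must be >= 0")
    return _grade(abs_diff, t, "triangle")


@dataclass
class FusionReport:
    """Full record of one fused grading: the routing inputs and the grade."""

    grade: SeverityGrade
    curve_type: str
    degenerate: bool
    cobb_deg: float
    triangle_diff_deg: float
    type_result: CurveTypeResult = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "curve_type": self.curve_type,
            "degenerate": self.degenerate,
            "method": self.grade.method,
            "cobb_deg": self.cobb_deg,
            "triangle_diff_deg": self.triangle_diff_deg,
            "class_index": self.grade.class_index,
            "class_label": self.grade.class_label,
        }


def fusion_grade(
    kp: BackKeypoints,
    triangle_thresholds=DEFAULT_TRIANGLE_THRESHOLDS,
    n_samples: int = 200,
    window_frac: float = 0.1,
    step: int = 2,
) -> SeverityGrade:
    """Fused severity grade: C-type backs are graded by the scapular-triangle
    index, S/multi backs by the accumulated Cobb angle."""
    return fusion_report(
        kp, triangle_thresholds=triangle_thresholds,
        n_samples=n_samples, window_frac=window_frac, step=step,
    ).grade


def fusion_report(
    kp: BackKeypoints,
    triangle_thresholds=DEFAULT_TRIANGLE_THRESHOLDS,
    n_samples: int = 200,
    window_frac: float = 0.1,
    step: int = 2,
) -> FusionReport:
    curve, type_result = analyze_curve(
        kp, n_samples=n_samples, window_frac=window_frac, step=step
    )
    cobb = cobb_angle(curve, type_result)
    tri = triangle_angle_diff(kp)
    if type_result.label == "C":
        grade = grade_from_triangle(tri.abs_diff, triangle_thresholds)
    else:
        grade = grade_from_cobb(cobb.total_angle)
    return FusionReport(
        grade=grade,
        curve_type=type_result.label,
        degenerate=type_result.degenerate,
        cobb_deg=cobb.total_angle,
        triangle_diff_deg=tri.abs_diff,
        type_result=type_result,
    )
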