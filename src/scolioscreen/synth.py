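"""Ground-truthed synthetic inputs for every pipeline stage.

Clinical photo sets are private, so validation rests on synthetic cases
whose ground truth is known by construction:

* **Coronal cases** — spine landmarks sampled from the sine family
  ``d(t) = amplitude * L * sin(m * pi * t / L)`` on a spine of length L,
  with m = 1, 2, 3 interior extrema for the C / S / multi archetypes and
  m = 0 for a straight spine.  The interior-extremum count maps one-to-one
  onto the clinical curve taxonomy, giving an unambiguous type label.  The
  five spine landmarks sit at t = {0, 1/4, 1/2, 3/4, 1} * L; scapular
  landmarks are placed symmetrically with configurable asymmetry.  The
  reference Cobb angle applies the same segment rule as the measurement
  path, but in closed form on the degree-4 interpolant of the noiseless
  landmarks (exact polynomial roots and exact slope maximisation), so the
  two routes share no grid, window or detection code.
* **Sagittal cases** — a back-contour profile built as a baseline plus two
  Gaussian bumps whose apex heights differ by exactly
  ``separation * tan(true_atr)``, rasterised into a binary mask by filling
  below the profile.  Bump centres stay ~1/3 of the image width away from
  the borders, outside the scalogram's blind zone near signal edges.

Noise is positional Gaussian jitter on keypoints and Gaussian column-height
jitter on mask borders, expressed in pixels; generators are bit-reproducible
under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .contour import ContourProfile, rasterize_profile
from .errors import ConfigError
from .keypoints import SPINE_LABELS, BackKeypoints, Keypoint

_KIND_TO_M = {"straight": 0, "C": 1, "S": 2, "multi": 3}


@dataclass
class SyntheticCoronalCase:
    keypoints: BackKeypoints
    kind: str  # generator archetype, incl. "straight"
    true_type: str  # expected classifier label ("C" for straight, degenerate)
    true_cobb: float  # degrees, closed form on the noiseless interpolant
    amplitude: float  # fraction of spine length
    noise_sd: float  # pixels
    seed: int


@dataclass
class SyntheticSagittalCase:
    mask: np.ndarray
    profile: ContourProfile  # noiseless float ground truth
    true_atr: float  # degrees
    bump_centers: tuple[float, float]
    bump_widths: tuple[float, float]
    bump_heights: tuple[float, float]
    noise_sd: float
    seed: int


def _case_seed(seed: int, index: int) -> int:
    """Deterministic per-case child seed, kept below 2**31."""
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] & 0x7FFFFFFF)


# ----------------------------------------------------------- coronal truth


def _exact_cobb_from_poly(coeffs_u: np.ndarray, L: float) -> float:
    """Segment-rule Cobb angle of d(t) = p(u), u = t/L, in closed form.

    Apexes are the real roots of p' in [0, 1] and inflections those of p'';
    |slope| maxima over an interval are taken over its endpoints and the
    interior critical points of p'.  Mirrors the measurement rule without
    sharing its sampling grid or detection machinery.
    """
    p = np.polynomial.polynomial.Polynomial(np.asarray(coeffs_u, float))
    d1 = p.deriv()
    d2 = p.deriv(2)

    def real_roots(poly):
        # drop negligible leading coefficients: a ~1e-13 quartic term left
        # over from solving the interpolation system would otherwise wreck
        # the companion-matrix root finder
        poly = poly.trim(tol=1e-9 * max(1.0, np.abs(poly.coef).max()))
        if len(poly.coef) <= 1 or np.allclose(poly.coef, 0):
            return []
        return sorted(
            float(r.real)
            for r in poly.roots()
            if abs(r.imag) < 1e-9 and -1e-9 <= r.real <= 1 + 1e-9
        )

    extrema = real_roots(d1)
    inflections = real_roots(d2)

    def max_abs_slope(a: float, b: float) -> float:
        cands = [a, b] + [x for x in inflections if a < x < b]
        vals = [d1(x) / L for x in cands]
        return vals[int(np.argmax(np.abs(vals)))]

    def segment_angle(a: float, b: float, split: float) -> float:
        mu = max_abs_slope(a, split)
        ml = max_abs_slope(split, b)
        return abs(math.degrees(math.atan(mu) - math.atan(ml)))

    if len(extrema) <= 1:
        split = extrema[0] if extrema else 0.5
        return segment_angle(0.0, 1.0, split)

    cuts = [x for x in inflections if 0.0 < x < 1.0]
    bounds = [0.0, *cuts, 1.0]
    total = 0.0
    for a, b in zip(bounds, bounds[1:]):
        inside = [x for x in extrema if a <= x <= b]
        split = inside[0] if inside else 0.5 * (a + b)
        total += segment_angle(a, b, split)
    return total


def gen_coronal_case(
    kind: str,
    amplitude: float = 0.05,
    spine_length: float = 800.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    scapula_offset_frac: float = 0.22,
    scapula_asym: float = 0.0,
) -> SyntheticCoronalCase:
    """One synthetic standing-photo keypoint set with analytic ground truth.

    ``scapula_offset_frac`` sets the scapulae's lateral distance from the
    spine axis as a fraction of spine length; ``scapula_asym`` lifts the
    left scapula by that many pixels to create trunk asymmetry.
    """
    if kind not in _KIND_TO_M:
        raise ConfigError(f"unknown archetype {kind!r}")
    if not 0.0 <= amplitude <= 0.2:
        raise ConfigError(f"amplitude must be in [0, 0.2], got {amplitude}")
    if spine_length < 100:
        raise ConfigError("spine_length must be >= 100 pixels")
    m = _KIND_TO_M[kind]
    L = float(spine_length)
    rng = np.random.default_rng(seed)

    margin = 0.125 * L
    width = int(round(L))
    height = int(round(L + 2 * margin))
    x0, y0 = width / 2.0, margin

    t = np.array([0.0, 0.25, 0.5, 0.75, 1.0]) * L
    d = amplitude * L * np.sin(m * np.pi * t / L)

    # reference Cobb from the noiseless interpolant, before noise is added
    u = t / L
    V = np.vander(u, 5, increasing=True)
    coeffs_u = np.linalg.solve(V, d)
    true_cobb = 0.0 if m == 0 else _exact_cobb_from_poly(coeffs_u, L)

    xs = x0 + d
    ys = y0 + t
    if noise_sd > 0:
        xs = xs + rng.normal(0.0, noise_sd, size=5)
        for _ in range(100):
            ny = ys + rng.normal(0.0, noise_sd, size=5)
            if np.all(np.diff(ny) > 0):
                ys_noisy = ny
                break
        else:  # pragma: no cover - spacing >> noise in practice
            ys_noisy = np.sort(ys + rng.normal(0.0, noise_sd, size=5))
        ys = ys_noisy
    xs = np.clip(xs, 0, width - 1)
    ys = np.clip(ys, 0, height - 1)

    sc_dx = scapula_offset_frac * L
    sc_y = y0 + 0.2 * L
    scap = [
        Keypoint("scapula_left", float(np.clip(x0 - sc_dx, 0, width - 1)),
                 float(np.clip(sc_y - scapula_asym, 0, height - 1))),
        Keypoint("scapula_right", float(np.clip(x0 + sc_dx, 0, width - 1)),
                 float(np.clip(sc_y, 0, height - 1))),
    ]
    points = [
        Keypoint(lab, float(xs[i]), float(ys[i])) for i, lab in enumerate(SPINE_LABELS)
    ] + scap
    kp = BackKeypoints(
        points=points,
        image_width=width,
        image_height=height,
        source_id=f"synthetic/{kind}/amp={amplitude:g}/seed={seed}",
    )
    return SyntheticCoronalCase(
        keypoints=kp,
        kind=kind,
        true_type="C" if kind == "straight" else kind,
        true_cobb=float(true_cobb),
        amplitude=float(amplitude),
        noise_sd=float(noise_sd),
        seed=int(seed),
    )


def gen_cohort(
    n_per_class: int = 100,
    noise_sd: float = 0.0,
    seed: int = 0,
    amplitudes=None,
    kinds: tuple[str, ...] = ("C", "S", "multi"),
    spine_length: float = 800.0,
) -> list[SyntheticCoronalCase]:
    """Balanced cohort over the archetypes with a declared amplitude grid.

    Amplitudes default to ``linspace(0.01, 0.15, n_per_class)`` (1-15% of
    spine length); per-case seeds derive deterministically from ``seed``.
    """
    if n_per_class < 1:
        raise ConfigError("n_per_class must be >= 1")
    amps = (
        np.linspace(0.01, 0.15, n_per_class)
        if amplitudes is None
        else np.asarray(amplitudes, float)
    )
    cases = []
    idx = 0
    for kind in kinds:
        for i in range(n_per_class):
            cases.append(
                gen_coronal_case(
                    kind,
                    amplitude=float(amps[i % len(amps)]),
                    spine_length=spine_length,
                    noise_sd=noise_sd,
                    seed=_case_seed(seed, idx),
                )
            )
            idx += 1
    return cases


# ----------------------------------------------------------------- sagittal


def gen_sagittal_case(
    true_atr: float,
    image_size: tuple[int, int] = (640, 400),
    separation: float = 200.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    bump_sigma: float = 45.0,
    baseline: float = 140.0,
    bump_height: float = 90.0,
) -> SyntheticSagittalCase:
    """One synthetic bent-back mask with known trunk rotation.

    The profile is ``baseline + h1 * G(c - c1) + h2 * G(c - c2)`` with
    Gaussian bumps G of scale ``bump_sigma`` centred ``separation`` pixels
    apart around the image midline; ``h1``/``h2`` are raised and lowered
    symmetrically about ``bump_height`` so the *apex* heights (including
    each bump's tail under the other) differ by exactly
    ``separation * tan(true_atr)``.  The mask fills the area below the
    profile; ``noise_sd`` adds Gaussian jitter to each column height before
    rasterisation (border-pixel noise).
    """
    W, H = int(image_size[0]), int(image_size[1])
    if not 0.0 <= true_atr < 45.0:
        raise ConfigError("true_atr must be in [0, 45) degrees")
    if separation < W / 5:
        raise ConfigError("separation must be at least image width / 5")
    rng = np.random.default_rng(seed)

    c1 = W / 2.0 - separation / 2.0
    c2 = W / 2.0 + separation / 2.0
    g = math.exp(-(separation**2) / (2.0 * bump_sigma**2))
    dh = separation * math.tan(math.radians(true_atr))
    # rotation lifts one scapula and lowers the other about the midline, so
    # the apex offset is split symmetrically across the two bumps
    h1 = bump_height + dh / (2.0 * (1.0 - g))
    h2 = bump_height - dh / (2.0 * (1.0 - g))
    if h2 < 5.0:
        raise ConfigError(
            "bumps not resolvable: requested rotation flattens the lower bump"
        )

    cols = np.arange(W, dtype=float)
    prof = (
        baseline
        + h1 * np.exp(-((cols - c1) ** 2) / (2.0 * bump_sigma**2))
        + h2 * np.exp(-((cols - c2) ** 2) / (2.0 * bump_sigma**2))
    )
    if prof.max() >= H - 1:
        raise ConfigError("profile exceeds image height")

    noisy = prof if noise_sd == 0 else prof + rng.normal(0.0, noise_sd, size=W)
    mask = rasterize_profile(np.clip(noisy, 0, H), H)

    return SyntheticSagittalCase(
        mask=mask,
        profile=ContourProfile(
            heights=prof.copy(), valid_mask=np.ones(W, bool), source_operator="synthetic"
        ),
        true_atr=float(true_atr),
        bump_centers=(c1, c2),
        bump_widths=(bump_sigma, bump_sigma),
        bump_heights=(h1 + h2 * g, h2 + h1 * g),
        noise_sd=float(noise_sd),
        seed=int(seed),
    )
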