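"""Back-keypoint domain types, file I/O, and the OKS similarity metric.

Coordinate convention (used throughout the package): image pixel frame,
origin at the top-left corner, ``x`` rightward, ``y`` downward, 0-based.
"Higher on the back" therefore means *smaller* ``y``.  All angles elsewhere
in the package are reported in degrees.

A standing back photo is annotated with seven landmarks: five points along
the spine ordered cranio-caudally (``spine0`` topmost .. ``spine4``
bottommost, serial numbers 0-4) and the two scapular prominences
(``scapula_left``/``scapula_right``, serial numbers 5-6).  Any keypoint
detector that emits the JSON/CSV schema below can feed the pipeline; none is
bundled.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import SchemaError, UndefinedMetricError

SPINE_LABELS = ("spine0", "spine1", "spine2", "spine3", "spine4")
SCAPULA_LABELS = ("scapula_left", "scapula_right")
ALL_LABELS = SPINE_LABELS + SCAPULA_LABELS


@dataclass(frozen=True)
class Keypoint:
    label: str
    x: float
    y: float
    visible: bool = True


@dataclass
class BackKeypoints:
    """The 7 labeled pixel coordinates of one standing back photo.

    Invariants (enforced on construction):

    * exactly one point per label in :data:`ALL_LABELS`;
    * every visible point lies inside the image;
    * the five spine points are strictly monotone in ``y``
      (``spine0`` topmost, ``spine4`` bottommost).
    """

    points: list[Keypoint]
    image_width: int
    image_height: int
    source_id: str = ""
    _by_label: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        seen: dict[str, Keypoint] = {}
        for p in self.points:
            if p.label not in ALL_LABELS:
                raise SchemaError(f"unknown label {p.label!r}")
            if p.label in seen:
                raise SchemaError(f"duplicate label {p.label}")
            seen[p.label] = p
        for label in ALL_LABELS:
            if label not in seen:
                raise SchemaError(f"missing label {label}")
        for p in self.points:
            if p.visible and not (
                0 <= p.x < self.image_width and 0 <= p.y < self.image_height
            ):
                raise SchemaError(
                    f"point {p.label} at ({p.x}, {p.y}) outside "
                    f"{self.image_width}x{self.image_height} image"
                )
        ys = [seen[label].y for label in SPINE_LABELS]
        if not all(a < b for a, b in zip(ys, ys[1:])):
            raise SchemaError(
                "spine points not strictly monotone top-to-bottom: "
                f"y = {ys}"
            )
        object.__setattr__(self, "_by_label", seen)

    def point(self, label: str) -> Keypoint:
        return self._by_label[label]

    def spine_xy(self) -> np.ndarray:
        """(5, 2) array of spine coordinates, ordered spine0..spine4."""
        return np.array(
            [[self._by_label[lab].x, self._by_label[lab].y] for lab in SPINE_LABELS],
            dtype=float,
        )

    def xy(self) -> np.ndarray:
        """(7, 2) array in canonical label order."""
        return np.array(
            [[self._by_label[lab].x, self._by_label[lab].y] for lab in ALL_LABELS],
            dtype=float,
        )

    def visibility(self) -> np.ndarray:
        return np.array(
            [self._by_label[lab].visible for lab in ALL_LABELS], dtype=bool
        )

    def translated(self, dx: float, dy: float) -> "BackKeypoints":
        """Rigidly translated copy (image bounds grown to keep points inside)."""
        pts = [replace(p, x=p.x + dx, y=p.y + dy) for p in self.points]
        return BackKeypoints(
            points=pts,
            image_width=int(math.ceil(self.image_width + max(dx, 0) + 1)),
            image_height=int(math.ceil(self.image_height + max(dy, 0) + 1)),
            source_id=self.source_id,
        )

    # ---------------------------------------------------------------- I/O

    def to_dict(self) -> dict:
        return {
            "image": {"width": self.image_width, "height": self.image_height},
            "source_id": self.source_id,
            "points": [
                {"label": p.label, "x": p.x, "y": p.y, "visible": p.visible}
                for p in self.points
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BackKeypoints":
        try:
            image = d["image"]
            pts = [
                Keypoint(
                    label=str(q["label"]),
                    x=float(q["x"]),
                    y=float(q["y"]),
                    visible=bool(q.get("visible", True)),
                )
                for q in d["points"]
            ]
            return cls(
                points=pts,
                image_width=int(image["width"]),
                image_height=int(image["height"]),
                source_id=str(d.get("source_id", "")),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"malformed keypoint record: {exc}") from exc


def save_keypoints(kp: BackKeypoints, path, format: str = "json") -> None:
    if format == "json":
        with open(path, "w") as fh:
            json.dump(kp.to_dict(), fh, indent=2)
    elif format == "csv":
        rows = [
            {"label": p.label, "x": p.x, "y": p.y, "visible": p.visible}
            for p in kp.points
        ]
        df = pd.DataFrame(rows)
        df.attrs = {}
        # image dims ride along as commented header lines
        with open(path, "w") as fh:
            fh.write(f"# image_width={kp.image_width}\n")
            fh.write(f"# image_height={kp.image_height}\n")
            df.to_csv(fh, index=False)
    else:
        raise SchemaError(f"unknown keypoint format {format!r}")


def load_keypoints(path, format: str | None = None) -> BackKeypoints:
    """Load and validate a keypoint file (JSON schema or CSV alternative).

    The format is inferred from the extension when not given.  Any schema
    violation raises :class:`~scolioscreen.errors.SchemaError` naming the
    offending field.
    """
    fmt = format
    if fmt is None:
        fmt = "csv" if str(path).lower().endswith(".csv") else "json"
    if fmt == "json":
        try:
            with open(path) as fh:
                d = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"invalid JSON in {path}: {exc}") from exc
        return BackKeypoints.from_dict(d)
    if fmt == "csv":
        width = height = None
        with open(path) as fh:
            lines = fh.readlines()
        body = []
        for line in lines:
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                if key.strip() == "image_width":
                    width = int(val)
                elif key.strip() == "image_height":
                    height = int(val)
            else:
                body.append(line)
        if width is None or height is None:
            raise SchemaError("CSV missing image_width/image_height header")
        from io import StringIO

        df = pd.read_csv(StringIO("".join(body)))
        for col in ("label", "x", "y"):
            if col not in df.columns:
                raise SchemaError(f"CSV missing column {col}")
        pts = [
            Keypoint(
                label=str(r["label"]),
                x=float(r["x"]),
                y=float(r["y"]),
                visible=bool(r["visible"]) if "visible" in df.columns else True,
            )
            for _, r in df.iterrows()
        ]
        return BackKeypoints(points=pts, image_width=width, image_height=height)
    raise SchemaError(f"unknown keypoint format {fmt!r}")


# ------------------------------------------------------------------- OKS


@dataclass
class KeypointMatch:
    """A predicted/reference keypoint pairing with the pieces of the OKS sum.

    ``distances`` are per-point Euclidean pixel distances d_n, ``scale`` the
    object scale s in pixels, ``weights`` the per-point constants k_n and
    ``visible`` the reference visibility indicators v_n.
    """

    predicted: BackKeypoints
    actual: BackKeypoints
    distances: np.ndarray
    scale: float
    weights: np.ndarray
    visible: np.ndarray

    @classmethod
    def build(
        cls,
        predicted: BackKeypoints,
        actual: BackKeypoints,
        scale: float | None = None,
        weights=None,
    ) -> "KeypointMatch":
        """Pair two annotations.

        ``scale`` defaults to the bounding-box diagonal of the reference
        points and ``weights`` to 1 for every point; both are configurable
        because no canonical values exist for back landmarks.
        """
        pxy, axy = predicted.xy(), actual.xy()
        d = np.linalg.norm(pxy - axy, axis=1)
        vis = actual.visibility()
        if scale is None:
            vxy = axy[vis] if vis.any() else axy
            span = vxy.max(axis=0) - vxy.min(axis=0)
            scale = float(np.hypot(*span))
        if scale <= 0:
            raise UndefinedMetricError("OKS scale must be positive")
        w = np.ones(len(ALL_LABELS)) if weights is None else np.asarray(weights, float)
        if w.shape != (len(ALL_LABELS),) or (w <= 0).any():
            raise UndefinedMetricError("OKS weights must be 7 positive values")
        return cls(predicted, actual, d, float(scale), w, vis)


def compute_oks(match: KeypointMatch) -> float:
    """Object keypoint similarity in [0, 1].

    OKS = sum_n exp(-d_n^2 / (2 s^2 k_n^2)) [v_n > 0] / sum_n [v_n > 0],
    the visibility-weighted mean of per-point Gaussian agreement terms;
    1 - OKS is the keypoint loss.  Raises if no reference point is visible.
    """
    v = match.visible
    if not v.any():
        raise UndefinedMetricError("OKS undefined: no visible reference point")
    d = match.distances[v]
    k = match.weights[v]
    terms = np.exp(-(d**2) / (2.0 * match.scale**2 * k**2))
    return float(terms.sum() / v.sum())
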