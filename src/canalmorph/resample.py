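"""Arc-length resampling of canal centrelines into an anchored semilandmark scheme.

The semicircular-canal system is digitised as four centreline curves — the
anterior, posterior and lateral canals plus the crus commune — anchored at five
fixed junction landmarks.  Each canal is resampled to a fixed number of
equally-spaced (by arc length) sliding semilandmarks; the crus commune receives
a smaller number.  With the default counts (28 per canal, 3 for the crus,
5 anchors) the assembled configuration has 92 landmarks.

Arc length is measured on the piecewise-linear polyline joining the digitised
points; no spline is fitted, so resampling is deterministic and invariant to
refinement of the input polyline.

Landmark ordering of an assembled configuration (stable, documented):

    0–4                anchors, in ``ANCHOR_LABELS`` order
    5 … 4+n_canal      anterior-canal semilandmarks (vestibule -> crus apex)
    …                  posterior-canal semilandmarks (vestibule -> crus apex)
    …                  lateral-canal semilandmarks (anterior -> posterior end)
    last n_crus        crus-commune semilandmarks (apex -> vestibule base)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

CURVE_NAMES = ("anterior", "posterior", "lateral", "crus")

#: Anchor landmarks, in configuration order.
ANCHOR_LABELS = (
    "ant_vestibule",   # anterior canal / lateral canal junction at the vestibule
    "post_vestibule",  # posterior canal junction at the vestibule
    "lat_posterior",   # posterior end of the lateral canal
    "crus_apex",       # junction of anterior and posterior canals with the crus
    "crus_base",       # crus commune junction with the vestibule
)

#: Which anchors each curve must start and end on.
CURVE_ENDPOINTS = {
    "anterior": ("ant_vestibule", "crus_apex"),
    "posterior": ("post_vestibule", "crus_apex"),
    "lateral": ("ant_vestibule", "lat_posterior"),
    "crus": ("crus_apex", "crus_base"),
}


class DegenerateCurveError(ValueError):
    """Raised for curves with zero total arc length."""


@dataclass
class CentrelineCurve:
    """An ordered 3D polyline through the lumen of one canal segment (mm)."""

    name: str
    points: np.ndarray  # (m, 3)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"curve {self.name!r}: points must be (m, 3)")
        if len(self.points) < 2:
            raise ValueError(f"curve {self.name!r}: need at least 2 points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError(f"curve {self.name!r}: non-finite coordinates")

    @property
    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class SlidingScheme:
    """Fixed anchors vs sliding curve semilandmarks of a configuration.

    ``curves`` maps a curve name to (semilandmark indices in curve order,
    (start anchor index, end anchor index)).  Indices refer to rows of the
    assembled configuration.
    """

    fixed_indices: tuple[int, ...]
    curves: list[tuple[str, tuple[int, ...], tuple[int, int]]] = field(
        default_factory=list
    )

    @property
    def sliding_indices(self) -> tuple[int, ...]:
        out: list[int] = []
        for _, idx, _ in self.curves:
            out.extend(idx)
        return tuple(out)

    @property
    def n_landmarks(self) -> int:
        return len(self.fixed_indices) + len(self.sliding_indices)

    def tangent_directions(self, coords: np.ndarray) -> dict[int, np.ndarray]:
        """Unit tangent per sliding landmark, by centred finite differences.

        Neighbours along each curve include the curve's anchor endpoints, so
        semilandmarks adjacent to an anchor use the anchor as one neighbour.
        """
        coords = np.asarray(coords, dtype=float)
        tangents: dict[int, np.ndarray] = {}
        for _name, idx, (a0, a1) in self.curves:
            chain = [a0, *idx, a1]
            for j, lm in enumerate(idx, start=1):
                t = coords[chain[j + 1]] - coords[chain[j - 1]]
                nrm = np.linalg.norm(t)
                if nrm < 1e-30:
                    t = np.zeros(3)
                else:
                    t = t / nrm
                tangents[lm] = t
        return tangents

    def to_json(self, path) -> None:
        obj = {
            "fixed_indices": list(self.fixed_indices),
            "curves": [
                {"name": n, "indices": list(i), "anchors": list(a)}
                for n, i, a in self.curves
            ],
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SlidingScheme":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            fixed_indices=tuple(obj["fixed_indices"]),
            curves=[
                (c["name"], tuple(c["indices"]), tuple(c["anchors"]))
                for c in obj["curves"]
            ],
        )


def arc_length_resample(curve: CentrelineCurve, n: int) -> np.ndarray:
    """Resample a polyline to ``n`` points equally spaced by arc length.

    The first and last output points are the input endpoints exactly; the
    spacing between consecutive output points along the input polyline is
    total_length / (n - 1).
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    pts = curve.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = float(seg.sum())
    if total <= 0.0:
        raise DegenerateCurveError(
            f"curve {curve.name!r} has zero arc length (all points coincident)"
        )
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, total, n)
    out = np.empty((n, 3))
    for c in range(3):
        out[:, c] = np.interp(targets, cum, pts[:, c])
    out[0] = pts[0]
    out[-1] = pts[-1]
    return out


def assemble_configuration(
    anterior: CentrelineCurve,
    posterior: CentrelineCurve,
    lateral: CentrelineCurve,
    crus: CentrelineCurve,
    anchors: dict[str, np.ndarray],
    n_canal: int = 28,
    n_crus: int = 3,
    snap_tol_factor: float = 1e-6,
):
    """Resample the four centreline curves into one landmark configuration.

    Each curve is resampled to ``n + 2`` equally spaced points; the two
    endpoints are snapped onto their designated anchors (they must lie within
    ``snap_tol_factor * curve arc length`` of them) and the ``n`` interior
    points become sliding semilandmarks.  Returns ``(coords, scheme)`` where
    coords is the (k, 3) configuration, k = 3 * n_canal + n_crus + 5.
    """
    from .io import LandmarkConfiguration  # local import to avoid a cycle

    curves = {
        "anterior": anterior,
        "posterior": posterior,
        "lateral": lateral,
        "crus": crus,
    }
    missing = set(ANCHOR_LABELS) - set(anchors)
    if missing:
        raise ValueError(f"missing anchors: {sorted(missing)}")
    anchor_xyz = {k: np.asarray(anchors[k], dtype=float) for k in ANCHOR_LABELS}

    counts = {"anterior": n_canal, "posterior": n_canal, "lateral": n_canal,
              "crus": n_crus}
    blocks: dict[str, np.ndarray] = {}
    for name, curve in curves.items():
        a_start, a_end = CURVE_ENDPOINTS[name]
        tol = snap_tol_factor * curve.arc_length
        for end, label in ((curve.points[0], a_start), (curve.points[-1], a_end)):
            d = float(np.linalg.norm(end - anchor_xyz[label]))
            if d > tol:
                raise ValueError(
                    f"curve {name!r} endpoint is {d:.3g} from anchor "
                    f"{label!r}, beyond snap tolerance {tol:.3g}"
                )
        res = arc_length_resample(curve, counts[name] + 2)
        res[0] = anchor_xyz[a_start]
        res[-1] = anchor_xyz[a_end]
        blocks[name] = res

    k = 3 * n_canal + n_crus + 5
    coords = np.empty((k, 3))
    for i, label in enumerate(ANCHOR_LABELS):
        coords[i] = anchor_xyz[label]
    anchor_index = {label: i for i, label in enumerate(ANCHOR_LABELS)}

    scheme_curves = []
    pos = 5
    for name in ("anterior", "posterior", "lateral", "crus"):
        n = counts[name]
        idx = tuple(range(pos, pos + n))
        coords[pos:pos + n] = blocks[name][1:-1]
        a0, a1 = CURVE_ENDPOINTS[name]
        scheme_curves.append((name, idx, (anchor_index[a0], anchor_index[a1])))
        pos += n

    scheme = SlidingScheme(fixed_indices=tuple(range(5)), curves=scheme_curves)
    config = LandmarkConfiguration(specimen_id="assembled", coords=coords)
    return config, scheme
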