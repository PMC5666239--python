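"""Generalized Procrustes analysis with bending-energy sliding semilandmarks.

Configurations are translated to the origin, scaled to unit centroid size
(full Procrustes) and rotated to an iteratively updated consensus.  When a
:class:`~canalmorph.resample.SlidingScheme` is supplied, each GPA iteration
first lets the semilandmarks slide along their local tangent directions so as
to minimise the thin-plate-spline bending energy between each specimen and the
current consensus; anchors never move.  The 3D TPS kernel is U(r) = -r, the
conditionally positive definite choice used by mainstream 3D morphometrics
software, so bending-energy values are comparable across tools.

After convergence every aligned configuration is rotated into a canonical
frame derived from the consensus' principal axes, which makes the output
invariant (to numerical tolerance) to arbitrary rigid motions and scalings of
the inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import LandmarkConfiguration, ShapeDataset
from .resample import SlidingScheme

logger = logging.getLogger(__name__)


class DegenerateConfigurationError(ValueError):
    pass


def centroid_size(coords: np.ndarray) -> float:
    """Square root of the summed squared landmark distances from the centroid."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 3:
        raise ValueError("need a (k >= 3, d) coordinate array")
    centred = coords - coords.mean(axis=0)
    cs = float(np.sqrt((centred ** 2).sum()))
    if cs <= 0.0:
        raise DegenerateConfigurationError("all landmarks coincide; CS = 0")
    return cs


def optimal_rotation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Proper rotation R (det = +1) minimising ||A @ R - B||_F for centred A, B.

    Reflections are forbidden: if the unconstrained optimum is a reflection the
    smallest singular direction is sign-flipped.
    """
    H = A.T @ B
    U, _s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    if d == 0:  # rank-deficient cross-covariance: fall back to +1
        d = 1.0
    D = np.diag([1.0] * (H.shape[0] - 1) + [d])
    return U @ D @ Vt


def bending_energy_matrix(reference: np.ndarray | LandmarkConfiguration) -> np.ndarray:
    """k x k TPS bending-energy matrix of a 3D reference configuration.

    Symmetric PSD; its null space contains all affine functions of the
    reference coordinates, so affine deformations cost zero energy.
    """
    ref = reference.coords if isinstance(reference, LandmarkConfiguration) else reference
    ref = np.asarray(ref, dtype=float)
    k = ref.shape[0]
    diff = ref[:, None, :] - ref[None, :, :]
    r = np.linalg.norm(diff, axis=2)
    off = r + np.eye(k)
    if off.min() < 1e-12 * max(r.max(), 1.0):
        i, j = np.unravel_index(np.argmin(off), off.shape)
        raise np.linalg.LinAlgError(
            f"TPS system singular: landmarks {i} and {j} are (near-)duplicates"
        )
    K = -r  # 3D thin-plate kernel U(r) = -r (conditionally positive definite)
    Q = np.hstack([np.ones((k, 1)), ref])
    L = np.zeros((k + 4, k + 4))
    L[:k, :k] = K
    L[:k, k:] = Q
    L[k:, :k] = Q.T
    try:
        Linv = np.linalg.inv(L)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"TPS system singular: {exc}") from exc
    Be = Linv[:k, :k]
    return 0.5 * (Be + Be.T)


def bending_energy(be: np.ndarray, displacement: np.ndarray) -> float:
    """TPS bending energy trace(V' Be V) of a k x 3 displacement field."""
    return float(np.einsum("ki,kl,li->", displacement, be, displacement))


def slide_semilandmarks(
    coords: np.ndarray,
    reference: np.ndarray,
    scheme: SlidingScheme,
    be: np.ndarray | None = None,
) -> np.ndarray:
    """Slide semilandmarks along their tangents to minimise bending energy.

    Solves the tangent-restricted generalized least-squares problem in closed
    form: with one sliding amount t_i per semilandmark along its unit tangent
    u_i, the bending energy of (coords + slide - reference) is quadratic in t
    and the minimiser solves a linear system.  Anchors are untouched, and the
    post-slide energy never exceeds the pre-slide energy (t = 0 is feasible;
    if the solve is unreliable the slide falls back to zero, logged).
    """
    coords = np.asarray(coords, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if be is None:
        be = bending_energy_matrix(reference)
    tangents = scheme.tangent_directions(coords)
    idx = np.array(sorted(tangents), dtype=int)
    U = np.stack([tangents[i] for i in idx])  # (m, 3)
    V = coords - reference
    A = (U @ U.T) * be[np.ix_(idx, idx)]
    g = np.einsum("mi,mi->m", U, (be @ V)[idx])
    try:
        t = np.linalg.solve(A, -g)
    except np.linalg.LinAlgError:
        logger.warning("sliding system singular; using minimum-norm solution")
        t = np.linalg.lstsq(A, -g, rcond=None)[0]
    out = coords.copy()
    out[idx] += t[:, None] * U
    # guaranteed descent check: fall back to no slide on numerical failure
    if bending_energy(be, out - reference) > bending_energy(be, V) + 1e-12:
        logger.warning("sliding did not reduce bending energy; slide skipped")
        return coords.copy()
    return out


@dataclass
class AlignedShapes:
    """Procrustes-aligned coordinates with consensus and centroid sizes."""

    aligned: np.ndarray          # (n, k, 3) unit-CS aligned configurations
    consensus: np.ndarray        # (k, 3), unit centroid size
    centroid_sizes: np.ndarray   # (n,), in original units (mm)
    ids: list[str]
    iterations_used: int
    converged: bool
    slid: bool

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def k(self) -> int:
        return self.aligned.shape[1]

    @property
    def flat(self) -> np.ndarray:
        """Aligned coordinates flattened to (n, 3k); the shape variables."""
        return self.aligned.reshape(self.n, -1)

    @property
    def residuals(self) -> np.ndarray:
        """Aligned coordinates minus consensus, flattened to (n, 3k)."""
        return self.flat - self.consensus.reshape(1, -1)


def _center_scale(coords: np.ndarray) -> tuple[np.ndarray, float]:
    c = coords - coords.mean(axis=0)
    cs = float(np.sqrt((c ** 2).sum()))
    if cs <= 0:
        raise DegenerateConfigurationError("all landmarks coincide")
    return c / cs, cs


def _canonical_frame(consensus: np.ndarray) -> np.ndarray:
    """Deterministic proper rotation sending the consensus to principal axes.

    Axis signs are fixed by the largest-magnitude projection; guards output
    determinism against the arbitrary orientation of the first specimen.
    """
    cov = consensus.T @ consensus
    w, P = np.linalg.eigh(cov)
    P = P[:, ::-1]  # descending variance
    proj = consensus @ P
    for j in range(3):
        col = proj[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            P[:, j] = -P[:, j]
    if np.linalg.det(P) < 0:
        P[:, 2] = -P[:, 2]
    return P


def gpa(
    dataset: ShapeDataset | list[LandmarkConfiguration] | np.ndarray,
    scheme: SlidingScheme | None = None,
    slide: bool = False,
    max_iter: int = 10,
    tol: float = 1e-8,
) -> AlignedShapes:
    """Generalized Procrustes alignment, optionally with sliding semilandmarks.

    Iterates centre/scale/rotate-to-consensus with consensus recomputation
    until the consensus changes by less than ``tol`` (Frobenius norm).  With
    ``slide=True`` (requires a scheme) one bending-energy sliding pass against
    the current consensus runs each iteration before the consensus update.
    """
    if isinstance(dataset, ShapeDataset):
        arr = dataset.coords_array()
        ids = dataset.ids
        if scheme is None:
            scheme = dataset.scheme
    elif isinstance(dataset, np.ndarray):
        arr = np.asarray(dataset, dtype=float)
        ids = [f"specimen_{i}" for i in range(arr.shape[0])]
    else:
        arr = np.stack([c.coords for c in dataset])
        ids = [c.specimen_id for c in dataset]
    n = arr.shape[0]
    if n < 2:
        raise ValueError("GPA needs at least 2 configurations")
    if slide and scheme is None:
        raise ValueError("slide=True requires a SlidingScheme")

    X0 = np.empty_like(arr, dtype=float)
    cs = np.empty(n)
    for i in range(n):
        X0[i], cs[i] = _center_scale(arr[i])

    # Sliding always restarts from the pristine configurations against the
    # current consensus: re-sliding already-slid points lets semilandmarks
    # drift along their curves indefinitely (the bending-energy criterion is
    # nearly indifferent to a common along-curve reparametrization).
    X = X0.copy()
    consensus, _ = _center_scale(X0[0].copy())
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(n):
            X[i] = X0[i] @ optimal_rotation(X0[i], consensus)
        if slide:
            be = bending_energy_matrix(consensus)
            rotated = X.copy()
            for i in range(n):
                X[i] = slide_semilandmarks(X[i], consensus, scheme, be)
            # remove the common sliding displacement: it is a pure
            # reparametrization of the consensus along the curves, carries no
            # shape information, and left in place it makes the consensus
            # drift by ~1e-3 per iteration instead of converging
            X -= (X - rotated).mean(axis=0)
            for i in range(n):
                X[i], _ = _center_scale(X[i])
                X[i] = X[i] @ optimal_rotation(X[i], consensus)
        new_consensus, _ = _center_scale(X.mean(axis=0))
        change = float(np.linalg.norm(new_consensus - consensus))
        consensus = new_consensus
        if change < tol:
            converged = True
            break
    if not converged:
        logger.warning("GPA did not converge in %d iterations", max_iter)

    # final rotation pass to the converged consensus, then canonical frame
    for i in range(n):
        X[i] = X[i] @ optimal_rotation(X[i], consensus)
    P = _canonical_frame(consensus)
    consensus = consensus @ P
    for i in range(n):
        X[i] = X[i] @ P

    return AlignedShapes(
        aligned=X,
        consensus=consensus,
        centroid_sizes=cs,
        ids=list(ids),
        iterations_used=it,
        converged=converged,
        slid=bool(slide),
    )


def opa_fit(coords: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Ordinary Procrustes fit (centre, unit-scale, rotate) onto a reference."""
    x, _ = _center_scale(np.asarray(coords, dtype=float))
    ref = np.asarray(reference, dtype=float)
    refc = ref - ref.mean(axis=0)
    return x @ optimal_rotation(x, refc)


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Full Procrustes distance between two configurations (pairwise GPA)."""
    res = gpa(np.stack([np.asarray(a, float), np.asarray(b, float)]), max_iter=50,
              tol=1e-12)
    return float(np.linalg.norm(res.aligned[0] - res.aligned[1]))
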