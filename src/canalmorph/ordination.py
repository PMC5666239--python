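"""Ordination of shape variables: PCA, shape warps, out-of-sample projection,
phylomorphospace, and per-axis group separation tests.

PCA is computed by singular value decomposition of the column-centred shape
matrix.  Eigenvector signs follow a fixed convention (the largest-magnitude
loading of each axis is positive) so outputs are deterministic across
platforms.  Out-of-sample specimens (fossils) are ordinary-Procrustes fitted
to the training consensus — centre, unit scale, rotate, no sliding — and then
projected by matrix multiplication with the eigenvectors, mirroring how
specimens excluded from the eigendecomposition are placed into an existing
morphospace.

The phylomorphospace places internal tree nodes at their maximum-likelihood
(GLS) ancestral estimates under Brownian motion, computed per axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .superimpose import AlignedShapes, opa_fit


@dataclass
class PCAModel:
    mean: np.ndarray          # (p,)
    eigenvectors: np.ndarray  # (p, m), orthonormal columns
    eigenvalues: np.ndarray   # (m,), descending
    scores: np.ndarray        # (n, m)
    ids: list[str]

    @property
    def variance_fractions(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()

    @property
    def n_axes(self) -> int:
        return self.eigenvectors.shape[1]


def pca(aligned: AlignedShapes | np.ndarray, ids: list[str] | None = None,
        rank_tol: float = 1e-10) -> PCAModel:
    """PCA of shape variables; axes ordered by decreasing eigenvalue.

    Near-zero axes (singular value below ``rank_tol`` x the largest) are
    dropped; for Procrustes-aligned 3D data at most min(n - 1, 3k - 7) axes
    carry variance.
    """
    if isinstance(aligned, AlignedShapes):
        X = aligned.flat
        ids = aligned.ids
    else:
        X = np.asarray(aligned, dtype=float)
        ids = ids or [f"specimen_{i}" for i in range(X.shape[0])]
    n = X.shape[0]
    if n < 3:
        raise ValueError("PCA needs at least 3 specimens")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    keep = s > rank_tol * max(s[0], 1e-300)
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    axes = Vt.T
    scores = U * s
    # deterministic sign convention: largest-magnitude loading positive
    for j in range(axes.shape[1]):
        col = axes[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            axes[:, j] = -col
            scores[:, j] = -scores[:, j]
    eigenvalues = s ** 2 / (n - 1)
    return PCAModel(mean=mean, eigenvectors=axes, eigenvalues=eigenvalues,
                    scores=scores, ids=list(ids))


def project(new_coords: np.ndarray, model: PCAModel,
            consensus: np.ndarray | None = None) -> np.ndarray:
    """Project configurations or flat shape vectors into an existing PC space.

    ``new_coords`` may be a (k, 3) configuration (or (n, k, 3) stack), in which
    case it is OPA-fitted to the training ``consensus`` first, or an already
    aligned flat vector/matrix with 3k columns.
    """
    x = np.asarray(new_coords, dtype=float)
    single = x.ndim <= 2 and (x.ndim == 1 or x.shape == (x.shape[0], 3))
    p = model.mean.size
    if x.ndim == 1:
        flat = x[None, :]
    elif x.ndim == 2 and x.shape[1] == 3:
        if consensus is None:
            raise ValueError("projecting a raw configuration needs a consensus")
        if 3 * x.shape[0] != p:
            raise ValueError(f"landmark count mismatch: {x.shape[0]} vs {p // 3}")
        flat = opa_fit(x, consensus).reshape(1, -1)
    elif x.ndim == 2:
        flat = x
    else:
        if consensus is None:
            raise ValueError("projecting raw configurations needs a consensus")
        flat = np.stack([opa_fit(c, consensus).reshape(-1) for c in x])
    if flat.shape[1] != p:
        raise ValueError(f"dimension mismatch: {flat.shape[1]} vs {p}")
    scores = (flat - model.mean) @ model.eigenvectors
    return scores[0] if single else scores


def back_transform(scores: np.ndarray, model: PCAModel) -> np.ndarray:
    """Invert projection on the retained subspace: mean + scores @ axes'.

    Returns a (k, 3) landmark configuration (or (n, k, 3) stack).  Score
    vectors shorter than the retained axis count address leading axes only.
    """
    s = np.atleast_2d(np.asarray(scores, dtype=float))
    m = s.shape[1]
    if m > model.n_axes:
        raise ValueError(f"{m} scores but only {model.n_axes} retained axes")
    flat = model.mean + s @ model.eigenvectors[:, :m].T
    out = flat.reshape(s.shape[0], -1, 3)
    return out[0] if np.asarray(scores).ndim == 1 else out


def pc_warps(model: PCAModel, axis: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Shapes at the observed minimum and maximum score along one PC axis."""
    lo = model.scores[:, axis].min()
    hi = model.scores[:, axis].max()
    z = np.zeros(model.n_axes)
    zl, zh = z.copy(), z.copy()
    zl[axis], zh[axis] = lo, hi
    return back_transform(zl, model), back_transform(zh, model)


@dataclass
class PhylomorphospaceProjection:
    tip_scores: dict[str, np.ndarray]
    node_scores: dict[str, np.ndarray]   # internal node id -> estimate
    edges: list[tuple[str, str]]         # (parent id, child id) for drawing


def _node_ids(tree: dendropy.Tree) -> dict:
    ids = {}
    counter = 0
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            ids[nd] = nd.taxon.label
        else:
            ids[nd] = f"node_{counter}"
            counter += 1
    return ids


def phylomorphospace(tree: dendropy.Tree, scores: np.ndarray,
                     labels: list[str]) -> PhylomorphospaceProjection:
    """Ancestral score estimates under Brownian motion for every internal node.

    Joint ML estimates minimise the branch-length-weighted sum of squared
    changes, a sparse linear (weighted graph Laplacian) system; the root value
    coincides with the GLS estimate (1'C^-1 1)^-1 1'C^-1 y per axis.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] != len(labels):
        raise ValueError("one score row per tip label required")
    tips = {t.label for t in tree.taxon_namespace}
    unmatched = sorted(set(labels) ^ tips)
    if unmatched:
        raise ValueError(f"tips and score labels do not match: {unmatched}")
    row = {lab: i for i, lab in enumerate(labels)}

    nodes = list(tree.preorder_node_iter())
    ids = _node_ids(tree)
    internal = [nd for nd in nodes if not nd.is_leaf()]
    pos = {nd: i for i, nd in enumerate(internal)}
    m = len(internal)
    p = scores.shape[1]
    L = np.zeros((m, m))
    b = np.zeros((m, p))
    for nd in internal:
        i = pos[nd]
        for ch in nd.child_nodes():
            w = 1.0 / max(ch.edge.length or 0.0, 1e-12)
            L[i, i] += w
            if ch.is_leaf():
                b[i] += w * scores[row[ch.taxon.label]]
            else:
                j = pos[ch]
                L[i, j] -= w
                L[j, i] -= w
                L[j, j] += w
    est = np.linalg.solve(L, b)

    node_scores = {ids[nd]: est[pos[nd]] for nd in internal}
    tip_scores = {lab: scores[row[lab]] for lab in labels}
    edges = []
    for nd in nodes:
        for ch in nd.child_nodes():
            edges.append((ids[nd], ids[ch]))
    return PhylomorphospaceProjection(tip_scores, node_scores, edges)


def per_axis_group_test(scores: np.ndarray, groups, nperm: int = 10000,
                        seed: int | None = None, alpha: float = 0.05,
                        joint: bool = True) -> pd.DataFrame:
    """One-way ANOVA per PC axis with permutation p-values.

    Flags which axes separate the groups at the given alpha.  A final "joint"
    row tests all axes together with the trace-based (summed-SS) statistic.
    Groups with a single member are excluded (with a warning in the table's
    attrs).
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    dropped = [str(l) for l, c in zip(labels, counts) if c < 2]
    keep = ~np.isin(groups, dropped)
    scores, groups = scores[keep], groups[keep]
    labels = np.unique(groups)
    g = len(labels)
    if g < 2:
        raise ValueError("need at least 2 groups with >= 2 members")
    n, p = scores.shape
    rng = np.random.default_rng(seed)

    G = (groups[:, None] == labels[None, :]).astype(float)  # (n, g)
    cnt = G.sum(axis=0)

    def batch_ss(Y3: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Between/within SS per axis for a (B, n, p) batch."""
        means = np.einsum("ng,bnp->bgp", G, Y3) / cnt[None, :, None]
        grand = Y3.mean(axis=1, keepdims=True)
        ssb = (cnt[None, :, None] * (means - grand) ** 2).sum(axis=1)
        sst = ((Y3 - grand) ** 2).sum(axis=1)
        return ssb, sst - ssb

    ssb, ssw = (a[0] for a in batch_ss(scores[None]))
    df_b, df_w = g - 1, n - g
    F = (ssb / df_b) / (ssw / df_w)
    count_ge = np.zeros(p)
    joint_obs = ssb.sum()
    joint_count = 0
    done = 0
    while done < nperm:
        B = min(512, nperm - done)
        idx = np.stack([rng.permutation(n) for _ in range(B)])
        pb, pw = batch_ss(scores[idx])
        Fp = (pb / df_b) / (pw / df_w)
        count_ge += (Fp >= F).sum(axis=0)
        joint_count += int((pb.sum(axis=1) >= joint_obs).sum())
        done += B
    pvals = (1.0 + count_ge) / (1.0 + nperm)

    rows = [{"axis": f"PC{j + 1}", "F": F[j], "p": pvals[j],
             "significant": pvals[j] < alpha} for j in range(p)]
    if joint:
        rows.append({"axis": "joint", "F": np.nan,
                     "p": (1.0 + joint_count) / (1.0 + nperm),
                     "significant": (1.0 + joint_count) / (1.0 + nperm) < alpha})
    out = pd.DataFrame(rows)
    out.attrs["excluded_groups"] = dropped
    out.attrs["n"] = int(n)
    return out
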