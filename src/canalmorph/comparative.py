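"""Phylogenetic comparative statistics on multivariate shape data.

Implements the distance-based (trace) Procrustes ANOVA with residual
randomization (RRPP), its phylogenetic GLS counterpart, the multivariate
generalization of Blomberg's K for phylogenetic signal, pairwise group-mean
shape tests, phylogenetic regression residuals, and ordinary least-squares
slopes with confidence intervals for allometry.

Sums of squares are sequential (Type I) in the user-given term order,
computed as traces of projector differences applied to the shape matrix —
equivalent to partitioning squared Procrustes distances among specimens and
therefore usable when variables far outnumber specimens.  Significance comes
from permuting reduced-model residuals (RRPP): for term i the residuals of
the model holding terms 1..i-1 are permuted, added back to the reduced
fitted values, and the term's SS recomputed; the observed arrangement counts
in both numerator and denominator, so p >= 1/(nperm + 1).  Effect sizes are
Z = (SS_obs - mean SS_perm) / sd SS_perm on the raw SS distribution.

PGLS premultiplies the shape data and the model matrix by the inverse matrix
square root of the Brownian-motion phylogenetic covariance C (shared
root-to-ancestor path lengths); with a star phylogeny of unit depth it
reduces exactly to the ordinary Procrustes ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import stats as sps


# --------------------------------------------------------------------------
# phylogenetic covariance


def phylo_cov_matrix(tree: dendropy.Tree,
                     order: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion covariance: C[i, j] = root-to-MRCA path length of i, j."""
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    if order is not None:
        missing = set(order) - set(labels)
        if missing:
            raise ValueError(f"species not in tree: {sorted(missing)}")
        pick = {lab: lf for lab, lf in zip(labels, leaves)}
        leaves = [pick[lab] for lab in order]
        labels = list(order)
    depths = np.array([lf.root_distance for lf in leaves])
    if depths.max() <= 0:
        raise ValueError("tree has zero depth")
    pdm = tree.phylogenetic_distance_matrix()
    s = len(leaves)
    C = np.empty((s, s))
    for i in range(s):
        C[i, i] = depths[i]
        for j in range(i + 1, s):
            d = pdm.patristic_distance(leaves[i].taxon, leaves[j].taxon)
            C[i, j] = C[j, i] = 0.5 * (depths[i] + depths[j] - d)
    return C, labels


def inv_sqrt_psd(C: np.ndarray, rcond: float = 1e-12) -> np.ndarray:
    """Symmetric inverse matrix square root via eigendecomposition."""
    w, V = np.linalg.eigh(C)
    if w.min() <= rcond * w.max():
        raise np.linalg.LinAlgError("covariance matrix is singular")
    return (V * (1.0 / np.sqrt(w))) @ V.T


# --------------------------------------------------------------------------
# phylogenetic signal


@dataclass
class PhyloSignalResult:
    K: float
    p: float | None
    nperm: int


def _kmult_stat(Y: np.ndarray, Cinv: np.ndarray, ones: np.ndarray,
                denom_expect: float) -> float:
    a = (ones @ Cinv @ Y) / (ones @ Cinv @ ones)
    D = Y - a  # deviations from the phylogenetic (GLS) mean
    mse0 = float(np.einsum("ij,ij->", D, D))
    mse = float(np.einsum("ji,jk,ki->", D, Cinv, D))
    if mse0 <= 0:
        raise ValueError("tip data have zero variance; K undefined")
    return (mse0 / mse) / denom_expect


def kmult(Y: np.ndarray, tree: dendropy.Tree, labels: list[str],
          nperm: int = 10000, seed: int | None = None) -> PhyloSignalResult:
    """Multivariate Blomberg's K with a tip-label permutation test.

    K is the ratio of observed MSE0/MSE (deviations from the GLS mean, raw vs
    phylogenetically standardized) to its Brownian-motion expectation
    (tr(C) - n / sum(C^-1)) / (n - 1); K = 1 under Brownian motion, K < 1
    indicates less similarity among relatives than BM predicts (convergence).
    ``nperm=0`` skips the test (p = None).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.ndim == 2 and Y.shape[0] == 1:
        Y = Y.T
    n = Y.shape[0]
    if n < 4:
        raise ValueError("phylogenetic signal needs at least 4 tips")
    if len(labels) != n:
        raise ValueError("one row per tip label required")
    C, _ = phylo_cov_matrix(tree, order=list(labels))
    Cinv = np.linalg.inv(C)
    ones = np.ones(n)
    denom = (np.trace(C) - n / float(ones @ Cinv @ ones)) / (n - 1)
    K_obs = _kmult_stat(Y, Cinv, ones, denom)
    if nperm <= 0:
        return PhyloSignalResult(K=K_obs, p=None, nperm=0)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(nperm):
        K_p = _kmult_stat(Y[rng.permutation(n)], Cinv, ones, denom)
        if K_p >= K_obs:
            count += 1
    return PhyloSignalResult(K=K_obs, p=(1.0 + count) / (1.0 + nperm),
                             nperm=nperm)


# --------------------------------------------------------------------------
# model matrices


def _encode_single(data: pd.DataFrame, name: str) -> np.ndarray:
    col = data[name]
    if col.isna().any():
        raise ValueError(f"term {name!r} has missing values; drop those rows")
    if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
        d = pd.get_dummies(col, drop_first=True, dtype=float)
        return d.to_numpy()
    return col.to_numpy(dtype=float)[:, None]


def build_term_blocks(data: pd.DataFrame, terms: list[str]) -> list[np.ndarray]:
    """Encode model terms: factors as treatment dummies, covariates as-is,
    "a:b" interactions as elementwise products of the encoded blocks."""
    blocks = []
    for term in terms:
        parts = term.split(":")
        enc = _encode_single(data, parts[0])
        for part in parts[1:]:
            other = _encode_single(data, part)
            enc = np.einsum("ni,nj->nij", enc, other).reshape(len(data), -1)
        blocks.append(enc)
    return blocks


# --------------------------------------------------------------------------
# Procrustes ANOVA via RRPP


@dataclass
class AnovaTable:
    rows: list[dict] = field(default_factory=list)
    nperm: int = 0
    seed: int | None = None
    n: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows,
                            columns=["term", "df", "SS", "MS", "R2", "F", "Z", "p"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    def __getitem__(self, term: str) -> dict:
        for r in self.rows:
            if r["term"] == term:
                return r
        raise KeyError(term)


def _seq_projectors(blocks: list[np.ndarray], intercept: np.ndarray):
    """Orthonormal bases Q_0 c= Q_1 c= ... for the sequential model sequence.

    Returns the list of bases (n x r_i) and the rank added by each term.
    Raises on aliased (rank-deficient) terms.
    """
    X = intercept
    Q, _ = np.linalg.qr(X)
    rank = np.linalg.matrix_rank(X)
    Qs = [Q[:, :rank]]
    ranks = [rank]
    for i, blk in enumerate(blocks):
        X = np.hstack([X, blk])
        r = np.linalg.matrix_rank(X)
        if r <= ranks[-1]:
            raise np.linalg.LinAlgError(
                f"model matrix rank-deficient: term {i} adds no rank (aliased)"
            )
        # re-orthonormalize via SVD for numerical stability
        U, s, _ = np.linalg.svd(X, full_matrices=False)
        Qs.append(U[:, : r])
        ranks.append(r)
    return Qs, np.diff(ranks).tolist()


def _rrpp_anova(Y: np.ndarray, blocks: list[np.ndarray], terms: list[str],
                intercept: np.ndarray, nperm: int, seed: int | None,
                chunk: int = 512) -> AnovaTable:
    n, p = Y.shape
    Qs, term_ranks = _seq_projectors(blocks, intercept)

    def ss_fit(Q: np.ndarray, Ymat: np.ndarray) -> float:
        return float(np.einsum("ij,ij->", Q.T @ Ymat, Q.T @ Ymat))

    fit_ss = [ss_fit(Q, Y) for Q in Qs]
    tot = float(np.einsum("ij,ij->", Y, Y))
    ss_terms = np.diff(fit_ss)
    ss_total = tot - fit_ss[0]          # around the (possibly GLS) mean
    ss_resid = tot - fit_ss[-1]
    df_terms = term_ranks
    df_resid = n - int(round(Qs[-1].shape[1]))
    df_total = n - int(round(Qs[0].shape[1]))
    ms_resid = ss_resid / df_resid if df_resid > 0 else np.nan

    rng = np.random.default_rng(seed)
    nt = len(blocks)
    count_ge = np.zeros(nt)
    sum_perm = np.zeros(nt)
    sumsq_perm = np.zeros(nt)
    if nperm > 0:
        perms = np.stack([rng.permutation(n) for _ in range(nperm)])
        for i in range(nt):
            Qr, Qf = Qs[i], Qs[i + 1]
            fitted = Qr @ (Qr.T @ Y)
            resid = Y - fitted
            done = 0
            while done < nperm:
                B = min(chunk, nperm - done)
                Yp = fitted[None] + resid[perms[done:done + B]]
                a = np.einsum("rn,bnp->brp", Qf.T, Yp)
                b = np.einsum("rn,bnp->brp", Qr.T, Yp)
                ssp = np.einsum("brp,brp->b", a, a) - np.einsum("brp,brp->b", b, b)
                count_ge[i] += int((ssp >= ss_terms[i] - 1e-12).sum())
                sum_perm[i] += ssp.sum()
                sumsq_perm[i] += (ssp ** 2).sum()
                done += B

    rows = []
    for i, term in enumerate(terms):
        ss = float(ss_terms[i])
        ms = ss / df_terms[i]
        row = {
            "term": term,
            "df": int(df_terms[i]),
            "SS": ss,
            "MS": ms,
            "R2": ss / ss_total,
            "F": ms / ms_resid,
            "Z": np.nan,
            "p": np.nan,
        }
        if nperm > 0:
            mean = sum_perm[i] / nperm
            var = sumsq_perm[i] / nperm - mean ** 2
            sd = np.sqrt(max(var, 0.0))
            row["Z"] = (ss - mean) / sd if sd > 0 else np.nan
            row["p"] = (1.0 + count_ge[i]) / (1.0 + nperm)
        rows.append(row)
    rows.append({"term": "residuals", "df": int(df_resid), "SS": float(ss_resid),
                 "MS": float(ms_resid), "R2": np.nan, "F": np.nan, "Z": np.nan,
                 "p": np.nan})
    rows.append({"term": "total", "df": int(df_total), "SS": float(ss_total),
                 "MS": np.nan, "R2": np.nan, "F": np.nan, "Z": np.nan, "p": np.nan})
    return AnovaTable(rows=rows, nperm=nperm, seed=seed, n=n)


def procrustes_anova(Y: np.ndarray, data: pd.DataFrame, terms: list[str],
                     nperm: int = 10000, seed: int | None = None) -> AnovaTable:
    """Sequential Procrustes ANOVA/ANCOVA on a multivariate shape matrix.

    ``Y`` is (n, p) shape variables (e.g. Procrustes-aligned coordinates);
    ``terms`` are column names of ``data``, with "a:b" for interactions,
    entered in order (Type I SS).  Significance by RRPP permutation.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1:
        Y = Y.T
    if len(data) != Y.shape[0]:
        raise ValueError("data must have one row per shape row")
    blocks = build_term_blocks(data, terms)
    intercept = np.ones((Y.shape[0], 1))
    return _rrpp_anova(Y, blocks, terms, intercept, nperm, seed)


def procrustes_pgls(Y: np.ndarray, data: pd.DataFrame, terms: list[str],
                    tree: dendropy.Tree, labels: list[str],
                    nperm: int = 10000, seed: int | None = None) -> AnovaTable:
    """Phylogenetic Procrustes ANOVA: RRPP in the GLS-transformed space.

    Rows of ``Y``/``data`` correspond to species ``labels`` matched to tree
    tips.  Both the shape data and the model matrix (including the intercept)
    are premultiplied by C^(-1/2); on a unit-depth star phylogeny the result
    equals :func:`procrustes_anova` exactly.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1:
        Y = Y.T
    C, _ = phylo_cov_matrix(tree, order=list(labels))
    T = inv_sqrt_psd(C)
    blocks = [T @ b for b in build_term_blocks(data, terms)]
    intercept = T @ np.ones((Y.shape[0], 1))
    return _rrpp_anova(T @ Y, blocks, terms, intercept, nperm, seed)


# --------------------------------------------------------------------------
# pairwise group-mean shape tests


def pairwise_group_test(Y: np.ndarray, groups, nperm: int = 10000,
                        seed: int | None = None):
    """Pairwise Euclidean distances between group mean shapes with RRPP p-values.

    The null permutes the residuals of the reduced (intercept-only) model —
    the RRPP null for the group term — and recomputes all pairwise group-mean
    distances under each permutation.  Returns (distance DataFrame, p-value
    DataFrame); singleton groups are excluded (recorded in
    ``attrs['excluded_groups']``).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    dropped = [str(l) for l, c in zip(labels, counts) if c < 2]
    keep = ~np.isin(groups, dropped)
    Y, groups = Y[keep], groups[keep]
    labels = np.unique(groups)
    g = len(labels)
    if g < 2:
        raise ValueError("need at least 2 groups with >= 2 members")
    n = Y.shape[0]
    G = (groups[:, None] == labels[None, :]).astype(float)
    cnt = G.sum(axis=0)

    def pair_dists(Ymat: np.ndarray) -> np.ndarray:
        means = (G.T @ Ymat) / cnt[:, None]
        diff = means[:, None, :] - means[None, :, :]
        return np.sqrt((diff ** 2).sum(axis=2))

    obs = pair_dists(Y)
    grand = Y.mean(axis=0)
    resid = Y - grand  # reduced (intercept-only) model residuals
    rng = np.random.default_rng(seed)
    count_ge = np.zeros((g, g))
    for _ in range(nperm):
        Yp = grand[None, :] + resid[rng.permutation(n)]
        count_ge += pair_dists(Yp) >= obs - 1e-15
    pvals = (1.0 + count_ge) / (1.0 + nperm)
    np.fill_diagonal(pvals, np.nan)
    d_df = pd.DataFrame(obs, index=labels, columns=labels)
    p_df = pd.DataFrame(pvals, index=labels, columns=labels)
    for df in (d_df, p_df):
        df.attrs["excluded_groups"] = dropped
    return d_df, p_df


# --------------------------------------------------------------------------
# phylogenetic residuals and allometry


def phylo_residuals(Y: np.ndarray, x: np.ndarray, tree: dendropy.Tree,
                    labels: list[str]) -> np.ndarray:
    """Residuals of a per-column GLS regression of Y on x under Brownian motion.

    beta = (X' C^-1 X)^-1 X' C^-1 Y with X = [1, x]; residuals Y - X beta are
    returned in the original (untransformed) space.  With a star phylogeny of
    equal depths this equals OLS residuals.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1:
        Y = Y.T
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant")
    C, _ = phylo_cov_matrix(tree, order=list(labels))
    Cinv = np.linalg.inv(C)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ Cinv @ X, X.T @ Cinv @ Y)
    return Y - X @ beta


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    level: float
    n: int

    @property
    def negative_allometry(self) -> bool:
        """In the log-log convention a slope below 1 is negative allometry."""
        return self.slope < 1.0


def ols_slope_ci(x, y, level: float = 0.95) -> RegressionResult:
    """Least-squares slope of y on x with a t-based confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant")
    res = sps.linregress(x, y)
    if x.size == 3 and res.stderr == 0:
        half = 0.0
    else:
        half = sps.t.ppf(0.5 + level / 2, x.size - 2) * res.stderr
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            ci_low=float(res.slope - half),
                            ci_high=float(res.slope + half),
                            level=level, n=int(x.size))
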