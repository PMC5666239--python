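"""Canonical variate analysis of ecomorph groups with Mahalanobis typicality
probabilities and log-likelihood assignment of unknown specimens.

The CVA axes are generalized eigenvectors of the between-group covariance
against the pooled within-group covariance, scaled so that the pooled
within-group covariance of the canonical scores is the identity — Euclidean
distance in CV space is therefore Mahalanobis distance.  Unknowns (fossils,
unassigned species) are projected with the trained axes and never influence
the fit.

Typicality probabilities compare a specimen's Mahalanobis distance to a group
mean against a bootstrap null of within-group distances: each of ``nresample``
draws resamples the group members with replacement and contributes the
members' distances to the resampled mean; the pooled null with a +1
small-sample correction gives a strictly positive p.  Membership in a group is
rejected when p < 0.05.  Log-likelihoods (multivariate normal, pooled
covariance) always assign a nearest group, with no alternative hypothesis —
the contrast between the two is what flags specimens outside all known groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats as sps

logger = logging.getLogger(__name__)


def reduce_dimensions(scores: np.ndarray, variance_fractions: np.ndarray,
                      n_groups: int, variance_target: float = 0.99,
                      hard_cap: int | None = None) -> tuple[np.ndarray, int]:
    """Retain the leading axes jointly representing ``variance_target``.

    Keeps the largest axis count whose cumulative variance fraction does not
    exceed the target (at least one axis), so the retained set "represents"
    the target without over-shooting it by including trailing noise axes.
    The count is capped at min(hard_cap, n_specimens - n_groups - 1) so the
    pooled within-group covariance stays invertible; a warning is logged when
    the cap bites.  Returns (reduced scores, retained count).
    """
    scores = np.asarray(scores, dtype=float)
    vf = np.asarray(variance_fractions, dtype=float)
    n = scores.shape[0]
    cum = np.cumsum(vf)
    m = max(1, int((cum <= variance_target + 1e-12).sum()))
    m = min(m, scores.shape[1])
    cap = n - n_groups - 1
    if hard_cap is not None:
        cap = min(cap, hard_cap)
    if m > cap:
        logger.warning("variance target needs %d axes; capped at %d", m, cap)
        m = cap
    logger.info("retained %d PC axes (%.1f%% of variance)", m,
                100 * cum[min(m, len(cum)) - 1])
    return scores[:, :m], m


@dataclass
class CVAModel:
    axes: np.ndarray                  # (p, g-1), within-whitening canonical axes
    grand_mean: np.ndarray            # (p,)
    group_labels: list[str]
    group_means_cv: np.ndarray        # (g, g-1)
    group_scores: dict[str, np.ndarray] = field(repr=False, default=None)
    scores: np.ndarray = field(repr=False, default=None)  # (n, g-1) training
    eigenvalues: np.ndarray = None
    retained_pc_count: int = 0

    @property
    def n_axes(self) -> int:
        return self.axes.shape[1]

    @property
    def between_fractions(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.grand_mean) @ self.axes


def _within_between(X: np.ndarray, groups: np.ndarray):
    labels = [str(l) for l in pd.unique(groups)]
    n, p = X.shape
    g = len(labels)
    W = np.zeros((p, p))
    means = np.empty((g, p))
    grand = X.mean(axis=0)
    B = np.zeros((p, p))
    for i, lab in enumerate(labels):
        sub = X[groups == lab]
        means[i] = sub.mean(axis=0)
        d = sub - means[i]
        W += d.T @ d
        mdiff = means[i] - grand
        B += len(sub) * np.outer(mdiff, mdiff)
    W /= n - g
    B /= g - 1
    return labels, means, grand, W, B


def cva(X: np.ndarray, groups) -> CVAModel:
    """Canonical variate analysis maximizing between- over within-group variance.

    Axes are eigenvectors of within^-1 @ between ordered by eigenvalue and
    normalized so that pooled within-group covariance of the scores is the
    identity (Mahalanobis scaling).  Requires a nonsingular pooled
    within-group covariance — reduce dimensionality first if this fails.
    """
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups).astype(str)
    labels, means, grand, W, B = _within_between(X, groups)
    g = len(labels)
    if g < 2:
        raise ValueError("CVA needs at least 2 groups")
    try:
        evals, evecs = sla.eigh(B, W)
    except (sla.LinAlgError, np.linalg.LinAlgError) as exc:
        raise np.linalg.LinAlgError(
            "pooled within-group covariance is singular; retain fewer PC axes"
        ) from exc
    order = np.argsort(evals)[::-1][: g - 1]
    A = evecs[:, order]           # A' W A = I by the generalized eigh
    evals = np.maximum(evals[order], 0.0)
    for j in range(A.shape[1]):   # deterministic sign convention
        col = A[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            A[:, j] = -col
    scores = (X - grand) @ A
    model = CVAModel(
        axes=A,
        grand_mean=grand,
        group_labels=labels,
        group_means_cv=(means - grand) @ A,
        eigenvalues=evals,
        scores=scores,
    )
    model.group_scores = {lab: scores[groups == lab] for lab in labels}
    return model


def mahalanobis_distance(x: np.ndarray, mean: np.ndarray,
                         cov: np.ndarray) -> float:
    """sqrt((x - mu)' Sigma^-1 (x - mu)); Euclidean when Sigma = I."""
    d = np.asarray(x, dtype=float) - np.asarray(mean, dtype=float)
    try:
        c = sla.cho_factor(np.asarray(cov, dtype=float))
    except (sla.LinAlgError, np.linalg.LinAlgError) as exc:
        raise np.linalg.LinAlgError("covariance is singular") from exc
    return float(np.sqrt(d @ sla.cho_solve(c, d)))


def cross_validate(X: np.ndarray, groups, seed: int | None = None):
    """Leave-one-out cross-validated CVA classification accuracy.

    For each specimen the CVA is refit without it and the specimen assigned to
    the group with the smallest Mahalanobis distance (Euclidean in the refit
    CV space).  Returns (accuracy, confusion DataFrame with true rows /
    predicted columns).
    """
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups).astype(str)
    labels = [str(l) for l in pd.unique(groups)]
    counts = {lab: int((groups == lab).sum()) for lab in labels}
    small = [lab for lab, c in counts.items() if c < 2]
    if small:
        raise ValueError(f"groups with a single member cannot be "
                         f"cross-validated: {small}")
    n = X.shape[0]
    confusion = pd.DataFrame(0, index=labels, columns=labels)
    correct = 0
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        model = cva(X[mask], groups[mask])
        z = model.transform(X[i])
        dists = np.linalg.norm(model.group_means_cv - z, axis=1)
        pred = model.group_labels[int(np.argmin(dists))]
        confusion.loc[groups[i], pred] += 1
        correct += pred == groups[i]
        mask[i] = True
    return correct / n, confusion


def typicality_probability(score: np.ndarray, group_scores: np.ndarray,
                           nresample: int = 10000, seed: int | None = None,
                           cov: np.ndarray | None = None,
                           chunk: int = 512) -> float:
    """Bootstrap typicality probability of group membership.

    The specimen's Mahalanobis distance to the group mean (identity covariance
    in CV space unless ``cov`` is given) is compared against a pooled null of
    member-to-resampled-mean distances over ``nresample`` bootstrap draws;
    p = (1 + #{null >= d}) / (1 + pooled count).  Membership is rejected at
    p < 0.05.
    """
    G = np.atleast_2d(np.asarray(group_scores, dtype=float))
    n, p = G.shape
    if n < 3:
        raise ValueError("typicality needs a group of at least 3 members")
    x = np.asarray(score, dtype=float)
    if cov is not None:
        w, V = np.linalg.eigh(np.asarray(cov, dtype=float))
        if w.min() <= 1e-12 * w.max():
            raise np.linalg.LinAlgError("group covariance is degenerate")
        Wh = (V * (1.0 / np.sqrt(w))) @ V.T  # whitening transform
        G = G @ Wh
        x = x @ Wh
    d_obs = float(np.linalg.norm(x - G.mean(axis=0)))
    rng = np.random.default_rng(seed)
    count = 0
    total = 0
    done = 0
    while done < nresample:
        B = min(chunk, nresample - done)
        idx = rng.integers(0, n, size=(B, n))
        mu_star = G[idx].mean(axis=1)                    # (B, p)
        d_null = np.linalg.norm(G[None, :, :] - mu_star[:, None, :], axis=2)
        count += int((d_null >= d_obs).sum())
        total += d_null.size
        done += B
    return (1.0 + count) / (1.0 + total)


def log_likelihood_assign(score: np.ndarray, group_means: np.ndarray,
                          group_labels: list[str],
                          cov: np.ndarray | None = None):
    """Multivariate-normal log-likelihood of a specimen under each group.

    Uses the pooled within-group covariance (identity in CV space by
    construction).  Returns (per-group log-likelihoods, normalized relative
    likelihoods, assigned label, tied flag); ties break by label order.
    """
    score = np.asarray(score, dtype=float)
    means = np.asarray(group_means, dtype=float)
    p = score.size
    if cov is None:
        cov = np.eye(p)
    lls = np.array([
        sps.multivariate_normal.logpdf(score, mean=m, cov=cov) for m in means
    ])
    best = int(np.argmax(lls))
    tied = bool(np.any(np.abs(lls - lls[best]) < 1e-9) and
                (np.abs(lls - lls[best]) < 1e-9).sum() > 1)
    rel = np.exp(lls - lls.max())
    rel = rel / rel.sum()
    return lls, rel, group_labels[best], tied


def group_separation_test(scores: np.ndarray, groups, nperm: int = 10000,
                          seed: int | None = None) -> pd.DataFrame:
    """Pairwise permutation test on Mahalanobis distances between group means.

    The statistic per pair is the Mahalanobis distance between the two group
    means (pooled within-group covariance held fixed); the null permutes group
    labels within the pair.  Returns the symmetric p-value matrix (diagonal
    NaN); singleton groups are excluded.
    """
    X = np.asarray(scores, dtype=float)
    groups = np.asarray(groups).astype(str)
    labels, counts = np.unique(groups, return_counts=True)
    dropped = [str(l) for l, c in zip(labels, counts) if c < 2]
    keep = ~np.isin(groups, dropped)
    X, groups = X[keep], groups[keep]
    labels = [str(l) for l in pd.unique(groups)]
    g = len(labels)
    if g < 2:
        raise ValueError("need at least 2 groups with >= 2 members")
    _, _, _, W, _ = _within_between(X, groups)
    w, V = np.linalg.eigh(W)
    if w.min() <= 1e-12 * w.max():
        raise np.linalg.LinAlgError("pooled within-group covariance singular")
    Wh = (V * (1.0 / np.sqrt(w))) @ V.T
    Z = X @ Wh  # Mahalanobis distance = Euclidean here
    rng = np.random.default_rng(seed)
    pmat = pd.DataFrame(np.nan, index=labels, columns=labels)
    for a in range(g):
        for b in range(a + 1, g):
            za = Z[groups == labels[a]]
            zb = Z[groups == labels[b]]
            obs = float(np.linalg.norm(za.mean(axis=0) - zb.mean(axis=0)))
            pool = np.vstack([za, zb])
            na = len(za)
            count = 0
            for _ in range(nperm):
                perm = rng.permutation(len(pool))
                d = np.linalg.norm(pool[perm[:na]].mean(axis=0)
                                   - pool[perm[na:]].mean(axis=0))
                if d >= obs - 1e-15:
                    count += 1
            pmat.iloc[a, b] = pmat.iloc[b, a] = (1.0 + count) / (1.0 + nperm)
    pmat.attrs["excluded_groups"] = dropped
    return pmat


@dataclass
class Ellipse:
    center: np.ndarray
    radii: np.ndarray      # semi-axes, descending
    angle: float           # radians, first axis vs x
    level: float
    degenerate: bool


def confidence_ellipse(points: np.ndarray, level: float = 0.95) -> Ellipse:
    """Confidence ellipse of a 2D point cloud from its mean and covariance.

    Semi-axes scale with sqrt(eigenvalue * chi2.ppf(level, df=2)); level 0
    collapses the ellipse onto the mean, and collinear points are flagged
    degenerate.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 two-dimensional points")
    mean = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    w, V = np.linalg.eigh(cov)
    w = w[::-1]
    V = V[:, ::-1]
    q = sps.chi2.ppf(level, df=2) if level > 0 else 0.0
    radii = np.sqrt(np.maximum(w, 0.0) * q)
    degenerate = bool(w[-1] <= 1e-12 * max(w[0], 1e-300))
    return Ellipse(center=mean, radii=radii,
                   angle=float(np.arctan2(V[1, 0], V[0, 0])),
                   level=level, degenerate=degenerate)


@dataclass
class ClassificationResult:
    """Per-specimen, per-group distances, typicality and likelihoods."""

    specimen_id: str
    group_labels: list[str]
    distances: np.ndarray          # Mahalanobis D per group
    typicality: np.ndarray         # typicality p per group
    log_likelihood: np.ndarray
    relative_likelihood: np.ndarray
    assigned: str
    tied: bool
    rejected_all: bool             # all typicality p < alpha

    def to_row(self) -> dict:
        row = {"specimen_id": self.specimen_id, "assigned": self.assigned,
               "rejected_all": self.rejected_all}
        for j, lab in enumerate(self.group_labels):
            row[f"D_{lab}"] = self.distances[j]
            row[f"p_{lab}"] = self.typicality[j]
            row[f"loglik_{lab}"] = self.log_likelihood[j]
            row[f"rel_lik_{lab}"] = self.relative_likelihood[j]
        return row


def classify_unknowns(model: CVAModel, unknown_scores: np.ndarray,
                      unknown_ids: list[str], nresample: int = 10000,
                      seed: int | None = None,
                      alpha: float = 0.05) -> list[ClassificationResult]:
    """Classify reduced-PC unknowns against a trained CVA model.

    Unknowns are projected into CV space with the trained axes (they never
    influence the fit), given per-group Mahalanobis distances, bootstrap
    typicality probabilities and normal log-likelihoods.  ``rejected_all`` is
    set when every group's typicality p falls below ``alpha`` — the specimen
    is unlike any known group even though the likelihood still names a
    nearest one.
    """
    Z = np.atleast_2d(model.transform(unknown_scores))
    results = []
    ss = np.random.SeedSequence(seed)
    for row, sid in zip(Z, unknown_ids):
        dists = np.linalg.norm(model.group_means_cv - row, axis=1)
        typ = np.array([
            typicality_probability(row, model.group_scores[lab],
                                   nresample=nresample,
                                   seed=int(child.generate_state(1)[0] % (2**31)))
            for lab, child in zip(model.group_labels, ss.spawn(len(model.group_labels)))
        ])
        lls, rel, assigned, tied = log_likelihood_assign(
            row, model.group_means_cv, model.group_labels)
        results.append(ClassificationResult(
            specimen_id=str(sid), group_labels=list(model.group_labels),
            distances=dists, typicality=typ, log_likelihood=lls,
            relative_likelihood=rel, assigned=assigned, tied=tied,
            rejected_all=bool((typ < alpha).all()),
        ))
    return results


def classification_table(results: list[ClassificationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])
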