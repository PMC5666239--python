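"""Synthetic semicircular-canal datasets with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a parametric three-loop canal system (anterior and posterior loops in
near-vertical planes, a lateral loop in a near-horizontal plane, joined by a
crus commune) digitised into the anchored 92-landmark scheme; an ultrametric
pure-birth phylogeny; Brownian-motion shape evolution along it; six convergent
ecomorph groups whose mean-shape offsets are distinct template-parameter
deformations (torsion, eccentricity, crus length) assigned to species
scattered across the tree; unassigned "unique" species; ontogenetic size
series with a log-linear allometric shape trend and a centroid-size /
skull-length allometry of known slope; habitat (perch) covariates that are
independent of shape unless requested; and fossil outliers far outside every
group.

Every random draw is governed by (tree_seed, trait_seed), so datasets are
byte-identical across runs, and a ground-truth record stores every injected
effect.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd

from .io import LandmarkConfiguration, ShapeDataset
from .resample import CentrelineCurve, assemble_configuration
from .superimpose import centroid_size

GROUP_LABELS = ("CG", "GB", "TC", "TG", "Tr", "Tw")
ISLANDS = ("Hispaniola", "Cuba", "Jamaica", "PuertoRico")

#: Template-parameter tweak defining each ecomorph's deformation direction.
GROUP_DEFORMATIONS = {
    "CG": {"torsion_anterior": 0.10},
    "GB": {"ecc_anterior": 1.30},
    "TC": {"torsion_lateral": 0.10},
    "TG": {"ecc_lateral": 1.30},
    "Tr": {"crus_length": 0.72},
    "Tw": {"ecc_posterior": 1.30, "torsion_posterior": 0.06},
}


@dataclass
class SimulationSpec:
    """Study-design parameters of a synthetic dataset.

    Magnitudes are in unit-centroid-size shape space: ``ecomorph_effect`` is
    the Procrustes-norm offset of a group mean from the base template, and
    ``noise_sd`` the per-coordinate landmark digitising noise.
    """

    n_species: int = 41
    n_per_species: int = 3
    tree_seed: int = 1
    trait_seed: int = 2
    bm_rate: float = 4e-4          # variance per unit tree depth, per dimension
    n_bm_dims: int = 3
    ecomorph_effect: float = 0.04
    n_groups: int = 6
    n_unique: int = 8
    n_fossils: int = 5
    fossil_effect_multiplier: float = 5.0
    allometry_slope: float = 0.63  # log CS on log skull length
    allometry_shape_coef: float = 0.03  # shape shift per unit log CS
    noise_sd: float = 5e-4
    perch_association: bool = False
    n_canal: int = 28
    n_crus: int = 3

    def __post_init__(self) -> None:
        if self.n_groups > len(GROUP_LABELS):
            raise ValueError(f"at most {len(GROUP_LABELS)} ecomorph groups")
        if self.n_groups + self.n_unique > self.n_species:
            raise ValueError("n_groups + n_unique exceeds n_species")
        for name in ("bm_rate", "ecomorph_effect", "noise_sd",
                     "allometry_shape_coef", "fossil_effect_multiplier"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# --------------------------------------------------------------------------
# template geometry


def _arc(p0, p1, normal, sweep: float, eccentricity: float = 1.0,
         torsion: float = 0.0, n_dense: int = 400) -> np.ndarray:
    """Circular arc of given sweep (radians) joining p0 to p1, eccentricity
    scaling applied about the chord line (endpoints fixed), torsion as a
    sinusoidal out-of-plane displacement vanishing at the endpoints."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    chord = p1 - p0
    c = np.linalg.norm(chord)
    e1 = chord / c
    nrm = np.asarray(normal, float)
    nrm = nrm - (nrm @ e1) * e1
    nrm = nrm / np.linalg.norm(nrm)
    e2 = np.cross(nrm, e1)
    m = 0.5 * (p0 + p1)
    r = c / (2.0 * np.sin(sweep / 2.0))
    h = r * np.cos(sweep / 2.0)        # negative when sweep > pi
    center = m + h * e2

    def ang(p):
        v = p - center
        return np.arctan2(v @ e2, v @ e1)

    a0, a1 = ang(p0), ang(p1)
    # choose the direction whose travelled angle equals the sweep
    delta = (a1 - a0) % (2 * np.pi)
    if not np.isclose(delta, sweep, atol=1e-9):
        delta = delta - 2 * np.pi  # go the other way
    s = np.linspace(0.0, 1.0, n_dense)
    phi = a0 + delta * s
    pts = center[None, :] + r * (np.cos(phi)[:, None] * e1[None, :]
                                 + np.sin(phi)[:, None] * e2[None, :])
    # eccentricity: scale offsets from the chord line, which leaves the
    # endpoints (on the chord) fixed
    off = (pts - m) @ e2
    pts = pts + (eccentricity - 1.0) * off[:, None] * e2[None, :]
    pts = pts + torsion * np.sin(2 * np.pi * s)[:, None] * nrm[None, :]
    pts[0], pts[-1] = p0, p1
    return pts


def template_canal_system(
    torsion_anterior: float = 0.03,
    torsion_posterior: float = 0.03,
    torsion_lateral: float = 0.03,
    ecc_anterior: float = 1.0,
    ecc_posterior: float = 1.0,
    ecc_lateral: float = 1.0,
    crus_length: float = 0.55,
    n_dense: int = 400,
) -> tuple[dict[str, CentrelineCurve], dict[str, np.ndarray]]:
    """Parametric canal-system centrelines plus their five anchor points.

    Three near-circular loops in approximately orthogonal planes (anterior and
    posterior vertical, lateral horizontal) join a short crus commune.  The
    parameters control the shape features the analysis axes describe: loop
    eccentricity (in-plane axis ratio), out-of-plane torsion, and crus length.
    """
    anchors = {
        "ant_vestibule": np.array([0.30, 0.05, 0.20]),
        "post_vestibule": np.array([-0.05, 0.30, 0.20]),
        "lat_posterior": np.array([-0.25, 0.25, 0.25]),
        "crus_apex": np.array([0.0, 0.0, 1.0]),
        "crus_base": np.array([0.0, 0.0, 1.0 - crus_length]),
    }
    curves = {
        "anterior": CentrelineCurve("anterior", _arc(
            anchors["ant_vestibule"], anchors["crus_apex"],
            normal=[0.25, -0.95, 0.0], sweep=np.deg2rad(265),
            eccentricity=ecc_anterior, torsion=torsion_anterior,
            n_dense=n_dense)),
        "posterior": CentrelineCurve("posterior", _arc(
            anchors["post_vestibule"], anchors["crus_apex"],
            normal=[0.95, 0.25, 0.0], sweep=np.deg2rad(265),
            eccentricity=ecc_posterior, torsion=torsion_posterior,
            n_dense=n_dense)),
        "lateral": CentrelineCurve("lateral", _arc(
            anchors["ant_vestibule"], anchors["lat_posterior"],
            normal=[0.05, -0.05, 1.0], sweep=np.deg2rad(240),
            eccentricity=ecc_lateral, torsion=torsion_lateral,
            n_dense=n_dense)),
        "crus": CentrelineCurve("crus", _arc(
            anchors["crus_apex"], anchors["crus_base"],
            normal=[1.0, -1.0, 0.0], sweep=np.deg2rad(25),
            n_dense=max(50, n_dense // 4))),
    }
    return curves, anchors


def template_configuration(n_canal: int = 28, n_crus: int = 3, **params):
    """Assemble the template into a landmark configuration + sliding scheme."""
    curves, anchors = template_canal_system(**params)
    return assemble_configuration(
        curves["anterior"], curves["posterior"], curves["lateral"],
        curves["crus"], anchors, n_canal=n_canal, n_crus=n_crus)


# --------------------------------------------------------------------------
# tree and Brownian motion


def simulate_tree(n_tips: int, seed: int) -> dendropy.Tree:
    """Ultrametric pure-birth tree with depth normalized to 1."""
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    tree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips,
        rng=random.Random(seed))
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    depth = max(lf.root_distance for lf in tree.leaf_node_iter())
    # the process stops at the n-th speciation, leaving a zero-length cherry;
    # let every lineage evolve a little longer so the covariance matrix is
    # nonsingular, then normalize
    for lf in tree.leaf_node_iter():
        lf.edge.length += 0.05 * depth
    depth *= 1.05
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= depth
    # make tips exactly ultrametric at depth 1 (absorb float error)
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    for lf in tree.leaf_node_iter():
        lf.edge.length += 1.0 - lf.root_distance
    width = len(str(n_tips))
    for i, lf in enumerate(sorted(tree.leaf_node_iter(),
                                  key=lambda l: l.taxon.label), start=1):
        lf.taxon.label = f"sp{i:0{width}d}"
    return tree


def simulate_bm(tree: dendropy.Tree, rate: float, dims: int,
                seed: int) -> tuple[np.ndarray, list[str]]:
    """Multivariate Brownian motion tip values, independent dimensions.

    Each dimension has tip covariance rate * C (C the shared-path-length
    matrix); sampled by the Cholesky factor of C, root state zero.
    """
    from .comparative import phylo_cov_matrix

    if rate < 0:
        raise ValueError("rate must be >= 0")
    C, labels = phylo_cov_matrix(tree)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((len(labels), dims))
    if rate == 0:
        return np.zeros((len(labels), dims)), labels
    L = np.linalg.cholesky(C + 1e-12 * np.eye(len(labels)))
    return np.sqrt(rate) * (L @ z), labels


# --------------------------------------------------------------------------
# dataset synthesis


@dataclass
class SimulatedData:
    dataset: ShapeDataset
    tree: dendropy.Tree
    ground_truth: dict = field(default_factory=dict)


def _unit_shape(coords: np.ndarray) -> np.ndarray:
    c = coords - coords.mean(axis=0)
    return c / centroid_size(coords)


def _direction(base_cfg: np.ndarray, tweaked_cfg: np.ndarray) -> np.ndarray:
    """Unit-Frobenius-norm shape-space direction between two templates."""
    d = _unit_shape(tweaked_cfg) - _unit_shape(base_cfg)
    return d / np.linalg.norm(d)


def simulate_dataset(spec: SimulationSpec) -> SimulatedData:
    """Generate a landmark dataset with the structure the analyses assume.

    Per species: a Brownian-motion deviation from the template consensus plus,
    for ecomorph species, that group's deformation direction scaled by
    ``ecomorph_effect`` (group membership scattered across the tree in
    round-robin order along a random tip permutation, so groups are
    convergent, not clades).  Per specimen: an ontogenetic size draw, an
    allometric shape shift proportional to log centroid size along one fixed
    direction, isotropic landmark noise, and metadata with skull length
    generated so that log CS regresses on log skull length with slope
    ``allometry_slope``.  Fossils are placed far outside every group (offset
    ``fossil_effect_multiplier x ecomorph_effect`` along mixed directions) and
    carry the 'fossil' label; perch covariates are independent of shape when
    ``perch_association`` is off.
    """
    rng = np.random.default_rng(spec.trait_seed)
    tree = simulate_tree(spec.n_species, spec.tree_seed)
    species = sorted(t.label for t in tree.taxon_namespace)

    base_cfg, scheme = template_configuration(spec.n_canal, spec.n_crus)
    base = _unit_shape(base_cfg.coords)
    k = base.shape[0]

    # ecomorph deformation directions from template-parameter tweaks
    group_labels = list(GROUP_LABELS[: spec.n_groups])
    group_dirs = {}
    for lab in group_labels:
        cfg_g, _ = template_configuration(spec.n_canal, spec.n_crus,
                                          **GROUP_DEFORMATIONS[lab])
        group_dirs[lab] = _direction(base_cfg.coords, cfg_g.coords)

    # convergent assignment: round-robin along a random species permutation
    perm = rng.permutation(spec.n_species)
    assignment: dict[str, str] = {}
    n_eco = spec.n_species - spec.n_unique
    for pos, sp_idx in enumerate(perm):
        sp = species[sp_idx]
        if pos < n_eco:
            assignment[sp] = group_labels[pos % spec.n_groups]
        else:
            assignment[sp] = "unique"

    # BM deviations along fixed random orthonormal shape directions
    bm_basis = np.linalg.qr(rng.standard_normal((3 * k, spec.n_bm_dims)))[0]
    bm_tips, bm_labels = simulate_bm(
        tree, spec.bm_rate, spec.n_bm_dims,
        seed=int(rng.integers(2**31)))
    bm_row = {lab: bm_tips[i] for i, lab in enumerate(bm_labels)}

    allo_dir = rng.standard_normal(3 * k)
    allo_dir /= np.linalg.norm(allo_dir)

    # unique species: individual directions mixing two group deformations
    unique_dirs = {}
    for sp in species:
        if assignment[sp] == "unique":
            w = rng.standard_normal(len(group_labels))
            d = sum(wi * group_dirs[lab].reshape(-1)
                    for wi, lab in zip(w, group_labels))
            d /= np.linalg.norm(d)
            unique_dirs[sp] = d.reshape(k, 3)

    configs: list[LandmarkConfiguration] = []
    meta_rows: list[dict] = []
    ref_log_cs = np.log(2.0)

    def make_specimen(sid, sp_shape, size_mm, species_name, island, ecomorph,
                      sex_age):
        shape = sp_shape + spec.allometry_shape_coef * (
            np.log(size_mm) - ref_log_cs) * allo_dir.reshape(k, 3)
        shape = shape + rng.normal(0.0, spec.noise_sd, size=(k, 3))
        shape = _unit_shape(shape) * size_mm
        configs.append(LandmarkConfiguration(sid, shape))
        log_cs = np.log(centroid_size(shape))
        log_sl = (log_cs - ref_log_cs) / spec.allometry_slope + np.log(10.0) \
            + rng.normal(0.0, 0.02)
        sl = float(np.exp(log_sl))
        sw = sl / float(rng.normal(2.0, 0.08))
        if spec.perch_association and ecomorph in group_labels:
            gi = group_labels.index(ecomorph)
            ph = float(np.exp(rng.normal(0.3 * gi, 0.3)))
            pdm = float(np.exp(rng.normal(-0.2 * gi, 0.3)))
        else:
            ph = float(np.exp(rng.normal(0.5, 0.8)))
            pdm = float(np.exp(rng.normal(-1.0, 0.6)))
        meta_rows.append({
            "specimen_id": sid, "species": species_name, "island": island,
            "ecomorph": ecomorph, "sex_age_class": sex_age,
            "skull_length": sl, "skull_width": sw,
            "perch_height": ph, "perch_diameter": pdm,
        })

    for si, sp in enumerate(species):
        eco = assignment[sp]
        shape = base.copy()
        shape += (bm_basis @ bm_row[sp]).reshape(k, 3)
        if eco in group_dirs:
            shape += spec.ecomorph_effect * group_dirs[eco]
        elif eco == "unique":
            shape += 0.7 * spec.ecomorph_effect * unique_dirs[sp]
        adult = float(np.exp(rng.normal(np.log(2.0), 0.15)))
        if spec.n_per_species <= 1:
            sizes = [adult]
        else:
            juv = np.sort(adult * np.exp(
                rng.uniform(np.log(0.5), -0.05, size=spec.n_per_species - 1)))
            sizes = [*juv, adult]
        island = ISLANDS[si % len(ISLANDS)]
        for j, size in enumerate(sizes):
            sex_age = "adult_male" if j == len(sizes) - 1 else "juvenile"
            make_specimen(f"{sp}_{j + 1:02d}", shape, size, sp, island, eco,
                          sex_age)

    fossil_mixes = []
    for f in range(spec.n_fossils):
        w = rng.standard_normal(len(group_labels))
        w[f % len(group_labels)] *= 3.0  # pull toward varied directions
        own = rng.standard_normal((k, 3))
        own -= own.mean(axis=0)
        d = sum(wi * group_dirs[lab] for wi, lab in zip(w, group_labels))
        d = d + 0.5 * own / np.linalg.norm(own)
        d /= np.linalg.norm(d)
        fossil_mixes.append(d)
        shape = base + spec.fossil_effect_multiplier * spec.ecomorph_effect * d
        size = float(np.exp(rng.normal(np.log(1.5), 0.15)))
        make_specimen(f"fossil_{f + 1:02d}", shape, size,
                      f"fossil_sp{f + 1:02d}", "Hispaniola", "fossil",
                      "adult_male")

    metadata = pd.DataFrame(meta_rows)
    dataset = ShapeDataset(configs, metadata=metadata, scheme=scheme)
    ground_truth = {
        "spec": asdict(spec),
        "assignment": assignment,
        "group_deformations": {g: GROUP_DEFORMATIONS[g] for g in group_labels},
        "allometry_slope": spec.allometry_slope,
        "ecomorph_effect": spec.ecomorph_effect,
        "noise_sd": spec.noise_sd,
        "bm_rate": spec.bm_rate,
        "fossil_offset": spec.fossil_effect_multiplier * spec.ecomorph_effect,
        "n_specimens": len(configs),
    }
    return SimulatedData(dataset=dataset, tree=tree, ground_truth=ground_truth)
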