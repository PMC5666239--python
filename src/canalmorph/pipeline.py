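"""End-to-end pipeline driver: align -> ordinate -> comparative -> classify.

Mirrors a standard ecomorphological shape workflow.  Two alignments are run:
the full dataset (all modern specimens, including ontogenetic series) for the
CVA/classification stage, and a phylogenetic subset (largest adult per
species, matched to the tree) for phylogenetic signal, Procrustes
ANOVA/PGLS and the phylomorphospace.  Fossils never enter any alignment
consensus or eigendecomposition; they are ordinary-Procrustes projected.

A single global seed is expanded deterministically into per-stage seeds, and
every output bundle carries the full configuration so results can be
reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as cls
from . import comparative as cmp
from . import io as cio
from . import ordination as ord_
from . import superimpose as sup

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    # inputs (unused when simulate is set)
    landmarks: str | None = None
    metadata: str | None = None
    tree: str | None = None
    scheme: str | None = None
    simulate: dict | None = None        # SimulationSpec fields
    # gpa
    slide: bool = True
    gpa_max_iter: int = 10
    gpa_tol: float = 1e-8
    # statistics
    nperm: int = 10000
    nresample: int = 10000
    variance_target: float = 0.99
    hard_cap: int = 40
    seed: int = 1
    # stages
    run_pgls: bool = True
    outdir: str | None = None

    def validate(self) -> None:
        if self.simulate is None:
            if not (self.landmarks and self.metadata):
                raise ValueError("config needs landmark and metadata paths, "
                                 "or a 'simulate' block")
            if self.run_pgls and not self.tree:
                raise ValueError("PGLS requested but no tree provided")
        if self.nperm < 1 or self.nresample < 1:
            raise ValueError("nperm and nresample must be positive")

    @classmethod
    def from_yaml(cls_, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls_)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls_(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def stage_seeds(seed: int) -> dict[str, int]:
    """Expand one global seed into independent per-stage seeds."""
    ss = np.random.SeedSequence(seed)
    names = ["simulate_tree", "simulate_traits", "kmult", "anova", "pgls",
             "pairwise", "per_axis", "cva", "typicality", "separation"]
    return {name: int(child.generate_state(1)[0] % (2**31))
            for name, child in zip(names, ss.spawn(len(names)))}


def _load_inputs(config: PipelineConfig):
    from .simulate import SimulationSpec, simulate_dataset

    seeds = stage_seeds(config.seed)
    if config.simulate is not None:
        spec_kwargs = dict(config.simulate)
        spec_kwargs.setdefault("tree_seed", seeds["simulate_tree"])
        spec_kwargs.setdefault("trait_seed", seeds["simulate_traits"])
        sim = simulate_dataset(SimulationSpec(**spec_kwargs))
        return sim.dataset, sim.tree, sim.ground_truth, seeds
    metadata = cio.read_metadata(config.metadata)
    dataset = cio.read_landmarks(config.landmarks, metadata=metadata)
    if config.scheme:
        from .resample import SlidingScheme
        dataset.scheme = SlidingScheme.from_json(config.scheme)
    tree = cio.read_tree(config.tree) if config.tree else None
    return dataset, tree, None, seeds


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order; returns (and optionally writes) a bundle."""
    config.validate()
    t0 = time.perf_counter()
    results: dict = {}
    stage = "load"
    try:
        dataset, tree, ground_truth, seeds = _load_inputs(config)
        meta = dataset.metadata
        if meta is None:
            raise ValueError("pipeline requires specimen metadata")
        meta = cio.add_head_proportion(meta)
        modern = meta.loc[meta["ecomorph"] != "fossil", "specimen_id"].tolist()
        fossil_ids = meta.loc[meta["ecomorph"] == "fossil",
                              "specimen_id"].tolist()
        logger.info("loaded %d specimens (%d modern, %d fossil), k=%d",
                    dataset.n, len(modern), len(fossil_ids), dataset.k)

        stage = "gpa_full"
        full = dataset.subset(modern)
        aligned_full = sup.gpa(full, scheme=dataset.scheme, slide=config.slide,
                               max_iter=config.gpa_max_iter, tol=config.gpa_tol)
        results["gpa_full"] = {
            "n": aligned_full.n, "k": aligned_full.k,
            "iterations": aligned_full.iterations_used,
            "converged": bool(aligned_full.converged),
        }

        stage = "phylo_subset"
        meta_modern = meta[meta["ecomorph"] != "fossil"].copy()
        cs_map = dict(zip(aligned_full.ids, aligned_full.centroid_sizes))
        meta_modern["log_cs"] = np.log([cs_map[i]
                                        for i in meta_modern["specimen_id"]])
        adults = meta_modern[meta_modern["sex_age_class"] == "adult_male"]
        if adults.empty:
            adults = meta_modern
        subset_ids = (adults.sort_values("log_cs")
                      .groupby("species", sort=True).tail(1))
        subset_ids = subset_ids.sort_values("species")["specimen_id"].tolist()
        phylo_ds = dataset.subset(subset_ids)
        aligned_sub = sup.gpa(phylo_ds, scheme=dataset.scheme,
                              slide=config.slide,
                              max_iter=config.gpa_max_iter, tol=config.gpa_tol)
        sub_meta = meta_modern.set_index("specimen_id").loc[aligned_sub.ids]
        sub_species = sub_meta["species"].tolist()
        results["phylo_subset_n"] = aligned_sub.n

        stage = "pca"
        pca_model = ord_.pca(aligned_sub)
        results["pc_variance_fractions"] = pca_model.variance_fractions[:10]
        if fossil_ids:
            fossils = dataset.subset(fossil_ids)
            fossil_scores = ord_.project(fossils.coords_array(), pca_model,
                                         consensus=aligned_sub.consensus)
            results["fossil_pc_scores"] = pd.DataFrame(
                fossil_scores[:, :3], index=fossil_ids,
                columns=["PC1", "PC2", "PC3"]).reset_index(names="specimen_id")

        eco_mask = sub_meta["ecomorph"].isin(cio.ECOMORPH_LABELS[:6]).to_numpy()
        stage = "per_axis_manova"
        per_axis = ord_.per_axis_group_test(
            pca_model.scores[eco_mask][:, :min(10, pca_model.n_axes)],
            sub_meta["ecomorph"].to_numpy()[eco_mask],
            nperm=config.nperm, seed=seeds["per_axis"])
        results["per_axis_tests"] = per_axis

        stage = "phylomorphospace"
        if tree is not None:
            pms = ord_.phylomorphospace(
                tree, pca_model.scores[:, :2], sub_species)
            results["phylomorphospace"] = {
                "node_scores": {k: v.tolist()
                                for k, v in pms.node_scores.items()},
                "edges": pms.edges,
            }

        stage = "comparative"
        sub_shape = aligned_sub.flat
        sub_data = pd.DataFrame({
            "ecomorph": pd.Categorical(sub_meta["ecomorph"]),
            "log_cs": np.log(aligned_sub.centroid_sizes),
            "head_proportion": sub_meta["head_proportion"].to_numpy(),
            "perch_height": sub_meta["perch_height"].to_numpy(),
            "perch_diameter": sub_meta["perch_diameter"].to_numpy(),
        })
        eco_rows = eco_mask
        anova = cmp.procrustes_anova(
            sub_shape[eco_rows], sub_data[eco_rows],
            ["ecomorph", "log_cs", "ecomorph:log_cs"],
            nperm=config.nperm, seed=seeds["anova"])
        results["anova_ecomorph_size"] = anova.to_frame()
        anova_perch = cmp.procrustes_anova(
            sub_shape, sub_data,
            ["perch_height", "perch_diameter", "perch_height:perch_diameter"],
            nperm=config.nperm, seed=seeds["anova"])
        results["anova_perch"] = anova_perch.to_frame()

        if tree is not None:
            stage = "kmult"
            sig = cmp.kmult(sub_shape, tree, sub_species,
                            nperm=config.nperm, seed=seeds["kmult"])
            results["phylo_signal"] = {"K": sig.K, "p": sig.p,
                                       "nperm": sig.nperm}
            if config.run_pgls:
                stage = "pgls"
                eco_species = [s for s, m in zip(sub_species, eco_rows) if m]
                eco_tree = tree.extract_tree_with_taxa_labels(eco_species)
                pgls = cmp.procrustes_pgls(
                    sub_shape[eco_rows], sub_data[eco_rows],
                    ["ecomorph", "log_cs", "ecomorph:log_cs"],
                    eco_tree, eco_species,
                    nperm=config.nperm, seed=seeds["pgls"])
                results["pgls_ecomorph_size"] = pgls.to_frame()
            stage = "phylo_residuals"
            resid = cmp.phylo_residuals(
                pca_model.scores, np.log(aligned_sub.centroid_sizes),
                tree, sub_species)
            results["phylo_corrected_scores_sd"] = resid.std(axis=0)[:5]

        stage = "pairwise"
        dists, pvals = cmp.pairwise_group_test(
            sub_shape[eco_rows], sub_meta["ecomorph"].to_numpy()[eco_rows],
            nperm=config.nperm, seed=seeds["pairwise"])
        results["pairwise_distances"] = dists.reset_index(names="group")
        results["pairwise_p"] = pvals.reset_index(names="group")

        stage = "allometry"
        valid = meta_modern["skull_length"].notna().to_numpy()
        n_dropped = int((~valid).sum())
        if n_dropped:
            logger.info("allometry: dropped %d rows with missing skull length",
                        n_dropped)
        reg = cmp.ols_slope_ci(
            np.log(meta_modern.loc[valid, "skull_length"].to_numpy(float)),
            meta_modern.loc[valid, "log_cs"].to_numpy(float))
        results["allometry"] = {
            "slope": reg.slope, "ci_low": reg.ci_low, "ci_high": reg.ci_high,
            "level": reg.level, "n": reg.n,
            "negative_allometry": bool(reg.negative_allometry),
        }

        stage = "cva"
        full_meta = meta_modern.set_index("specimen_id").loc[aligned_full.ids]
        eco_full = full_meta["ecomorph"].isin(cio.ECOMORPH_LABELS[:6]).to_numpy()
        pca_full = ord_.pca(sup.AlignedShapes(
            aligned=aligned_full.aligned[eco_full],
            consensus=aligned_full.consensus,
            centroid_sizes=aligned_full.centroid_sizes[eco_full],
            ids=[i for i, m in zip(aligned_full.ids, eco_full) if m],
            iterations_used=aligned_full.iterations_used,
            converged=aligned_full.converged, slid=aligned_full.slid))
        groups_full = full_meta["ecomorph"].to_numpy()[eco_full]
        n_groups = len(np.unique(groups_full))
        reduced, retained = cls.reduce_dimensions(
            pca_full.scores, pca_full.variance_fractions, n_groups,
            variance_target=config.variance_target, hard_cap=config.hard_cap)
        cva_model = cls.cva(reduced, groups_full)
        accuracy, confusion = cls.cross_validate(reduced, groups_full)
        separation = cls.group_separation_test(
            cva_model.scores, groups_full, nperm=config.nperm,
            seed=seeds["separation"])
        results["cva"] = {
            "retained_pc_count": retained,
            "cross_validation_accuracy": accuracy,
            "n": int(eco_full.sum()),
            "between_fractions": cva_model.between_fractions,
        }
        results["cva_confusion"] = confusion.reset_index(names="group")
        results["group_separation_p"] = separation.reset_index(names="group")
        ellipses = {}
        for lab in cva_model.group_labels:
            pts = cva_model.group_scores[lab][:, :2]
            if len(pts) < 3:
                ellipses[lab] = {"degenerate": True, "n": int(len(pts))}
                continue
            e = cls.confidence_ellipse(pts)
            ellipses[lab] = {"center": e.center, "radii": e.radii,
                             "angle": e.angle, "degenerate": e.degenerate}
        results["cva_ellipses"] = ellipses

        stage = "classify"
        unknown_ids = (full_meta.index[full_meta["ecomorph"] == "unique"]
                       .tolist() + fossil_ids)
        if unknown_ids:
            rows = []
            id_to_row = {sid: i for i, sid in enumerate(aligned_full.ids)}
            for sid in unknown_ids:
                if sid in id_to_row:
                    flat = aligned_full.flat[id_to_row[sid]]
                else:  # fossil: OPA fit onto the full-alignment consensus
                    cfg = dataset.subset([sid]).configurations[0]
                    flat = sup.opa_fit(cfg.coords,
                                       aligned_full.consensus).reshape(-1)
                rows.append(flat)
            unknown_scores = (np.stack(rows) - pca_full.mean) \
                @ pca_full.eigenvectors[:, :retained]
            classified = cls.classify_unknowns(
                cva_model, unknown_scores, unknown_ids,
                nresample=config.nresample, seed=seeds["typicality"])
            results["classification"] = cls.classification_table(classified)

        if ground_truth is not None:
            results["ground_truth"] = ground_truth
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    results["wall_time_s"] = time.perf_counter() - t0
    if config.outdir:
        params = dataclasses.asdict(config)
        params["stage_seeds"] = seeds
        cio.write_results(results, config.outdir, params=params)
        config.to_yaml(Path(config.outdir) / "config.yaml")
    return results
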