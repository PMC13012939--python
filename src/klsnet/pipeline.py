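"""End-to-end orchestration: simulate -> networks -> topology -> stats ->
classify, with a JSON run manifest for reproducibility."""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atlases import atlas_for_metric
from .classify import FeatureMatrix, nested_cv_classify, permutation_test_auc
from .cohort import (
    DEFAULT_CT_EFFECT,
    DEFAULT_GMV_EFFECT,
    EffectConfig,
    generate_cohort,
    generate_roi_samples,
    read_cohort,
    read_roi_samples,
    write_cohort,
)
from .config import PipelineConfig
from .io import matrix_filename, read_similarity_matrix, write_similarity_matrix
from .network import build_similarity_matrix
from .stats import (
    ancova_group_effect,
    cohort_table,
    correlate_with_outcomes,
    covariate_frame,
    edgewise_stats,
    fdr_adjust,
)
from .topology import compute_topology_profile, nodal_auc_table, sparsity_grid

logger = logging.getLogger("klsnet")

#: 13-entry local imaging feature panel used by the classifier by default
DEFAULT_FEATURE_PANEL = [
    "mean:GMV:Hippocampus_L",
    "mean:GMV:Hippocampus_R",
    "mean:GMV:Thalamus_L",
    "mean:CT:lh-entorhinal",
    "mean:CT:lh-isthmuscingulate",
    "mean:CT:lh-supramarginal",
    "auc:GMV:degree:Hippocampus_L",
    "auc:GMV:degree:Hippocampus_R",
    "auc:GMV:degree:Thalamus_L",
    "auc:GMV:bc:Frontal_Inf_Orb_L",
    "auc:GMV:bc:Thalamus_L",
    "auc:GMV:nle:Thalamus_L",
    "edge:GMV:Hippocampus_L:Hippocampus_R",
]

_DEFAULT_EFFECTS = {"GMV": DEFAULT_GMV_EFFECT, "CT": DEFAULT_CT_EFFECT}

_STAGES = ("simulate", "networks", "topology", "stats", "classify")


def stage_seed(seed: int, stage: str) -> int:
    """Independent per-stage seed substream: toggling one stage leaves the
    randomness of the others untouched."""
    idx = _STAGES.index(stage)
    return int(np.random.SeedSequence([seed, idx]).generate_state(1)[0])


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _effect_config(cfg: PipelineConfig, metric: str, seed: int) -> EffectConfig:
    if metric in cfg.effects:
        e = cfg.effects[metric]
        return EffectConfig(
            affected_rois=tuple(tuple(x) for x in e.affected_rois),
            effect_size_emci=e.effect_size_emci,
            effect_size_lmci=e.effect_size_lmci,
            cognition_coupling=e.cognition_coupling,
            noise_sd=e.noise_sd,
            samples_per_roi_mean=e.samples_per_roi_mean,
            seed=seed,
        )
    base = _DEFAULT_EFFECTS.get(metric, EffectConfig())
    import dataclasses

    return dataclasses.replace(base, seed=seed)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages and return the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def register(name: str, path: Path) -> None:
        artifacts[name] = str(path)

    # --- simulate ---------------------------------------------------------
    cohort, samples = None, {}
    if cfg.run_simulate:
        logger.info("stage simulate: %d subjects", cfg.n_cn + cfg.n_emci + cfg.n_lmci)
        sseed = stage_seed(cfg.seed, "simulate")
        cohort = generate_cohort(cfg.n_cn, cfg.n_emci, cfg.n_lmci, seed=sseed)
        for metric in cfg.metrics:
            eff = _effect_config(cfg, metric, sseed)
            samples[metric] = generate_roi_samples(cohort, metric, cfg=eff)
        paths = write_cohort(cohort, samples, out)
        for name, p in paths.items():
            register(name, Path(p))
    else:
        if (out / "cohort.csv").exists():
            cohort = read_cohort(out)
            for metric in cfg.metrics:
                if (out / f"roi_samples_{metric}.tsv").exists():
                    samples[metric] = read_roi_samples(out, metric)

    # --- networks ---------------------------------------------------------
    matrices: dict[str, list] = {}
    mat_dir = out / "matrices"
    if cfg.run_networks:
        if not samples:
            raise RuntimeError("stage networks: no ROI samples available")
        mat_dir.mkdir(exist_ok=True)
        for metric, sets in samples.items():
            mats = []
            for ss in sets:
                try:
                    mat = build_similarity_matrix(
                        ss, m=cfg.grid_size,
                        bandwidth_rule=cfg.bandwidth_rule, epsilon=cfg.epsilon,
                    )
                except ValueError as exc:
                    raise RuntimeError(
                        f"stage networks failed for subject {ss.subject_id}: {exc}"
                    ) from exc
                p = mat_dir / matrix_filename(ss.subject_id, metric, ss.atlas)
                write_similarity_matrix(mat, p)
                register(f"matrix:{ss.subject_id}:{metric}", p)
                mats.append(mat)
            matrices[metric] = mats
            logger.info("stage networks: %s -> %d matrices", metric, len(mats))
    elif mat_dir.exists() and cohort is not None:
        for metric in cfg.metrics:
            atlas = atlas_for_metric(metric)
            mats = []
            for rec in cohort:
                p = mat_dir / matrix_filename(rec.subject_id, metric, atlas)
                if p.exists():
                    mats.append(
                        read_similarity_matrix(p, metric, atlas, rec.subject_id)
                    )
            if mats:
                matrices[metric] = mats

    # --- topology ---------------------------------------------------------
    profiles: dict[str, list] = {}
    if cfg.run_topology:
        if not matrices:
            raise RuntimeError("stage topology: no similarity matrices available")
        tseed = stage_seed(cfg.seed, "topology")
        g_rows, n_rows, a_rows = [], [], []
        for metric, mats in matrices.items():
            profs = []
            for mat in mats:
                prof = compute_topology_profile(
                    mat, n_nulls=cfg.n_nulls, seed=tseed
                )
                profs.append(prof)
                gt = prof.global_table.reset_index()
                gt.insert(0, "metric", metric)
                gt.insert(0, "subject_id", mat.subject_id)
                g_rows.append(gt)
                nt = prof.nodal_table.copy()
                nt.insert(0, "metric", metric)
                nt.insert(0, "subject_id", mat.subject_id)
                n_rows.append(nt)
                arow = {"subject_id": mat.subject_id, "metric": metric}
                arow.update({f"auc_{k}": v for k, v in prof.auc.items()})
                a_rows.append(arow)
            profiles[metric] = profs
            logger.info("stage topology: %s -> %d profiles", metric, len(profs))
        for name, frame in (
            ("topology_global", pd.concat(g_rows, ignore_index=True)),
            ("topology_nodal", pd.concat(n_rows, ignore_index=True)),
            ("topology_auc", pd.DataFrame(a_rows)),
        ):
            p = out / f"{name}.csv"
            frame.to_csv(p, index=False)
            register(name, p)

    # --- stats ------------------------------------------------------------
    if cfg.run_stats:
        if cohort is None:
            raise RuntimeError("stage stats: no cohort available")
        groups = np.array([r.group for r in cohort])
        p = out / "cohort_table.csv"
        cohort_table(cohort).to_csv(p, index=False)
        register("cohort_table", p)

        anc_rows, post_rows = [], []
        for metric, profs in profiles.items():
            include_tiv = metric == "GMV"
            cov = covariate_frame(cohort, include_tiv=include_tiv)
            aucs = {pr.subject_id: nodal_auc_table(pr) for pr in profs}
            rois = list(aucs[cohort[0].subject_id].index)
            for nm in ("degree", "bc", "ne", "nle"):
                node_p = []
                results = []
                for roi in rois:
                    vals = np.array([aucs[r.subject_id].loc[roi, nm] for r in cohort])
                    res = ancova_group_effect(
                        vals, groups, cov, include_tiv=include_tiv,
                        outcome_id=f"{metric}:{nm}:{roi}",
                    )
                    results.append(res)
                    node_p.append(res.p)
                adj = fdr_adjust(np.array(node_p))
                for res, pf in zip(results, adj):
                    anc_rows.append(
                        {
                            "outcome_id": res.outcome_id, "f": res.f_stat,
                            "p": res.p, "p_fdr": pf,
                            "partial_eta2": res.partial_eta2, "n": res.n,
                        }
                    )
                    for pair, d, pb in res.pairwise:
                        post_rows.append(
                            {"outcome_id": res.outcome_id, "pair": pair,
                             "cohens_d": d, "p_bonf": pb}
                        )
        if anc_rows:
            p = out / "ancova_results.csv"
            pd.DataFrame(anc_rows).to_csv(p, index=False)
            register("ancova_results", p)
            p = out / "posthoc.csv"
            pd.DataFrame(post_rows).to_csv(p, index=False)
            register("posthoc", p)
        if matrices:
            metric = cfg.metrics[0]
            if metric in matrices:
                cov = covariate_frame(cohort, include_tiv=(metric == "GMV"))
                edges = edgewise_stats(
                    matrices[metric], groups, cov, include_tiv=(metric == "GMV")
                )
                p = out / "edges_stats.csv"
                edges.to_csv(p, index=False)
                register("edges_stats", p)
        feats = _assemble_features(cfg, cohort, samples, matrices, profiles)
        if feats is not None:
            outcomes = pd.DataFrame(
                {"adas13": [r.adas13 for r in cohort],
                 "moca": [r.moca for r in cohort],
                 "mmse": [r.mmse for r in cohort]},
                index=[r.subject_id for r in cohort],
            )
            corr = correlate_with_outcomes(feats, outcomes)
            p = out / "correlations.csv"
            corr.to_csv(p, index=False)
            register("correlations", p)

    # --- classify ---------------------------------------------------------
    if cfg.run_classify:
        if cohort is None:
            raise RuntimeError("stage classify: no cohort available")
        feats = _assemble_features(cfg, cohort, samples, matrices, profiles)
        if feats is None or feats.shape[1] == 0:
            raise RuntimeError("stage classify: no features available")
        cseed = stage_seed(cfg.seed, "classify")
        grid = tuple(np.logspace(-3, 3, cfg.penalty_grid_size))
        reports = {}
        roc_rows = []
        for a, b in (("CN", "EMCI"), ("CN", "LMCI"), ("EMCI", "LMCI")):
            sel = [r for r in cohort if r.group in (a, b)]
            sids = [r.subject_id for r in sel]
            y = np.array([1 if r.group == b else 0 for r in sel])
            fm = FeatureMatrix(
                tuple(sids), tuple(feats.columns),
                feats.loc[sids].to_numpy(float), y,
            )
            cov = covariate_frame(sel, include_tiv=True)
            rep = nested_cv_classify(
                fm, cov, outer_folds=cfg.outer_folds,
                inner_folds=cfg.inner_folds, seed=cseed,
                penalty_grid=grid, task=f"{a}-{b}",
            )
            if cfg.n_permutations > 0:
                rep.permutation_p = permutation_test_auc(
                    fm, cov, rep.auc, cfg.n_permutations, seed=cseed,
                    outer_folds=cfg.outer_folds, inner_folds=cfg.inner_folds,
                    penalty_grid=grid,
                )
                rep.n_permutations = cfg.n_permutations
            reports[rep.task] = rep
            for sid, score, lab in zip(sids, rep.pooled_scores, y):
                roc_rows.append(
                    {"task": rep.task, "subject_id": sid,
                     "score": score, "label": int(lab)}
                )
            logger.info("stage classify: %s AUC=%.3f", rep.task, rep.auc)
        payload = {
            task: {
                "auc": r.auc, "accuracy": r.accuracy,
                "sensitivity": r.sensitivity, "specificity": r.specificity,
                "threshold": r.threshold, "permutation_p": r.permutation_p,
                "n_permutations": r.n_permutations, "seed": r.seed,
                "selected_features": r.selected_features,
                "selection_frequency": r.selection_frequency,
            }
            for task, r in reports.items()
        }
        p = out / "classification_report.json"
        p.write_text(json.dumps(payload, indent=2, sort_keys=True))
        register("classification_report", p)
        p = out / "roc_points.csv"
        pd.DataFrame(roc_rows).to_csv(p, index=False)
        register("roc_points", p)

    manifest = {
        "klsnet_version": __version__,
        "numpy_version": np.__version__,
        "seed": cfg.seed,
        "stage_seeds": {s: stage_seed(cfg.seed, s) for s in _STAGES},
        "config_hash": cfg.config_hash(),
        "config": cfg.to_dict(),
        "artifacts": {
            name: {"path": path, "sha256": _sha256(Path(path))}
            for name, path in sorted(artifacts.items())
        },
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _assemble_features(
    cfg: PipelineConfig, cohort, samples, matrices, profiles
) -> pd.DataFrame | None:
    """Build the classifier feature table from the configured panel.

    Feature ids: ``mean:<metric>:<roi>`` (ROI sample mean),
    ``auc:<metric>:<nodal-metric>:<roi>`` (nodal AUC),
    ``edge:<metric>:<roi_i>:<roi_j>`` (similarity entry). Entries whose
    source stage did not run are skipped with a warning.
    """
    panel = cfg.feature_panel or DEFAULT_FEATURE_PANEL
    sids = [r.subject_id for r in cohort]
    cols: dict[str, np.ndarray] = {}
    auc_cache: dict[str, dict[str, pd.DataFrame]] = {
        metric: {pr.subject_id: nodal_auc_table(pr) for pr in profs}
        for metric, profs in profiles.items()
    }
    for feat in panel:
        parts = feat.split(":")
        kind, metric = parts[0], parts[1]
        if kind == "mean":
            if metric not in samples:
                warnings.warn(f"feature {feat}: samples for {metric} unavailable")
                continue
            roi = parts[2]
            by_sid = {s.subject_id: s for s in samples[metric]}
            cols[feat] = np.array(
                [by_sid[sid].samples[roi].mean() for sid in sids]
            )
        elif kind == "auc":
            if metric not in auc_cache:
                warnings.warn(f"feature {feat}: topology for {metric} unavailable")
                continue
            nm, roi = parts[2], parts[3]
            cols[feat] = np.array(
                [auc_cache[metric][sid].loc[roi, nm] for sid in sids]
            )
        elif kind == "edge":
            if metric not in matrices:
                warnings.warn(f"feature {feat}: matrices for {metric} unavailable")
                continue
            ri, rj = parts[2], parts[3]
            by_sid = {m.subject_id: m for m in matrices[metric]}
            vals = []
            for sid in sids:
                m = by_sid[sid]
                vals.append(m.values[m.labels.index(ri), m.labels.index(rj)])
            cols[feat] = np.array(vals)
        else:
            raise ValueError(f"unknown feature kind in {feat!r}")
    if not cols:
        return None
    return pd.DataFrame(cols, index=sids)
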