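"""End-to-end orchestration on a synthetic cohort.

Stages: cohort synthesis -> two-channel assembly -> ROI extraction ->
CAE-FC training/assignment -> pattern-frequency histograms -> EFA ->
QCT metrics -> subject k-means -> cohort statistics -> airway
resistance/deposition surrogate.  Every stage writes its outputs as
CSV/JSON into the run directory and a manifest records parameters,
seeds and per-file checksums; a rerun with the same config reproduces
identical checksums.

The default configuration is the package's synthetic study condition:
two groups of 10 subjects on 64 mm^3 grids whose tissue-pattern
mixtures differ (an "exposed-like" group enriched for deflation-limited
and hypo-inflated patterns vs a mostly-normal control group).
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .airway import breathing_waveform, deposition_1d, pressure_drop
from .caefc import assign_patches, select_cluster_count, train_caefc
from .clusters import kmeans_factor_space, representative_subject
from .containers import SubjectProfile
from .deformation import build_two_channel, jacobian_determinant
from .efa import factor_associations, factor_variable_correlations, fit_efa
from .qct import qct_record, qct_table
from .quantify import histogram_matrix, pattern_summaries, subject_histogram
from .roi import sample_random_rois, sliding_window_rois
from .stats import games_howell, welch_anova, welch_t
from .synthetic import generate_airway_tree, generate_cohort

__all__ = ["default_config", "run_pipeline"]

# per-stage seed offsets fanned out from the global seed
_STAGE_SEED = {"cohort": 1, "rois": 2, "caefc": 3, "efa": 4, "kmeans": 5, "tree": 6}


def default_config() -> dict:
    return {
        "seed": 0,
        "shape": [64, 64, 64],
        "spacing": 1.0,
        "cohort": {
            "n_per_group": {"exposed": 10, "control": 10},
            "group_mixtures": {
                "exposed": {"normal": 0.45, "low_j": 0.25,
                            "hypoinflated": 0.20, "hyperlucent": 0.10},
                "control": {"normal": 0.70, "hyperlucent": 0.20,
                            "low_j": 0.07, "hypoinflated": 0.03},
            },
            "covariate_shifts": {
                "exposed": {"exposure_p": 1.0, "gender_p": 0.45},
                "control": {"exposure_p": 0.0, "gender_p": 0.8},
            },
            # within-group Dirichlet concentration: high enough that
            # subject mixtures stay well separated between groups
            "mixture_concentration": 300.0,
        },
        "roi": {"roi_mm": 20.0, "stride_mm": 5.0, "min_lung_fraction": 0.5,
                "n_train_per_subject": 24},
        "caefc": {"n_pattern_clusters": 8, "candidates": None, "epochs": 20,
                  "batch_size": 32, "learning_rate": 3e-3, "n_models": 1},
        "efa": {"n_factors": 2, "rotation": "varimax"},
        "kmeans": {"n_clusters": 2, "n_restarts": 10},
        "airway": {"n_generations": 8, "root_diameter": 16.0,
                   "reduction_ratio": 0.78, "asymmetry": 0.1,
                   "particle_diameter_um": 0.5},
        "stages": {"qct": True, "correlations": True, "stats": True, "airway": True},
    }


def _merge(base: dict, override: dict | None) -> dict:
    """Merge a user config onto the defaults: top-level sections merge
    key-by-key, but mapping-valued settings inside a section (group
    tables, mixtures, stage toggles ...) replace wholesale."""
    if not override:
        return base
    out = dict(base)
    for section, v in override.items():
        if isinstance(v, dict) and isinstance(base.get(section), dict):
            merged = dict(base[section])
            merged.update(v)
            out[section] = merged
        else:
            out[section] = v
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(out_dir: str | Path, config: dict | None = None) -> Path:
    """Run every stage; returns the run directory (with manifest.json)."""
    cfg = _merge(default_config(), config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    t0 = time.time()
    written: list[Path] = []

    def save_df(df: pd.DataFrame, name: str, index=True):
        p = out / name
        df.to_csv(p, index=index)
        written.append(p)
        return p

    # --- cohort -----------------------------------------------------------
    records, metadata = generate_cohort(
        n_per_group=cfg["cohort"]["n_per_group"],
        group_mixtures=cfg["cohort"]["group_mixtures"],
        covariate_shifts=cfg["cohort"].get("covariate_shifts"),
        mixture_concentration=cfg["cohort"].get("mixture_concentration", 300.0),
        seed=seed + _STAGE_SEED["cohort"],
        shape=tuple(cfg["shape"]),
        spacing=float(cfg["spacing"]),
    )
    save_df(metadata, "metadata.csv", index=False)

    # --- two-channel + ROIs -------------------------------------------------
    roi_cfg = cfg["roi"]
    train_patches, window_patches, window_subjects = [], [], []
    volumes = {}
    for i, (profile, scan) in enumerate(records):
        vol = build_two_channel(scan)
        volumes[profile.subject_id] = (profile, scan, vol)
        train_patches += sample_random_rois(
            vol, roi_cfg["n_train_per_subject"], roi_mm=roi_cfg["roi_mm"],
            min_lung_fraction=roi_cfg["min_lung_fraction"],
            seed=seed + _STAGE_SEED["rois"] + i, label_grid=scan.pattern_label,
        )
        wins = sliding_window_rois(
            vol, roi_mm=roi_cfg["roi_mm"], stride_mm=roi_cfg["stride_mm"],
            min_lung_fraction=roi_cfg["min_lung_fraction"],
        )
        window_patches.append(wins)
        window_subjects.append(profile.subject_id)

    # --- CAE-FC -------------------------------------------------------------
    cae_cfg = cfg["caefc"]
    if cae_cfg.get("candidates"):
        C, loss_table = select_cluster_count(
            train_patches, cae_cfg["candidates"], epochs=cae_cfg["epochs"],
            batch_size=cae_cfg["batch_size"], learning_rate=cae_cfg["learning_rate"],
            seed=seed + _STAGE_SEED["caefc"],
        )
        (out / "cluster_count_selection.json").write_text(
            json.dumps({"selected": C, "losses": loss_table}, indent=1))
        written.append(out / "cluster_count_selection.json")
    else:
        C = cae_cfg["n_pattern_clusters"]
    # an ensemble of independently seeded CAE-FC models: each model is a
    # full pattern-cluster quantization; per-subject histograms from all
    # models are concatenated so the factor analysis pools them
    n_models = int(cae_cfg.get("n_models", 1))
    models = []
    for rep in range(n_models):
        model = train_caefc(
            train_patches, C, epochs=cae_cfg["epochs"], batch_size=cae_cfg["batch_size"],
            learning_rate=cae_cfg["learning_rate"],
            seed=seed + _STAGE_SEED["caefc"] + 1000 * rep,
        )
        name = "caefc_model.npz" if n_models == 1 else f"caefc_model_m{rep}.npz"
        model.save(out / name)
        written.append(out / name)
        models.append(model)
    save_df(
        pd.DataFrame({f"loss_m{rep}": m.training_log for rep, m in enumerate(models)})
        .rename_axis("epoch").reset_index(),
        "training_loss.csv", index=False)

    # --- histograms ---------------------------------------------------------
    blocks = []
    all_summ_assign, all_summ_patches = [], []
    for rep, model in enumerate(models):
        hists = []
        for sid, wins in zip(window_subjects, window_patches):
            asg = assign_patches(model, wins)
            hists.append(subject_histogram(asg, C, subject_id=sid))
            if rep == 0:
                base = len(all_summ_patches)
                for a in asg:
                    a.patch_id += base
                all_summ_assign += asg
                all_summ_patches += wins
        block = histogram_matrix(hists)
        if n_models > 1:
            block.columns = [f"m{rep}{c}" for c in block.columns]
        blocks.append(block)
    hist_df = pd.concat(blocks, axis=1)
    save_df(hist_df, "histograms.csv")
    summ = pattern_summaries(all_summ_assign, all_summ_patches, C)
    save_df(pd.DataFrame([s.__dict__ for s in summ]), "pattern_summaries.csv", index=False)

    # --- EFA ----------------------------------------------------------------
    efa_cfg = cfg["efa"]
    fm = fit_efa(hist_df, n_factors=efa_cfg["n_factors"],
                 rotation=efa_cfg["rotation"], seed=seed + _STAGE_SEED["efa"])
    save_df(fm.loadings_frame(), "factor_loadings.csv")
    scores_df = pd.DataFrame(fm.scores, index=hist_df.index,
                             columns=[f"F{i}" for i in range(fm.n_factors)])
    save_df(scores_df, "factor_scores.csv")
    assoc = factor_associations(fm)
    (out / "factor_associations.json").write_text(assoc.to_json(indent=1))
    written.append(out / "factor_associations.json")

    # --- QCT ----------------------------------------------------------------
    stages = cfg["stages"]
    tree_cfg = cfg["airway"]
    trees = {}
    if stages["qct"]:
        qct_records = []
        for i, sid in enumerate(window_subjects):
            profile, scan, vol = volumes[sid]
            tree = generate_airway_tree(
                n_generations=tree_cfg["n_generations"],
                root_diameter=tree_cfg["root_diameter"],
                reduction_ratio=tree_cfg["reduction_ratio"],
                asymmetry=tree_cfg["asymmetry"],
                seed=seed + _STAGE_SEED["tree"] + i,
            )
            trees[sid] = tree
            jac = jacobian_determinant(scan.displacement, scan.spacing)
            qct_records.append(qct_record(scan, jac, airway_volume_ml=tree.volume_ml()))
        qdf = qct_table(qct_records)
        save_df(qdf, "qct_metrics.csv")

    # --- factor/variable correlations --------------------------------------
    if stages["qct"] and stages["correlations"]:
        variables = metadata.set_index("subject_id")[
            ["age", "height", "weight", "gender", "exposure"]
        ].join(qdf[["RV_TLC", "Tissue_pct_Total", "LAA_TLC_pct_Total", "fSAD_pct_Total"]])
        full_corr, masked_corr = factor_variable_correlations(
            fm.scores, variables.loc[hist_df.index], binary={"gender", "exposure"})
        save_df(full_corr, "factor_correlations_full.csv")
        (out / "factor_correlations_masked.json").write_text(masked_corr.to_json(indent=1))
        written.append(out / "factor_correlations_masked.json")

    # --- subject clustering -------------------------------------------------
    km_cfg = cfg["kmeans"]
    assignments, centroids = kmeans_factor_space(
        fm.scores, list(hist_df.index), n_clusters=km_cfg["n_clusters"],
        seed=seed + _STAGE_SEED["kmeans"], n_restarts=km_cfg["n_restarts"],
    )
    cluster_df = pd.DataFrame([a.__dict__ for a in assignments])
    save_df(cluster_df, "subject_clusters.csv", index=False)

    # --- cohort statistics --------------------------------------------------
    if stages["stats"]:
        merged = metadata.set_index("subject_id").join(
            cluster_df.set_index("subject_id")["cluster_id"])
        stats_rows = []
        for var in ("age", "height", "weight", "fvc_pct", "fev1_pct"):
            groups = [g[var].to_numpy() for _, g in merged.groupby("cluster_id") if len(g) >= 2]
            if len(groups) >= 2:
                f, d1, d2, p = welch_anova(groups)
                stats_rows.append({"variable": var, "test": "welch_anova", "stat": f, "p": p})
        save_df(pd.DataFrame(stats_rows), "cohort_stats.csv", index=False)

    # --- airway surrogate for representative subjects -----------------------
    if stages["airway"] and stages["qct"]:
        dep_rows = []
        for cid in sorted(cluster_df["cluster_id"].unique()):
            rep = representative_subject(assignments, cid)
            profile = volumes[rep][0]
            wf = breathing_waveform(profile.weight)
            tree = trees[rep]
            dp = pressure_drop(tree, wf.peak_flow)
            dep = deposition_1d(tree, wf,
                                particle_diameter_um=tree_cfg["particle_diameter_um"])
            dep_rows.append({
                "cluster_id": int(cid), "subject_id": rep,
                "tidal_volume_ml": wf.tidal_volume, "peak_flow_ml_s": wf.peak_flow,
                "total_path_dp_pa": float(dp["path_dp_pa"].max()),
                "total_conducting_df": dep.total_df, "escape_fraction": dep.escape,
            })
        save_df(pd.DataFrame(dep_rows), "airway_deposition.csv", index=False)

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "elapsed_s": round(time.time() - t0, 2),
        "checksums": {p.name: _sha256(p) for p in written},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
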