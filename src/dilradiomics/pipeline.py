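"""End-to-end orchestration: simulate -> extract -> PLSC -> train -> map.

Each stage reads the previous stage's artifacts from a working directory,
writes its own (CSV/JSON/NIfTI) together with a JSON manifest recording
settings, seed and input hashes, and can be rerun idempotently. The
in-memory helpers (``extract_features``, ``latent_dataset``, ...) carry the
same computation for library users and the test-suite.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ann, lesionmap, plsc, radfeat
from .synthcohort import CohortConfig, SyntheticSubject, generate_cohort, read_cohort, write_cohort

__all__ = ["PipelineConfig", "extract_features", "latent_dataset",
           "loocv_with_plsc_refit", "run_stage", "run_all", "STAGES"]

STAGES = ("simulate", "extract", "plsc", "train", "evaluate", "map",
          "variability")


@dataclass
class PipelineConfig:
    """All tunables of the analysis, with the study defaults."""

    workdir: str = "results/pipeline"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    harmonize_adc: bool = True
    n_permutations: int = 10_000
    n_boot: int = 500
    alpha: float = 0.05
    silhouette_threshold: float = 0.5
    k_per_modality: int = 4
    n_hidden: int = 5
    learning_rate: float = 0.01
    momentum: float = 0.01
    max_epochs: int = 300
    n_iter: int = 100
    train_frac: float = 2 / 3
    map_window: int = 25
    map_stride: int = 4
    p_thr: float = 0.001
    n_variability_subjects: int = 19
    seed: int = 42

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2 ** 31)


# ---------------------------------------------------------------------------
# In-memory computation helpers
# ---------------------------------------------------------------------------

def extract_features(subjects: list[SyntheticSubject],
                     harmonize_adc: bool = True) -> pd.DataFrame:
    """168-feature rows for every subject x ROI x modality.

    Volumes are harmonized by the subject's NT-mask mean (ADC included by
    default) before extraction.
    """
    rows = []
    for s in subjects:
        t2w = radfeat.harmonize(s.t2w_volume, s.nt_mask)
        adc = radfeat.harmonize(s.adc_volume, s.nt_mask) if harmonize_adc \
            else s.adc_volume
        for modality, vol in (("T2W", t2w), ("ADC", adc)):
            for roi_kind, mask in (("DIL", s.dil_mask), ("NT", s.nt_mask)):
                fv = radfeat.extract_all(vol, mask, modality=modality,
                                         roi_kind=roi_kind,
                                         subject_id=s.subject_id)
                rows.append({"subject_id": s.subject_id, "roi_kind": roi_kind,
                             "modality": modality, "group_tag": s.group_tag,
                             **dict(zip(radfeat.FEATURE_NAMES, fv.values))})
    return pd.DataFrame(rows)


@dataclass
class LatentScaler:
    """Z-scoring of latent rows with training-set statistics."""

    means: np.ndarray
    stds: np.ndarray

    def __call__(self, rows: np.ndarray) -> np.ndarray:
        return (np.asarray(rows, dtype=float) - self.means) / self.stds


def latent_dataset(selection: plsc.LatentFeatureSet
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray, LatentScaler]:
    """(features, labels, subject_ids, scaler) ready for the classifier.

    Latent scores are z-scored column-wise (training statistics stored in
    the returned scaler) and labels are boolean with DIL = True.
    """
    if selection.is_empty:
        raise ValueError("empty latent selection; nothing to classify")
    means = selection.features.mean(axis=0)
    stds = selection.features.std(axis=0, ddof=1)
    stds = np.where(stds == 0, 1.0, stds)
    scaler = LatentScaler(means=means, stds=stds)
    return (scaler(selection.features), selection.labels == "DIL",
            selection.subject_ids, scaler)


def loocv_with_plsc_refit(feature_table: pd.DataFrame, n_hidden: int = 5,
                          config: ann.TrainConfig | None = None,
                          k_per_modality: int = 4, init_seed: int = 0,
                          alpha: float = 0.05,
                          silhouette_threshold: float = 0.5) -> ann.CVResult:
    """Leakage-free LOOCV: PLSC, selection and scaling refit per fold.

    The held-out subject's rows are projected through the fold's model.
    The fold's latent selection is pinned to the training fold's choice;
    folds with an empty selection fall back to the first
    ``k_per_modality`` latents per block.
    """
    subjects = feature_table["subject_id"].unique()
    if len(subjects) < 3:
        raise ValueError("LOOCV needs at least 3 subjects")
    all_preds, all_labels = [], []
    for held in subjects:
        tr = feature_table[feature_table["subject_id"] != held]
        te = feature_table[feature_table["subject_id"] == held]
        bx, by = plsc.build_blocks(tr)
        model = plsc.fit_plsc(bx, by)
        sel = plsc.select_discriminant(model, k_per_modality=k_per_modality,
                                       alpha=alpha,
                                       silhouette_threshold=silhouette_threshold)
        if sel.is_empty:
            sel.selected_x = np.arange(k_per_modality)
            sel.selected_y = np.arange(k_per_modality)
            sel.features = np.hstack([model.Lx[:, :k_per_modality],
                                      model.Ly[:, :k_per_modality]])
        X, y, sids, scaler = latent_dataset(sel)
        t = np.where(y, 1.0, -1.0)
        init = ann.init_model(X.shape[1], n_hidden, seed=init_seed)
        trained, _, _ = ann.train(init, X, t, config or ann.TrainConfig())
        te_x, te_y, te_labels = _rows_by_modality(te)
        latent = scaler(plsc.project_selected(model, sel, te_x, te_y))
        all_preds.append(ann.forward(trained, latent))
        all_labels.append(te_labels == "DIL")
    preds = np.concatenate(all_preds)
    labels = np.concatenate(all_labels)
    return ann.CVResult(predictions=preds, labels=labels,
                        roc=ann.roc_analysis(preds, labels))


def _rows_by_modality(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    names = radfeat.FEATURE_NAMES
    key = ["subject_id", "roi_kind"]
    px = table[table["modality"] == "T2W"].set_index(key)[names]
    py = table[table["modality"] == "ADC"].set_index(key)[names]
    py = py.loc[px.index]
    labels = np.asarray([k[1] for k in px.index])
    return px.to_numpy(float), py.to_numpy(float), labels


# ---------------------------------------------------------------------------
# Stage runner
# ---------------------------------------------------------------------------

def _write_manifest(workdir: Path, stage: str, settings: dict,
                    outputs: list[str]) -> None:
    digest = {}
    for name in outputs:
        p = workdir / name
        if p.exists():
            digest[name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
    (workdir / f"{stage}.manifest.json").write_text(json.dumps({
        "stage": stage, "settings": settings, "outputs": digest}, indent=2,
        default=str))


def _require(workdir: Path, name: str, stage_needed: str) -> Path:
    p = workdir / name
    if not p.exists():
        raise FileNotFoundError(
            f"missing artifact {name}; run the '{stage_needed}' stage first")
    return p


def _stage_simulate(cfg: PipelineConfig, wd: Path) -> dict:
    subjects = generate_cohort(cfg.cohort)
    write_cohort(subjects, wd / "cohort", spacing=cfg.cohort.voxel_spacing)
    return {"n_subjects": len(subjects)}


def _stage_extract(cfg: PipelineConfig, wd: Path) -> dict:
    manifest = _require(wd, "cohort/subjects.csv", "simulate")
    subjects = read_cohort(manifest)
    table = extract_features(subjects, harmonize_adc=cfg.harmonize_adc)
    table.to_csv(wd / "features.csv", index=False)
    (wd / "extraction_settings.json").write_text(json.dumps({
        "harmonize_adc": cfg.harmonize_adc,
        "feature_names": radfeat.FEATURE_NAMES}, indent=2))
    return {"n_rows": len(table)}


def _load_plsc_state(wd: Path):
    table = pd.read_csv(_require(wd, "features.csv", "extract"))
    bx, by = plsc.build_blocks(table)
    model = plsc.fit_plsc(bx, by)
    return table, model


def _stage_plsc(cfg: PipelineConfig, wd: Path) -> dict:
    table, model = _load_plsc_state(wd)
    seed = cfg.stage_seed("plsc")
    perm = plsc.permutation_test_inertia(model.block_x, model.block_y,
                                         n_permutations=cfg.n_permutations,
                                         seed=seed)
    rank_x, rank_y = plsc.bootstrap_ratios(model.block_x, model.block_y,
                                           n_boot=cfg.n_boot, seed=seed)
    sel = plsc.select_discriminant(model, k_per_modality=cfg.k_per_modality,
                                   alpha=cfg.alpha,
                                   silhouette_threshold=cfg.silhouette_threshold)
    np.savez(wd / "plsc_model.npz", U=model.U, V=model.V,
             singular_values=model.singular_values,
             x_means=model.block_x.col_means, x_scales=model.block_x.col_scales,
             y_means=model.block_y.col_means, y_scales=model.block_y.col_scales,
             selected_x=sel.selected_x, selected_y=sel.selected_y)
    scores = pd.DataFrame({"subject_id": model.block_x.subject_ids,
                           "roi_kind": model.block_x.roi_kinds})
    for k in range(min(8, model.Lx.shape[1])):
        scores[f"T2W_LV{k + 1}"] = model.Lx[:, k]
        scores[f"ADC_LV{k + 1}"] = model.Ly[:, k]
    scores.to_csv(wd / "latent_scores.csv", index=False)
    ranking = pd.concat([rank_x.table().assign(modality="T2W"),
                         rank_y.table().assign(modality="ADC")])
    ranking["category"] = ranking["feature"].str.split("_").str[0]
    ranking.to_csv(wd / "ranking.csv", index=False)
    summary = {"inertia": model.inertia, "permutation_p": perm.p_value,
               "selected_x": sel.selected_x.tolist(),
               "selected_y": sel.selected_y.tolist(),
               "empty_selection": bool(sel.is_empty)}
    (wd / "plsc_summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def _rebuild_selection(cfg, wd):
    table, model = _load_plsc_state(wd)
    state = np.load(_require(wd, "plsc_model.npz", "plsc"))
    sel = plsc.LatentFeatureSet(
        features=np.hstack([model.Lx[:, state["selected_x"]],
                            model.Ly[:, state["selected_y"]]]),
        labels=model.block_x.roi_kinds,
        subject_ids=model.block_x.subject_ids,
        selected_x=state["selected_x"], selected_y=state["selected_y"])
    return table, model, sel


def _stage_train(cfg: PipelineConfig, wd: Path) -> dict:
    table, model, sel = _rebuild_selection(cfg, wd)
    if sel.is_empty:
        (wd / "train_summary.json").write_text(json.dumps(
            {"empty_selection": True}, indent=2))
        return {"empty_selection": True}
    X, y, sids, scaler = latent_dataset(sel)
    tcfg = ann.TrainConfig(cfg.learning_rate, cfg.momentum, cfg.max_epochs)
    seed = cfg.stage_seed("train")
    cv = ann.loocv(X, y, sids, n_hidden=cfg.n_hidden, config=tcfg,
                   init_seed=seed)
    t = np.where(y, 1.0, -1.0)
    final, _, _ = ann.train(ann.init_model(X.shape[1], cfg.n_hidden, seed),
                            X, t, tcfg)
    np.savez(wd / "ann_model.npz", W1=final.W1, b1=final.b1, W2=final.W2,
             b2=final.b2, latent_means=scaler.means, latent_stds=scaler.stds)
    pd.DataFrame({"epoch": np.arange(1, len(cv.ccf_curve) + 1),
                  "ccf": cv.ccf_curve}).to_csv(wd / "ccf_curve.csv", index=False)
    summary = {"loocv_auroc": cv.roc.auroc, "auccf": cv.auccf,
               "stop_epoch": cv.stop_epoch, "n_hidden": cfg.n_hidden,
               "optimal_cutpoint": cv.roc.optimal_cutpoint,
               "ppv": cv.roc.ppv, "npv": cv.roc.npv}
    (wd / "train_summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def _stage_evaluate(cfg: PipelineConfig, wd: Path) -> dict:
    table, model, sel = _rebuild_selection(cfg, wd)
    if sel.is_empty:
        return {"empty_selection": True}
    X, y, sids, _ = latent_dataset(sel)
    tcfg = ann.TrainConfig(cfg.learning_rate, cfg.momentum, cfg.max_epochs)
    seed = cfg.stage_seed("evaluate")
    split = ann.split_strategy(X, y, sids, n_iter=cfg.n_iter,
                               train_frac=cfg.train_frac, config=tcfg,
                               seed=seed, n_hidden=cfg.n_hidden)
    groups = table.drop_duplicates("subject_id").set_index("subject_id")["group_tag"]
    tags = np.asarray([groups[s] for s in sids])
    summary = {"split_auroc_mean": float(split.auroc_samples.mean()),
               "split_auroc_ci": split.auroc_ci,
               "split_ppv_mean": float(split.ppv_samples.mean()),
               "split_npv_mean": float(split.npv_samples.mean())}
    if (tags == "B").any() and (tags == "A").any():
        roc_b, _ = ann.cross_cohort_eval(
            X[tags == "A"], y[tags == "A"], sids[tags == "A"],
            X[tags == "B"], y[tags == "B"], sids[tags == "B"],
            n_hidden=cfg.n_hidden, config=tcfg, init_seed=seed)
        summary.update({"cross_cohort_auroc": roc_b.auroc,
                        "cross_cohort_sensitivity": roc_b.sensitivity,
                        "cross_cohort_specificity": roc_b.specificity})
    pd.DataFrame({"iteration": np.arange(1, cfg.n_iter + 1),
                  "auroc": split.auroc_samples, "ppv": split.ppv_samples,
                  "npv": split.npv_samples}).to_csv(wd / "metrics.csv",
                                                    index=False)
    (wd / "evaluate_summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def _stage_map(cfg: PipelineConfig, wd: Path) -> dict:
    import nibabel as nib

    table, model, sel = _rebuild_selection(cfg, wd)
    if sel.is_empty:
        return {"empty_selection": True}
    X, y, sids, scaler = latent_dataset(sel)
    t = np.where(y, 1.0, -1.0)
    seed = cfg.stage_seed("map")
    trained, _, _ = ann.train(
        ann.init_model(X.shape[1], cfg.n_hidden, seed), X, t,
        ann.TrainConfig(cfg.learning_rate, cfg.momentum, cfg.max_epochs))
    subjects = read_cohort(_require(wd, "cohort/subjects.csv", "simulate"))
    held_out = [s for s in subjects if s.group_tag == "B"][:2] or subjects[-2:]
    rows = []
    for s in held_out:
        z = int(np.nonzero(s.dil_mask.any(axis=(1, 2)))[0].mean())
        pmap = lesionmap.probability_map(
            s.t2w_volume, s.adc_volume, s.nt_mask, model, sel, trained,
            window=cfg.map_window, stride=cfg.map_stride,
            slice_indices=[z], latent_scaler=scaler)
        patch = lesionmap.threshold_map(pmap, s.t2w_volume.shape,
                                        p_thr=cfg.p_thr)
        d = lesionmap.dice(patch[z], s.dil_mask[z])
        rows.append({"subject_id": s.subject_id, "slice": z, "dice": d})
        affine = np.diag([*cfg.cohort.voxel_spacing[::-1], 1.0])
        nib.save(nib.Nifti1Image(pmap.probabilities[0].T.astype(np.float32),
                                 affine),
                 wd / f"{s.subject_id}_probmap.nii.gz")
    pd.DataFrame(rows).to_csv(wd / "dice_report.csv", index=False)
    return {"dice": [r["dice"] for r in rows]}


def _stage_variability(cfg: PipelineConfig, wd: Path) -> dict:
    table, model, sel = _rebuild_selection(cfg, wd)
    if sel.is_empty:
        return {"empty_selection": True}
    subjects = read_cohort(_require(wd, "cohort/subjects.csv", "simulate"))
    rng = np.random.default_rng(cfg.stage_seed("variability"))
    n = min(cfg.n_variability_subjects, len(subjects))
    chosen = [subjects[i] for i in rng.choice(len(subjects), n, replace=False)]
    result = lesionmap.contour_variability_test(
        chosen, model, sel, harmonize_adc=cfg.harmonize_adc)
    pd.DataFrame({"latent": np.arange(1, len(result.F) + 1),
                  "F": result.F, "F_critical": result.F_critical,
                  "passed": result.passed}).to_csv(wd / "variability_report.csv",
                                                   index=False)
    return {"F_critical": result.F_critical,
            "all_passed": result.all_passed}


_STAGE_FNS = {"simulate": _stage_simulate, "extract": _stage_extract,
              "plsc": _stage_plsc, "train": _stage_train,
              "evaluate": _stage_evaluate, "map": _stage_map,
              "variability": _stage_variability}


def run_stage(stage_name: str, config: PipelineConfig) -> dict:
    """Run one pipeline stage; returns its summary dictionary."""
    if stage_name not in _STAGE_FNS:
        raise ValueError(f"unknown stage {stage_name!r}; choose from {STAGES}")
    wd = Path(config.workdir)
    wd.mkdir(parents=True, exist_ok=True)
    summary = _STAGE_FNS[stage_name](config, wd)
    settings = asdict(config)
    settings["stage_seed"] = config.stage_seed(stage_name)
    _write_manifest(wd, stage_name, settings,
                    [p.name for p in wd.iterdir() if p.is_file()])
    return summary


def run_all(config: PipelineConfig) -> dict:
    """Run every stage in order; returns the combined report."""
    report = {}
    for stage in STAGES:
        report[stage] = run_stage(stage, config)
    wd = Path(config.workdir)
    (wd / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
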