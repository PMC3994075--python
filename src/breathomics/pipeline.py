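"""End-to-end orchestration: simulate -> preprocess -> features -> models.

``run_pipeline`` executes the whole analysis on a synthetic cohort with one
master seed: render breathograms, clean and align them, build the compound
table, fit the two binary random-forest models (model 1: healthy vs asthma,
model 2: transient wheeze vs asthma), project every sample into the
combined proximity-PCA space, and corroborate the selected VOC union with a
dissimilarity-PLS-DA model on the inclusion-visit samples of the two wheeze
classes.  All stage outputs are written as TSV/JSON with a run manifest of
content digests, so a rerun with the same config is bit-checkable.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import dplsda as dp
from . import evaluate, features, io, preprocess, projection, rf, synthetic

MODEL1 = ("healthy", "asthma")            # deviant-process model
MODEL2 = ("transient_wheeze", "asthma")   # asthma-specific model


class CohortConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_subjects_per_class: tuple[int, int, int] = (12, 20, 20)
    samples_per_subject: tuple[int, int] = (3, 5)
    n_compounds: int = 80
    n_shared_effects: int = 7
    n_healthy_model_effects: int = 5
    n_wheeze_model_effects: int = 5
    effect_size: float = 1.5
    subject_sd: float = 0.4
    sample_sd: float = 0.3
    noise_sd: float = 0.01
    baseline_amplitude: float = 1.0
    max_rt_shift: float = 0.1
    zero_inflation: float = 0.3
    grid_step: float = 0.02


class PreprocessConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    trim_lo: float = 1.3
    trim_hi: float = 23.0
    wavelet: str = "db4"
    level: int = 2
    lam: float = 1e8
    p: float = 0.1
    segment_len: int = 20
    slack: int = 7
    reference: Optional[str] = None  # sample id; default: most-correlated sample


class FeaturesConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    rt_tolerance: float = 0.1
    min_spectral_correlation: float = 0.9
    presence_fraction: float = 0.20
    normalization: Literal["tic", "pqn"] = "tic"

    @field_validator("presence_fraction")
    @classmethod
    def _fraction_range(cls, v: float) -> float:
        if not 0.0 < v <= 1.0:
            raise ValueError("presence_fraction must be in (0, 1]")
        return v


class RFConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_trees: int = 1000
    resample_unit: Literal["sample", "subject"] = "sample"
    k_top: int = 12
    test_fraction: float = 0.2


class DPLSDAConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    max_lv: Optional[int] = None  # default min(n_train - 1, 15)


class RunConfig(BaseModel):
    """Schema-validated configuration of a full pipeline run."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    features: FeaturesConfig = Field(default_factory=FeaturesConfig)
    rf: RFConfig = Field(default_factory=RFConfig)
    dplsda: DPLSDAConfig = Field(default_factory=DPLSDAConfig)


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _spawn_seeds(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def simulate_stage(config: RunConfig):
    """Library, cohort and rendered breathograms from the master seed."""
    c = config.cohort
    library = synthetic.generate_compound_library(c.n_compounds, seed=config.seed)
    effect_table = synthetic.make_effect_table(
        library,
        n_shared=c.n_shared_effects,
        n_healthy_model=c.n_healthy_model_effects,
        n_wheeze_model=c.n_wheeze_model_effects,
        effect=c.effect_size,
        seed=config.seed,
    )
    design = synthetic.CohortDesign(
        n_subjects_per_class=c.n_subjects_per_class,
        samples_per_subject=c.samples_per_subject,
        n_compounds=c.n_compounds,
        effect_table=effect_table,
        subject_sd=c.subject_sd,
        sample_sd=c.sample_sd,
        noise_sd=c.noise_sd,
        baseline_amplitude=c.baseline_amplitude,
        max_rt_shift=c.max_rt_shift,
        zero_inflation=c.zero_inflation,
        seed=config.seed,
    )
    meta, truth = synthetic.generate_cohort(design, library)
    chroms = synthetic.render_cohort(meta, truth, library, design,
                                     grid_step=c.grid_step)
    return library, design, meta, truth, chroms


def preprocess_stage(chroms, config: RunConfig):
    """Trim, denoise, baseline-correct, align and integrate every sample."""
    p = config.preprocess
    cleaned = []
    for ch in chroms:
        c = preprocess.trim_retention_window(ch, p.trim_lo, p.trim_hi)
        c = preprocess.denoise_wavelet(c, wavelet=p.wavelet, level=p.level)
        c, _ = preprocess.correct_baseline(c, lam=p.lam, p=p.p)
        cleaned.append(c)
    if p.reference is not None:
        ref_idx = next(
            i for i, c in enumerate(cleaned) if c.sample_id == p.reference
        )
    else:
        ref_idx = preprocess.choose_reference(cleaned)
    reference = cleaned[ref_idx]
    aligned = []
    for i, c in enumerate(cleaned):
        if i == ref_idx:
            aligned.append(c)
            continue
        a, _ = preprocess.align_cow(
            c, reference, segment_len=p.segment_len, slack=p.slack
        )
        aligned.append(a)
    peaklists = [preprocess.detect_and_integrate_peaks(c) for c in aligned]
    return aligned, peaklists, reference.sample_id


def features_stage(peaklists, meta, config: RunConfig):
    """Merge peaks into compounds, normalize, apply the presence rule."""
    f = config.features
    ctable = features.merge_compounds_across_samples(
        peaklists,
        rt_tolerance=f.rt_tolerance,
        min_spectral_correlation=f.min_spectral_correlation,
    )
    table = ctable.values.loc[meta["sample_id"]]
    table = table.loc[:, table.sum(axis=0) > 0]
    norm = features.normalize_total_area(table)
    if f.normalization == "pqn":
        norm = features.normalize_pqn(norm)
    filtered = features.apply_presence_filter(norm, meta, f.presence_fraction)
    ctable2 = features.CompoundTable(
        values=filtered,
        consensus_rt=ctable.consensus_rt.loc[filtered.columns],
        consensus_spectra=ctable.consensus_spectra[
            [list(ctable.values.columns).index(c) for c in filtered.columns]
        ],
    )
    return ctable2, int(table.shape[1]), int(filtered.shape[1])


def rf_model_stage(
    table: pd.DataFrame,
    meta: pd.DataFrame,
    split: rf.SplitPlan,
    classes: tuple[str, str],
    config: RunConfig,
    seed: int,
):
    """Train and validate one binary forest; return its result bundle."""
    m = meta.set_index("sample_id")
    in_model = m.loc[table.index, "class"].isin(classes)
    train_ids = [s for s in split.train_samples if in_model.get(s, False)]
    test_ids = [s for s in split.test_samples if in_model.get(s, False)]
    Xtr = table.loc[train_ids]
    ytr = m.loc[train_ids, "class"]
    result = rf.train_forest(
        Xtr,
        ytr,
        n_trees=config.rf.n_trees,
        resample_unit=config.rf.resample_unit,
        subjects=m.loc[train_ids, "subject_id"],
        seed=seed,
    )
    importance = rf.permutation_importance(result, Xtr, ytr, seed=seed + 1)
    votes, pred = rf.predict_samples(result, table.loc[test_ids])
    yte = m.loc[test_ids, "class"]
    test_accuracy = float((pred == yte).mean())
    roc = rf.roc_analysis(votes[classes[1]], yte, positive_class=classes[1])
    subj_pred = rf.aggregate_subject_votes(pred, meta)
    subj_truth = (
        m.loc[test_ids].groupby("subject_id")["class"].first().loc[subj_pred.index]
    )
    defined = subj_pred != "undefined"
    subject_accuracy = (
        float((subj_pred[defined] == subj_truth[defined]).mean())
        if defined.any()
        else float("nan")
    )
    return {
        "rf": result,
        "importance": importance,
        "votes": votes,
        "pred": pred,
        "test_accuracy": test_accuracy,
        "subject_accuracy": subject_accuracy,
        "n_tied_subjects": int((~defined).sum()),
        "roc": roc,
        "train_ids": train_ids,
        "test_ids": test_ids,
    }


def dplsda_stage(
    table: pd.DataFrame,
    meta: pd.DataFrame,
    split: rf.SplitPlan,
    vocs: list[str],
    max_lv: int | None,
):
    """d-PLS-DA on inclusion-visit wheeze samples, restricted to the VOCs."""
    m = meta.set_index("sample_id")
    mask = (m.loc[table.index, "visit"] == 1) & m.loc[table.index, "class"].isin(
        MODEL2
    )
    ids = list(table.index[mask])
    train_ids = [s for s in ids if s in set(split.train_samples)]
    test_ids = [s for s in ids if s in set(split.test_samples)]
    cols = [v for v in vocs if v in table.columns]
    train_r, test_r = dp.rank_table_for_queries(
        table.loc[train_ids, cols], table.loc[test_ids, cols]
    )
    D_train = dp.dissimilarity_matrix(train_r, train_r)
    model = dp.fit_with_cv(
        D_train, m.loc[train_ids, "class"], max_lv=max_lv, classes=MODEL2
    )
    D_test = dp.dissimilarity_matrix(test_r, train_r)
    y_hat, pred = dp.predict_dplsda(model, D_test)
    yte = m.loc[test_ids, "class"].to_numpy()
    test_accuracy = float((pred == yte).mean())
    per_class = {
        cls: float((pred[yte == cls] == cls).mean()) if (yte == cls).any() else None
        for cls in MODEL2
    }
    pred_s = pd.Series(pred, index=pd.Index(test_ids, name="sample_id"))
    subj_pred = rf.aggregate_subject_votes(pred_s, meta)
    subj_truth = (
        m.loc[test_ids].groupby("subject_id")["class"].first().loc[subj_pred.index]
    )
    defined = subj_pred != "undefined"
    subject_accuracy = (
        float((subj_pred[defined] == subj_truth[defined]).mean())
        if defined.any()
        else float("nan")
    )
    return {
        "model": model,
        "train_ids": train_ids,
        "test_ids": test_ids,
        "y_hat": y_hat,
        "pred": pred,
        "test_accuracy": test_accuracy,
        "per_class_accuracy": per_class,
        "subject_accuracy": subject_accuracy,
        "n_lv": model.n_lv,
        "rmsecv": model.rmsecv,
    }


def _centroid_separation(scores: pd.DataFrame, axes=("score1", "score3")) -> float:
    """Minimal pairwise centroid distance in pooled-SD units."""
    X = scores[list(axes)].to_numpy(dtype=float)
    cls = scores["class"]
    groups = [X[(cls == c).to_numpy()] for c in sorted(cls.unique())]
    pooled = np.sqrt(
        sum(((g - g.mean(axis=0)) ** 2).sum() for g in groups)
        / max(sum(len(g) for g in groups) - len(groups), 1)
        / len(axes)
    )
    dmin = np.inf
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            d = np.linalg.norm(groups[i].mean(axis=0) - groups[j].mean(axis=0))
            dmin = min(dmin, d)
    return float(dmin / pooled) if pooled > 0 else float("inf")


def run_pipeline(config: RunConfig, out_dir: str) -> dict:
    """Execute every stage; write outputs and a manifest; return results."""
    os.makedirs(out_dir, exist_ok=True)
    t0 = time.time()
    stage_log: dict[str, float] = {}
    seeds = _spawn_seeds(config.seed, 4)

    library, design, meta, truth, chroms = simulate_stage(config)
    stage_log["simulate"] = time.time() - t0

    t = time.time()
    aligned, peaklists, reference_id = preprocess_stage(chroms, config)
    stage_log["preprocess"] = time.time() - t

    t = time.time()
    ctable, n_before, n_after = features_stage(peaklists, meta, config)
    table = ctable.values
    stage_log["features"] = time.time() - t

    t = time.time()
    split = rf.duplex_split(table, meta, test_fraction=config.rf.test_fraction)
    model1 = rf_model_stage(table, meta, split, MODEL1, config, seeds[0])
    model2 = rf_model_stage(table, meta, split, MODEL2, config, seeds[1])
    vocs = rf.select_discriminatory_vocs(
        model1["importance"], model2["importance"], k=config.rf.k_top
    )
    stage_log["rf"] = time.time() - t

    t = time.time()
    prox1 = rf.compute_proximity(
        model1["rf"], table.loc[model1["train_ids"]]
    )
    prox2 = rf.compute_proximity(
        model2["rf"], table.loc[model2["train_ids"]]
    )
    pca1 = projection.pca_on_proximity(prox1)
    pca2 = projection.pca_on_proximity(prox2)
    scores1 = projection.project_samples(model1["rf"], table, pca1)
    scores2 = projection.project_samples(model2["rf"], table, pca2)
    combined = projection.combine_projection_scores(scores2, scores1, meta)
    stage_log["projection"] = time.time() - t

    t = time.time()
    dres = dplsda_stage(table, meta, split, vocs, config.dplsda.max_lv)
    stage_log["dplsda"] = time.time() - t

    mapping = evaluate.match_compounds_to_library(ctable, library)
    signs = evaluate.estimated_signs(table, meta)
    recovery = evaluate.recovery_score(vocs, truth, mapping=mapping, signs=signs)

    results = {
        "config": config.model_dump(),
        "seeds": seeds,
        "reference_sample": reference_id,
        "n_samples": int(len(meta)),
        "n_variables_before_filter": n_before,
        "n_variables_after_filter": n_after,
        "split": {
            "train_subjects": split.train_subjects,
            "test_subjects": split.test_subjects,
        },
        "model1": _model_summary(model1),
        "model2": _model_summary(model2),
        "voc_union": vocs,
        "voc_union_size": len(vocs),
        "projection_separation_sd": _centroid_separation(combined),
        "dplsda": {
            "test_accuracy": dres["test_accuracy"],
            "per_class_accuracy": dres["per_class_accuracy"],
            "subject_accuracy": dres["subject_accuracy"],
            "n_lv": dres["n_lv"],
            "rmsecv": list(map(float, dres["rmsecv"])),
        },
        "recovery": recovery,
    }

    # persist stage outputs
    io.write_meta_tsv(meta, os.path.join(out_dir, "meta.tsv"))
    io.write_table_tsv(truth.abundances, os.path.join(out_dir, "true_abundances.tsv"))
    io.write_peaklists_tsv(peaklists, os.path.join(out_dir, "peaks.tsv"))
    io.write_table_tsv(table, os.path.join(out_dir, "compound_table.tsv"))
    combined.to_csv(os.path.join(out_dir, "projection_scores.tsv"), sep="\t")
    pd.DataFrame(
        {
            "model1": model1["importance"],
            "model2": model2["importance"],
        }
    ).to_csv(os.path.join(out_dir, "importances.tsv"), sep="\t")
    with open(os.path.join(out_dir, "results.json"), "w") as f:
        json.dump(results, f, indent=2, default=_jsonable)
    with open(os.path.join(out_dir, "report.md"), "w") as f:
        f.write(make_report(results))

    from . import plots  # deferred: matplotlib import is slow

    plots.plot_projection(combined, os.path.join(out_dir, "projection.png"))
    plots.plot_roc(model1["roc"], os.path.join(out_dir, "roc_model1.png"),
                   title="healthy vs asthma")
    plots.plot_roc(model2["roc"], os.path.join(out_dir, "roc_model2.png"),
                   title="transient wheeze vs asthma")
    plots.plot_rmsecv(np.asarray(dres["rmsecv"]), dres["n_lv"],
                      os.path.join(out_dir, "rmsecv.png"))

    manifest = {
        "config_sha256": hashlib.sha256(
            json.dumps(config.model_dump(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "stage_seconds": stage_log,
        "outputs": {
            name: _digest(os.path.join(out_dir, name))
            for name in sorted(os.listdir(out_dir))
            if name != "manifest.json"
        },
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as f:
        json.dump(manifest, f, indent=2)
    results["manifest"] = manifest
    return results


def _model_summary(m: dict) -> dict:
    return {
        "oob_error": m["rf"].oob_error,
        "test_accuracy": m["test_accuracy"],
        "subject_accuracy": m["subject_accuracy"],
        "n_tied_subjects": m["n_tied_subjects"],
        "auc": m["roc"].auc,
        "optimal_cutoff": m["roc"].optimal_cutoff,
        "n_train_samples": len(m["train_ids"]),
        "n_test_samples": len(m["test_ids"]),
    }


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def make_report(results: dict) -> str:
    """Human-readable summary of a finished run."""
    required = ("model1", "model2", "voc_union", "dplsda")
    missing = [k for k in required if k not in results]
    if missing:
        raise ValueError(f"incomplete results; missing stages: {missing}")
    m1, m2, d = results["model1"], results["model2"], results["dplsda"]
    lines = [
        "# Breathomics pipeline report",
        "",
        f"Samples: {results.get('n_samples', '?')}; variables "
        f"{results.get('n_variables_before_filter', '?')} -> "
        f"{results.get('n_variables_after_filter', '?')} after the 20% rule.",
        "",
        "## Random-forest models",
        "",
        "| model | oob error | test accuracy | subject accuracy (ties) | AUC | cutoff |",
        "|---|---|---|---|---|---|",
        f"| 1: healthy vs asthma | {m1['oob_error']:.3f} | {m1['test_accuracy']:.3f}"
        f" | {m1['subject_accuracy']:.3f} ({m1['n_tied_subjects']}) |"
        f" {m1['auc']:.3f} | {m1['optimal_cutoff']:.2f} |",
        f"| 2: transient vs asthma | {m2['oob_error']:.3f} | {m2['test_accuracy']:.3f}"
        f" | {m2['subject_accuracy']:.3f} ({m2['n_tied_subjects']}) |"
        f" {m2['auc']:.3f} | {m2['optimal_cutoff']:.2f} |",
        "",
        f"Discriminatory VOC union (top-"
        f"{results.get('config', {}).get('rf', {}).get('k_top', 12)} of each model): "
        f"{results['voc_union_size']} compounds.",
        "",
        "## Projection",
        "",
        f"Minimal class-centroid separation in (score1, score3): "
        f"{results.get('projection_separation_sd', float('nan')):.2f} pooled SDs.",
        "",
        "## d-PLS-DA (inclusion visit, transient wheeze vs asthma)",
        "",
        f"Latent variables: {d['n_lv']} (LOO RMSECV); "
        f"test accuracy {d['test_accuracy']:.3f}; per-class "
        f"{d['per_class_accuracy']}; subject-level {d['subject_accuracy']:.3f}.",
    ]
    rec = results.get("recovery")
    if rec and rec.get("n_planted"):
        lines += [
            "",
            "## Ground-truth recovery (synthetic cohorts only)",
            "",
            f"Planted discriminatory VOCs: {rec['n_planted']}; recovered "
            f"{rec['n_recovered']} (recall {rec['recall']:.2f}); sign agreement "
            f"{rec['sign_correct']}/{rec['sign_checked']}.",
        ]
    return "\n".join(lines) + "\n"
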