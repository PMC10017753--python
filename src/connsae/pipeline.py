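"""End-to-end orchestration: cohort -> networks -> features -> model -> report.

`run_pipeline` executes the full analysis from a single `RunConfig`:

1. generate a synthetic cohort (or load one from delimited text files);
2. build the weighted structural network per subject, select the
   small-world cost range on the cohort-mean functional correlation matrix,
   and assemble the 685-feature table (per-cost functional metrics averaged
   over the retained range);
3. cross-validate the semi-supervised autoencoder and the PCA+SVM baseline
   on identical stratified folds;
4. compute fold-averaged permutation importance and apply the mean+2SD rule;
5. if any features were flagged important, run the brain-behaviour stage
   (SVR per symptom scale, Bonferroni-corrected latent correlations, and the
   bootstrap path model using a full-sample model's latent code);
6. write a versioned machine-readable report plus a human-readable summary.

The global seed fans out deterministically to per-stage seeds; intermediate
artefacts (feature table, per-fold predictions and selections) are cached to
the output directory so individual stages can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .behavior import correlate_latents, fit_path_model, fit_svr_cv
from .cohort import (Cohort, CohortConfig, chi_square_independence,
                     generate_cohort, welch_t_from_summary)
from .features import minmax_apply, minmax_fit, rank_and_select
from .importance import cv_permutation_importance, identify_important_features
from .networks import (DEFAULT_COST_GRID, DEFAULT_SIGMA_THRESHOLD,
                       binarize_at_cost, build_structural_network,
                       select_smallworld_cost_range)
from .ssae import AEConfig, cross_validate_ssae, encode, pca_svm_baseline, train_ssae

__all__ = ["RunConfig", "run_pipeline", "write_report", "compute_feature_table",
           "validate_report", "REPORT_SCHEMA_VERSION"]

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1.0"

#: required top-level keys and their types in a pipeline report
_REPORT_SCHEMA: dict[str, type] = {
    "schema_version": str,
    "seed": int,
    "cohort": dict,
    "networks": dict,
    "features": dict,
    "model": dict,
    "importance": dict,
    "behavior": dict,
}


@dataclass
class RunConfig:
    """Everything one pipeline run needs; exactly one input source."""

    cohort: CohortConfig | None = None
    input_dir: str | None = None
    output_dir: str = "connsae_run"
    seed: int = 0
    cost_grid: tuple[float, ...] = DEFAULT_COST_GRID
    sigma_threshold: float = DEFAULT_SIGMA_THRESHOLD
    sigma_n_random: int = 20
    ae: AEConfig = field(default_factory=AEConfig)
    n_folds: int = 5
    n_select: int = 60
    importance_m: int = 1000
    svr_importance_m: int = 200
    path_n_boot: int = 5000
    targets: tuple[str, ...] = ("inattention_t", "hyperactivity_t")

    def __post_init__(self) -> None:
        if (self.cohort is None) == (self.input_dir is None):
            raise ValueError("provide exactly one of cohort config or input_dir")
        if self.cohort is not None and self.cohort.n_per_group < 1:
            raise ValueError("cohort must have subjects")


def _stage_seeds(seed: int, n: int = 6) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31))
            for s in np.random.SeedSequence(seed).spawn(n)]


def compute_feature_table(cohort: Cohort,
                          cost_grid: tuple[float, ...] = DEFAULT_COST_GRID,
                          sigma_threshold: float = DEFAULT_SIGMA_THRESHOLD,
                          n_random: int = 20,
                          seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Per-subject 685-feature table plus network-stage metadata.

    The small-world cost range is selected once, on the cohort-mean
    functional correlation matrix, so every subject's functional metrics are
    averaged over the same retained costs and the feature columns are
    comparable across subjects.
    """
    mean_corr = np.mean(np.stack(cohort.functional_corr), axis=0)
    fns = select_smallworld_cost_range(mean_corr, cost_grid=cost_grid,
                                       sigma_threshold=sigma_threshold,
                                       n_random=n_random, seed=seed)
    rows = []
    for subj, counts, corr in zip(cohort.subjects, cohort.structural_counts,
                                  cohort.functional_corr):
        sn = build_structural_network(counts)
        struct = _metrics.compute_nodal_metrics(sn.weights, weighted=True)
        # binarize this subject at the cohort-level retained costs
        adjs = [binarize_at_cost(corr, c) for c in fns.costs]
        func = _metrics.average_metrics_over_costs(adjs)
        vec = _metrics.assemble_feature_vector(struct, func)
        rows.append(vec.rename(subj.id))
    table = pd.DataFrame(rows)
    table.insert(0, "group", [s.group for s in cohort.subjects])
    meta = {"retained_costs": [float(c) for c in fns.costs],
            "sigma_per_cost": {str(k): v for k, v in fns.sigma_per_cost.items()}}
    return table, meta


def _cohort_summary(cohort: Cohort) -> dict:
    df = cohort.metadata_frame()
    out: dict = {"n_total": len(df),
                 "n_per_group": df.groupby("group").size().to_dict()}
    sex_tab = pd.crosstab(df["group"], df["sex"]).to_numpy()
    eth_tab = pd.crosstab(df["group"], df["ethnicity"]).to_numpy()
    try:
        stat, dfree, p = chi_square_independence(sex_tab)
        out["sex_chi2"] = {"statistic": stat, "df": dfree, "p": p}
    except ValueError:
        out["sex_chi2"] = None
    try:
        stat, dfree, p = chi_square_independence(eth_tab)
        out["ethnicity_chi2"] = {"statistic": stat, "df": dfree, "p": p}
    except ValueError:
        out["ethnicity_chi2"] = None
    for var in ("age", "ses", "iq", "inattention_t", "hyperactivity_t"):
        g = df.groupby("group")[var]
        means, sds, ns = g.mean(), g.std(ddof=1), g.size()
        t, dfree, p = welch_t_from_summary(
            means["control"], sds["control"], int(ns["control"]),
            means["tbi"], sds["tbi"], int(ns["tbi"]))
        out[var] = {"control_mean": float(means["control"]),
                    "control_sd": float(sds["control"]),
                    "tbi_mean": float(means["tbi"]),
                    "tbi_sd": float(sds["tbi"]),
                    "welch_t": t, "df": dfree, "p": p}
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the report dict (also written to disk)."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    s_cohort, s_network, s_cv, s_baseline, s_importance, s_behavior = seeds

    # ---- stage 1: cohort -------------------------------------------------
    try:
        if config.cohort is not None:
            cohort_cfg = dataclasses.replace(config.cohort, seed=s_cohort)
            cohort = generate_cohort(cohort_cfg)
        else:
            cohort = Cohort.load(config.input_dir)
    except Exception as exc:
        raise RuntimeError(f"stage 'cohort' failed: {exc}") from exc
    logger.info("cohort: %d subjects", len(cohort.subjects))

    # ---- stage 2: networks + features -----------------------------------
    try:
        table, net_meta = compute_feature_table(
            cohort, cost_grid=config.cost_grid,
            sigma_threshold=config.sigma_threshold,
            n_random=config.sigma_n_random, seed=s_network)
    except Exception as exc:
        raise RuntimeError(f"stage 'metrics' failed: {exc}") from exc
    table.to_csv(out_dir / "features.csv")
    feature_cols = [c for c in table.columns if c != "group"]
    X = table[feature_cols].to_numpy()
    y = (table["group"] == "tbi").to_numpy().astype(float)
    logger.info("features: %d subjects x %d features", *X.shape)

    # ---- stage 3: SSAE CV + baseline ------------------------------------
    try:
        ae_cfg = dataclasses.replace(config.ae, seed=s_cv)
        cv = cross_validate_ssae(X, y, ae_cfg, k=config.n_folds,
                                 n_select=config.n_select, seed=s_cv)
        baseline = pca_svm_baseline(X, y, k=config.n_folds, seed=s_cv)
    except Exception as exc:
        raise RuntimeError(f"stage 'train' failed: {exc}") from exc
    pred_rows = []
    for f, (_, va) in enumerate(cv.fold_indices):
        yv, pv = cv.predictions[f]
        for i, yy, pp in zip(va, yv, pv):
            pred_rows.append({"id": table.index[i], "fold": f,
                              "y": int(yy), "p": float(pp)})
    pd.DataFrame(pred_rows).to_csv(out_dir / "fold_predictions.csv", index=False)
    with open(out_dir / "fold_selections.json", "w") as fh:
        json.dump([sel.to_dict() if sel is not None else None
                   for sel in cv.selections], fh)

    # ---- stage 4: permutation importance --------------------------------
    try:
        mean_fi, fold_fis = cv_permutation_importance(
            cv, X, y, n_source_features=X.shape[1], m=config.importance_m,
            seed=s_importance)
        candidates = np.flatnonzero(~np.isnan(mean_fi))
        important = [int(candidates[i]) for i in
                     identify_important_features(mean_fi[candidates])]
    except Exception as exc:
        raise RuntimeError(f"stage 'importance' failed: {exc}") from exc
    cand_names = [feature_cols[i] for i in candidates]
    fi_table = pd.DataFrame({
        "feature": cand_names,
        "modality": [n.split("_")[0] for n in cand_names],
        "metric": ["_".join(n.split("_")[1:-1]) for n in cand_names],
        "node": [int(n.split("_")[-1]) for n in cand_names],
        "fi": mean_fi[candidates],
        "selected": [int(i) in important for i in candidates],
    }).sort_values("fi", ascending=False)
    fi_table.to_csv(out_dir / "importance.csv", index=False)

    # ---- stage 5: brain-behaviour ---------------------------------------
    behavior: dict = {}
    if not important:
        behavior["skipped"] = "no features passed the mean+2SD importance rule"
        logger.warning(behavior["skipped"])
    else:
        try:
            behavior = _run_behavior_stage(
                cohort, X, y, important, feature_cols, config, s_behavior,
                out_dir)
        except Exception as exc:
            raise RuntimeError(f"stage 'behavior' failed: {exc}") from exc

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": int(config.seed),
        "cohort": _cohort_summary(cohort),
        "networks": net_meta,
        "features": {"n_source": int(X.shape[1]),
                     "n_structural": 5 * (cohort.structural_counts[0].shape[0]),
                     "n_functional": 5 * (cohort.functional_corr[0].shape[0]),
                     "n_selected_per_fold": config.n_select},
        "model": {"ssae": cv.to_dict(), "pca_svm_baseline": baseline.to_dict()},
        "importance": {
            "m": config.importance_m,
            "n_candidates": int(len(candidates)),
            "important_features": [feature_cols[i] for i in important],
            "table": fi_table.to_dict("records"),
        },
        "behavior": behavior,
    }
    write_report(report, out_dir)
    return report


def _run_behavior_stage(cohort: Cohort, X: np.ndarray, y: np.ndarray,
                        important: list[int], feature_cols: list[str],
                        config: RunConfig, seed: int,
                        out_dir: Path | None = None) -> dict:
    meta = cohort.metadata_frame()
    # full-sample model for one consistent latent space
    scaler = minmax_fit(X)
    Xs = minmax_apply(scaler, X)
    if X.shape[1] > config.ae.input_dim:
        sel = rank_and_select(Xs, y, k=config.n_select, seed=seed)
        Xin = Xs[:, sel.selected]
    else:
        Xin = Xs
    full_model = train_ssae(Xin, y, dataclasses.replace(config.ae, seed=seed))
    latents = encode(full_model, Xin)

    covars = meta[["age", "ses", "iq"]].copy()
    covars["sex"] = (meta["sex"] == "M").astype(float)
    covars["handedness"] = (meta["handedness"] == "right").astype(float)

    X_imp = X[:, important]
    out: dict = {"important_features": [feature_cols[i] for i in important]}
    for target in config.targets:
        t = meta[target].to_numpy(dtype=float)
        svr = fit_svr_cv(X_imp, t, k=config.n_folds, seed=seed,
                         m_importance=config.svr_importance_m)
        if out_dir is not None:
            # observed-vs-predicted scatter data, per fold, T-score scale
            svr.predictions.to_csv(out_dir / f"svr_predictions_{target}.csv",
                                   index=False)
        lat_corr = correlate_latents(latents, t)
        sig = lat_corr[lat_corr["significant"]]["latent"].tolist()
        entry = {"svr": svr.to_dict(),
                 "latent_correlations": lat_corr.to_dict("records"),
                 "significant_latents": sig}
        if sig:
            path = fit_path_model(
                pd.DataFrame(X_imp, columns=[feature_cols[i] for i in important]),
                pd.DataFrame(latents[:, sig],
                             columns=[f"latent_{j}" for j in sig]),
                t, covariates=covars, n_boot=config.path_n_boot, seed=seed)
            entry["path_model"] = path.to_dict()
        else:
            entry["path_model"] = None
        out[target] = entry
    return out


def validate_report(report: dict) -> None:
    """Check a report against the bundled top-level schema; raises on failure."""
    for key, typ in _REPORT_SCHEMA.items():
        if key not in report:
            raise ValueError(f"report missing key {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(f"report[{key!r}] must be {typ.__name__}")
    if report["schema_version"] != REPORT_SCHEMA_VERSION:
        raise ValueError("unknown schema version")


def _fmt_pct(mean: float, sd: float) -> str:
    return f"{100 * mean:.2f}% ± {100 * sd:05.2f}%"


def write_report(report: dict, out_dir: str | Path) -> tuple[Path, Path]:
    """Write report.json and a human-readable summary; returns both paths."""
    validate_report(report)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    json_path = out_dir / "report.json"
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    m = report["model"]["ssae"]
    b = report["model"]["pca_svm_baseline"]
    lines = [
        f"connsae pipeline report (schema {report['schema_version']}, seed {report['seed']})",
        f"subjects: {report['cohort']['n_total']} "
        f"({report['cohort']['n_per_group']})",
        f"source features: {report['features']['n_source']} "
        f"({report['features']['n_structural']} structural + "
        f"{report['features']['n_functional']} functional); "
        f"{report['features']['n_selected_per_fold']} selected per fold",
        f"retained costs: {report['networks']['retained_costs']}",
        "SSAE  accuracy " + _fmt_pct(m["accuracy"]["mean"], m["accuracy"]["sd"])
        + f", AUC {m['auc']['mean']:.3f} ± {m['auc']['sd']:.3f}"
        + f", reconstruction MSE {m['reconstruction_mse']['mean']:.3f}"
        + f" ± {m['reconstruction_mse']['sd']:.3f}",
        "PCA+SVM accuracy " + _fmt_pct(b["accuracy"]["mean"], b["accuracy"]["sd"])
        + f", AUC {b['auc']['mean']:.3f} ± {b['auc']['sd']:.3f}",
        f"stop reasons per fold: {m['stop_reasons']}",
        f"important features (mean+2SD rule): "
        f"{report['importance']['important_features']}",
    ]
    if "skipped" in report["behavior"]:
        lines.append(f"behavior stage skipped: {report['behavior']['skipped']}")
    else:
        for target in report["behavior"]:
            entry = report["behavior"][target]
            if not isinstance(entry, dict) or "svr" not in entry:
                continue
            lines.append(
                f"SVR {target}: R2 "
                + _fmt_pct(entry["svr"]["r2"]["mean"], entry["svr"]["r2"]["sd"])
                + f", MSE {entry['svr']['mse']['mean']:.3f}"
                + f" ± {entry['svr']['mse']['sd']:.3f}")
    txt_path = out_dir / "summary.txt"
    txt_path.write_text("\n".join(lines) + "\n")
    return json_path, txt_path
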