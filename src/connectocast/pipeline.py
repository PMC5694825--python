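"""End-to-end orchestration: simulate -> metrics -> impair -> predict -> report.

Each stage reads its inputs from files written by the previous stage and
writes its outputs plus a small manifest (sha256 of its inputs), so a
re-run with unchanged inputs skips the stage. Re-running the whole pipeline
with the same config and seed reproduces the consolidated JSON report
bit-identically.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as cio
from . import metrics as cm
from . import predict as cp
from . import scoring as cs
from . import synth

log = logging.getLogger("connectocast")

_STAGE_SEEDS = {"simulate": 0, "split": 1, "rfe": 2, "forest": 3,
                "bootstrap": 4, "regress": 5}


def _substream_seed(seed: int, stage: str, extra: int = 0) -> int:
    ss = np.random.SeedSequence(seed, spawn_key=(_STAGE_SEEDS[stage], extra))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Pipeline configuration; built from a YAML mapping or keyword args."""

    out_dir: Path
    seed: int = 0
    cohort: synth.CohortConfig | None = None  # simulate when set
    matrices_dir: Path | None = None  # else: read existing inputs
    cognition_csv: Path | None = None
    covariates_csv: Path | None = None
    density_mode: str = "cohort_common"
    models: tuple[int, ...] = (1, 3)
    model2_regions: tuple[str, ...] = cp.MODEL2_REGIONS
    n_rfe_partitions: int = 100
    zscore_reference: str = "timepoint"
    run_regression: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        cohort = d.pop("cohort", None)
        if cohort is not None:
            if "predictive_regions" in cohort:
                cohort["predictive_regions"] = tuple(cohort["predictive_regions"])
            cohort = synth.CohortConfig(**cohort)
        cfg = cls(
            out_dir=Path(d.pop("out_dir")),
            cohort=cohort,
            **{k: (tuple(v) if k in ("models", "model2_regions") else v)
               for k, v in d.items()},
        )
        for name in ("matrices_dir", "cognition_csv", "covariates_csv"):
            v = getattr(cfg, name)
            if v is not None:
                setattr(cfg, name, Path(v))
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def validate(self) -> None:
        if self.cohort is None:
            for name in ("matrices_dir", "cognition_csv", "covariates_csv"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(
                        f"pipeline input {name} missing or nonexistent: {p}"
                    )


def _stage_fresh(out_dir: Path, name: str, input_hash: str,
                 outputs: Sequence[Path]) -> bool:
    """True when the stage's manifest matches and all outputs exist."""
    manifest = out_dir / ".stages" / f"{name}.json"
    if not manifest.exists() or not all(Path(o).exists() for o in outputs):
        return False
    return cio.read_json(manifest).get("input_hash") == input_hash


def _write_manifest(out_dir: Path, name: str, input_hash: str) -> None:
    (out_dir / ".stages").mkdir(parents=True, exist_ok=True)
    cio.write_json(out_dir / ".stages" / f"{name}.json", {"input_hash": input_hash})


def simulate_stage(cohort_config: synth.CohortConfig, out_dir: Path) -> dict[str, Path]:
    """Generate and write a synthetic cohort (skipped when up to date)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_repr = repr(cohort_config).encode()
    import hashlib

    input_hash = hashlib.sha256(cfg_repr).hexdigest()
    paths = {
        "matrices": out_dir / "matrices",
        "cognition": out_dir / "cognition.csv",
        "covariates": out_dir / "covariates.csv",
        "truth": out_dir / "truth.csv",
    }
    if _stage_fresh(out_dir, "simulate", input_hash,
                    [paths["cognition"], paths["covariates"], paths["truth"]]):
        log.info("simulate: up to date, skipping")
        return paths
    t0 = time.perf_counter()
    cohort = synth.generate_cohort(cohort_config)
    synth.write_cohort(cohort, out_dir)
    _write_manifest(out_dir, "simulate", input_hash)
    log.info("simulate: %d subjects in %.1fs",
             len(cohort.subjects), time.perf_counter() - t0)
    return paths


def metrics_stage(
    matrices_dir: Path,
    subject_ids: Sequence[str],
    out_dir: Path,
    mode: str = "cohort_common",
    density: float | None = None,
    seed: int = 0,
) -> dict[str, Path]:
    """Binarize baseline matrices and write nodal metrics, partition, hubs.

    ``density=None`` uses minimum connection density (per ``mode``); a float
    binarizes every subject at that fixed edge density instead.
    """
    matrices_dir = Path(matrices_dir)
    if not matrices_dir.exists():
        raise FileNotFoundError(f"matrix directory does not exist: {matrices_dir}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    available = cio.matrix_paths(matrices_dir, "baseline")
    missing = [s for s in subject_ids if s not in available]
    if missing:
        raise FileNotFoundError(f"no baseline matrix for subjects: {missing}")
    files = [available[s] for s in subject_ids]
    import hashlib

    input_hash = hashlib.sha256(
        (cio.sha256_of(files) + f"|mode={mode}|density={density}").encode()
    ).hexdigest()
    paths = {
        "node_metrics": out_dir / "node_metrics.csv",
        "group_metrics": out_dir / "group_metrics.csv",
        "partition": out_dir / "partition.csv",
        "hubs": out_dir / "hubs.csv",
    }
    if _stage_fresh(out_dir, "metrics", input_hash, list(paths.values())):
        log.info("metrics: up to date, skipping")
        return paths
    t0 = time.perf_counter()
    matrices = [cio.read_matrix(f) for f in files]
    if density is not None:
        if not 0.0 < density <= 1.0:
            raise ValueError(f"density must be in (0, 1], got {density}")
        n = matrices[0].n_regions
        m = round(density * n * (n - 1) / 2)
        nets = [cm.binarize_at_edge_count(mx, m) for mx in matrices]
    else:
        nets = cm.binarize_cohort(matrices, mode=mode)
    tables = []
    for sid, net in zip(subject_ids, nets):
        t = cm.node_metric_table(net, seed=seed)
        t.insert(0, "subject_id", sid)
        t["density"] = net.density
        tables.append(t)
    node_metrics = pd.concat(tables, ignore_index=True)
    cio.write_table(paths["node_metrics"], node_metrics)

    # Group-representative network: partition + participation for hub typing;
    # degree/clustering/betweenness are subject-level means (Table-style).
    mean_net = cm.group_mean_network(nets)
    partition = cm.detect_modules(mean_net, seed=seed)
    group = (
        node_metrics.groupby("region", sort=False)[
            ["degree", "clustering", "betweenness"]
        ]
        .mean()
        .reset_index()
    )
    order = {r: i for i, r in enumerate(mean_net.labels)}
    group = group.sort_values("region", key=lambda s: s.map(order)).reset_index(drop=True)
    group["module"] = partition.module_of
    group["participation"] = cm.participation_coefficient(mean_net, partition)
    cio.write_table(paths["group_metrics"], group)
    cio.write_table(
        paths["partition"],
        pd.DataFrame({"region": mean_net.labels, "module": partition.module_of}),
    )
    hubs = cm.classify_hubs(group)
    cio.write_table(paths["hubs"], hubs)
    _write_manifest(out_dir, "metrics", input_hash)
    log.info("metrics: %d subjects, density %.3f, Q=%.3f in %.1fs",
             len(nets), nets[0].density, partition.modularity,
             time.perf_counter() - t0)
    return paths


def impair_stage(
    cognition_csv: Path,
    out_dir: Path,
    control_group: str = "control",
    reference: str = "timepoint",
) -> dict[str, Path]:
    """Z-score cognition, apply the ICCTF rule, test incidence difference."""
    cognition_csv = Path(cognition_csv)
    if not cognition_csv.exists():
        raise FileNotFoundError(f"cognition table does not exist: {cognition_csv}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    input_hash = cio.sha256_of([cognition_csv])
    paths = {
        "zscores": out_dir / "zscores.csv",
        "impairment": out_dir / "impairment.csv",
        "incidence": out_dir / "incidence.json",
    }
    if _stage_fresh(out_dir, "impair", input_hash, list(paths.values())):
        log.info("impair: up to date, skipping")
        return paths
    cognition = cio.read_table(cognition_csv)
    z = cs.compute_zscores(cognition, control_group=control_group, reference=reference)
    cio.write_table(paths["zscores"], z)
    status = cs.label_cohort(z)
    cio.write_table(paths["impairment"], status)
    counts = {}
    for grp, sub in status.groupby("group"):
        counts[grp] = {
            "n": int(len(sub)),
            "impaired": int((sub["outcome"] == "impaired").sum()),
            "persistent": int((sub["category"] == "persistent").sum()),
            "late_onset": int((sub["category"] == "late_onset").sum()),
        }
    incidence: dict = {"counts": counts}
    groups = sorted(counts)
    if len(groups) == 2:
        g1, g2 = ("patient", "control") if {"patient", "control"} <= set(groups) else groups
        chi2, p = cs.incidence_proportion_test(
            counts[g1]["impaired"], counts[g1]["n"],
            counts[g2]["impaired"], counts[g2]["n"],
        )
        incidence["chi_squared"] = chi2
        incidence["p_value"] = p
    cio.write_json(paths["incidence"], incidence)
    _write_manifest(out_dir, "impair", input_hash)
    log.info("impair: %s", {g: c["impaired"] for g, c in counts.items()})
    return paths


def _clustering_wide(node_metrics: pd.DataFrame) -> pd.DataFrame:
    wide = node_metrics.pivot(index="subject_id", columns="region", values="clustering")
    region_order = node_metrics["region"].drop_duplicates().tolist()
    return wide[region_order]


def predict_stage(
    node_metrics_csv: Path,
    covariates_csv: Path,
    impairment_csv: Path,
    model: int,
    seed: int,
    out_dir: Path,
    n_rfe_partitions: int = 100,
    model2_regions: tuple[str, ...] = cp.MODEL2_REGIONS,
) -> dict:
    """Run split -> RFE -> forest -> hold-out evaluation for one model spec."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage_name = f"predict_model{model}"
    import hashlib

    input_hash = hashlib.sha256(
        (cio.sha256_of([node_metrics_csv, covariates_csv, impairment_csv])
         + f"|model={model}|seed={seed}|parts={n_rfe_partitions}"
         + f"|regions={model2_regions}").encode()
    ).hexdigest()
    eval_path = out_dir / f"model_{model}_evaluation.json"
    scores_path = out_dir / f"model_{model}_scores.csv"
    if _stage_fresh(out_dir, stage_name, input_hash, [eval_path, scores_path]):
        log.info("%s: up to date, skipping", stage_name)
        result = cio.read_json(eval_path)
        scores = cio.read_table(scores_path)
        result["_scores"] = scores["score"].to_numpy()
        result["_labels"] = scores["label"].to_numpy()
        return result

    node_metrics = cio.read_table(node_metrics_csv)
    covariates = cio.read_table(covariates_csv)
    status = cio.read_table(impairment_csv)
    patients = status[status["group"] == "patient"].set_index("subject_id")
    outcome = (patients["outcome"] == "impaired").astype(int)
    clustering = _clustering_wide(node_metrics).loc[outcome.index]

    fm = cp.assemble_features(clustering, covariates, outcome, model,
                              model2_regions=model2_regions)
    # One shared hold-out across model specs, so AUCs compare on the same
    # subjects (the split substream deliberately ignores the model id).
    split = cp.stratified_split(fm.outcome, fraction=0.75,
                                seed=_substream_seed(seed, "split"))
    X_train = fm.features.loc[split.train_ids]
    y_train = fm.outcome.loc[split.train_ids]
    X_test = fm.features.loc[split.test_ids]
    y_test = fm.outcome.loc[split.test_ids]

    rfe = cp.rfe_select(X_train, y_train, n_partitions=n_rfe_partitions,
                        seed=_substream_seed(seed, "rfe", model))
    sel = rfe.selected_features
    forest, oob_error, importances = cp.train_forest(
        X_train[sel], y_train, n_trees=500,
        seed=_substream_seed(seed, "forest", model),
    )
    ev = cp.evaluate_holdout(forest, X_test[sel], y_test,
                             oob_error=oob_error, importances=importances)

    result = {
        "model": model,
        "selected_features": sel,
        "n_train": len(split.train_ids),
        "n_test": ev.n_test,
        "accuracy": ev.accuracy,
        "sensitivity": ev.sensitivity,
        "specificity": ev.specificity,
        "auc": ev.auc,
        "binomial_p": ev.binomial_p,
        "oob_error": ev.oob_error,
        "importances": {k: float(v) for k, v in ev.importances.items()},
        "test_ids": list(split.test_ids),
    }
    cio.write_json(out_dir / f"model_{model}_evaluation.json", result)
    pd.DataFrame(
        {"subject_id": split.test_ids, "score": ev.scores, "label": ev.labels}
    ).to_csv(out_dir / f"model_{model}_scores.csv", index=False)
    imp = pd.DataFrame(sorted(ev.importances.items(), key=lambda kv: -kv[1]),
                       columns=["feature", "mean_decrease_gini"])
    cio.write_table(out_dir / f"model_{model}_importances.csv", imp)
    _write_manifest(out_dir, stage_name, input_hash)
    result["_scores"] = ev.scores
    result["_labels"] = ev.labels
    return result


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order and write ``report.json``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.cohort is not None:
        # The pipeline seed governs every source of randomness, including
        # the simulated cohort: the cohort's own seed is derived from it.
        cohort_cfg = synth_replace_seed(
            config.cohort, _substream_seed(config.seed, "simulate")
        )
        sim = simulate_stage(cohort_cfg, out / "cohort")
        matrices_dir = sim["matrices"]
        cognition_csv = sim["cognition"]
        covariates_csv = sim["covariates"]
    else:
        matrices_dir = Path(config.matrices_dir)
        cognition_csv = Path(config.cognition_csv)
        covariates_csv = Path(config.covariates_csv)

    covariates = cio.read_table(covariates_csv)
    patient_ids = covariates.loc[covariates["group"] == "patient", "subject_id"].tolist()

    met = metrics_stage(matrices_dir, patient_ids, out / "metrics",
                        mode=config.density_mode, seed=config.seed)
    imp = impair_stage(cognition_csv, out / "impair",
                       reference=config.zscore_reference)

    evaluations = {}
    for model in config.models:
        evaluations[model] = predict_stage(
            met["node_metrics"], covariates_csv, imp["impairment"],
            model, config.seed, out / "predict",
            n_rfe_partitions=config.n_rfe_partitions,
            model2_regions=config.model2_regions,
        )

    comparisons = {}
    models = sorted(evaluations)
    for i, m1 in enumerate(models):
        for m2 in models[i + 1:]:
            e1, e2 = evaluations[m1], evaluations[m2]
            if e1["test_ids"] != e2["test_ids"]:
                continue  # AUC comparison requires shared hold-out subjects
            cmp_ = cp.compare_aucs(
                e1["_scores"], e2["_scores"], e1["_labels"],
                seed=_substream_seed(config.seed, "bootstrap", m1 * 10 + m2),
            )
            comparisons[f"model_{m1}_vs_model_{m2}"] = {
                "auc1": cmp_.auc1, "auc2": cmp_.auc2,
                "z": cmp_.z, "p": cmp_.p,
            }
    if comparisons:
        cio.write_json(out / "predict" / "auc_comparisons.json", comparisons)

    regression = {}
    best_model = max(evaluations, key=lambda m: evaluations[m]["auc"] or 0.0) \
        if evaluations else None
    if config.run_regression and best_model is not None:
        brain = [f for f in evaluations[best_model]["selected_features"]
                 if f.startswith(cp.CLUSTERING_PREFIX)]
        if brain:
            z = cio.read_table(imp["zscores"])
            node_metrics = cio.read_table(met["node_metrics"])
            status = cio.read_table(imp["impairment"])
            pids = status.loc[status["group"] == "patient", "subject_id"]
            clustering = _clustering_wide(node_metrics).loc[pids]
            Xr = clustering[[f[len(cp.CLUSTERING_PREFIX):] for f in brain]]
            Xr.columns = brain
            zy1 = z[(z["timepoint"] == "year1") & (z["subject_id"].isin(pids))]
            for t_idx, (test, sub) in enumerate(sorted(zy1.groupby("test"))):
                y = sub.set_index("subject_id")["zscore"].loc[Xr.index]
                ev = cp.rf_regress(Xr, y,
                                   seed=_substream_seed(config.seed, "regress", t_idx))
                regression[test] = {
                    "r_squared": ev.r_squared,
                    "adjusted_r_squared": ev.adjusted_r_squared,
                    "p_value": ev.p_value,
                    "importances_pct_inc_mse": ev.importances,
                }
            cio.write_json(out / "predict" / "regression.json", regression)

    hubs = cio.read_table(met["hubs"])
    report = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            "models": list(config.models),
            "density_mode": config.density_mode,
            "n_rfe_partitions": config.n_rfe_partitions,
            "cohort": repr(config.cohort) if config.cohort else None,
        },
        "inputs": {
            "cognition_sha256": cio.sha256_of([cognition_csv]),
            "covariates_sha256": cio.sha256_of([covariates_csv]),
        },
        "incidence": cio.read_json(imp["incidence"]),
        "models": {
            str(m): {k: v for k, v in e.items() if not k.startswith("_")}
            for m, e in evaluations.items()
        },
        "auc_comparisons": comparisons,
        "regression": regression,
        "hubs": hubs.to_dict(orient="records"),
    }
    cio.write_json(out / "report.json", report)
    return report


def synth_replace_seed(cfg: synth.CohortConfig, seed: int) -> synth.CohortConfig:
    from dataclasses import replace

    return replace(cfg, seed=seed)
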