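"""Prodromal subtyping and end-to-end orchestration.

The operating threshold learned from the Control/PD ROC is applied,
unchanged, to the model-averaged scores of the independent prodromal
cohort: subjects at or above it form subgroup 1 (PD-like progression),
the rest subgroup 2 (control-like).  No information from the prodromal
group enters the threshold or any trained model — the pipeline stages are
ordered so this firewall is auditable.  Subgroup clinical trajectories
are summarized descriptively (mean, SD, interquartile range per visit);
no significance tests are run on these small subgroups.
"""

from __future__ import annotations

import hashlib
import json
import logging
import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from longconn.metrics import evaluate
from longconn.model import ModelSpec, cross_validated_scores, ensemble_predict
from longconn.relevance import ensemble_relevance, prominent_connections
from longconn.simulate import (
    CLINICAL_SCALES,
    ClinicalTable,
    CohortDataset,
    SimulationConfig,
    simulate_clinical,
    simulate_cohort,
)

logger = logging.getLogger("longconn")


@dataclass
class SubtypeAssignment:
    """Threshold-based split of an independent cohort."""

    assignments: pd.Series  # subject_id -> 1 (PD-like) or 2 (control-like)
    threshold: float
    source: str = "roc_cnt_vs_pd"

    @property
    def counts(self) -> dict:
        vc = self.assignments.value_counts()
        return {1: int(vc.get(1, 0)), 2: int(vc.get(2, 0))}


def subtype(scores: pd.Series, threshold: float) -> SubtypeAssignment:
    """Assign subgroup 1 iff score >= threshold (a subject exactly at the
    screening threshold is flagged), subgroup 2 otherwise."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    s = pd.Series(scores, dtype=float)
    return SubtypeAssignment(
        assignments=pd.Series(
            np.where(s.to_numpy() >= threshold, 1, 2), index=s.index, name="subgroup"
        ),
        threshold=float(threshold),
    )


def trajectory_summary(
    clinical: ClinicalTable, assignment: SubtypeAssignment
) -> pd.DataFrame:
    """Descriptive per-subgroup trajectories of every clinical scale.

    One row per (subgroup, scale, visit) with mean, SD (NaN and flagged
    for single-subject cells — never imputed), quartiles and n.
    """
    df = clinical.data.merge(
        assignment.assignments.rename("subgroup"),
        left_on="subject_id",
        right_index=True,
        how="inner",
    )
    if df.empty:
        raise ValueError("no clinical data for any assigned subject")
    rows = []
    for (grp, visit), sub in df.groupby(["subgroup", "visit_years"]):
        for scale in CLINICAL_SCALES:
            vals = sub[scale].dropna().to_numpy(dtype=float)
            n = len(vals)
            rows.append(
                {
                    "subgroup": grp,
                    "scale": scale,
                    "visit_years": visit,
                    "n": n,
                    "mean": vals.mean() if n else np.nan,
                    "sd": vals.std(ddof=1) if n > 1 else np.nan,
                    "q25": np.percentile(vals, 25) if n else np.nan,
                    "q75": np.percentile(vals, 75) if n else np.nan,
                    "sd_defined": n > 1,
                }
            )
    return (
        pd.DataFrame(rows)
        .sort_values(["subgroup", "scale", "visit_years"])
        .reset_index(drop=True)
    )


def _provenance(config: SimulationConfig, seed: int, extra: dict) -> dict:
    import longconn

    cfg = dataclasses.asdict(config)
    cfg["affected_edges"] = [list(t) for t in config.affected_edges]
    blob = json.dumps(cfg, sort_keys=True).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "config": cfg,
        "seed": seed,
        "versions": {
            "longconn": longconn.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        **extra,
    }


def run_full_analysis(
    config: SimulationConfig,
    spec: ModelSpec = ModelSpec(),
    k: int | None = None,
    n_perm: int = 1000,
    n_boot: int = 1000,
    seed: int = 0,
    out: str | Path | None = None,
    cohort: CohortDataset | None = None,
) -> dict:
    """Run the whole pipeline on a simulated (or supplied) cohort.

    Stages: simulate -> featurize -> stratified CV on Controls+PD ->
    model-average the prodromal cohort -> permutation relevance ->
    evaluation reports (CNT vs PD, CNT vs PROD) -> subtype the prodromal
    cohort at the CNT/PD threshold -> clinical trajectory summary.
    Fully deterministic given config + seed.  If ``out`` is given, every
    artifact is also written there (TSV/JSON) with a provenance block.
    """
    stage = "simulate"
    try:
        if cohort is None:
            cohort = simulate_cohort(config)
        manifest = cohort.manifest.set_index("subject_id")
        groups = manifest["group"]

        stage = "train_eval"
        train = cohort.features.loc[groups.isin(["CNT", "PD"])[cohort.features.index]]
        y_train = (groups.loc[train.index] == "PD").astype(int).to_numpy()
        k_eff = k if k is not None else int(y_train.sum())
        oof, ensemble = cross_validated_scores(train, y_train, spec, k=k_eff, seed=seed)

        has_prod = bool((groups == "PROD").any())
        prod_scores = None
        if has_prod:
            prod = cohort.features.loc[groups.loc[cohort.features.index] == "PROD"]
            prod_scores = ensemble_predict(ensemble, prod)
        else:
            logger.warning("no PROD subjects: subtyping stage will be skipped")

        stage = "report_cnt_pd"
        report_pd, roc_pd, _ = evaluate(
            oof.scores.to_numpy(),
            y_train,
            age=manifest.loc[train.index, "age"].to_numpy(),
            gender=manifest.loc[train.index, "gender"].to_numpy(),
            n_boot=n_boot,
            seed=seed,
            settings={"contrast": "CNT_vs_PD", "model": spec.family,
                      "scaling": spec.scaling, "k": k_eff},
        )
        from longconn.metrics import optimal_threshold

        threshold = optimal_threshold(roc_pd)

        report_prod = None
        if has_prod:
            stage = "report_cnt_prod"
            cnt_mask = groups.loc[train.index] == "CNT"
            scores_cp = np.r_[
                oof.scores.to_numpy()[cnt_mask.to_numpy()],
                prod_scores.scores.to_numpy(),
            ]
            ids_cp = list(train.index[cnt_mask]) + list(prod_scores.scores.index)
            y_cp = np.r_[
                np.zeros(int(cnt_mask.sum()), dtype=int),
                np.ones(len(prod_scores.scores), dtype=int),
            ]
            report_prod, _, _ = evaluate(
                scores_cp,
                y_cp,
                age=manifest.loc[ids_cp, "age"].to_numpy(),
                gender=manifest.loc[ids_cp, "gender"].to_numpy(),
                n_boot=n_boot,
                seed=seed,
                settings={"contrast": "CNT_vs_PROD", "model": spec.family,
                          "scaling": spec.scaling, "k": k_eff},
            )

        stage = "relevance"
        relevance = ensemble_relevance(
            ensemble, train, y_train, n_perm=n_perm, seed=seed
        )
        prominent = prominent_connections(relevance, threshold=5.0)

        stage = "subtyping"
        assignment = trajectories = clinical = None
        if has_prod:
            assignment = subtype(prod_scores.scores, threshold)
            clinical = simulate_clinical(config, cohort)
            trajectories = trajectory_summary(clinical, assignment)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    results = {
        "cohort": cohort,
        "oof_scores": oof,
        "prod_scores": prod_scores,
        "ensemble": ensemble,
        "report_cnt_pd": report_pd,
        "report_cnt_prod": report_prod,
        "threshold": threshold,
        "relevance": relevance,
        "prominent": prominent,
        "subtypes": assignment,
        "clinical": clinical,
        "trajectories": trajectories,
        "provenance": _provenance(
            config, seed,
            {"model": spec.family, "scaling": spec.scaling, "k": k_eff,
             "n_perm": n_perm, "n_boot": n_boot},
        ),
    }
    if out is not None:
        write_results(results, out)
    return results


def _score_frame(results: dict) -> pd.DataFrame:
    cohort: CohortDataset = results["cohort"]
    groups = cohort.manifest.set_index("subject_id")["group"]
    frames = [
        pd.DataFrame(
            {
                "score": results["oof_scores"].scores,
                "provenance": results["oof_scores"].provenance,
            }
        )
    ]
    if results["prod_scores"] is not None:
        frames.append(
            pd.DataFrame(
                {
                    "score": results["prod_scores"].scores,
                    "provenance": results["prod_scores"].provenance,
                }
            )
        )
    df = pd.concat(frames)
    df.insert(0, "group", groups.loc[df.index])
    df.index.name = "subject_id"
    return df.reset_index()


def write_results(results: dict, out: str | Path) -> None:
    """Write score/relevance/report/subtype artifacts as TSV + JSON."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)

    _score_frame(results).to_csv(out / "scores.tsv", sep="\t", index=False)
    results["relevance"].to_csv(out / "relevance.tsv", sep="\t", index=False)
    results["prominent"].to_csv(out / "prominent_connections.tsv", sep="\t", index=False)

    reports = {
        "cnt_vs_pd": results["report_cnt_pd"].to_dict(),
        "cnt_vs_prod": (
            results["report_cnt_prod"].to_dict()
            if results["report_cnt_prod"] is not None
            else None
        ),
        "subtyping_threshold": results["threshold"],
        "provenance": results["provenance"],
    }
    (out / "report.json").write_text(json.dumps(reports, indent=2, default=float))

    if results["subtypes"] is not None:
        results["subtypes"].assignments.rename("subgroup").to_csv(
            out / "subtypes.tsv", sep="\t"
        )
        results["trajectories"].to_csv(out / "trajectories.tsv", sep="\t", index=False)
        results["clinical"].data.to_csv(out / "clinical.tsv", sep="\t", index=False)
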