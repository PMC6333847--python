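"""Synthetic longitudinal connectome cohorts with known ground truth.

The generator emulates the structure of a three-group longitudinal imaging
study (30 controls, 21 de-novo Parkinson's disease, 16 prodromal subjects,
each scanned at baseline and ~400 days later) at the level of connectome
matrices — everything upstream (acquisition, registration, tractography)
is out of scope.

Generative model, per subject and edge:

* baseline streamline counts are negative-binomial around edge-specific
  mean counts (drawn once per simulation from a log-normal, so the edge
  "wiring profile" is shared across subjects);
* baseline mean FA is logit-normal around an edge-specific level in
  roughly [0.25, 0.6]; baseline mean MD is log-normal around
  0.7e-3 mm^2/s; both are forced to 0 wherever the count is 0 (no
  streamlines, nothing to average);
* follow-up = baseline + change.  The change is zero-mean noise with
  standard deviation sigma_m * sqrt(2 * (1 - rho)), where sigma_m is the
  metric's marginal scale and rho the within-subject baseline/follow-up
  correlation — controls progress only by noise;
* subjects of the PD-like latent class additionally receive, on each
  configured affected edge, a directed mean shift of ``effect_size``
  change-SDs (counts and FA decrease, MD increases — degeneration signs)
  plus variance inflation.  With ``effect_size = 0`` the PD-like change
  model coincides with the control one, giving an exact null.

Group means differ only in the *change*, never at baseline, so the only
signal available downstream is progression itself.  Prodromal subjects are
a latent mixture: PD-like with probability ``prod_mixture`` (default
11/16), control-like otherwise.

Clinical rating scales (UPDRS-III, H&Y, MoCA, SDM) are simulated per
visit (baseline, year 1, year 1.5) conditional on the latent class, with
baseline magnitudes keyed to the subject's nominal group.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from longconn.atlas import N_EDGES, edge_index
from longconn.connectome import (
    METRICS,
    TIMEPOINTS,
    Connectome,
    build_feature_vector,
    connectome_filename,
    feature_names,
    featurize_directory,
    validate_connectome,
    write_connectome_csv,
)

GROUPS = ("CNT", "PD", "PROD")

#: Default implanted effects: 2 streamline-count + 3 FA edges within the
#: pallido-thalamo-striatal circuit, no MD edge.
DEFAULT_AFFECTED_EDGES: tuple[tuple[str, str, str], ...] = (
    ("R-RN", "L-GPi", "streamline_count"),
    ("L-PUT", "L-THAL", "streamline_count"),
    ("R-GPe", "L-GPe", "mean_fa"),
    ("L-PUT", "L-GPe", "mean_fa"),
    ("R-CAUD", "R-THAL", "mean_fa"),
)

CLINICAL_SCALES = ("updrs3", "hy", "moca", "sdm")
CLINICAL_VISITS = (0.0, 1.0, 1.5)  # years from baseline


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the cohort generator; defaults mirror the studied cohort."""

    n_cnt: int = 30
    n_pd: int = 21
    n_prod: int = 16
    affected_edges: tuple[tuple[str, str, str], ...] = DEFAULT_AFFECTED_EDGES
    effect_size: float = 3.0  # mean longitudinal shift, in change-SD units
    prod_mixture: float = 11.0 / 16.0  # P(PROD subject is PD-like)
    prod_attenuation: float = 1.0  # effect multiplier for PD-like PROD subjects
    rho: float = 0.7  # within-subject baseline/follow-up correlation
    count_dispersion: float = 8.0  # negative-binomial size parameter
    count_log_mean: float = 4.4  # log of median edge-wise mean count (~80)
    count_log_sd: float = 1.0
    fa_jitter_sd: float = 0.03  # marginal FA scale (raw units)
    md_mean: float = 0.7e-3  # mm^2/s
    md_jitter_sd: float = 0.05e-3  # marginal MD scale (mm^2/s)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cnt, self.n_pd, self.n_prod) < 2:
            raise ValueError("each group needs at least 2 subjects")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0.0 <= self.prod_mixture <= 1.0:
            raise ValueError("prod_mixture must lie in [0, 1]")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        for a, b, metric in self.affected_edges:
            edge_index(a, b)  # validates the labels
            if metric not in METRICS:
                raise ValueError(f"unknown metric in affected_edges: {metric!r}")

    def affected_feature_indices(self) -> list[int]:
        """Positions of the implanted (pair, metric) triples in the 360-vector."""
        return [
            METRICS.index(metric) * N_EDGES + edge_index(a, b)
            for a, b, metric in self.affected_edges
        ]


@dataclass
class CohortDataset:
    """Features, labels, covariates and (synthetic-only) ground truth."""

    features: pd.DataFrame  # n x 360, indexed by subject_id
    manifest: pd.DataFrame  # subject_id, group, age, gender, days_between_scans
    truth: dict  # affected_edges, latent_class per subject
    config: SimulationConfig | None = None
    connectomes: dict = field(default_factory=dict, repr=False)

    @property
    def labels(self) -> pd.Series:
        return self.manifest.set_index("subject_id")["group"].loc[self.features.index]

    def subset(self, groups: Sequence[str]) -> "CohortDataset":
        keep = self.manifest["group"].isin(groups)
        sids = self.manifest.loc[keep, "subject_id"]
        return CohortDataset(
            features=self.features.loc[sids],
            manifest=self.manifest.loc[keep].reset_index(drop=True),
            truth=self.truth,
            config=self.config,
        )


@dataclass
class ClinicalTable:
    """Long-format clinical scores: one row per subject and visit."""

    data: pd.DataFrame  # subject_id, group, visit_years, updrs3, hy, moca, sdm

    def scale(self, name: str) -> pd.DataFrame:
        """Wide table of one scale: subjects x visits."""
        return self.data.pivot(index="subject_id", columns="visit_years", values=name)


def _edge_profiles(cfg: SimulationConfig, rng: np.random.Generator) -> dict:
    """Edge-specific population parameters, shared by every subject."""
    return {
        "count_mean": np.exp(rng.normal(cfg.count_log_mean, cfg.count_log_sd, N_EDGES)),
        "fa_mean": rng.uniform(0.25, 0.6, N_EDGES),
        "md_mean": cfg.md_mean * np.exp(rng.normal(0.0, 0.1, N_EDGES)),
    }


# Degeneration direction of the implanted change, per metric.
_EFFECT_DIRECTION = {"streamline_count": -1.0, "mean_fa": -1.0, "mean_md": +1.0}


def _subject_connectomes(
    cfg: SimulationConfig,
    profiles: dict,
    sid: str,
    pd_like: bool,
    effect_scale: float,
    rng: np.random.Generator,
) -> list[Connectome]:
    """Six validated connectomes (2 timepoints x 3 metrics) for one subject."""
    change_factor = np.sqrt(2.0 * (1.0 - cfg.rho))

    lam = profiles["count_mean"]
    r = cfg.count_dispersion
    # negative binomial via gamma-Poisson mixture: mean lam, var lam + lam^2/r
    base_count = rng.poisson(rng.gamma(r, lam / r)).astype(float)
    count_sd = np.sqrt(lam + lam**2 / r)

    fa_base = expit(rng.normal(logit(profiles["fa_mean"]), 0.15))
    md_base = profiles["md_mean"] * np.exp(rng.normal(0.0, 0.15, N_EDGES))

    base = {
        "streamline_count": base_count,
        "mean_fa": fa_base,
        "mean_md": md_base,
    }
    scale = {
        "streamline_count": count_sd,
        "mean_fa": np.full(N_EDGES, cfg.fa_jitter_sd),
        "mean_md": np.full(N_EDGES, cfg.md_jitter_sd),
    }

    # zero-mean change; affected edges of PD-like subjects get a directed
    # shift of effect_scale change-SDs plus variance inflation
    shift = {m: np.zeros(N_EDGES) for m in METRICS}
    inflate = {m: np.ones(N_EDGES) for m in METRICS}
    if pd_like and effect_scale > 0:
        for a, b, metric in cfg.affected_edges:
            e = edge_index(a, b)
            tau = scale[metric][e] * change_factor
            shift[metric][e] += _EFFECT_DIRECTION[metric] * effect_scale * tau
            inflate[metric][e] = 1.0 + 0.25 * effect_scale

    fu = {}
    for metric in METRICS:
        tau = scale[metric] * change_factor
        fu[metric] = base[metric] + shift[metric] + tau * inflate[metric] * rng.normal(
            size=N_EDGES
        )
    fu["streamline_count"] = np.clip(np.round(fu["streamline_count"]), 0.0, None)
    fu["mean_fa"] = np.clip(fu["mean_fa"], 0.0, 1.0)
    fu["mean_md"] = np.clip(fu["mean_md"], 1e-6, None)

    # no streamlines => no streamline-averaged tensor metric
    for vals in (base, fu):
        zero = vals["streamline_count"] == 0
        vals["mean_fa"] = np.where(zero, 0.0, vals["mean_fa"])
        vals["mean_md"] = np.where(zero, 0.0, vals["mean_md"])

    out = []
    iu = np.triu_indices(16, k=1)
    for tp, vals in zip(TIMEPOINTS, (base, fu)):
        for metric in METRICS:
            m = np.zeros((16, 16))
            m[iu] = vals[metric]
            m += m.T
            out.append(validate_connectome(m, metric, subject_id=sid, timepoint=tp))
    return out


# Male fraction per group, matching the studied cohort (19/30, 17/21, 14/16).
_P_MALE = {"CNT": 19 / 30, "PD": 17 / 21, "PROD": 14 / 16}


def simulate_cohort(config: SimulationConfig) -> CohortDataset:
    """Draw a full three-group cohort and featurize it.

    Deterministic given ``config`` (including its seed).  Features are
    computed through the same vectorization path as real data.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_struct, rng_noise, _ = [np.random.default_rng(s) for s in ss.spawn(3)]

    profiles = _edge_profiles(config, rng_struct)

    subjects: list[tuple[str, str, bool, float]] = []  # sid, group, pd_like, effect
    for i in range(config.n_cnt):
        subjects.append((f"CNT{i + 1:03d}", "CNT", False, 0.0))
    for i in range(config.n_pd):
        subjects.append((f"PD{i + 1:03d}", "PD", True, config.effect_size))
    for i in range(config.n_prod):
        pd_like = bool(rng_struct.random() < config.prod_mixture)
        subjects.append(
            (
                f"PROD{i + 1:03d}",
                "PROD",
                pd_like,
                config.effect_size * config.prod_attenuation,
            )
        )

    rows, manifest_rows, connectomes = [], [], {}
    latent = {}
    for sid, group, pd_like, eff in subjects:
        conns = _subject_connectomes(config, profiles, sid, pd_like, eff, rng_noise)
        for c in conns:
            connectomes[(sid, c.timepoint, c.metric)] = c
        rows.append(build_feature_vector(conns).values)
        latent[sid] = "pd_like" if pd_like else "control_like"
        age = float(np.clip(rng_struct.normal(66.0, 5.0), 45.0, 85.0))
        gender = "M" if rng_struct.random() < _P_MALE[group] else "F"
        days = float(np.clip(rng_struct.normal(400.0, 80.0), 200.0, None))
        manifest_rows.append(
            {
                "subject_id": sid,
                "group": group,
                "age": round(age, 2),
                "gender": gender,
                "days_between_scans": round(days, 1),
            }
        )

    features = pd.DataFrame(
        np.vstack(rows),
        index=pd.Index([s[0] for s in subjects], name="subject_id"),
        columns=feature_names(),
    )
    truth = {
        "affected_edges": [list(t) for t in config.affected_edges],
        "affected_feature_indices": config.affected_feature_indices(),
        "latent_class": latent,
    }
    return CohortDataset(
        features=features,
        manifest=pd.DataFrame(manifest_rows),
        truth=truth,
        config=config,
        connectomes=connectomes,
    )


# Baseline clinical means/SDs keyed to the nominal group (UPDRS-III, MoCA, SDM)
# and latent-class-driven yearly drifts.
_CLINICAL_BASELINE = {
    "updrs3": {"CNT": (0.93, 1.76), "PROD": (3.56, 4.66), "PD": (20.76, 8.26)},
    "moca": {"CNT": (27.93, 0.92), "PROD": (27.18, 1.97), "PD": (26.33, 2.14)},
    "sdm": {"CNT": (43.13, 7.67), "PROD": (34.18, 7.09), "PD": (38.57, 9.82)},
}


def simulate_clinical(
    config: SimulationConfig, cohort: CohortDataset
) -> ClinicalTable:
    """Simulate clinical rating scales per visit, conditional on latent class.

    PD-like subjects drift upward on the motor scales (UPDRS-III, H&Y) and
    downward on SDM; control-like subjects stay near their baseline, with
    H&Y pinned at 0 almost always.  All scales respect their ranges
    (UPDRS-III 0-132, H&Y half-steps 0-5, MoCA 0-30, SDM >= 0).
    """
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(3)[2])

    recs = []
    for _, rec in cohort.manifest.iterrows():
        sid, group = rec["subject_id"], rec["group"]
        pd_like = cohort.truth["latent_class"][sid] == "pd_like"

        mu, sd = _CLINICAL_BASELINE["updrs3"][group]
        updrs0 = max(0.0, rng.normal(mu, sd))
        updrs_slope = rng.normal(3.0, 2.0) if pd_like else rng.normal(0.2, 0.8)

        if pd_like and group == "PD":
            hy0 = float(np.clip(np.round(rng.normal(1.5, 0.5) * 2) / 2, 1.0, 3.0))
        elif pd_like:  # prodromal PD-like: still near stage 0 at baseline
            hy0 = 0.5 if rng.random() < 0.15 else 0.0
        else:
            hy0 = 0.0
        hy_slope = abs(rng.normal(0.3, 0.2)) if pd_like else (
            0.5 if rng.random() < 0.02 else 0.0
        )

        mu, sd = _CLINICAL_BASELINE["moca"][group]
        moca0 = rng.normal(mu, sd)
        moca_slope = rng.normal(-1.2, 0.8)

        mu, sd = _CLINICAL_BASELINE["sdm"][group]
        sdm0 = max(0.0, rng.normal(mu, sd))
        sdm_slope = rng.normal(-2.5, 1.5) if pd_like else rng.normal(-0.3, 1.0)

        for t in CLINICAL_VISITS:
            recs.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "visit_years": t,
                    "updrs3": int(np.clip(round(updrs0 + updrs_slope * t + rng.normal(0, 1.0 if t else 0.0)), 0, 132)),
                    "hy": float(np.clip(np.round((hy0 + hy_slope * t) * 2) / 2, 0.0, 5.0)),
                    "moca": int(np.clip(round(moca0 + moca_slope * t + rng.normal(0, 0.5 if t else 0.0)), 0, 30)),
                    "sdm": int(np.clip(round(sdm0 + sdm_slope * t + rng.normal(0, 1.0 if t else 0.0)), 0, 110)),
                }
            )
    return ClinicalTable(data=pd.DataFrame(recs))


# ---------------------------------------------------------------------------
# On-disk round trip: CSV matrices + TSV manifest + truth/provenance JSON.


def write_cohort(cohort: CohortDataset, directory: str | Path) -> None:
    """Write connectome CSVs, manifest.tsv, features.tsv and truth.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if not cohort.connectomes:
        raise ValueError("cohort carries no connectome matrices to write")

    manifest = cohort.manifest.copy()
    for tp in TIMEPOINTS:
        for metric in METRICS:
            manifest[f"path_{tp}_{metric}"] = [
                connectome_filename(sid, tp, metric) for sid in manifest["subject_id"]
            ]
    for (sid, tp, metric), conn in cohort.connectomes.items():
        write_connectome_csv(conn, directory / connectome_filename(sid, tp, metric))
    manifest.to_csv(directory / "manifest.tsv", sep="\t", index=False)
    cohort.features.to_csv(directory / "features.tsv", sep="\t")

    provenance = {"truth": cohort.truth}
    if cohort.config is not None:
        provenance["config"] = dataclasses.asdict(cohort.config)
    (directory / "truth.json").write_text(json.dumps(provenance, indent=2))


def read_cohort(directory: str | Path) -> CohortDataset:
    """Re-read a written cohort; features are recomputed from the matrices."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.tsv", sep="\t")
    features = featurize_directory(directory, manifest)
    truth, config = {}, None
    truth_path = directory / "truth.json"
    if truth_path.exists():
        provenance = json.loads(truth_path.read_text())
        truth = provenance.get("truth", {})
        if "config" in provenance:
            raw = dict(provenance["config"])
            raw["affected_edges"] = tuple(tuple(t) for t in raw["affected_edges"])
            config = SimulationConfig(**raw)
    return CohortDataset(
        features=features,
        manifest=manifest[["subject_id", "group", "age", "gender", "days_between_scans"]],
        truth=truth,
        config=config,
    )
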