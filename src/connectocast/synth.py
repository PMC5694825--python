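"""Seeded synthetic cohorts for the impairment-prediction pipeline.

The generator emulates, at the connectivity-matrix level, the statistical
structure the downstream analysis assumes:

* **Modular weighted networks.** Each subject's region x region matrix is
  drawn edge-wise from Gaussians around a within-module or between-module
  mean (clipped to [-1, 1], symmetric, zero diagonal), giving the block
  community structure the modularity analysis expects.
* **A planted clustering deficit.** For patients whose hidden outcome is
  *impaired*, edge weights among each designated predictive region's
  binarized neighbors are scaled down by ``clustering_effect``, lowering
  that region's expected clustering coefficient while approximately
  preserving its degree. This is the baseline signal the classifier should
  recover.
* **Cognition trajectories.** Five test scores at three timepoints, drawn
  from fixed per-test reference distributions; impaired subjects are
  shifted down ``cognitive_effect_sd_units`` control-SDs on two tests at
  the timepoints their category dictates (persistent: all timepoints;
  late onset: follow-up only). The designated-impairment probability is
  analytically corrected for the ICCTF rule's background false-positive
  rate, so the *classified* impairment rate matches the configured target
  in expectation.

A single global seed expands to per-subject substreams keyed by (group,
within-group index, purpose), so changing the cohort size never reshuffles
existing subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from . import io as cio
from .metrics import WeightedConnectivityMatrix, binarize_to_min_density
from .scoring import TESTS, TEST_DIRECTIONS, TIMEPOINTS, Z_PAIR, Z_SINGLE

__all__ = [
    "ConfigError",
    "CohortConfig",
    "SubjectRecord",
    "SyntheticCohort",
    "generate_cohort",
    "generate_connectivity",
    "generate_cognition",
    "generate_covariates",
    "write_cohort",
    "REFERENCE_SCORES",
]


class ConfigError(ValueError):
    """Invalid cohort configuration."""


#: Per-test control raw-score (mean, SD). Arbitrary by construction:
#: z-normalization against the generated control sample makes the raw scale
#: immaterial downstream. Values sit in each instrument's plausible range
#: (RAVLT words recalled, CTMT seconds, COWA words produced).
REFERENCE_SCORES = {
    "RAVLT_A1": (6.5, 2.0),
    "RAVLT_A6": (10.5, 2.5),
    "CTMT_1": (35.0, 10.0),
    "CTMT_5": (80.0, 25.0),
    "COWA": (40.0, 11.0),
}

#: Number of tests an impaired subject is shifted on (the ICCTF pair rule).
N_AFFECTED_TESTS = 2

_GROUP_CODE = {"patient": 0, "control": 1}
_STREAM_COVARIATES = 0
_STREAM_OUTCOME = 1
_STREAM_COGNITION = 2
_STREAM_MATRIX = 10  # + timepoint index

# Generative moments used to standardize covariates for the optional
# outcome log-odds coupling.
_COVARIATE_MOMENTS = {
    "age": (49.5, 8.95),
    "education": (17.0, 2.8),
    "stage": (2.03, 0.59),
    "minority": (0.30, 0.458),
    "menopause": (0.31, 0.462),
    "cad": (50.0, 10.0),
}


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic cohort; defaults mirror the study conditions."""

    n_patients: int = 31
    n_controls: int = 43
    n_regions: int = 90
    n_modules: int = 5
    within_module_weight_mean: float = 0.5
    between_module_weight_mean: float = 0.2
    weight_sd: float = 0.12
    predictive_regions: tuple[int, ...] = (4, 22, 40, 58, 76)
    clustering_effect: float = 0.5
    impairment_rate_patients: float = 0.55
    impairment_rate_controls: float = 0.26
    late_onset_fraction: float = 0.41
    cognitive_effect_sd_units: float = 3.0
    covariate_logodds: dict = field(default_factory=dict)
    stage_probs: tuple[float, float, float] = (0.16, 0.65, 0.19)
    matrix_timepoints: tuple[str, ...] = TIMEPOINTS
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("impairment_rate_patients", "impairment_rate_controls",
                     "late_onset_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.within_module_weight_mean <= self.between_module_weight_mean:
            raise ConfigError("within-module mean must exceed between-module mean")
        if not 1 <= self.n_modules <= self.n_regions:
            raise ConfigError("need 1 <= n_modules <= n_regions")
        bad = [r for r in self.predictive_regions if not 0 <= r < self.n_regions]
        if bad:
            raise ConfigError(f"predictive regions out of range: {bad}")
        if self.clustering_effect < 0:
            raise ConfigError("clustering_effect must be >= 0")
        if self.cognitive_effect_sd_units < 0:
            raise ConfigError("cognitive_effect_sd_units must be >= 0")
        if abs(sum(self.stage_probs) - 1.0) > 1e-9:
            raise ConfigError("stage_probs must sum to 1")

    def region_labels(self) -> list[str]:
        return [f"R{i:03d}" for i in range(self.n_regions)]

    def region_modules(self) -> np.ndarray:
        """Contiguous block assignment of regions to modules."""
        return (np.arange(self.n_regions) * self.n_modules) // self.n_regions


@dataclass
class SubjectRecord:
    subject_id: str
    group: str  # "patient" | "control"
    index: int  # within-group index; keys the RNG substreams
    covariates: dict = field(default_factory=dict)
    true_outcome: bool = False
    true_category: str = "none"  # "persistent" | "late_onset" | "none"


def _rng(config: CohortConfig, record: SubjectRecord, stream: int) -> np.random.Generator:
    key = (_GROUP_CODE[record.group], record.index, stream)
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=key))


def _icctf_probability(
    shifts: Iterable[float], t_pair: float = Z_PAIR, t_single: float = Z_SINGLE
) -> float:
    """Probability the ICCTF rule fires for independent z_i ~ N(-shift_i, 1).

    ``t_pair``/``t_single`` are the thresholds expressed on the *true* z
    scale (they shift when the normalization reference is contaminated).
    Not-impaired means every score is above ``t_single`` and at most one
    lies in (t_single, t_pair]; everything else triggers the rule.
    """
    cs, bs = [], []
    for s in shifts:
        cs.append(1.0 - norm.cdf(t_pair + s))  # P(z > t_pair)
        bs.append(norm.cdf(t_pair + s) - norm.cdf(t_single + s))
    prod_c = float(np.prod(cs))
    p_not = prod_c
    for i, b in enumerate(bs):
        others = prod_c / cs[i] if cs[i] > 0 else float(np.prod(cs[:i] + cs[i + 1:]))
        p_not += b * others
    return 1.0 - p_not


def effective_raw_shift(config: CohortConfig) -> float:
    """Raw-scale downward shift realizing ``cognitive_effect_sd_units``.

    The shift is specified in *realized* control-SD units, but impaired
    controls sit inside the normalization sample and inflate its SD: with a
    fraction ``f = rate_controls * 2/5`` of control scores shifted by raw
    amount ``d``, the reference SD is ``s = sqrt(1 + f(1-f) d^2)`` reference
    units. Requiring the observed separation ``d / s`` to equal the
    configured value ``delta`` gives ``s^2 = 1 / (1 - f(1-f) delta^2)``.

    The observed separation saturates at ``1/sqrt(f(1-f))`` as ``d`` grows;
    an infeasible request is capped at 95% of that bound.
    """
    delta = config.cognitive_effect_sd_units
    if delta <= 0:
        return 0.0
    f = config.impairment_rate_controls * N_AFFECTED_TESTS / len(TESTS)
    if f <= 0:
        return delta
    max_sep = 1.0 / np.sqrt(f * (1.0 - f))
    delta = min(delta, 0.95 * max_sep)
    s_sq = 1.0 / (1.0 - f * (1.0 - f) * delta**2)
    return float(delta * np.sqrt(s_sq))


def designated_rate(config: CohortConfig, group: str) -> float:
    """Designation probability for a group's hidden impairment outcome.

    Equals the configured target rate: because the cognitive shift is
    expressed in realized control-SD units (see ``effective_raw_shift``),
    designated subjects trip the ICCTF rule almost surely and undesignated
    ones almost never, so classified incidence matches designation.
    """
    return (config.impairment_rate_patients if group == "patient"
            else config.impairment_rate_controls)


def generate_covariates(config: CohortConfig, record: SubjectRecord) -> dict:
    """Draw age, education, stage, minority, menopause and CAD for a subject."""
    rng = _rng(config, record, _STREAM_COVARIATES)
    return {
        "age": float(rng.uniform(34.0, 65.0)),
        "education": float(np.clip(np.round(rng.normal(17.0, 2.8)), 10, 22)),
        "stage": int(rng.choice([1, 2, 3], p=config.stage_probs)),
        "minority": int(rng.random() < 0.30),
        "menopause": int(rng.random() < 0.31),
        "cad": float(rng.normal(50.0, 10.0)),
    }


def assign_outcome(config: CohortConfig, record: SubjectRecord) -> None:
    """Designate the hidden impairment outcome and its category."""
    rng = _rng(config, record, _STREAM_OUTCOME)
    base = designated_rate(config, record.group)
    if config.covariate_logodds and 0.0 < base < 1.0:
        shift = 0.0
        for name, w in config.covariate_logodds.items():
            mu, sd = _COVARIATE_MOMENTS[name]
            shift += w * (record.covariates[name] - mu) / sd
        p = float(expit(logit(base) + shift))
    else:
        p = base
    record.true_outcome = bool(rng.random() < p)
    if record.true_outcome:
        record.true_category = ("late_onset" if rng.random() < config.late_onset_fraction
                                else "persistent")
    else:
        record.true_category = "none"


def generate_connectivity(
    config: CohortConfig, record: SubjectRecord, timepoint: str = "baseline"
) -> WeightedConnectivityMatrix:
    """Draw one subject-timepoint modular weighted connectivity matrix.

    Impaired patients carry the planted clustering deficit: edges among each
    predictive region's minimum-density neighbors are scaled by
    ``1 - clustering_effect``.
    """
    tp_index = TIMEPOINTS.index(timepoint)
    rng = _rng(config, record, _STREAM_MATRIX + tp_index)
    n = config.n_regions
    module_of = config.region_modules()
    iu, ju = np.triu_indices(n, k=1)
    means = np.where(
        module_of[iu] == module_of[ju],
        config.within_module_weight_mean,
        config.between_module_weight_mean,
    )
    upper = rng.normal(means, config.weight_sd)
    w = np.zeros((n, n))
    w[iu, ju] = upper
    w = w + w.T
    np.clip(w, -1.0, 1.0, out=w)
    labels = config.region_labels()

    if (record.group == "patient" and record.true_outcome
            and config.clustering_effect > 0 and config.predictive_regions):
        base = WeightedConnectivityMatrix(labels=labels, weights=w.copy())
        net = binarize_to_min_density(base, mode="per_subject")
        scale = 1.0 - min(config.clustering_effect, 1.0)
        for region in config.predictive_regions:
            nbrs = np.flatnonzero(net.adjacency[region])
            nbrs = nbrs[nbrs != region]
            if nbrs.size >= 2:
                block = np.ix_(nbrs, nbrs)
                w[block] = w[block] * scale
        np.fill_diagonal(w, 0.0)

    return WeightedConnectivityMatrix(labels=labels, weights=w)


def generate_cognition(config: CohortConfig, record: SubjectRecord) -> pd.DataFrame:
    """Draw one subject's raw cognitive scores at all three timepoints."""
    rng = _rng(config, record, _STREAM_COGNITION)
    raw_shift = effective_raw_shift(config)
    affected = set(rng.choice(len(TESTS), size=N_AFFECTED_TESTS, replace=False).tolist())
    if record.true_category == "persistent":
        shifted_tps = set(TIMEPOINTS)
    elif record.true_category == "late_onset":
        shifted_tps = {"year1"}
    else:
        shifted_tps = set()
    rows = []
    for tp in TIMEPOINTS:
        for t_idx, test in enumerate(TESTS):
            z = rng.normal()
            if record.true_outcome and t_idx in affected and tp in shifted_tps:
                z -= raw_shift
            mean, sd = REFERENCE_SCORES[test]
            if TEST_DIRECTIONS[test] == "higher_better":
                raw = mean + sd * z
            else:  # timed test: worse performance = larger raw value
                raw = mean - sd * z
            rows.append(
                {"subject_id": record.subject_id, "group": record.group,
                 "timepoint": tp, "test": test, "raw_score": round(raw, 4)}
            )
    return pd.DataFrame(rows)


@dataclass
class SyntheticCohort:
    """A generated cohort: subject table, matrices, cognition, provenance."""

    config: CohortConfig
    subjects: pd.DataFrame  # id, group, true labels + covariates
    matrices: dict  # (subject_id, timepoint) -> WeightedConnectivityMatrix
    cognition: pd.DataFrame  # long: subject_id, group, timepoint, test, raw_score

    def baseline_matrices(self, group: str = "patient"):
        """(subject_ids, matrices) for one group at baseline, in table order."""
        ids = self.subjects.loc[self.subjects["group"] == group, "subject_id"].tolist()
        return ids, [self.matrices[(sid, "baseline")] for sid in ids]


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the full cohort deterministically from ``config.seed``."""
    records: list[SubjectRecord] = []
    for group, n, prefix in (("patient", config.n_patients, "P"),
                             ("control", config.n_controls, "C")):
        for i in range(n):
            rec = SubjectRecord(subject_id=f"{prefix}{i:03d}", group=group, index=i)
            rec.covariates = generate_covariates(config, rec)
            assign_outcome(config, rec)
            records.append(rec)

    matrices = {}
    cognition_frames = []
    for rec in records:
        for tp in config.matrix_timepoints:
            matrices[(rec.subject_id, tp)] = generate_connectivity(config, rec, tp)
        cognition_frames.append(generate_cognition(config, rec))

    subjects = pd.DataFrame(
        [
            {"subject_id": r.subject_id, "group": r.group,
             "true_outcome": int(r.true_outcome), "true_category": r.true_category,
             **r.covariates}
            for r in records
        ]
    )
    return SyntheticCohort(
        config=config,
        subjects=subjects,
        matrices=matrices,
        cognition=pd.concat(cognition_frames, ignore_index=True),
    )


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write matrices and cohort tables; returns the paths written."""
    out_dir = Path(out_dir)
    mat_dir = out_dir / "matrices"
    mat_dir.mkdir(parents=True, exist_ok=True)
    for (sid, tp), mx in sorted(cohort.matrices.items()):
        cio.write_matrix(mat_dir / f"{sid}_{tp}.csv", mx)
    cov_cols = ["subject_id", "group", "age", "education", "stage",
                "minority", "menopause", "cad"]
    paths = {
        "matrices": mat_dir,
        "cognition": out_dir / "cognition.csv",
        "covariates": out_dir / "covariates.csv",
        "truth": out_dir / "truth.csv",
    }
    cio.write_table(paths["cognition"], cohort.cognition)
    cio.write_table(paths["covariates"], cohort.subjects[cov_cols])
    cio.write_table(
        paths["truth"],
        cohort.subjects[["subject_id", "group", "true_outcome", "true_category"]],
    )
    return paths
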