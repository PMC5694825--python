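"""Cognitive z-scoring, the ICCTF impairment rule, and incidence comparison.

Raw scores on five standardized tests (RAVLT trials A1 and A6, CTMT trails
1 and 5, COWA) are converted to z-scores against the healthy-control group's
mean and SD per test. Timed tests (CTMT) are sign-flipped so a negative z
always means worse performance. A timepoint is *impaired* under the ICCTF
criterion when at least two z-scores are −1.5 or lower, or at least one is
−2.0 or lower (thresholds inclusive). Longitudinally, a patient's outcome is
impaired when she is impaired at both baseline and 1-year follow-up
(*persistent*) or at follow-up only (*late onset*); impairment present at
baseline but resolved by follow-up falls outside both definitions and maps
to an unimpaired outcome, flagged as ``resolved`` for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TESTS",
    "TEST_DIRECTIONS",
    "TIMEPOINTS",
    "ImpairmentStatus",
    "compute_zscores",
    "classify_timepoint",
    "classify_longitudinal",
    "label_cohort",
    "incidence_proportion_test",
]

TESTS = ("RAVLT_A1", "RAVLT_A6", "CTMT_1", "CTMT_5", "COWA")

#: Timed tests score in seconds, so a *higher* raw value is worse.
TEST_DIRECTIONS = {
    "RAVLT_A1": "higher_better",
    "RAVLT_A6": "higher_better",
    "CTMT_1": "lower_better",
    "CTMT_5": "lower_better",
    "COWA": "higher_better",
}

TIMEPOINTS = ("baseline", "post_chemo", "year1")

#: ICCTF thresholds: >=2 scores at or below Z_PAIR, or >=1 at or below Z_SINGLE.
Z_PAIR = -1.5
Z_SINGLE = -2.0


@dataclass(frozen=True)
class ImpairmentStatus:
    subject_id: str
    impaired_at_baseline: bool
    impaired_at_year1: bool
    outcome_label: str  # "impaired" | "unimpaired"
    category: str  # "persistent" | "late_onset" | "none"
    resolved: bool = False  # baseline-only impairment, counted unimpaired


def compute_zscores(
    cognition: pd.DataFrame,
    control_group: str = "control",
    reference: str = "timepoint",
    directions: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Z-normalize raw scores against the control group's mean and SD.

    ``cognition`` is long format with columns ``subject_id, group, timepoint,
    test, raw_score``. ``reference='timepoint'`` normalizes each timepoint
    against the controls measured at that timepoint; ``reference='baseline'``
    reuses the baseline control statistics for all timepoints. Returns the
    table with a ``zscore`` column added; for timed (lower-better) tests the
    sign is flipped so negative z always means worse performance.
    """
    directions = directions or TEST_DIRECTIONS
    controls = cognition[cognition["group"] == control_group]
    if controls.empty:
        raise ValueError(f"no subjects in control group {control_group!r}")
    if reference == "baseline":
        ref = controls[controls["timepoint"] == "baseline"]
        ref_stats = ref.groupby("test")["raw_score"].agg(["mean", "std", "count"])
        key_cols = ["test"]
    elif reference == "timepoint":
        ref_stats = controls.groupby(["test", "timepoint"])["raw_score"].agg(
            ["mean", "std", "count"]
        )
        key_cols = ["test", "timepoint"]
    else:
        raise ValueError(f"unknown reference mode: {reference!r}")

    bad = ref_stats[(ref_stats["count"] < 2) | ~(ref_stats["std"] > 0)]
    if not bad.empty:
        raise ValueError(
            "control reference needs >=2 subjects and positive SD; "
            f"failing: {list(bad.index)}"
        )

    out = cognition.merge(
        ref_stats.reset_index()[key_cols + ["mean", "std"]], on=key_cols, how="left"
    )
    z = (out["raw_score"] - out["mean"]) / out["std"]
    flip = out["test"].map(lambda t: -1.0 if directions[t] == "lower_better" else 1.0)
    out["zscore"] = z * flip
    return out.drop(columns=["mean", "std"])


def classify_timepoint(zscores) -> bool:
    """Apply the ICCTF impairment rule to one timepoint's z-scores.

    Impaired iff at least two scores are <= -1.5 or at least one is <= -2.0.
    Missing (NaN) scores are ignored; all-missing is undeterminable.
    """
    z = np.asarray(zscores, dtype=float)
    z = z[~np.isnan(z)]
    if z.size == 0:
        raise ValueError("cannot classify a timepoint with no scores")
    return bool((z <= Z_PAIR).sum() >= 2 or (z <= Z_SINGLE).sum() >= 1)


def classify_longitudinal(
    subject_id: str, impaired_baseline: bool, impaired_year1: bool
) -> ImpairmentStatus:
    """Combine baseline and 1-year impairment flags into an outcome label."""
    if impaired_baseline and impaired_year1:
        outcome, category, resolved = "impaired", "persistent", False
    elif impaired_year1:
        outcome, category, resolved = "impaired", "late_onset", False
    elif impaired_baseline:
        outcome, category, resolved = "unimpaired", "none", True
    else:
        outcome, category, resolved = "unimpaired", "none", False
    return ImpairmentStatus(
        subject_id=subject_id,
        impaired_at_baseline=impaired_baseline,
        impaired_at_year1=impaired_year1,
        outcome_label=outcome,
        category=category,
        resolved=resolved,
    )


def label_cohort(zscores: pd.DataFrame) -> pd.DataFrame:
    """Classify every subject from a long z-score table.

    Requires baseline and year1 rows per subject; returns one row per
    subject with flags, outcome label and category.
    """
    rows = []
    for (sid, group), sub in zscores.groupby(["subject_id", "group"], sort=True):
        flags = {}
        for tp in ("baseline", "year1"):
            z = sub.loc[sub["timepoint"] == tp, "zscore"]
            if z.empty:
                raise ValueError(f"subject {sid} is missing timepoint {tp!r}")
            flags[tp] = classify_timepoint(z)
        status = classify_longitudinal(str(sid), flags["baseline"], flags["year1"])
        rows.append(
            {
                "subject_id": status.subject_id,
                "group": group,
                "impaired_at_baseline": status.impaired_at_baseline,
                "impaired_at_year1": status.impaired_at_year1,
                "outcome": status.outcome_label,
                "category": status.category,
                "resolved": status.resolved,
            }
        )
    return pd.DataFrame(rows)


def incidence_proportion_test(
    k1: int, n1: int, k2: int, n2: int, continuity: bool = False
) -> tuple[float, float]:
    """Two-sample equality-of-proportions test (Pearson chi-squared, df=1).

    Continuity correction is off by default; the uncorrected statistic is the
    one the classical two-proportion z-test squares to. Returns (X^2, p).
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0 or not 0 <= k <= n:
            raise ValueError("counts must satisfy 0 <= k <= n, n > 0")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if table.sum(axis=0).min() == 0:
        raise ValueError("degenerate 2x2 table: a margin is empty")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=continuity)
    return float(chi2), float(p)
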