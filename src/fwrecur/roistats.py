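"""Per-region summary statistics and cohort-level group comparisons.

For each patient and region of interest (contrast-enhancing tumor, pure
edema, edema with later recurrence) the 10th/50th/90th percentiles and the
mean of a scalar map are extracted.  Edema-with-recurrence is then compared
against recurrence-free edema across the cohort with the two-sided
Wilcoxon rank-sum (Mann-Whitney) test, one test per map kind x summary
statistic x correction state -- the layout of a
tissue-volume / MD / FA comparison table.

The unit of analysis is the patient: voxel values are first reduced to
per-patient summaries, and the two-sample test runs on one number per
patient per region, avoiding pseudo-replication of spatially correlated
voxels.  A pooled voxel-level mode is available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .phantom import LABEL_EDEMA_PURE, LABEL_EDEMA_RECUR, LABEL_TUMOR
from .tensors import ScalarMap

__all__ = [
    "REGION_CODES",
    "ROISummary",
    "GroupComparison",
    "extract_region_values",
    "summarize",
    "rank_sum_test",
    "summarize_cohort",
    "build_comparison_table",
]

#: Region names -> phantom label codes.
REGION_CODES = {
    "ce_tumor": LABEL_TUMOR,
    "edema_pure": LABEL_EDEMA_PURE,
    "edema_recur": LABEL_EDEMA_RECUR,
}

PERCENTILE_LEVELS = ("p10", "p50", "mean", "p90")


@dataclass
class ROISummary:
    patient_id: str
    region: str
    kind: str
    corrected: bool
    p10: float
    p50: float
    p90: float
    mean: float
    n_voxels: int
    n_missing: int = 0

    def __post_init__(self) -> None:
        if self.n_voxels <= 0:
            raise ValueError("summary requires at least one voxel")
        if not (self.p10 <= self.p50 <= self.p90):
            raise ValueError("percentiles must be monotone")


@dataclass
class GroupComparison:
    kind: str
    corrected: bool
    statistic_level: str  # p10 | p50 | mean | p90
    group_a: np.ndarray  # edema_pure per-patient values
    group_b: np.ndarray  # edema_recur per-patient values
    u_statistic: float
    p_value: float
    mode: str  # "exact" | "normal"
    degenerate: bool = False


def extract_region_values(
    scalar_map: ScalarMap | np.ndarray,
    labels: np.ndarray,
    region_code: int,
    patient_id: str = "?",
) -> tuple[np.ndarray, int]:
    """Finite map values inside one labelled region.

    Returns (values, n_missing); raises if the region code is absent.
    """
    values = scalar_map.values if isinstance(scalar_map, ScalarMap) else scalar_map
    if values.shape != labels.shape:
        raise ValueError("map and label volume are not aligned")
    in_region = labels == region_code
    if not np.any(in_region):
        raise ValueError(
            f"region code {region_code} empty for patient {patient_id}"
        )
    vals = values[in_region]
    finite = np.isfinite(vals)
    return vals[finite], int((~finite).sum())


def summarize(values: np.ndarray) -> tuple[float, float, float, float]:
    """(p10, p50, p90, mean) with linear-interpolation percentiles."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarize an empty value set")
    p10, p50, p90 = np.percentile(values, [10, 50, 90])
    return float(p10), float(p50), float(p90), float(values.mean())


def rank_sum_test(
    group_a,
    group_b,
    mode: str = "auto",
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    ``mode='exact'`` enumerates the null distribution (requires no ties);
    ``'normal'`` uses the tie-corrected normal approximation with
    continuity correction; ``'auto'`` picks exact when the pooled sample
    is small (n <= 12) and tie-free.  If every pooled value is identical
    the test is degenerate and p = 1 is returned with a flag.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return GroupComparison("", False, "", a, b,
                               u_statistic=a.size * b.size / 2.0,
                               p_value=1.0, mode="degenerate", degenerate=True)
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        mode = "exact" if (pooled.size <= 12 and not has_ties) else "normal"
    if mode == "exact" and has_ties:
        mode = "normal"
    method = "exact" if mode == "exact" else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return GroupComparison(
        "", False, "", a, b,
        u_statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        mode=mode,
    )


def summarize_cohort(
    maps_by_patient: dict[str, dict[tuple[str, bool], ScalarMap]],
    labels_by_patient: dict[str, np.ndarray],
    regions: tuple[str, ...] = ("ce_tumor", "edema_pure", "edema_recur"),
) -> pd.DataFrame:
    """Long-format table of per-patient per-region summaries.

    ``maps_by_patient[pid][(kind, corrected)]`` holds the scalar maps of
    one patient (kind in {"FA", "MD", "tissue_fraction"}).
    """
    rows = []
    for pid, maps in maps_by_patient.items():
        labels = labels_by_patient[pid]
        for (kind, corrected), smap in maps.items():
            for region in regions:
                vals, n_missing = extract_region_values(
                    smap, labels, REGION_CODES[region], pid
                )
                if vals.size == 0:
                    raise ValueError(
                        f"region {region} of patient {pid} has only missing values"
                    )
                p10, p50, p90, mean = summarize(vals)
                rows.append(
                    {
                        "patient_id": pid,
                        "region": region,
                        "kind": kind,
                        "corrected": corrected,
                        "p10": p10,
                        "p50": p50,
                        "p90": p90,
                        "mean": mean,
                        "n_voxels": int(vals.size),
                        "n_missing": n_missing,
                    }
                )
    return pd.DataFrame(rows)


def build_comparison_table(summaries: pd.DataFrame) -> pd.DataFrame:
    """Edema-with-recurrence vs pure-edema rank-sum p-values.

    One row per map kind x summary level x correction state.  The
    tissue-fraction map only exists on the corrected side, so its
    uncorrected cells are emitted with NaN p-values (not applicable).
    Patients lacking either region for a map are dropped from that
    comparison with a logged count.
    """
    rows = []
    kinds = summaries[["kind", "corrected"]].drop_duplicates()
    for kind in summaries["kind"].unique():
        for level in PERCENTILE_LEVELS:
            for corrected in (False, True):
                sub = summaries[
                    (summaries["kind"] == kind) & (summaries["corrected"] == corrected)
                ]
                if sub.empty:
                    rows.append(
                        {
                            "kind": kind,
                            "level": level,
                            "corrected": corrected,
                            "p_value": np.nan,
                            "n_patients": 0,
                            "note": "n/a",
                        }
                    )
                    continue
                wide = sub.pivot_table(
                    index="patient_id", columns="region", values=level
                )
                complete = wide.dropna(subset=["edema_pure", "edema_recur"])
                n_dropped = len(wide) - len(complete)
                comp = rank_sum_test(
                    complete["edema_pure"].to_numpy(),
                    complete["edema_recur"].to_numpy(),
                )
                rows.append(
                    {
                        "kind": kind,
                        "level": level,
                        "corrected": corrected,
                        "p_value": comp.p_value,
                        "n_patients": int(len(complete)),
                        "note": f"dropped={n_dropped}" if n_dropped else "",
                    }
                )
    return pd.DataFrame(rows)
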