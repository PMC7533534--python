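"""MAR/MNAR missingness classification and the two-step observation filter.

A protein's non-detections are informative when they concentrate in one
compartment — typical limit-of-detection (MNAR) behaviour for low-abundance
proteins.  Each protein's (observed, missing) x (group) 2x2 table is tested
with a likelihood-ratio G-test; the dataset-level pooled table is also
reported since group-wise censoring can be systemic.

The two-step filter mirrors a semi-conservative strategy: a hard >=50%
overall-observation filter removes sparsely observed proteins, then the
G-test flags (but does not remove) proteins whose missingness depends on
compartment, so that downstream complete-case summaries can treat them with
caution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy

from .io import IntensityMatrix, SampleMetadata

__all__ = [
    "MissingnessResult",
    "FilterReport",
    "gtest_2x2",
    "gtest_missingness",
    "pooled_gtest",
    "filter_by_observation_rate",
    "two_step_filter",
]


@dataclass
class MissingnessResult:
    protein_id: str
    g_stat: float
    df: int
    p_value: float
    classification: str  # MAR | MNAR | indeterminate

    def __post_init__(self) -> None:
        if self.g_stat < -1e-9:
            raise ValueError("G statistic must be non-negative")
        self.g_stat = max(self.g_stat, 0.0)


def gtest_2x2(table, williams: bool = True) -> tuple[float, float]:
    """Likelihood-ratio G-test of independence for a 2x2 table.

    ``G = 2 * sum O * ln(O/E)`` with ``0 * ln(0/E) = 0`` and expectations
    from the independence margins; p from chi-square with 1 df.  The Williams
    small-sample correction (on by default) divides G by
    ``1 + (N/r1 + N/r2 - 1)(N/c1 + N/c2 - 1) / (6N)``; without it the test is
    noticeably liberal at the group sizes typical of this design.
    A table with a zero margin carries no information: G = 0, p = 1.
    """
    O = np.asarray(table, dtype=float)
    if O.shape != (2, 2) or np.any(O < 0):
        raise ValueError("expected a non-negative 2x2 table")
    r = O.sum(axis=1)
    c = O.sum(axis=0)
    n = O.sum()
    if np.any(r == 0) or np.any(c == 0):
        return 0.0, 1.0
    E = np.outer(r, c) / n
    g = 2.0 * float(xlogy(O, O / E).sum())
    g = max(g, 0.0)
    if williams:
        q = 1.0 + (n / r[0] + n / r[1] - 1.0) * (n / c[0] + n / c[1] - 1.0) / (6.0 * n)
        g /= q
    return g, float(stats.chi2.sf(g, df=1))


def _group_observation_counts(
    matrix: IntensityMatrix, metadata: SampleMetadata, groups: tuple[str, str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    metadata.require_samples(matrix)
    cols = []
    for g in groups:
        ids = [s for s in metadata.samples_for(compartment=g) if s in matrix.sample_ids]
        if not ids:
            raise ValueError(f"group {g!r} absent from metadata/matrix")
        cols.append([matrix.sample_ids.index(s) for s in ids])
    obs = matrix.observed()
    o1 = obs[:, cols[0]].sum(axis=1)
    o2 = obs[:, cols[1]].sum(axis=1)
    return o1, len(cols[0]) - o1, o2, len(cols[1]) - o2


def gtest_missingness(
    matrix: IntensityMatrix,
    metadata: SampleMetadata,
    groups: tuple[str, str] = ("Glom", "PT"),
    alpha: float = 0.05,
    williams: bool = True,
) -> pd.DataFrame:
    """Per-protein G-test of missingness against group membership.

    Classification: MNAR if p < alpha; proteins fully observed in both
    groups are MAR with G = 0; proteins with no observation in either group
    are indeterminate (no evidence either way).
    """
    for g in groups:
        if not metadata.samples_for(compartment=g):
            raise ValueError(f"group {g!r} has no samples in metadata")
        if len(metadata.samples_for(compartment=g)) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    o1, m1, o2, m2 = _group_observation_counts(matrix, metadata, groups)
    rows = []
    for pid, a, b, c, d in zip(matrix.protein_ids, o1, o2, m1, m2):
        g_stat, p = gtest_2x2([[a, b], [c, d]], williams=williams)
        if a + b == 0:
            cls = "indeterminate"
        elif p < alpha:
            cls = "MNAR"
        else:
            cls = "MAR"
        rows.append(MissingnessResult(pid, g_stat, 1, p, cls))
    return pd.DataFrame([r.__dict__ for r in rows])


def pooled_gtest(
    matrix: IntensityMatrix,
    metadata: SampleMetadata,
    groups: tuple[str, str] = ("Glom", "PT"),
    williams: bool = True,
) -> MissingnessResult:
    """Dataset-level G-test on observation counts pooled over all proteins."""
    o1, m1, o2, m2 = _group_observation_counts(matrix, metadata, groups)
    table = [[o1.sum(), o2.sum()], [m1.sum(), m2.sum()]]
    g, p = gtest_2x2(table, williams=williams)
    cls = "MNAR" if p < 0.05 else "MAR"
    return MissingnessResult("__pooled__", g, 1, p, cls)


def filter_by_observation_rate(
    matrix: IntensityMatrix, min_frac: float = 0.5
) -> tuple[IntensityMatrix, list[str]]:
    """Retain proteins observed in at least ``min_frac`` of all samples
    (boundary inclusive)."""
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must lie in (0, 1]")
    frac = matrix.observed().mean(axis=1)
    keep = frac >= min_frac
    removed = [p for p, k in zip(matrix.protein_ids, keep) if not k]
    kept_ids = [p for p, k in zip(matrix.protein_ids, keep) if k]
    return matrix.subset_proteins(kept_ids), removed


@dataclass
class FilterReport:
    n_input: int
    n_removed_low_observation: int
    n_flagged_mnar: int
    removed_ids: list[str] = field(repr=False)
    mnar_ids: list[str] = field(repr=False)
    per_protein: pd.DataFrame = field(repr=False)
    pooled: MissingnessResult | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": ["input", "observation_rate_filter", "gtest_mnar_flag"],
                "n_proteins": [
                    self.n_input,
                    self.n_input - self.n_removed_low_observation,
                    self.n_input - self.n_removed_low_observation,
                ],
                "n_affected": [0, self.n_removed_low_observation, self.n_flagged_mnar],
            }
        )


def two_step_filter(
    matrix: IntensityMatrix,
    metadata: SampleMetadata,
    min_frac: float = 0.5,
    alpha: float = 0.05,
    groups: tuple[str, str] = ("Glom", "PT"),
    williams: bool = True,
) -> tuple[IntensityMatrix, FilterReport]:
    """Two-step semi-conservative missing-data filter.

    Step 1 removes proteins observed in fewer than ``min_frac`` of all
    samples; step 2 runs the per-protein missingness G-test on the survivors
    and *flags* MNAR proteins without removing them.  Only step 1 excludes.
    """
    filtered, removed = filter_by_observation_rate(matrix, min_frac)
    results = gtest_missingness(filtered, metadata, groups, alpha, williams)
    mnar_ids = results.loc[results["classification"] == "MNAR", "protein_id"].tolist()
    report = FilterReport(
        n_input=matrix.n_proteins,
        n_removed_low_observation=len(removed),
        n_flagged_mnar=len(mnar_ids),
        removed_ids=removed,
        mnar_ids=mnar_ids,
        per_protein=results,
        pooled=pooled_gtest(filtered, metadata, groups, williams),
    )
    return filtered, report
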