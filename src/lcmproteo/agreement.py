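"""Between-run and between-method agreement QC.

Bland–Altman-style paired-difference statistics and reproducibility limits,
run correlations, spectral-count abundance classes, 2x2 overlap tables with
exact tests, and hypergeometric annotation-set enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .contingency import ContingencyResult, fisher_exact
from .io import SpectralCountTable

__all__ = [
    "AgreementReport",
    "paired_difference_stats",
    "reproducibility_limit",
    "run_correlation",
    "abundance_classes",
    "overlap_table",
    "fisher_exact",
    "ContingencyResult",
    "set_enrichment",
    "bland_altman_table",
]


@dataclass
class AgreementReport:
    """Summary of agreement between two runs on commonly observed proteins."""

    n_common: int
    mean_diff: float
    sd_diff: float
    limit: float
    pct_within: float
    pearson_r: float
    n_discordant: int = 0  # observed in exactly one of the two runs

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_within <= 100.0:
            raise ValueError("pct_within outside [0, 100]")
        if self.limit < 0:
            raise ValueError("limit must be non-negative")
        if np.isfinite(self.pearson_r) and abs(self.pearson_r) > 1 + 1e-12:
            raise ValueError("|pearson_r| > 1")


def _common(run1, run2, zero_missing: bool):
    """Align two per-protein series; return common-observed values + discordant count."""
    s1 = pd.Series(run1).astype(float)
    s2 = pd.Series(run2).astype(float)
    s1, s2 = s1.align(s2, join="outer")
    if zero_missing:
        s1 = s1.replace(0.0, np.nan)
        s2 = s2.replace(0.0, np.nan)
    obs1, obs2 = s1.notna(), s2.notna()
    both = obs1 & obs2
    n_discordant = int((obs1 ^ obs2).sum())
    return s1[both].to_numpy(), s2[both].to_numpy(), n_discordant


def paired_difference_stats(
    run1, run2, k: float = 1.96, zero_missing: bool = True
) -> AgreementReport:
    """Agreement report for two runs indexed by protein.

    Only proteins observed in both runs enter (``zero_missing`` treats zeros
    as non-detections, the spectral-count convention); proteins observed in
    exactly one run are counted as ``n_discordant``.  ``mean_diff`` and
    ``sd_diff`` (denominator n-1) describe run1 - run2; the reproducibility
    limit is ``k * sd_diff`` centred at the mean difference.
    """
    v1, v2, n_disc = _common(run1, run2, zero_missing)
    if len(v1) < 3:
        raise ValueError("fewer than 3 commonly observed proteins")
    d = v1 - v2
    mean_diff = float(np.mean(d))
    sd_diff = float(np.std(d, ddof=1))
    limit, pct_within = reproducibility_limit(d, k=k)
    if np.std(v1) == 0 or np.std(v2) == 0:
        r = np.nan
    else:
        r = float(stats.pearsonr(v1, v2).statistic)
    return AgreementReport(len(d), mean_diff, sd_diff, limit, pct_within, r, n_disc)


def reproducibility_limit(diffs, k: float = 1.96, center: bool = True) -> tuple[float, float]:
    """Reproducibility limit ``k * SD(diffs)`` and the percentage of points within it.

    With ``center`` (default) the band is placed around the mean difference,
    Bland–Altman style; otherwise around zero.  For Normal differences about
    95% of points fall within the default 1.96-SD band.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[np.isfinite(d)]
    if len(d) < 3:
        raise ValueError("need at least 3 differences")
    sd = float(np.std(d, ddof=1))
    limit = k * sd
    ref = float(np.mean(d)) if center else 0.0
    pct_within = float(100.0 * np.mean(np.abs(d - ref) <= limit))
    return limit, pct_within


def run_correlation(run1, run2, zero_missing: bool = True) -> float:
    """Pearson correlation over proteins observed in both runs."""
    v1, v2, _ = _common(run1, run2, zero_missing)
    if len(v1) < 3:
        raise ValueError("fewer than 3 commonly observed proteins")
    if np.std(v1) == 0 or np.std(v2) == 0:
        raise ValueError("zero variance in a run; correlation undefined")
    return float(stats.pearsonr(v1, v2).statistic)


def abundance_classes(
    counts: SpectralCountTable, threshold: int = 5, rule: str = "max"
) -> pd.Series:
    """Per-protein abundance class: 'high' iff the per-run aggregate count
    (max by default, mean optional) reaches ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if rule not in ("max", "mean"):
        raise ValueError("rule must be 'max' or 'mean'")
    agg = counts.counts.max(axis=1) if rule == "max" else counts.counts.mean(axis=1)
    labels = np.where(agg >= threshold, "high", "low")
    return pd.Series(labels, index=counts.protein_ids, name="abundance_class")


def overlap_table(set_a, set_b) -> np.ndarray:
    """2x2 overlap counts ``[[unique_a, shared], [unique_b, shared]]``."""
    sa, sb = set(set_a), set(set_b)
    if not sa or not sb:
        raise ValueError("both sets must be non-empty")
    shared = len(sa & sb)
    return np.array([[len(sa) - shared, shared], [len(sb) - shared, shared]], dtype=np.int64)


def set_enrichment(query, annotation, background) -> tuple[float, float]:
    """Hypergeometric over-representation of an annotation set in a query set.

    Returns ``(fold, p)`` with fold = observed/expected overlap and p the
    one-sided upper-tail probability of at least the observed overlap when
    drawing ``|query|`` proteins from the background.
    """
    bg = set(background)
    if not bg:
        raise ValueError("background must be non-empty")
    q, ann = set(query), set(annotation)
    if not q <= bg or not ann <= bg:
        raise ValueError("query and annotation must be subsets of the background")
    n_bg, n_q, n_ann = len(bg), len(q), len(ann)
    k = len(q & ann)
    expected = n_q * n_ann / n_bg
    fold = k / expected if expected > 0 else np.nan
    p = float(stats.hypergeom.sf(k - 1, n_bg, n_ann, n_q))
    return fold, min(1.0, p)


def bland_altman_table(run1, run2, k: float = 1.96, zero_missing: bool = True) -> pd.DataFrame:
    """Per-protein mean/difference table with 2-SD and 3-SD band flags,
    suitable for plotting a difference-vs-mean QC figure."""
    s1 = pd.Series(run1).astype(float)
    s2 = pd.Series(run2).astype(float)
    s1, s2 = s1.align(s2, join="outer")
    if zero_missing:
        s1 = s1.replace(0.0, np.nan)
        s2 = s2.replace(0.0, np.nan)
    both = s1.notna() & s2.notna()
    v1, v2 = s1[both], s2[both]
    d = v1 - v2
    mean_diff, sd = float(d.mean()), float(d.std(ddof=1))
    return pd.DataFrame(
        {
            "protein_id": v1.index,
            "mean": (v1 + v2) / 2.0,
            "difference": d,
            "within_2sd": (d - mean_diff).abs() <= 2 * sd,
            "within_3sd": (d - mean_diff).abs() <= 3 * sd,
        }
    ).reset_index(drop=True)
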