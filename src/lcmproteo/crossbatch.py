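"""Cross-batch validation of enriched-protein abundances.

Per-batch mean abundances of a protein set are compared between two
independent batches: Pearson correlation, an ordinary least-squares fit of
batch 2 on batch 1, and pointwise 95% prediction intervals for the mean
abundance of each protein in a future batch,

    fitted +/- t_{n-2, 1-alpha/2} * s * sqrt(1 + 1/n + (x - xbar)^2 / Sxx),

with s the residual SD.  An empirical coverage check against a held-out
batch validates the interval construction on simulated data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import IntensityMatrix, SampleMetadata

__all__ = ["BatchAgreement", "batch_means", "batch_agreement", "coverage_check"]


def batch_means(
    matrix: IntensityMatrix,
    metadata: SampleMetadata,
    protein_ids,
    compartment: str,
) -> pd.DataFrame:
    """Per-protein mean log2 intensity of a compartment within each batch.

    Means are over observed samples only; a protein unobserved in a batch
    gets NaN there (dropped pairwise downstream).  Every batch must have at
    least one sample of the compartment.
    """
    protein_ids = list(protein_ids)
    if not protein_ids:
        raise ValueError("protein set is empty")
    metadata.require_samples(matrix)
    frame = matrix.to_frame().loc[protein_ids]
    out = {}
    for b in metadata.batches:
        ids = [s for s in metadata.samples_for(compartment=compartment, batch=b)
               if s in matrix.sample_ids]
        if not ids:
            raise ValueError(f"batch {b!r} has no {compartment} samples")
        out[b] = frame[ids].mean(axis=1, skipna=True)
    res = pd.DataFrame(out)
    res.index.name = "protein_id"
    return res


@dataclass
class BatchAgreement:
    pearson_r: float
    slope: float
    intercept: float
    resid_sd: float
    n: int
    x_mean: float
    sxx: float
    table: pd.DataFrame = field(repr=False)  # per-protein BatchComparison rows


def batch_agreement(means1, means2, alpha: float = 0.05, min_proteins: int = 10) -> BatchAgreement:
    """Correlation, regression and prediction intervals between two batches.

    ``means1``/``means2`` are per-protein series; proteins missing either
    mean are dropped pairwise.  The regression direction is fixed (batch 2 on
    batch 1); Pearson r is symmetric.
    """
    s1 = pd.Series(means1).astype(float)
    s2 = pd.Series(means2).astype(float)
    s1, s2 = s1.align(s2, join="inner")
    both = s1.notna() & s2.notna()
    x, y = s1[both].to_numpy(), s2[both].to_numpy()
    n = len(x)
    if n < min_proteins:
        raise ValueError(f"need at least {min_proteins} proteins with both means, got {n}")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValueError("zero variance in batch-1 means")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    fitted = intercept + slope * x
    resid = y - fitted
    s = float(np.sqrt(np.sum(resid**2) / (n - 2))) if n > 2 else 0.0
    r = float(stats.pearsonr(x, y).statistic) if np.std(y) > 0 else np.nan
    tcrit = float(stats.t.ppf(1 - alpha / 2, n - 2))
    half = tcrit * s * np.sqrt(1.0 + 1.0 / n + (x - x.mean()) ** 2 / sxx)
    table = pd.DataFrame(
        {
            "protein_id": s1[both].index,
            "mean_batch1": x,
            "mean_batch2": y,
            "fitted": fitted,
            "pi_low": fitted - half,
            "pi_high": fitted + half,
        }
    ).reset_index(drop=True)
    return BatchAgreement(r, slope, intercept, s, n, float(x.mean()), sxx, table)


def coverage_check(agreement: BatchAgreement, holdout_means) -> float:
    """Fraction of held-out batch means inside the prediction intervals.

    The holdout batch plays the role of the 'future repeat experiment': for a
    correctly specified model the expected coverage is ~0.95 at alpha 0.05.
    """
    hold = pd.Series(holdout_means).astype(float)
    tab = agreement.table.set_index("protein_id")
    common = tab.index.intersection(hold.dropna().index)
    if len(common) == 0:
        raise ValueError("no proteins shared with the holdout batch")
    h = hold.loc[common]
    inside = (h >= tab.loc[common, "pi_low"]) & (h <= tab.loc[common, "pi_high"])
    return float(inside.mean())
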