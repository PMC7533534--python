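"""Paired Glom-vs-PT differential abundance, unique-protein calling, and
bulk-tissue comparison.

Samples from the same kidney (within a batch) are paired; per protein, only
complete pairs — both compartments detected — enter the paired t-test
(complete-case analysis, no imputation).  P-values are Benjamini–Hochberg
adjusted across all tested proteins of the comparison, and a protein is
called enriched when it clears both the FDR gate (q <= 0.1 by default) and a
strict >2-fold change.  Proteins detected in every sample of one compartment
and in none of the other are called unique to it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import IntensityMatrix, SampleMetadata

__all__ = [
    "PairedSamples",
    "TTestResult",
    "pair_samples",
    "paired_t_test",
    "bh_adjust",
    "analyze_enrichment",
    "call_enrichment",
    "call_unique",
    "summarize_table1",
    "compare_to_bulk",
]


@dataclass
class PairedSamples:
    """Aligned per-kidney compartment values: rows proteins, columns pairs."""

    first: np.ndarray   # values in the first compartment (NaN = missing)
    second: np.ndarray  # values in the second compartment
    pair_labels: list[tuple[str, str]]  # (kidney_id, batch)
    protein_ids: list[str]

    @property
    def n_pairs(self) -> int:
        return self.first.shape[1]

    def complete(self) -> np.ndarray:
        """Boolean grid: pair has both compartments observed for the protein."""
        return np.isfinite(self.first) & np.isfinite(self.second)


def pair_samples(
    matrix: IntensityMatrix,
    metadata: SampleMetadata,
    compartments: tuple[str, str] = ("Glom", "PT"),
) -> PairedSamples:
    """Pair compartment samples within kidney (and batch).

    A kidney/batch contributes a pair only when it has both compartment
    samples in the matrix; metadata validation already guarantees at most one
    sample per kidney x compartment x batch.
    """
    metadata.require_samples(matrix)
    df = metadata.table.set_index("sample_id")
    col_of = {s: j for j, s in enumerate(matrix.sample_ids)}
    keys: dict[tuple[str, str], dict[str, int]] = {}
    for s in matrix.sample_ids:
        row = df.loc[s]
        if row["compartment"] in compartments:
            keys.setdefault((row["kidney_id"], row["batch"]), {})[row["compartment"]] = col_of[s]
    pairs = sorted(k for k, v in keys.items() if len(v) == 2)
    if not pairs:
        return PairedSamples(
            np.empty((matrix.n_proteins, 0)),
            np.empty((matrix.n_proteins, 0)),
            [],
            list(matrix.protein_ids),
        )
    idx1 = [keys[k][compartments[0]] for k in pairs]
    idx2 = [keys[k][compartments[1]] for k in pairs]
    return PairedSamples(
        matrix.values[:, idx1], matrix.values[:, idx2], pairs, list(matrix.protein_ids)
    )


class TTestResult(NamedTuple):
    t_stat: float
    p_value: float
    df: int
    degenerate: bool


def paired_t_test(diffs, min_pairs: int = 3) -> TTestResult:
    """One-sample t-test of the paired differences against zero.

    ``t = mean(d) / (sd(d)/sqrt(n))`` with n-1 df, two-sided p.  A zero
    spread is degenerate: p = 0 when the common difference is nonzero
    (infinitely strong evidence under the model), p = 1 when it is zero.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[np.isfinite(d)]
    n = len(d)
    if n < min_pairs:
        raise ValueError(f"need at least {min_pairs} complete pairs, got {n}")
    sd = np.std(d, ddof=1)
    if sd == 0.0:
        m = float(np.mean(d))
        if m == 0.0:
            return TTestResult(0.0, 1.0, n - 1, True)
        return TTestResult(np.inf if m > 0 else -np.inf, 0.0, n - 1, True)
    res = stats.ttest_1samp(d, 0.0)
    return TTestResult(float(res.statistic), float(res.pvalue), n - 1, False)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-preserving, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def analyze_enrichment(
    matrix: IntensityMatrix,
    metadata: SampleMetadata,
    compartments: tuple[str, str] = ("Glom", "PT"),
    min_pairs: int = 3,
    fdr_threshold: float = 0.1,
    fold_threshold: float = 2.0,
    min_detect: float = 1.0,
) -> pd.DataFrame:
    """Full per-protein enrichment table with calls.

    Columns: protein_id, mean/sd per compartment (over complete pairs),
    log2_fc (first minus second compartment), t_stat, p_value, q_value,
    n_pairs, degenerate, call.
    """
    paired = pair_samples(matrix, metadata, compartments)
    comp = paired.complete()
    # complete-case arrays: NaN outside complete pairs
    v1 = np.where(comp, paired.first, np.nan)
    v2 = np.where(comp, paired.second, np.nan)
    n_pairs = comp.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean1 = np.where(n_pairs > 0, np.nansum(v1, axis=1) / n_pairs, np.nan)
        mean2 = np.where(n_pairs > 0, np.nansum(v2, axis=1) / n_pairs, np.nan)
        sd1 = _nanstd1(v1, n_pairs)
        sd2 = _nanstd1(v2, n_pairs)
        mean_d = mean1 - mean2
        sd_d = _nanstd1(v1 - v2, n_pairs)
    tested = n_pairs >= min_pairs
    degenerate = tested & (sd_d == 0)
    t_stat = np.full(len(n_pairs), np.nan)
    p_value = np.full(len(n_pairs), np.nan)
    ok = tested & (sd_d > 0)
    t_stat[ok] = mean_d[ok] / (sd_d[ok] / np.sqrt(n_pairs[ok]))
    p_value[ok] = 2.0 * stats.t.sf(np.abs(t_stat[ok]), n_pairs[ok] - 1)
    # zero-spread convention: p = 0 for a nonzero common difference, else 1
    t_stat[degenerate] = np.where(
        mean_d[degenerate] == 0, 0.0, np.copysign(np.inf, mean_d[degenerate])
    )
    p_value[degenerate] = np.where(mean_d[degenerate] == 0, 1.0, 0.0)
    table = pd.DataFrame(
        dict(
            protein_id=paired.protein_ids,
            mean_glom=mean1, sd_glom=sd1, mean_pt=mean2, sd_pt=sd2,
            log2_fc=mean_d, t_stat=t_stat, p_value=p_value,
            q_value=np.nan, n_pairs=n_pairs, degenerate=degenerate,
        )
    )

    tested = table["p_value"].notna()
    q = np.full(len(table), np.nan)
    if tested.any():
        q[tested.to_numpy()] = bh_adjust(table.loc[tested, "p_value"].to_numpy())
    table["q_value"] = q

    unique_first, unique_second = call_unique(
        matrix, metadata, compartments=compartments, min_detect=min_detect
    )
    return call_enrichment(
        table,
        fdr_threshold=fdr_threshold,
        fold_threshold=fold_threshold,
        unique_glom=unique_first,
        unique_pt=unique_second,
    )


def _nanstd1(v: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Row-wise sample SD (ddof=1) ignoring NaN; NaN where n < 2."""
    out = np.full(v.shape[0], np.nan)
    ok = n > 1
    if ok.any():
        with np.errstate(invalid="ignore"):
            m = np.nanmean(v[ok], axis=1)
            ss = np.nansum((v[ok] - m[:, None]) ** 2, axis=1)
        out[ok] = np.sqrt(ss / (n[ok] - 1))
    return out


def call_enrichment(
    records: pd.DataFrame,
    fdr_threshold: float = 0.1,
    fold_threshold: float = 2.0,
    unique_glom: set[str] | None = None,
    unique_pt: set[str] | None = None,
) -> pd.DataFrame:
    """Assign per-protein calls from q-values, fold changes and unique sets.

    enriched_glom requires q <= fdr_threshold AND a strictly >fold_threshold
    linear fold change toward Glom (symmetric for PT); unique calls take
    precedence; proteins without a q-value (too few complete pairs) that are
    not unique are 'untested'.
    """
    out = records.copy()
    unique_glom = unique_glom or set()
    unique_pt = unique_pt or set()
    lfc = out["log2_fc"].to_numpy(dtype=float)
    qv = out["q_value"].to_numpy(dtype=float)
    log2_thr = np.log2(fold_threshold)
    with np.errstate(invalid="ignore"):
        enr_g = (qv <= fdr_threshold) & (lfc > log2_thr)
        enr_p = (qv <= fdr_threshold) & (-lfc > log2_thr)
    calls = np.where(np.isnan(qv), "untested", "ns")
    calls = np.where(enr_g, "enriched_glom", calls)
    calls = np.where(enr_p, "enriched_pt", calls)
    pid = out["protein_id"]
    calls = np.where(pid.isin(sorted(unique_glom)), "unique_glom", calls)
    calls = np.where(pid.isin(sorted(unique_pt)), "unique_pt", calls)
    out["call"] = calls
    return out


def call_unique(
    matrix: IntensityMatrix,
    metadata: SampleMetadata,
    compartments: tuple[str, str] = ("Glom", "PT"),
    min_detect: float = 1.0,
) -> tuple[set[str], set[str]]:
    """Proteins detected in >= ``min_detect`` fraction of one compartment's
    samples and in none of the other's.

    The default ``min_detect = 1.0`` requires complete detection on the
    present side (no missing values in the group).
    """
    metadata.require_samples(matrix)
    obs = matrix.observed()
    cols = {}
    for c in compartments:
        ids = [s for s in metadata.samples_for(compartment=c) if s in matrix.sample_ids]
        cols[c] = [matrix.sample_ids.index(s) for s in ids]
    if not cols[compartments[0]] or not cols[compartments[1]]:
        raise ValueError("both compartments need samples to call unique proteins")
    f1 = obs[:, cols[compartments[0]]].mean(axis=1)
    f2 = obs[:, cols[compartments[1]]].mean(axis=1)
    ids = np.asarray(matrix.protein_ids)
    unique_first = set(ids[(f1 >= min_detect) & (f2 == 0)])
    unique_second = set(ids[(f2 >= min_detect) & (f1 == 0)])
    return unique_first, unique_second


def summarize_table1(
    matrix: IntensityMatrix,
    metadata: SampleMetadata,
    unique_glom: set[str],
    unique_pt: set[str],
) -> pd.DataFrame:
    """Mean ± SD log2 relative intensity of each unique protein in its
    detected compartment, reported to 2 decimals (SD is NA for n = 1)."""
    metadata.require_samples(matrix)
    frame = matrix.to_frame()
    gene_of = (
        dict(zip(matrix.protein_ids, matrix.gene_symbols)) if matrix.gene_symbols else {}
    )
    rows = []
    for compartment, ids in (("Glom", sorted(unique_glom)), ("PT", sorted(unique_pt))):
        samples = [s for s in metadata.samples_for(compartment=compartment)
                   if s in matrix.sample_ids]
        for pid in ids:
            v = frame.loc[pid, samples].dropna().to_numpy(dtype=float)
            mean = float(np.mean(v)) if len(v) else np.nan
            sd = float(np.std(v, ddof=1)) if len(v) > 1 else np.nan
            rows.append(
                dict(
                    protein_id=pid,
                    gene_symbol=gene_of.get(pid, ""),
                    compartment=compartment,
                    n_observed=len(v),
                    mean=round(mean, 2) if np.isfinite(mean) else np.nan,
                    sd=round(sd, 2) if np.isfinite(sd) else np.nan,
                    summary=(
                        f"{mean:.2f} ± {sd:.2f}" if np.isfinite(sd)
                        else (f"{mean:.2f} ± NA" if np.isfinite(mean) else "NA")
                    ),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id", "gene_symbol", "compartment", "n_observed", "mean", "sd", "summary",
        ],
    )


def compare_to_bulk(matrix: IntensityMatrix, metadata: SampleMetadata) -> pd.DataFrame:
    """Flag sub-compartment proteins by bulk detectability.

    For every protein observed in at least one Glom or PT sample:
    'sub_compartment_only' when it is observed in zero Bulk samples,
    'detected_in_bulk' otherwise.
    """
    metadata.require_samples(matrix)
    bulk = [s for s in metadata.samples_for(compartment="Bulk") if s in matrix.sample_ids]
    if not bulk:
        raise ValueError("no Bulk samples in metadata/matrix")
    sub = [
        s
        for c in ("Glom", "PT")
        for s in metadata.samples_for(compartment=c)
        if s in matrix.sample_ids
    ]
    obs = matrix.observed()
    cols = {s: j for j, s in enumerate(matrix.sample_ids)}
    in_sub = obs[:, [cols[s] for s in sub]].any(axis=1)
    in_bulk = obs[:, [cols[s] for s in bulk]].any(axis=1)
    ids = np.asarray(matrix.protein_ids)
    flags = np.where(in_bulk, "detected_in_bulk", "sub_compartment_only")
    return pd.DataFrame({"protein_id": ids[in_sub], "bulk_flag": flags[in_sub]}).reset_index(
        drop=True
    )
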