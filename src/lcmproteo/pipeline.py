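"""One-shot pipeline tying the stages together.

Stage order mirrors the analysis workflow: (optionally) simulate ->
spectral-count QC -> missingness filter -> paired enrichment -> cross-batch
validation.  Every stage logs its parameters and row counts, writes TSV
artifacts, and the run ends with a JSON manifest listing each artifact with
a sha256 checksum, so a rerun with the same configuration can be verified
byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agreement, crossbatch, enrichment, io, missingness
from .simulate import SimConfig, generate_dataset, generate_spectral_counts

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("lcmproteo")


@dataclass
class PipelineConfig:
    """Everything needed to rerun an analysis end to end."""

    outdir: str = "lcmproteo_out"
    simulate: bool = True
    intensity_path: str | None = None
    metadata_path: str | None = None
    counts_path: str | None = None
    # stage parameters (defaults follow the published analysis)
    min_frac: float = 0.5          # observation-rate filter
    alpha: float = 0.05            # G-test significance
    williams: bool = True          # small-sample G correction
    fdr_threshold: float = 0.1     # BH gate
    fold_threshold: float = 2.0    # strict fold gate
    min_pairs: int = 3
    min_detect: float = 1.0        # unique-protein detection fraction
    repro_k: float = 1.96          # reproducibility-limit multiplier
    spectral_threshold: int = 5    # high/low abundance class cut
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        if not 0 < self.min_frac <= 1:
            raise ValueError("min_frac must lie in (0, 1]")
        if not 0 < self.alpha < 1 or not 0 < self.fdr_threshold < 1:
            raise ValueError("alpha and fdr_threshold must lie in (0, 1)")
        if self.fold_threshold < 1 or self.min_pairs < 2 or self.repro_k <= 0:
            raise ValueError("threshold outside its documented range")
        if not self.simulate:
            for name in ("intensity_path", "metadata_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"{name} required when simulate is false")

    # -- config file round-trip -------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow; return the artifact manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str) -> Path:
        path = out / name
        io.write_results(df, path)
        written.append(path)
        return path

    try:
        # ------------------------------------------------ inputs
        if config.simulate:
            log.info("stage=simulate params=%s", config.sim.to_dict())
            matrix, metadata, truth = generate_dataset(config.sim)
            counts = generate_spectral_counts(config.sim, n_runs=2)
            p = out / "intensity.tsv"
            io.write_intensity_table(matrix, p)
            written.append(p)
            p = out / "metadata.tsv"
            io.write_metadata(metadata, p)
            written.append(p)
            emit(truth, "truth.tsv")
            emit(counts.to_frame().reset_index(names="protein_id"), "spectral_counts.tsv")
        else:
            for name in ("intensity_path", "metadata_path"):
                p = getattr(config, name)
                if not Path(p).exists():
                    raise FileNotFoundError(f"input not found: {p}")
            matrix = io.read_intensity_table(config.intensity_path)
            metadata = io.read_metadata(config.metadata_path)
            counts = None
            if config.counts_path:
                cf = pd.read_csv(config.counts_path, sep="\t", index_col=0)
                counts = io.SpectralCountTable(
                    cf.to_numpy(), cf.index.tolist(), cf.columns.tolist()
                )
        log.info(
            "stage=input n_proteins=%d n_samples=%d", matrix.n_proteins, matrix.n_samples
        )

        # ------------------------------------------------ qc
        if counts is not None:
            run1, run2 = counts.run(counts.run_ids[0]), counts.run(counts.run_ids[1])
            rep = agreement.paired_difference_stats(run1, run2, k=config.repro_k)
            log.info(
                "stage=qc n_common=%d limit=%.4g pct_within=%.2f r=%.4f",
                rep.n_common, rep.limit, rep.pct_within, rep.pearson_r,
            )
            emit(pd.DataFrame([rep.__dict__]), "qc_agreement.tsv")
            emit(agreement.bland_altman_table(run1, run2, k=config.repro_k),
                 "qc_bland_altman.tsv")
            set1 = set(np.asarray(counts.protein_ids)[counts.counts[:, 0] > 0])
            set2 = set(np.asarray(counts.protein_ids)[counts.counts[:, 1] > 0])
            classes = agreement.abundance_classes(counts, threshold=config.spectral_threshold)
            tab = agreement.overlap_table(set1, set2)
            fisher = agreement.fisher_exact(tab)
            emit(
                pd.DataFrame(
                    [dict(
                        unique_run1=tab[0, 0], shared=tab[0, 1], unique_run2=tab[1, 0],
                        odds_ratio=fisher.odds_ratio, ci_low=fisher.ci_low,
                        ci_high=fisher.ci_high, p=fisher.p_two_sided,
                        n_high_abundance=int((classes == "high").sum()),
                    )]
                ),
                "qc_overlap.tsv",
            )

        # ------------------------------------------------ filter
        filtered, report = missingness.two_step_filter(
            matrix, metadata,
            min_frac=config.min_frac, alpha=config.alpha, williams=config.williams,
        )
        log.info(
            "stage=filter min_frac=%s alpha=%s removed=%d flagged_mnar=%d kept=%d",
            config.min_frac, config.alpha,
            report.n_removed_low_observation, report.n_flagged_mnar, filtered.n_proteins,
        )
        p = out / "filtered_intensity.tsv"
        io.write_intensity_table(filtered, p)
        written.append(p)
        emit(report.to_frame(), "filter_report.tsv")
        emit(report.per_protein, "missingness.tsv")

        # ------------------------------------------------ enrich
        records = enrichment.analyze_enrichment(
            filtered, metadata,
            min_pairs=config.min_pairs, fdr_threshold=config.fdr_threshold,
            fold_threshold=config.fold_threshold, min_detect=config.min_detect,
        )
        call_counts = records["call"].value_counts().to_dict()
        log.info("stage=enrich fdr=%s fold=%s calls=%s",
                 config.fdr_threshold, config.fold_threshold, call_counts)
        emit(records, "enrichment.tsv")
        uniq_g = set(records.loc[records["call"] == "unique_glom", "protein_id"])
        uniq_p = set(records.loc[records["call"] == "unique_pt", "protein_id"])
        emit(enrichment.summarize_table1(filtered, metadata, uniq_g, uniq_p),
             "unique_proteins.tsv")
        emit(enrichment.compare_to_bulk(filtered, metadata), "bulk_comparison.tsv")

        # ------------------------------------------------ validate
        batches = metadata.batches
        summary_rows = []
        for comp, call in (("Glom", "enriched_glom"), ("PT", "enriched_pt")):
            ids = records.loc[records["call"] == call, "protein_id"].tolist()
            if len(batches) < 2 or len(ids) < 10:
                log.info("stage=validate compartment=%s skipped (batches=%d, proteins=%d)",
                         comp, len(batches), len(ids))
                continue
            means = crossbatch.batch_means(filtered, metadata, ids, comp)
            agr = crossbatch.batch_agreement(means[batches[0]], means[batches[1]])
            log.info("stage=validate compartment=%s n=%d r=%.4f slope=%.4f",
                     comp, agr.n, agr.pearson_r, agr.slope)
            emit(agr.table, f"crossbatch_{comp.lower()}.tsv")
            summary_rows.append(
                dict(compartment=comp, n=agr.n, pearson_r=agr.pearson_r,
                     slope=agr.slope, intercept=agr.intercept, resid_sd=agr.resid_sd)
            )
        if summary_rows:
            emit(pd.DataFrame(summary_rows), "crossbatch_summary.tsv")

        # ------------------------------------------------ manifest
        manifest = {
            "config": config.to_dict(),
            "artifacts": {p.name: _sha256(p) for p in written},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        log.info("stage=done artifacts=%d", len(written))
        return manifest
    finally:
        log.removeHandler(handler)
        handler.close()
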