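"""End-to-end pipeline: flatten -> count -> estimate -> test -> attribute.

The pipeline ties the stages together with a YAML config, stage-level
logging of how many units were filtered, and provenance headers (package
version, config hash, seed) on every output TSV.  Reruns with identical
inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._io import read_tsv, write_tsv
from .annotation import flatten_gene_models, read_flattened_gff, read_gtf_exons, write_flattened_gff
from .counting import count_fragments, read_fragments_sam, read_fragments_tsv
from .enrichment import category_enrichment, matched_background
from .glm import DesignTable
from .model import ExonUsageModel

log = logging.getLogger("tdexon")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths and thresholds of a pipeline run.

    Exactly one count source must be given: ``annotation`` +
    ``alignments`` (SAM or fragment TSV per sample), or precomputed
    ``counts_prefix`` TSVs (inclusion/skipping/gene_totals written by a
    previous `count` stage or by the simulator).
    """

    out_dir: str
    design: str
    annotation: str | None = None
    gene_model: str | None = None  # pre-flattened GFF, alternative to annotation
    alignments: dict[str, str] = field(default_factory=dict)  # sample -> path
    counts_prefix: str | None = None
    labels: str | None = None  # unit_id -> category TSV for enrichment
    unit_type: str = "exonic_region"  # or "tss_cluster"
    fdr: float = 0.1
    score_min: float = 1.0
    skip_strong: float = 10.0
    high_expr: float = 100.0
    min_total: int = 10
    skip_floor: float = 1.0
    seed: int = 0
    aggregate_genes: bool = True

    def __post_init__(self) -> None:
        for name in ("fdr", "score_min", "skip_strong", "high_expr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        if self.unit_type not in ("exonic_region", "tss_cluster"):
            raise ValueError(f"unknown unit type {self.unit_type!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def hash(self) -> str:
        """Hash of the analysis inputs (the output location is excluded)."""
        d = asdict(self)
        d.pop("out_dir")
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _load_counts(cfg: PipelineConfig, out: Path):
    """Produce count tables + gene model via whichever entry point is set."""
    if cfg.counts_prefix:
        prefix = cfg.counts_prefix
        gff = Path(f"{prefix}.model.gff")
        model = read_flattened_gff(gff) if gff.exists() else None
        m = ExonUsageModel.from_tsv(
            f"{prefix}.inclusion.tsv",
            cfg.design,
            skipping_path=_opt(f"{prefix}.skipping.tsv"),
            gene_totals_path=_opt(f"{prefix}.gene_totals.tsv"),
            gff_path=str(gff) if gff.exists() else None,
            fdr=cfg.fdr,
            score_min=cfg.score_min,
            min_total=cfg.min_total,
            skip_floor=cfg.skip_floor,
        )
        return m
    if not ((cfg.annotation or cfg.gene_model) and cfg.alignments):
        raise ValueError("need counts_prefix, or annotation/gene_model + alignments")
    if cfg.gene_model:
        model = read_flattened_gff(cfg.gene_model)
    else:
        model = flatten_gene_models(
            read_gtf_exons(cfg.annotation), aggregate=cfg.aggregate_genes
        )
    write_flattened_gff(model, out / "model.gff")
    log.info("flatten: %d regions in %d gene groups", len(model), len(model.gene_ids))
    design = DesignTable.from_tsv(cfg.design)

    def frags():
        for sample, path in cfg.alignments.items():
            reader = (
                read_fragments_sam(path, sample)
                if str(path).endswith((".sam", ".bam"))
                else read_fragments_tsv(path)
            )
            yield from reader

    tables = count_fragments(frags(), model, samples=design.samples)
    st = tables.stats
    log.info(
        "count: %d fragments, %d counted, %d non-unique, %d ambiguous, "
        "%d outside regions, %d on unknown chromosomes",
        st.n_fragments, st.n_counted, st.n_nonunique, st.n_ambiguous,
        st.n_no_region, st.n_unknown_chrom,
    )
    return ExonUsageModel(
        tables, design, model,
        fdr=cfg.fdr, score_min=cfg.score_min,
        min_total=cfg.min_total, skip_floor=cfg.skip_floor,
    )


def _opt(path: str) -> str | None:
    return path if Path(path).exists() else None


def run_pipeline(cfg: PipelineConfig) -> "ExonUsageResults":
    """Run all stages and write the result bundle under ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": cfg.hash(), "seed": cfg.seed}

    model = _load_counts(cfg, out)
    schemes = ("reuc", "rsic") if cfg.unit_type == "exonic_region" else ("reuc",)
    results = model.fit(schemes=schemes)
    log.info(
        "estimate+test: %d regions, %d tested, %d TDU",
        len(results.tdu), results.n_tested, results.n_tdu,
    )

    results.reuc.to_tsv(out / "reuc.tsv", meta)
    if results.rsic is not None:
        results.rsic.to_tsv(out / "rsic.tsv", meta)
    write_tsv(results.tdu.reset_index(), out / "tdu.tsv", meta)

    if cfg.unit_type == "tss_cluster":
        calls = results.per_group_calls()
        write_tsv(calls.reset_index(), out / "group_tdu.tsv", meta)
        return results

    mech = results.attribute_mechanisms()
    write_tsv(mech.reset_index(), out / "mechanism.tsv", meta)
    log.info(
        "attribute: %s",
        dict(mech.loc[mech["label"] != "", "label"].value_counts()),
    )

    if model.gene_model is not None:
        genes = results.summarize_genes(high_expression_mean=cfg.high_expr)
        write_tsv(genes.reset_index(), out / "gene_summary.tsv", meta)
        if cfg.labels:
            labels = read_tsv(cfg.labels).set_index("unit_id")["category"]
            targets = [g for g in genes.index[genes["n_tdu_regions"] > 0]]
            pool = [g for g in genes.index if g in labels.index]
            covs = pd.DataFrame(
                {
                    "log_mean_count": np.log1p(genes["mean_fragments"]),
                    "n_regions": genes["n_regions"].astype(float),
                }
            )
            try:
                background = matched_background(targets, pool, covs)
                enr = category_enrichment(targets, background, labels)
                emeta = dict(meta, chi2=enr.attrs["chi2"], pvalue=enr.attrs["pvalue"])
                write_tsv(enr.reset_index(), out / "enrichment.tsv", emeta)
            except ValueError as e:
                log.warning("enrichment skipped: %s", e)
    return results
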