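"""Model/results interface for tissue-dependent exon usage analysis.

:class:`ExonUsageModel` holds the data (count tables + design + optional
gene model) and the analysis settings; :meth:`ExonUsageModel.fit` runs the
coefficient estimation and tissue-dependence testing and returns an
:class:`ExonUsageResults` carrying the REUC/RSIC matrices, per-region
test table and downstream summaries.

    >>> study = simulate_study(SimulationConfig(seed=1))
    >>> model = ExonUsageModel(study.tables, study.design, study.model)
    >>> res = model.fit()
    >>> print(res.summary())

The machinery is unit-agnostic: :meth:`ExonUsageModel.from_unit_counts`
accepts any units x samples count table with a unit -> group mapping
(e.g. CAGE transcription-start-site clusters within genes) and tests
differential usage of the units within their groups the same way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import FlattenedGeneModel
from .counting import CountTables, build_reuc_pairs
from .enrichment import summarize_gene_tdu
from .glm import DesignTable, SizeFactors, estimate_size_factors
from .inference import run_tdu_test
from .mechanism import attribute_mechanism
from .usage import UsageCoefficientMatrix, estimate_usage

__all__ = ["ExonUsageModel", "ExonUsageResults"]


class ExonUsageModel:
    """Tissue-dependent usage model for a fully crossed study.

    Parameters
    ----------
    tables
        Count tables (inclusion, rest-of-gene, skipping) per region x sample.
    design
        Sample layout (individual, tissue, sex), or a DataFrame thereof.
    gene_model
        Optional flattened gene model (needed for gene-level summaries).
    min_total, skip_floor
        Expression filters: minimum total count per region, minimum mean
        skipping count for the spliced-in fit.
    fdr, score_min
        TDU call thresholds: BH-adjusted p <= fdr and tissue score > score_min.
    alpha, prior_variance
        Optional overrides for the dispersion and the shrinkage prior
        (both estimated from the data by default).
    """

    def __init__(
        self,
        tables: CountTables,
        design: DesignTable | pd.DataFrame,
        gene_model: FlattenedGeneModel | None = None,
        *,
        min_total: int = 10,
        skip_floor: float = 1.0,
        fdr: float = 0.1,
        score_min: float = 1.0,
        alpha=None,
        prior_variance: float | None = None,
        prior_variance_sex: float | None = None,
    ) -> None:
        if isinstance(design, pd.DataFrame):
            design = DesignTable(design)
        self.tables = tables
        self.design = design
        self.gene_model = gene_model
        self.min_total = min_total
        self.skip_floor = skip_floor
        self.fdr = fdr
        self.score_min = score_min
        self.alpha = alpha
        self.prior_variance = prior_variance
        self.prior_variance_sex = prior_variance_sex
        if tables.rest is None and gene_model is not None:
            tables.rest = build_reuc_pairs(tables, gene_model)

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_tsv(
        cls,
        inclusion_path,
        design_path,
        *,
        skipping_path=None,
        gene_totals_path=None,
        gff_path=None,
        **kw,
    ) -> "ExonUsageModel":
        """Build from count TSVs (region rows x sample columns)."""
        from ._io import read_tsv
        from .annotation import read_flattened_gff

        def load(p):
            df = read_tsv(p)
            return df.set_index(df.columns[0]).astype(np.int64)

        inclusion = load(inclusion_path)
        skipping = (
            load(skipping_path)
            if skipping_path
            else pd.DataFrame(0, index=inclusion.index, columns=inclusion.columns)
        )
        model = read_flattened_gff(gff_path) if gff_path else None
        # region keys are "gene_id:region_id"; the prefix maps regions to genes
        gene_of = pd.Series(
            [str(k).rsplit(":", 1)[0] for k in inclusion.index], index=inclusion.index
        )
        if gene_totals_path:
            gene_totals = load(gene_totals_path)
        else:
            # column-sum accounting: once-per-fragment-per-gene approximation
            gene_totals = inclusion.groupby(gene_of).sum()
        tables = CountTables(
            inclusion=inclusion, skipping=skipping, gene_totals=gene_totals
        )
        totals = gene_totals.loc[gene_of].to_numpy()
        rest = totals - inclusion.to_numpy()
        if (rest < 0).any():
            raise ValueError("inclusion counts exceed gene totals")
        tables.rest = pd.DataFrame(rest, index=inclusion.index, columns=inclusion.columns)
        return cls(tables, DesignTable.from_tsv(design_path), model, **kw)

    @classmethod
    def from_fragments(
        cls, fragments, gene_model: FlattenedGeneModel, design, **kw
    ) -> "ExonUsageModel":
        """Count a fragment stream against a flattened gene model."""
        from .counting import count_fragments

        if isinstance(design, pd.DataFrame):
            design = DesignTable(design)
        tables = count_fragments(fragments, gene_model, samples=design.samples)
        return cls(tables, design, gene_model, **kw)

    @classmethod
    def from_unit_counts(
        cls, counts: pd.DataFrame, groups: pd.Series, design, **kw
    ) -> "ExonUsageModel":
        """Unit-level counts (e.g. TSS clusters) grouped into genes.

        ``counts`` is units x samples, ``groups`` maps unit id -> group id.
        The comparison counts are the other units of the same group
        (column-sum accounting); no skipping scheme is available.
        """
        groups = groups.reindex(counts.index)
        if groups.isna().any():
            raise ValueError("every unit needs a group assignment")
        gene_totals = counts.groupby(groups).sum()
        tables = CountTables(
            inclusion=counts.astype(np.int64),
            skipping=pd.DataFrame(0, index=counts.index, columns=counts.columns),
            gene_totals=gene_totals.astype(np.int64),
        )
        totals = gene_totals.loc[groups].to_numpy()
        tables.rest = pd.DataFrame(
            totals - counts.to_numpy(), index=counts.index, columns=counts.columns
        )
        m = cls(tables, design, None, **kw)
        m._unit_groups = groups
        return m

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        schemes: tuple[str, ...] = ("reuc", "rsic"),
        *,
        with_individual: bool = False,
        dispersion_trend: bool = True,
    ) -> "ExonUsageResults":
        """Estimate usage coefficients and test tissue dependence.

        Runs, per scheme: size factors (median-of-ratios on the inclusion
        matrix), per-region dispersions, empirical-Bayes shrinkage prior,
        penalized GLM fits; then the likelihood-ratio tissue test, tissue
        scores, BH adjustment and the TDU call on the exon-usage (REUC)
        scheme.
        """
        size_factors = estimate_size_factors(self.tables.inclusion[self.design.samples])
        common = dict(
            size_factors=size_factors,
            min_total=self.min_total,
            skip_floor=self.skip_floor,
            alpha=self.alpha,
            prior_variance=self.prior_variance,
            prior_variance_sex=self.prior_variance_sex,
            dispersion_trend=dispersion_trend,
        )
        reuc = estimate_usage(self.tables, self.design, "reuc", **common)
        rsic = (
            estimate_usage(self.tables, self.design, "rsic", **common)
            if "rsic" in schemes
            else None
        )
        tdu = run_tdu_test(
            self.tables,
            self.design,
            reuc,
            size_factors,
            scheme="reuc",
            fdr=self.fdr,
            score_min=self.score_min,
            with_individual=with_individual,
        )
        return ExonUsageResults(
            model=self,
            size_factors=size_factors,
            reuc=reuc,
            rsic=rsic,
            tdu=tdu,
        )


@dataclass
class ExonUsageResults:
    """Fitted usage coefficients, tests and derived summaries."""

    model: ExonUsageModel
    size_factors: SizeFactors
    reuc: UsageCoefficientMatrix
    rsic: UsageCoefficientMatrix | None
    tdu: pd.DataFrame
    _mechanism: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_tested(self) -> int:
        return int(self.tdu["pvalue"].notna().sum())

    @property
    def n_tdu(self) -> int:
        return int(self.tdu["is_tdu"].sum())

    @property
    def tdu_regions(self) -> list[str]:
        return list(self.tdu.index[self.tdu["is_tdu"]])

    def attribute_mechanisms(self, **kw) -> pd.DataFrame:
        """Splicing vs start/termination attribution of the TDU regions."""
        if self.rsic is None:
            raise ValueError("mechanism attribution needs the RSIC fit")
        if self._mechanism is None or kw:
            self._mechanism = attribute_mechanism(
                self.tdu, self.reuc, self.rsic, self.model.tables,
                self.size_factors, **kw,
            )
        return self._mechanism

    def summarize_genes(self, **kw) -> pd.DataFrame:
        if self.model.gene_model is None:
            raise ValueError("gene-level summaries need a gene model")
        return summarize_gene_tdu(
            self.tdu, self.model.gene_model,
            self.model.tables.inclusion[self.model.design.samples], **kw,
        )

    def per_group_calls(self) -> pd.DataFrame:
        """Group-level differential-usage calls for unit-count models.

        A group (e.g. gene) is called when any of its units (e.g. TSS
        clusters) shows TDU.
        """
        groups = getattr(self.model, "_unit_groups", None)
        if groups is None and self.model.gene_model is not None:
            gm = self.model.gene_model
            groups = pd.Series(
                [r.gene_id for r in gm.regions], index=gm.region_keys()
            )
        if groups is None:
            raise ValueError("no unit -> group mapping available")
        g = self.tdu.join(groups.rename("group"))
        out = g.groupby("group").agg(
            n_units=("is_tdu", "size"),
            n_tdu_units=("is_tdu", "sum"),
            min_padj=("padj", "min"),
        )
        out["is_tdu"] = out["n_tdu_units"] > 0
        return out

    def summary(self) -> str:
        """Human-readable run summary."""
        d = self.model.design
        lines = [
            "Tissue-dependent exon usage",
            "=" * 42,
            f"samples:             {d.n_samples} "
            f"({len(d.individuals)} individuals x {len(d.tissues)} tissues)",
            f"regions:             {len(self.tdu)}",
            f"tested regions:      {self.n_tested}",
            f"TDU regions:         {self.n_tdu} "
            f"(FDR {self.tdu.attrs.get('fdr', self.model.fdr):.0%}, "
            f"score > {self.tdu.attrs.get('score_min', self.model.score_min):g})",
            f"fraction TDU:        "
            f"{self.n_tdu / max(self.n_tested, 1):.3f} of tested",
            f"shrinkage prior var: {self.reuc.prior_variance:.4g}",
        ]
        if self._mechanism is not None:
            counts = self._mechanism.loc[
                self._mechanism["label"] != "", "label"
            ].value_counts()
            lines.append("mechanism labels:    " + ", ".join(
                f"{k}={v}" for k, v in counts.items()
            ))
        return "\n".join(lines)

    def plot_volcano(self, ax=None):
        """Tissue score vs -log10 p per region, with the call thresholds."""
        import matplotlib.pyplot as plt

        if ax is None:
            _fig, ax = plt.subplots()
        t = self.tdu.dropna(subset=["pvalue"])
        ax.scatter(
            t["tissue_score"], -np.log10(np.maximum(t["pvalue"], 1e-300)),
            s=6, c=np.where(t["is_tdu"], "crimson", "grey"), alpha=0.6,
        )
        ax.axvline(self.model.score_min, color="red", lw=0.8)
        ax.set_xlabel("tissue score")
        ax.set_ylabel("-log10 p-value")
        return ax
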