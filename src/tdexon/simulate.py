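"""Synthetic fully crossed exon-usage studies with known ground truth.

The generator inverts the analysis model: counts are drawn from a
Gamma-Poisson distribution with mean s_j * mu_ijl and dispersion alpha,
under a fully crossed individuals x tissues design.  Two mechanisms of
tissue-dependent usage are planted:

* splicing-driven: a cassette-like internal region whose inclusion mean
  is shifted up in the affected tissue(s) while its skipping-junction mean
  is shifted down by the same log amount (inclusion gain <-> skip loss,
  so gene-level expression is approximately conserved and not confounded
  with usage);
* start/termination-driven: a region whose inclusion mean is shifted
  with no change in exon-exon junction evidence.  Half of these events
  (by default) sit on a terminal (first or last) region, which has no
  skipping reads at all — transcripts that omit a terminal exon produce
  no junction across it; the other half emulate an internal alternative
  TSS/polyA site (as in genes whose shorter isoforms start mid-gene):
  an internal region with low constitutive skipping whose junction reads
  come from the same long isoform as its inclusion reads, so the
  skipping mean co-shifts proportionally with inclusion and the
  spliced-in ratio stays flat.

Internal unaffected regions carry a small constitutive skipping rate;
terminal regions are never skipped (there is no flanking exon on both
sides).  The generator can also emit the fragment stream that produces
exactly the emitted count tables when re-counted: per region, single-block
fragments inside the region, plus two-block junction fragments anchored in
the two neighbouring regions whose splice gap covers the skipped region.

Counts are deterministic given the seed (PRNG: numpy PCG64 via
``numpy.random.default_rng``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotation import ExonicRegion, FlattenedGeneModel
from .counting import CountTables, FragmentAlignment, build_reuc_pairs

__all__ = ["SimulationConfig", "SimulatedStudy", "simulate_study", "simulate_fragments", "gamma_poisson"]

REGION_WIDTH = 100
INTRON_WIDTH = 200
GENE_SPACING = 10_000
CHROM = "chrS"
FRAG_LEN = 50
ANCHOR_LEN = 30


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    Defaults describe a modest fully crossed multi-tissue cohort:
    10 individuals x 6 tissues, 300 genes of 3-8 exonic regions, baseline
    region means log-normal around 100 fragments, Gamma-Poisson dispersion
    0.05, library-size factors log-uniform in [0.5, 2], 10% of genes
    carrying one affected region with a 1.5 log-unit usage shift in one
    tissue, split evenly between the two mechanisms.
    """

    seed: int
    n_individuals: int = 10
    n_tissues: int = 6
    n_genes: int = 300
    regions_per_gene: tuple[int, int] = (3, 8)
    baseline_log_mean: tuple[float, float] = (math.log(100.0), 1.0)
    alpha: float = 0.05
    size_factor_range: tuple[float, float] = (0.5, 2.0)
    fraction_affected: float = 0.1
    effect_size: float = 1.5
    n_affected_tissues: int = 1
    splicing_fraction: float = 0.5
    sex_effect_sd: float = 0.0
    constitutive_skip_ratio: float = 0.0005
    spliced_skip_ratio: float = 0.3
    boundary_internal_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("simulation seed is mandatory")
        if self.n_individuals < 2 or self.n_tissues < 2:
            raise ValueError("need >= 2 individuals and >= 2 tissues")
        if self.n_affected_tissues >= self.n_tissues:
            raise ValueError("cannot affect all tissues (nothing to contrast)")
        if not math.isfinite(self.effect_size):
            raise ValueError("effect size must be finite")
        if self.regions_per_gene[0] < 1:
            raise ValueError("genes need >= 1 region")


@dataclass
class SimulatedStudy:
    tables: CountTables
    design: "DesignTable"
    truth: pd.DataFrame
    model: FlattenedGeneModel
    config: SimulationConfig
    size_factors_true: pd.Series

    def true_ut_matrix(self, region: str) -> pd.DataFrame:
        """Centred true interaction coefficients (individuals x tissues)."""
        row = self.truth.loc[region]
        individuals = self.design.individuals
        tissues = self.design.tissues
        shift = np.zeros(len(tissues))
        if row["mechanism"] != "none":
            affected = row["affected_tissues"].split(",")
            e = float(row["effect_size"])
            for i, t in enumerate(tissues):
                if t in affected:
                    shift[i] = e
        centred = shift - shift.mean()
        return pd.DataFrame(
            np.tile(centred, (len(individuals), 1)),
            index=individuals,
            columns=tissues,
        )

    def __iter__(self):
        # allow tuple-unpacking: tables, design, truth, model
        return iter((self.tables, self.design, self.truth, self.model))


def gamma_poisson(
    rng: np.random.Generator, mean, alpha: float, size=None
) -> np.ndarray:
    """Draw Gamma-Poisson counts: variance = mean + alpha * mean^2.

    alpha = 0 is the Poisson limit; otherwise a Poisson-gamma mixture with
    gamma shape 1/alpha and scale alpha*mean.
    """
    mean = np.asarray(mean, dtype=float)
    if alpha < 0:
        raise ValueError("dispersion must be >= 0")
    if alpha == 0:
        return rng.poisson(mean, size=size)
    shape = 1.0 / alpha
    lam = rng.gamma(shape, alpha * mean, size=size if size is not None else mean.shape)
    return rng.poisson(lam)


def _build_model(rng: np.random.Generator, cfg: SimulationConfig) -> FlattenedGeneModel:
    regions: list[ExonicRegion] = []
    pos = 1000
    lo, hi = cfg.regions_per_gene
    for g in range(1, cfg.n_genes + 1):
        gid = f"G{g:04d}"
        n_r = int(rng.integers(lo, hi + 1))
        start = pos
        for k in range(1, n_r + 1):
            regions.append(
                ExonicRegion(
                    region_id=f"E{k:03d}",
                    gene_id=gid,
                    chrom=CHROM,
                    start=start,
                    end=start + REGION_WIDTH,
                    strand="+",
                )
            )
            start += REGION_WIDTH + INTRON_WIDTH
        pos = start + GENE_SPACING
    return FlattenedGeneModel(
        regions=regions, aggregate_map={r.gene_id: r.gene_id for r in regions}
    )


def _generate(cfg: SimulationConfig):
    """Deterministic core: model, design, per-region truth, core counts C
    (single-block fragments) and skip counts rho."""
    from .glm import DesignTable

    rng = np.random.default_rng(cfg.seed)
    model = _build_model(rng, cfg)

    individuals = [f"I{u:02d}" for u in range(1, cfg.n_individuals + 1)]
    tissues = [f"T{t}" for t in range(1, cfg.n_tissues + 1)]
    sexes = {u: ("M" if i % 2 == 0 else "F") for i, u in enumerate(individuals)}
    rows = [
        {"sample": f"{u}.{t}", "individual": u, "tissue": t, "sex": sexes[u]}
        for u in individuals
        for t in tissues
    ]
    design = DesignTable(pd.DataFrame(rows))
    n = design.n_samples
    lo, hi = cfg.size_factor_range
    s = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))
    x_sex = design.x_sex
    tissue_of = design.table["tissue"].to_numpy()

    # choose affected genes / regions / mechanisms
    gene_ids = model.gene_ids
    n_aff = int(round(cfg.fraction_affected * len(gene_ids)))
    affected_genes = list(rng.choice(gene_ids, size=n_aff, replace=False))
    mech_of_gene: dict[str, str] = {}
    for g in affected_genes:
        mech_of_gene[g] = (
            "splicing" if rng.random() < cfg.splicing_fraction else "start_termination"
        )

    keys = model.region_keys()
    key_index = {k: i for i, k in enumerate(keys)}
    n_regions = len(keys)
    C = np.zeros((n_regions, n), dtype=np.int64)
    rho = np.zeros((n_regions, n), dtype=np.int64)

    truth_rows = []
    mu0, sig0 = cfg.baseline_log_mean
    for gid in gene_ids:
        regs = model.regions_of(gid)
        R = len(regs)
        mech = mech_of_gene.get(gid, "none")
        target_idx = -1
        if mech == "splicing" and R >= 3:
            target_idx = int(rng.integers(1, R - 1))  # internal region
        elif mech == "start_termination":
            # internal alternative TSS/polyA with probability
            # boundary_internal_fraction (needs an internal region)
            if R >= 3 and rng.random() < cfg.boundary_internal_fraction:
                target_idx = int(rng.integers(1, R - 1))
            else:
                target_idx = 0 if rng.random() < 0.5 else R - 1
        elif mech == "splicing":
            mech = "none"  # gene too short for a cassette exon
        affected_tissues: list[str] = []
        if mech != "none":
            affected_tissues = list(
                rng.choice(tissues, size=cfg.n_affected_tissues, replace=False)
            )
        aff_mask = np.isin(tissue_of, affected_tissues)

        for k, reg in enumerate(regs):
            base = float(np.exp(rng.normal(mu0, sig0)))
            beta_sex = (
                float(rng.normal(0, cfg.sex_effect_sd)) if cfg.sex_effect_sd > 0 else 0.0
            )
            is_target = k == target_idx and mech != "none"
            shift = np.where(aff_mask, cfg.effect_size, 0.0) if is_target else np.zeros(n)
            mu_incl = s * base * np.exp(x_sex * beta_sex + shift)
            C[key_index[reg.key]] = gamma_poisson(rng, mu_incl, cfg.alpha)

            internal = 0 < k < R - 1
            if internal:
                if is_target and mech == "splicing":
                    # cassette exon: skip junctions gain what inclusion loses
                    skip_base = cfg.spliced_skip_ratio * base
                    mu_skip = s * skip_base * np.exp(-shift)
                elif is_target:
                    # alternative internal boundary: both read classes come
                    # from the long isoform, so skipping co-shifts with
                    # inclusion and the spliced-in ratio is unchanged
                    skip_base = cfg.constitutive_skip_ratio * base
                    mu_skip = s * skip_base * np.exp(shift)
                else:
                    skip_base = cfg.constitutive_skip_ratio * base
                    mu_skip = s * skip_base
                rho[key_index[reg.key]] = gamma_poisson(rng, mu_skip, cfg.alpha)
            else:
                skip_base = 0.0

            truth_rows.append(
                {
                    "region": reg.key,
                    "gene_id": gid,
                    "ordinal": k + 1,
                    "n_regions": R,
                    "internal": internal,
                    "mechanism": mech if is_target else "none",
                    "affected_tissues": ",".join(affected_tissues) if is_target else "",
                    "effect_size": cfg.effect_size if is_target else 0.0,
                    "base_mean": base,
                    "skip_base_mean": skip_base,
                    "beta_sex_true": beta_sex,
                }
            )

    truth = pd.DataFrame(truth_rows).set_index("region")
    sf = pd.Series(s, index=design.samples, name="size_factor_true")
    return model, design, truth, C, rho, sf


def _assemble_tables(
    model: FlattenedGeneModel, design, C: np.ndarray, rho: np.ndarray
) -> CountTables:
    keys = model.region_keys()
    key_index = {k: i for i, k in enumerate(keys)}
    inclusion = C.copy()
    # each junction fragment skipping region k anchors in regions k-1, k+1
    for gid in model.gene_ids:
        regs = model.regions_of(gid)
        for k in range(1, len(regs) - 1):
            i = key_index[regs[k].key]
            inclusion[key_index[regs[k - 1].key]] += rho[i]
            inclusion[key_index[regs[k + 1].key]] += rho[i]
    gene_ids = model.gene_ids
    gene_totals = np.zeros((len(gene_ids), C.shape[1]), dtype=np.int64)
    for gi, gid in enumerate(gene_ids):
        idx = [key_index[r.key] for r in model.regions_of(gid)]
        gene_totals[gi] = C[idx].sum(axis=0) + rho[idx].sum(axis=0)
    samples = design.samples
    tables = CountTables(
        inclusion=pd.DataFrame(inclusion, index=keys, columns=samples),
        skipping=pd.DataFrame(rho, index=keys, columns=samples),
        gene_totals=pd.DataFrame(gene_totals, index=gene_ids, columns=samples),
    )
    tables.rest = build_reuc_pairs(tables, model)
    return tables


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Simulate count tables, design, truth table and gene model."""
    model, design, truth, C, rho, sf = _generate(cfg)
    tables = _assemble_tables(model, design, C, rho)
    return SimulatedStudy(
        tables=tables, design=design, truth=truth, model=model, config=cfg,
        size_factors_true=sf,
    )


def simulate_fragments(cfg: SimulationConfig):
    """Emit the fragment stream behind :func:`simulate_study`.

    Re-counting these fragments against the returned gene model
    reproduces the simulated count tables exactly.  Returns
    ``(fragments, study)`` with fragments as a list of
    :class:`~tdexon.counting.FragmentAlignment`.
    """
    model, design, truth, C, rho, sf = _generate(cfg)
    tables = _assemble_tables(model, design, C, rho)
    study = SimulatedStudy(
        tables=tables, design=design, truth=truth, model=model, config=cfg,
        size_factors_true=sf,
    )
    keys = model.region_keys()
    key_index = {k: i for i, k in enumerate(keys)}
    samples = design.samples
    fragments: list[FragmentAlignment] = []
    for gid in model.gene_ids:
        regs = model.regions_of(gid)
        for k, reg in enumerate(regs):
            i = key_index[reg.key]
            for j, sample in enumerate(samples):
                for _ in range(int(C[i, j])):
                    fragments.append(
                        FragmentAlignment(
                            sample, reg.chrom,
                            ((reg.start, reg.start + min(FRAG_LEN, reg.width)),),
                        )
                    )
                if 0 < k < len(regs) - 1 and rho[i].any():
                    up, down = regs[k - 1], regs[k + 1]
                    blocks = (
                        (up.end - ANCHOR_LEN, up.end),
                        (down.start, down.start + ANCHOR_LEN),
                    )
                    for _ in range(int(rho[i, j])):
                        fragments.append(
                            FragmentAlignment(sample, reg.chrom, blocks)
                        )
    return fragments, study
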