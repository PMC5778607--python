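"""REUC/RSIC estimation across regions of a study."""

import numpy as np
import pandas as pd
import pytest

from tdexon.counting import CountTables
from tdexon.glm import SizeFactors
from tdexon.simulate import SimulationConfig, simulate_study
from tdexon.usage import estimate_reucs, estimate_rsics, estimate_usage

from conftest import make_design, unit_size_factors


def tables_from_arrays(incl, rest, skip, samples, regions):
    t = CountTables(
        inclusion=pd.DataFrame(incl, index=regions, columns=samples),
        skipping=pd.DataFrame(skip, index=regions, columns=samples),
        gene_totals=pd.DataFrame(
            np.asarray(incl) + np.asarray(rest),
            index=regions, columns=samples,
        ),
    )
    t.rest = pd.DataFrame(rest, index=regions, columns=samples)
    return t


class TestEstimateReucs:
    def test_constant_usage_ratio_gives_near_zero_reucs(self):
        design = make_design(3, 2)
        n = design.n_samples
        regions = [f"g{i}:E001" for i in range(60)]
        rng = np.random.default_rng(0)
        depth = rng.integers(50, 200, size=(60, 1))
        incl = np.broadcast_to(depth, (60, n)).copy()
        rest = 3 * incl
        t = tables_from_arrays(incl, rest, np.zeros_like(incl), design.samples, regions)
        res = estimate_reucs(t, design, size_factors=unit_size_factors(design), alpha=0.01)
        assert np.nanmax(np.abs(res.values.to_numpy())) < 0.05

    def test_sample_mismatch_is_informative(self):
        design = make_design(2, 2)
        t = tables_from_arrays(
            np.ones((2, 3)), np.ones((2, 3)), np.zeros((2, 3)),
            ["x1", "x2", "x3"], ["g:E001", "g:E002"],
        )
        with pytest.raises(ValueError, match="mismatch"):
            estimate_reucs(t, design)

    def test_scale_invariance_of_one_sample(self):
        design = make_design(2, 2)
        n = design.n_samples
        rng = np.random.default_rng(1)
        regions = [f"g{i}:E001" for i in range(55)]
        incl = rng.poisson(80, size=(55, n))
        rest = rng.poisson(240, size=(55, n))
        t1 = tables_from_arrays(incl, rest, np.zeros_like(incl), design.samples, regions)
        incl2, rest2 = incl.copy(), rest.copy()
        incl2[:, 0] *= 2
        rest2[:, 0] *= 2
        t2 = tables_from_arrays(incl2, rest2, np.zeros_like(incl), design.samples, regions)
        s1 = pd.Series(1.0, index=design.samples)
        s2 = s1.copy()
        s2.iloc[0] = 2.0
        # unpenalized fits: the exact invariance property (the ridge trades
        # off likelihood mass against a fixed penalty, breaking exactness)
        r1 = estimate_usage(
            t1, design, "reuc", size_factors=SizeFactors(s1), alpha=0.05,
            prior_variance=np.inf, prior_variance_sex=np.inf,
        )
        r2 = estimate_usage(
            t2, design, "reuc", size_factors=SizeFactors(s2), alpha=0.05,
            prior_variance=np.inf, prior_variance_sex=np.inf,
        )
        assert np.allclose(r1.values.to_numpy(), r2.values.to_numpy(), atol=1e-6)

    def test_low_count_regions_are_flagged_not_zeroed(self):
        design = make_design(2, 2)
        n = design.n_samples
        regions = ["g0:E001", "g1:E001"]
        incl = np.array([[1] * n, [50] * n])
        rest = np.array([[1] * n, [150] * n])
        t = tables_from_arrays(incl, rest, np.zeros((2, n)), design.samples, regions)
        res = estimate_reucs(
            t, design, size_factors=unit_size_factors(design), alpha=0.01,
            min_total=10, prior_variance=1.0, prior_variance_sex=1.0,
        )
        assert not res.fit_flags.loc["g0:E001", "fitted"]
        assert res.fit_flags.loc["g0:E001", "reason"] == "low_count"
        assert res.values.loc["g0:E001"].isna().all()
        assert res.fit_flags.loc["g1:E001", "fitted"]


class TestEstimateRsics:
    def test_never_skipped_region_flagged_unestimable(self):
        design = make_design(2, 2)
        n = design.n_samples
        regions = ["g0:E002"]
        incl = np.full((1, n), 100)
        t = tables_from_arrays(incl, 2 * incl, np.zeros((1, n)), design.samples, regions)
        res = estimate_rsics(
            t, design, size_factors=unit_size_factors(design), alpha=0.01,
            prior_variance=1.0, prior_variance_sex=1.0,
        )
        assert not res.fit_flags.loc["g0:E002", "fitted"]
        assert res.fit_flags.loc["g0:E002", "reason"] == "never_skipped"


@pytest.fixture(scope="module")
def effect_study():
    cfg = SimulationConfig(
        seed=13, n_genes=60, n_individuals=6, n_tissues=4,
        fraction_affected=0.4, effect_size=1.5,
        baseline_log_mean=(np.log(200.0), 0.4),
    )
    return simulate_study(cfg)


@pytest.fixture(scope="module")
def effect_fits(effect_study):
    study = effect_study
    reuc = estimate_reucs(study.tables, study.design, alpha=study.config.alpha)
    rsic = estimate_rsics(study.tables, study.design, alpha=study.config.alpha)
    return reuc, rsic


class TestMechanismContracts:
    def test_splicing_events_move_both_coefficient_sets(self, effect_study, effect_fits):
        study = effect_study
        reuc, rsic = effect_fits
        good = 0
        events = study.truth.query("mechanism == 'splicing'").index
        for r in events:
            if not rsic.fit_flags.at[r, "fitted"]:
                continue
            x = reuc.values.loc[r].to_numpy()
            y = rsic.values.loc[r].to_numpy()
            ok = np.isfinite(x) & np.isfinite(y)
            r_p = np.corrcoef(x[ok], y[ok])[0, 1]
            good += r_p >= 0.8
        assert good >= 0.8 * len(events)

    def test_boundary_events_move_only_reucs(self):
        # moderately skipped exons (constitutive ratio 2%) so the absent
        # tissue shift of the spliced-in ratio is actually measurable —
        # at near-zero skip counts the RSIC is noise-dominated
        study = simulate_study(
            SimulationConfig(
                seed=17, n_genes=120, n_individuals=8, n_tissues=4,
                fraction_affected=0.4, effect_size=1.5,
                baseline_log_mean=(np.log(300.0), 0.4),
                constitutive_skip_ratio=0.05, splicing_fraction=0.0,
                boundary_internal_fraction=1.0,
            )
        )
        reuc = estimate_reucs(study.tables, study.design, alpha=study.config.alpha)
        rsic = estimate_rsics(study.tables, study.design, alpha=study.config.alpha)
        events = study.truth.query("mechanism == 'start_termination'")
        assert len(events) >= 30
        reuc_ok, rsic_flat, n_rsic = 0, 0, 0
        for r in events.index:
            affected = study.truth.at[r, "affected_tissues"].split(",")[0]
            reuc_ok += reuc.matrix(r)[affected].mean() > 0.5  # REUC responds
            if not events.at[r, "internal"]:
                assert not rsic.fit_flags.at[r, "fitted"]  # never skipped
            elif rsic.fit_flags.at[r, "fitted"]:
                n_rsic += 1
                tissue_means = rsic.matrix(r).mean(axis=0)
                rsic_flat += abs(tissue_means[affected]) < 0.2
        assert reuc_ok >= 0.95 * len(events)
        assert n_rsic >= 20
        assert rsic_flat >= 0.9 * n_rsic  # spliced-in ratio does not respond

    def test_recovered_shift_magnitude_and_sign(self, effect_study, effect_fits):
        """Planted shifts are recovered with correct sign; magnitudes match
        the ridge-attenuated truth kappa*beta with kappa = pv / (pv + v),
        v the delta-method sampling variance of a log usage ratio."""
        study = effect_study
        reuc, _ = effect_fits
        alpha = study.config.alpha
        pv = reuc.prior_variance
        events = study.truth.query("mechanism != 'none'").index
        signs, errs = [], []
        for r in events:
            truth_m = study.true_ut_matrix(r)
            est_m = reuc.matrix(r)
            affected = study.truth.at[r, "affected_tissues"].split(",")[0]
            est = est_m[affected].mean()
            v = (
                1 / study.tables.inclusion.loc[r].mean()
                + 1 / study.tables.rest.loc[r].mean()
                + 2 * alpha
            )
            kappa = pv / (pv + v)
            signs.append(est > 0)
            errs.append(est - kappa * truth_m[affected].iloc[0])
        assert np.mean(signs) >= 0.95
        assert np.all(np.abs(errs) < 0.2)
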