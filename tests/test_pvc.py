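"""Pure-tissue regression, redistribution and T1 correction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrsipvc import (
    MetaboliteMap,
    SequenceParams,
    T1Table,
    TissueFractions,
    default_t1_table,
    fit_pure_tissue,
    neutral_t1_table,
    normalized_gm_fraction,
    redistribute_voxel,
    run_pvc,
    t1_correction_factor,
)
from mrsipvc.atlas import regrid_nearest
from mrsipvc.errors import InsufficientDataError, MissingT1Error
from mrsipvc.pvc import PureTissueEstimate

# Independent scalar evaluation of the steady-state saturation ratio
# E(tCr=1000 ms)/E(met=1500 ms) at 35 deg / TR 300 ms, frozen.
T1_FACTOR_ORACLE = 1.1977108558952003


def native_fractions(g, tissue=None):
    """Native-grid adjusted fractions with normalized GM fraction g."""
    g = np.asarray(g, dtype=float)
    t = np.ones_like(g) if tissue is None else np.asarray(tissue, float)
    shape = g.shape + (1, 1)
    return TissueFractions(
        gm=(g * t).reshape(shape),
        wm=((1 - g) * t).reshape(shape),
        csf=(1 - t).reshape(shape),
        adjusted=True,
    )


class TestNormalizedGmFraction:
    @pytest.mark.parametrize(
        "f_gm, f_wm, expected",
        [(0.5, 0.5, 0.5), (0.0, 0.8, 0.0), (0.3, 0.1, 0.75)],
    )
    def test_arithmetic(self, f_gm, f_wm, expected):
        assert normalized_gm_fraction(f_gm, f_wm) == pytest.approx(expected)

    def test_no_tissue_is_undefined(self):
        assert np.isnan(normalized_gm_fraction(0.0, 0.0))

    def test_negative_fraction_rejected(self):
        with pytest.raises(ValueError):
            normalized_gm_fraction(-0.1, 0.5)


class TestFitPureTissue:
    def test_noiseless_line_recovered_exactly(self):
        g = np.linspace(0, 1, 100)
        fr = native_fractions(g)
        m = MetaboliteMap((0.7 + 0.3 * g).reshape(-1, 1, 1), "Glu")
        est = fit_pure_tissue(m, fr)
        assert est.s_wm == pytest.approx(0.7, abs=1e-12)
        assert est.s_gm == pytest.approx(1.0, abs=1e-12)
        assert est.n_voxels == 100

    def test_constant_map_gives_zero_slope(self):
        g = np.linspace(0, 1, 50)
        fr = native_fractions(g)
        m = MetaboliteMap(np.full((50, 1, 1), 0.9), "Glu")
        est = fit_pure_tissue(m, fr)
        assert est.slope == pytest.approx(0.0, abs=1e-12)
        assert est.s_gm == pytest.approx(0.9, abs=1e-12)
        assert est.s_wm == pytest.approx(0.9, abs=1e-12)

    def test_noisy_recovery_within_three_standard_errors(self, rng):
        # OLS oracle via statsmodels on the same data
        import statsmodels.api as sm

        s_gm, s_wm, n, sd = 1.2, 0.7, 500, 0.05
        g = rng.uniform(0, 1, n)
        y = s_wm + (s_gm - s_wm) * g + rng.normal(0, sd, n)
        fr = native_fractions(g)
        est = fit_pure_tissue(MetaboliteMap(y.reshape(-1, 1, 1), "Glu"), fr)

        oracle = sm.OLS(y, sm.add_constant(g)).fit()
        np.testing.assert_allclose(
            [est.intercept, est.slope], oracle.params, rtol=1e-10
        )
        se_int, se_slope = oracle.bse
        assert abs(est.s_wm - s_wm) < 3 * se_int
        cov = np.asarray(oracle.cov_params())
        se_gm = np.sqrt(cov[0, 0] + cov[1, 1] + 2 * cov[0, 1])
        assert abs(est.s_gm - s_gm) < 3 * se_gm
        assert est.se_s_wm == pytest.approx(se_int, rel=1e-8)
        assert est.se_s_gm == pytest.approx(se_gm, rel=1e-8)

    def test_low_tissue_voxels_excluded(self):
        g = np.linspace(0, 1, 40)
        tissue = np.where(np.arange(40) < 20, 1.0, 0.2)  # half mostly CSF
        fr = native_fractions(g, tissue)
        values = (0.7 + 0.3 * g) * tissue
        est = fit_pure_tissue(
            MetaboliteMap(values.reshape(-1, 1, 1), "Glu"), fr,
            min_tissue=0.5,
        )
        assert est.n_voxels == 20

    def test_too_few_voxels_rejected(self):
        g = np.linspace(0, 1, 5)
        fr = native_fractions(g)
        m = MetaboliteMap(g.reshape(-1, 1, 1), "Glu")
        with pytest.raises(InsufficientDataError):
            fit_pure_tissue(m, fr, min_voxels=10)

    def test_negative_extrapolation_warns_but_returns(self):
        g = np.linspace(0, 1, 30)
        fr = native_fractions(g)
        m = MetaboliteMap((0.5 - 0.8 * g).reshape(-1, 1, 1), "Glu")
        with pytest.warns(UserWarning, match="negative"):
            est = fit_pure_tissue(m, fr)
        assert est.s_gm == pytest.approx(-0.3, abs=1e-10)


class TestRedistribution:
    est = PureTissueEstimate(
        s_gm=1.2, s_wm=0.7, slope=0.5, intercept=0.7, n_voxels=100, r2=1.0
    )

    def test_homogeneous_voxel_unchanged(self):
        cells = TissueFractions(
            gm=np.full((5, 5, 10), 0.6), wm=np.full((5, 5, 10), 0.4),
            csf=np.zeros((5, 5, 10)), adjusted=True,
        )
        out = redistribute_voxel(0.95, cells, self.est)
        np.testing.assert_allclose(out, 0.95, atol=1e-12)

    def test_half_csf_half_gm_conservation_algebra(self):
        gm = np.zeros((2, 1, 1))
        gm[0] = 1.0
        csf = np.zeros((2, 1, 1))
        csf[1] = 1.0
        cells = TissueFractions(
            gm=gm, wm=np.zeros((2, 1, 1)), csf=csf, adjusted=True
        )
        out = redistribute_voxel(0.6, cells, self.est)
        assert out[0, 0, 0] == pytest.approx(1.2)  # 2 x measured
        assert out[1, 0, 0] == 0.0
        assert out.mean() == pytest.approx(0.6, abs=1e-15)

    def test_random_fixture_mean_preserved_and_proportional(self, rng):
        for _ in range(20):
            gm = rng.random((5, 5, 10))
            wm = rng.random((5, 5, 10)) * (1 - gm)
            csf = 1 - gm - wm
            cells = TissueFractions(gm=gm, wm=wm, csf=csf, adjusted=True)
            measured = rng.uniform(0.2, 2.0)
            out = redistribute_voxel(measured, cells, self.est)
            assert out.mean() == pytest.approx(measured, abs=1e-12)
            # independent element-wise recomputation
            p = gm * self.est.s_gm + wm * self.est.s_wm
            for idx in [(0, 0, 0), (2, 3, 4), (4, 4, 9)]:
                assert out[idx] == pytest.approx(
                    measured * p[idx] / p.mean(), rel=1e-12
                )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 2**31 - 1),
        measured=st.floats(0.01, 5.0),
        s_gm=st.floats(0.1, 3.0),
        s_wm=st.floats(0.1, 3.0),
    )
    def test_conservation_holds_for_any_composition(
        self, seed, measured, s_gm, s_wm
    ):
        rng = np.random.default_rng(seed)
        gm = rng.random((5, 5, 10))
        wm = rng.random((5, 5, 10)) * (1 - gm)
        cells = TissueFractions(
            gm=gm, wm=wm, csf=1 - gm - wm, adjusted=True
        )
        est = PureTissueEstimate(
            s_gm=s_gm, s_wm=s_wm, slope=s_gm - s_wm, intercept=s_wm,
            n_voxels=10, r2=1.0,
        )
        out = redistribute_voxel(measured, cells, est)
        assert out.mean() == pytest.approx(measured, rel=1e-12)
        assert (out >= 0).all()

    def test_all_csf_voxel_yields_missing(self):
        z = np.zeros((5, 5, 10))
        cells = TissueFractions(gm=z, wm=z, csf=np.ones_like(z), adjusted=True)
        out = redistribute_voxel(0.4, cells, self.est)
        assert np.isnan(out).all()


class TestT1Correction:
    def test_equal_t1_gives_unit_factor(self):
        t1s = neutral_t1_table(["Glu"])
        assert t1_correction_factor("Glu", "GM", t1s, SequenceParams()) == 1.0

    def test_long_tr_limit_is_unity(self):
        t1s = T1Table({("tCr", "GM"): 1000.0, ("Glu", "GM"): 1500.0})
        seq = SequenceParams(flip_angle_deg=35.0, tr_ms=1e6)
        assert t1_correction_factor("Glu", "GM", t1s, seq) == pytest.approx(
            1.0, abs=1e-6
        )

    def test_closed_form_oracle_value(self):
        t1s = T1Table({("tCr", "GM"): 1000.0, ("Glu", "GM"): 1500.0})
        factor = t1_correction_factor("Glu", "GM", t1s, SequenceParams())
        assert factor == pytest.approx(T1_FACTOR_ORACLE, rel=1e-12)

    def test_monotone_in_metabolite_t1(self):
        factors = []
        for t1_met in (800.0, 1200.0, 1600.0, 2000.0):
            t1s = T1Table({("tCr", "GM"): 1000.0, ("Glu", "GM"): t1_met})
            factors.append(
                t1_correction_factor("Glu", "GM", t1s, SequenceParams())
            )
        assert all(b > a for a, b in zip(factors, factors[1:]))

    def test_missing_entry_names_metabolite_and_tissue(self):
        t1s = T1Table({("tCr", "GM"): 1000.0})
        with pytest.raises(MissingT1Error) as err:
            t1_correction_factor("Glu", "GM", t1s, SequenceParams())
        assert err.value.metabolite == "Glu"
        assert "GM" in str(err.value)

    def test_default_table_covers_common_metabolites(self):
        t1s = default_t1_table()
        for met in ("Glu", "tNAA", "tCho"):
            factor = t1_correction_factor(met, "WM", t1s, SequenceParams())
            assert factor > 0


class TestRunPvc:
    def test_noiseless_phantom_recovers_psf_consistent_truth(
        self, small_study, small_geometry
    ):
        result = run_pvc(
            small_study.native["Glu"], small_study.fractions_psf,
            small_geometry, t1s=neutral_t1_table(["Glu"]),
        )
        s_gm, s_wm = small_study.spec.pure_values["Glu"]
        assert result.estimate.s_gm == pytest.approx(s_gm, abs=1e-9)
        assert result.estimate.s_wm == pytest.approx(s_wm, abs=1e-9)
        gate = small_study.fractions_psf.tissue >= 0.5
        err = np.abs(
            result.corrected.values - small_study.truth_psf["Glu"]
        )[gate]
        assert np.nanmax(err) < 1e-6

    def test_corrected_nucleus_mean_closer_to_gm_truth(
        self, small_study, small_geometry
    ):
        # deep-GM nucleus bordered by WM: PVC should push the ROI mean
        # toward the pure-GM level and not shrink its spread
        result = run_pvc(
            small_study.native["Glu"], small_study.fractions_psf,
            small_geometry, t1s=None,
        )
        uncorrected = regrid_nearest(small_study.native["Glu"], small_geometry)
        s_gm = small_study.spec.pure_values["Glu"][0]
        x, y, _ = np.indices(small_geometry.slab_shape).astype(float)
        nucleus = ((x - 22) / 6) ** 2 + ((y - 30) / 8) ** 2 <= 1.0
        deep_wm = small_study.fractions_raw.wm > 0.99
        mean_unc = np.nanmean(uncorrected.values[nucleus])
        mean_cor = np.nanmean(result.corrected.values[nucleus])
        assert abs(mean_cor - s_gm) < abs(mean_unc - s_gm)
        # GM-WM contrast is restored, not flattened
        contrast_unc = mean_unc - np.nanmean(uncorrected.values[deep_wm])
        contrast_cor = mean_cor - np.nanmean(result.corrected.values[deep_wm])
        assert contrast_cor > contrast_unc

    def test_all_missing_input_gives_all_missing_output(self, small_geometry):
        m = MetaboliteMap(
            np.full(small_geometry.native_shape, np.nan), "Glu"
        )
        shape = small_geometry.slab_shape
        fr = TissueFractions(
            gm=np.full(shape, 0.5), wm=np.full(shape, 0.5),
            csf=np.zeros(shape), adjusted=True,
        )
        result = run_pvc(m, fr, small_geometry)
        assert np.isnan(result.corrected.values).all()
        assert result.report["counts"]["cells_output"] == 0
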