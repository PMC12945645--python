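"""SUVR, CBF quantification, tensor fitting, FA and age correction."""
import numpy as np
import pytest

from mmnds.errors import InvalidParameterError, QuantificationError
from mmnds.quantify import (
    ASLQuantParams,
    AgeModel,
    DiffusionScheme,
    age_correct_fa,
    average_plds,
    compute_suv,
    compute_suvr,
    estimate_age_model,
    fit_diffusion_tensor,
    fractional_anisotropy,
    quantify_cbf,
    relative_cbf,
)
from mmnds.synth import make_scheme, simulate_dwi_series, tensor_field_from_fa
from mmnds.volumes import BinaryMask, GridSpec, ScalarVolume


def _vol(grid, values):
    return ScalarVolume(grid, np.asarray(values, float).reshape(grid.shape))


@pytest.fixture
def line_grid():
    return GridSpec(shape=(3, 1, 1), voxel_size_mm=(1.0, 1.0, 1.0))


@pytest.fixture
def line_mask(line_grid):
    return BinaryMask(line_grid, np.ones(line_grid.shape, bool))


class TestSUV:
    def test_hand_values(self, line_grid):
        # activity {2,4,6} kBq/mL, dose 200 MBq, weight 80 kg -> scale 2.5
        suv = compute_suv(_vol(line_grid, [2, 4, 6]), 200.0, 80.0)
        assert np.allclose(suv.values.ravel(), [0.8, 1.6, 2.4])

    def test_linearity_in_activity(self, line_grid):
        a = _vol(line_grid, [1, 2, 3])
        doubled = compute_suv(_vol(line_grid, [2, 4, 6]), 300.0, 70.0)
        assert np.allclose(doubled.values, 2 * compute_suv(a, 300.0, 70.0).values)

    def test_invalid_dose(self, line_grid):
        with pytest.raises(InvalidParameterError):
            compute_suv(_vol(line_grid, [1, 1, 1]), -5.0, 70.0)

    def test_suvr_hand_values(self, line_grid, line_mask):
        suvr = compute_suvr(_vol(line_grid, [2, 4, 6]), line_mask)
        assert np.allclose(suvr.values.ravel(), [0.5, 1.0, 1.5])
        assert suvr.values.mean() == pytest.approx(1.0, abs=1e-9)

    def test_suvr_scale_invariant(self, line_grid, line_mask):
        a = compute_suvr(_vol(line_grid, [2, 4, 6]), line_mask)
        b = compute_suvr(_vol(line_grid, [20, 40, 60]), line_mask)
        assert np.allclose(a.values, b.values)

    def test_suvr_dose_weight_invariant(self, line_grid, line_mask):
        act = _vol(line_grid, [2, 4, 6])
        a = compute_suvr(compute_suv(act, 200.0, 80.0), line_mask)
        b = compute_suvr(compute_suv(act, 450.0, 60.0), line_mask)
        assert np.allclose(a.values, b.values)

    def test_zero_reference_rejected(self, line_grid, line_mask):
        with pytest.raises(QuantificationError):
            compute_suvr(_vol(line_grid, [0, 0, 0]), line_mask)


class TestCBF:
    def test_zero_dm_gives_zero(self, line_grid):
        m0 = _vol(line_grid, [100, 100, 100])
        same = _vol(line_grid, [50, 50, 50])
        cbf = quantify_cbf(same, same, m0, 1.8)
        assert np.allclose(cbf.values, 0.0)

    def test_linearity_in_dm(self, line_grid):
        m0 = _vol(line_grid, [100, 100, 100])
        base = _vol(line_grid, [50, 50, 50])
        c1 = quantify_cbf(base, _vol(line_grid, [51, 51, 51]), m0, 1.8)
        c2 = quantify_cbf(base, _vol(line_grid, [52, 52, 52]), m0, 1.8)
        assert np.allclose(c2.values, 2 * c1.values)

    def test_consensus_model_value(self, line_grid):
        # independent evaluation of the closed form: dM/M0 = 0.01 at PLD 1.8 s
        # with defaults tau=1.5, alpha=0.85, T1b=1.65, lambda=0.9
        # -> 6000*0.9*0.01*exp(1.8/1.65) / (2*0.85*1.65*(1-exp(-1.5/1.65)))
        expected = (6000 * 0.9 * 0.01 * np.exp(1.8 / 1.65)
                    / (2 * 0.85 * 1.65 * (1 - np.exp(-1.5 / 1.65))))
        m0 = _vol(line_grid, [100, 100, 100])
        cbf = quantify_cbf(_vol(line_grid, [0, 0, 0]), _vol(line_grid, [1, 1, 1]),
                           m0, 1.8)
        assert cbf.values.ravel()[0] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(96.0, rel=0.01)

    def test_nonpositive_m0_yields_nan(self, line_grid):
        m0 = _vol(line_grid, [100, 0, -5])
        cbf = quantify_cbf(_vol(line_grid, [0, 0, 0]), _vol(line_grid, [1, 1, 1]),
                           m0, 1.5)
        assert np.isfinite(cbf.values.ravel()[0])
        assert np.isnan(cbf.values.ravel()[1:]).all()

    def test_relative_cbf_hand_values(self, line_grid, line_mask):
        rcbf = relative_cbf(_vol(line_grid, [30, 60, 90]), line_mask)
        assert np.allclose(rcbf.values.ravel(), [0.5, 1.0, 1.5])

    def test_rcbf_invariant_to_labeling_efficiency(self, line_grid, line_mask):
        m0 = _vol(line_grid, [100, 110, 120])
        label = _vol(line_grid, [50, 50, 50])
        control = _vol(line_grid, [51, 52, 53])
        out = {}
        for alpha in (0.85, 0.425):
            cbf = quantify_cbf(label, control, m0, 1.8,
                               ASLQuantParams(labeling_efficiency=alpha))
            out[alpha] = relative_cbf(cbf, line_mask).values
        assert np.allclose(out[0.85], out[0.425])

    def test_average_plds(self, line_grid):
        maps = [_vol(line_grid, [v, v, v]) for v in (0.8, 1.0, 1.2)]
        avg = average_plds(maps)
        assert np.allclose(avg.values, 1.0)
        single = average_plds([maps[0]])
        assert np.allclose(single.values, maps[0].values)


class TestFA:
    def test_isotropic_is_zero(self):
        assert fractional_anisotropy(2.0, 2.0, 2.0) == pytest.approx(0.0)

    def test_stick_is_one(self):
        assert fractional_anisotropy(3.0, 0.0, 0.0) == pytest.approx(1.0)

    def test_reference_value(self):
        # (1.7, 0.3, 0.3)e-3: dev^2 = 2*(0.46667e-3)^2 + (0.93333e-3)^2
        # = 1.30667e-6, norm^2 = 3.07e-6
        # -> FA = sqrt(1.5 * 1.30667 / 3.07) = 0.79903 (~0.80)
        assert fractional_anisotropy(1.7e-3, 0.3e-3, 0.3e-3) == pytest.approx(
            0.79903, abs=5e-4)

    def test_scale_invariance(self, rng):
        lams = rng.random((50, 3)) + 0.01
        fa1 = fractional_anisotropy(lams[:, 0], lams[:, 1], lams[:, 2])
        c = 7.3
        fa2 = fractional_anisotropy(c * lams[:, 0], c * lams[:, 1], c * lams[:, 2])
        assert np.allclose(fa1, fa2, rtol=1e-12)

    def test_all_zero_convention(self):
        assert fractional_anisotropy(0.0, 0.0, 0.0) == 0.0


class TestTensorFit:
    @pytest.fixture
    def scheme(self):
        return make_scheme(n_directions=20, seed=4)

    @pytest.fixture
    def tiny_grid(self):
        return GridSpec(shape=(3, 3, 3), voxel_size_mm=(2.0, 2.0, 2.0))

    def test_isotropic_signals_give_zero_fa(self, scheme, tiny_grid):
        fa_target = ScalarVolume(tiny_grid, np.zeros(tiny_grid.shape))
        tensors = tensor_field_from_fa(fa_target)
        vols = simulate_dwi_series(tensors, scheme, 1000.0, noise_sd=0.0)
        # isotropy: every diffusion-weighted volume identical
        dwi = [v.values for v, b in zip(vols, scheme.b_values) if b > 0]
        for v in dwi[1:]:
            assert np.allclose(v, dwi[0], rtol=1e-12)
        fit = fit_diffusion_tensor(vols, scheme)
        assert np.nanmax(fit.fa_map().values) < 1e-9

    def test_noiseless_recovery_to_machine_precision(self, scheme, tiny_grid, rng):
        # forward-model oracle: an arbitrary SPD tensor must be recovered
        a = rng.normal(size=(3, 3)) * 2e-4
        d_true = a @ a.T + 1e-4 * np.eye(3)
        comps = np.empty(tiny_grid.shape + (6,))
        for k, (i, j) in enumerate([(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]):
            comps[..., k] = d_true[i, j]
        from mmnds.quantify import TensorVolume
        truth = TensorVolume(tiny_grid, comps)
        vols = simulate_dwi_series(truth, scheme, 1500.0, noise_sd=0.0)
        fit = fit_diffusion_tensor(vols, scheme)
        assert np.abs(fit.components - comps).max() < 1e-9

    def test_b0_equals_s0(self, scheme, tiny_grid):
        truth = tensor_field_from_fa(ScalarVolume(tiny_grid, np.full(tiny_grid.shape, 0.4)))
        vols = simulate_dwi_series(truth, scheme, 1234.5, noise_sd=0.0)
        b0 = vols[int(np.argmin(scheme.b_values))]
        assert np.allclose(b0.values, 1234.5)

    def test_duplicate_rows_match_weighted_normal_equations(self, tiny_grid, rng):
        # oracle: duplicating a gradient-table row equals doubling its weight
        base = make_scheme(n_directions=12, seed=9)
        b = np.concatenate([base.b_values, base.b_values[-1:]])
        g = np.vstack([base.directions, base.directions[-1:]])
        dup_scheme = DiffusionScheme(b, g)
        truth = tensor_field_from_fa(
            ScalarVolume(tiny_grid, rng.uniform(0.1, 0.6, tiny_grid.shape)))
        vols = simulate_dwi_series(truth, base, 1000.0, noise_sd=5.0, seed=3)
        dup_vols = vols + [vols[-1]]
        fit = fit_diffusion_tensor(dup_vols, dup_scheme)
        from mmnds.quantify import _design_matrix
        X = _design_matrix(base.b_values, base.directions)
        w = np.ones(len(vols))
        w[-1] = 2.0
        y = np.log(np.stack([v.values.reshape(-1) for v in vols]))
        coef = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w[:, None] * y))
        assert np.allclose(fit.components.reshape(-1, 6), coef[1:].T, atol=1e-10)

    def test_nonpositive_signal_skipped(self, scheme, tiny_grid):
        truth = tensor_field_from_fa(ScalarVolume(tiny_grid, np.full(tiny_grid.shape, 0.3)))
        vols = simulate_dwi_series(truth, scheme, 1000.0, noise_sd=0.0)
        vols[3].values[1, 1, 1] = -2.0
        fit = fit_diffusion_tensor(vols, scheme)
        assert np.isnan(fit.components[1, 1, 1]).all()
        assert np.isfinite(fit.components[0, 0, 0]).all()

    def test_underdetermined_scheme_rejected(self):
        with pytest.raises(InvalidParameterError):
            DiffusionScheme(np.array([0.0, 1000.0, 1000.0]),
                            np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0.0]]))


class TestAgeCorrection:
    def test_zero_slope_is_identity(self, small_grid, rng):
        fa = ScalarVolume(small_grid, rng.uniform(0, 1, small_grid.shape))
        out = age_correct_fa(fa, 70.0, AgeModel(0.0, 60.0))
        assert np.allclose(out.values, fa.values)

    def test_reference_age_is_identity(self, small_grid, rng):
        fa = ScalarVolume(small_grid, rng.uniform(0, 1, small_grid.shape))
        out = age_correct_fa(fa, 60.0, AgeModel(0.002, 60.0))
        assert np.allclose(out.values, fa.values)

    def test_estimated_model_flattens_age_trend(self, small_grid, rng):
        # regression oracle: inject FA = 0.5 - 0.002 * (age - 60) + noise,
        # fit on "controls", corrected means must have |slope| < 2 SE
        from mmnds.volumes import BinaryMask, masked_mean
        mask = BinaryMask(small_grid, np.ones(small_grid.shape, bool))
        ages = rng.uniform(40, 85, 24)
        maps = [ScalarVolume(small_grid,
                             np.clip(0.5 - 0.002 * (a - 60)
                                     + rng.normal(0, 0.005, small_grid.shape), 0, 1))
                for a in ages]
        model = estimate_age_model(maps, ages, mask)
        assert model.slope_per_year == pytest.approx(0.002, rel=0.3)
        corrected = [masked_mean(age_correct_fa(m, a, model), mask)
                     for m, a in zip(maps, ages)]
        slope, intercept = np.polyfit(ages, corrected, 1)
        resid = np.array(corrected) - (slope * ages + intercept)
        se = np.sqrt(resid.var(ddof=2) / np.sum((ages - ages.mean()) ** 2))
        assert abs(slope) < 2 * se
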