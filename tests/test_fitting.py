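import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from renodiff.exceptions import FitError, ValidationError
from renodiff.fitting import (
    FitConfig,
    average_directions,
    fit_biexp,
    fit_mono,
    fit_tensor_wlls,
    fit_triexp,
    fit_volume,
)
from renodiff.signal_models import (
    BiExpParams,
    MonoParams,
    TensorFit,
    TriExpParams,
    predict_biexp,
    predict_mono,
    predict_tensor,
    predict_triexp,
    tensor_fa,
    tensor_from_md_fa,
    tensor_md,
)
from renodiff.synthetic_data import (
    PRESETS,
    add_rician_noise,
    default_phantom_spec,
    make_phantom,
    protocol_scheme,
)
from tests.conftest import noise_free_biexp, noise_free_triexp

B10 = np.array([0.0, 10.0, 25.0, 40.0, 75.0, 100.0, 200.0, 300.0, 500.0, 700.0])


# ---------------------------------------------------------------------------
# direction averaging


class TestAverageDirections:
    def test_identical_signals(self, ivim_scheme):
        sig = np.full(len(ivim_scheme), 5.0)
        for mode in ("geometric", "arithmetic"):
            s, b = average_directions(sig, ivim_scheme, mode)
            np.testing.assert_allclose(s, 5.0)
            np.testing.assert_array_equal(b, ivim_scheme.unique_bvalues)

    def test_geometric_closed_form(self):
        from renodiff.io_formats import AcquisitionScheme

        scheme = AcquisitionScheme([0, 100, 100], [[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        s, b = average_directions([1.0, np.e**0, np.e**2], scheme, "geometric")
        assert s[1] == pytest.approx(np.e, rel=1e-12)

    def test_geometric_mean_of_balanced_tensor_data_is_md_decay(self, rng):
        # the 6-direction set is balanced: mean(g^T D g) = MD for any D,
        # so the geometric mean across directions decays with D = MD
        a = rng.normal(size=(3, 3))
        m = a @ a.T / 3.0
        t = TensorFit.from_matrix(1.0, m)
        scheme = protocol_scheme("ivim")
        sig = predict_tensor(t, scheme.bvalues, scheme.directions)
        s, b = average_directions(sig, scheme, "geometric")
        expected = np.exp(-b * 1e-3 * tensor_md(t))
        np.testing.assert_allclose(s, expected, rtol=1e-10)

    def test_nonpositive_falls_back_to_arithmetic(self, ivim_scheme, caplog):
        sig = np.full(len(ivim_scheme), 4.0)
        sig[3] = -1.0
        b_bad = ivim_scheme.bvalues[3]
        with caplog.at_level("WARNING"):
            s, b = average_directions(sig, ivim_scheme, "geometric")
        shell = sig[ivim_scheme.bvalues == b_bad]
        assert s[list(b).index(b_bad)] == pytest.approx(np.mean(shell))
        assert "arithmetic" in caplog.text


# ---------------------------------------------------------------------------
# mono


class TestFitMono:
    def test_exact_recovery(self):
        sig = np.exp(-B10 * 1e-3 * 1.5)
        res = fit_mono(sig, B10)
        assert res.params.D_mono == pytest.approx(1.5, abs=1e-9)
        assert res.params.S0 == pytest.approx(1.0, abs=1e-9)

    def test_constant_signal_gives_zero_d(self):
        res = fit_mono(np.full(len(B10), 3.0), B10)
        assert res.params.D_mono == pytest.approx(0.0, abs=1e-12)

    def test_rank_deficiency_error(self):
        with pytest.raises(FitError):
            fit_mono([1.0, 1.0], [100.0, 100.0])

    def test_mono_on_triexp_signal_near_md_scale(self, cortex, ivim_scheme):
        # D_mono from a tri-exp cortex decay lands on the same order as MD
        s, b = noise_free_triexp(cortex, ivim_scheme)
        d = fit_mono(s, b).params.D_mono
        assert 1.0 < d < 3.0


# ---------------------------------------------------------------------------
# tensor WLLS


class TestFitTensor:
    def test_isotropic_recovery(self, dti_scheme):
        t = TensorFit.from_matrix(100.0, 2.16 * np.eye(3))
        sig = predict_tensor(t, dti_scheme.bvalues, dti_scheme.directions)
        res = fit_tensor_wlls(sig, dti_scheme)
        assert tensor_md(res.params) == pytest.approx(2.16, abs=1e-6)
        assert tensor_fa(res.params) == pytest.approx(0.0, abs=1e-6)
        assert res.n_rejected == 0

    def test_spike_rejected(self, dti_scheme, cortex):
        t = cortex.tensor_params(s0=100.0, axis=(1.0, 0.5, 0.2))
        sig = predict_tensor(t, dti_scheme.bvalues, dti_scheme.directions)
        clean = fit_tensor_wlls(sig, dti_scheme)
        spiked = sig.copy()
        spiked[7] *= 10.0
        res = fit_tensor_wlls(spiked, dti_scheme)
        assert res.n_rejected >= 1
        np.testing.assert_allclose(
            res.params.matrix, clean.params.matrix, atol=1e-6
        )
        # oracle: fit with the spike manually removed
        keep = np.ones(len(sig), dtype=bool)
        keep[7] = False
        from renodiff.io_formats import AcquisitionScheme

        sub = AcquisitionScheme(dti_scheme.bvalues[keep], dti_scheme.directions[keep])
        manual = fit_tensor_wlls(sig[keep], sub)
        np.testing.assert_allclose(res.params.matrix, manual.params.matrix, atol=1e-6)

    def test_anisotropic_fa_recovery(self, dti_scheme):
        t = tensor_from_md_fa(2.16, 0.38, axis=(0.3, -1.0, 0.7), S0=50.0)
        sig = predict_tensor(t, dti_scheme.bvalues, dti_scheme.directions)
        res = fit_tensor_wlls(sig, dti_scheme)
        assert tensor_fa(res.params) == pytest.approx(0.38, abs=1e-3)
        assert tensor_md(res.params) == pytest.approx(2.16, rel=1e-6)

    def test_too_few_measurements(self, dti_scheme):
        sig = np.ones(len(dti_scheme))
        sig[6:] = np.nan
        with pytest.raises(FitError, match="usable"):
            fit_tensor_wlls(sig, dti_scheme)

    def test_noise_free_equals_plain_ols(self, dti_scheme, cyst):
        # weights converge immediately and nothing is rejected
        t = cyst.tensor_params(s0=10.0)
        sig = predict_tensor(t, dti_scheme.bvalues, dti_scheme.directions)
        res = fit_tensor_wlls(sig, dti_scheme)
        assert res.n_rejected == 0
        assert res.n_iterations <= 2
        np.testing.assert_allclose(res.params.matrix, t.matrix, atol=1e-9)


# ---------------------------------------------------------------------------
# bi-exponential


class TestFitBiexp:
    def test_cortex_preset_recovery(self, cortex, ivim_scheme):
        s, b = noise_free_biexp(cortex, ivim_scheme)
        p = fit_biexp(s, b).params
        assert p.f_star == pytest.approx(0.101, rel=0.01)
        assert p.D_bi == pytest.approx(1.93, rel=0.01)

    def test_fstar_zero_data(self):
        sig = 10.0 * np.exp(-B10 * 1e-3 * 2.2)
        p = fit_biexp(sig, B10).params
        assert p.f_star <= 0.005
        assert p.D_bi == pytest.approx(2.2, abs=1e-3)

    def test_grid_oracle(self, cyst, ivim_scheme):
        # exhaustive lattice over (f_star, D_bi) with D_star fixed
        s, b = noise_free_biexp(cyst, ivim_scheme)
        config = FitConfig(model="biexp")
        res = fit_biexp(s, b, config)
        f_grid = np.linspace(0, 0.5, 101)
        d_grid = np.linspace(0.1, 4.0, 201)
        s0 = s[b == 0][0]
        best = np.inf
        for f in f_grid:
            pred = s0 * (
                f * np.exp(-b[:, None] * 1e-3 * config.d_star)
                + (1 - f) * np.exp(-b[:, None] * 1e-3 * d_grid[None, :])
            )
            rss = np.sum((pred - s[:, None]) ** 2, axis=0)
            best = min(best, rss.min())
        assert res.rss <= best + 1e-12

    def test_preconditions(self):
        with pytest.raises(ValidationError):
            fit_biexp([1.0, 0.5, 0.2], [0.0, 100.0, 300.0])  # no b >= 500


# ---------------------------------------------------------------------------
# tri-exponential


class TestFitTriexp:
    def test_cortex_preset_recovery(self, cortex, ivim_scheme):
        s, b = noise_free_triexp(cortex, ivim_scheme)
        p = fit_triexp(s, b).params
        assert p.f_fast == pytest.approx(0.0414, rel=0.01)
        assert p.f_interm == pytest.approx(0.288, rel=0.01)
        assert p.D_tri == pytest.approx(1.41, rel=0.01)

    def test_zero_fraction_data(self):
        sig = 5.0 * np.exp(-B10 * 1e-3 * 1.8)
        p = fit_triexp(sig, B10).params
        assert p.f_fast <= 0.005
        assert p.f_interm <= 0.005
        assert p.D_tri == pytest.approx(1.8, abs=1e-3)

    def test_necrotic_lesion_preset(self, ivim_scheme):
        s, b = noise_free_triexp(PRESETS["cc_rcc_extensive_necrosis"], ivim_scheme)
        p = fit_triexp(s, b).params
        assert p.D_tri == pytest.approx(0.71, rel=0.01)

    def test_free_mode_recovers_fixed_data(self, cortex, ivim_scheme):
        s, b = noise_free_triexp(cortex, ivim_scheme)
        config = FitConfig(model="triexp", pseudo_diffusion="free")
        p = fit_triexp(s, b, config).params
        assert p.D_tri == pytest.approx(1.41, rel=0.02)
        assert p.f_interm == pytest.approx(0.288, rel=0.05)

    def test_too_few_bvalues(self):
        with pytest.raises(ValidationError):
            fit_triexp([1, 0.9, 0.8, 0.7, 0.6], [0, 100, 200, 300, 500])


@settings(max_examples=25, deadline=None)
@given(
    st.floats(0.01, 0.25),
    st.floats(0.05, 0.45),
    st.floats(0.3, 3.5),
)
def test_exact_recovery_property(ff, fi, dt):
    """Fixed-mode NLLS recovers any in-bounds generator to 1% relative."""
    p = TriExpParams(S0=100.0, f_fast=ff, D_fast=50.0, f_interm=fi,
                     D_interm=6.0, D_tri=dt)
    sig = predict_triexp(p, B10)
    est = fit_triexp(sig, B10).params
    assert est.f_fast == pytest.approx(ff, rel=0.01, abs=1e-4)
    assert est.f_interm == pytest.approx(fi, rel=0.01)
    assert est.D_tri == pytest.approx(dt, rel=0.01)


@settings(max_examples=25, deadline=None)
@given(st.floats(0.01, 0.5), st.floats(0.2, 3.5))
def test_biexp_exact_recovery_property(f, d):
    p = BiExpParams(S0=10.0, f_star=f, D_star=50.0, D_bi=d)
    sig = predict_biexp(p, B10)
    est = fit_biexp(sig, B10).params
    assert est.f_star == pytest.approx(f, rel=0.01, abs=1e-4)
    assert est.D_bi == pytest.approx(d, rel=0.01)


@settings(max_examples=10, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_noise_never_violates_bounds(seed):
    rng = np.random.default_rng(seed)
    p = PRESETS["healthy_cortex"].triexp_params(s0=100.0)
    sig = predict_triexp(p, B10)
    noisy = add_rician_noise(sig, sigma=5.0, seed=rng)
    est = fit_triexp(noisy, B10).params
    assert 0.0 <= est.f_fast <= 1.0
    assert 0.0 <= est.f_interm <= 1.0
    assert est.f_fast + est.f_interm <= 1.0 + 1e-9
    assert 0.0 <= est.D_tri <= 4.0


# ---------------------------------------------------------------------------
# volume driver


class TestFitVolume:
    def test_three_label_phantom_noise_free(self, ivim_scheme):
        spec = default_phantom_spec(
            presets=("healthy_cortex", "rcc", "cyst"), shape=(9, 4, 3), snr=50.0
        )
        vol, labels, truth = make_phantom(spec, ivim_scheme)
        maps = fit_volume(vol, ivim_scheme, labels.mask(), FitConfig(model="triexp"))
        m = labels.mask()
        for name in ("f_fast", "f_interm", "D_tri"):
            est, tru = maps[name][m], truth[name][m]
            np.testing.assert_allclose(est, tru, rtol=0.01, atol=1e-4)
        assert np.all(np.isnan(maps["D_tri"][~m]))

    def test_single_voxel_mask(self, cortex, ivim_scheme):
        sig = predict_triexp(cortex.triexp_params(s0=100.0), ivim_scheme.bvalues)
        vol = np.broadcast_to(sig, (3, 3, 2, len(ivim_scheme))).copy()
        mask = np.zeros((3, 3, 2), dtype=bool)
        mask[1, 2, 0] = True
        maps = fit_volume(vol, ivim_scheme, mask, FitConfig(model="triexp"))
        assert np.sum(np.isfinite(maps["D_tri"])) == 1

    def test_empty_mask_rejected(self, ivim_scheme):
        vol = np.ones((2, 2, 2, len(ivim_scheme)))
        with pytest.raises(ValidationError, match="empty"):
            fit_volume(vol, ivim_scheme, np.zeros((2, 2, 2), dtype=bool))

    def test_nan_voxels_skipped_and_flagged(self, cortex, ivim_scheme):
        sig = predict_triexp(cortex.triexp_params(s0=100.0), ivim_scheme.bvalues)
        vol = np.broadcast_to(sig, (2, 2, 1, len(ivim_scheme))).copy()
        vol[0, 0, 0, 5] = np.nan
        mask = np.ones((2, 2, 1), dtype=bool)
        maps = fit_volume(vol, ivim_scheme, mask, FitConfig(model="triexp"))
        assert maps["converged"][0, 0, 0] == 0.0
        assert np.isnan(maps["D_tri"][0, 0, 0])
        assert maps["converged"][1, 1, 0] == 1.0
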