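"""Monte Carlo inversion: candidate sampling, NNLS weight fit, per-voxel
estimation, bootstrap replication."""

import numpy as np
import pytest
from scipy.optimize import lsq_linear
from scipy.stats import kstest

from dwspectra import metrics, phantoms
from dwspectra.dispersion import ComponentSet, DiffusionComponent
from dwspectra.inversion import (
    InversionConfig,
    SignalModel,
    bootstrap_invert,
    fit_weights,
    invert_voxel,
    invert_volume,
    mutate,
    residual_map,
    sample_candidates,
    voxel_seed_sequence,
)

W50 = 2 * np.pi * 190.0


def quick_config(**kw):
    base = dict(
        mode="omega_dependent", preset="preclinical", rng_seed=7,
        n_proliferation=8, n_mutation=8, n_in=60,
    )
    base.update(kw)
    return InversionConfig(**base)


class TestSampleCandidates:
    def test_draws_respect_limits_and_d0_constraint(self):
        cfg = InversionConfig(preset="preclinical")
        cs = sample_candidates(cfg, 200, np.random.default_rng(0))
        lim = cfg.limits
        for arr in (cs.d_a, cs.d_r, cs.d_0):
            assert arr.min() >= lim.d_min and arr.max() <= lim.d_max
        assert np.all(cs.d_0 >= np.maximum(cs.d_a, cs.d_r) - 1e-30)
        assert cs.gamma_a.min() >= lim.gamma_min and cs.gamma_a.max() <= lim.gamma_max
        assert cs.r_1.min() >= lim.r1_min and cs.r_2.max() <= lim.r2_max
        assert np.all((cs.theta >= 0) & (cs.theta <= np.pi / 2))

    def test_static_mode_has_no_dispersion_dimensions(self):
        cfg = InversionConfig(mode="static", preset="clinical")
        cs = sample_candidates(cfg, 50, np.random.default_rng(1))
        assert np.all(np.isinf(cs.gamma_a)) and np.all(np.isinf(cs.gamma_r))
        assert np.allclose(cs.d_0, np.maximum(cs.d_a, cs.d_r))

    def test_fixed_seed_is_bit_identical(self):
        cfg = InversionConfig()
        a = sample_candidates(cfg, 100, np.random.default_rng(42))
        b = sample_candidates(cfg, 100, np.random.default_rng(42))
        assert np.array_equal(a.d_a, b.d_a) and np.array_equal(a.phi, b.phi)

    def test_log_diffusivities_are_uniform(self):
        cfg = InversionConfig(preset="preclinical")
        cs = sample_candidates(cfg, 100_000, np.random.default_rng(3))
        lim = cfg.limits
        for arr in (cs.d_a, cs.d_r):
            u = (np.log(arr) - np.log(lim.d_min)) / (
                np.log(lim.d_max) - np.log(lim.d_min)
            )
            assert kstest(u, "uniform").pvalue > 0.01


class TestMutate:
    def test_stays_within_limits_and_hemisphere(self):
        cfg = quick_config()
        rng = np.random.default_rng(5)
        cs = sample_candidates(cfg, 300, rng)
        mut = mutate(cs, cfg, rng)
        lim = cfg.limits
        assert mut.d_a.min() >= lim.d_min and mut.d_a.max() <= lim.d_max
        assert np.all(mut.d_0 >= np.maximum(mut.d_a, mut.d_r) - 1e-30)
        assert np.all((mut.theta >= 0) & (mut.theta <= np.pi / 2 + 1e-12))

    def test_orientation_tilt_is_capped(self):
        cfg = quick_config()
        rng = np.random.default_rng(6)
        cs = sample_candidates(cfg, 500, rng)
        mut = mutate(cs, cfg, rng)
        # compare axes up to hemisphere folding
        cosang = np.abs(np.einsum("ni,ni->n", cs.axis, mut.axis))
        assert np.all(cosang >= np.cos(cfg.mutation_angle) - 1e-9)


class TestFitWeights:
    def test_exact_recovery_of_representable_signal(self, reduced_model):
        cfg = quick_config()
        cs = sample_candidates(cfg, 50, np.random.default_rng(11))
        k = reduced_model.kernel(cs, cfg.mode)
        w_true = np.zeros(50)
        w_true[[4, 17, 31]] = [0.5, 0.3, 0.2]
        sig = k @ w_true
        w = fit_weights(k, sig)
        assert np.allclose(w, w_true, rtol=1e-6, atol=1e-9)

    def test_zero_signals_give_zero_weights(self, reduced_model):
        cfg = quick_config()
        cs = sample_candidates(cfg, 30, np.random.default_rng(12))
        k = reduced_model.kernel(cs, cfg.mode)
        assert np.all(fit_weights(k, np.zeros(k.shape[0])) == 0)

    def test_matches_independent_bounded_solver(self, reduced_model, rng):
        cfg = quick_config()
        cs = sample_candidates(cfg, 50, np.random.default_rng(13))
        k = reduced_model.kernel(cs, cfg.mode)
        sig = k @ rng.uniform(0, 1, 50) + rng.normal(0, 0.01, k.shape[0])
        w = fit_weights(k, sig)
        ref = lsq_linear(k, sig, bounds=(0, np.inf), method="bvls")
        obj = np.sum((k @ w - sig) ** 2)
        obj_ref = np.sum((k @ ref.x - sig) ** 2)
        assert abs(obj - obj_ref) < 1e-10 * max(obj_ref, 1e-30)

    def test_all_zero_column_dropped(self):
        k = np.array([[1.0, 0.0], [0.5, 0.0]])
        w = fit_weights(k, np.array([1.0, 0.5]))
        assert w[1] == 0 and w[0] == pytest.approx(1.0)


class TestInvertVoxel:
    def test_noiseless_isotropic_recovery(self, reduced_model):
        salt = phantoms.make_preset("salt")
        sig = reduced_model.signals(salt, "omega_dependent")
        cfg = quick_config(n_proliferation=15, n_mutation=15, n_in=120)
        sol = invert_voxel(reduced_model, sig, cfg, np.random.default_rng(2))
        est = metrics.mean_d_iso(sol.components, W50)
        assert abs(est - 0.4e-9) / 0.4e-9 < 0.05
        assert abs(sol.components.s0 - 1.0) < 0.02

    def test_rss_history_monotone_over_proliferation(self, reduced_model):
        tum = phantoms.make_preset("tumor")
        sig = reduced_model.signals(tum, "omega_dependent")
        cfg = quick_config()
        sol = invert_voxel(reduced_model, sig, cfg, np.random.default_rng(8))
        prolif = np.array(sol.rss_history[: cfg.n_proliferation])
        assert np.all(np.diff(prolif) <= 1e-12)

    def test_deterministic_given_seed(self, reduced_model):
        wm = phantoms.make_preset("wm")
        sig = reduced_model.signals(wm, "omega_dependent")
        cfg = quick_config()
        a = invert_voxel(reduced_model, sig, cfg, np.random.default_rng(9))
        b = invert_voxel(reduced_model, sig, cfg, np.random.default_rng(9))
        assert np.array_equal(a.components.w, b.components.w)
        assert np.array_equal(a.fitted, b.fitted)

    def test_dispersion_free_voxel_fits_equally_in_both_modes(self, reduced_model):
        lam = phantoms.make_preset("lamellar")
        snr = 100.0
        sig = reduced_model.signals(lam, "omega_dependent")
        sig = sig + np.random.default_rng(31).normal(0, lam.s0 / snr, sig.shape)
        rms = {}
        for mode in ("omega_dependent", "static"):
            cfg = quick_config(mode=mode, n_proliferation=12, n_mutation=12, n_in=100)
            sol = invert_voxel(reduced_model, sig, cfg, np.random.default_rng(3))
            rms[mode] = np.sqrt(sol.rss / reduced_model.n_acq)
        # Gaussian diffusion: both modes land at the noise floor
        floor = 1.0 / snr
        assert rms["omega_dependent"] < 2.5 * floor
        assert rms["static"] < 2.5 * floor
        ratio = rms["omega_dependent"] / rms["static"]
        assert 1 / 1.5 < ratio < 1.5

    def test_dispersive_voxel_fits_better_with_frequency(self, reduced_model):
        tum = phantoms.make_preset("tumor")
        sig = reduced_model.signals(tum, "omega_dependent")
        rms = {}
        for mode in ("omega_dependent", "static"):
            cfg = quick_config(mode=mode, n_proliferation=12, n_mutation=12, n_in=100)
            sol = invert_voxel(reduced_model, sig, cfg, np.random.default_rng(4))
            rms[mode] = np.sqrt(sol.rss / reduced_model.n_acq)
        assert rms["omega_dependent"] < rms["static"]

    def test_mode_nesting_residual_bound(self, reduced_model, rng):
        # any static solution is representable in the omega-dependent space,
        # so the omega optimum can only be better (up to Monte Carlo noise)
        ratios = []
        n_vox = 8
        for i in range(n_vox):
            preset = ("salt", "wm", "lamellar", "csf")[i % 4]
            cs = phantoms.make_preset(preset)
            sig = reduced_model.signals(cs, "omega_dependent")
            sig = sig + rng.normal(0, cs.s0 / 100, sig.shape)
            res = {}
            for mode in ("omega_dependent", "static"):
                cfg = quick_config(
                    mode=mode, rng_seed=i, n_proliferation=15, n_mutation=15, n_in=150
                )
                sol = invert_voxel(
                    reduced_model, sig, cfg, np.random.default_rng(100 + i)
                )
                res[mode] = np.sqrt(sol.rss)
            ratios.append(res["omega_dependent"] / res["static"])
        ratios = np.array(ratios)
        assert np.median(ratios) <= 1.1
        assert ratios.max() < 1.3


class TestParameterRecovery:
    def test_mixed_voxel_bin_fractions_recovered(self, reduced_model, rng):
        """A half WM-like, half CSF-like voxel at SNR 100 recovers its
        bin-resolved signal fractions with median absolute error < 0.1."""
        mixed = phantoms.make_preset("mixed")
        truth = metrics.bin_fractions(mixed, metrics.MOUSE_BINS, W50)
        clean = reduced_model.signals(mixed, "omega_dependent")
        errs = []
        for i in range(6):
            sig = clean + rng.normal(0, mixed.s0 / 100, clean.shape)
            cfg = quick_config(
                rng_seed=i, n_proliferation=15, n_mutation=15, n_in=150,
                n_bootstrap=10,
            )
            ens = bootstrap_invert(reduced_model, sig, cfg, voxel_index=i)
            f = np.median(
                [
                    metrics.bin_fractions(s.components, metrics.MOUSE_BINS, W50)
                    for s in ens.solutions
                ],
                axis=0,
            )
            errs.append(np.abs(f - truth))
        assert np.all(np.median(np.array(errs), axis=0) < 0.1)


class TestBootstrap:
    def test_degenerate_bootstrap_equals_plain_inversion(self, reduced_model):
        salt = phantoms.make_preset("salt")
        sig = reduced_model.signals(salt, "omega_dependent")
        cfg = quick_config(n_bootstrap=1)
        ens = bootstrap_invert(reduced_model, sig, cfg, voxel_index=5, full_first=True)
        rng = np.random.default_rng(voxel_seed_sequence(cfg.rng_seed, 5, 0))
        direct = invert_voxel(reduced_model, sig, cfg, rng)
        assert np.array_equal(ens.solutions[0].components.w, direct.components.w)
        assert np.array_equal(ens.indices[0], np.arange(reduced_model.n_acq))

    def test_fixed_master_seed_reproducible(self, reduced_model):
        wm = phantoms.make_preset("wm")
        sig = reduced_model.signals(wm, "omega_dependent")
        cfg = quick_config(n_bootstrap=3)
        e1 = bootstrap_invert(reduced_model, sig, cfg, voxel_index=2)
        e2 = bootstrap_invert(reduced_model, sig, cfg, voxel_index=2)
        for a, b in zip(e1.solutions, e2.solutions):
            assert np.array_equal(a.components.w, b.components.w)

    def test_replicate_index_multisets_have_protocol_length(self, reduced_model):
        salt = phantoms.make_preset("salt")
        sig = reduced_model.signals(salt, "omega_dependent")
        cfg = quick_config(n_bootstrap=4)
        ens = bootstrap_invert(reduced_model, sig, cfg)
        for idx in ens.indices:
            assert len(idx) == reduced_model.n_acq

    def test_replicate_spread_shrinks_with_snr(self, reduced_model):
        salt = phantoms.make_preset("salt")
        clean = reduced_model.signals(salt, "omega_dependent")
        iqrs = {}
        for snr in (50, 200):
            noise_rng = np.random.default_rng(17)
            sig = clean + noise_rng.normal(0, salt.s0 / snr, clean.shape)
            cfg = quick_config(n_bootstrap=8)
            ens = bootstrap_invert(reduced_model, sig, cfg)
            vals = [metrics.mean_d_iso(s.components, W50) for s in ens.solutions]
            q75, q25 = np.percentile(vals, [75, 25])
            iqrs[snr] = q75 - q25
        assert iqrs[50] > 0
        assert iqrs[200] < iqrs[50]


class TestResidualMap:
    def test_noiseless_representable_voxel_near_zero(self, reduced_model):
        # the candidate pool contains the true components, so the NNLS fit
        # is exact and the normalized residual vanishes
        from dwspectra.inversion import VoxelSolution

        cfg = quick_config()
        cs = sample_candidates(cfg, 30, np.random.default_rng(21))
        w = np.zeros(30)
        w[[3, 9]] = [0.7, 0.3]
        truth = cs.with_weights(w)
        sig = reduced_model.signals(truth, cfg.mode)
        k = reduced_model.kernel(cs, cfg.mode)
        w_fit = fit_weights(k, sig)
        fitted = k @ w_fit
        sol = VoxelSolution(
            components=cs.with_weights(w_fit), fitted=fitted,
            residual=sig - fitted, rss=float(np.sum((sig - fitted) ** 2)),
        )
        res = residual_map(sig, sol)
        assert np.nanmax(np.abs(res)) < 1e-6

    def test_pure_noise_voxel_rms_matches_sigma(self, reduced_model):
        # a voxel holding a known component plus noise: the residual RMS
        # after fitting should approximate sigma / S0
        salt = phantoms.make_preset("salt")
        clean = reduced_model.signals(salt, "omega_dependent")
        sigma = salt.s0 / 40
        sig = clean + np.random.default_rng(23).normal(0, sigma, clean.shape)
        cfg = quick_config(n_proliferation=12, n_mutation=12, n_in=100)
        sol = invert_voxel(reduced_model, sig, cfg, np.random.default_rng(24))
        res = residual_map(sig, sol)
        rms = np.sqrt(np.nanmean(res**2))
        assert abs(rms - sigma / salt.s0) < 0.2 * sigma / salt.s0

    def test_zero_s0_gives_nan(self):
        from dwspectra.inversion import VoxelSolution

        sol = VoxelSolution(
            components=ComponentSet.empty(), fitted=np.zeros(5),
            residual=np.zeros(5), rss=0.0,
        )
        assert np.all(np.isnan(residual_map(np.ones(5), sol)))


class TestInvertVolume:
    def test_worker_count_does_not_change_results(self, reduced_model):
        spec = phantoms.PhantomSpec(preset="salt", shape=(2, 1, 1), snr=100, seed=1)
        data, _ = phantoms.synth_dataset(spec, reduced_model.protocol, reduced_model)
        cfg = quick_config(n_bootstrap=2, n_proliferation=4, n_mutation=4, n_in=30)
        serial = invert_volume(reduced_model, data, cfg, n_jobs=1)
        parallel = invert_volume(reduced_model, data, cfg, n_jobs=2)
        for v in serial:
            for a, b in zip(serial[v].solutions, parallel[v].solutions):
                assert np.array_equal(a.components.w, b.components.w)

    def test_mismatched_data_rejected(self, reduced_model):
        with pytest.raises(ValueError, match="match"):
            invert_volume(reduced_model, np.zeros((2, 2, 1, 7)), quick_config())
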