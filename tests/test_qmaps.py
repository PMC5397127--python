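"""Quantitative map estimation: R2*, TE=0 amplitudes, A/R1, MT saturation."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.optimize import fsolve

from mtvbm.phantom import (
    DEFAULT_PROTOCOLS,
    MTW_PROTOCOL,
    PDW_PROTOCOL,
    T1W_PROTOCOL,
    AcquisitionProtocol,
    CohortSpec,
    MultiEchoVolume,
    PhantomSpec,
    ernst_signal,
    flash_signal,
    make_phantom,
    simulate_acquisition,
    simulate_cohort,
)
from mtvbm.qmaps import (
    compute_mtsat,
    estimate_a_r1,
    extrapolate_te0,
    fit_quantitative_maps,
    fit_r2star,
)


def _decay_volume(s0, r2s, protocol=PDW_PROTOCOL, shape=(2, 2, 2)):
    te = np.asarray(protocol.echo_times)
    data = np.broadcast_to(
        s0 * np.exp(-te * r2s), shape + (len(te),)
    ).copy()
    return MultiEchoVolume(data=data, protocol=protocol)


class TestFitR2star:
    def test_constant_signal_gives_zero_rate(self):
        vol = _decay_volume(100.0, 0.0)
        fit = fit_r2star(vol)
        assert np.allclose(fit.r2star, 0.0)
        assert np.allclose(fit.ln_s0, np.log(100.0))
        assert fit.valid_mask.all()

    def test_exact_recovery_at_study_echoes(self):
        """Noiseless mono-exponential decay sampled at the 8 PDw echoes is
        recovered to machine precision by the log-linear fit."""
        fit = fit_r2star(_decay_volume(100.0, 14.0))
        assert np.allclose(fit.r2star, 14.0, rtol=1e-12)

    def test_nonpositive_echo_dropped_from_fit(self):
        vol = _decay_volume(100.0, 14.0)
        vol.data[0, 0, 0, 3] = 0.0  # unusable echo at one voxel
        fit = fit_r2star(vol)
        # Remaining 7 echoes still determine the exact line.
        assert fit.valid_mask[0, 0, 0]
        assert fit.r2star[0, 0, 0] == pytest.approx(14.0, rel=1e-10)

    def test_too_few_positive_echoes_marks_voxel_invalid(self):
        vol = _decay_volume(100.0, 14.0)
        vol.data[0, 0, 0, :6] = -1.0  # only two usable echoes left
        fit = fit_r2star(vol)
        assert not fit.valid_mask[0, 0, 0]
        assert fit.valid_mask[1, 1, 1]

    def test_negative_fitted_rate_clamped_and_flagged(self):
        te = np.asarray(PDW_PROTOCOL.echo_times)
        data = np.exp(+5.0 * te)[None, None, None, :] * 10.0  # rising signal
        fit = fit_r2star(MultiEchoVolume(data=data, protocol=PDW_PROTOCOL))
        assert fit.r2star[0, 0, 0] == 0.0
        assert fit.clamped_mask[0, 0, 0]


class TestExtrapolateTe0:
    def test_roundtrip_removes_decay_weighting(self, default_phantom, noiseless_volumes):
        """The TE=0 amplitude equals the forward model's TE=0 value."""
        amp, valid = extrapolate_te0(noiseless_volumes["pdw"])
        expected = flash_signal(
            default_phantom.fields["a"],
            default_phantom.fields["r1"],
            0.0,
            0.0,
            PDW_PROTOCOL,
            0.0,
        )
        wm = default_phantom.wm_mask
        assert valid[wm].all()
        np.testing.assert_allclose(amp[wm], expected[wm], rtol=1e-10)

    def test_single_echo_amplitude_flagged(self):
        proto = AcquisitionProtocol(
            name="pdw", tr=0.024, flip_angle=0.1, echo_times=(0.00251,)
        )
        data = np.full((2, 2, 2, 1), 42.0)
        amp, valid = extrapolate_te0(MultiEchoVolume(data=data, protocol=proto))
        assert np.allclose(amp, 42.0)
        assert not valid.any()

    def test_linearity_in_signal(self):
        vol = _decay_volume(100.0, 14.0)
        doubled = MultiEchoVolume(data=vol.data * 2.0, protocol=vol.protocol)
        a1, _ = extrapolate_te0(vol)
        a2, _ = extrapolate_te0(doubled)
        np.testing.assert_allclose(a2, 2.0 * a1, rtol=1e-12)


def _te0_amplitudes(a, r1, proto):
    return flash_signal(a, r1, 0.0, 0.0, proto, 0.0)


class TestEstimateAR1:
    def test_exact_algebraic_roundtrip(self):
        s_pd = np.full((3, 3, 3), _te0_amplitudes(1000.0, 1.0, PDW_PROTOCOL))
        s_t1 = np.full((3, 3, 3), _te0_amplitudes(1000.0, 1.0, T1W_PROTOCOL))
        a, r1, valid = estimate_a_r1(s_pd, s_t1, PDW_PROTOCOL, T1W_PROTOCOL)
        assert valid.all()
        np.testing.assert_allclose(a, 1000.0, rtol=1e-12)
        np.testing.assert_allclose(r1, 1.0, rtol=1e-12)

    def test_closed_form_matches_numerical_solver(self, rng):
        """The closed-form dual-angle solution agrees with a numerical
        two-unknown root finder on 100 random parameter draws."""
        for _ in range(100):
            a_true = rng.uniform(100.0, 3000.0)
            r1_true = rng.uniform(0.3, 2.5)
            s_pd = _te0_amplitudes(a_true, r1_true, PDW_PROTOCOL)
            s_t1 = _te0_amplitudes(a_true, r1_true, T1W_PROTOCOL)

            def equations(x):
                a, r1 = x
                return (
                    _te0_amplitudes(a, r1, PDW_PROTOCOL) - s_pd,
                    _te0_amplitudes(a, r1, T1W_PROTOCOL) - s_t1,
                )

            num = fsolve(equations, x0=(500.0, 1.0), full_output=False)
            grid = np.full((1, 1, 1), s_pd), np.full((1, 1, 1), s_t1)
            a_cf, r1_cf, valid = estimate_a_r1(*grid, PDW_PROTOCOL, T1W_PROTOCOL)
            assert valid.all()
            assert a_cf[0, 0, 0] == pytest.approx(num[0], rel=1e-6)
            assert r1_cf[0, 0, 0] == pytest.approx(num[1], rel=1e-6)
            assert a_cf[0, 0, 0] == pytest.approx(a_true, rel=1e-9)
            assert r1_cf[0, 0, 0] == pytest.approx(r1_true, rel=1e-9)

    def test_degenerate_denominator_marks_invalid(self):
        s_pd = np.full((2, 2, 2), 50.0)
        # S_PD/a_PD == S_T1/a_T1 makes the system unsolvable.
        s_t1 = s_pd * (T1W_PROTOCOL.flip_angle / PDW_PROTOCOL.flip_angle)
        _, _, valid = estimate_a_r1(s_pd, s_t1, PDW_PROTOCOL, T1W_PROTOCOL)
        assert not valid.any()

    def test_scale_equivariance(self):
        s_pd = np.full((2, 2, 2), _te0_amplitudes(800.0, 0.9, PDW_PROTOCOL))
        s_t1 = np.full((2, 2, 2), _te0_amplitudes(800.0, 0.9, T1W_PROTOCOL))
        a1, r1a, _ = estimate_a_r1(s_pd, s_t1, PDW_PROTOCOL, T1W_PROTOCOL)
        a2, r1b, _ = estimate_a_r1(3 * s_pd, 3 * s_t1, PDW_PROTOCOL, T1W_PROTOCOL)
        np.testing.assert_allclose(a2, 3 * a1, rtol=1e-12)
        np.testing.assert_allclose(r1b, r1a, rtol=1e-12)

    def test_equal_flip_angles_rejected(self):
        proto = AcquisitionProtocol(
            name="t1w",
            tr=0.019,
            flip_angle=PDW_PROTOCOL.flip_angle,
            echo_times=(0.00251,),
        )
        s = np.full((2, 2, 2), 50.0)
        with pytest.raises(ValueError, match="flip angles"):
            estimate_a_r1(s, s, PDW_PROTOCOL, proto)


class TestComputeMtsat:
    def test_no_saturation_case(self):
        a = np.full((2, 2, 2), 800.0)
        r1 = np.full((2, 2, 2), 0.9)
        s_mt = flash_signal(800.0, 0.9, 0.0, 0.0, MTW_PROTOCOL, 0.0) * np.ones_like(a)
        delta, valid = compute_mtsat(s_mt, a, r1, MTW_PROTOCOL)
        assert valid.all()
        np.testing.assert_allclose(delta, 0.0, atol=1e-12)

    def test_requires_mt_on_protocol(self):
        a = np.full((2, 2, 2), 800.0)
        with pytest.raises(ValueError, match="MT-on"):
            compute_mtsat(a, a, a, PDW_PROTOCOL)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            compute_mtsat(
                np.zeros((2, 2, 2)), np.zeros((3, 3, 3)), np.zeros((2, 2, 2)),
                MTW_PROTOCOL,
            )


class TestFullChain:
    def test_noiseless_parameter_recovery(self, default_phantom, noiseless_volumes):
        """A, R1, MT saturation and R2* all recovered voxelwise to better
        than 1e-8 relative error inside the brain."""
        qmaps = fit_quantitative_maps(
            noiseless_volumes["pdw"],
            noiseless_volumes["t1w"],
            noiseless_volumes["mtw"],
        )
        brain = default_phantom.brain_mask
        assert qmaps.valid_mask[brain].all()
        for name in ("a", "r1", "mtsat", "r2star"):
            est = getattr(qmaps, name)[brain]
            truth = default_phantom.fields[name][brain]
            rel = np.abs(est - truth) / np.maximum(np.abs(truth), 1e-30)
            assert rel.max() < 1e-8, name

    def test_gm_mtsat_recovered_through_cohort_simulation(self):
        """Noiseless cohort simulation returns the generating GM saturation."""
        cohort = CohortSpec(
            n_per_group=2, noise_sigma=0.0, atrophy_fraction=0.0,
            delta_r2star=0.0, r2star_subject_sd=0.0, age_r2star_slope=0.0,
            seed=0,
        )
        subject = next(iter(simulate_cohort(cohort, PhantomSpec.small())))
        qmaps = fit_quantitative_maps(
            subject.volumes["pdw"], subject.volumes["t1w"], subject.volumes["mtw"]
        )
        gm = subject.phantom.gm_mask
        truth = subject.phantom.spec.tissues["cortical_gm"].mtsat
        np.testing.assert_allclose(qmaps.mtsat[gm], truth, rtol=1e-10)

    def test_iron_invariance_of_mtsat(self):
        """Raising striatal R2* from 14 to 25 1/s (R1 fixed) leaves the
        estimated striatal saturation unchanged to 1e-10 — iron cannot leak
        into the MT-saturation map through the decay term."""
        estimates = []
        for r2s in (14.0, 25.0):
            spec = PhantomSpec.small()
            tissues = dict(spec.tissues)
            tissues["striatal_gm"] = replace(tissues["striatal_gm"], r2star=r2s)
            phantom = make_phantom(replace(spec, tissues=tissues))
            vols = {
                n: simulate_acquisition(phantom.fields, p)
                for n, p in DEFAULT_PROTOCOLS.items()
            }
            qmaps = fit_quantitative_maps(vols["pdw"], vols["t1w"], vols["mtw"])
            estimates.append(qmaps.mtsat[phantom.striatal_mask].mean())
        assert estimates[0] == pytest.approx(estimates[1], rel=1e-10)

    def test_noise_propagation_into_mtsat_is_modest(self):
        """At 0.5% noise the median absolute GM saturation error stays
        below 10% of the GM saturation value (fixed-seed Monte Carlo)."""
        spec = PhantomSpec.small()
        phantom = make_phantom(spec)
        vols = {
            n: simulate_acquisition(
                phantom.fields, p, noise_sigma=0.005, seed=hash(n) % 2**31,
                wm_mask=phantom.wm_mask,
            )
            for n, p in DEFAULT_PROTOCOLS.items()
        }
        qmaps = fit_quantitative_maps(vols["pdw"], vols["t1w"], vols["mtw"])
        gm = phantom.gm_mask & qmaps.valid_mask
        truth = spec.tissues["cortical_gm"].mtsat
        err = np.median(np.abs(qmaps.mtsat[gm] - truth))
        assert err < 0.1 * truth

    def test_rational_model_bias_against_full_ernst(self):
        """Fitting the rational-model closed forms to full-Ernst signals
        keeps the R1 error under 5% for T1 between 0.5 and 2 s."""
        for t1 in (0.5, 1.0, 1.5, 2.0):
            r1 = 1.0 / t1
            s_pd = np.full((1, 1, 1), ernst_signal(800.0, r1, 0.0, PDW_PROTOCOL, 0.0))
            s_t1 = np.full((1, 1, 1), ernst_signal(800.0, r1, 0.0, T1W_PROTOCOL, 0.0))
            _, r1_est, valid = estimate_a_r1(s_pd, s_t1, PDW_PROTOCOL, T1W_PROTOCOL)
            assert valid.all()
            assert r1_est[0, 0, 0] == pytest.approx(r1, rel=0.05)
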