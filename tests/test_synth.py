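"""Generator-level checks: IBI model statistics, waveform ground truth,
clamp-family closed forms and Ca2+ ground truth."""

import numpy as np
import pytest

from cardiokit.synth import (
    AfterdepSpec,
    APShapeParams,
    CaSimParams,
    IBIModelParams,
    ICAL_STEPS,
    IsoproterenolScenario,
    IsoSegment,
    TrainsScenario,
    boltzmann,
    default_ical_params,
    default_if_params,
    generate_ap_trace,
    generate_ca_trace,
    generate_clamp_family,
    generate_ibi_sequence,
    generate_intervention_session,
    ical_peak_current,
    if_steady_state_current,
)
from cardiokit.clamp import if_density


class TestIBISequence:
    def test_zero_noise_returns_exact_mean(self):
        p = IBIModelParams(mean_ibi=1.3, n_beats=50, seed=0)
        assert np.all(generate_ibi_sequence(p) == 1.3)

    def test_white_component_sd_matches_sigma_short(self):
        p = IBIModelParams(mean_ibi=1.0, sigma_short=0.05, n_beats=10000, seed=11)
        sd = np.std(generate_ibi_sequence(p), ddof=1)
        assert abs(sd - 0.05) / 0.05 < 0.05

    def test_ar1_lag1_autocorrelation_near_phi(self):
        p = IBIModelParams(mean_ibi=1.0, sigma_long=0.1, phi=0.9, n_beats=10000, seed=7)
        x = generate_ibi_sequence(p)
        xc = x - x.mean()
        lag1 = np.sum(xc[1:] * xc[:-1]) / np.sum(xc * xc)
        assert abs(lag1 - 0.9) < 0.05

    def test_reproducible_for_fixed_seed(self):
        p = IBIModelParams(mean_ibi=1.0, sigma_short=0.05, sigma_long=0.1,
                           phi=0.5, n_beats=200, seed=42)
        assert np.array_equal(generate_ibi_sequence(p), generate_ibi_sequence(p))

    def test_clipped_below_at_fraction_of_mean(self):
        p = IBIModelParams(mean_ibi=1.0, sigma_short=2.0, n_beats=2000, seed=3)
        assert generate_ibi_sequence(p).min() >= 0.2

    @pytest.mark.parametrize("bad", [
        dict(mean_ibi=-1.0), dict(mean_ibi=np.nan), dict(phi=1.0),
        dict(sigma_short=-0.1), dict(n_beats=0),
    ])
    def test_invalid_parameters_rejected(self, bad):
        kwargs = dict(mean_ibi=1.0, n_beats=10)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            IBIModelParams(**kwargs)


class TestAPTrace:
    def test_beat_count_by_construction(self, regular_trace):
        _, gt = regular_trace
        assert gt.beat_times.size == 60

    def test_fixed_seed_bit_identical(self, slow_trace):
        shape = APShapeParams(noise_sd=0.5)
        t1, _ = generate_ap_trace(shape, np.full(5, 2.0), seed=9)
        t2, _ = generate_ap_trace(shape, np.full(5, 2.0), seed=9)
        assert np.array_equal(t1.v, t2.v)

    def test_injected_bump_is_localized_raised_cosine(self, clean_shape):
        ev = AfterdepSpec(beat_index=2, latency_ms=250, amplitude_fraction=0.05,
                          width_ms=60)
        with_ev, gt = generate_ap_trace(clean_shape, np.full(5, 3.0), events=[ev])
        without, _ = generate_ap_trace(clean_shape, np.full(5, 3.0))
        t_c = gt.events[0].time
        a = gt.beat_times[2]
        repol90 = a + clean_shape.apd90 / 1e3
        assert repol90 < t_c < gt.beat_times[3]
        diff = with_ev.v - without.v
        assert diff.max() == pytest.approx(0.05 * clean_shape.apa, rel=1e-4)
        nz = with_ev.t[np.abs(diff) > 1e-9]
        assert nz.min() >= t_c - 0.031 and nz.max() <= t_c + 0.031

    def test_bump_overlapping_next_upstroke_rejected(self, clean_shape):
        ev = AfterdepSpec(beat_index=2, latency_ms=2600, amplitude_fraction=0.05)
        with pytest.raises(ValueError, match="overlap"):
            generate_ap_trace(clean_shape, np.full(5, 3.0), events=[ev])

    def test_ead_bump_must_precede_repol90(self, clean_shape):
        ev = AfterdepSpec(beat_index=2, latency_ms=-10, amplitude_fraction=0.05,
                          width_ms=60)
        with pytest.raises(ValueError, match="90%-repolarization"):
            generate_ap_trace(clean_shape, np.full(5, 3.0), events=[ev])

    def test_event_on_missing_beat_rejected(self, clean_shape):
        ev = AfterdepSpec(beat_index=50, latency_ms=250, amplitude_fraction=0.05)
        with pytest.raises(ValueError):
            generate_ap_trace(clean_shape, np.full(5, 3.0), events=[ev])


class TestInterventionSession:
    def test_isoproterenol_segment_rates(self, clean_shape):
        segs = tuple(
            IsoSegment(lbl, mult, 30.0)
            for lbl, mult in [("base", 1.0), ("a", 1.1), ("b", 1.3),
                              ("c", 1.6), ("d", 2.0)]
        )
        _, gt = generate_intervention_session(
            clean_shape, np.full(10, 2.0), IsoproterenolScenario(segs), seed=0
        )
        rates = [round(seg[3], 6) for seg in gt.segments]
        assert rates == [30.0, 33.0, 39.0, 48.0, 60.0]

    def test_cease_flag_spans_segment(self, clean_shape):
        segs = (IsoSegment("base", 1.0, 30.0), IsoSegment("drug", 2.0, 30.0, cease=True))
        _, gt = generate_intervention_session(
            clean_shape, np.full(10, 2.0), IsoproterenolScenario(segs), seed=0
        )
        (c0, c1), = gt.cessation_intervals
        lbl, s0, s1, _ = gt.segments[1]
        assert (c0, c1) == (s0, s1)

    def test_train_stimulus_protocol_arithmetic(self, clean_shape):
        sc = TrainsScenario(frequencies=(0.5, 1.0, 1.5, 2.0))
        _, gt = generate_intervention_session(clean_shape, np.full(10, 2.0), sc, seed=0)
        assert len(gt.stim_trains) == 4
        for (freq, stims), expected_isi in zip(gt.stim_trains, (2.0, 1.0, 1/1.5, 0.5)):
            assert len(stims) == 20
            assert np.allclose(np.diff(stims), expected_isi)
        # 20-s pause between each train's last stimulus and the next train
        for (f0, s0), (f1, s1) in zip(gt.stim_trains[:-1], gt.stim_trains[1:]):
            assert s1[0] - s0[-1] == pytest.approx(20.0)

    def test_nonpositive_multiplier_rejected(self):
        with pytest.raises(ValueError):
            IsoSegment("x", multiplier=0.0)


class TestClampFamily:
    def test_boltzmann_midpoint(self):
        assert boltzmann(-90.0, -90.0, 10.0) == pytest.approx(0.5)

    def test_zero_driving_force_leak_only(self):
        p = default_if_params(leak_g=0.0)
        rec = generate_clamp_family(p, "if", steps=[p.erev])[0]
        assert if_density(rec) == pytest.approx(0.0, abs=1e-12)

    def test_if_activates_with_hyperpolarization(self):
        p = default_if_params()
        i = if_steady_state_current(p, np.array([-120.0, -60.0]))
        assert i[0] < i[1] < 0

    def test_ical_peak_between_minus10_and_plus20(self):
        p = default_ical_params()
        peaks = ical_peak_current(p, np.array(ICAL_STEPS))
        v_star = ICAL_STEPS[int(np.argmin(peaks))]
        assert -10.0 <= v_star <= 20.0

    def test_empty_step_list_rejected(self):
        with pytest.raises(ValueError):
            generate_clamp_family(default_if_params(), "if", steps=[])


class TestCaTrace:
    def test_amplitude_change_is_factor_definition(self):
        _, gt = generate_ca_trace(CaSimParams(caffeine_amp_factor=2.0))
        assert gt.amp_change_pct == pytest.approx(100.0)
        _, gt = generate_ca_trace(
            CaSimParams(caffeine_amp_factor=0.6, caffeine_decay_tau=0.15,
                        post_caffeine_pause=15.0)
        )
        assert gt.amp_change_pct == pytest.approx(-40.0)

    def test_recovery_time_is_pause_by_construction(self):
        _, gt = generate_ca_trace(CaSimParams(post_caffeine_pause=30.0))
        assert gt.recovery_time == 30.0

    def test_overlapping_caffeine_and_resumption_rejected(self):
        with pytest.raises(ValueError, match="decaying"):
            generate_ca_trace(CaSimParams(post_caffeine_pause=2.0,
                                          caffeine_decay_tau=1.5))

    def test_needs_five_paced_transients(self):
        with pytest.raises(ValueError, match="5 paced"):
            generate_ca_trace(CaSimParams(caffeine_time=4.0))
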