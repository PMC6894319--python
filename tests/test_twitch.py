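import numpy as np
import pandas as pd
import pytest

from hectpipe.mechanics import DataError, ForceTrace, TissueGeometry
from hectpipe.synthetic import TwitchSimParams, generate_twitch_trace, twitch_kernel
from hectpipe.twitch import (
    TwitchConfig,
    analyze_trace,
    detect_twitches,
    fold_change_vs_control,
    summarize_recording,
)


def kernel_oracle(amplitude=10.0, ttp=0.2, tau=0.35, onset_frac=0.05, dt=1e-6):
    """Analytic twitch metrics from a densely evaluated kernel."""
    t = np.arange(0.0, 4.0, dt)
    g = amplitude * twitch_kernel(t, ttp, tau)
    d = np.gradient(g, dt)
    i_peak = int(g.argmax())
    onset = t[np.argmax(g > onset_frac * amplitude)]
    rt50 = t[i_peak + np.argmax(g[i_peak:] <= 0.5 * amplitude)] - t[i_peak]
    rt90 = t[i_peak + np.argmax(g[i_peak:] <= 0.1 * amplitude)] - t[i_peak]
    return {
        "df_un": amplitude,
        "dfdt_max_un_per_s": d.max(),
        "dfdt_min_un_per_s": d.min(),
        "ttp_s": t[i_peak] - onset,
        "rt50_s": rt50,
        "rt90_s": rt90,
    }


class TestDetection:
    def test_clean_trace_yields_fifteen_segments_at_truth(self, clean_paced_sim, fine_cfg):
        segments = detect_twitches(clean_paced_sim.trace, fine_cfg)
        assert len(segments) == 15
        fs = clean_paced_sim.trace.sampling_rate
        peak_times = clean_paced_sim.trace.time_s[[s.i_peak for s in segments]]
        expected = clean_paced_sim.beat_times + clean_paced_sim.params.time_to_peak
        np.testing.assert_allclose(peak_times, expected, atol=1.5 / fs)

    def test_flat_trace_yields_empty_list(self):
        t = np.arange(0, 10, 0.01)
        trace = ForceTrace(time_s=t, force_un=np.full_like(t, 3.0))
        assert detect_twitches(trace) == []

    def test_short_trace_rejected(self):
        t = np.arange(0, 1, 0.01)
        with pytest.raises(DataError):
            detect_twitches(ForceTrace(time_s=t, force_un=np.zeros_like(t)))

    def test_segments_ordered_and_disjoint(self, clean_paced_sim, fine_cfg):
        segments = detect_twitches(clean_paced_sim.trace, fine_cfg)
        for a, b in zip(segments, segments[1:]):
            assert a.i_onset < a.i_peak < a.i_end
            assert a.i_end <= b.i_onset

    def test_high_snr_detection_nearly_perfect(self):
        # amplitude/noise = 20; onsets matched within +/-50 ms against the
        # generator ground truth, excluding twitches clipped by the window
        sens, prec = [], []
        for seed in range(100):
            params = TwitchSimParams(
                spontaneous_rate=0.39,
                interval_cv=0.14,
                amplitude_mean=10.0,
                amplitude_cv=0.1,
                noise_sd=0.5,
                seed=seed,
            )
            sim = generate_twitch_trace(params)
            detected = np.array([tw.t_onset for tw in analyze_trace(sim.trace)])
            t_max = params.duration - (params.time_to_peak + 2 * params.relax_tau)
            truth = sim.beat_times[sim.beat_times < t_max]
            tp = sum(1 for bt in truth if detected.size and np.min(np.abs(detected - bt)) < 0.05)
            fp = sum(1 for d in detected if np.min(np.abs(sim.beat_times - d)) > 0.05)
            sens.append(tp / truth.size)
            prec.append((detected.size - fp) / detected.size)
        assert np.mean(sens) >= 0.99
        assert np.mean(prec) >= 0.99


@pytest.fixture(scope="module")
def slow_paced():
    # 0.25 Hz pacing at fine sampling: full relaxation between twitches
    return generate_twitch_trace(
        TwitchSimParams(
            mode="paced",
            pace_freq=0.25,
            amplitude_mean=10.0,
            amplitude_cv=0.0,
            noise_sd=0.0,
            baseline_force=20.0,
            sampling_rate=2000.0,
            seed=0,
        )
    )


class TestMetrics:

    def test_noise_free_metrics_match_analytic_kernel(self, slow_paced, fine_cfg):
        tw = analyze_trace(slow_paced.trace, fine_cfg)[3]
        oracle = kernel_oracle()
        assert tw.df_un == pytest.approx(oracle["df_un"], rel=0.01)
        assert tw.passive_force_un == pytest.approx(20.0, abs=0.2)
        assert tw.dfdt_max_un_per_s == pytest.approx(oracle["dfdt_max_un_per_s"], rel=0.01)
        assert tw.dfdt_min_un_per_s == pytest.approx(oracle["dfdt_min_un_per_s"], rel=0.01)
        assert tw.ttp_s == pytest.approx(oracle["ttp_s"], rel=0.01)
        assert tw.rt50_s == pytest.approx(oracle["rt50_s"], rel=0.01)
        assert tw.rt90_s == pytest.approx(oracle["rt90_s"], rel=0.01)

    def test_offset_invariance_and_passive_shift(self, slow_paced, fine_cfg):
        base = analyze_trace(slow_paced.trace, fine_cfg)[2]
        shifted_trace = ForceTrace(
            time_s=slow_paced.trace.time_s.copy(),
            force_un=slow_paced.trace.force_un + 5.0,
        )
        shifted = analyze_trace(shifted_trace, fine_cfg)[2]
        assert shifted.df_un == pytest.approx(base.df_un, rel=1e-6)
        assert shifted.ttp_s == pytest.approx(base.ttp_s, abs=1e-3)
        assert shifted.rt50_s == pytest.approx(base.rt50_s, abs=1e-3)
        assert shifted.passive_force_un == pytest.approx(base.passive_force_un + 5.0, rel=1e-6)

    def test_force_scaling_equivariance(self, slow_paced, fine_cfg):
        base = analyze_trace(slow_paced.trace, fine_cfg)[2]
        scaled_trace = ForceTrace(
            time_s=slow_paced.trace.time_s.copy(),
            force_un=slow_paced.trace.force_un * 3.0,
        )
        scaled = analyze_trace(scaled_trace, fine_cfg)[2]
        assert scaled.df_un == pytest.approx(3 * base.df_un, rel=1e-6)
        assert scaled.dfdt_max_un_per_s == pytest.approx(3 * base.dfdt_max_un_per_s, rel=1e-6)
        assert scaled.dfdt_min_un_per_s == pytest.approx(3 * base.dfdt_min_un_per_s, rel=1e-6)
        assert scaled.ttp_s == pytest.approx(base.ttp_s, abs=1e-3)

    def test_time_reversal_swaps_rates_of_symmetric_twitch(self, fine_cfg):
        fs = 1000.0
        t = np.arange(0, 6, 1 / fs)
        pulse = np.exp(-((t - 3.0) ** 2) / (2 * 0.15**2))
        trace = ForceTrace(time_s=t, force_un=10 * pulse)
        rev = ForceTrace(time_s=t, force_un=10 * pulse[::-1])
        tw_f = analyze_trace(trace, fine_cfg)[0]
        tw_r = analyze_trace(rev, fine_cfg)[0]
        assert tw_f.dfdt_max_un_per_s == pytest.approx(-tw_r.dfdt_min_un_per_s, rel=1e-3)
        assert tw_f.dfdt_min_un_per_s == pytest.approx(-tw_r.dfdt_max_un_per_s, rel=1e-3)


class TestSummary:
    def test_summary_aggregates_and_attaches_stress(self, clean_paced_sim, fine_cfg):
        geom = TissueGeometry(1.0)
        summary = summarize_recording(clean_paced_sim.trace, geom, fine_cfg)
        assert summary.valid and summary.n_twitches == 15
        assert summary.means["df_un"] == pytest.approx(10.0, rel=0.01)
        assert summary.sds["df_un"] == pytest.approx(0.0, abs=0.05)
        csa = geom.cross_sectional_area_mm2
        assert summary.developed_stress_un_per_mm2 == pytest.approx(
            summary.means["df_un"] / csa
        )

    def test_flat_recording_flagged_invalid(self):
        t = np.arange(0, 30, 0.01)
        summary = summarize_recording(ForceTrace(time_s=t, force_un=np.full_like(t, 2.0)))
        assert not summary.valid and summary.n_twitches == 0


class TestFoldChange:
    def test_day_matched_normalization(self):
        frame = pd.DataFrame(
            {
                "group": ["control"] * 3 + ["treated"],
                "day": [6, 6, 6, 6],
                "value": [2.0, 2.0, 2.0, 4.0],
            }
        )
        out = fold_change_vs_control(frame)
        assert out.loc[out["group"] == "treated", "fold_change"].iloc[0] == pytest.approx(2.0)
        np.testing.assert_allclose(out.loc[out["group"] == "control", "fold_change"], 1.0)

    def test_scale_invariance(self, rng):
        frame = pd.DataFrame(
            {
                "group": ["control", "control", "treated", "treated"] * 2,
                "day": [6] * 4 + [8] * 4,
                "value": rng.uniform(1, 5, 8),
            }
        )
        a = fold_change_vs_control(frame)["fold_change"]
        frame2 = frame.assign(value=frame["value"] * 7.3)
        b = fold_change_vs_control(frame2)["fold_change"]
        np.testing.assert_allclose(a, b)

    def test_missing_day_control_errors(self):
        frame = pd.DataFrame({"group": ["treated"], "day": [8], "value": [1.0]})
        with pytest.raises(DataError, match="day 8"):
            fold_change_vs_control(frame)

    def test_group_df_ratio_recovery(self):
        # groups generated at a true developed-force ratio of 2.1
        vals = []
        for group, amp, n in (("control", 10.0, 15), ("treated", 21.0, 15)):
            for i in range(n):
                sim = generate_twitch_trace(
                    TwitchSimParams(
                        mode="paced",
                        pace_freq=0.75,
                        amplitude_mean=amp,
                        amplitude_cv=0.1,
                        noise_sd=0.3,
                        seed=1000 + i if group == "control" else 2000 + i,
                    )
                )
                summary = summarize_recording(sim.trace)
                vals.append({"group": group, "day": 6, "value": summary.means["df_un"]})
        out = fold_change_vs_control(pd.DataFrame(vals))
        treated = out.loc[out["group"] == "treated", "fold_change"]
        assert treated.mean() == pytest.approx(2.1, rel=0.05)
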