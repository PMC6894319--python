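# hectpipe

Analysis pipeline for engineered cardiac tissue (hECT) experiments:
twitch-force signal processing, beat-rate variability, force–frequency
regression, fiber-orientation circular statistics, image quantification,
and targeted gene-panel statistics — together with synthetic-data
generators that produce every raw input with known ground truth, so the
whole pipeline is verifiable by parameter recovery without any external
download.

It is written for labs that measure contractility of muscle strips
suspended between flexible posts: the posts act as cantilever force
sensors (`F = k·δ`, `k = 3EI/L³`), and a 30-s recording per tissue yields
developed force (DF), developed stress (DS = DF/CSA), maximum contraction
and relaxation rates (±dF/dt), passive force, and twitch timing
(TTP, RT50, RT90). Spontaneous recordings add beat rate, its coefficient
of variation (COV = SD/mean of inter-beat intervals) and Poincaré
SD1/SD2; paced recordings add 1:1-capture detection and the
force–frequency relationship (per-tissue DF normalized to 0.25 Hz,
group slope by pooled OLS, slope comparison via a group×frequency
interaction). Structural images are quantified with a structure-tensor
orientation field in 7×7-pixel subregions and axial circular statistics
(CSD = (180/π)·½·√(2(1−r)), 0° aligned → 40.5° random). Gene panels are
normalized to housekeeping genes (geometric mean) and to TNNT2, tested
per gene (Student t, BH q alongside), and linked to contractile metrics
by NIPALS partial least squares regression with correlation loadings and
leave-one-out predictability R².

See `docs/methods.md` for the models, defaults, and numerical choices.

## Worked example

Simulate a spontaneous recording (true DF 10 µN, rate 0.39 Hz, interval
CV 0.14, noise 0.5 µN) and analyze it:

```python
from hectpipe.synthetic import TwitchSimParams, generate_twitch_trace
from hectpipe.twitch import summarize_recording
from hectpipe.rhythm import beat_series, poincare_pairs
from hectpipe.mechanics import TissueGeometry

sim = generate_twitch_trace(TwitchSimParams(
    mode="spontaneous", spontaneous_rate=0.39, interval_cv=0.14,
    amplitude_mean=10.0, noise_sd=0.5, seed=7))
summary = summarize_recording(sim.trace, TissueGeometry(diameter_mm=0.6))
series = beat_series(summary.peak_times, sim.trace.duration)
pc = poincare_pairs(series)
```

which prints (via the fields shown):

```
twitches detected : 11
developed force   : 10.01 +/- 0.81 uN
+dF/dt            : 107.0 uN/s
-dF/dt            : -49.4 uN/s
developed stress  : 35.4 uN/mm^2
beat rate         : 0.399 Hz   COV 0.093
Poincare SD1/SD2  : 0.233 / 0.244 s
```

The detector found all 11 simulated twitches; the mean developed force
matches the generating 10 µN; the beat rate matches the generating
0.39 Hz; the COV of 0.093 is this particular 10-interval sample's true
variability (short windows scatter around the generating 0.14). The
−dF/dt sign is the stored convention — magnitudes are compared in group
tables.

A full two-group study (traces, images, panel counts → per-recording
metrics, day-matched group comparisons, FFR slopes, image and panel
statistics) runs from the shell:

```sh
hectpipe simulate --seed 11 --out raw/
hectpipe analyze --manifest raw/manifest.tsv --seed 11 --out results/
hectpipe report --in results/
```

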