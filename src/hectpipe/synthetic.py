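"""Synthetic raw-data generators with known ground truth.

Every raw input the pipeline consumes can be generated here with known
parameters, so each analysis stage is tested by parameter recovery:

* twitch force traces (spontaneous or field-paced), built from a unimodal
  double-exponential twitch kernel on a resting baseline, with per-beat
  amplitude variability, interval variability, Gaussian noise and linear
  drift;
* oriented-texture images emulating collagen-fiber micrographs, built by
  superposing line segments at angles drawn from an axial von Mises
  distribution;
* two-channel particle images (all nuclei vs a labeled subset) of
  non-overlapping discs;
* targeted gene-panel count tables with negative-binomial noise,
  per-sample library-size factors, and configurable group fold changes;
* per-tissue force-frequency measurement sets with a configurable true
  slope of the normalized force-frequency relation.

All generators take a mandatory integer seed and are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .mechanics import ForceTrace, ParameterError

__all__ = [
    "TwitchSimParams",
    "FiberSimParams",
    "PanelGene",
    "PanelSimParams",
    "SimulatedTrace",
    "twitch_kernel",
    "rise_tau_for_peak_time",
    "generate_twitch_trace",
    "generate_fiber_image",
    "generate_particle_image",
    "generate_panel_counts",
    "generate_ffr_measurements",
    "DEFAULT_PANEL_GENES",
]

# Spontaneous beat intervals are floored here (seconds) so that sampled
# intervals can never produce overlapping twitches; a bounded refractory
# period is physiological.
_MIN_INTERVAL_S = 0.2


# ---------------------------------------------------------------------------
# Twitch traces
# ---------------------------------------------------------------------------

def rise_tau_for_peak_time(time_to_peak: float, relax_tau: float) -> float:
    """Rise time-constant of the double-exponential kernel whose peak falls
    at ``time_to_peak`` given decay constant ``relax_tau``.

    The kernel ``g(t) = (1 - exp(-t/a)) * exp(-t/b)`` peaks at
    ``t* = a * ln(1 + b/a)``, which increases monotonically from 0 (a -> 0)
    to b (a -> inf); a peak time is therefore representable iff
    ``0 < time_to_peak < relax_tau``.
    """
    if not 0 < time_to_peak < relax_tau:
        raise ParameterError("time_to_peak must lie in (0, relax_tau)")

    def peak_time(a: float) -> float:
        return a * math.log1p(relax_tau / a) - time_to_peak

    return brentq(peak_time, 1e-9, 1e6, xtol=1e-12, rtol=1e-14)


def twitch_kernel(t: np.ndarray, time_to_peak: float, relax_tau: float) -> np.ndarray:
    """Unit-amplitude twitch waveform.

    Product of a rising and a decaying exponential, scaled so the maximum
    is exactly 1 and occurs at ``time_to_peak``; zero for t < 0.
    """
    a = rise_tau_for_peak_time(time_to_peak, relax_tau)
    t = np.asarray(t, dtype=float)
    g = np.where(t >= 0, (1.0 - np.exp(-np.maximum(t, 0.0) / a)) * np.exp(-np.maximum(t, 0.0) / relax_tau), 0.0)
    # at the stationary point exp(-t*/a) = a/(a+b), so the peak value has a
    # closed form used for exact normalization
    peak_value = (relax_tau / (a + relax_tau)) * math.exp(-time_to_peak / relax_tau)
    return g / peak_value


@dataclass(frozen=True)
class TwitchSimParams:
    """Parameters of a simulated 30-s contractility recording.

    Defaults emulate a spontaneously beating control tissue: resting
    (passive) force offset 20 uN relative to the fabrication reference,
    developed force ~10 uN per twitch, spontaneous rate 0.39 Hz with
    interval coefficient of variation 0.14.
    """

    sampling_rate: float = 100.0          # Hz
    duration: float = 30.0                # s
    baseline_force: float = 20.0          # uN, passive offset vs fabrication zero
    amplitude_mean: float = 10.0          # uN developed force per twitch
    amplitude_cv: float = 0.1
    time_to_peak: float = 0.20            # s
    relax_tau: float = 0.35               # s
    mode: Literal["spontaneous", "paced"] = "spontaneous"
    spontaneous_rate: float = 0.39        # Hz
    interval_cv: float = 0.14
    pace_freq: Optional[float] = None     # Hz
    capture_ratio: int = 1                # 1 twitch per n stimuli
    noise_sd: float = 0.2                 # uN
    drift_per_s: float = 0.0              # uN/s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0 or self.duration <= 0:
            raise ParameterError("sampling_rate and duration must be positive")
        if self.amplitude_mean < 0 or self.amplitude_cv < 0:
            raise ParameterError("amplitude parameters must be non-negative")
        if self.interval_cv < 0 or self.noise_sd < 0:
            raise ParameterError("interval_cv and noise_sd must be non-negative")
        if self.capture_ratio < 1:
            raise ParameterError("capture_ratio must be >= 1")
        if self.mode == "paced" and (self.pace_freq is None or self.pace_freq <= 0):
            raise ParameterError("paced mode requires a positive pace_freq")
        if self.mode == "spontaneous" and self.spontaneous_rate <= 0:
            raise ParameterError("spontaneous mode requires a positive rate")


@dataclass
class SimulatedTrace:
    """A generated force trace together with its ground truth."""

    trace: ForceTrace
    beat_times: np.ndarray      # twitch onset times, s
    amplitudes: np.ndarray      # per-twitch developed force, uN
    params: TwitchSimParams


def _beat_times(params: TwitchSimParams, rng: np.random.Generator) -> np.ndarray:
    if params.mode == "paced":
        n_stimuli = int(math.floor(params.duration * params.pace_freq))
        stim = np.arange(n_stimuli) / params.pace_freq
        return stim[:: params.capture_ratio]
    mean_interval = 1.0 / params.spontaneous_rate
    sd = params.interval_cv * mean_interval
    times = []
    # first beat after one (jittered) interval so no twitch is clipped at t=0
    t = max(rng.normal(mean_interval, sd), _MIN_INTERVAL_S)
    while t < params.duration:
        times.append(t)
        t += max(rng.normal(mean_interval, sd), _MIN_INTERVAL_S)
    return np.asarray(times)


def generate_twitch_trace(params: TwitchSimParams) -> SimulatedTrace:
    """Simulate a force recording as baseline + sum of twitch kernels.

    Each beat i contributes ``A_i * g(t - t_i)`` where ``g`` is the
    unit-amplitude kernel of :func:`twitch_kernel`; Gaussian measurement
    noise and a linear drift are added on top.  Ground-truth beat times
    and amplitudes are returned alongside the trace.
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration * params.sampling_rate))
    t = np.arange(n) / params.sampling_rate

    beat_times = _beat_times(params, rng)
    if params.amplitude_cv > 0:
        amplitudes = params.amplitude_mean * np.maximum(
            rng.normal(1.0, params.amplitude_cv, size=beat_times.size), 0.0
        )
    else:
        amplitudes = np.full(beat_times.size, params.amplitude_mean)

    force = np.full(n, params.baseline_force, dtype=float)
    if params.amplitude_mean > 0 and beat_times.size:
        kernel_support = params.time_to_peak + 12.0 * params.relax_tau
        for t_i, a_i in zip(beat_times, amplitudes):
            i0 = int(math.ceil(t_i * params.sampling_rate))
            i1 = min(n, int(math.ceil((t_i + kernel_support) * params.sampling_rate)))
            if i0 >= n:
                continue
            force[i0:i1] += a_i * twitch_kernel(t[i0:i1] - t_i, params.time_to_peak, params.relax_tau)
    force += params.drift_per_s * t
    if params.noise_sd > 0:
        force += rng.normal(0.0, params.noise_sd, size=n)

    meta = {
        "pacing_mode": params.mode,
        "pacing_hz": params.pace_freq if params.mode == "paced" else None,
        "duration_s": params.duration,
    }
    return SimulatedTrace(
        trace=ForceTrace(time_s=t, force_un=force, metadata=meta),
        beat_times=beat_times,
        amplitudes=amplitudes,
        params=params,
    )


# ---------------------------------------------------------------------------
# Oriented-texture and particle images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FiberSimParams:
    """Parameters of a synthetic fiber-texture image.

    ``dispersion`` is the von Mises concentration kappa applied on doubled
    angles (the standard axial-data device); kappa = 0 gives uniformly
    random orientations, large kappa approaches a single angle.
    """

    image_size: int = 128                 # pixels, square
    mean_angle: float = 0.0               # degrees in (-90, 90], 0 = horizontal
    dispersion: float = 5.0               # von Mises kappa on doubled angles
    texture_wavelength: float = 8.0       # typical fiber spacing/length scale, px
    n_fibers: int = 400
    noise_sd: float = 0.02                # intensity units (image max ~1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 16:
            raise ParameterError("image_size must be >= 16")
        if self.dispersion < 0:
            raise ParameterError("dispersion must be >= 0")


def sample_axial_angles(
    mean_angle_deg: float, kappa: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw axial angles (degrees in (-90, 90]) from a von Mises
    distribution on doubled angles centred at ``2 * mean_angle``."""
    if kappa == 0:
        doubled = rng.uniform(-math.pi, math.pi, size)
    else:
        doubled = rng.vonmises(math.radians(2.0 * mean_angle_deg), kappa, size)
    angles = np.degrees(doubled) / 2.0
    return fold_axial(angles)


def fold_axial(angles_deg: np.ndarray) -> np.ndarray:
    """Fold angles into the axial range (-90, 90]."""
    folded = np.mod(np.asarray(angles_deg, dtype=float) + 90.0, 180.0) - 90.0
    return np.where(folded == -90.0, 90.0, folded)


def generate_fiber_image(params: FiberSimParams) -> tuple[np.ndarray, np.ndarray]:
    """Render an oriented texture by superposing line segments.

    Each segment is drawn at an angle sampled from the axial von Mises
    distribution, with a Gaussian intensity profile across its width.
    Angles are measured counterclockwise from the image x-axis with y
    pointing up (so a horizontal fiber is 0 deg, vertical is 90 deg),
    matching the orientation-analysis convention.

    Returns ``(image, true_angles_deg)``.
    """
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(params.seed)
    size = params.image_size
    img = np.zeros((size, size), dtype=float)
    angles = sample_axial_angles(params.mean_angle, params.dispersion, params.n_fibers, rng)
    half_len = 1.5 * params.texture_wavelength
    n_pts = max(int(4 * half_len), 8)
    s = np.linspace(-half_len, half_len, n_pts)
    for theta in angles:
        cx, cy = rng.uniform(0, size, 2)
        dx = math.cos(math.radians(theta))
        dy = -math.sin(math.radians(theta))  # row index grows downward
        rows = cy + s * dy
        cols = cx + s * dx
        keep = (rows >= 0) & (rows < size - 1) & (cols >= 0) & (cols < size - 1)
        rows, cols = rows[keep], cols[keep]
        # bilinear splatting keeps the rendered line free of stair-step
        # artifacts that would bias gradient orientations
        r0 = np.floor(rows).astype(int)
        c0 = np.floor(cols).astype(int)
        fr = rows - r0
        fc = cols - c0
        np.add.at(img, (r0, c0), (1 - fr) * (1 - fc))
        np.add.at(img, (r0, c0 + 1), (1 - fr) * fc)
        np.add.at(img, (r0 + 1, c0), fr * (1 - fc))
        np.add.at(img, (r0 + 1, c0 + 1), fr * fc)
    img = gaussian_filter(img, sigma=max(params.texture_wavelength / 8.0, 0.6))
    if img.max() > 0:
        img /= img.max()
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, img.shape)
    return img, angles


def generate_particle_image(
    n_nuclei: int,
    labeled_fraction: float,
    radius: float = 4.0,
    image_size: int = 256,
    seed: int = 0,
    max_tries: int = 20000,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-channel particle image: all nuclei, and a labeled subset.

    Places ``n_nuclei`` non-overlapping discs of the given radius by
    rejection sampling; exactly ``round(labeled_fraction * n_nuclei)`` of
    them are copied into the label channel.  Raises a ``ParameterError``
    if the packing cannot be realised within the retry budget.
    """
    if not 0.0 <= labeled_fraction <= 1.0:
        raise ParameterError("labeled_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    centers: list[tuple[float, float]] = []
    tries = 0
    # a 2-px moat keeps rasterized discs from touching even diagonally
    min_sep2 = (2.0 * radius + 3.0) ** 2
    while len(centers) < n_nuclei:
        tries += 1
        if tries > max_tries:
            raise ParameterError(
                f"could not place {n_nuclei} non-overlapping discs of radius "
                f"{radius} in a {image_size}x{image_size} image"
            )
        x = rng.uniform(radius + 1, image_size - radius - 1)
        y = rng.uniform(radius + 1, image_size - radius - 1)
        if all((x - cx) ** 2 + (y - cy) ** 2 >= min_sep2 for cx, cy in centers):
            centers.append((x, y))

    yy, xx = np.mgrid[0:image_size, 0:image_size]
    nuclei = np.zeros((image_size, image_size), dtype=float)
    label = np.zeros_like(nuclei)
    n_labeled = int(round(labeled_fraction * n_nuclei))
    labeled_idx = set(rng.choice(n_nuclei, size=n_labeled, replace=False).tolist()) if n_labeled else set()
    for i, (cx, cy) in enumerate(centers):
        disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
        nuclei[disc] = 1.0
        if i in labeled_idx:
            label[disc] = 1.0
    return nuclei, label


# ---------------------------------------------------------------------------
# Gene-panel counts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelGene:
    symbol: str
    gene_class: Literal["endogenous", "housekeeping"]
    baseline_mean: float
    fold_change: float = 1.0

    def __post_init__(self) -> None:
        if self.baseline_mean <= 0:
            raise ParameterError(f"baseline mean for {self.symbol} must be positive")
        if self.gene_class == "housekeeping" and self.fold_change != 1.0:
            raise ParameterError("housekeeping genes must have fold change 1")


# Endogenous panel patterned on the published 59-gene myocardial codeset:
# treated-vs-control fold changes as reported, plus the five reference
# genes and the cardiac normalizer TNNT2 (fold 1 by construction).
_TABLE_FOLDS = {
    "ACTA1": 2.35, "ACTA2": 1.17, "ACTN2": 1.00, "ADRB1": 1.39, "ADRB2": 1.35,
    "ADRB3": 0.84, "AGTR1": 0.34, "ATP2A2": 0.95, "BAX": 1.11, "BCL2": 0.57,
    "BCL2L1": 1.08, "BCL2L2": 0.88, "CACNA1C": 1.06, "CASP3": 0.79, "CASP8": 0.70,
    "CASP9": 1.05, "CASQ2": 0.49, "CD34": 1.15, "CD44": 2.28, "CDK1": 0.39,
    "CNTN2": 0.53, "COL1A1": 2.18, "COL3A1": 1.74, "CTGF": 1.13, "DDR2": 0.86,
    "ENG": 2.04, "GATA4": 1.25, "GJA1": 0.88, "GJA5": 0.58, "HCN1": 0.40,
    "HCN2": 1.43, "HCN3": 0.95, "HCN4": 1.16, "IRX4": 0.96, "JUP": 1.01,
    "KCNH2": 1.12, "KCNQ1": 1.87, "MESP1": 2.34, "MYC": 1.73, "MYH6": 0.74,
    "MYH7": 1.24, "MYL2": 1.53, "MYL7": 0.69, "NFATC1": 2.19, "NKX2-5": 1.19,
    "NPPA": 1.78, "NPPB": 1.64, "PECAM1": 1.55, "PLN": 1.37, "POSTN": 3.82,
    "RYR2": 0.82, "SLC8A1": 1.09, "TGFB1": 2.14, "TNNI1": 0.98, "TNNI3": 1.90,
    "TNNT2": 1.00, "TP53": 1.01, "VIM": 0.86, "WT1": 0.56,
}
_HOUSEKEEPING = ("B2M", "EEF1A1", "GAPDH", "RNPS1", "SRP14")

DEFAULT_PANEL_GENES: tuple[PanelGene, ...] = tuple(
    [PanelGene(sym, "housekeeping", 8000.0) for sym in _HOUSEKEEPING]
    + [
        PanelGene(sym, "endogenous", 20000.0 if sym == "TNNT2" else 1500.0, fc)
        for sym, fc in _TABLE_FOLDS.items()
    ]
)


@dataclass(frozen=True)
class PanelSimParams:
    """Parameters of a synthetic two-group gene-panel count table.

    Counts are negative-binomial with mean
    ``baseline * fold_change^{group} * size_factor`` and variance
    ``m + dispersion * m^2``; size factors are log-normal with the given
    coefficient of variation, emulating per-sample library-size /
    hybridization-efficiency differences.
    """

    gene_table: Sequence[PanelGene] = DEFAULT_PANEL_GENES
    nb_dispersion: float = 0.05
    library_size_cv: float = 0.15
    n_per_group: int = 3
    group_names: tuple[str, str] = ("control", "treated")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nb_dispersion < 0 or self.library_size_cv < 0:
            raise ParameterError("dispersion and library_size_cv must be >= 0")
        if self.n_per_group < 2:
            raise ParameterError("n_per_group must be >= 2")


def generate_panel_counts(params: PanelSimParams):
    """Simulate a genes x samples count matrix; see :class:`PanelSimParams`.

    With ``nb_dispersion == 0`` and ``library_size_cv == 0`` the output is
    deterministic: counts equal the rounded means.

    Returns a :class:`~hectpipe.genepanel.PanelMatrix` whose metadata
    records the ground-truth fold changes and size factors.
    """
    from .genepanel import PanelMatrix

    rng = np.random.default_rng(params.seed)
    genes = list(params.gene_table)
    n = params.n_per_group
    sample_names = [f"{g}_{i+1}" for g in params.group_names for i in range(n)]
    groups = pd.Series(
        [params.group_names[0]] * n + [params.group_names[1]] * n, index=sample_names
    )

    if params.library_size_cv > 0:
        sigma = math.sqrt(math.log1p(params.library_size_cv**2))
        size_factors = rng.lognormal(-sigma**2 / 2.0, sigma, size=2 * n)
    else:
        size_factors = np.ones(2 * n)

    counts = np.zeros((len(genes), 2 * n))
    for gi, gene in enumerate(genes):
        means = np.array(
            [
                gene.baseline_mean
                * (gene.fold_change if groups.iloc[si] == params.group_names[1] else 1.0)
                * size_factors[si]
                for si in range(2 * n)
            ]
        )
        if params.nb_dispersion == 0:
            counts[gi] = np.rint(means)
        else:
            nb_n = 1.0 / params.nb_dispersion
            nb_p = nb_n / (nb_n + means)
            counts[gi] = rng.negative_binomial(nb_n, nb_p)

    frame = pd.DataFrame(counts, index=[g.symbol for g in genes], columns=sample_names)
    classes = pd.Series({g.symbol: g.gene_class for g in genes})
    truth = {
        "fold_changes": {g.symbol: g.fold_change for g in genes},
        "size_factors": dict(zip(sample_names, size_factors.tolist())),
    }
    return PanelMatrix(counts=frame, gene_classes=classes, groups=groups, metadata={"truth": truth})


# ---------------------------------------------------------------------------
# Force-frequency measurement sets
# ---------------------------------------------------------------------------

def generate_ffr_measurements(
    true_slope: float,
    n_tissues: int,
    frequencies: Sequence[float] = (0.25, 0.5, 0.75, 1.0),
    base_df_mean: float = 10.0,
    base_df_cv: float = 0.3,
    noise_sd: float = 0.1,
    group: str = "control",
    seed: int = 0,
) -> pd.DataFrame:
    """Per-tissue developed-force measurements across pacing frequencies.

    The ground truth is the slope of the *normalized* force-frequency
    relation: each tissue's expected developed force is
    ``base_t * (1 + true_slope * (f - f0))`` with ``f0`` the lowest pacing
    frequency, multiplicative tissue-to-tissue base variability, and
    additive relative noise of standard deviation ``noise_sd`` per point.

    Returns a long DataFrame with columns tissue, group, pace_freq_hz, df_un.
    """
    rng = np.random.default_rng(seed)
    f0 = min(frequencies)
    rows = []
    for ti in range(n_tissues):
        base = base_df_mean * max(rng.normal(1.0, base_df_cv), 0.1)
        for f in frequencies:
            expected = 1.0 + true_slope * (f - f0)
            value = base * max(expected + rng.normal(0.0, noise_sd), 0.02)
            rows.append(
                {"tissue": f"{group}_t{ti+1}", "group": group, "pace_freq_hz": f, "df_un": value}
            )
    return pd.DataFrame(rows)
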