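"""Batch orchestration: simulate a study, analyze a manifest, report.

A study follows the contractility-testing protocol: tissues from two
groups are recorded for 30 s without stimulation (spontaneous rate and
beat-rate variability) and under field pacing at 0.25-1.0 Hz in 0.25-Hz
increments (12-V biphasic, 5-ms pulses — stored as protocol metadata);
fiber-texture and particle images and a gene-panel count table complete
the inputs.  Analysis runs mechanics → twitch → rhythm → force-frequency
per recording, image quantification per image, and panel statistics per
count table, then aggregates per-day group comparisons with day-matched
control normalization.  All randomness flows from the single study seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .ffr import build_ffr, compare_slopes, ffr_slope
from .fiberimage import (
    OrientationConfig,
    circular_stats,
    labeled_percentage,
    orientation_field,
)
from .genepanel import differential_expression, isoform_ratio, normalize_panel
from .mechanics import DataError, PostSpec, TissueGeometry
from .rhythm import CaptureConfig, InsufficientDataError, beat_series, detect_capture, poincare_pairs
from .stats import two_group_test
from .synthetic import (
    FiberSimParams,
    PanelSimParams,
    TwitchSimParams,
    generate_fiber_image,
    generate_panel_counts,
    generate_particle_image,
    generate_twitch_trace,
)
from .twitch import TwitchConfig, fold_change_vs_control, summarize_recording

log = logging.getLogger("hectpipe")

__all__ = ["StudyConfig", "simulate_study", "run_study", "write_report"]


@dataclass
class StudyConfig:
    """Study-level configuration; loadable from a YAML file."""

    seed: int = 0
    groups: tuple[str, str] = ("control", "treated")
    n_per_group: int = 6
    days: tuple[int, ...] = (6, 8, 10)
    pacing_frequencies_hz: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0)
    pulse_description: str = "12-V biphasic, 5-ms duration"
    post_k_un_per_um: float = 0.5
    diameter_mm: float = 0.6
    control_df_un: float = 10.0
    treated_df_fold: float = 2.1
    spontaneous_rate_hz: float = 0.39
    interval_cv: float = 0.14
    noise_sd_un: float = 0.2
    sampling_rate_hz: float = 100.0
    duration_s: float = 30.0
    twitch: TwitchConfig = field(default_factory=TwitchConfig)
    capture: CaptureConfig = field(default_factory=CaptureConfig)
    orientation: OrientationConfig = field(default_factory=OrientationConfig)

    def __post_init__(self) -> None:
        if list(self.pacing_frequencies_hz) != sorted(self.pacing_frequencies_hz):
            raise DataError("pacing frequencies must be strictly increasing")
        if list(self.days) != sorted(set(self.days)):
            raise DataError("days must be strictly increasing")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for fld in dataclasses.fields(cls):
            if fld.name not in raw:
                continue
            val = raw[fld.name]
            if fld.name in ("twitch", "capture", "orientation"):
                sub = {"twitch": TwitchConfig, "capture": CaptureConfig, "orientation": OrientationConfig}[fld.name]
                val = sub(**val)
            elif isinstance(val, list):
                val = tuple(val)
            kwargs[fld.name] = val
        return cls(**kwargs)


def simulate_study(config: StudyConfig, out_dir) -> Path:
    """Generate a complete synthetic study under ``out_dir``.

    Writes spontaneous and paced force traces per tissue/day, one fiber
    image and one particle image pair per group, a panel count table, and
    a manifest indexing everything.  Deterministic for a given seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root_rng = np.random.default_rng(config.seed)
    rows = []
    for gi, group in enumerate(config.groups):
        df_mean = config.control_df_un * (config.treated_df_fold if gi == 1 else 1.0)
        for ti in range(config.n_per_group):
            tissue = f"{group}_t{ti+1}"
            diameter = config.diameter_mm * float(root_rng.normal(1.0, 0.05))
            for day in config.days:
                # mild maturation trend over days
                day_scale = 1.0 + 0.05 * (day - config.days[0])
                base = dict(
                    sampling_rate=config.sampling_rate_hz,
                    duration=config.duration_s,
                    amplitude_mean=df_mean * day_scale,
                    noise_sd=config.noise_sd_un,
                )
                spont = generate_twitch_trace(
                    TwitchSimParams(
                        mode="spontaneous",
                        spontaneous_rate=config.spontaneous_rate_hz,
                        interval_cv=config.interval_cv,
                        seed=int(root_rng.integers(2**31 - 1)),
                        **base,
                    )
                )
                name = f"{tissue}_d{day}_spont.tsv"
                hio.write_trace(spont.trace, out / name)
                rows.append((name, "trace", tissue, group, day, "", diameter))
                for freq in config.pacing_frequencies_hz:
                    # control tissues may lose 1:1 capture at high rates
                    lose = gi == 0 and freq >= 0.75 and root_rng.uniform() < 0.3
                    paced = generate_twitch_trace(
                        TwitchSimParams(
                            mode="paced",
                            pace_freq=freq,
                            capture_ratio=2 if lose else 1,
                            amplitude_cv=0.05,
                            seed=int(root_rng.integers(2**31 - 1)),
                            **{**base, "amplitude_mean": base["amplitude_mean"] * (1.0 - 0.6 * (freq - 0.25))},
                        )
                    )
                    name = f"{tissue}_d{day}_p{int(freq*100)}.tsv"
                    hio.write_trace(paced.trace, out / name)
                    rows.append((name, "trace", tissue, group, day, freq, diameter))
        img, _ = generate_fiber_image(
            FiberSimParams(mean_angle=0.0, dispersion=3.0, seed=int(root_rng.integers(2**31 - 1)))
        )
        hio.write_image(img, out / f"{group}_fibers.tif")
        rows.append((f"{group}_fibers.tif", "image", "", group, config.days[0], "", ""))
        nuc, lab = generate_particle_image(
            60, 0.097, image_size=220, seed=int(root_rng.integers(2**31 - 1))
        )
        hio.write_image(nuc, out / f"{group}_nuclei.tif")
        hio.write_image(lab, out / f"{group}_label.tif")
        rows.append((f"{group}_nuclei.tif;{group}_label.tif", "image_pair", "", group, config.days[0], "", ""))
    panel = generate_panel_counts(PanelSimParams(seed=int(root_rng.integers(2**31 - 1))))
    hio.write_panel(panel, out / "panel_counts.tsv")
    rows.append(("panel_counts.tsv", "panel", "", "", config.days[-1], "", ""))

    manifest = pd.DataFrame(rows, columns=list(hio.MANIFEST_COLUMNS))
    hio.write_manifest(manifest, out / "manifest.tsv")
    return out / "manifest.tsv"


def _analyze_traces(manifest: pd.DataFrame, base: Path, config: StudyConfig) -> pd.DataFrame:
    rows = []
    for _, rec in manifest[manifest["kind"] == "trace"].iterrows():
        trace = hio.read_trace(base / rec["path"])
        diameter = float(rec["diameter_mm"]) if rec["diameter_mm"] != "" else config.diameter_mm
        geom = TissueGeometry(diameter_mm=diameter)
        summary = summarize_recording(trace, geom, config.twitch)
        paced = rec["pacing_hz"] not in ("", None) and not pd.isna(rec["pacing_hz"])
        row = {
            "path": rec["path"],
            "tissue": rec["tissue_id"],
            "group": rec["group"],
            "day": int(rec["day"]),
            "pacing_hz": float(rec["pacing_hz"]) if paced else np.nan,
            "valid": summary.valid,
            "n_twitches": summary.n_twitches,
            "ds_un_per_mm2": summary.developed_stress_un_per_mm2,
        }
        if not summary.valid:
            row["exclusion_reason"] = "no_detectable_twitches"
            log.info("excluded %s: no detectable twitches", rec["path"])
            rows.append(row)
            continue
        row.update({k: v for k, v in summary.means.items()})
        if paced:
            try:
                series = beat_series(summary.peak_times, trace.duration)
                row["captured_1to1"] = detect_capture(series, row["pacing_hz"], config.capture).captured_1to1
            except InsufficientDataError:
                row["captured_1to1"] = False
        else:
            try:
                series = beat_series(summary.peak_times, trace.duration)
                poinc = poincare_pairs(series)
                row.update(
                    spont_rate_hz=series.mean_rate_hz,
                    cov=series.cov,
                    sd1=poinc.sd1,
                    sd2=poinc.sd2,
                )
            except InsufficientDataError:
                row["exclusion_reason"] = "too_few_beats"
                log.info("excluded %s: too few beats for rhythm analysis", rec["path"])
        rows.append(row)
    return pd.DataFrame(rows)


def _group_comparisons(recordings: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Day-matched, control-normalized two-group comparisons of paced metrics."""
    ctrl, treat = config.groups
    out = []
    paced = recordings[(recordings["valid"]) & recordings["pacing_hz"].notna()]
    if paced.empty:
        return pd.DataFrame()
    # compare at the lowest common pacing frequency
    freq = paced["pacing_hz"].min()
    paced = paced[np.isclose(paced["pacing_hz"], freq)]
    for metric in ("df_un", "dfdt_max_un_per_s", "dfdt_min_un_per_s", "ds_un_per_mm2", "passive_force_un"):
        if metric not in paced.columns:
            continue
        sub = paced[["group", "day", metric]].rename(columns={metric: "value"}).dropna()
        if metric == "dfdt_min_un_per_s":
            sub["value"] = sub["value"].abs()
        normed = fold_change_vs_control(sub, control_group=ctrl)
        for day, day_rows in normed.groupby("day"):
            a = day_rows.loc[day_rows["group"] == ctrl, "fold_change"]
            b = day_rows.loc[day_rows["group"] == treat, "fold_change"]
            if len(a) < 2 or len(b) < 2:
                log.warning("day %s metric %s: group too small, comparison skipped", day, metric)
                continue
            cmp = two_group_test(a, b, metric=metric)
            out.append(
                {
                    "day": day,
                    "pacing_hz": freq,
                    "metric": metric,
                    f"{ctrl}_mean": cmp.mean_a,
                    f"{ctrl}_sd": cmp.sd_a,
                    f"{treat}_mean": cmp.mean_b,
                    f"{treat}_sd": cmp.sd_b,
                    "t": cmp.t,
                    "p": cmp.p,
                }
            )
    return pd.DataFrame(out)


def run_study(config: StudyConfig, manifest_path, out_dir) -> dict:
    """Analyze every manifest entry and write the report bundle.

    Emits per-recording metrics, per-day group comparisons, the
    force-frequency section, image quantification, and panel statistics,
    plus a machine-readable ``summary.json``.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = hio.read_manifest(manifest_path)
    missing = [p for p in manifest["path"] if not all((base / q).exists() for q in str(p).split(";"))]
    if missing:
        raise DataError(f"manifest files not found: {missing}")

    summary: dict = {"seed": config.seed}
    recordings = _analyze_traces(manifest, base, config)
    if not recordings.empty:
        recordings.to_csv(out / "recordings.csv", index=False)
        comparisons = _group_comparisons(recordings, config)
        if not comparisons.empty:
            comparisons.to_csv(out / "group_comparisons.csv", index=False)
            summary["group_comparisons"] = comparisons.to_dict(orient="records")
        else:
            log.warning("fewer than two groups with data: comparisons skipped")

        spont = recordings[recordings["pacing_hz"].isna() & recordings["valid"]]
        if "cov" in spont.columns and not spont.empty:
            summary["spontaneous"] = (
                spont.groupby(["group", "day"])[["spont_rate_hz", "cov"]]
                .agg(["mean", "std"])
                .round(6)
                .to_dict()
            ) and {
                f"{g}_d{d}": {
                    "rate_hz_mean": float(s["spont_rate_hz"].mean()),
                    "cov_mean": float(s["cov"].mean()),
                    "n": int(len(s)),
                }
                for (g, d), s in spont.groupby(["group", "day"])
            }

        paced = recordings[recordings["pacing_hz"].notna() & recordings["valid"]]
        cap = (
            paced[paced["captured_1to1"].eq(True)]
            if "captured_1to1" in paced.columns
            else paced.iloc[0:0]
        )
        if not cap.empty:
            meas = cap.rename(columns={"pacing_hz": "pace_freq_hz", "df_un": "df_un"})[
                ["tissue", "group", "pace_freq_hz", "df_un"]
            ]
            ffr_data = build_ffr(meas.groupby(["tissue", "group", "pace_freq_hz"], as_index=False).mean())
            for tissue, reason in ffr_data.excluded:
                log.info("FFR: excluded %s (%s)", tissue, reason)
            ffr_section = {"excluded": [list(e) for e in ffr_data.excluded]}
            for group in config.groups:
                if (ffr_data.data["group"] == group).sum() >= 3:
                    res = ffr_slope(ffr_data, group)
                    ffr_section[group] = {
                        "slope_per_hz": res.slope_per_hz,
                        "p_vs_zero": res.p_vs_zero,
                        "n_points": res.n_points,
                    }
            if all(g in ffr_section for g in config.groups):
                ffr_section["p_slope_difference"] = compare_slopes(
                    ffr_data, config.groups[0], config.groups[1]
                )["p_slope_difference"]
            summary["ffr"] = ffr_section

    image_rows = []
    for _, rec in manifest[manifest["kind"] == "image"].iterrows():
        img = hio.read_image(base / rec["path"])
        fld = orientation_field(img, config.orientation)
        cs = circular_stats(fld.angles_deg, fld.weights)
        image_rows.append(
            {
                "path": rec["path"],
                "group": rec["group"],
                "mean_angle_deg": cs.mean_angle_deg,
                "csd_deg": cs.csd_deg,
                "n_blocks": cs.n,
            }
        )
    for _, rec in manifest[manifest["kind"] == "image_pair"].iterrows():
        p_nuc, p_lab = str(rec["path"]).split(";")
        quant = labeled_percentage(hio.read_image(base / p_nuc), hio.read_image(base / p_lab))
        image_rows.append(
            {
                "path": rec["path"],
                "group": rec["group"],
                "count_total": quant.count_total,
                "count_labeled": quant.count_labeled,
                "labeled_percentage": quant.labeled_percentage,
            }
        )
    if image_rows:
        pd.DataFrame(image_rows).to_csv(out / "images.csv", index=False)
        summary["images"] = image_rows

    for _, rec in manifest[manifest["kind"] == "panel"].iterrows():
        pm = hio.read_panel(base / rec["path"])
        normalized = normalize_panel(pm)
        groups = sorted(pm.groups.unique())
        deg = differential_expression(normalized, control_group=groups[0], treated_group=groups[-1])
        deg.to_csv(out / "differential_expression.csv")
        ratios = {}
        for a, b in (("MYH7", "MYH6"), ("MYL2", "MYL7"), ("TNNI3", "TNNI1")):
            if a in normalized.values.index and b in normalized.values.index:
                ratios[f"{a}/{b}"] = isoform_ratio(normalized, a, b)["mean_of_ratios"].to_dict()
        summary["panel"] = {
            "n_genes": int(len(deg)),
            "n_significant": int((deg["p_value"] < 0.05).sum()),
            "isoform_ratios": ratios,
        }

    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    return summary


def write_report(analysis_dir, path=None) -> str:
    """Render a plain-text report from an analysis output directory."""
    analysis_dir = Path(analysis_dir)
    summary = json.loads((analysis_dir / "summary.json").read_text())
    lines = ["hectpipe study report", "=" * 22]
    if "group_comparisons" in summary:
        lines.append("\nPaced contractility (fold change vs day-matched control):")
        for row in summary["group_comparisons"]:
            lines.append(
                f"  day {row['day']} {row['metric']}: treated {row[list(row)[5]]:.3g} "
                f"vs control 1.0, p={row['p']:.4g}"
            )
    if "ffr" in summary:
        lines.append("\nForce-frequency relationship (normalized DF vs pacing rate):")
        for key, val in summary["ffr"].items():
            if isinstance(val, dict) and "slope_per_hz" in val:
                lines.append(
                    f"  {key}: slope {val['slope_per_hz']:.3f} Hz^-1 (p vs 0 = {val['p_vs_zero']:.3g})"
                )
        if "p_slope_difference" in summary["ffr"]:
            lines.append(f"  slope difference p = {summary['ffr']['p_slope_difference']:.3g}")
    if "spontaneous" in summary:
        lines.append("\nSpontaneous rhythm:")
        for key, val in summary["spontaneous"].items():
            lines.append(
                f"  {key}: rate {val['rate_hz_mean']:.3f} Hz, COV {val['cov_mean']:.3f} (n={val['n']})"
            )
    if "panel" in summary:
        lines.append(
            f"\nGene panel: {summary['panel']['n_significant']} of "
            f"{summary['panel']['n_genes']} genes at p<0.05"
        )
        for name, vals in summary["panel"]["isoform_ratios"].items():
            lines.append(f"  {name}: " + ", ".join(f"{g}={v:.2f}" for g, v in vals.items()))
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
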