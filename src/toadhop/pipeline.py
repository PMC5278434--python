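"""End-to-end orchestration: simulate -> analyze -> stats -> report.

Configuration is a single structured mapping (YAML on disk) with
``sim``, ``pipeline`` and ``stats`` sections plus a global seed.  Every
analysis constant — the 5 cm/s initiation threshold, the 3 mm contact
tolerance, the band method, the lift-off acceleration band, dropout
tolerance — is exposed here with its default.  A run writes a manifest
recording the full config, package versions, and SHA-256 checksums of its
outputs, so a run is reproducible from (config, seed) alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .hop_kinematics import (EventDetectionError, build_alignment_band,
                             compute_kinematics, detect_events, hop_metrics,
                             metrics_to_frame)
from .synthetic_hops import HopSimConfig, simulate_cohort, config_to_dict
from .trajectories import (HopRecording, read_recordings, write_recordings)
from . import stats as ths

log = logging.getLogger("toadhop")


@dataclass
class PipelineConfig:
    """Analysis-stage parameters (all units SI, angles in degrees)."""

    smoothing: float | str = "auto"     # spline residual target or "auto"
    speed_threshold: float = 0.05       # m/s; hop-initiation rule
    contact_tolerance: float = 0.003    # m; wrist touchdown tolerance
    liftoff_accel_band: float = 0.15    # fraction of g
    liftoff_min_duration: float = 0.010  # s
    band_method: str = "fixed_halfwidth"  # or "ci_of_mean"
    band_halfwidth: float = 15.0        # deg, fixed_halfwidth only
    band_pooling: str = "all"           # "all" | "treatment" | "animal"
    dropout_tolerance_frames: int = 0
    alignment_min_duration: float = 0.020  # s; sustained band-entry rule


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "toadhop_run"
    sim: HopSimConfig = field(default_factory=HopSimConfig)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    log_level: str = "INFO"


def load_config(path) -> RunConfig:
    """Load a YAML run config; missing keys take their defaults.

    Platform heights may be given in cm under ``sim.treatments_cm``; they
    are converted to metres on load.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim_raw = dict(raw.get("sim", {}))
    if "treatments_cm" in sim_raw:
        sim_raw["treatments"] = {
            k: float(v) / 100.0 for k, v in sim_raw.pop("treatments_cm").items()
        }
    for key in ("hops_per_treatment", "takeoff_speed", "takeoff_angle",
                "snout_to_humerus_offset"):
        if key in sim_raw:
            sim_raw[key] = tuple(sim_raw[key])
    sim = HopSimConfig(**sim_raw)
    pipe = PipelineConfig(**raw.get("pipeline", {}))
    return RunConfig(
        seed=int(raw.get("seed", 0)),
        outdir=str(raw.get("outdir", "toadhop_run")),
        sim=sim,
        pipeline=pipe,
        log_level=str(raw.get("log_level", "INFO")),
    )


def analyze_recordings(
    recordings: list[HopRecording],
    pipeline: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Two-pass cohort analysis.

    Pass 1 computes kinematics, events and delta_TD for every hop; pass 2
    builds the alignment band from the pooled delta_TD of included hops and
    derives the alignment metrics.  Returns ``(metrics, series, info)``
    where ``series`` is the long per-frame table (hop_id, time, alpha,
    gamma, delta) and ``info`` records the band(s) and any skipped hops.
    """
    cfg = pipeline or PipelineConfig()
    analyzed = []
    skipped: dict[str, str] = {}
    for rec in recordings:
        try:
            series = compute_kinematics(rec, cfg.smoothing)
            events = detect_events(
                series,
                speed_threshold=cfg.speed_threshold,
                contact_tolerance=cfg.contact_tolerance,
                accel_band=cfg.liftoff_accel_band,
                liftoff_min_duration=cfg.liftoff_min_duration)
        except EventDetectionError as err:
            log.warning("hop %s skipped: %s", rec.hop_id, err)
            skipped[rec.hop_id] = str(err)
            continue
        analyzed.append((rec, series, events))

    def delta_td(series, events):
        i = series.index_of(events.touchdown)
        return float(series.gamma[i] - series.alpha[i])

    def pool_key(rec):
        if cfg.band_pooling == "treatment":
            return rec.treatment
        if cfg.band_pooling == "animal":
            return rec.animal_id
        return "all"

    pools: dict[str, list[float]] = {}
    for rec, series, events in analyzed:
        if events.included:
            pools.setdefault(pool_key(rec), []).append(
                delta_td(series, events))
    bands = {
        key: build_alignment_band(vals, cfg.band_method, cfg.band_halfwidth)
        for key, vals in pools.items()
    }

    metrics = []
    frames = []
    for rec, series, events in analyzed:
        band = bands.get(pool_key(rec))
        if band is None:       # excluded hop in an otherwise empty pool
            continue
        metrics.append(hop_metrics(rec, series, events, band,
                                   cfg.dropout_tolerance_frames,
                                   cfg.alignment_min_duration))
        frames.append(pd.DataFrame({
            "hop_id": rec.hop_id,
            "time_s": series.times,
            "alpha_deg": series.alpha,
            "gamma_deg": series.gamma,
            "delta_deg": series.delta,
        }))
    table = metrics_to_frame(metrics)
    series_table = (pd.concat(frames, ignore_index=True)
                    if frames else pd.DataFrame())
    info = {
        "bands": {k: dataclasses.asdict(b) for k, b in bands.items()},
        "skipped": skipped,
        "n_analyzed": len(analyzed),
        "n_included": int(table["included"].sum()) if len(table) else 0,
    }
    return table, series_table, info


HEADLINE_METRICS = ("alpha_td", "gamma_td", "delta_td", "o_t0", "o_lo",
                    "d_a", "aerial_duration", "excursion")


def stats_report(metrics: pd.DataFrame) -> tuple[str, dict]:
    """The four headline analyses as a text report plus a result dict.

    1. per-animal OLS of alpha_TD on gamma_TD;
    2. random-intercept LMM of alpha_TD (on gamma_TD, and on platform
       height as a single covariate) with full-vs-null LRTs;
    3. treatment LRTs on the alignment onsets O_T0 and O_LO;
    4. treatment LRT on the alignment duration D_a;
    plus means-of-individual-means treatment summaries and the
    continual-alignment fraction.
    """
    heights = {"flat": 0.0, "low": 0.05, "high": 0.09}
    metrics = metrics.copy()
    metrics["platform_height"] = metrics["treatment"].map(heights)
    out: dict = {}
    lines = ["toadhop stats report", "=" * 60, ""]

    fits = ths.per_animal_regression(metrics)
    out["regressions"] = fits
    lines.append("Per-animal regression: alpha_TD ~ gamma_TD")
    for f in fits:
        lines.append(
            f"  {f.animal_id}: slope {f.slope:+.3f}  intercept "
            f"{f.intercept:+.2f} deg  r^2 {f.r_squared:.3f}  "
            f"p {f.p_value:.2e}  n {f.n_hops}")
    lines.append("")

    for label, response, covariate in (
            ("LMM: alpha_TD ~ gamma_TD", "alpha_td", "gamma_td"),
            ("LMM: alpha_TD ~ platform height", "alpha_td",
             "platform_height")):
        full, null, lrt = ths.lmm_lrt(metrics, response, covariate=covariate)
        out[label] = (full, null, lrt)
        coef = full.fixed_effects[covariate]
        lines.append(f"{label}: coef {coef:+.3f}, sigma_b "
                     f"{full.sigma_b:.2f}, sigma_e {full.sigma_e:.2f}, "
                     f"chi2({lrt.df}) {lrt.chi_sq:.2f}, p {lrt.p_value:.2e}")
    lines.append("")

    for label, response in (("onset LRT: O_T0 ~ treatment", "o_t0"),
                            ("onset LRT: O_LO ~ treatment", "o_lo"),
                            ("duration LRT: D_a ~ treatment", "d_a")):
        full, null, lrt = ths.lmm_lrt(metrics, response)
        out[label] = (full, null, lrt)
        lines.append(f"{label}: chi2({lrt.df}) {lrt.chi_sq:.2f}, "
                     f"p {lrt.p_value:.2e}")
    lines.append("")

    summary = ths.summarize_treatments(metrics, list(HEADLINE_METRICS))
    out["treatment_summary"] = summary
    lines.append("Treatment summaries (means of individual means +/- SD):")
    for _, row in summary.iterrows():
        lines.append(
            f"  {row['treatment']:>5s}  {row['metric']:<16s} "
            f"{row['mean_of_means']:+.3f} +/- {row['sd_of_means']:.3f} "
            f"(n={int(row['n_animals'])})")
    lines.append("")

    frac = ths.continual_alignment_fraction(metrics)
    out["continual_alignment_fraction"] = frac
    lines.append(f"Continual alignment fraction: {frac:.3f}")
    return "\n".join(lines) + "\n", out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full(config: RunConfig) -> dict:
    """simulate -> analyze -> stats; returns the manifest dict.

    Deterministic for a fixed config and seed.  On a stage failure the
    partial outputs are retained next to a ``FAILED`` marker naming the
    stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    stage = "simulate"
    try:
        recordings, truth = simulate_cohort(config.sim, seed=config.seed)
        traj_path = outdir / "trajectories.csv"
        write_recordings(recordings, traj_path)
        truth.to_frame().to_csv(outdir / "ground_truth.csv", index=False,
                                float_format="%.9g")

        stage = "analyze"
        metrics, series, info = analyze_recordings(recordings,
                                                   config.pipeline)
        metrics_path = outdir / "metrics.csv"
        metrics.to_csv(metrics_path, index=False, float_format="%.9g")
        series.to_csv(outdir / "series.csv", index=False,
                      float_format="%.6g")

        stage = "stats"
        report, _ = stats_report(metrics)
        (outdir / "stats_report.txt").write_text(report)
    except Exception as err:
        (outdir / "FAILED").write_text(f"stage {stage}: {err}\n")
        raise RuntimeError(f"stage {stage} failed: {err}") from err

    cfg_dict = {
        "seed": config.seed,
        "outdir": config.outdir,
        "sim": config_to_dict(config.sim),
        "pipeline": dataclasses.asdict(config.pipeline),
    }
    # hash only the scientific configuration, not the output location
    cfg_json = json.dumps({k: v for k, v in cfg_dict.items()
                           if k != "outdir"}, sort_keys=True, default=str)
    manifest = {
        "toadhop_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "n_hops": len(recordings),
        "n_included": info["n_included"],
        "skipped": info["skipped"],
        "bands": info["bands"],
        "checksums": {
            p.name: _sha256(p)
            for p in sorted(outdir.glob("*.csv"))
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest


def analyze_files(paths, pipeline: PipelineConfig | None = None):
    """Read trajectory CSV file(s) and run the cohort analysis."""
    recordings: list[HopRecording] = []
    for p in paths:
        recordings.extend(read_recordings(p))
    return analyze_recordings(recordings, pipeline)
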