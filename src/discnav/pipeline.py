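"""End-to-end analysis: cohort directory in, per-larva and population results out.

Stages: read the trajectory/compass/metadata/GPS tables, reduce each
deployment to a 1 Hz track, compute kinematics, classify it against the
device-bias filter, build each deployment's environmental reference
directions, run the hypothesis battery on the oriented larvae, and fit the
ontogenetic trends. Everything downstream of the (separately seeded)
simulator is deterministic, so re-running on the same inputs reproduces the
outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime
from importlib.metadata import version, PackageNotFoundError
from pathlib import Path

import numpy as np
import pandas as pd

from . import frames, kinematics
from .ontogeny import LarvaResult, TrendFit, fit_linear_trend, fit_orientation_logistic, \
    trend_curve_frame
from .references import DeploymentContext, HypothesisResult, hypothesis_battery

log = logging.getLogger(__name__)

__all__ = ["GroupSummary", "RunReport", "run_pipeline", "format_report",
            "parse_config_file", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "alpha": 0.05,
    "rotation_sign": 1,
    "acclimation_s": 300.0,
    "arena_radius_cm": 10.0,
    "natal_reef_lat": 16.8130,
    "natal_reef_lon": -88.0810,
}


@dataclass
class GroupSummary:
    """One Table-style row: hypothesis x age group circular summary."""

    hypothesis: str
    age_group: str
    n: int
    mean_bearing_deg: float
    circ_sd_rad: float
    r: float
    p: float

    @classmethod
    def from_hypothesis_result(cls, hr: HypothesisResult) -> "GroupSummary":
        s = hr.summary
        return cls(hr.hypothesis, hr.age_group, s.n, s.mean_bearing_deg,
                   s.circ_sd_rad, s.r, s.p_value)


@dataclass
class RunReport:
    counts: dict
    per_larva: pd.DataFrame
    group_summaries: list
    trend_fits: dict
    provenance: dict = field(default_factory=dict)

    @property
    def oriented_fraction(self) -> float:
        return self.counts["oriented"] / self.counts["total"]


def parse_config_file(path) -> dict:
    """Parse a plain-text ``key = value`` config file ('#' comments allowed)."""
    cfg: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        try:
            cfg[key] = int(value)
        except ValueError:
            try:
                cfg[key] = float(value)
            except ValueError:
                cfg[key] = value
    return cfg


def _load_contexts(data_dir: Path, cfg: dict) -> dict[str, DeploymentContext]:
    meta = pd.read_csv(data_dir / "metadata.csv")
    required = {"deployment_id", "start_utc", "lat", "lon", "wind_dir_deg", "age_dph"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata.csv: missing columns {sorted(missing)}")
    gps_path = data_dir / "gps.csv"
    tracks: dict[str, list] = {}
    if gps_path.exists():
        gps = pd.read_csv(gps_path)
        for dep, g in gps.groupby("deployment_id", sort=True):
            g = g.sort_values("utc")
            tracks[str(dep)] = [
                (datetime.fromisoformat(row.utc), float(row.lat), float(row.lon))
                for row in g.itertuples()
            ]
    contexts = {}
    for row in meta.itertuples():
        dep = str(row.deployment_id)
        contexts[dep] = DeploymentContext(
            deployment_id=dep,
            start_utc=datetime.fromisoformat(str(row.start_utc)),
            lat=float(row.lat),
            lon=float(row.lon),
            natal_reef_lat=float(cfg["natal_reef_lat"]),
            natal_reef_lon=float(cfg["natal_reef_lon"]),
            wind_dir_deg=float(row.wind_dir_deg),
            gps_track=tracks.get(dep, []),
            age_dph=int(row.age_dph),
        )
    return contexts


def run_pipeline(data_dir, config: dict | None = None, out_dir=None) -> RunReport:
    """Analyze a cohort directory; optionally write the result files.

    ``config`` overrides are merged over the directory's ``config.cfg`` (if
    present) which is merged over package defaults. With ``out_dir`` set,
    writes per_larva.csv, group_summary.csv, trends.csv and
    run_summary.json.
    """
    data_dir = Path(data_dir)
    cfg = dict(DEFAULT_CONFIG)
    cfg_path = data_dir / "config.cfg"
    if cfg_path.exists():
        cfg.update(parse_config_file(cfg_path))
    if config:
        cfg.update(config)
    alpha = float(cfg["alpha"])

    trajectories = kinematics.read_trajectories_csv(data_dir / "trajectories.csv")
    compasses = frames.read_compass_csv(data_dir / "compass.csv")
    contexts = _load_contexts(data_dir, cfg)

    results: list[LarvaResult] = []
    for dep_id in sorted(trajectories):
        traj = trajectories[dep_id]
        traj.acclimation_s = float(cfg["acclimation_s"])
        traj.arena_radius_cm = float(cfg["arena_radius_cm"])
        compass = compasses.get(dep_id)
        if compass is None:
            log.warning("%s: no compass series; deployment skipped", dep_id)
            continue
        ctx = contexts.get(dep_id)
        if ctx is None:
            log.warning("%s: no metadata row; deployment skipped", dep_id)
            continue
        track = kinematics.subsample_1hz(traj)
        kin = kinematics.summarize_kinematics(track)
        fa = frames.classify_deployment(
            track, compass, alpha=alpha, rotation_sign=int(cfg["rotation_sign"])
        )
        results.append(
            LarvaResult(
                deployment_id=dep_id,
                age_dph=ctx.age_dph,
                mean_speed_cm_s=kin.mean_speed_cm_s,
                mean_turning_deg=kin.mean_turning_deg,
                classification=fa.classification,
                bearing_cardinal_deg=fa.bearing_cardinal_deg,
                rho=fa.rho_cardinal,
                p_cardinal=fa.p_cardinal,
            )
        )

    counts = {
        "total": len(results),
        "non_oriented": sum(r.classification == frames.NON_ORIENTED for r in results),
        "device_biased": sum(r.classification == frames.DEVICE_BIASED for r in results),
        "oriented": sum(r.classification == frames.ORIENTED for r in results),
    }

    summaries = [
        GroupSummary.from_hypothesis_result(hr)
        for hr in hypothesis_battery(results, contexts)
    ]

    trend_fits: dict[str, TrendFit] = {}
    for response in ("speed", "turning"):
        try:
            trend_fits[response] = fit_linear_trend(results, response)
        except ValueError as exc:
            log.warning("linear trend %s not fitted: %s", response, exc)
    try:
        trend_fits["oriented"] = fit_orientation_logistic(results)
    except ValueError as exc:
        log.warning("logistic trend not fitted: %s", exc)

    try:
        pkg_version = version("discnav")
    except PackageNotFoundError:  # running from a source tree
        pkg_version = "unknown"
    provenance = {
        "config": {k: cfg[k] for k in sorted(cfg)},
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "package_version": pkg_version,
    }
    report = RunReport(
        counts=counts,
        per_larva=_per_larva_frame(results),
        group_summaries=summaries,
        trend_fits=trend_fits,
        provenance=provenance,
    )
    if out_dir is not None:
        write_report_files(report, out_dir)
    return report


def _per_larva_frame(results: list[LarvaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "deployment_id": r.deployment_id,
                "age_dph": r.age_dph,
                "mean_speed_cm_s": r.mean_speed_cm_s,
                "mean_turning_deg": r.mean_turning_deg,
                "classification": r.classification,
                "bearing_cardinal_deg": r.bearing_cardinal_deg,
                "rho": r.rho,
                "p_cardinal": r.p_cardinal,
            }
            for r in results
        ]
    )


def write_report_files(report: RunReport, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.per_larva.to_csv(out / "per_larva.csv", index=False, float_format="%.10g")
    pd.DataFrame(
        [
            {
                "hypothesis": g.hypothesis,
                "age_group": g.age_group,
                "n": g.n,
                "mean_bearing_deg": g.mean_bearing_deg,
                "circ_sd_rad": g.circ_sd_rad,
                "r": g.r,
                "p": g.p,
            }
            for g in report.group_summaries
        ]
    ).to_csv(out / "group_summary.csv", index=False, float_format="%.10g")
    ages = np.arange(2.0, 31.0)
    curves = [
        trend_curve_frame(fit, ages) for fit in report.trend_fits.values()
    ]
    if curves:
        pd.concat(curves, ignore_index=True).to_csv(
            out / "trends.csv", index=False, float_format="%.10g"
        )
    summary = {
        "counts": report.counts,
        "oriented_fraction_pct": round(100.0 * report.oriented_fraction, 1),
        "trends": {
            name: {
                "slope": fit.slope,
                "intercept": fit.intercept,
                "test_stat": fit.test_stat,
                "df": fit.df,
                "p": fit.p,
                "n": fit.n,
                "reliable": fit.reliable,
            }
            for name, fit in report.trend_fits.items()
        },
        "provenance": report.provenance,
    }
    (out / "run_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))


def format_report(report: RunReport) -> str:
    """Human-readable summary: counts, oriented percentage, hypothesis grid.

    Bearings print with 1 decimal, r and p with 2, mirroring the precision
    conventionally reported for this kind of table.
    """
    c = report.counts
    lines = [
        "Deployment classification",
        f"  total:          {c['total']}",
        f"  non-oriented:   {c['non_oriented']}",
        f"  device-biased:  {c['device_biased']}",
        f"  oriented:       {c['oriented']} "
        f"({100.0 * report.oriented_fraction:.1f}% of larvae; "
        f"{c['oriented']} out of {c['total']})",
        "",
        "Second-order Rayleigh tests by orientation hypothesis",
        f"  {'hypothesis':<12} {'ages':>6} {'n':>4} {'mean±SD':>14} {'r':>5} {'p':>6}",
    ]
    for g in report.group_summaries:
        mean = (
            "undef"
            if np.isnan(g.mean_bearing_deg)
            else f"{round(g.mean_bearing_deg, 1) % 360.0:.1f}"
        )
        lines.append(
            f"  {g.hypothesis:<12} {g.age_group:>6} {g.n:>4} "
            f"{mean:>8} ± {g.circ_sd_rad:4.2f} {g.r:5.2f} {g.p:6.2f}"
        )
    lines.append("")
    for name, fit in report.trend_fits.items():
        stat = "chi2" if name == "oriented" else "t"
        flag = "" if fit.reliable else "  [unreliable]"
        lines.append(
            f"{name} ~ age: slope {fit.slope:.4g}, intercept {fit.intercept:.4g}, "
            f"{stat} = {fit.test_stat:.2f}, df = {fit.df}, p = {fit.p:.2f}{flag}"
        )
    return "\n".join(lines) + "\n"
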