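"""Synthetic arenas with known ground truth.

Generates egg point patterns and trajectory traces with the statistical
structure the analysis assumes, so every pipeline stage — geometric
quantification, binomial GLM fitting, simultaneous contrasts, bootstrap
bands — can be exercised and validated with no external data.

What is emulated (defaults in :class:`SimulationConfig`):

* per-arena egg counts ~ Poisson(90) — arenas average ~90 eggs;
* each egg laid off-lawn with a condition- (optionally time-) dependent
  probability; P(off) may be constant or logit-linear in hours;
* lawn radius 1.5 mm inside a 3.0 mm filter-paper corral; on-lawn eggs
  uniform on the lawn disk, off-lawn eggs uniform on the lawn-corral
  annulus (area-weighted radius);
* 20 h of trajectory data at 15 frames/hour (300 frames/arena); control
  arenas hold a baseline mean distance, predator-exposed arenas ramp
  logistically to just outside the lawn edge starting at the changepoint
  (default 5.5 h), with i.i.d. gaussian frame noise.

Not emulated: spatial clustering of off-lawn eggs along bacterial streaks,
within-arena worm identity, or any mechanistic predator-prey interaction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .arena_io import ArenaGeometry, EggTable, classify_on_off
from .tracks import TrackTable

__all__ = [
    "ConditionConfig",
    "SimulationConfig",
    "TrajectoryConfig",
    "simulate_egg_arenas",
    "simulate_tracks",
    "write_fixture_bundle",
]


@dataclass
class ConditionConfig:
    """One experimental condition of the egg-laying assay.

    ``p_off`` is the ground-truth off-lawn probability; alternatively
    ``logit_intercept``/``logit_slope_per_h`` define a logit-linear time
    course evaluated at each arena's ``time_h`` (arenas cycle through
    ``times_h``).  ``shifted`` marks the condition as predator-exposed for
    trajectory simulation.
    """

    label: str
    n_arenas: int = 12
    p_off: float | None = 0.1
    logit_intercept: float | None = None
    logit_slope_per_h: float | None = None
    times_h: list[float] | None = None
    n_prey: int = 6
    shifted: bool = False

    def p_off_at(self, time_h: float) -> float:
        if self.logit_intercept is not None:
            eta = self.logit_intercept + (self.logit_slope_per_h or 0.0) * time_h
            return float(1.0 / (1.0 + np.exp(-eta)))
        if self.p_off is None:
            raise ValueError(f"condition {self.label!r} defines neither p_off nor a logit line")
        return self.p_off


@dataclass
class TrajectoryConfig:
    """Trajectory generator block: a baseline mean distance with a logistic
    ramp to just outside the lawn edge beginning at the changepoint."""

    frames_per_hour: int = 15
    duration_h: float = 20.0
    baseline_dist_mm: float = 0.5
    shifted_dist_mm: float = 1.75
    changepoint_h: float = 5.5
    ramp_width_h: float = 1.0
    noise_sd_mm: float = 0.2
    n_worms_range: tuple[int, int] = (2, 6)

    def __post_init__(self) -> None:
        if not 0 < self.changepoint_h < self.duration_h:
            raise ValueError("changepoint must fall within the assay duration")


@dataclass
class SimulationConfig:
    """Full synthetic-assay configuration with geometry, conditions and
    trajectory blocks; every random draw flows from ``seed``."""

    seed: int = 0
    lawn_radius_mm: float = 1.5
    corral_radius_mm: float = 3.0
    mm_per_px: float = 0.005
    center_px: tuple[float, float] = (900.0, 900.0)
    eggs_per_arena_rate: float = 90.0
    conditions: list[ConditionConfig] = field(
        default_factory=lambda: [
            ConditionConfig(label="mock", p_off=0.10, shifted=False, n_prey=6),
            ConditionConfig(label="predator", p_off=0.70, shifted=True, n_prey=3),
        ]
    )
    trajectory: TrajectoryConfig = field(default_factory=TrajectoryConfig)

    def __post_init__(self) -> None:
        if not self.corral_radius_mm > self.lawn_radius_mm:
            raise ValueError("corral radius must exceed lawn radius")
        if not self.eggs_per_arena_rate > 0:
            raise ValueError("eggs_per_arena_rate must be > 0")
        for c in self.conditions:
            if c.p_off is not None and not 0.0 <= c.p_off <= 1.0:
                raise ValueError(f"p_off out of [0, 1] for condition {c.label!r}")

    @property
    def geometry(self) -> ArenaGeometry:
        return ArenaGeometry(
            center_xy=self.center_px,
            lawn_radius_px=self.lawn_radius_mm / self.mm_per_px,
            mm_per_px=self.mm_per_px,
            corral_radius_px=self.corral_radius_mm / self.mm_per_px,
        )

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        conds = [ConditionConfig(**c) for c in cfg.pop("conditions", [])]
        traj = TrajectoryConfig(**cfg.pop("trajectory", {}))
        out = cls(**cfg)
        if conds:
            out.conditions = conds
        out.trajectory = traj
        return out


def _radial_positions(rng, n, r_lo_mm, r_hi_mm, geometry: ArenaGeometry) -> np.ndarray:
    """n points uniform on the annulus r in (r_lo, r_hi] (area-weighted),
    returned as (n, 2) pixel coordinates about the lawn center."""
    r = np.sqrt(rng.uniform(r_lo_mm**2, r_hi_mm**2, size=n))
    theta = rng.uniform(0, 2 * np.pi, size=n)
    cx, cy = geometry.center_xy
    x = cx + (r / geometry.mm_per_px) * np.cos(theta)
    y = cy + (r / geometry.mm_per_px) * np.sin(theta)
    return np.column_stack([x, y])


def simulate_egg_arenas(config: SimulationConfig, seed: int | None = None) -> tuple[EggTable, dict]:
    """Simulate egg point patterns for every configured condition.

    Per arena the egg count is Poisson(``eggs_per_arena_rate``); each egg is
    off-lawn with the condition's ground-truth probability; on-lawn eggs are
    uniform on the lawn disk, off-lawn eggs uniform on the lawn-corral
    annulus.  Returns the :class:`EggTable` (pixel coordinates, canonical
    schema) and a ground-truth record (true p_off per condition, seed).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    geom = config.geometry
    eps = 1e-9  # keep off-lawn radii strictly outside the lawn edge
    rows = []
    geoms = {}
    truth_conditions = {}
    for cond in config.conditions:
        times = cond.times_h or [np.nan]
        truth_conditions[cond.label] = {
            "p_off": None if cond.logit_intercept is not None else cond.p_off,
            "logit_intercept": cond.logit_intercept,
            "logit_slope_per_h": cond.logit_slope_per_h,
            "n_arenas": cond.n_arenas,
            "n_prey": cond.n_prey,
        }
        for i in range(cond.n_arenas):
            arena_id = f"{cond.label}_{i + 1:03d}"
            geoms[arena_id] = geom
            t = times[i % len(times)]
            p = cond.p_off_at(0.0 if np.isnan(t) else t)
            n_eggs = rng.poisson(config.eggs_per_arena_rate)
            off = rng.random(n_eggs) < p
            xy = np.empty((n_eggs, 2))
            n_off = int(off.sum())
            if n_off:
                xy[off] = _radial_positions(
                    rng, n_off, config.lawn_radius_mm + eps, config.corral_radius_mm, geom
                )
            if n_eggs - n_off:
                xy[~off] = _radial_positions(rng, n_eggs - n_off, 0.0, config.lawn_radius_mm, geom)
            arena = pd.DataFrame(
                {
                    "arena": arena_id,
                    "condition": cond.label,
                    "x_px": xy[:, 0],
                    "y_px": xy[:, 1],
                    "lawn_radius_px": geom.lawn_radius_px,
                    "mm_per_px": geom.mm_per_px,
                }
            )
            if not np.isnan(t):
                arena["time_h"] = t
            rows.append(arena)

    df = pd.concat(rows, ignore_index=True)
    cx, cy = geom.center_xy
    df["dist_center_mm"] = geom.mm_per_px * np.hypot(df["x_px"] - cx, df["y_px"] - cy)
    df["dist_edge_mm"] = df["dist_center_mm"] - geom.lawn_radius_mm
    df["off_lawn"] = classify_on_off(df["dist_edge_mm"].to_numpy())
    truth = {
        "seed": config.seed if seed is None else seed,
        "eggs_per_arena_rate": config.eggs_per_arena_rate,
        "conditions": truth_conditions,
    }
    return EggTable(data=df, geometries=geoms), truth


def _ramp(t: np.ndarray, traj: TrajectoryConfig) -> np.ndarray:
    """Logistic 0->1 ramp beginning at the changepoint (centered half a ramp
    width later; 10-90% rise spans ~ramp_width_h)."""
    scale = traj.ramp_width_h / np.log(81.0)
    center = traj.changepoint_h + traj.ramp_width_h / 2.0
    return 1.0 / (1.0 + np.exp(-(t - center) / scale))


def simulate_tracks(config: SimulationConfig, seed: int | None = None) -> TrackTable:
    """Simulate per-arena mean-distance traces for every condition.

    Control arenas stay at the baseline distance throughout; predator-exposed
    (``shifted``) arenas ramp logistically from baseline to the shifted
    distance (just outside the lawn edge) after the changepoint.  I.i.d.
    gaussian noise is added per frame; negative distances are truncated at 0
    (count recorded in ``table.data.attrs['n_truncated']``).
    """
    traj = config.trajectory
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    n_frames = int(round(traj.duration_h * traj.frames_per_hour))
    frames = np.arange(n_frames)
    time_h = frames / traj.frames_per_hour
    geom = config.geometry

    rows = []
    n_truncated = 0
    for cond in config.conditions:
        base = np.full(n_frames, traj.baseline_dist_mm)
        if cond.shifted:
            base = base + (traj.shifted_dist_mm - traj.baseline_dist_mm) * _ramp(time_h, traj)
        for i in range(cond.n_arenas):
            arena_id = f"{cond.label}_{i + 1:03d}"
            n_worms = int(rng.integers(traj.n_worms_range[0], traj.n_worms_range[1] + 1))
            trace = base + rng.normal(0.0, traj.noise_sd_mm, size=n_frames)
            neg = trace < 0
            n_truncated += int(neg.sum())
            trace[neg] = 0.0
            rows.append(
                pd.DataFrame(
                    {
                        "frame": frames,
                        "time_h": time_h,
                        "arena": arena_id,
                        "condition": cond.label,
                        "n_worms": n_worms,
                        "lawn_radius_px": geom.lawn_radius_px,
                        "mm_per_px": geom.mm_per_px,
                        "dist_center_mm": trace,
                    }
                )
            )
    df = pd.concat(rows, ignore_index=True)
    df["dist_edge_mm"] = df["dist_center_mm"] - config.lawn_radius_mm
    df["off_lawn"] = classify_on_off(df["dist_edge_mm"].to_numpy())
    df.attrs["n_truncated"] = n_truncated
    geoms = {a: geom for a in df["arena"].unique()}
    return TrackTable(data=df, geometries=geoms)


def write_fixture_bundle(config: SimulationConfig, outdir) -> dict[str, Path]:
    """Write a complete synthetic fixture bundle to ``outdir``.

    Emits ``eggs.csv``, ``tracks.csv``, ``geometry.csv``, ``model.yaml`` and
    ``truth.json`` in the canonical schemas; byte-identical for a fixed
    config (seed included).
    """
    from .arena_io import write_egg_table
    from .tracks import write_track_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    eggs, truth = simulate_egg_arenas(config)
    trk = simulate_tracks(config)

    paths = {
        "eggs": outdir / "eggs.csv",
        "tracks": outdir / "tracks.csv",
        "geometry": outdir / "geometry.csv",
        "model": outdir / "model.yaml",
        "truth": outdir / "truth.json",
    }
    write_egg_table(eggs, paths["eggs"])
    write_track_table(trk, paths["tracks"])
    geom = config.geometry
    pd.DataFrame(
        {
            "arena": list(eggs.geometries),
            "cx_px": geom.center_xy[0],
            "cy_px": geom.center_xy[1],
            "lawn_radius_px": geom.lawn_radius_px,
            "corral_radius_px": geom.corral_radius_px,
            "mm_per_px": geom.mm_per_px,
        }
    ).to_csv(paths["geometry"], index=False)
    ref = config.conditions[0].label
    model = {
        "response": "binomial_counts",
        "interaction_order": 1,
        "terms": [{"name": "condition", "type": "categorical", "reference": ref}],
    }
    with open(paths["model"], "w") as fh:
        yaml.safe_dump(model, fh, sort_keys=False)
    with open(paths["truth"], "w") as fh:
        json.dump({**truth, "config": _config_dict(config)}, fh, indent=2, sort_keys=True)
    return paths


def _config_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["trajectory"]["n_worms_range"] = list(d["trajectory"]["n_worms_range"])
    d["center_px"] = list(d["center_px"])
    return d
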