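"""Worm-trajectory time-series analysis: bootstrap mean bands and overlap.

The arena imager reports, per arena and frame (15 frames/hour over 20 h, so
300 time points), the average distance of the tracked worms from the arena
center.  Between-condition inference follows the nonparametric bootstrap:
whole arena traces — the biological replicates — are resampled with
replacement, the pointwise mean is recorded per iteration, and the band is
the empirical 2.5-97.5% quantile envelope.  Two conditions differ (p < 0.05)
wherever their bands fail to overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .arena_io import ArenaGeometry, SchemaError, classify_on_off

__all__ = [
    "BootstrapBand",
    "OverlapReport",
    "TrackTable",
    "arena_average_trace",
    "band_overlap",
    "bootstrap_bands",
    "fold_change_bands",
    "read_track_table",
    "write_track_table",
]

TRACK_REQUIRED = ["frame", "time_h", "arena", "condition", "dist_center_mm"]


@dataclass
class TrackTable:
    """Tabular worm-position time series (one row per arena x frame)."""

    data: pd.DataFrame
    geometries: dict[str, ArenaGeometry] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.data)


def read_track_table(path, schema: Mapping[str, str] | None = None) -> TrackTable:
    """Read a trajectory CSV (canonical columns: frame, time_h, arena,
    condition, n_worms, lawn_radius_px, mm_per_px, dist_center_mm,
    dist_edge_mm, off_lawn).

    Frames out of order within an arena are sorted with a warning; a
    monotone frame index per arena is enforced on output.  Distance-derived
    columns are filled in from ``dist_center_mm`` and the lawn radius when
    absent.
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    for col in TRACK_REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"track table missing required column {col!r}")

    unsorted = df.groupby("arena", sort=False)["frame"].apply(lambda s: not s.is_monotonic_increasing)
    if unsorted.any():
        warnings.warn(
            f"out-of-order frames in arena(s) {list(unsorted.index[unsorted])}; sorted",
            stacklevel=2,
        )
        df = df.sort_values(["arena", "frame"], kind="stable").reset_index(drop=True)

    geoms: dict[str, ArenaGeometry] = {}
    if {"lawn_radius_px", "mm_per_px"} <= set(df.columns):
        for arena, grp in df.groupby("arena", sort=False):
            geoms[arena] = ArenaGeometry(
                center_xy=(0.0, 0.0),
                lawn_radius_px=float(grp["lawn_radius_px"].iloc[0]),
                mm_per_px=float(grp["mm_per_px"].iloc[0]),
            )
        if "dist_edge_mm" not in df.columns:
            lawn_mm = df["arena"].map({a: g.lawn_radius_mm for a, g in geoms.items()})
            df["dist_edge_mm"] = df["dist_center_mm"] - lawn_mm
        if "off_lawn" not in df.columns and "dist_edge_mm" in df.columns:
            df["off_lawn"] = classify_on_off(df["dist_edge_mm"].to_numpy())
    return TrackTable(data=df, geometries=geoms)


def write_track_table(table: TrackTable, path) -> None:
    table.data.to_csv(path, index=False)


def arena_average_trace(table: TrackTable, value: str = "dist_center_mm") -> pd.DataFrame:
    """Per-arena mean-distance traces on a common time grid.

    Returns a DataFrame indexed by ``time_h`` with one column per arena.  The
    source data is already arena-averaged (one row per arena x frame); if
    several rows share an (arena, frame) — per-worm records — they are
    averaged.  Frames missing for an arena stay NaN; arenas with no frames at
    all are excluded with a warning.
    """
    df = table.data
    counts = df.groupby("arena", sort=False)[value].count()
    empty = counts.index[counts == 0]
    if len(empty):
        warnings.warn(f"arena(s) with no observations excluded: {list(empty)}", stacklevel=2)
        df = df[~df["arena"].isin(empty)]
    wide = df.pivot_table(index="time_h", columns="arena", values=value, aggfunc="mean")
    return wide.sort_index()


@dataclass
class BootstrapBand:
    """Pointwise mean trace with its empirical bootstrap quantile envelope."""

    time_h: np.ndarray
    mean: np.ndarray
    q025: np.ndarray
    q975: np.ndarray
    n_boot: int
    seed: int | None
    #: time points where no arena had data (band undefined there)
    undefined: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.undefined is None:
            self.undefined = ~np.isfinite(self.mean)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_h": self.time_h, "mean": self.mean, "q025": self.q025, "q975": self.q975}
        )


def _as_trace_matrix(traces) -> tuple[np.ndarray, np.ndarray]:
    """(arenas x time) matrix and the time grid from a wide DataFrame or array."""
    if isinstance(traces, pd.DataFrame):
        return traces.to_numpy(float).T, traces.index.to_numpy(float)
    arr = np.atleast_2d(np.asarray(traces, float))
    return arr, np.arange(arr.shape[1], dtype=float)


def _boot_stat_quantiles(stat_fn, n_arenas, n_boot, rng, T, chunk=2000):
    """Empirical 2.5/97.5% quantiles of a per-iteration pointwise statistic.

    ``stat_fn(idx)`` maps a (chunk, n_arenas) index array to a (chunk, T)
    statistic; results accumulate in float32 to bound memory at default 1e5
    iterations x 300 time points.
    """
    out = np.empty((n_boot, T), dtype=np.float32)
    done = 0
    while done < n_boot:
        m = min(chunk, n_boot - done)
        idx = rng.integers(0, n_arenas, size=(m, n_arenas))
        out[done:done + m] = stat_fn(idx)
        done += m
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        q = np.nanquantile(out.astype(float), [0.025, 0.975], axis=0)
    return q[0], q[1]


def bootstrap_bands(
    traces, n_boot: int = 100_000, seed: int | None = None
) -> BootstrapBand:
    """Bootstrap mean band from per-arena traces.

    The resampling unit is the whole arena trace: each of ``n_boot``
    iterations draws N arenas with replacement and records the pointwise mean
    (ignoring missing values); the band is the pointwise empirical 2.5% and
    97.5% quantile over iterations.  The central trace is the pointwise mean
    of the observed arenas.  Deterministic for a fixed seed.
    """
    data, time_h = _as_trace_matrix(traces)
    n_arenas, T = data.shape
    if n_arenas < 1 or n_boot < 1:
        raise ValueError("need >= 1 arena and >= 1 bootstrap iteration")
    rng = np.random.default_rng(seed)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(data, axis=0)
        q025, q975 = _boot_stat_quantiles(
            lambda idx: np.nanmean(data[idx], axis=1), n_arenas, n_boot, rng, T
        )
    undefined = np.all(np.isnan(data), axis=0)
    if undefined.any():
        warnings.warn(
            f"{int(undefined.sum())} time point(s) have no data in any arena; band undefined there",
            stacklevel=2,
        )
    return BootstrapBand(
        time_h=time_h, mean=mean, q025=q025, q975=q975,
        n_boot=n_boot, seed=seed, undefined=undefined,
    )


@dataclass
class OverlapReport:
    """Where two bootstrap bands fail to overlap.

    ``fraction_disjoint`` uses only time points where both bands are defined;
    ``fraction_disjoint_all`` divides by all time points on the grid.
    """

    time_h: np.ndarray
    disjoint: np.ndarray          # bool per time point (False where undefined)
    valid: np.ndarray             # both bands defined
    fraction_disjoint: float
    fraction_disjoint_all: float


def band_overlap(band_a: BootstrapBand, band_b: BootstrapBand) -> OverlapReport:
    """Per-time-point non-overlap of two bands on an identical time grid.

    Bands are treated as closed intervals: touching envelopes count as
    overlapping.  Mismatched time grids raise (no silent interpolation).
    """
    if band_a.time_h.shape != band_b.time_h.shape or not np.allclose(
        band_a.time_h, band_b.time_h
    ):
        raise ValueError("bands have different time grids")
    valid = ~(band_a.undefined | band_b.undefined)
    disjoint = np.zeros_like(valid)
    disjoint[valid] = (band_a.q025[valid] > band_b.q975[valid]) | (
        band_b.q025[valid] > band_a.q975[valid]
    )
    n_valid = int(valid.sum())
    frac = float(disjoint.sum() / n_valid) if n_valid else np.nan
    return OverlapReport(
        time_h=band_a.time_h,
        disjoint=disjoint,
        valid=valid,
        fraction_disjoint=frac,
        fraction_disjoint_all=float(disjoint.sum() / len(valid)),
    )


def fold_change_bands(
    traces_a,
    traces_b,
    n_boot: int = 100_000,
    seed: int | None = None,
    min_denominator: float = 1e-9,
) -> BootstrapBand:
    """Bootstrap band of the pointwise ratio mean_a(t) / mean_b(t).

    Each iteration independently resamples both conditions' arenas; the band
    comes from the empirical quantiles of the per-iteration ratio.  Time
    points where the denominator mean falls within ``min_denominator`` of
    zero are suppressed (NaN) and flagged as undefined.
    """
    A, time_a = _as_trace_matrix(traces_a)
    B, time_b = _as_trace_matrix(traces_b)
    if A.shape[1] != B.shape[1] or not np.allclose(time_a, time_b):
        raise ValueError("conditions must share one time grid")
    rng = np.random.default_rng(seed)
    T = A.shape[1]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_a, mean_b = np.nanmean(A, axis=0), np.nanmean(B, axis=0)
        near_zero = ~np.isfinite(mean_b) | (np.abs(mean_b) < min_denominator)
        ratio = np.where(near_zero, np.nan, mean_a / np.where(near_zero, 1.0, mean_b))

        def stat(idx_a):
            idx_b = rng.integers(0, B.shape[0], size=idx_a.shape[0] * B.shape[0]).reshape(
                idx_a.shape[0], B.shape[0]
            )
            num = np.nanmean(A[idx_a], axis=1)
            den = np.nanmean(B[idx_b], axis=1)
            den = np.where(np.abs(den) < min_denominator, np.nan, den)
            return num / den

        q025, q975 = _boot_stat_quantiles(stat, A.shape[0], n_boot, rng, T)

    undefined = near_zero | np.all(np.isnan(A), axis=0)
    if near_zero.any():
        warnings.warn(
            f"{int(near_zero.sum())} time point(s) with near-zero denominator suppressed",
            stacklevel=2,
        )
    return BootstrapBand(
        time_h=time_a, mean=ratio, q025=q025, q975=q975,
        n_boot=n_boot, seed=seed, undefined=undefined,
    )
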