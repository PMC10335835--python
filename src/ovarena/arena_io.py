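"""Reading, writing and geometric quantification of arena egg-position tables.

The assay records eggs laid by *C. elegans* inside a circular corral whose
center holds a small bacterial lawn.  Raw observations are pixel coordinates
per egg plus, per arena, the lawn radius (pixels) and a mm-per-pixel
conversion factor.  This module turns those into analysis-ready distances
(mm from lawn center, signed mm from the lawn edge) and the binary on/off
lawn classification that the binomial models consume.

Conventions
-----------
* ``dist_edge_mm = dist_center_mm - lawn_radius_mm`` exactly (negative inside
  the lawn).
* An egg exactly on the lawn edge (``dist_edge_mm == 0``) counts as on-lawn:
  "off" means strictly outside the closed lawn disk.
* Coordinates are continuous; no rounding to integer pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ArenaGeometry",
    "EggTable",
    "SchemaError",
    "QCRules",
    "classify_on_off",
    "compute_egg_distances",
    "distance_histogram",
    "qc_filter_arenas",
    "read_egg_table",
    "read_geometry_table",
    "tabulate_counts",
    "write_egg_table",
]

#: canonical column names for egg tables
EGG_COLUMNS = [
    "arena",
    "condition",
    "x_px",
    "y_px",
    "lawn_radius_px",
    "mm_per_px",
    "dist_center_mm",
    "dist_edge_mm",
    "off_lawn",
]

#: optional factor columns recognized without mapping
OPTIONAL_FACTORS = ["genotype", "lawn_type", "rest_period_h", "dopamine_mM", "time_h"]

REQUIRED_EGG_COLUMNS = ["arena", "condition", "x_px", "y_px", "lawn_radius_px", "mm_per_px"]

#: tolerance (mm) when verifying precomputed distance columns against coordinates
DIST_VERIFY_TOL_MM = 1e-6


class SchemaError(ValueError):
    """A required column is missing or a value cannot be parsed."""


@dataclass(frozen=True)
class ArenaGeometry:
    """Circle geometry of a single arena.

    Parameters
    ----------
    center_xy : (float, float)
        Lawn center in pixel coordinates.
    lawn_radius_px : float
        Radius of the bacterial lawn, pixels.
    mm_per_px : float
        Conversion factor from pixels to millimetres.
    corral_radius_px : float, optional
        Radius of the filter-paper corral confining the worms; must exceed
        the lawn radius when given.
    """

    center_xy: tuple[float, float]
    lawn_radius_px: float
    mm_per_px: float
    corral_radius_px: float | None = None

    def __post_init__(self) -> None:
        if not self.lawn_radius_px > 0:
            raise ValueError("lawn_radius_px must be > 0")
        if not self.mm_per_px > 0:
            raise ValueError("mm_per_px must be > 0")
        if self.corral_radius_px is not None and not self.corral_radius_px > self.lawn_radius_px:
            raise ValueError("corral_radius_px must exceed lawn_radius_px")

    @property
    def lawn_radius_mm(self) -> float:
        return self.lawn_radius_px * self.mm_per_px

    @property
    def corral_radius_mm(self) -> float | None:
        if self.corral_radius_px is None:
            return None
        return self.corral_radius_px * self.mm_per_px


@dataclass
class EggTable:
    """Per-egg observations plus the geometry of each arena.

    ``data`` holds one row per egg with canonical columns (see
    :data:`EGG_COLUMNS` plus any factor columns present); ``geometries`` maps
    every ``arena`` id appearing in ``data`` to its :class:`ArenaGeometry`.
    """

    data: pd.DataFrame
    geometries: dict[str, ArenaGeometry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(self.data["arena"].unique()) - set(self.geometries)
        if missing:
            raise ValueError(f"arenas without geometry record: {sorted(map(str, missing))}")

    @property
    def factor_columns(self) -> list[str]:
        known = {"arena", "x_px", "y_px", "lawn_radius_px", "mm_per_px",
                 "dist_center_mm", "dist_edge_mm", "off_lawn"}
        return [c for c in self.data.columns if c not in known]

    def __len__(self) -> int:
        return len(self.data)


def compute_egg_distances(
    xy: Sequence[float] | np.ndarray, geometry: ArenaGeometry
) -> tuple[np.ndarray, np.ndarray] | tuple[float, float]:
    """Distance of point(s) from lawn center and (signed) from lawn edge, in mm.

    ``xy`` is a single ``(x, y)`` pair or an ``(n, 2)`` array of pixel
    coordinates.  Returns ``(dist_center_mm, dist_edge_mm)`` where
    ``dist_edge_mm = dist_center_mm - lawn_radius_mm`` (negative inside the
    lawn).
    """
    pts = np.asarray(xy, dtype=float)
    scalar = pts.ndim == 1
    pts = np.atleast_2d(pts)
    cx, cy = geometry.center_xy
    dist_center = geometry.mm_per_px * np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
    dist_edge = dist_center - geometry.lawn_radius_mm
    if scalar:
        return float(dist_center[0]), float(dist_edge[0])
    return dist_center, dist_edge


def classify_on_off(dist_edge_mm: float | np.ndarray | pd.Series) -> np.ndarray | int:
    """1 for off-lawn (strictly outside the lawn), 0 for on-lawn.

    The boundary itself (``dist_edge_mm == 0``) is on-lawn.
    """
    arr = np.asarray(dist_edge_mm, dtype=float)
    flags = (arr > 0).astype(int)
    if flags.ndim == 0:
        return int(flags)
    return flags


def read_geometry_table(path, schema: Mapping[str, str] | None = None) -> dict[str, ArenaGeometry]:
    """Read a per-arena geometry CSV: arena, cx_px, cy_px, lawn_radius_px,
    mm_per_px and optionally corral_radius_px."""
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    required = ["arena", "cx_px", "cy_px", "lawn_radius_px", "mm_per_px"]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"geometry table missing required column {col!r}")
    geoms: dict[str, ArenaGeometry] = {}
    for _, row in df.iterrows():
        corral = row.get("corral_radius_px")
        geoms[row["arena"]] = ArenaGeometry(
            center_xy=(float(row["cx_px"]), float(row["cy_px"])),
            lawn_radius_px=float(row["lawn_radius_px"]),
            mm_per_px=float(row["mm_per_px"]),
            corral_radius_px=None if corral is None or pd.isna(corral) else float(corral),
        )
    return geoms


def _coerce_numeric(df: pd.DataFrame, columns: Iterable[str]) -> None:
    for col in columns:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            rows = df.index[bad].tolist()
            raise SchemaError(f"non-numeric value in column {col!r} at row(s) {rows[:10]}")
        df[col] = coerced


def read_egg_table(
    path,
    schema: Mapping[str, str] | None = None,
    geometries: Mapping[str, ArenaGeometry] | None = None,
) -> EggTable:
    """Read an egg-position CSV into an :class:`EggTable`.

    Parameters
    ----------
    path : path-like
        CSV file (comma-separated, UTF-8, header row).
    schema : mapping, optional
        Map canonical column name -> file column name, to absorb
        source-data naming variants.
    geometries : mapping, optional
        Per-arena :class:`ArenaGeometry`.  When absent, geometry is taken from
        the per-row ``lawn_radius_px`` / ``mm_per_px`` columns with the lawn
        center read from ``cx_px``/``cy_px`` columns if present, else (0, 0).

    Derived columns (``dist_center_mm``, ``dist_edge_mm``, ``off_lawn``) are
    recomputed from coordinates when absent.  When the file carries its own
    values they are verified against the recomputation; disagreement beyond
    1e-6 mm raises a warning listing the offending rows (file values are
    replaced by recomputed ones).
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    for col in REQUIRED_EGG_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"egg table missing required column {col!r}")
    _coerce_numeric(
        df,
        ["x_px", "y_px", "lawn_radius_px", "mm_per_px", "cx_px", "cy_px",
         "dist_center_mm", "dist_edge_mm", "time_h"],
    )

    geoms = dict(geometries) if geometries else {}
    if not geoms:
        for arena, grp in df.groupby("arena", sort=False):
            cx = float(grp["cx_px"].iloc[0]) if "cx_px" in grp.columns else 0.0
            cy = float(grp["cy_px"].iloc[0]) if "cy_px" in grp.columns else 0.0
            corral = None
            if "corral_radius_px" in grp.columns and not pd.isna(grp["corral_radius_px"].iloc[0]):
                corral = float(grp["corral_radius_px"].iloc[0])
            geoms[arena] = ArenaGeometry(
                center_xy=(cx, cy),
                lawn_radius_px=float(grp["lawn_radius_px"].iloc[0]),
                mm_per_px=float(grp["mm_per_px"].iloc[0]),
                corral_radius_px=corral,
            )

    dist_center = np.empty(len(df))
    dist_edge = np.empty(len(df))
    for arena, grp in df.groupby("arena", sort=False):
        dc, de = compute_egg_distances(grp[["x_px", "y_px"]].to_numpy(float), geoms[arena])
        dist_center[df.index.get_indexer(grp.index)] = dc
        dist_edge[df.index.get_indexer(grp.index)] = de

    for col, computed in (("dist_center_mm", dist_center), ("dist_edge_mm", dist_edge)):
        if col in df.columns:
            mismatch = np.abs(df[col].to_numpy(float) - computed) > DIST_VERIFY_TOL_MM
            if mismatch.any():
                rows = df.index[mismatch].tolist()
                warnings.warn(
                    f"column {col!r} disagrees with coordinates beyond "
                    f"{DIST_VERIFY_TOL_MM} mm at row(s) {rows[:20]}; recomputed values used",
                    stacklevel=2,
                )
    df["dist_center_mm"] = dist_center
    df["dist_edge_mm"] = dist_edge
    df["off_lawn"] = classify_on_off(dist_edge)
    return EggTable(data=df, geometries=geoms)


def write_egg_table(table: EggTable, path) -> None:
    """Write an :class:`EggTable` to CSV in the canonical schema.

    Lawn centers are embedded as ``cx_px``/``cy_px`` columns so the file
    round-trips through :func:`read_egg_table` without a geometry side file.
    """
    df = table.data.copy()
    cx = df["arena"].map({a: g.center_xy[0] for a, g in table.geometries.items()})
    cy = df["arena"].map({a: g.center_xy[1] for a, g in table.geometries.items()})
    df.insert(min(2, len(df.columns)), "cx_px", cx)
    df.insert(min(3, len(df.columns)), "cy_px", cy)
    corral = {a: g.corral_radius_px for a, g in table.geometries.items()}
    if any(v is not None for v in corral.values()):
        df["corral_radius_px"] = df["arena"].map(corral)
    df.to_csv(path, index=False)


def tabulate_counts(table: EggTable, grouping: Sequence[str] = ("condition",)) -> pd.DataFrame:
    """Tally off/on-lawn egg counts per arena and factor combination.

    Returns one row per ``arena`` x grouping-factor combination with columns
    ``n_off`` and ``n_on``.  Total eggs are conserved:
    ``(n_off + n_on).sum() == len(table)``.
    """
    df = table.data
    if df.empty:
        warnings.warn("empty egg table; no counts produced", stacklevel=2)
        return pd.DataFrame(columns=["arena", *grouping, "n_off", "n_on"])
    for factor in grouping:
        if factor not in df.columns:
            raise SchemaError(f"grouping factor {factor!r} not in table")
    keys = ["arena", *[g for g in grouping if g != "arena"]]
    out = (
        df.groupby(keys, sort=False, dropna=False)["off_lawn"]
        .agg(n_off="sum", n_total="count")
        .reset_index()
    )
    out["n_on"] = out["n_total"] - out["n_off"]
    return out.drop(columns="n_total")


@dataclass
class QCRules:
    """Arena discard rules.

    An arena is discarded when: at least ``max_escaped_worms`` worms escaped
    the corral; a predator was observed in a control (mock) arena; or the
    arena holds zero eggs.  Flags are read from the columns named here when
    present; absent columns simply skip that rule.
    """

    max_escaped_worms: int = 2
    escaped_column: str = "escaped_worms"
    predator_in_control_column: str = "predator_in_control"
    require_eggs: bool = True


def qc_filter_arenas(
    counts: pd.DataFrame, rules: QCRules | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply arena quality-control discard rules.

    Parameters
    ----------
    counts : DataFrame
        Per-arena records (e.g. from :func:`tabulate_counts`), optionally
        carrying QC flag columns.
    rules : QCRules

    Returns
    -------
    (kept, discard_log) : the surviving rows, and a log with one row per
    discarded arena naming the triggered rule.
    """
    rules = rules or QCRules()
    reasons: list[tuple[object, str]] = []
    drop = pd.Series(False, index=counts.index)

    if rules.escaped_column in counts.columns:
        hit = counts[rules.escaped_column].fillna(0) >= rules.max_escaped_worms
        for idx in counts.index[hit & ~drop]:
            reasons.append((counts.loc[idx, "arena"], f">= {rules.max_escaped_worms} escaped worms"))
        drop |= hit
    if rules.predator_in_control_column in counts.columns:
        hit = counts[rules.predator_in_control_column].fillna(False).astype(bool)
        for idx in counts.index[hit & ~drop]:
            reasons.append((counts.loc[idx, "arena"], "predator observed in control arena"))
        drop |= hit
    if rules.require_eggs and {"n_off", "n_on"} <= set(counts.columns):
        hit = (counts["n_off"] + counts["n_on"]) == 0
        for idx in counts.index[hit & ~drop]:
            reasons.append((counts.loc[idx, "arena"], "zero eggs"))
        drop |= hit

    log = pd.DataFrame(reasons, columns=["arena", "rule"])
    return counts.loc[~drop].copy(), log


def distance_histogram(
    table: EggTable, bin_width_mm: float = 0.25
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Radial egg-distance histograms, per arena and averaged across arenas.

    Bins are half-open ``[lo, hi)`` of width ``bin_width_mm`` starting at 0.
    Per-arena histograms are normalized to proportions; the across-arena
    average is the unweighted mean of those proportions per bin (each arena
    contributes equally regardless of its egg count).  Zero-egg arenas are
    excluded with a warning.
    """
    if not bin_width_mm > 0:
        raise ValueError("bin_width_mm must be > 0")
    df = table.data
    max_dist = float(df["dist_center_mm"].max()) if len(df) else 0.0
    n_bins = max(1, int(np.floor(max_dist / bin_width_mm)) + 1)
    edges = np.arange(n_bins + 1) * bin_width_mm

    rows = []
    for arena, grp in df.groupby("arena", sort=False):
        if len(grp) == 0:
            warnings.warn(f"arena {arena!r} has zero eggs; excluded from histogram", stacklevel=2)
            continue
        # np.histogram's last bin is closed; pad so all bins behave half-open
        counts, _ = np.histogram(grp["dist_center_mm"], bins=np.append(edges, np.inf))
        props = counts[:-1] / len(grp)
        props[-1] += counts[-1] / len(grp)  # overflow folded into last bin
        rows.append(pd.Series(props, name=arena))
    per_arena = pd.DataFrame(rows)
    per_arena.columns = pd.IntervalIndex.from_breaks(edges, closed="left")
    per_arena.index.name = "arena"
    average = per_arena.mean(axis=0).to_frame("proportion")
    return per_arena, average
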