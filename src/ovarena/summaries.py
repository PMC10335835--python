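"""Scalar summaries outside the GLM core: egg dispersion, fluorescence
normalization, eggs per animal, and the mouthform contingency test."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .arena_io import EggTable

__all__ = [
    "dispersion_summary",
    "eggs_per_worm",
    "fisher_exact_2x2",
    "normalize_fluorescence",
]


def dispersion_summary(
    table: EggTable, group: list[str] | tuple[str, ...] = ("arena",)
) -> pd.DataFrame:
    """Mean, sample SD and coefficient of variation of egg distances per group.

    The CV (SD divided by mean, dimensionless) is the dispersion metric for
    eggs laid in bacteria-filled arenas, where on/off classification is
    meaningless.  SD uses the n-1 denominator; single-egg groups get NaN
    SD/CV, and CV is NaN where the mean distance is 0.
    """
    df = table.data
    g = df.groupby(list(group), sort=False, dropna=False)["dist_center_mm"]
    out = g.agg(mean_dist_mm="mean", sd_dist_mm="std", n_eggs="count").reset_index()
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = out["sd_dist_mm"] / out["mean_dist_mm"]
    out["cv"] = cv.where(out["mean_dist_mm"] != 0, np.nan)
    return out


def normalize_fluorescence(
    records: pd.DataFrame,
    control_label,
    condition_column: str = "condition",
    gfp_column: str = "gfp",
    dsred_column: str = "dsred",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-animal log2(GFP/dsRed), centered on the control-group mean.

    The reporter signal (GFP) is ratioed against a constitutive marker
    (dsRed), log2-transformed, and expressed relative to the mock mean so
    control animals average exactly 0.  Records with non-positive intensity
    are rejected and returned in a second DataFrame with the reason.

    Downstream group comparisons use the gaussian model path plus
    multivariate-t post hocs rather than re-implementing ANOVA here.
    """
    df = records.copy()
    bad = (df[gfp_column] <= 0) | (df[dsred_column] <= 0) | df[gfp_column].isna() | df[dsred_column].isna()
    rejected = df.loc[bad].copy()
    rejected["reason"] = "non-positive or missing intensity"
    df = df.loc[~bad].copy()
    ctrl = df[condition_column] == control_label
    if not ctrl.any():
        raise ValueError(f"control group {control_label!r} empty after filtering")
    df["log2_ratio"] = np.log2(df[gfp_column] / df[dsred_column])
    df["normalized"] = df["log2_ratio"] - df.loc[ctrl, "log2_ratio"].mean()
    return df, rejected


def eggs_per_worm(counts: pd.DataFrame, n_prey: int | pd.Series | str = "n_prey") -> pd.Series:
    """Total eggs per prey animal for each arena record.

    ``n_prey`` is a column name in ``counts``, a Series aligned to it, or a
    single integer (e.g. 6 prey in mock arenas vs 3 in predator arenas when
    supplied per-row).
    """
    if isinstance(n_prey, str):
        n = counts[n_prey]
    else:
        n = pd.Series(n_prey, index=counts.index) if np.isscalar(n_prey) else pd.Series(n_prey)
    if (n < 1).any():
        raise ValueError("n_prey must be >= 1 for every arena")
    return (counts["n_off"] + counts["n_on"]) / n


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Fisher's exact test of a 2x2 contingency table (two-sided).

    Used for eurystomatous vs stenostomatous mouthform counts across
    conditions.  The two-sided p sums hypergeometric probabilities of all
    tables (at fixed margins) no more probable than the observed one; the
    sample odds ratio is reported (inf/nan for zero cells as appropriate).
    A zero margin carries no information: p = 1 with a warning.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t != np.floor(t)) or np.any(t < 0):
            raise ValueError("counts must be nonnegative integers")
        t = t.astype(int)
    if 0 in t.sum(axis=0) or 0 in t.sum(axis=1):
        import warnings

        warnings.warn("zero margin; Fisher test uninformative (p = 1)", stacklevel=2)
        a, b, c, d = t.ravel()
        orr = np.nan if (b * c == 0 and a * d == 0) else (np.inf if b * c == 0 else a * d / (b * c))
        return float(orr), 1.0
    res = stats.fisher_exact(t, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
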