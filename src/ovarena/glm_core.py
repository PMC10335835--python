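"""Binomial (logit-link) and gaussian linear models with factorial designs.

The behavioral readout — the probability P(off) that an egg is laid off the
bacterial lawn — is modeled on the logit scale,

    log( P(off) / (1 - P(off)) ) = X @ beta,

with per-arena (n_off, n_on) counts as binomial responses and factorial
designs of condition, genotype, lawn type and (continuous) time.  The module
provides treatment-coded design construction, maximum-likelihood fitting by
iteratively reweighted least squares (IRLS), likelihood-ratio analysis of
deviance with marginality-respecting (Type II) term tests, inverse-logit
predictions with confidence intervals, the analogous gaussian least-squares
path for egg-count and fluorescence responses, and a Brown-Forsythe
(median-centered Levene) spread test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, gammaln, logit

__all__ = [
    "DesignMatrix",
    "DesignSpec",
    "DevianceTable",
    "GLMFit",
    "GLMPrediction",
    "Term",
    "analysis_of_deviance",
    "build_design",
    "fit_binomial_glm",
    "fit_gaussian_lm",
    "levene_test",
    "predict_poff",
]

#: normal quantile for 95% confidence intervals
Z_95 = 1.959964

#: |beta| beyond which a non-converged binomial fit is reported as separated
SEPARATION_BOUND = 15.0


@dataclass(frozen=True)
class Term:
    """One model term: a categorical factor (with declared reference level)
    or a continuous covariate."""

    name: str
    kind: str = "categorical"  # "categorical" | "continuous"
    reference: object | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "continuous"):
            raise ValueError(f"unknown term kind {self.kind!r}")


@dataclass
class DesignSpec:
    """Model specification: response family, ordered terms, interaction order.

    ``interaction_order`` n includes all products of up to n distinct terms
    (a full factorial truncated at order n).
    """

    response: str  # "binomial_counts" | "gaussian"
    terms: list[Term]
    interaction_order: int = 1

    def __post_init__(self) -> None:
        if self.response not in ("binomial_counts", "gaussian"):
            raise ValueError(f"unknown response {self.response!r}")
        if not 1 <= self.interaction_order <= len(self.terms):
            raise ValueError("interaction_order must be between 1 and the number of terms")

    @property
    def term_groups(self) -> list[tuple[str, ...]]:
        """All term-name tuples in the model, mains first then interactions."""
        names = [t.name for t in self.terms]
        groups: list[tuple[str, ...]] = []
        for order in range(1, self.interaction_order + 1):
            groups.extend(itertools.combinations(names, order))
        return groups

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "DesignSpec":
        """Build from a plain config mapping (e.g. parsed model YAML)."""
        terms = [
            Term(t["name"], t.get("type", t.get("kind", "categorical")), t.get("reference"))
            for t in cfg["terms"]
        ]
        return cls(
            response=cfg.get("response", "binomial_counts"),
            terms=terms,
            interaction_order=int(cfg.get("interaction_order", 1)),
        )


@dataclass
class DesignMatrix:
    """Treatment-coded design matrix with enough metadata to re-encode new
    factor settings (for prediction and contrast construction)."""

    X: np.ndarray
    labels: list[str]
    spec: DesignSpec
    levels: dict[str, list]          # observed level order per categorical factor
    dropped: list[str] = field(default_factory=list)  # aliased columns removed

    @property
    def n_coef(self) -> int:
        return self.X.shape[1]

    def row(self, settings: Mapping[str, object]) -> np.ndarray:
        """Design row for one combination of factor levels / covariate values.

        Raises ``KeyError`` for a factor level never seen in the training data.
        """
        cols = {"Intercept": 1.0}
        for term in self.spec.terms:
            if term.name not in settings:
                raise KeyError(f"no value supplied for term {term.name!r}")
            value = settings[term.name]
            if term.kind == "continuous":
                cols[term.name] = float(value)
            else:
                lv = self.levels[term.name]
                if value not in lv:
                    raise KeyError(f"unseen level {value!r} for factor {term.name!r}")
                for level in lv[1:]:
                    cols[f"{term.name}[{level}]"] = 1.0 if value == level else 0.0
        out = np.zeros(len(self.labels))
        for j, label in enumerate(self.labels):
            out[j] = np.prod([cols[p] for p in label.split(":")]) if label != "Intercept" else 1.0
        return out


def _term_columns(
    df: pd.DataFrame, term: Term, levels: dict[str, list]
) -> list[tuple[str, np.ndarray]]:
    if term.kind == "continuous":
        vals = pd.to_numeric(df[term.name]).to_numpy(float)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite values in continuous term {term.name!r}")
        return [(term.name, vals)]
    observed = list(pd.unique(df[term.name]))
    ref = term.reference if term.reference is not None else observed[0]
    if ref not in observed:
        raise ValueError(f"reference level {ref!r} of {term.name!r} not among observed levels")
    ordered = [ref] + [l for l in observed if l != ref]
    levels[term.name] = ordered
    return [
        (f"{term.name}[{lev}]", (df[term.name] == lev).to_numpy(float)) for lev in ordered[1:]
    ]


def build_design(
    data: pd.DataFrame, spec: DesignSpec, term_groups: Sequence[tuple[str, ...]] | None = None
) -> DesignMatrix:
    """Build the treatment-coded design matrix for ``spec`` on ``data``.

    Categorical factors are reference-cell coded (indicator per non-reference
    level); interaction columns are elementwise products of the parent
    columns.  Aliased (rank-deficient) columns are dropped with a warning and
    recorded in ``DesignMatrix.dropped``.

    ``term_groups`` restricts the model to a subset of the spec's term tuples
    (used internally for analysis-of-deviance submodels).
    """
    levels: dict[str, list] = {}
    base = {t.name: _term_columns(data, t, levels) for t in spec.terms}
    groups = list(term_groups) if term_groups is not None else spec.term_groups

    labels = ["Intercept"]
    cols = [np.ones(len(data))]
    for group in groups:
        parts = [base[name] for name in group]
        for combo in itertools.product(*parts):
            labels.append(":".join(lab for lab, _ in combo))
            col = np.ones(len(data))
            for _, vals in combo:
                col = col * vals
            cols.append(col)
    X = np.column_stack(cols)

    # drop aliased columns via pivoted QR
    rank = np.linalg.matrix_rank(X)
    dropped: list[str] = []
    if rank < X.shape[1]:
        _, r, piv = _pivoted_qr(X)
        keep = np.sort(piv[:rank])
        dropped = [labels[j] for j in range(X.shape[1]) if j not in keep]
        warnings.warn(f"rank-deficient design; dropped aliased column(s): {dropped}", stacklevel=2)
        X = X[:, keep]
        labels = [labels[j] for j in keep]
    return DesignMatrix(X=X, labels=labels, spec=spec, levels=levels, dropped=dropped)


def _pivoted_qr(X: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(X, mode="economic", pivoting=True)
    return q, r, piv


@dataclass
class GLMFit:
    """A fitted binomial or gaussian linear model."""

    beta: np.ndarray
    cov_beta: np.ndarray
    deviance: float
    null_deviance: float
    loglik: float
    df_residual: int
    family: str                     # "binomial" | "gaussian"
    design: DesignMatrix
    converged: bool = True
    n_iter: int = 0
    dispersion: float | None = None  # gaussian residual variance
    separated: bool = False

    @property
    def labels(self) -> list[str]:
        return self.design.labels

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "labels": self.labels,
            "beta": self.beta.tolist(),
            "cov_beta": self.cov_beta.tolist(),
            "deviance": self.deviance,
            "null_deviance": self.null_deviance,
            "loglik": self.loglik,
            "df_residual": self.df_residual,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "dispersion": self.dispersion,
        }


def _binom_loglik(y: np.ndarray, n: np.ndarray, p: np.ndarray) -> float:
    const = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
    return float(np.sum(const + y * np.log(p) + (n - y) * np.log1p(-p)))


def _binom_deviance(y: np.ndarray, n: np.ndarray, p: np.ndarray) -> float:
    mu = n * p
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        t2 = np.where(n - y > 0, (n - y) * np.log((n - y) / (n - mu)), 0.0)
    return float(2.0 * np.sum(t1 + t2))


def fit_binomial_glm(
    design: DesignMatrix,
    counts: np.ndarray | pd.DataFrame,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> GLMFit:
    """Maximum-likelihood logistic fit of (n_off, n_on) counts by IRLS.

    Iterates weighted least squares on the working response until the
    relative deviance change drops below ``tol``, with step-halving whenever
    a step increases the deviance.  ``cov_beta`` is the inverse expected
    information at the optimum.  Complete/quasi-separation is reported via
    ``separated`` when the fit fails to converge with a coefficient beyond
    +/-15 on the logit scale.
    """
    c = counts[["n_off", "n_on"]].to_numpy(float) if isinstance(counts, pd.DataFrame) else np.asarray(counts, float)
    y, n = c[:, 0], c[:, 0] + c[:, 1]
    if np.any(n < 1):
        raise ValueError("every unit needs n_off + n_on >= 1")
    X = design.X

    beta = np.zeros(X.shape[1])
    eta = logit((y + 0.5) / (n + 1.0))  # empirical-logit start
    p = expit(eta)
    dev = _binom_deviance(y, n, p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = n * p * (1 - p)
        z = eta + (y - n * p) / w
        sw = np.sqrt(w)
        new_beta, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        step = new_beta - beta
        # step-halving on deviance increase
        for _ in range(30):
            cand = beta + step
            eta_c = X @ cand
            p_c = expit(eta_c)
            dev_c = _binom_deviance(y, n, p_c)
            if dev_c <= dev + 1e-12:
                break
            step = step / 2.0
        beta, eta, p = cand, eta_c, p_c
        old_dev, dev = dev, dev_c
        if abs(old_dev - dev) < tol * (abs(dev) + 0.1):
            converged = True
            break

    # a coefficient diverging past the logit bound marks complete or
    # quasi-separation: the MLE does not exist and the fit is not trusted
    separated = bool(np.any(np.abs(beta) > SEPARATION_BOUND))
    if separated:
        converged = False
        warnings.warn(
            "complete or quasi-separation suspected (|beta| exceeds "
            f"{SEPARATION_BOUND} on the logit scale); estimates diverge",
            stacklevel=2,
        )
    elif not converged:
        warnings.warn("IRLS did not converge within max_iter", stacklevel=2)

    w = n * p * (1 - p)
    info = X.T @ (X * w[:, None])
    cov = np.linalg.pinv(info)
    p0 = np.full_like(p, y.sum() / n.sum())
    return GLMFit(
        beta=beta,
        cov_beta=cov,
        deviance=dev,
        null_deviance=_binom_deviance(y, n, p0),
        loglik=_binom_loglik(y, n, np.clip(p, 1e-300, 1 - 1e-16)),
        df_residual=len(y) - X.shape[1],
        family="binomial",
        design=design,
        converged=converged,
        n_iter=it,
        separated=separated,
    )


def fit_gaussian_lm(design: DesignMatrix, y: np.ndarray | pd.Series) -> GLMFit:
    """Ordinary least squares with the same fit container as the binomial path.

    ``dispersion`` is the residual mean square (RSS / df_residual) and
    ``cov_beta = dispersion * (X'X)^-1``.
    """
    yv = np.asarray(y, float)
    X = design.X
    if len(yv) <= X.shape[1]:
        raise ValueError("need more observations than coefficients")
    beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
    resid = yv - X @ beta
    rss = float(resid @ resid)
    df_resid = len(yv) - X.shape[1]
    sigma2 = rss / df_resid if df_resid > 0 else np.nan
    xtx_inv = np.linalg.pinv(X.T @ X)
    tss = float(np.sum((yv - yv.mean()) ** 2))
    n_obs = len(yv)
    # gaussian loglik at the MLE variance rss/n
    s2_ml = max(rss / n_obs, 1e-300)
    loglik = -0.5 * n_obs * (np.log(2 * np.pi * s2_ml) + 1.0)
    return GLMFit(
        beta=beta,
        cov_beta=sigma2 * xtx_inv,
        deviance=rss,
        null_deviance=tss,
        loglik=loglik,
        df_residual=df_resid,
        family="gaussian",
        design=design,
        converged=True,
        n_iter=1,
        dispersion=sigma2,
    )


@dataclass
class DevianceTable:
    """Per-term likelihood-ratio (or F) tests from analysis of deviance."""

    table: pd.DataFrame  # index: term; columns: statistic, df, p_value (+df_denom for F)
    kind: str            # "LR" | "F"

    def __repr__(self) -> str:  # pragma: no cover
        return f"DevianceTable(kind={self.kind!r})\n{self.table}"


def _contains(inner: tuple[str, ...], outer: tuple[str, ...]) -> bool:
    return set(inner) < set(outer)


def _fit_group_model(data, spec, groups, response):
    design = build_design(data, spec, term_groups=groups)
    if spec.response == "binomial_counts":
        return fit_binomial_glm(design, response)
    return fit_gaussian_lm(design, response)


def analysis_of_deviance(
    data: pd.DataFrame,
    spec: DesignSpec,
    response: np.ndarray | pd.DataFrame | pd.Series | None = None,
) -> DevianceTable:
    """Marginality-respecting (Type II) likelihood-ratio tests per model term.

    For each term T the comparison is between the model containing every term
    that does not contain T, with and without T itself; the statistic is the
    deviance difference on chi-squared df equal to the coefficients removed.
    Gaussian models use the analogous F tests on residual sums of squares.

    ``response`` defaults to the ``n_off``/``n_on`` columns of ``data`` for
    binomial specs.
    """
    if response is None:
        if spec.response != "binomial_counts":
            raise ValueError("response vector required for gaussian models")
        response = data[["n_off", "n_on"]]

    all_groups = spec.term_groups
    full = _fit_group_model(data, spec, all_groups, response)
    if spec.response == "binomial_counts" and not full.converged:
        raise RuntimeError("full model did not converge; analysis of deviance aborted")

    rows = []
    for term in all_groups:
        others = [g for g in all_groups if g != term and not _contains(term, g)]
        try:
            with_term = _fit_group_model(data, spec, others + [term], response)
            without_term = _fit_group_model(data, spec, others, response)
        except RuntimeError:
            rows.append((":".join(term), np.nan, 0, np.nan))
            continue
        df_term = without_term.df_residual - with_term.df_residual
        if spec.response == "binomial_counts":
            if not (with_term.converged and without_term.converged):
                rows.append((":".join(term), np.nan, df_term, np.nan))
                continue
            lr = max(without_term.deviance - with_term.deviance, 0.0)
            pval = stats.chi2.sf(lr, df_term) if df_term >= 1 else np.nan
            rows.append((":".join(term), lr, df_term, pval))
        else:
            rss_gap = max(without_term.deviance - with_term.deviance, 0.0)
            f = (rss_gap / df_term) / full.dispersion
            pval = stats.f.sf(f, df_term, full.df_residual)
            rows.append((":".join(term), f, df_term, pval))

    table = pd.DataFrame(rows, columns=["term", "statistic", "df", "p_value"]).set_index("term")
    if spec.response == "gaussian":
        table["df_denom"] = full.df_residual
    return DevianceTable(table=table, kind="LR" if spec.response == "binomial_counts" else "F")


@dataclass
class GLMPrediction:
    """Expected response with a 95% confidence interval.

    For binomial fits the interval is computed on the logit scale and
    back-transformed, so it is asymmetric about the point estimate and always
    inside (0, 1).
    """

    p: np.ndarray
    eta: np.ndarray
    se_eta: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"p": self.p, "eta": self.eta, "se_eta": self.se_eta,
             "ci_low": self.ci_low, "ci_high": self.ci_high}
        )


def predict_poff(
    fit: GLMFit, newdata: Mapping[str, object] | Sequence[Mapping[str, object]] | pd.DataFrame
) -> GLMPrediction:
    """Expected P(off) (or gaussian mean) with 95% CI at new factor settings.

    ``newdata`` is a single mapping of term -> level/value, a sequence of
    such mappings, or a DataFrame with one column per term.
    """
    if isinstance(newdata, Mapping):
        records = [newdata]
    elif isinstance(newdata, pd.DataFrame):
        records = newdata.to_dict("records")
    else:
        records = list(newdata)
    rows = np.array([fit.design.row(r) for r in records])
    eta = rows @ fit.beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", rows, fit.cov_beta, rows))
    lo, hi = eta - Z_95 * se, eta + Z_95 * se
    if fit.family == "binomial":
        return GLMPrediction(p=expit(eta), eta=eta, se_eta=se, ci_low=expit(lo), ci_high=expit(hi))
    return GLMPrediction(p=eta, eta=eta, se_eta=se, ci_low=lo, ci_high=hi)


def levene_test(values: np.ndarray | pd.Series, groups: np.ndarray | pd.Series) -> tuple[float, float]:
    """Brown-Forsythe test of equal spread across groups.

    One-way ANOVA F on absolute deviations from group medians; robust check
    for heteroscedasticity before/after log transformation of fluorescence
    intensities.  Requires >= 2 groups with >= 2 observations each.
    """
    v = np.asarray(values, float)
    g = np.asarray(groups)
    samples = [v[g == lev] for lev in pd.unique(g)]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if all(np.ptp(s) == 0 for s in samples):
        raise ValueError("zero spread in every group; statistic undefined")
    stat, p = stats.levene(*samples, center="median")
    return float(stat), float(p)
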