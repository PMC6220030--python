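"""Per-probe region-specificity models with empirical-Bayes variance moderation.

Each probe's log2 expression is regressed on an intercept, donor indicator
variables, and an indicator for the focal region.  The residual variances
are then shrunk toward a common prior value estimated from all probes (a
scaled inverse-chi-square prior with ``d0`` degrees of freedom and scale
``s0sq``), and the focal-region coefficient is tested with a moderated
t-statistic on ``d0 + d`` degrees of freedom.

The prior is fitted by the method of moments on log variances: with
``e_g = log s2_g - psi(d/2) + log(d/2)`` the excess spread of ``e`` over
the chi-square sampling spread identifies ``d0`` through a trigamma
inversion, and its mean identifies ``s0sq``.  When the observed spread
does not exceed the sampling spread, ``d0`` is infinite and all variances
are shrunk to the common value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionBundle

logger = logging.getLogger(__name__)

__all__ = [
    "VariancePrior",
    "DesignError",
    "fit_region_model",
    "estimate_variance_prior",
    "moderate",
    "bh_adjust",
    "significant_upregulated",
    "trigamma_inverse",
]


class DesignError(ValueError):
    """The region/donor design cannot be fit (absent region, collinearity)."""


@dataclass(frozen=True)
class VariancePrior:
    """Scaled inverse-chi-square prior on per-probe residual variances.

    ``d0`` may be ``math.inf`` when the empirical spread of log variances
    is no larger than chi-square sampling noise.
    """

    d0: float
    s0sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValueError("d0 must be positive (possibly inf)")
        if not (self.s0sq > 0):
            raise ValueError("s0sq must be positive")


def build_design(sample_annot: pd.DataFrame, focal_region: str) -> pd.DataFrame:
    """Intercept + (n_donors - 1) donor indicators + focal-region indicator.

    Donors lacking the focal region still contribute samples (their region
    indicator is simply 0 throughout).
    """
    regions = sample_annot["region_name"]
    if focal_region not in set(regions):
        raise DesignError(f"focal region {focal_region!r} absent from the atlas")
    donors = sorted(sample_annot["donor_id"].unique())
    cols = {"intercept": np.ones(len(sample_annot))}
    for donor in donors[1:]:
        cols[f"donor_{donor}"] = (sample_annot["donor_id"] == donor).to_numpy(float)
    cols["focal"] = (regions == focal_region).to_numpy(float)
    design = pd.DataFrame(cols, index=sample_annot.index)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        raise DesignError(
            f"design for focal region {focal_region!r} is rank-deficient "
            f"(rank {rank} < {design.shape[1]} columns); a donor's samples "
            "may coincide with the focal indicator"
        )
    return design


def fit_region_model(bundle: ExpressionBundle, focal_region: str) -> pd.DataFrame:
    """Ordinary least squares for every probe against the shared design.

    Returns a DataFrame indexed by probe id with columns ``beta`` (focal
    coefficient, log2 units), ``s2`` (residual variance), ``d`` (residual
    degrees of freedom), ``v`` (unscaled coefficient variance for the focal
    column), ``stderr_unmoderated`` and ``t_ordinary``.
    """
    n = bundle.n_samples
    if n < 4 and len(bundle.donors) < 2:
        raise DesignError("need >=2 donors or >=4 samples to fit the region model")
    design = build_design(bundle.sample_annot, focal_region)
    X = design.to_numpy()
    Y = bundle.matrix.to_numpy()  # probes x samples
    p = X.shape[1]
    d = n - p
    if d < 1:
        raise DesignError(f"no residual degrees of freedom (n={n}, rank={p})")
    xtx_inv = np.linalg.inv(X.T @ X)
    coef = Y @ X @ xtx_inv.T  # probes x p
    resid = Y - coef @ X.T
    rss = np.einsum("ij,ij->i", resid, resid)
    rss = np.maximum(rss, 0.0)
    s2 = rss / d
    v = float(xtx_inv[-1, -1])
    beta = coef[:, -1]
    stderr = np.sqrt(s2 * v)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ord = np.where(stderr > 0, beta / stderr, np.where(beta == 0, 0.0, np.inf * np.sign(beta)))
    return pd.DataFrame(
        {
            "beta": beta,
            "s2": s2,
            "d": float(d),
            "v": v,
            "stderr_unmoderated": stderr,
            "t_ordinary": t_ord,
        },
        index=bundle.matrix.index.copy(),
    )


def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve ``psi'(x) = y`` for x > 0 by Newton iteration with a bisection fallback."""
    if y <= 0:
        return math.inf
    # Newton on f(x) = trigamma(x) - y; trigamma is convex decreasing
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        f = float(special.polygamma(1, x)) - y
        fprime = float(special.polygamma(2, x))
        step = f / fprime
        x_new = x - step
        if x_new <= 0:
            break
        if abs(x_new - x) < tol * (1 + abs(x)):
            return x_new
        x = x_new
    # bisection fallback on a bracketing interval
    lo, hi = 1e-8, 1e8
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        if float(special.polygamma(1, mid)) > y:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1 + tol:
            return math.sqrt(lo * hi)
    return math.sqrt(lo * hi)


def estimate_variance_prior(s2_values: np.ndarray, d: float) -> VariancePrior:
    """Fit (d0, s0sq) from per-probe sample variances with d residual df.

    Zero variances are excluded from moment estimation.  Returns an
    infinite ``d0`` (complete shrinkage) when the log-variance spread does
    not exceed chi-square sampling noise.
    """
    s2 = np.asarray(s2_values, dtype=float)
    s2 = s2[np.isfinite(s2)]
    positive = s2[s2 > 0]
    if positive.size == 0:
        raise ValueError("all residual variances are zero; degenerate atlas")
    if positive.size < 100:
        logger.warning(
            "variance prior estimated from only %d positive variances", positive.size
        )
    half_d = d / 2.0
    e = np.log(positive) - special.digamma(half_d) + math.log(half_d)
    emean = float(np.mean(e))
    if positive.size > 1:
        evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, half_d))
    else:
        evar = -1.0
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0sq = math.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    else:
        # no excess spread beyond sampling noise: complete shrinkage to the
        # geometric-mean common variance
        d0 = math.inf
        s0sq = math.exp(float(np.mean(np.log(positive))))
    return VariancePrior(d0=d0, s0sq=s0sq)


def moderate(stats_df: pd.DataFrame, prior: VariancePrior) -> pd.DataFrame:
    """Moderated t-statistics: shrink s2 toward the prior, test on d0 + d df.

    ``s2_tilde = (d0*s0sq + d*s2) / (d0 + d)``;
    ``t_tilde = beta / sqrt(s2_tilde * v)``; two-sided p on ``d0 + d``
    degrees of freedom (normal when d0 is infinite); q is the BH adjustment.
    """
    beta = stats_df["beta"].to_numpy(float)
    s2 = stats_df["s2"].to_numpy(float)
    d = stats_df["d"].to_numpy(float)
    v = stats_df["v"].to_numpy(float)
    d0, s0sq = prior.d0, prior.s0sq
    if math.isinf(d0):
        s2_tilde = np.full_like(s2, s0sq)
        df_total = np.full_like(s2, np.inf)
    else:
        s2_tilde = (d0 * s0sq + d * s2) / (d0 + d)
        df_total = d0 + d
    with np.errstate(divide="ignore", invalid="ignore"):
        t_tilde = np.where(
            s2_tilde > 0,
            beta / np.sqrt(s2_tilde * v),
            np.where(beta == 0, 0.0, np.inf * np.sign(beta)),
        )
    if math.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(t_tilde))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_tilde), df_total)
    p = np.clip(p, 0.0, 1.0)
    out = stats_df.copy()
    out["s2_tilde"] = s2_tilde
    out["t_tilde"] = t_tilde
    out["df_total"] = df_total
    out["p"] = p
    out["q"] = bh_adjust(p)
    return out


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def significant_upregulated(moderated: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Probes with q strictly below alpha and a positive focal effect, by p ascending."""
    mask = (moderated["q"] < alpha) & (moderated["beta"] > 0)
    return moderated.loc[mask].sort_values("p", kind="mergesort")
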