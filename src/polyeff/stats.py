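"""Per-gene transcription (TC) and translation (TL) efficiency statistics.

The design is a four-cell gene-wise linear model over (fraction, time):

    TL = (p6 - p0) - (np6 - np0)        # translation efficiency
    TC = (p6 + np6)/2 - (p0 + np0)/2    # transcription efficiency

where p/np denote per-gene condition means (log2) of the polysomal and
non-polysomal fractions.  Both contrasts are tested with an empirical-Bayes
moderated t-statistic: gene-wise residual variances s_g^2 (pooled over the
four cells, d_g = N - 4 df) are shrunk toward a prior s0^2 with d0 prior
degrees of freedom, estimated across genes by method of moments on
log(s_g^2).  Raw two-sided p-values are adjusted by Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .datamodel import ExpressionDataset, FormatError

__all__ = [
    "ConditionMeans",
    "ModerationPrior",
    "condition_means",
    "efficiencies",
    "estimate_prior",
    "moderated_t",
    "bh_adjust",
    "analyze",
]

# contrast scale = sum(c_i^2)/r for the cell-mean contrast
TL_CONTRAST_SCALE_NUM = 4.0  # coefficients (+1, -1, -1, +1)
TC_CONTRAST_SCALE_NUM = 1.0  # coefficients (+1/2, +1/2, -1/2, -1/2)


@dataclass
class ConditionMeans:
    """Per-gene design-cell means and pooled residual variance."""

    genes: list[str]
    p0: np.ndarray
    p6: np.ndarray
    np0: np.ndarray
    np6: np.ndarray
    s_sq: np.ndarray
    df: int
    n_per_cell: dict[tuple[str, int], int] | None = None


@dataclass(frozen=True)
class ModerationPrior:
    """Hyperparameters of the scaled inverse-chi-square variance prior."""

    d0: float  # prior degrees of freedom; may be +inf
    s0_sq: float  # prior variance, log2^2

    def __post_init__(self) -> None:
        if not self.d0 > 0:
            raise ValueError("d0 must be positive")
        if not self.s0_sq > 0:
            raise ValueError("s0_sq must be positive")


def condition_means(data: ExpressionDataset) -> ConditionMeans:
    """Arithmetic cell means plus pooled within-cell variance (d = N - 4)."""
    data.validate_design(min_replicates=2)
    cells = data.cell_columns()
    n_total = data.n_samples
    df = n_total - 4
    if df < 1:
        raise FormatError(
            f"residual degrees of freedom {df} < 1; need more replicates"
        )
    means = {}
    sse = np.zeros(data.n_genes)
    for cell, cols in cells.items():
        block = data.values[:, cols]
        m = block.mean(axis=1)
        means[cell] = m
        sse += ((block - m[:, None]) ** 2).sum(axis=1)
    return ConditionMeans(
        genes=list(data.genes),
        p0=means[("polysomal", 0)],
        p6=means[("polysomal", 6)],
        np0=means[("nonpolysomal", 0)],
        np6=means[("nonpolysomal", 6)],
        s_sq=sse / df,
        df=df,
        n_per_cell={c: len(cols) for c, cols in cells.items()},
    )


def efficiencies(means: ConditionMeans) -> tuple[np.ndarray, np.ndarray]:
    """Return per-gene (TC, TL).

    Identity: p6 - p0 = TC + TL/2 and np6 - np0 = TC - TL/2.
    """
    tl = (means.p6 - means.p0) - (means.np6 - means.np0)
    tc = (means.p6 + means.np6) / 2.0 - (means.p0 + means.np0) / 2.0
    return tc, tl


def _trigamma(x: np.ndarray | float) -> np.ndarray | float:
    return special.polygamma(1, x)


def _solve_trigamma(y: float, tol: float = 1e-10) -> float:
    """Solve trigamma(x) = y for x > 0 by bisection (trigamma is strictly
    decreasing from +inf to 0)."""
    lo, hi = 1e-3, 10.0
    while _trigamma(lo) < y:
        lo /= 10.0
        if lo < 1e-300:
            raise ArithmeticError("trigamma inversion underflow")
    while _trigamma(hi) > y:
        hi *= 10.0
        if hi > 1e300:
            raise ArithmeticError("trigamma inversion overflow")
    while hi - lo > tol * max(1.0, lo):
        mid = 0.5 * (lo + hi)
        if _trigamma(mid) > y:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def estimate_prior(
    s_sq: np.ndarray, d_g: float | np.ndarray
) -> ModerationPrior:
    """Method-of-moments fit of (d0, s0^2) from gene-wise sample variances.

    Works on e_g = log(s_g^2) - digamma(d_g/2) + log(d_g/2), whose mean and
    excess variance identify the prior.  Genes with zero variance are
    excluded from the fit (log undefined); when the excess variance is
    non-positive the prior is degenerate (d0 = +inf).
    """
    s_sq = np.asarray(s_sq, dtype=float)
    d = np.broadcast_to(np.asarray(d_g, dtype=float), s_sq.shape)
    pos = s_sq > 0
    if not pos.any():
        raise ValueError("all gene variances are zero; cannot estimate a prior")
    s_pos, d_pos = s_sq[pos], d[pos]
    e = np.log(s_pos) - special.digamma(d_pos / 2.0) + np.log(d_pos / 2.0)
    mean_e = float(e.mean())
    if e.size < 2:
        return ModerationPrior(d0=np.inf, s0_sq=float(np.exp(mean_e)))
    var_e = float(e.var(ddof=1))
    excess = var_e - float(_trigamma(d_pos / 2.0).mean())
    if excess <= 0:
        return ModerationPrior(d0=np.inf, s0_sq=float(np.exp(mean_e)))
    half_d0 = _solve_trigamma(excess)
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(mean_e + special.digamma(half_d0) - np.log(half_d0)))
    return ModerationPrior(d0=d0, s0_sq=s0_sq)


def moderated_t(
    effect: np.ndarray | float,
    s_sq: np.ndarray | float,
    d_g: float,
    prior: ModerationPrior,
    contrast_scale: float,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Moderated t, two-sided p and total df for one contrast.

    Posterior variance s~^2 = (d0*s0^2 + d_g*s_g^2)/(d0 + d_g); the statistic
    is effect / sqrt(s~^2 * contrast_scale) on d0 + d_g df (normal when d0 is
    infinite).  ``contrast_scale`` is sum(c_i^2)/r: 4/r for TL, 1/r for TC.
    """
    effect = np.asarray(effect, dtype=float)
    s_sq = np.asarray(s_sq, dtype=float)
    if np.isinf(prior.d0):
        s_post = np.full_like(s_sq, prior.s0_sq)
        df_total = np.inf
    else:
        s_post = (prior.d0 * prior.s0_sq + d_g * s_sq) / (prior.d0 + d_g)
        df_total = prior.d0 + d_g
    se = np.sqrt(s_post * contrast_scale)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / np.where(se > 0, se, 1.0), 0.0)
    degenerate = (se == 0) & (effect != 0)
    if np.any(degenerate):
        warnings.warn(
            "zero posterior variance for some genes; p set to 0", RuntimeWarning
        )
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p = np.where(degenerate, 0.0, p)
    p = np.where((se == 0) & (effect == 0), 1.0, p)
    return t, p, df_total


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def analyze(
    data: ExpressionDataset,
    prior: ModerationPrior | None = None,
    include_spikeins: bool = False,
) -> pd.DataFrame:
    """Full per-gene efficiency table: TC, TL, t, p and fdr for both contrasts.

    The moderation prior is estimated from the data unless supplied.  Spike-in
    probes are excluded from both the prior fit and the output by default.
    """
    means = condition_means(data)
    tc, tl = efficiencies(means)
    keep = np.ones(data.n_genes, dtype=bool)
    if not include_spikeins:
        keep = ~data.spikein
    if prior is None:
        prior = estimate_prior(means.s_sq[keep], means.df)
    # sum of 1/n over the four cells; equals 4/r when balanced
    inv_n = sum(1.0 / n for n in means.n_per_cell.values())
    t_tl, p_tl, _ = moderated_t(
        tl[keep], means.s_sq[keep], means.df, prior, inv_n
    )
    t_tc, p_tc, _ = moderated_t(
        tc[keep], means.s_sq[keep], means.df, prior, inv_n / 4.0
    )
    genes = [g for g, k in zip(data.genes, keep) if k]
    return pd.DataFrame(
        {
            "gene_id": genes,
            "TC": tc[keep],
            "TL": tl[keep],
            "t_TC": t_tc,
            "t_TL": t_tl,
            "p_TC": p_tc,
            "p_TL": p_tl,
            "fdr_TC": bh_adjust(p_tc),
            "fdr_TL": bh_adjust(p_tl),
        }
    )
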