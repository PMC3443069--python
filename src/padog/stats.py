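"""Per-gene two-sample statistics: ordinary and moderated t-scores.

The moderated t shrinks each gene's residual variance toward a common prior
value estimated by empirical Bayes: the sample variances are modelled as
``s2_g ~ s0_sq * F(df, d0)`` and the prior parameters ``(d0, s0_sq)`` are
obtained by matching the mean and variance of ``log s2_g`` through the
digamma/trigamma identities of the log-F distribution. The shrunken variance
is the posterior mean ``(d0*s0_sq + df*s2_g) / (d0 + df)``.

All core routines accept a matrix of variances/effects with one row per
label permutation so a full permutation analysis is a handful of vectorised
array operations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import special

logger = logging.getLogger(__name__)

__all__ = [
    "GeneStats",
    "ordinary_t",
    "moderated_t",
    "fit_variance_prior",
    "trigamma_inverse",
]

_MIN_GENES_FOR_PRIOR = 10


@dataclass
class GeneStats:
    """Per-gene differential-expression statistics for one labelling."""

    gene_ids: list[str]
    effect: np.ndarray          # mean(case) - mean(control)
    t_ordinary: np.ndarray
    t_moderated: np.ndarray | None
    s2: np.ndarray              # residual variance
    df: int                     # residual degrees of freedom
    d0: float = 0.0             # prior degrees of freedom (may be inf)
    s0_sq: float = np.nan       # prior variance
    se_unit: float = np.nan     # design factor: se = sqrt(s2) * se_unit
    zero_variance: np.ndarray | None = None


def trigamma_inverse(y):
    """Solve ``trigamma(x) = y`` for x > 0 (vectorised Newton iteration).

    Newton steps are taken on 1/trigamma, which is nearly linear in x, so a
    handful of iterations reaches full double precision.
    """
    y = np.asarray(y, dtype=float)
    scalar = y.ndim == 0
    y = np.atleast_1d(y).copy()
    x = np.full_like(y, np.nan)
    big = y > 1e7          # trigamma(x) ~ 1/x for tiny x
    small = y < 1e-6       # trigamma(x) ~ 1/x for large x
    x[big] = 1.0 / np.sqrt(y[big])
    x[small] = 1.0 / y[small]
    todo = ~(big | small)
    if todo.any():
        z = y[todo]
        xt = 0.5 + 1.0 / z
        for _ in range(50):
            tri = special.polygamma(1, xt)
            dif = tri * (1.0 - tri / z) / special.polygamma(2, xt)
            xt = xt + dif
            if np.max(np.abs(dif / xt)) < 1e-8:
                break
        x[todo] = xt
    return float(x[0]) if scalar else x


def _pooled_group_stats(X: np.ndarray, case_masks: np.ndarray):
    """Effect / pooled variance for each gene under each case labelling.

    ``X`` is genes x samples, ``case_masks`` is labellings x samples boolean.
    Returns effect (R, G), s2 (R, G), residual df and the standard-error
    design unit sqrt(1/n1 + 1/n0). Group sizes are constant over labellings.
    """
    X = np.asarray(X, dtype=float)
    masks = np.atleast_2d(np.asarray(case_masks, dtype=bool))
    n = X.shape[1]
    n1 = int(masks[0].sum())
    n0 = n - n1
    if n1 < 2 or n0 < 2:
        raise ValueError(f"each group needs >=2 samples, got {n1} vs {n0}")
    m = masks.astype(float)
    sum1 = m @ X.T                      # (R, G)
    sumsq1 = m @ (X.T ** 2)
    tot = X.sum(axis=1)
    totsq = (X ** 2).sum(axis=1)
    sum0 = tot - sum1
    sumsq0 = totsq - sumsq1
    mean1 = sum1 / n1
    mean0 = sum0 / n0
    ss = (sumsq1 - n1 * mean1 ** 2) + (sumsq0 - n0 * mean0 ** 2)
    df = n1 + n0 - 2
    s2 = np.maximum(ss, 0.0) / df
    effect = mean1 - mean0
    unit = np.sqrt(1.0 / n1 + 1.0 / n0)
    return effect, s2, df, unit


def _paired_group_stats(diffs: np.ndarray, swaps: np.ndarray):
    """One-sample stats on within-block differences under sign flips.

    ``diffs`` is genes x blocks (case minus control per block); ``swaps`` is
    labellings x blocks in {+1, -1}. The sum of squared differences is
    flip-invariant, so only the mean changes across labellings.
    """
    D = np.asarray(diffs, dtype=float)
    W = np.atleast_2d(np.asarray(swaps, dtype=float))
    nb = D.shape[1]
    if nb < 2:
        raise ValueError(f"paired design needs >=2 blocks, got {nb}")
    mean_d = (W @ D.T) / nb             # (R, G)
    sumsq = (D ** 2).sum(axis=1)        # (G,)
    df = nb - 1
    s2 = np.maximum(sumsq - nb * mean_d ** 2, 0.0) / df
    unit = np.sqrt(1.0 / nb)
    return mean_d, s2, df, unit


def _t_from(effect, s2, unit):
    """t = effect / (sqrt(s2) * unit) with an infinity sentinel at s2 == 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / (np.sqrt(s2) * unit)
    zero = s2 <= 0.0
    if np.any(zero):
        t = np.where(zero & (effect > 0), np.inf, t)
        t = np.where(zero & (effect < 0), -np.inf, t)
        t = np.where(zero & (effect == 0), 0.0, t)
    return t, zero


def fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Estimate prior df ``d0`` and prior variance ``s0_sq`` from sample variances.

    Moment matching on ``log s2``: with ``e = log s2 - digamma(df/2) + log(df/2)``,
    ``E[e] = log s0_sq - digamma(d0/2) + log(d0/2)`` and
    ``Var[e] = trigamma(df/2) + trigamma(d0/2)``; the trigamma equation is
    inverted numerically. When the dispersion of ``log s2`` is at or below the
    sampling floor ``trigamma(df/2)``, ``d0 = inf`` and ``s0_sq = exp(mean e)``.
    Fewer than 10 finite positive variances: no shrinkage (``d0 = 0``), logged.
    """
    d0, s0 = _fit_variance_prior_rows(np.atleast_2d(np.asarray(s2, float)), df)
    return float(d0[0]), float(s0[0])


def _fit_variance_prior_rows(s2: np.ndarray, df: int):
    R, G = s2.shape
    ok = np.isfinite(s2) & (s2 > 0)
    n_ok = ok.sum(axis=1)
    e = np.where(ok, np.log(np.where(ok, s2, 1.0)), np.nan)
    e = e - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = np.nanmean(np.where(ok, e, np.nan), axis=1)
    # unbiased variance of e per row
    dev2 = np.where(ok, (e - emean[:, None]) ** 2, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        evar = dev2.sum(axis=1) / np.maximum(n_ok - 1, 1)
    target = evar - special.polygamma(1, df / 2.0)

    d0 = np.zeros(R)
    s0 = np.full(R, np.nan)
    few = n_ok < _MIN_GENES_FOR_PRIOR
    if few.any():
        logger.warning(
            "variance prior: %d labelling(s) with <%d usable variances; "
            "falling back to no shrinkage (d0=0)",
            int(few.sum()), _MIN_GENES_FOR_PRIOR,
        )
        # d0 stays 0; s0 undefined but unused when d0 == 0
    inf_rows = (~few) & (target <= 0)
    d0[inf_rows] = np.inf
    s0[inf_rows] = np.exp(emean[inf_rows])
    # exactly zero dispersion: the variances carry no sampling noise, so the
    # common value itself is the prior (skip the chi-square bias correction)
    hi = np.where(ok, s2, -np.inf).max(axis=1)
    lo = np.where(ok, s2, np.inf).min(axis=1)
    degenerate = (~few) & (hi == lo)
    if degenerate.any():
        s0[degenerate] = hi[degenerate]
        d0[degenerate] = np.inf
    fin = (~few) & (target > 0)
    if fin.any():
        half = trigamma_inverse(target[fin])
        d0[fin] = 2.0 * half
        s0[fin] = np.exp(emean[fin] + special.digamma(half) - np.log(half))
    return d0, s0


def _shrink_s2(s2: np.ndarray, df: int, d0: np.ndarray, s0_sq: np.ndarray):
    """Posterior-mean variance (d0*s0 + df*s2)/(d0 + df), rows = labellings."""
    d0c = np.atleast_1d(np.asarray(d0, float))[:, None]
    s0c = np.atleast_1d(np.asarray(s0_sq, float))[:, None]
    out = np.empty_like(s2)
    finite = np.isfinite(d0c)[:, 0]
    if finite.any():
        out[finite] = (d0c[finite] * s0c[finite] + df * s2[finite]) / (d0c[finite] + df)
    if (~finite).any():
        out[~finite] = np.broadcast_to(s0c[~finite], s2[~finite].shape)
    zero_prior = d0c[:, 0] == 0
    if zero_prior.any():
        out[zero_prior] = s2[zero_prior]
    return out


def _stats_for_masks(dataset, case_masks=None, swaps=None, moderated=True,
                     d0_override=None):
    """Internal driver returning (t, effect, s2, df, unit, d0, s0) as row-stacked arrays."""
    if dataset.block is not None and swaps is None and case_masks is None:
        swaps = np.ones((1, len(np.unique(dataset.block))))
    if swaps is not None:
        diffs = paired_differences(dataset)
        effect, s2, df, unit = _paired_group_stats(diffs, swaps)
    else:
        if case_masks is None:
            case_masks = dataset.is_case[None, :]
        effect, s2, df, unit = _pooled_group_stats(dataset.matrix, case_masks)
    t_ord, zero = _t_from(effect, s2, unit)
    if np.all(zero):
        raise ValueError("zero variance in every gene")
    if not moderated:
        return t_ord, t_ord, effect, s2, df, unit, np.zeros(len(s2)), np.full(len(s2), np.nan), zero
    if d0_override is not None and d0_override == 0:
        d0 = np.zeros(len(s2))
        s0 = np.full(len(s2), np.nan)
    else:
        d0, s0 = _fit_variance_prior_rows(s2, df)
    s2_shr = _shrink_s2(s2, df, d0, s0)
    t_mod, _ = _t_from(effect, s2_shr, unit)
    return t_ord, t_mod, effect, s2, df, unit, d0, s0, zero


def paired_differences(dataset) -> np.ndarray:
    """Genes x blocks matrix of (case - control) differences."""
    if dataset.block is None:
        raise ValueError("dataset has no pairing blocks")
    case = dataset.is_case
    blocks = np.unique(dataset.block)
    D = np.empty((dataset.n_genes, len(blocks)))
    for j, b in enumerate(blocks):
        sel = dataset.block == b
        D[:, j] = dataset.matrix[:, sel & case].ravel() - dataset.matrix[:, sel & ~case].ravel()
    return D


def ordinary_t(dataset, paired: bool | None = None) -> GeneStats:
    """Ordinary two-sample t-scores (pooled variance) or paired one-sample t.

    Paired analysis is used automatically when the dataset carries blocks,
    unless ``paired=False`` forces the unpaired path.
    """
    use_paired = dataset.block is not None if paired is None else paired
    if use_paired:
        nb = len(np.unique(dataset.block))
        t, _, eff, s2, df, unit, d0, s0, zero = _stats_for_masks(
            dataset, swaps=np.ones((1, nb)), moderated=False)
    else:
        t, _, eff, s2, df, unit, d0, s0, zero = _stats_for_masks(
            dataset, case_masks=dataset.is_case[None, :], moderated=False)
    return GeneStats(dataset.gene_ids, eff[0], t[0], None, s2[0], df,
                     0.0, np.nan, unit, zero[0])


def moderated_t(dataset, paired: bool | None = None, d0: float | None = None) -> GeneStats:
    """Moderated t-scores with empirical-Bayes variance shrinkage.

    ``d0=0`` forces no shrinkage (moderated == ordinary); by default the
    prior is estimated from the data with :func:`fit_variance_prior`.
    """
    use_paired = dataset.block is not None if paired is None else paired
    kwargs = dict(moderated=True, d0_override=d0)
    if use_paired:
        nb = len(np.unique(dataset.block))
        res = _stats_for_masks(dataset, swaps=np.ones((1, nb)), **kwargs)
    else:
        res = _stats_for_masks(dataset, case_masks=dataset.is_case[None, :], **kwargs)
    t_ord, t_mod, eff, s2, df, unit, d0_est, s0, zero = res
    return GeneStats(dataset.gene_ids, eff[0], t_ord[0], t_mod[0], s2[0], df,
                     float(d0_est[0]), float(s0[0]), unit, zero[0])


def stats_table(stats: GeneStats):
    """Diagnostic per-gene table (gene_id, effect, t_ordinary, t_moderated, s2, flags)."""
    import pandas as pd

    return pd.DataFrame({
        "gene_id": stats.gene_ids,
        "effect": stats.effect,
        "t_ordinary": stats.t_ordinary,
        "t_moderated": stats.t_moderated if stats.t_moderated is not None else np.nan,
        "s2": stats.s2,
        "zero_variance": stats.zero_variance,
    })
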