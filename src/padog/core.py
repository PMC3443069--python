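"""The down-weighted gene set statistic and its permutation test.

For each gene ``g`` in ``G`` (the measured genes mapped to at least one
analysed set), let ``f(g)`` be the number of sets containing ``g`` (capped
at a high quantile to tame heavy-tailed collections) and

    w(g) = 1 + ((f_max - f(g)) / (f_max - f_min)) ** alpha

so set-specific genes carry weight 2 and ubiquitous genes weight 1; with
``alpha < 1`` the weight falls off faster at low frequencies. Each set is
scored by the mean of ``|T(g)| * w(g)`` over its genes, where ``T`` is the
moderated t-score. Scores are standardised twice: first against the mean and
standard deviation of ``|T| * w`` over all genes of ``G`` (the standard
deviation divided by ``sqrt(N)`` for a set of ``N`` genes, as the central
limit theorem gives for a mean of ``N`` random genes — no gene resampling is
needed), then across the collection (subtract the mean, divide by the sd of
the per-set scores). Significance comes from permuting sample labels and
recomputing everything; p is the fraction of permutations whose standardised
score meets or exceeds the observed one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .engine import PermutationEngine
from .io import ExpressionDataset, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "WeightingConfig",
    "PadogConfig",
    "GeneWeights",
    "gene_frequencies",
    "gene_weights",
    "set_score",
    "standardize_scores",
    "permutation_test",
    "bh_fdr",
]


@dataclass
class WeightingConfig:
    """Frequency-to-weight mapping parameters.

    ``cap_quantile=1.0`` disables frequency capping; ``alpha=1`` gives the
    plain linear ramp between weight 2 (rarest) and 1 (most frequent).
    """

    cap_quantile: float = 0.99
    alpha: float = 0.5

    def __post_init__(self):
        if not 0.0 < self.cap_quantile <= 1.0:
            raise ValueError("cap_quantile must be in (0, 1]")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


@dataclass
class PadogConfig:
    n_perm: int = 1000
    seed: int | None = None
    use_weights: bool = True
    use_moderated: bool = True
    paired: bool | None = None
    add_one: bool = False      # p = (b+1)/(R+1) instead of the literal b/R
    min_set_size: int = 3

    def __post_init__(self):
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


@dataclass
class GeneWeights:
    gene_ids: list[str]
    f: np.ndarray              # capped per-gene set frequency
    w: np.ndarray | None = None
    f_min: float = field(default=np.nan)
    f_max: float = field(default=np.nan)


def gene_frequencies(collection: GeneSetCollection, genes: list[str] | None = None,
                     cap_quantile: float = 0.99) -> GeneWeights:
    """Count, per gene of ``G``, the number of sets containing it; cap the tail.

    Frequencies above the ``cap_quantile`` quantile of the raw counts are
    replaced by that quantile value. Every gene of ``G`` belongs to at least
    one set, so f >= 1.
    """
    if genes is None:
        genes = sorted(collection.all_genes())
    counts = pd.Series(0.0, index=pd.Index(genes))
    for gset in collection.sets.values():
        hit = counts.index.intersection(gset)
        counts[hit] += 1.0
    f = counts.to_numpy()
    if np.any(f < 1):
        raise ValueError("every gene of G must appear in at least one set")
    if cap_quantile < 1.0:
        cap = float(np.quantile(f, cap_quantile))
        f = np.minimum(f, cap)
    return GeneWeights(list(genes), f, None, float(f.min()), float(f.max()))


def gene_weights(freqs: GeneWeights, cfg: WeightingConfig | None = None) -> GeneWeights:
    """Map capped frequencies to weights in [1, 2], decreasing in frequency."""
    cfg = cfg or WeightingConfig()
    f = freqs.f
    fmin, fmax = freqs.f_min, freqs.f_max
    if fmax > fmin:
        w = 1.0 + ((fmax - f) / (fmax - fmin)) ** cfg.alpha
    else:
        w = np.ones_like(f)
    return GeneWeights(freqs.gene_ids, f, w, fmin, fmax)


def set_score(abs_scores: np.ndarray, weights: np.ndarray, idx=None) -> float:
    """Mean of |T(g)| * w(g) over a set's genes (one set, one labelling)."""
    a = np.asarray(abs_scores, float)
    w = np.asarray(weights, float)
    if idx is not None:
        a, w = a[idx], w[idx]
    if a.size == 0:
        raise ValueError("empty gene set")
    return float(np.mean(a * w))


def standardize_scores(S0: np.ndarray, abs_weighted: np.ndarray, sizes: np.ndarray):
    """Two-stage standardisation of per-set scores (single labelling).

    Returns ``(S0_row, S0_star)``: the row-randomisation standardisation
    against the genome-wide |T|w distribution (sd scaled by 1/sqrt(N)), then
    the across-sets z-score.
    """
    S0 = np.asarray(S0, float)[None, :]
    aw = np.asarray(abs_weighted, float)[None, :]
    row, star = _standardize_rows(S0, aw, np.asarray(sizes, float))
    return row[0], star[0]


def _standardize_rows(S0: np.ndarray, abs_weighted: np.ndarray, sizes: np.ndarray):
    """Vectorised two-stage standardisation, rows = labellings."""
    mu = abs_weighted.mean(axis=1, keepdims=True)
    sd = abs_weighted.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd <= 0):
        raise ValueError("standard deviation of |T|*w over G is zero")
    row = (S0 - mu) / (sd / np.sqrt(sizes)[None, :])
    m = row.mean(axis=1, keepdims=True)
    s = row.std(axis=1, ddof=1, keepdims=True)
    star = np.zeros_like(row)
    ok = (s > 0)[:, 0]
    if not np.all(ok):
        logger.warning("across-set sd of standardised scores is zero for %d "
                       "labelling(s); scores set to 0", int((~ok).sum()))
    star[ok] = (row[ok] - m[ok]) / s[ok]
    return row, star


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, float)
    if p.size == 1:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def rank_pct(p: np.ndarray) -> np.ndarray:
    """Percentile rank by ascending p: i / N_GS * 100, average rank on ties."""
    s = pd.Series(p)
    return (s.rank(method="average") / len(s) * 100).to_numpy()


def scores_from_gene_stats(T: np.ndarray, weights: np.ndarray,
                           membership: np.ndarray, sizes: np.ndarray):
    """Per-set standardised scores for every labelling.

    ``T`` is labellings x genes, ``membership`` genes x sets (0/1).
    Infinite gene scores (zero-variance genes without shrinkage) are clipped
    to the largest finite magnitude so a single degenerate gene cannot
    poison a whole set.
    """
    A = np.abs(T)
    if not np.all(np.isfinite(A)):
        finite_max = np.nanmax(np.where(np.isfinite(A), A, np.nan))
        A = np.where(np.isfinite(A), A, finite_max)
    AW = A * weights[None, :]
    S0 = (AW @ membership) / sizes[None, :]
    row, star = _standardize_rows(S0, AW, sizes)
    return S0, row, star


def permutation_p(star: np.ndarray, add_one: bool = False) -> np.ndarray:
    """Fraction of permutation rows (1..R) at or above the observed row 0."""
    R = star.shape[0] - 1
    if R < 1:
        raise ValueError("need at least one permutation")
    # ties count against significance; the tolerance keeps exact theoretical
    # ties (e.g. the complement labelling) ties under floating-point noise
    tol = 1e-9 * (1.0 + np.abs(star[0]))
    b = (star[1:] >= (star[0] - tol)[None, :]).sum(axis=0)
    if add_one:
        return (b + 1.0) / (R + 1.0)
    return b / float(R)


def permutation_test(dataset: ExpressionDataset, collection: GeneSetCollection,
                     cfg: PadogConfig | None = None,
                     wcfg: WeightingConfig | None = None,
                     engine: PermutationEngine | None = None) -> pd.DataFrame:
    """Full down-weighted gene set analysis of one dataset.

    Returns one row per analysed set with columns ``set_id, name, size, S0,
    S0_star, p, q, rank_pct`` sorted by ascending p. An existing
    :class:`PermutationEngine` may be passed to share the permutation stream
    with other methods; otherwise one is built from ``cfg``.
    """
    cfg = cfg or PadogConfig()
    wcfg = wcfg or WeightingConfig()
    restricted, genes = collection.restrict_to_measured(dataset, cfg.min_set_size)
    if len(genes) == dataset.n_genes and list(genes) == list(dataset.gene_ids):
        sub = dataset
    else:
        gidx = pd.Index(dataset.gene_ids).get_indexer(genes)
        sub = ExpressionDataset(
            matrix=dataset.matrix[gidx], gene_ids=list(genes),
            sample_ids=dataset.sample_ids, group=dataset.group,
            control_level=dataset.control_level, block=dataset.block,
        )
    if engine is None:
        engine = PermutationEngine(sub, cfg.n_perm, cfg.seed, cfg.paired)
        logger.info("permutation test: %d permutations (exhaustive=%s), seed=%s",
                    engine.n_perm, engine.exhaustive, cfg.seed)
    if cfg.use_weights:
        w = gene_weights(gene_frequencies(restricted, genes, wcfg.cap_quantile), wcfg).w
    else:
        w = np.ones(len(genes))
    T = engine.t_moderated if cfg.use_moderated else engine.t_ordinary
    if list(engine.dataset.gene_ids) != list(genes):
        # engine built on the full matrix: select the mapped genes
        cols = pd.Index(engine.dataset.gene_ids).get_indexer(genes)
        T = T[:, cols]
    M = restricted.membership_matrix(pd.Index(genes))
    sizes = M.sum(axis=0)
    S0, row, star = scores_from_gene_stats(T, w, M, sizes)
    p = permutation_p(star, cfg.add_one)
    q = bh_fdr(p)
    out = pd.DataFrame({
        "set_id": restricted.set_ids,
        "name": [restricted.names.get(s, s) for s in restricted.set_ids],
        "size": sizes.astype(int),
        "S0": S0[0],
        "S0_star": star[0],
        "p": p,
        "q": q,
        "rank_pct": rank_pct(p),
    })
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)
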