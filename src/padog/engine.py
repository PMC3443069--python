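"""Sample-label permutation engine shared by all gene set statistics.

The null distribution is over permutations of the sample labels only (gene
rows are never permuted). Unpaired designs resample which samples carry the
case label, preserving group sizes; paired designs independently swap the
labels within each block. The identity labelling is excluded from the null.
When the space of distinct labellings is no larger than the requested count,
all distinct non-identity labellings are enumerated instead and the
effective count is logged.

One :class:`PermutationEngine` per dataset computes each family of gene-level
statistics (ordinary t, moderated t, signal-to-noise) once, so that PADOG and
the comparators consume the identical permutation stream.
"""

from __future__ import annotations

import itertools
import logging
import math
from functools import cached_property

import numpy as np

from . import stats as _st

logger = logging.getLogger(__name__)

__all__ = ["PermutationEngine", "unpaired_label_masks", "paired_label_swaps"]


def unpaired_label_masks(is_case: np.ndarray, n_perm: int, rng: np.random.Generator):
    """Case-label masks: row 0 observed, rows 1.. permuted. Returns (masks, exhaustive)."""
    is_case = np.asarray(is_case, dtype=bool)
    n = len(is_case)
    n1 = int(is_case.sum())
    total = math.comb(n, n1)
    if total - 1 <= n_perm:
        masks = np.zeros((total, n), dtype=bool)
        masks[0] = is_case
        obs = tuple(np.flatnonzero(is_case))
        r = 1
        for combo in itertools.combinations(range(n), n1):
            if combo == obs:
                continue
            masks[r, list(combo)] = True
            r += 1
        logger.info("unpaired permutations: enumerating all %d distinct non-identity "
                    "labellings (requested %d)", total - 1, n_perm)
        return masks, True
    masks = np.zeros((n_perm + 1, n), dtype=bool)
    masks[0] = is_case
    obs = np.flatnonzero(is_case)
    for r in range(1, n_perm + 1):
        while True:
            pick = rng.choice(n, size=n1, replace=False)
            if not np.array_equal(np.sort(pick), obs):
                break
        masks[r, pick] = True
    return masks, False


def paired_label_swaps(n_blocks: int, n_perm: int, rng: np.random.Generator):
    """Within-block sign-swap matrix in {+1,-1}: row 0 is the identity (+1)."""
    total = 2 ** n_blocks
    if total - 1 <= n_perm:
        rows = [bits for bits in itertools.product((1.0, -1.0), repeat=n_blocks)
                if any(b < 0 for b in bits)]
        swaps = np.vstack([np.ones((1, n_blocks)), np.array(rows)])
        logger.info("paired permutations: enumerating all %d distinct non-identity "
                    "swap patterns (requested %d)", total - 1, n_perm)
        return swaps, True
    swaps = np.ones((n_perm + 1, n_blocks))
    for r in range(1, n_perm + 1):
        while True:
            s = rng.choice([1.0, -1.0], size=n_blocks)
            if np.any(s < 0):
                break
        swaps[r] = s
    return swaps, False


class PermutationEngine:
    """Gene-level statistics for the observed labelling and all permutations.

    Row 0 of every statistic matrix is the observed labelling; rows 1..R are
    the permutations. The empirical-Bayes variance prior of the moderated t
    is re-estimated within each permutation, so every permutation is a full
    re-analysis.
    """

    def __init__(self, dataset, n_perm: int = 1000, seed=None, paired: bool | None = None):
        self.dataset = dataset
        self.paired = dataset.block is not None if paired is None else paired
        if self.paired and dataset.block is None:
            raise ValueError("paired analysis requested but dataset has no blocks")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        if self.paired:
            nb = len(np.unique(dataset.block))
            self.swaps, self.exhaustive = paired_label_swaps(nb, n_perm, rng)
            self.masks = None
            self.n_perm = self.swaps.shape[0] - 1
        else:
            self.masks, self.exhaustive = unpaired_label_masks(
                dataset.is_case, n_perm, rng)
            self.swaps = None
            self.n_perm = self.masks.shape[0] - 1

    # ---- gene-level statistic families (labellings x genes) ----

    @cached_property
    def _base(self):
        if self.paired:
            diffs = _st.paired_differences(self.dataset)
            effect, s2, df, unit = _st._paired_group_stats(diffs, self.swaps)
        else:
            effect, s2, df, unit = _st._pooled_group_stats(
                self.dataset.matrix, self.masks)
        return effect, s2, df, unit

    @property
    def df(self) -> int:
        return self._base[2]

    @cached_property
    def t_ordinary(self) -> np.ndarray:
        effect, s2, df, unit = self._base
        t, _ = _st._t_from(effect, s2, unit)
        return t

    @cached_property
    def t_moderated(self) -> np.ndarray:
        effect, s2, df, unit = self._base
        d0, s0 = _st._fit_variance_prior_rows(s2, df)
        s2_shr = _st._shrink_s2(s2, df, d0, s0)
        t, _ = _st._t_from(effect, s2_shr, unit)
        return t

    @cached_property
    def signal_to_noise(self) -> np.ndarray:
        """Per-group signal-to-noise (m1-m0)/(sd1+sd0), the classic GSEA metric."""
        if self.paired:
            # fall back to the paired t as ranking metric
            return self.t_ordinary
        X = self.dataset.matrix
        masks = self.masks.astype(float)
        n = X.shape[1]
        n1 = int(self.masks[0].sum())
        n0 = n - n1
        sum1 = masks @ X.T
        sumsq1 = masks @ (X.T ** 2)
        sum0 = X.sum(axis=1) - sum1
        sumsq0 = (X ** 2).sum(axis=1) - sumsq1
        m1, m0 = sum1 / n1, sum0 / n0
        v1 = np.maximum(sumsq1 - n1 * m1 ** 2, 0.0) / (n1 - 1)
        v0 = np.maximum(sumsq0 - n0 * m0 ** 2, 0.0) / (n0 - 1)
        sd1, sd0 = np.sqrt(v1), np.sqrt(v0)
        # Broad-style floor keeps the denominator away from zero
        sd1 = np.maximum(sd1, 0.2 * np.abs(m1) + 1e-8)
        sd0 = np.maximum(sd0, 0.2 * np.abs(m0) + 1e-8)
        return (m1 - m0) / (sd1 + sd0)

    def scores(self, kind: str) -> np.ndarray:
        if kind == "moderated":
            return self.t_moderated
        if kind == "ordinary":
            return self.t_ordinary
        if kind == "s2n":
            return self.signal_to_noise
        raise ValueError(f"unknown gene score kind {kind!r}")
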