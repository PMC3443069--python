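"""Target-pathway ranking benchmark.

The evaluation framework scores a gene set method by where it places each
dataset's *target* set — the pathway describing the condition the samples
were collected for — in the ascending-p ordering of all analysed sets. The
rank of a target with the i-th smallest p among N_GS sets is i/N_GS*100
(average rank on ties). Per-method summaries aggregate the target p-values
(geometric mean, median, % below 0.05 nominally and after FDR adjustment)
and ranks (mean, median). Two methods are compared by a one-tailed paired
Wilcoxon signed-rank test on the target ranks, paired at the dataset level,
and optionally by a linear mixed-effects model with a random intercept per
target pathway to absorb the dependence created by pathways that recur
across datasets.

A reference table of 24 public expression datasets (GEO accessions) and
their target pathway identifiers ships with the package
(``data/geo_targets.tsv``); the expression data themselves are not bundled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "BenchmarkSummary",
    "target_rank",
    "collect_records",
    "summarize",
    "compare_to_reference",
    "load_reference_targets",
]


@dataclass
class BenchmarkSummary:
    p_geomean: float
    p_median: float
    pct_p_lt_05: float
    pct_q_lt_05: float
    rank_mean: float
    rank_median: float
    n: int


def target_rank(results: pd.DataFrame, target_set_id: str) -> float:
    """Percentile rank of the target set in the ascending-p ordering.

    ``results`` is a per-set table with columns ``set_id`` and ``p`` (the
    output schema of the analysis functions). Ties share the average rank.
    """
    if target_set_id not in set(results["set_id"]):
        raise KeyError(f"target set {target_set_id!r} not among analysed sets")
    ranks = results["p"].rank(method="average")
    pos = results.index[results["set_id"] == target_set_id][0]
    return float(ranks.loc[pos] / len(results) * 100.0)


def collect_records(per_dataset_results: dict[str, pd.DataFrame],
                    targets: dict[str, str], method: str = "") -> pd.DataFrame:
    """Per-dataset target records (dataset_id, target, p, q, rank_pct)."""
    rows = []
    for did, res in per_dataset_results.items():
        tset = targets[did]
        sub = res.set_index("set_id")
        if tset not in sub.index:
            raise KeyError(f"target set {tset!r} absent from results of {did!r}")
        rows.append((did, tset, method, float(sub.loc[tset, "p"]),
                     float(sub.loc[tset, "q"]), target_rank(res, tset)))
    return pd.DataFrame(rows, columns=["dataset_id", "target_set_id", "method",
                                       "p", "q", "rank_pct"])


def summarize(records: pd.DataFrame, n_perm: int = 1000) -> BenchmarkSummary:
    """Aggregate target p-values and ranks across datasets.

    Zero p-values (possible under the literal permutation count) enter the
    geometric mean floored at 1/(2*n_perm), logged.
    """
    p = records["p"].to_numpy(dtype=float)
    floor = 1.0 / (2.0 * n_perm)
    if np.any(p <= 0):
        logger.info("geometric mean: flooring %d zero p-value(s) at %g",
                    int((p <= 0).sum()), floor)
    p_floored = np.maximum(p, floor)
    return BenchmarkSummary(
        p_geomean=float(np.exp(np.mean(np.log(p_floored)))),
        p_median=float(np.median(p)),
        pct_p_lt_05=float(100.0 * np.mean(p < 0.05)),
        pct_q_lt_05=float(100.0 * np.mean(records["q"].to_numpy() < 0.05)),
        rank_mean=float(records["rank_pct"].mean()),
        rank_median=float(records["rank_pct"].median()),
        n=len(records),
    )


def compare_to_reference(records_a: pd.DataFrame, records_ref: pd.DataFrame,
                         fit_lme: bool = False):
    """Are method A's target ranks smaller (better) than the reference's?

    One-tailed paired Wilcoxon signed-rank test on the per-dataset rank
    differences (alternative: A < reference). With ``fit_lme=True`` also fits
    rank ~ method + dataset with a random intercept per target pathway and
    returns the method coefficient and its one-tailed p.
    Returns ``(wilcoxon_p, lme_coef, lme_p)`` (the last two None unless
    requested).
    """
    a = records_a.set_index("dataset_id")["rank_pct"]
    r = records_ref.set_index("dataset_id")["rank_pct"]
    mismatched = set(a.index) ^ set(r.index)
    if mismatched:
        raise ValueError(f"datasets not paired between methods: {sorted(mismatched)}")
    r = r.loc[a.index]
    diff = (a - r).to_numpy()
    if np.all(diff == 0):
        logger.warning("identical ranks in both methods; Wilcoxon p set to 0.5")
        wp = 0.5
    else:
        method = "exact" if (len(diff) <= 30 and not np.any(diff == 0)
                             and len(np.unique(np.abs(diff))) == len(diff)) else "auto"
        wp = float(sps.wilcoxon(diff, alternative="less", method=method).pvalue)
    lme_coef = lme_p = None
    if fit_lme:
        lme_coef, lme_p = _fit_rank_lme(records_a, records_ref)
    return wp, lme_coef, lme_p


def _fit_rank_lme(records_a: pd.DataFrame, records_ref: pd.DataFrame):
    """Mixed model of ranks with dataset fixed effects and pathway random intercepts."""
    import statsmodels.formula.api as smf

    df = pd.concat([
        records_a.assign(is_a=1.0),
        records_ref.assign(is_a=0.0),
    ], ignore_index=True)
    model = smf.mixedlm("rank_pct ~ is_a + C(dataset_id)", df,
                        groups=df["target_set_id"])
    try:
        fit = model.fit(reml=True)
    except Exception as exc:  # singular fits happen on degenerate toy inputs
        logger.warning("mixed-effects fit failed (%s); returning None", exc)
        return None, None
    coef = float(fit.params["is_a"])
    z = coef / float(fit.bse["is_a"])
    p_one_tailed = float(sps.norm.cdf(z))      # alternative: coef < 0 (better ranks)
    return coef, p_one_tailed


def load_reference_targets() -> pd.DataFrame:
    """The packaged table of 24 GEO datasets and their target pathway ids."""
    with resources.files("padog").joinpath("data/geo_targets.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_results_dir(results_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Read ``<dataset_id>.tsv`` result tables (the ``padog run`` output schema)."""
    out = {}
    for path in sorted(Path(results_dir).glob("*.tsv")):
        out[path.stem] = pd.read_csv(path, sep="\t")
    if not out:
        raise ValueError(f"no result TSVs found in {results_dir}")
    return out
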