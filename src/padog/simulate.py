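"""Synthetic sensitivity and specificity studies.

Sensitivity: expression for 1000 genes x 100 samples (50 per condition) is
drawn i.i.d. N(0,1); 50 gene sets of 20 genes partition the genes; the first
set (GS1) receives a mean shift in group 2 under five scenarios (numbers of
up/down genes and shift size below). Orthogonally, three overlap setups vary
GS1's relation to GS50: I — disjoint sets; II — GS1's shifted (DE) genes are
also placed in GS50; III — GS1's unshifted genes are also placed in GS50.
The setups change the gene-frequency weights and therefore only affect the
down-weighted method. Fifty replicate datasets per cell; the target set's
p-value is recorded per replicate and summarised by mean and median.

Specificity: datasets drawn entirely from N(0,1) (no signal) are analysed
against a fixed gene set collection with realistic overlap; the pooled
fraction of set p-values below alpha estimates the false positive rate. A
second design permutes the labels of supplied datasets before analysis and
summarises the target sets' p-values and ranks, which should be uniform.

The generators are the study conditions: defaults are fixed to the sizes,
shifts and counts above and all randomness flows from an explicit seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .comparators import gsa_analyze, gsea_analyze
from .core import PadogConfig, WeightingConfig, permutation_test
from .engine import PermutationEngine
from .io import ExpressionDataset, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioSpec",
    "SCENARIOS",
    "SETUPS",
    "make_null_dataset",
    "make_sim_collection",
    "inject_effect",
    "make_overlap_collection",
    "run_sensitivity",
    "run_specificity_random",
    "run_specificity_label_perm",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """Differential-expression recipe: counts of up/down genes and shift size."""

    n_up: int
    n_down: int
    delta: float

    def __post_init__(self):
        if self.delta < 0:
            raise ValueError("delta must be non-negative")

    @property
    def n_de(self) -> int:
        return self.n_up + self.n_down


#: the five shift scenarios applied to GS1 (plus a pure-null scenario 0)
SCENARIOS: dict[int, ScenarioSpec] = {
    0: ScenarioSpec(0, 0, 0.0),
    1: ScenarioSpec(15, 0, 0.3),
    2: ScenarioSpec(10, 5, 0.3),
    3: ScenarioSpec(8, 7, 0.3),
    4: ScenarioSpec(7, 3, 0.4),
    5: ScenarioSpec(5, 5, 0.4),
}

SETUPS = ("I", "II", "III")

_SET_SIZE = 20
_N_SETS = 50


def make_null_dataset(n_genes: int = 1000, n_per_group: int = 50,
                      seed=None) -> ExpressionDataset:
    """i.i.d. N(0,1) expression, two equal groups, no signal."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = rng.standard_normal((n_genes, 2 * n_per_group))
    gene_ids = [f"g{i+1:04d}" for i in range(n_genes)]
    sample_ids = [f"s{j+1:03d}" for j in range(2 * n_per_group)]
    group = np.array(["control"] * n_per_group + ["case"] * n_per_group)
    return ExpressionDataset(X, gene_ids, sample_ids, group, "control")


def make_sim_collection(setup: str = "I",
                        scenario: ScenarioSpec | int = 1,
                        n_genes: int = 1000) -> GeneSetCollection:
    """Fifty sets of 20 genes partitioning the genome, with optional GS50 overlap.

    Setup II appends GS1's DE genes to GS50; setup III appends GS1's non-DE
    genes. Only GS50's membership changes between setups.
    """
    if isinstance(scenario, int):
        scenario = SCENARIOS[scenario]
    if _N_SETS * _SET_SIZE != n_genes:
        raise ValueError(f"need n_genes == {_N_SETS * _SET_SIZE}")
    gene_ids = [f"g{i+1:04d}" for i in range(n_genes)]
    sets = {
        f"GS{k+1}": gene_ids[k * _SET_SIZE:(k + 1) * _SET_SIZE]
        for k in range(_N_SETS)
    }
    gs1 = sets["GS1"]
    if setup == "II":
        sets["GS50"] = sets["GS50"] + gs1[: scenario.n_de]
    elif setup == "III":
        sets["GS50"] = sets["GS50"] + gs1[scenario.n_de:]
    elif setup != "I":
        raise ValueError(f"unknown setup {setup!r}")
    return GeneSetCollection(sets)


def inject_effect(dataset: ExpressionDataset, scenario: ScenarioSpec | int,
                  target_genes: list[str]) -> ExpressionDataset:
    """Shift the first n_up target genes by +delta and the next n_down by
    -delta in the case group. Returns a new dataset."""
    if isinstance(scenario, int):
        scenario = SCENARIOS[scenario]
    if scenario.n_de > len(target_genes):
        raise ValueError(
            f"scenario needs {scenario.n_de} target genes, got {len(target_genes)}")
    X = dataset.matrix.copy()
    case = dataset.is_case
    gidx = pd.Index(dataset.gene_ids)
    up = gidx.get_indexer(target_genes[: scenario.n_up])
    down = gidx.get_indexer(target_genes[scenario.n_up: scenario.n_de])
    X[np.ix_(up, np.flatnonzero(case))] += scenario.delta
    X[np.ix_(down, np.flatnonzero(case))] -= scenario.delta
    return ExpressionDataset(X, dataset.gene_ids, dataset.sample_ids,
                             dataset.group, dataset.control_level, dataset.block)


def _analyze_target(method: str, dataset, collection, engine, cfg, wcfg,
                    target: str) -> float:
    if method in ("padog", "noM", "noW", "noMnoW"):
        c = PadogConfig(n_perm=cfg.n_perm, add_one=cfg.add_one,
                        use_moderated=method in ("padog", "noW"),
                        use_weights=method in ("padog", "noM"),
                        min_set_size=cfg.min_set_size)
        res = permutation_test(dataset, collection, c, wcfg, engine=engine)
    elif method == "gsa":
        res = gsa_analyze(dataset, collection, cfg, engine=engine)
    elif method == "gsea":
        res = gsea_analyze(dataset, collection, cfg, engine=engine)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.set_index("set_id").loc[target, "p"])


def run_sensitivity(methods=("padog", "gsa", "gsea"),
                    scenarios=(1, 2, 3, 4, 5),
                    setups=SETUPS,
                    n_rep: int = 50,
                    n_perm: int = 1000,
                    seed: int | None = 0,
                    wcfg: WeightingConfig | None = None) -> pd.DataFrame:
    """The full sensitivity grid: GS1's p per method/scenario/setup/replicate.

    Within a replicate, every method and setup sees the same dataset and the
    same permutation stream, so contrasts between cells are paired. The
    comparators are insensitive to the overlap setups (weights do not enter
    them), so they are evaluated once per replicate and copied across setups.
    Frequency capping is disabled here: the simulated collections carry only
    two frequency values (1 and 2) and a high-quantile cap would erase the
    overlap structure under study.
    """
    wcfg = wcfg or WeightingConfig(cap_quantile=1.0)
    root = np.random.SeedSequence(seed)
    rows = []
    for scn in scenarios:
        spec = SCENARIOS[scn] if isinstance(scn, int) else scn
        colls = {s: make_sim_collection(s, spec) for s in setups}
        gs1 = make_sim_collection("I", spec).sets["GS1"]
        for rep, ss in enumerate(root.spawn(n_rep)):
            data_rng, perm_rng = [np.random.default_rng(s) for s in ss.spawn(2)]
            ds = make_null_dataset(seed=data_rng)
            ds = inject_effect(ds, spec, gs1)
            cfg = PadogConfig(n_perm=n_perm)
            eng = PermutationEngine(ds, n_perm, perm_rng)
            for method in methods:
                if method in ("gsa", "gsea"):
                    p = _analyze_target(method, ds, colls[setups[0]], eng, cfg,
                                        wcfg, "GS1")
                    for s in setups:
                        rows.append((scn, s, method, rep, p))
                else:
                    for s in setups:
                        p = _analyze_target(method, ds, colls[s], eng, cfg,
                                            wcfg, "GS1")
                        rows.append((scn, s, method, rep, p))
    return pd.DataFrame(rows, columns=["scenario", "setup", "method",
                                       "replicate", "p"])


def sensitivity_table(results: pd.DataFrame, agg: str = "mean") -> pd.DataFrame:
    """Pivot replicate-level results to a scenario x method/setup table."""
    df = results.copy()
    df["column"] = np.where(df["method"].isin(["gsa", "gsea"]),
                            df["method"].str.upper(),
                            df["method"] + " " + df["setup"])
    df = df.drop_duplicates(["scenario", "column", "replicate"])
    return df.pivot_table(index="scenario", columns="column", values="p",
                          aggfunc=agg)


def make_overlap_collection(n_sets: int = 80, n_genes: int = 4000,
                            size_range: tuple[int, int] = (20, 200),
                            popularity_exponent: float = 1.2,
                            seed: int | None = 12345) -> GeneSetCollection:
    """A synthetic pathway-like collection with heavy-tailed gene sharing.

    Genes are sampled into sets with probability proportional to a Zipf-like
    popularity weight, so a minority of genes recur across many sets while
    most genes stay set-specific — mimicking the frequency profile of curated
    pathway collections. Sizes are log-uniform within ``size_range``.
    """
    rng = np.random.default_rng(seed)
    gene_ids = np.array([f"g{i+1:05d}" for i in range(n_genes)])
    pop = (np.arange(n_genes) + 1.0) ** (-popularity_exponent)
    pop = rng.permutation(pop)
    pop /= pop.sum()
    lo, hi = size_range
    sizes = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_sets)).astype(int)
    sets = {}
    for k in range(n_sets):
        members = rng.choice(n_genes, size=sizes[k], replace=False, p=pop)
        sets[f"P{k+1:03d}"] = list(gene_ids[np.sort(members)])
    return GeneSetCollection(sets)


def run_specificity_random(collection: GeneSetCollection | None = None,
                           shapes: list[tuple[int, int, int]] | None = None,
                           n_rep_per_shape: int = 50,
                           alphas=(0.05, 0.01),
                           methods=("padog", "gsa", "gsea"),
                           n_perm: int = 500,
                           seed: int | None = 0,
                           wcfg: WeightingConfig | None = None) -> pd.DataFrame:
    """False-positive rates on pure-noise data with a fixed overlapping collection.

    Every replica dataset is drawn from N(0,1) at one of the supplied
    (n_genes, n1, n2) shapes; all methods share each replica's permutation
    stream. Returns the pooled fraction of set p-values below each alpha,
    one row per method, plus the pooled p-value count.
    """
    wcfg = wcfg or WeightingConfig()
    collection = collection or make_overlap_collection()
    root = np.random.SeedSequence(seed)
    if shapes is None:
        shape_rng = np.random.default_rng(root.spawn(1)[0])
        shapes = [(5000, int(shape_rng.integers(10, 61)), int(shape_rng.integers(10, 61)))
                  for _ in range(24)]
    pvals: dict[str, list[float]] = {m: [] for m in methods}
    for (n_genes, n1, n2) in shapes:
        for ss in root.spawn(n_rep_per_shape):
            data_rng, perm_rng = [np.random.default_rng(s) for s in ss.spawn(2)]
            X = data_rng.standard_normal((n_genes, n1 + n2))
            ds = ExpressionDataset(
                X, [f"g{i+1:05d}" for i in range(n_genes)],
                [f"s{j+1:03d}" for j in range(n1 + n2)],
                np.array(["control"] * n1 + ["case"] * n2), "control")
            restricted, genes = collection.restrict_to_measured(ds)
            gidx = pd.Index(ds.gene_ids).get_indexer(genes)
            sub = ExpressionDataset(X[gidx], list(genes), ds.sample_ids,
                                    ds.group, "control")
            eng = PermutationEngine(sub, n_perm, perm_rng)
            cfg = PadogConfig(n_perm=n_perm)
            for m in methods:
                if m == "padog":
                    res = permutation_test(sub, restricted, cfg, wcfg, engine=eng)
                elif m == "gsa":
                    res = gsa_analyze(sub, restricted, cfg, engine=eng)
                else:
                    res = gsea_analyze(sub, restricted, cfg, engine=eng)
                pvals[m].extend(res["p"].tolist())
    rows = []
    for m in methods:
        p = np.asarray(pvals[m])
        rows.append((m, *[float((p < a).mean()) for a in alphas], p.size))
    return pd.DataFrame(rows, columns=["method", *[f"fpr_{a}" for a in alphas],
                                       "n_pvalues"])


def run_specificity_label_perm(datasets: dict[str, ExpressionDataset],
                               collection: GeneSetCollection,
                               targets: dict[str, str],
                               methods=("padog", "gsa", "gsea"),
                               n_trials: int = 100,
                               n_perm: int = 500,
                               seed: int | None = 0,
                               wcfg: WeightingConfig | None = None) -> pd.DataFrame:
    """Null benchmark: permute each dataset's labels before analysis.

    Every method sees the same label permutation in a given trial. Reports,
    averaged over trials, the median target-set p, the median target rank
    percentile and the percentage of target sets with p < 0.05 — all of which
    should sit near 0.5 / 50 / 5 when the methods are well calibrated.
    """
    from .benchmark import target_rank

    wcfg = wcfg or WeightingConfig()
    root = np.random.SeedSequence(seed)
    per_trial = {m: [] for m in methods}
    for trial_ss in root.spawn(n_trials):
        stats = {m: {"p": [], "rank": []} for m in methods}
        for (did, ds), ds_ss in zip(datasets.items(), trial_ss.spawn(len(datasets))):
            lab_rng, perm_rng = [np.random.default_rng(s) for s in ds_ss.spawn(2)]
            shuffled = ExpressionDataset(
                ds.matrix, ds.gene_ids, ds.sample_ids,
                lab_rng.permutation(ds.group), ds.control_level, None)
            restricted, genes = collection.restrict_to_measured(shuffled)
            gidx = pd.Index(shuffled.gene_ids).get_indexer(genes)
            sub = ExpressionDataset(shuffled.matrix[gidx], list(genes),
                                    ds.sample_ids, shuffled.group,
                                    ds.control_level)
            eng = PermutationEngine(sub, n_perm, perm_rng)
            cfg = PadogConfig(n_perm=n_perm)
            for m in methods:
                if m == "padog":
                    res = permutation_test(sub, restricted, cfg, wcfg, engine=eng)
                elif m == "gsa":
                    res = gsa_analyze(sub, restricted, cfg, engine=eng)
                else:
                    res = gsea_analyze(sub, restricted, cfg, engine=eng)
                tset = targets[did]
                stats[m]["p"].append(float(res.set_index("set_id").loc[tset, "p"]))
                stats[m]["rank"].append(target_rank(res, tset))
        for m in methods:
            p = np.asarray(stats[m]["p"])
            per_trial[m].append((np.median(p), np.median(stats[m]["rank"]),
                                 100.0 * float((p < 0.05).mean())))
    rows = []
    for m in methods:
        arr = np.asarray(per_trial[m])
        rows.append((m, *arr.mean(axis=0), len(arr)))
    return pd.DataFrame(rows, columns=["method", "p_median", "rank_median",
                                       "pct_p_lt_05", "n_trials"])
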