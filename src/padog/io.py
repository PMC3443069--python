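"""Reading, writing and validation of gene set collections and expression data.

Gene identifiers are opaque strings: callers are expected to supply one row
per gene (probe-to-gene collapsing happens upstream of this package).
Gene sets travel in GMT format (one set per line: id, description, gene ids,
tab separated); expression matrices and sample designs travel as TSV/CSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "ExpressionDataset",
    "read_gmt",
    "write_gmt",
    "read_expression",
]

#: group labels recognised as the reference (control) level, lower-cased
_CONTROL_ALIASES = ("control", "ctrl", "c", "0", "reference", "normal")


@dataclass
class GeneSetCollection:
    """An ordered collection of named gene sets.

    ``sets`` maps set id to a list of unique gene ids (insertion order kept);
    ``names`` optionally maps set id to a display name.
    """

    sets: dict[str, list[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, genes in self.sets.items():
            if len(genes) != len(set(genes)):
                seen: set[str] = set()
                self.sets[sid] = [g for g in genes if not (g in seen or seen.add(g))]

    @property
    def n_sets(self) -> int:
        return len(self.sets)

    @property
    def set_ids(self) -> list[str]:
        return list(self.sets)

    def sizes(self) -> dict[str, int]:
        return {sid: len(genes) for sid, genes in self.sets.items()}

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out.update(genes)
        return out

    def restrict_to_measured(
        self, measured: "ExpressionDataset | set[str] | list[str]", min_size: int = 3
    ) -> tuple["GeneSetCollection", list[str]]:
        """Intersect every set with the measured genes.

        Sets that fall below ``min_size`` genes are dropped with a warning.
        Returns the restricted collection and ``G``, the sorted union of the
        genes of the restricted sets (genes measured but mapped to no set are
        excluded from ``G``). Idempotent.
        """
        if isinstance(measured, ExpressionDataset):
            measured_ids = set(measured.gene_ids)
        else:
            measured_ids = set(measured)
        new_sets: dict[str, list[str]] = {}
        dropped = []
        for sid, genes in self.sets.items():
            kept = [g for g in genes if g in measured_ids]
            if len(kept) >= min_size:
                new_sets[sid] = kept
            else:
                dropped.append(sid)
        if dropped:
            logger.warning(
                "dropped %d gene set(s) with fewer than %d measured genes: %s",
                len(dropped), min_size, ", ".join(dropped[:10]),
            )
        if not new_sets:
            raise ValueError("no overlap between expression data and gene sets")
        restricted = GeneSetCollection(
            new_sets, {k: v for k, v in self.names.items() if k in new_sets}
        )
        genes_in_sets = sorted(restricted.all_genes())
        return restricted, genes_in_sets

    def membership_matrix(self, gene_index: "pd.Index | list[str]") -> np.ndarray:
        """Dense genes x sets 0/1 indicator aligned to ``gene_index``."""
        idx = pd.Index(gene_index)
        mat = np.zeros((len(idx), self.n_sets), dtype=float)
        for j, genes in enumerate(self.sets.values()):
            rows = idx.get_indexer(genes)
            mat[rows[rows >= 0], j] = 1.0
        return mat


@dataclass
class ExpressionDataset:
    """A log-scale genes x samples expression matrix with a two-group design.

    ``group`` holds per-sample condition labels with exactly two levels;
    ``control_level`` names the reference level. ``block`` optionally gives a
    pairing id per sample; each block must contain exactly one sample of each
    group.
    """

    matrix: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    group: np.ndarray
    control_level: str
    block: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.group = np.asarray(self.group)
        if self.matrix.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids are not unique")
        levels = set(np.unique(self.group))
        if len(levels) != 2:
            raise ValueError(f"group must have exactly 2 levels, got {sorted(levels)}")
        if self.control_level not in levels:
            raise ValueError(f"control level {self.control_level!r} not among group labels")
        counts = {lv: int((self.group == lv).sum()) for lv in levels}
        if min(counts.values()) < 2:
            raise ValueError(f"each group needs >=2 samples, got {counts}")
        if self.block is not None:
            self.block = np.asarray(self.block)
            for b in np.unique(self.block):
                sub = self.group[self.block == b]
                if len(sub) != 2 or sub[0] == sub[1]:
                    raise ValueError(
                        f"block {b!r} must contain exactly one sample per group"
                    )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def is_case(self) -> np.ndarray:
        """Boolean mask of non-reference (case) samples."""
        return self.group != self.control_level

    def case_control_counts(self) -> tuple[int, int]:
        case = self.is_case
        return int(case.sum()), int((~case).sum())


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: ``set_id<TAB>description<TAB>gene1<TAB>gene2...``.

    Duplicate gene ids within a line are de-duplicated (first occurrence
    kept); duplicate set ids and lines with fewer than 3 fields are errors.
    """
    sets: dict[str, list[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            sid, desc = fields[0], fields[1]
            if sid in sets:
                raise ValueError(f"{path}: line {lineno}: duplicate set id {sid!r}")
            genes: list[str] = []
            seen: set[str] = set()
            for g in fields[2:]:
                if g and g not in seen:
                    genes.append(g)
                    seen.add(g)
            sets[sid] = genes
            names[sid] = desc
    if not sets:
        raise ValueError(f"{path}: no gene sets")
    return GeneSetCollection(sets, names)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, genes in collection.sets.items():
            desc = collection.names.get(sid, sid)
            fh.write("\t".join([sid, desc, *genes]) + "\n")


def _read_table(path: str | Path, index_col=0) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, index_col=index_col)


def read_expression(path: str | Path, design_path: str | Path) -> ExpressionDataset:
    """Read an expression matrix and its sample design.

    The matrix file has gene ids in the first column and sample ids in the
    header. The design file needs columns ``sample_id`` and ``group`` and may
    carry ``block`` for paired designs. Samples are aligned between the two
    files; the control level is detected from common aliases, otherwise the
    lexicographically first group label is used as reference.
    """
    expr = _read_table(path)
    bad = expr.columns[~expr.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
    if len(bad):
        col = bad[0]
        row = expr.index[pd.to_numeric(expr[col], errors="coerce").isna()][0]
        raise ValueError(f"non-numeric expression value at gene {row!r}, sample {col!r}")
    design = _read_table(design_path, index_col=None)
    design.columns = [c.lower() for c in design.columns]
    if "sample_id" not in design.columns or "group" not in design.columns:
        raise ValueError("design file needs columns 'sample_id' and 'group'")
    design = design.set_index("sample_id")
    missing = set(expr.columns) ^ set(design.index)
    if missing:
        raise ValueError(f"sample mismatch between matrix and design: {sorted(missing)}")
    design = design.loc[expr.columns]
    group = design["group"].astype(str).to_numpy()
    levels = sorted(set(group))
    control = next(
        (lv for lv in levels if lv.lower() in _CONTROL_ALIASES), levels[0]
    )
    block = design["block"].to_numpy() if "block" in design.columns else None
    return ExpressionDataset(
        matrix=expr.to_numpy(dtype=float),
        gene_ids=list(expr.index.astype(str)),
        sample_ids=list(expr.columns.astype(str)),
        group=group,
        control_level=control,
        block=block,
    )
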