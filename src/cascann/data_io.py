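"""Tabular input/output: expression matrices, binding p-values, edge lists,
binding sites and protein-interaction pairs.

All files are headered, UTF-8, tab-separated text.  Missing numeric values
are written as the empty string and accepted on input as either the empty
string or ``NA`` — never as a sentinel number, because downstream filters
need to see missingness explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, ParseError, ValidationError

_NA_VALUES = ["", "NA"]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentMeta:
    """Metadata for one experiment column.

    ``time_point`` is a 1-based ordinal within ``condition``; ``None`` marks
    single-sample conditions, which downstream time-shift code skips.
    Experiments sharing ``replicate_group`` are replicates of one
    measurement and are averaged before modeling.
    """

    experiment_id: str
    category: str
    condition: str
    time_point: int | None = None
    time_value: float | None = None
    replicate_group: str | None = None


@dataclass
class ExpressionMatrix:
    """genes x experiments matrix of log2 ratios; NaN flags missing."""

    genes: list[str]
    experiments: list[ExperimentMeta]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.experiments)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.experiments)} experiments"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate gene IDs")
        ids = [e.experiment_id for e in self.experiments]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate experiment IDs")
        self._gene_index = {g: i for i, g in enumerate(self.genes)}

    @property
    def experiment_ids(self) -> list[str]:
        return [e.experiment_id for e in self.experiments]

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_experiments(self) -> int:
        return len(self.experiments)

    def __contains__(self, gene: str) -> bool:
        return gene in self._gene_index

    def row(self, gene: str) -> np.ndarray:
        """Expression profile of ``gene`` across all experiments."""
        try:
            return self.values[self._gene_index[gene]]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in expression matrix") from None

    def select_experiments(self, keep: Sequence[int]) -> "ExpressionMatrix":
        keep = list(keep)
        return ExpressionMatrix(
            genes=list(self.genes),
            experiments=[self.experiments[i] for i in keep],
            values=self.values[:, keep].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.experiment_ids)


@dataclass
class BindingPValueMatrix:
    """TFs x genes matrix of binding confidence p-values in [0, 1]."""

    tfs: list[str]
    genes: list[str]
    pvalues: np.ndarray

    def __post_init__(self) -> None:
        self.pvalues = np.asarray(self.pvalues, dtype=float)
        if self.pvalues.shape != (len(self.tfs), len(self.genes)):
            raise ValidationError("p-value matrix shape mismatch")
        present = self.pvalues[~np.isnan(self.pvalues)]
        if present.size and (present.min() < 0.0 or present.max() > 1.0):
            raise ValidationError("binding p-values must lie in [0, 1]")
        self._tf_index = {t: i for i, t in enumerate(self.tfs)}
        self._gene_index = {g: i for i, g in enumerate(self.genes)}

    def has_tf(self, tf: str) -> bool:
        return tf in self._tf_index

    def pvalue(self, tf: str, gene: str) -> float:
        """p(tf, gene); NaN if either ID or the entry is missing."""
        i = self._tf_index.get(tf)
        j = self._gene_index.get(gene)
        if i is None or j is None:
            return float("nan")
        return float(self.pvalues[i, j])

    def gene_column(self, gene: str) -> np.ndarray:
        return self.pvalues[:, self._gene_index[gene]]


@dataclass(frozen=True)
class RegulatorEdgeSet:
    """Directed regulator -> target-gene pairs (self-loops permitted)."""

    edges: frozenset[tuple[str, str]]

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, edge: tuple[str, str]) -> bool:
        return edge in self.edges

    def __iter__(self):
        return iter(self.edges)

    def regulators_of(self, gene: str) -> frozenset[str]:
        return frozenset(t for t, g in self.edges if g == gene)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "RegulatorEdgeSet":
        return cls(frozenset((str(a), str(b)) for a, b in pairs))


@dataclass(frozen=True)
class BindingSite:
    tf: str
    target_gene: str
    upstream_offset: int  # bp upstream of transcription start, 1-based

    def __post_init__(self) -> None:
        if self.upstream_offset < 1:
            raise ValidationError(
                f"upstream_offset must be >= 1, got {self.upstream_offset}"
            )


@dataclass(frozen=True)
class BindingSiteTable:
    rows: tuple[BindingSite, ...]

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, str, int]]) -> "BindingSiteTable":
        return cls(tuple(BindingSite(str(t), str(g), int(o)) for t, g, o in rows))

    def sites_for(self, tf: str, gene: str) -> list[int]:
        return [r.upstream_offset for r in self.rows
                if r.tf == tf and r.target_gene == gene]


@dataclass(frozen=True)
class PpiPairSet:
    """Undirected protein-protein interaction pairs."""

    pairs: frozenset[frozenset[str]]

    def __post_init__(self) -> None:
        for p in self.pairs:
            if len(p) != 2:
                raise ValidationError(f"PPI pair must join two distinct proteins: {set(p)}")

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return frozenset(pair) in self.pairs

    def neighbors(self, protein: str) -> frozenset[str]:
        out = set()
        for p in self.pairs:
            if protein in p:
                out.update(p - {protein})
        return frozenset(out)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "PpiPairSet":
        return cls(frozenset(frozenset((str(a), str(b))) for a, b in pairs if a != b))


# ---------------------------------------------------------------------------
# expression IO
# ---------------------------------------------------------------------------

def _read_numeric_matrix(path: str | Path, index_name: str) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.columns[0] != index_name:
        raise ParseError(
            f"{path}: first column must be {index_name!r}, got {raw.columns[0]!r}"
        )
    raw = raw.set_index(raw.columns[0])
    numeric = raw.apply(
        lambda col: pd.to_numeric(col.mask(col.isin(_NA_VALUES)), errors="coerce"))
    bad = numeric.isna() & ~raw.isin(_NA_VALUES)
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: malformed numeric cell {raw.iat[i, j]!r} at row "
            f"{raw.index[i]!r}, column {raw.columns[j]!r}"
        )
    return numeric


def _parse_meta_row(row: pd.Series) -> ExperimentMeta:
    tp = row.get("time_point", "")
    tv = row.get("time_value", "")
    return ExperimentMeta(
        experiment_id=str(row["experiment_id"]),
        category=str(row["category"]),
        condition=str(row["condition"]),
        time_point=None if tp in _NA_VALUES else int(float(tp)),
        time_value=None if tv in _NA_VALUES else float(tv),
        replicate_group=str(row["replicate_group"]),
    )


def read_expression(matrix_path: str | Path, meta_path: str | Path) -> ExpressionMatrix:
    """Read an expression matrix TSV joined with its experiment metadata.

    The matrix file has a ``gene`` first column and one column per
    experiment; the metadata file has columns experiment_id, category,
    condition, time_point, time_value, replicate_group.  Experiment IDs
    present in one file but not the other are a :class:`ConsistencyError`.
    """
    numeric = _read_numeric_matrix(matrix_path, "gene")
    meta_df = pd.read_csv(meta_path, sep="\t", dtype=str, keep_default_na=False)
    required = {"experiment_id", "category", "condition", "replicate_group"}
    if not required.issubset(meta_df.columns):
        raise ParseError(f"{meta_path}: missing columns {required - set(meta_df.columns)}")

    meta_by_id = {}
    for _, row in meta_df.iterrows():
        m = _parse_meta_row(row)
        if m.experiment_id in meta_by_id:
            raise ConsistencyError(f"duplicate metadata for experiment {m.experiment_id!r}")
        meta_by_id[m.experiment_id] = m

    matrix_ids = list(numeric.columns)
    missing = [e for e in matrix_ids if e not in meta_by_id]
    extra = [e for e in meta_by_id if e not in set(matrix_ids)]
    if missing or extra:
        raise ConsistencyError(
            f"experiment ID mismatch between matrix and metadata: "
            f"matrix-only={missing}, metadata-only={extra}"
        )
    return ExpressionMatrix(
        genes=[str(g) for g in numeric.index],
        experiments=[meta_by_id[e] for e in matrix_ids],
        values=numeric.to_numpy(dtype=float),
    )


def write_expression(expr: ExpressionMatrix, matrix_path: str | Path,
                     meta_path: str | Path) -> None:
    frame = expr.to_frame()
    frame.index.name = "gene"
    frame.to_csv(matrix_path, sep="\t", na_rep="", float_format="%.10g")
    rows = []
    for m in expr.experiments:
        rows.append({
            "experiment_id": m.experiment_id,
            "category": m.category,
            "condition": m.condition,
            "time_point": "" if m.time_point is None else m.time_point,
            "time_value": "" if m.time_value is None else repr(m.time_value),
            "replicate_group": "" if m.replicate_group is None else m.replicate_group,
        })
    pd.DataFrame(rows).to_csv(meta_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# other tabular readers/writers
# ---------------------------------------------------------------------------

def read_binding(path: str | Path) -> BindingPValueMatrix:
    numeric = _read_numeric_matrix(path, "tf")
    return BindingPValueMatrix(
        tfs=[str(t) for t in numeric.index],
        genes=[str(g) for g in numeric.columns],
        pvalues=numeric.to_numpy(dtype=float),
    )


def write_binding(binding: BindingPValueMatrix, path: str | Path) -> None:
    frame = pd.DataFrame(binding.pvalues, index=binding.tfs, columns=binding.genes)
    frame.index.name = "tf"
    frame.to_csv(path, sep="\t", na_rep="", float_format="%.10g")


def read_edges(path: str | Path) -> RegulatorEdgeSet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"regulator", "target"}.issubset(df.columns):
        raise ParseError(f"{path}: expected columns 'regulator' and 'target'")
    return RegulatorEdgeSet.from_pairs(zip(df["regulator"], df["target"]))


def write_edges(edges: RegulatorEdgeSet, path: str | Path) -> None:
    df = pd.DataFrame(sorted(edges.edges), columns=["regulator", "target"])
    df.to_csv(path, sep="\t", index=False)


def read_sites(path: str | Path) -> BindingSiteTable:
    df = pd.read_csv(path, sep="\t", dtype={"tf": str, "target": str,
                                            "upstream_offset": int})
    if not {"tf", "target", "upstream_offset"}.issubset(df.columns):
        raise ParseError(f"{path}: expected columns tf, target, upstream_offset")
    return BindingSiteTable.from_rows(
        zip(df["tf"], df["target"], df["upstream_offset"]))


def write_sites(sites: BindingSiteTable, path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.tf, r.target_gene, r.upstream_offset) for r in sites.rows],
        columns=["tf", "target", "upstream_offset"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_ppi(path: str | Path) -> PpiPairSet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"protein_a", "protein_b"}.issubset(df.columns):
        raise ParseError(f"{path}: expected columns protein_a, protein_b")
    return PpiPairSet.from_pairs(zip(df["protein_a"], df["protein_b"]))


def write_ppi(ppi: PpiPairSet, path: str | Path) -> None:
    rows = sorted(tuple(sorted(p)) for p in ppi.pairs)
    pd.DataFrame(rows, columns=["protein_a", "protein_b"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pre-processing
# ---------------------------------------------------------------------------

def average_replicates(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse replicate columns to their per-gene arithmetic mean.

    Replicates are experiments sharing ``replicate_group``.  The mean
    ignores missing entries; an all-missing group stays missing.  The
    surviving column keeps the metadata of the group's first member.
    Replicates disagreeing on category/condition/time_point are an error.
    """
    groups: dict[str, list[int]] = {}
    order: list[str] = []
    for i, m in enumerate(expr.experiments):
        if m.replicate_group is None:
            raise ValidationError(
                f"experiment {m.experiment_id!r} has no replicate_group")
        if m.replicate_group not in groups:
            groups[m.replicate_group] = []
            order.append(m.replicate_group)
        groups[m.replicate_group].append(i)

    new_meta: list[ExperimentMeta] = []
    cols: list[np.ndarray] = []
    for g in order:
        idx = groups[g]
        members = [expr.experiments[i] for i in idx]
        keys = {(m.category, m.condition, m.time_point) for m in members}
        if len(keys) > 1:
            raise ConsistencyError(
                f"replicate group {g!r} mixes categories/conditions/time points: {keys}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            cols.append(np.nanmean(expr.values[:, idx], axis=1))
        new_meta.append(members[0])
    return ExpressionMatrix(
        genes=list(expr.genes),
        experiments=new_meta,
        values=np.column_stack(cols) if cols else np.empty((expr.n_genes, 0)),
    )


def partition_by_category(
    expr: ExpressionMatrix,
    exclude_conditions: Iterable[str] = (),
) -> dict[str, ExpressionMatrix]:
    """Drop excluded conditions, then split columns by category label."""
    exclude = set(exclude_conditions)
    by_cat: dict[str, list[int]] = {}
    for i, m in enumerate(expr.experiments):
        if m.condition in exclude:
            continue
        by_cat.setdefault(m.category, []).append(i)

    out: dict[str, ExpressionMatrix] = {}
    seen_categories = {m.category for m in expr.experiments}
    for cat in sorted(seen_categories):
        idx = by_cat.get(cat, [])
        if not idx:
            warnings.warn(f"category {cat!r} is empty after condition filtering; omitted")
            continue
        out[cat] = expr.select_experiments(idx)
    return out
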