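"""Heuristic discovery of gene modules: sets of genes bound by a common
regulator set at a stringent p-value cutoff, refined and extended by
expression coherence with a relaxed combined binding criterion.

The expression-coherence metric is Euclidean distance between per-gene
z-scored profiles; its radius defaults to ``0.8 * sqrt(m)`` for ``m``
experiments and is configurable, as is the relaxed combined-p rule
(product of per-regulator p-values against ``relaxed_p ** |R|``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import BindingPValueMatrix, ExpressionMatrix
from .errors import ParseError, ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GramParams:
    stringent_p: float = 0.001
    relaxed_p: float = 0.01
    missing_frac_max: float = 0.20
    min_core_size: int = 3
    coherence_radius: float | None = None  # None -> 0.8 * sqrt(n_experiments)

    def __post_init__(self) -> None:
        if not (0 < self.stringent_p <= self.relaxed_p <= 1):
            raise ValidationError("need 0 < stringent_p <= relaxed_p <= 1")
        if not (0 <= self.missing_frac_max < 1):
            raise ValidationError("need 0 <= missing_frac_max < 1")
        if self.min_core_size < 1:
            raise ValidationError("min_core_size must be >= 1")
        if self.coherence_radius is not None and self.coherence_radius <= 0:
            raise ValidationError("coherence_radius must be positive")

    def radius_for(self, n_experiments: int) -> float:
        if self.coherence_radius is not None:
            return self.coherence_radius
        return 0.8 * np.sqrt(n_experiments)


@dataclass(frozen=True)
class GeneModule:
    """A co-expressed gene set with its direct regulators."""

    module_id: int
    regulators: frozenset[str]
    genes: frozenset[str]
    category: str
    mean_profile: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not self.regulators:
            raise ValidationError("module must have at least one regulator")
        if not self.genes:
            raise ValidationError("module must have at least one gene")


def filter_missingness(
    expr: ExpressionMatrix,
    binding: BindingPValueMatrix,
    params: GramParams = GramParams(),
) -> frozenset[str]:
    """Genes whose expression AND binding missing fractions are both at most
    ``missing_frac_max`` (rejection is strictly-more-than the threshold).
    Genes absent from the binding matrix are rejected.
    """
    eps = 1e-12  # guard against float division artifacts at the boundary
    kept = []
    for g in expr.genes:
        row = expr.row(g)
        if row.size == 0:
            continue
        expr_frac = np.isnan(row).mean()
        if expr_frac > params.missing_frac_max + eps:
            continue
        if g not in binding._gene_index:  # noqa: SLF001 - package-internal
            continue
        col = binding.gene_column(g)
        if col.size == 0 or np.isnan(col).mean() > params.missing_frac_max + eps:
            continue
        kept.append(g)
    return frozenset(kept)


def find_core_sets(
    binding: BindingPValueMatrix,
    admissible: frozenset[str],
    params: GramParams = GramParams(),
) -> list[tuple[frozenset[str], frozenset[str]]]:
    """Candidate (regulator set, core gene set) pairs.

    Candidate regulator sets are the deduplicated per-gene stringent-binding
    TF sets; the core of a set R is every admissible gene bound by all of R
    at ``stringent_p``.  Cores below ``min_core_size`` are dropped.
    Missing p-values fail every cutoff.
    """
    stringent: dict[str, frozenset[str]] = {}
    for g in sorted(admissible):
        if g not in binding._gene_index:  # noqa: SLF001
            continue
        col = binding.gene_column(g)
        with np.errstate(invalid="ignore"):
            hits = np.asarray(col <= params.stringent_p)
        tfs = frozenset(t for t, h in zip(binding.tfs, hits) if h)
        if tfs:
            stringent[g] = tfs

    candidates = sorted({r for r in stringent.values()}, key=lambda r: sorted(r))
    out = []
    for reg_set in candidates:
        core = frozenset(g for g, tfs in stringent.items() if reg_set <= tfs)
        if len(core) >= params.min_core_size:
            out.append((reg_set, core))
    return out


def _zscore_rows(values: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(values, axis=1, keepdims=True)
        sd = np.nanstd(values, axis=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return (values - mu) / sd


def _profile_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance with pairwise deletion, rescaled to full length so
    it stays comparable with a radius defined for m experiments."""
    obs = ~np.isnan(a) & ~np.isnan(b)
    n_obs = int(obs.sum())
    if n_obs == 0:
        return float("inf")
    d2 = float(np.sum((a[obs] - b[obs]) ** 2))
    return float(np.sqrt(d2 * a.size / n_obs))


def refine_and_extend(
    core: tuple[frozenset[str], frozenset[str]],
    expr: ExpressionMatrix,
    binding: BindingPValueMatrix,
    admissible: frozenset[str],
    params: GramParams = GramParams(),
    category: str = "",
) -> GeneModule | None:
    """Refine a core by expression coherence, then extend it with admissible
    genes that are both coherent and pass the relaxed combined-p rule.

    Returns ``None`` when refinement leaves fewer than ``min_core_size``
    genes.  The combined p-value of a candidate is the product of its
    per-regulator p-values, compared against ``relaxed_p ** |R|``; missing
    binding entries count as p = 1 (i.e. they fail).
    """
    reg_set, core_genes = core
    radius = params.radius_for(expr.n_experiments)
    z = _zscore_rows(expr.values)
    z_by_gene = {g: z[i] for i, g in enumerate(expr.genes)}

    core_list = sorted(g for g in core_genes if g in z_by_gene)
    if not core_list:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(np.vstack([z_by_gene[g] for g in core_list]), axis=0)

    refined = [g for g in core_list
               if _profile_distance(z_by_gene[g], mean) <= radius]
    if len(refined) < params.min_core_size:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(np.vstack([z_by_gene[g] for g in refined]), axis=0)

    members = set(refined)
    threshold = params.relaxed_p ** len(reg_set)
    for g in sorted(admissible - members):
        if g not in z_by_gene:
            continue
        if _profile_distance(z_by_gene[g], mean) > radius:
            continue
        combined = 1.0
        for t in reg_set:
            p = binding.pvalue(t, g)
            combined *= 1.0 if np.isnan(p) else p
        if combined <= threshold:
            members.add(g)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        final_mean = np.nanmean(np.vstack([z_by_gene[g] for g in sorted(members)]),
                                axis=0)
    return GeneModule(
        module_id=-1,
        regulators=reg_set,
        genes=frozenset(members),
        category=category,
        mean_profile=tuple(float(x) for x in final_mean),
    )


def find_modules(
    expr: ExpressionMatrix,
    binding: BindingPValueMatrix,
    params: GramParams = GramParams(),
    category: str = "",
) -> list[GeneModule]:
    """Full module discovery: missingness filter -> stringent cores ->
    refine/extend.  Modules are deduplicated on (regulators, genes), sorted
    by descending gene count (ties by sorted regulator/gene IDs), and
    numbered in that order.  Genes may belong to several modules.
    """
    admissible = filter_missingness(expr, binding, params)
    if len(admissible) < params.min_core_size:
        log.warning("only %d admissible genes (< min_core_size=%d); no modules",
                    len(admissible), params.min_core_size)
        return []

    raw: list[GeneModule] = []
    seen: set[tuple[frozenset[str], frozenset[str]]] = set()
    for core in find_core_sets(binding, admissible, params):
        mod = refine_and_extend(core, expr, binding, admissible, params, category)
        if mod is None:
            continue
        key = (mod.regulators, mod.genes)
        if key in seen:
            continue
        seen.add(key)
        raw.append(mod)

    raw.sort(key=lambda m: (-len(m.genes), sorted(m.regulators), sorted(m.genes)))
    return [
        GeneModule(module_id=i + 1, regulators=m.regulators, genes=m.genes,
                   category=m.category, mean_profile=m.mean_profile)
        for i, m in enumerate(raw)
    ]


# ---------------------------------------------------------------------------
# module file IO (schema: module_id, category, regulators, genes)
# ---------------------------------------------------------------------------

def write_modules(modules: list[GeneModule], path: str | Path) -> None:
    rows = [
        {
            "module_id": m.module_id,
            "category": m.category,
            "regulators": ",".join(sorted(m.regulators)),
            "genes": ",".join(sorted(m.genes)),
        }
        for m in modules
    ]
    pd.DataFrame(rows, columns=["module_id", "category", "regulators", "genes"]).to_csv(
        path, sep="\t", index=False)


def read_modules(path: str | Path) -> list[GeneModule]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"module_id", "category", "regulators", "genes"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        out.append(GeneModule(
            module_id=int(row["module_id"]),
            regulators=frozenset(row["regulators"].split(",")),
            genes=frozenset(row["genes"].split(",")),
            category="" if pd.isna(row["category"]) else str(row["category"]),
        ))
    return out
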