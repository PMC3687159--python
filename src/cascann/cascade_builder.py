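"""Extend gene modules into three-layer cascades.

The middle layer is the module's regulator set; the upper layer is the
union of each middle TF's upstream regulators, taken from a directed edge
list pre-filtered by the promoter-window binding-site rule.  Modules are
excluded when the upper layer is empty, too large (> ``max_upper``), or
would place the same TF in both layers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

from .data_io import BindingSiteTable, RegulatorEdgeSet
from .errors import ValidationError
from .module_finder import GeneModule

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Cascade:
    """A three-layer directed graph: upper TFs -> middle TFs -> one target."""

    target_gene: str
    middle_tfs: tuple[str, ...]
    upper_tfs: tuple[str, ...]
    input_edges: frozenset[tuple[str, str]]
    category: str = ""
    source_module: int = -1

    def __post_init__(self) -> None:
        if not self.middle_tfs:
            raise ValidationError("cascade needs at least one middle TF")
        if not self.upper_tfs:
            raise ValidationError("cascade needs at least one upper TF")
        upper, middle = set(self.upper_tfs), set(self.middle_tfs)
        if upper & middle:
            raise ValidationError(
                f"TF(s) {sorted(upper & middle)} appear in both layers")
        for u, m in self.input_edges:
            if u not in upper or m not in middle:
                raise ValidationError(f"edge ({u},{m}) leaves the layer sets")
        if upper - {u for u, _ in self.input_edges}:
            raise ValidationError("every upper TF must carry at least one edge")
        if middle - {m for _, m in self.input_edges}:
            raise ValidationError("every middle TF needs an incoming edge")

    @property
    def cascade_id(self) -> str:
        return f"{self.category or 'X'}:m{self.source_module}:{self.target_gene}"

    def n_free_parameters(self) -> int:
        # |edges| input weights + per-middle bias and output weight + output bias
        return len(self.input_edges) + 2 * len(self.middle_tfs) + 1

    def to_record(self) -> dict:
        return {
            "target_gene": self.target_gene,
            "middle_tfs": list(self.middle_tfs),
            "upper_tfs": list(self.upper_tfs),
            "input_edges": sorted(list(e) for e in self.input_edges),
            "category": self.category,
            "source_module": self.source_module,
        }

    @classmethod
    def from_record(cls, rec: dict) -> "Cascade":
        return cls(
            target_gene=rec["target_gene"],
            middle_tfs=tuple(rec["middle_tfs"]),
            upper_tfs=tuple(rec["upper_tfs"]),
            input_edges=frozenset((u, m) for u, m in rec["input_edges"]),
            category=rec.get("category", ""),
            source_module=rec.get("source_module", -1),
        )


def filter_edges_by_promoter(
    edges: RegulatorEdgeSet,
    sites: BindingSiteTable,
    window_bp: int = 1000,
) -> RegulatorEdgeSet:
    """Keep edge (t, g) iff the site table holds a (t, g) site within
    [1, window_bp] bp upstream (inclusive boundary)."""
    supported: set[tuple[str, str]] = set()
    for row in sites:
        if 1 <= row.upstream_offset <= window_bp:
            supported.add((row.tf, row.target_gene))
    return RegulatorEdgeSet(frozenset(e for e in edges if e in supported))


def upstream_regulators(
    middle_tf: str,
    filtered_edges: RegulatorEdgeSet,
    alias: dict[str, str] | None = None,
) -> frozenset[str]:
    """Regulators of the gene encoding ``middle_tf``, excluding itself.

    ``alias`` optionally maps TF name -> encoding-gene ID when the two
    namespaces differ; by default they are identical.
    """
    gene = (alias or {}).get(middle_tf, middle_tf)
    return frozenset(t for t, g in filtered_edges if g == gene and t != middle_tf)


def build_cascades(
    modules: list[GeneModule],
    filtered_edges: RegulatorEdgeSet,
    max_upper: int = 15,
    min_module_regulators: int = 2,
    complete_bipartite: bool = False,
    alias: dict[str, str] | None = None,
) -> list[Cascade]:
    """One cascade per gene of every module that survives the exclusion
    rules.  Cascades from a module share layers and edges and differ only
    in ``target_gene``.
    """
    out: list[Cascade] = []
    for mod in modules:
        if len(mod.regulators) < min_module_regulators:
            log.info("module %d: %d regulator(s) < %d, skipped (dimer route)",
                     mod.module_id, len(mod.regulators), min_module_regulators)
            continue
        middle = tuple(sorted(mod.regulators))
        upstream = {m: upstream_regulators(m, filtered_edges, alias) for m in middle}
        union = frozenset().union(*upstream.values())
        if not union:
            log.info("module %d: no known upstream regulators, excluded",
                     mod.module_id)
            continue
        if len(union) > max_upper:
            log.info("module %d: %d upstream TFs > %d, excluded",
                     mod.module_id, len(union), max_upper)
            continue
        if union & set(middle):
            log.info("module %d: TF(s) %s in both layers, excluded",
                     mod.module_id, sorted(union & set(middle)))
            continue
        if any(not upstream[m] for m in middle):
            orphans = [m for m in middle if not upstream[m]]
            log.info("module %d: middle TF(s) %s have no upstream edge, excluded",
                     mod.module_id, orphans)
            continue
        upper = tuple(sorted(union))
        if complete_bipartite:
            edges = frozenset((u, m) for u in upper for m in middle)
        else:
            edges = frozenset((u, m) for m in middle for u in upstream[m])
        for gene in sorted(mod.genes):
            out.append(Cascade(
                target_gene=gene,
                middle_tfs=middle,
                upper_tfs=upper,
                input_edges=edges,
                category=mod.category,
                source_module=mod.module_id,
            ))
    return out


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_cascades(cascades: list[Cascade], path: str | Path) -> None:
    """One JSON record per line, resumable."""
    with open(path, "w", encoding="utf-8") as fh:
        for c in cascades:
            fh.write(json.dumps(c.to_record(), sort_keys=True) + "\n")


def read_cascades(path: str | Path) -> list[Cascade]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(Cascade.from_record(json.loads(line)))
    return out


def write_dot(cascade: Cascade, path: str | Path) -> None:
    """GraphViz-compatible edge dump for quick inspection."""
    lines = ["digraph cascade {"]
    for u, m in sorted(cascade.input_edges):
        lines.append(f'  "{u}" -> "{m}";')
    for m in cascade.middle_tfs:
        lines.append(f'  "{m}" -> "{cascade.target_gene}";')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
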