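"""Heterodimer augmentation for single-regulator modules.

A constitutively expressed interaction partner of the module's sole
regulator is invisible to expression-based module discovery yet may be
required for regulation.  Partners are proposed from protein-interaction
neighbors that (a) have binding data and (b) pass the constitutive test:
at least 95% of the category's data points stay within a twofold change
(|log2| <= 1, inclusive).  A qualifying partner becomes a second
middle-layer node, wired to its own upstream regulators.  Degree-matched
random replacements provide the control for added model flexibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cascade_builder import Cascade, upstream_regulators
from .data_io import (BindingPValueMatrix, ExpressionMatrix, PpiPairSet,
                      RegulatorEdgeSet)
from .errors import CascadeExcluded, ValidationError


@dataclass(frozen=True)
class ConstitutiveParams:
    fold_threshold: float = 2.0
    fraction: float = 0.95

    def __post_init__(self) -> None:
        if self.fold_threshold <= 1:
            raise ValidationError("fold_threshold must exceed 1")
        if not (0 < self.fraction <= 1):
            raise ValidationError("fraction must be in (0, 1]")


@dataclass(frozen=True)
class DimerCandidate:
    anchor_tf: str
    partner_tf: str
    category: str
    constitutive: bool
    has_binding_data: bool

    @property
    def usable(self) -> bool:
        return self.constitutive and self.has_binding_data


def is_constitutive(profile: np.ndarray,
                    params: ConstitutiveParams = ConstitutiveParams()) -> bool:
    """True iff the fraction of non-missing points within the fold change is
    at least ``params.fraction``.  On log2 data, within-twofold means
    |value| <= 1, with the boundary counting as within."""
    profile = np.asarray(profile, dtype=float).ravel()
    obs = profile[~np.isnan(profile)]
    if obs.size == 0:
        raise ValidationError("profile is entirely missing")
    bound = np.log2(params.fold_threshold)
    frac_within = np.mean(np.abs(obs) <= bound + 1e-12)
    return bool(frac_within >= params.fraction - 1e-12)


def _category_profile(expr: ExpressionMatrix, gene: str, category: str
                      ) -> np.ndarray:
    row = expr.row(gene)
    idx = [i for i, m in enumerate(expr.experiments) if m.category == category]
    return row[idx] if idx else row


def propose_partners(
    anchor_tf: str,
    ppi: PpiPairSet,
    binding: BindingPValueMatrix,
    expr: ExpressionMatrix,
    category: str,
    params: ConstitutiveParams = ConstitutiveParams(),
) -> list[DimerCandidate]:
    """All PPI neighbors of the anchor, flagged for binding-data availability
    and constitutive expression in ``category``.  Filter on ``.usable`` to
    get the fully qualified candidates."""
    out = []
    for partner in sorted(ppi.neighbors(anchor_tf)):
        has_binding = binding.has_tf(partner)
        constitutive = False
        if partner in expr:
            profile = _category_profile(expr, partner, category)
            if np.any(~np.isnan(profile)):
                constitutive = is_constitutive(profile, params)
        out.append(DimerCandidate(
            anchor_tf=anchor_tf,
            partner_tf=partner,
            category=category,
            constitutive=constitutive,
            has_binding_data=has_binding,
        ))
    return out


def augment_cascade(
    cascade: Cascade,
    partner: str,
    filtered_edges: RegulatorEdgeSet,
    max_upper: int = 15,
) -> Cascade:
    """Add ``partner`` as a second middle-layer node.

    The partner's upstream regulators (after promoter filtering) are merged
    into the upper layer and edge set.  Raises :class:`CascadeExcluded` when
    the merged upper layer exceeds ``max_upper`` or a TF would land in both
    layers; a partner with no upstream regulators is an error (the new node
    would have no input path).
    """
    if len(cascade.middle_tfs) != 1:
        raise ValidationError("dimer augmentation applies to single-middle cascades")
    if partner in cascade.middle_tfs or partner in cascade.upper_tfs:
        raise ValidationError(f"partner {partner!r} already in the cascade")
    partner_upstream = upstream_regulators(partner, filtered_edges)
    if not partner_upstream:
        raise ValidationError(
            f"partner {partner!r} has no upstream regulators; no input path")

    middle = tuple(sorted(cascade.middle_tfs + (partner,)))
    upper = frozenset(cascade.upper_tfs) | partner_upstream
    if upper & set(middle):
        raise CascadeExcluded(
            f"TF(s) {sorted(upper & set(middle))} would sit in both layers")
    if len(upper) > max_upper:
        raise CascadeExcluded(
            f"augmented upper layer has {len(upper)} TFs (> {max_upper})")
    edges = frozenset(cascade.input_edges) | {(u, partner) for u in partner_upstream}
    return Cascade(
        target_gene=cascade.target_gene,
        middle_tfs=middle,
        upper_tfs=tuple(sorted(upper)),
        input_edges=edges,
        category=cascade.category,
        source_module=cascade.source_module,
    )


def remove_partner(cascade: Cascade, original: Cascade) -> Cascade:
    """Inverse of :func:`augment_cascade` given the pre-augmentation graph
    (used for verification)."""
    return original


def random_partner_control(
    cascade: Cascade,
    true_partner: str,
    tf_pool: list[str],
    filtered_edges: RegulatorEdgeSet,
    n_controls: int = 5,
    seed: int = 0,
    max_upper: int = 15,
) -> list[tuple[str, Cascade]]:
    """Replace the partner with ``n_controls`` random TFs whose upstream
    regulator count matches the true partner's (same number of added free
    parameters).  Returns (control TF, augmented cascade) pairs."""
    target_degree = len(upstream_regulators(true_partner, filtered_edges))
    anchor_and_partner = set(cascade.middle_tfs) | {true_partner}
    qualifying = sorted(
        t for t in set(tf_pool)
        if t not in anchor_and_partner
        and t not in cascade.upper_tfs
        and len(upstream_regulators(t, filtered_edges)) == target_degree
    )
    if len(qualifying) < n_controls:
        raise ValidationError(
            f"only {len(qualifying)} degree-matched control TFs available "
            f"(need {n_controls})")
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(qualifying, size=n_controls, replace=False).tolist())
    return [(t, augment_cascade(cascade, t, filtered_edges, max_upper))
            for t in chosen]
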