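"""Synthetic input bundles generated from a planted ground-truth cascade.

Every pipeline stage is testable offline: the generator emits a full set of
inputs (expression + metadata, binding p-values, regulator edges, binding
sites, PPI pairs) whose statistical structure matches the modeling
assumptions — smooth per-condition TF trajectories (random walks, so time
shifts are identifiable), logistic middle-layer activities, a linear target
readout with optional per-TF delays and an optional multiplicative dimer
term, plus Gaussian measurement noise.

Upper-TF walks carry a hidden pre-roll of ``max(planted shifts)`` steps so
the planted lagged relation holds at every *recorded* time point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cascade_ann import CascadeANN, logsig, mask_from_cascade
from .cascade_builder import Cascade
from .data_io import (BindingPValueMatrix, BindingSiteTable, ExperimentMeta,
                      ExpressionMatrix, PpiPairSet, RegulatorEdgeSet)
from .errors import ValidationError

# middle-TF expression = RESCALE_SPAN * (activity - RESCALE_CENTER), putting
# logistic activities on a roughly [-2, 2] log2 scale
RESCALE_SPAN = 4.0
RESCALE_CENTER = 0.5

WALK_START_SD = 1.0
WALK_RHO = 0.5        # mean reversion keeps lag-1 autocorrelation moderate,
WALK_STEP_SD = 1.0    # so planted time shifts stay identifiable
TRUE_BINDING_P = 1e-4
TRUE_SITE_OFFSET = 500
DECOY_SITE_OFFSET = 1500


@dataclass(frozen=True)
class SyntheticSpec:
    n_categories: int = 1
    conditions_per_category: int = 6
    timepoints_per_condition: int = 4
    n_upper: int = 3
    n_middle: int = 2
    n_module_genes: int = 6
    n_background_genes: int = 24
    n_extra_tfs: int = 1          # binding-matrix TFs regulating nothing
    planted_shifts: tuple[int, ...] = ()  # per upper TF; empty = all zero
    dimer: bool = False
    n_partner_upper: int = 2
    n_control_tfs: int = 0        # degree-matched pool for replacement controls
    null_target: bool = False     # module genes independent of every TF
    noise_sd: float = 0.05
    weight_scale: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.planted_shifts:
            if len(self.planted_shifts) != self.n_upper:
                raise ValidationError("planted_shifts must cover every upper TF")
            if max(self.planted_shifts) > self.timepoints_per_condition - 1:
                raise ValidationError(
                    "planted shifts exceed timepoints_per_condition - 1")
            if min(self.planted_shifts) < 0:
                raise ValidationError("planted shifts must be >= 0")
        if self.dimer and self.n_middle != 1:
            raise ValidationError("dimer generation requires a single middle TF")

    @property
    def shifts(self) -> tuple[int, ...]:
        return self.planted_shifts or (0,) * self.n_upper


@dataclass
class GroundTruth:
    cascade: Cascade
    dimer_cascade: Cascade | None
    ann: CascadeANN
    planted_shifts: dict[str, int]
    anchor: str | None
    partner: str | None
    module_genes: tuple[str, ...]
    control_tfs: tuple[str, ...]
    rescale: tuple[float, float] = (RESCALE_SPAN, RESCALE_CENTER)


@dataclass
class Bundle:
    expression: ExpressionMatrix
    binding: BindingPValueMatrix
    edges: RegulatorEdgeSet
    sites: BindingSiteTable
    ppi: PpiPairSet
    truth: GroundTruth


def _walk(rng: np.random.Generator, length: int) -> np.ndarray:
    """Mean-reverting (AR(1)) trajectory: smooth in time, yet each step
    carries fresh innovation — a pure cumulative walk is so strongly
    autocorrelated that neighboring time shifts become indistinguishable."""
    x = np.empty(length)
    x[0] = rng.normal(0.0, WALK_START_SD)
    for t in range(1, length):
        x[t] = WALK_RHO * x[t - 1] + rng.normal(0.0, WALK_STEP_SD)
    return x


def generate_bundle(spec: SyntheticSpec) -> Bundle:
    rng = np.random.default_rng(spec.seed)
    T = spec.timepoints_per_condition
    kmax = max(spec.shifts)
    cats = [chr(ord("A") + i) for i in range(spec.n_categories)]

    upper = [f"U{i+1}" for i in range(spec.n_upper)]
    middle = [f"M{j+1}" for j in range(spec.n_middle)]
    extra_tfs = [f"E{i+1}" for i in range(spec.n_extra_tfs)]
    module_genes = [f"G{i+1}" for i in range(spec.n_module_genes)]
    background = [f"B{i+1}" for i in range(spec.n_background_genes)]
    partner = "P1" if spec.dimer else None
    partner_upper = [f"Q{i+1}" for i in range(spec.n_partner_upper)] if spec.dimer else []
    control_tfs = [f"C{i+1}" for i in range(spec.n_control_tfs)]
    control_upper = {c: [f"D{c[1:]}_{i+1}" for i in range(spec.n_partner_upper)]
                     for c in control_tfs}

    # planted parameters ---------------------------------------------------
    W = rng.uniform(1.0, spec.weight_scale, size=(spec.n_upper, spec.n_middle))
    W *= rng.choice([-1.0, 1.0], size=W.shape)
    b_mid = rng.uniform(-0.5, 0.5, size=spec.n_middle)
    w_out = rng.uniform(1.5, 2.5, size=spec.n_middle)
    w_out *= rng.choice([-1.0, 1.0], size=w_out.shape)
    b_out = float(rng.uniform(-0.3, 0.3))
    if spec.dimer:
        W_p = rng.uniform(1.0, spec.weight_scale, size=spec.n_partner_upper)
        W_p *= rng.choice([-1.0, 1.0], size=W_p.shape)
        b_p = float(rng.uniform(-0.5, 0.5))
        w_dimer = 3.0

    # per-condition simulation --------------------------------------------
    meta: list[ExperimentMeta] = []
    col_values: dict[str, list[float]] = {
        g: [] for g in (upper + middle + extra_tfs + module_genes + background
                        + ([partner] if partner else []) + partner_upper
                        + control_tfs
                        + [d for ds in control_upper.values() for d in ds])}

    for cat in cats:
        for c in range(spec.conditions_per_category):
            cond = f"{cat}cond{c+1}"
            uw = np.vstack([_walk(rng, T + kmax) for _ in upper])  # hidden pre-roll
            qw = np.vstack([_walk(rng, T) for _ in partner_upper]) \
                if partner_upper else np.empty((0, T))
            # middle activities at recorded steps, with per-upper-TF lags
            h = np.empty((spec.n_middle, T))
            for t in range(T):
                a = t + kmax
                x = np.array([uw[i, a - spec.shifts[i]] for i in range(spec.n_upper)])
                h[:, t] = logsig(x @ W + b_mid)
            if spec.dimer:
                h_p = logsig(W_p @ qw + b_p) if partner_upper else np.full(T, 0.5)
                f = w_dimer * h[0] * h_p + b_out
            else:
                f = w_out @ h + b_out

            for t in range(T):
                meta.append(ExperimentMeta(
                    experiment_id=f"{cond}_t{t+1}", category=cat, condition=cond,
                    time_point=t + 1, time_value=float((t + 1) * 10),
                    replicate_group=f"{cond}_t{t+1}"))
            for i, u in enumerate(upper):
                col_values[u].extend(uw[i, kmax:])
            for i, q in enumerate(partner_upper):
                col_values[q].extend(qw[i])
            for j, m in enumerate(middle):
                expr_m = RESCALE_SPAN * (h[j] - RESCALE_CENTER) \
                    + rng.normal(0, spec.noise_sd, size=T)
                col_values[m].extend(expr_m)
            if partner:
                col_values[partner].extend(
                    np.clip(rng.normal(0, 0.1, size=T), -0.9, 0.9))
            for g in module_genes:
                if spec.null_target:
                    col_values[g].extend(rng.normal(0, 1.0, size=T))
                else:
                    col_values[g].extend(f + rng.normal(0, spec.noise_sd, size=T))
            for e in extra_tfs:
                col_values[e].extend(_walk(rng, T))
            for b in background:
                col_values[b].extend(_walk(rng, T))
            for ctf in control_tfs:
                col_values[ctf].extend(_walk(rng, T))
                for d in control_upper[ctf]:
                    col_values[d].extend(_walk(rng, T))

    genes = list(col_values)
    expr = ExpressionMatrix(
        genes=genes,
        experiments=meta,
        values=np.vstack([np.asarray(col_values[g]) for g in genes]),
    )

    # binding p-values -----------------------------------------------------
    binding_tfs = middle + ([partner] if partner else []) + extra_tfs
    binding_genes = module_genes + background
    pvals = rng.uniform(0.3, 1.0, size=(len(binding_tfs), len(binding_genes)))
    for j, m in enumerate(middle):
        for g in module_genes:
            pvals[j, binding_genes.index(g)] = TRUE_BINDING_P
    binding = BindingPValueMatrix(tfs=binding_tfs, genes=binding_genes,
                                  pvalues=pvals)

    # regulator edges + binding sites consistent with the planted graph ----
    true_edges: list[tuple[str, str]] = []
    for m in middle:
        true_edges += [(u, m) for u in upper]
        true_edges += [(m, g) for g in module_genes]
    if partner:
        true_edges += [(q, partner) for q in partner_upper]
    for ctf in control_tfs:
        true_edges += [(d, ctf) for d in control_upper[ctf]]
    edges = RegulatorEdgeSet.from_pairs(true_edges)
    site_rows = [(t, g, TRUE_SITE_OFFSET) for t, g in true_edges]
    # decoy sites beyond the promoter window for a few non-edges
    for b in background[: min(3, len(background))]:
        site_rows.append((upper[0], b, DECOY_SITE_OFFSET))
    sites = BindingSiteTable.from_rows(site_rows)

    # PPI pairs ------------------------------------------------------------
    ppi_pairs: list[tuple[str, str]] = []
    if partner:
        ppi_pairs.append((middle[0], partner))
    if len(background) >= 2:
        ppi_pairs.append((background[0], background[1]))
    ppi = PpiPairSet.from_pairs(ppi_pairs)

    # ground truth ---------------------------------------------------------
    cat0 = cats[0]
    cascade = Cascade(
        target_gene=module_genes[0],
        middle_tfs=tuple(middle),
        upper_tfs=tuple(upper),
        input_edges=frozenset((u, m) for u in upper for m in middle),
        category=cat0 if spec.n_categories == 1 else "",
        source_module=1,
    )
    dimer_cascade = None
    if spec.dimer:
        dimer_cascade = Cascade(
            target_gene=module_genes[0],
            middle_tfs=tuple(sorted(middle + [partner])),
            upper_tfs=tuple(sorted(set(upper) | set(partner_upper))),
            input_edges=frozenset(
                [(u, m) for u in upper for m in middle]
                + [(q, partner) for q in partner_upper]),
            category=cascade.category,
            source_module=1,
        )
    truth_ann = CascadeANN(
        cascade=cascade, W_in=W.copy(), b_mid=b_mid.copy(), w_out=w_out.copy(),
        b_out=b_out, mask=mask_from_cascade(cascade))
    truth = GroundTruth(
        cascade=cascade,
        dimer_cascade=dimer_cascade,
        ann=truth_ann,
        planted_shifts=dict(zip(upper, spec.shifts)),
        anchor=middle[0] if spec.dimer else None,
        partner=partner,
        module_genes=tuple(module_genes),
        control_tfs=tuple(control_tfs),
    )
    return Bundle(expression=expr, binding=binding, edges=edges, sites=sites,
                  ppi=ppi, truth=truth)


FIXTURE_NAMES = ("planted_module", "planted_delays", "planted_dimer", "pure_noise")


def make_fixture(name: str, seed: int = 0) -> SyntheticSpec:
    """Canonical specs used throughout the test suite."""
    if name == "planted_module":
        return SyntheticSpec(
            conditions_per_category=6, timepoints_per_condition=4,
            n_upper=3, n_middle=2, n_module_genes=6, n_background_genes=24,
            n_extra_tfs=1, noise_sd=0.05, seed=seed)
    if name == "planted_delays":
        return SyntheticSpec(
            conditions_per_category=6, timepoints_per_condition=4,
            n_upper=3, n_middle=1, n_module_genes=3, n_background_genes=4,
            planted_shifts=(2, 0, 1), noise_sd=0.05, seed=seed)
    if name == "planted_dimer":
        return SyntheticSpec(
            conditions_per_category=6, timepoints_per_condition=4,
            n_upper=2, n_middle=1, n_module_genes=4, n_background_genes=4,
            dimer=True, n_partner_upper=2, n_control_tfs=6,
            noise_sd=0.05, seed=seed)
    if name == "pure_noise":
        return SyntheticSpec(
            conditions_per_category=6, timepoints_per_condition=4,
            n_upper=3, n_middle=2, n_module_genes=3, n_background_genes=4,
            null_target=True, noise_sd=0.05, seed=seed)
    raise ValidationError(
        f"unknown fixture {name!r}; choose one of {FIXTURE_NAMES}")
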