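"""Asynchronous (time-delayed) regulation search.

Each upper-layer TF may act ``k`` time steps before the target responds,
with ``k`` per TF and 0 <= k <= n-1 where n is the smallest time-point
count among the category's multi-time-point conditions.  All (max_shift+1)^N
assignments are enumerated; each yields a shifted design built per
condition, pairing target values at step j with TF values at steps j - k_i
(only steps with every index valid contribute).  Every design is evaluated
with the standard repeated-split protocol; the best assignment (highest
mean CC, ties to the smaller total shift, then lexicographic) is compared
against the shuffled-target null.

Note on bounds: the source narrative is internally inconsistent about both
the admissible range of k (a strict "0 < k < n-1" alongside worked examples
using k = 0 and k = n-1) and the number of combinations ("n*N" vs. the
independent per-TF cross product).  This implementation uses the inclusive
range 0..n-1 and the full cross product, which match the worked examples.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .cascade_ann import TrainParams
from .cascade_builder import Cascade
from .data_io import ExpressionMatrix
from .errors import ValidationError
from .eval_harness import (MIN_SAMPLES, EvalParams, EvalResult, NullComparison,
                           evaluate_design, shuffle_null_design)


@dataclass(frozen=True)
class ShiftAssignment:
    """Backward shift k per upper TF, aligned with ``tfs``."""

    tfs: tuple[str, ...]
    shifts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.tfs) != len(self.shifts):
            raise ValidationError("one shift per TF required")
        if any(k < 0 for k in self.shifts):
            raise ValidationError("shifts must be >= 0")

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.tfs, self.shifts))

    @property
    def total(self) -> int:
        return sum(self.shifts)

    @property
    def max(self) -> int:
        return max(self.shifts)

    @property
    def is_zero(self) -> bool:
        return all(k == 0 for k in self.shifts)


@dataclass
class ShiftSearchResult:
    cascade: Cascade
    max_shift: int
    results: dict[ShiftAssignment, EvalResult | None]
    best: ShiftAssignment
    best_result: EvalResult
    successes: list[ShiftAssignment]
    null: NullComparison | None = None


def _conditions(expr: ExpressionMatrix, category: str | None
                ) -> dict[str, list[int]]:
    """Condition -> experiment indices ordered by time point.  Restricts to
    ``category`` when given and present in the metadata."""
    out: dict[str, list[int]] = {}
    for i, m in enumerate(expr.experiments):
        if category and m.category != category:
            continue
        out.setdefault(m.condition, []).append(i)
    for cond, idx in out.items():
        idx.sort(key=lambda i: (expr.experiments[i].time_point is None,
                                expr.experiments[i].time_point or 0))
    return out


def max_shift(expr: ExpressionMatrix, category: str) -> int:
    """n - 1, where n is the minimum time-point count among the category's
    multi-time-point conditions (single-point conditions are excluded)."""
    counts = []
    for cond, idx in _conditions(expr, category).items():
        tps = [expr.experiments[i].time_point for i in idx]
        if any(t is None for t in tps):
            continue
        if len(tps) >= 2:
            counts.append(len(tps))
    if not counts:
        raise ValidationError(
            f"category {category!r} has no condition with >= 2 time points")
    return min(counts) - 1


def enumerate_assignments(
    upper_tfs: tuple[str, ...] | list[str],
    max_shift: int,
    cap: int = 100_000,
) -> list[ShiftAssignment]:
    """The full cross product {0..max_shift}^N in lexicographic order."""
    if max_shift < 0:
        raise ValidationError("max_shift must be >= 0")
    tfs = tuple(upper_tfs)
    count = (max_shift + 1) ** len(tfs)
    if count > cap:
        raise ValidationError(
            f"{count} shift assignments exceed the cap of {cap}; reduce "
            f"max_shift or restrict per-TF shift sets")
    return [ShiftAssignment(tfs, ks)
            for ks in itertools.product(range(max_shift + 1), repeat=len(tfs))]


def build_shifted_design(
    cascade: Cascade,
    expr: ExpressionMatrix,
    assignment: ShiftAssignment,
) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix pairing target(t_j) with TF_i(t_{j-k_i}) per condition.

    Only multi-time-point conditions contribute shifted samples; a condition
    with m points yields max(0, m - max_i k_i) samples.  Single-time-point
    conditions contribute their one sample only under the all-zero
    assignment.
    """
    if set(assignment.tfs) != set(cascade.upper_tfs):
        raise ValidationError("assignment does not cover the cascade's upper layer")
    shifts = assignment.as_dict()
    ks = [shifts[t] for t in cascade.upper_tfs]

    tf_rows = {t: expr.row(t) for t in cascade.upper_tfs}
    y_row = expr.row(cascade.target_gene)

    X_rows: list[list[float]] = []
    y_vals: list[float] = []
    for cond, idx in _conditions(expr, cascade.category or None).items():
        tps = [expr.experiments[i].time_point for i in idx]
        multi = len(idx) >= 2 and all(t is not None for t in tps)
        if not multi:
            if assignment.is_zero:
                for i in idx:
                    X_rows.append([tf_rows[t][i] for t in cascade.upper_tfs])
                    y_vals.append(y_row[i])
            continue
        m = len(idx)
        for j in range(1, m + 1):  # 1-based step within the condition
            if any(j - k < 1 for k in ks):
                continue
            X_rows.append([tf_rows[t][idx[j - 1 - shifts[t]]]
                           for t in cascade.upper_tfs])
            y_vals.append(y_row[idx[j - 1]])
    if not X_rows:
        return (np.empty((0, len(cascade.upper_tfs))), np.empty(0))
    return np.asarray(X_rows, dtype=float), np.asarray(y_vals, dtype=float)


def search_shifts(
    cascade: Cascade,
    expr: ExpressionMatrix,
    eval_params: EvalParams = EvalParams(),
    train_params: TrainParams = TrainParams(),
    shift_bound: int | None = None,
    cap: int = 100_000,
    null_shuffles: int = 20,
) -> ShiftSearchResult:
    """Evaluate every shift assignment and report the optimum.

    Assignments whose shifted design has too few complete samples are
    recorded with a ``None`` result and never become best.  When
    ``null_shuffles`` > 0 the best assignment's design is additionally
    compared to the shuffled-target null.
    """
    bound = max_shift(expr, cascade.category) if shift_bound is None else shift_bound
    assignments = enumerate_assignments(cascade.upper_tfs, bound, cap)

    results: dict[ShiftAssignment, EvalResult | None] = {}
    for a in assignments:
        X, y = build_shifted_design(cascade, expr, a)
        complete = np.isfinite(X).all(axis=1) & np.isfinite(y)
        if int(complete.sum()) < MIN_SAMPLES:
            results[a] = None
            continue
        results[a] = evaluate_design(X, y, cascade, eval_params, train_params)

    scored = [(a, r) for a, r in results.items() if r is not None]
    if not scored:
        raise ValidationError(
            "no shift assignment leaves enough samples to evaluate")
    best, best_result = min(
        scored, key=lambda ar: (-ar[1].mean_cc, ar[0].total, ar[0].shifts))
    successes = [a for a, r in scored
                 if r.mean_cc > eval_params.success_threshold]

    null = None
    if null_shuffles > 0:
        Xb, yb = build_shifted_design(cascade, expr, best)
        null = shuffle_null_design(Xb, yb, cascade, eval_params, train_params,
                                   n_shuffles=null_shuffles, observed=best_result)
    return ShiftSearchResult(
        cascade=cascade,
        max_shift=bound,
        results=results,
        best=best,
        best_result=best_result,
        successes=successes,
        null=null,
    )
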