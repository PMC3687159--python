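"""Repeated random-split evaluation of cascade models.

Protocol: for each repetition, samples (experiment columns) are split
50/25/25 into train/validation/test, a freshly initialized masked network
is trained with Levenberg-Marquardt, and the Pearson correlation between
its test predictions and the held-out target values is recorded.  A model
succeeds when its mean test correlation over all repetitions is strictly
above the threshold (default 0.70).  Statistical significance is assessed
against a null built by shuffling the target gene's expression values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .cascade_ann import TrainParams, forward, init_ann, train_lm
from .cascade_builder import Cascade
from .data_io import ExpressionMatrix
from .errors import ValidationError

MIN_SAMPLES = 8  # below this, floor-based 50/25/25 splitting can empty a part


@dataclass(frozen=True)
class EvalParams:
    n_reps: int = 100
    train_frac: float = 0.50
    val_frac: float = 0.25
    test_frac: float = 0.25
    success_threshold: float = 0.70
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.train_frac, self.val_frac, self.test_frac)
        if any(f <= 0 for f in fracs) or abs(sum(fracs) - 1.0) > 1e-9:
            raise ValidationError("split fractions must be positive and sum to 1")
        if self.n_reps < 1:
            raise ValidationError("n_reps must be >= 1")


@dataclass
class EvalResult:
    cascade: Cascade | None
    n_reps: int
    per_rep_test_cc: np.ndarray
    mean_cc: float
    std_cc: float
    success: bool
    split_seed: int
    n_samples: int = 0
    n_degenerate: int = 0  # repetitions where a zero-variance CC was clamped to 0

    @classmethod
    def from_ccs(cls, cascade: Cascade | None, ccs: np.ndarray, params: EvalParams,
                 n_samples: int, n_degenerate: int = 0) -> "EvalResult":
        ccs = np.asarray(ccs, dtype=float)
        mean = float(np.mean(ccs))
        return cls(
            cascade=cascade,
            n_reps=len(ccs),
            per_rep_test_cc=ccs,
            mean_cc=mean,
            std_cc=float(np.std(ccs)),
            success=mean > params.success_threshold,
            split_seed=params.seed,
            n_samples=n_samples,
            n_degenerate=n_degenerate,
        )


@dataclass
class NullComparison:
    observed: EvalResult
    shuffled_mean_ccs: np.ndarray
    max_shuffled_cc: float
    verdict: bool  # observed mean CC strictly above the best shuffled mean CC


def split_samples(n: int, params: EvalParams, rep_index: int
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive (train, val, test) index arrays.

    A seeded permutation (keyed by (seed, rep_index)) is cut at
    floor(n*train_frac) and floor(n*(train_frac+val_frac)).
    """
    if n < MIN_SAMPLES:
        raise ValidationError(
            f"need at least {MIN_SAMPLES} samples to split, got {n}; supply more data")
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, rep_index]))
    perm = rng.permutation(n)
    c1 = int(np.floor(n * params.train_frac))
    c2 = int(np.floor(n * (params.train_frac + params.val_frac)))
    return perm[:c1], perm[c1:c2], perm[c2:]


def pearson_cc(pred: np.ndarray, actual: np.ndarray) -> float:
    """Product-moment correlation; a zero-variance side yields 0.0."""
    cc, _ = _cc_with_flag(pred, actual)
    return cc


def _cc_with_flag(pred: np.ndarray, actual: np.ndarray) -> tuple[float, bool]:
    pred = np.asarray(pred, dtype=float).ravel()
    actual = np.asarray(actual, dtype=float).ravel()
    if pred.shape != actual.shape:
        raise ValidationError("pred/actual length mismatch")
    if pred.size < 3:
        raise ValidationError("need at least 3 points for a correlation")
    p = pred - pred.mean()
    a = actual - actual.mean()
    denom = np.sqrt((p * p).sum() * (a * a).sum())
    if denom == 0 or not np.isfinite(denom):
        return 0.0, True
    return float(np.clip((p * a).sum() / denom, -1.0, 1.0)), False


def _drop_missing(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    keep = np.isfinite(X).all(axis=1) & np.isfinite(y)
    return X[keep], y[keep]


def evaluate_design(
    X: np.ndarray,
    y: np.ndarray,
    cascade: Cascade,
    eval_params: EvalParams = EvalParams(),
    train_params: TrainParams = TrainParams(),
) -> EvalResult:
    """Run the full repeated-split protocol on an explicit design matrix.

    Rows with any missing value (input or target) are dropped up front
    (listwise deletion).  Columns of ``X`` must follow ``cascade.upper_tfs``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    X, y = _drop_missing(X, y)
    n = len(y)
    if n < MIN_SAMPLES:
        raise ValidationError(
            f"only {n} complete samples available (need >= {MIN_SAMPLES})")

    ccs = np.empty(eval_params.n_reps)
    n_degenerate = 0
    for rep in range(eval_params.n_reps):
        tr, va, te = split_samples(n, eval_params, rep)
        init_seed = np.random.SeedSequence([eval_params.seed, rep, 1])
        ann = init_ann(cascade, init_seed)
        trained, _ = train_lm(ann, X[tr], y[tr], X[va], y[va], train_params)
        cc, degenerate = _cc_with_flag(forward(trained, X[te]), y[te])
        ccs[rep] = cc
        n_degenerate += int(degenerate)
    return EvalResult.from_ccs(cascade, ccs, eval_params, n, n_degenerate)


def design_from_expression(cascade: Cascade, expr: ExpressionMatrix
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Synchronous design: TF expression and target expression at the same
    experiment columns."""
    cols = []
    for tf in cascade.upper_tfs:
        if tf not in expr:
            raise ValidationError(f"upper TF {tf!r} absent from expression matrix")
        cols.append(expr.row(tf))
    if cascade.target_gene not in expr:
        raise ValidationError(
            f"target gene {cascade.target_gene!r} absent from expression matrix")
    X = np.column_stack(cols)
    y = expr.row(cascade.target_gene).copy()
    return X, y


def evaluate_cascade(
    cascade: Cascade,
    expr: ExpressionMatrix,
    eval_params: EvalParams = EvalParams(),
    train_params: TrainParams = TrainParams(),
) -> EvalResult:
    X, y = design_from_expression(cascade, expr)
    return evaluate_design(X, y, cascade, eval_params, train_params)


def shuffle_null_design(
    X: np.ndarray,
    y: np.ndarray,
    cascade: Cascade,
    eval_params: EvalParams = EvalParams(),
    train_params: TrainParams = TrainParams(),
    n_shuffles: int = 100,
    observed: EvalResult | None = None,
) -> NullComparison:
    """Re-run the full evaluation with the target values permuted, once per
    shuffle trial; the verdict is True iff the unshuffled mean CC strictly
    exceeds the maximum shuffled mean CC."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    X, y = _drop_missing(X, y)
    if observed is None:
        observed = evaluate_design(X, y, cascade, eval_params, train_params)
    null_means = np.empty(n_shuffles)
    for s in range(n_shuffles):
        rng = np.random.default_rng(
            np.random.SeedSequence([eval_params.seed, 104729, s]))
        y_perm = y[rng.permutation(len(y))]
        res = evaluate_design(X, y_perm, cascade,
                              replace(eval_params, seed=eval_params.seed + s + 1),
                              train_params)
        null_means[s] = res.mean_cc
    max_null = float(null_means.max())
    return NullComparison(
        observed=observed,
        shuffled_mean_ccs=null_means,
        max_shuffled_cc=max_null,
        verdict=observed.mean_cc > max_null,
    )


def shuffle_null(
    cascade: Cascade,
    expr: ExpressionMatrix,
    eval_params: EvalParams = EvalParams(),
    train_params: TrainParams = TrainParams(),
    n_shuffles: int = 100,
) -> NullComparison:
    X, y = design_from_expression(cascade, expr)
    return shuffle_null_design(X, y, cascade, eval_params, train_params, n_shuffles)
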