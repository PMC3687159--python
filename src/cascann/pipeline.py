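"""Pipeline orchestration and tabular reports.

Stages (``modules`` -> ``cascades`` -> ``synchronous`` -> {``asynchronous``,
``dimers``, ``null``} -> ``report``) communicate through serialized
intermediates in the output directory, so runs are resumable and each stage
can be re-run independently yet reproducibly: every per-cascade seed is
derived from the global seed with a counter-based scheme.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import data_io
from .cascade_ann import TrainParams
from .cascade_builder import (Cascade, build_cascades, filter_edges_by_promoter,
                              read_cascades, upstream_regulators, write_cascades)
from .errors import CascadeExcluded, DependencyError, ValidationError
from .eval_harness import EvalParams, EvalResult, evaluate_cascade, shuffle_null
from .heterodimer import ConstitutiveParams, augment_cascade, propose_partners, \
    random_partner_control
from .module_finder import GeneModule, GramParams, find_modules, read_modules, \
    write_modules
from .timeshift import search_shifts

log = logging.getLogger(__name__)

STAGES = ("modules", "cascades", "synchronous", "asynchronous", "dimers",
          "null", "report")
_FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    expression: str = ""
    metadata: str = ""
    binding: str = ""
    edges: str = ""
    sites: str = ""
    ppi: str = ""
    outdir: str = "out"
    exclude_conditions: tuple[str, ...] = ()
    window_bp: int = 1000
    max_upper: int = 15
    min_module_regulators: int = 2
    n_shuffles: int = 20
    n_controls: int = 5
    shift_cap: int = 100_000
    seed: int = 0
    gram: GramParams = field(default_factory=GramParams)
    eval: EvalParams = field(default_factory=EvalParams)
    train: TrainParams = field(default_factory=TrainParams)
    constitutive: ConstitutiveParams = field(default_factory=ConstitutiveParams)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        raw.update(overrides)
        kwargs = {}
        for name, sub in (("gram", GramParams), ("eval", EvalParams),
                          ("train", TrainParams), ("constitutive", ConstitutiveParams)):
            if name in raw:
                kwargs[name] = sub(**raw.pop(name))
        if "exclude_conditions" in raw:
            raw["exclude_conditions"] = tuple(raw["exclude_conditions"])
        kwargs.update(raw)
        return cls(**kwargs)

    def log_parameters(self) -> None:
        """Record every parameter in effect so the run is self-describing."""
        for f in dataclasses.fields(self):
            log.info("config %s = %r", f.name, getattr(self, f.name))


def _cascade_seed(global_seed: int, *counters: int) -> int:
    return int(np.random.SeedSequence([global_seed, *counters]).generate_state(1)[0])


def _load_category_expression(config: RunConfig) -> dict[str, data_io.ExpressionMatrix]:
    expr = data_io.read_expression(config.expression, config.metadata)
    expr = data_io.average_replicates(expr)
    return data_io.partition_by_category(expr, config.exclude_conditions)


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise DependencyError(
            f"missing intermediate {path.name!r}; run the {stage!r} stage first")
    return path


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_modules(config: RunConfig, out: Path) -> list[GeneModule]:
    by_cat = _load_category_expression(config)
    binding = data_io.read_binding(config.binding)
    modules: list[GeneModule] = []
    next_id = 1
    for cat, expr in sorted(by_cat.items()):
        found = find_modules(expr, binding, config.gram, category=cat)
        for m in found:
            modules.append(dataclasses.replace(m, module_id=next_id))
            next_id += 1
    write_modules(modules, out / "modules.tsv")
    return modules


def _filtered_edges(config: RunConfig) -> data_io.RegulatorEdgeSet:
    edges = data_io.read_edges(config.edges)
    sites = data_io.read_sites(config.sites)
    return filter_edges_by_promoter(edges, sites, config.window_bp)


def stage_cascades(config: RunConfig, out: Path) -> list[Cascade]:
    modules = read_modules(_require(out / "modules.tsv", "modules"))
    cascades = build_cascades(
        modules, _filtered_edges(config),
        max_upper=config.max_upper,
        min_module_regulators=config.min_module_regulators)
    write_cascades(cascades, out / "cascades.jsonl")
    return cascades


def _result_row(cascade: Cascade, res: EvalResult) -> dict:
    return {
        "cascade_id": cascade.cascade_id,
        "target_gene": cascade.target_gene,
        "category": cascade.category,
        "n_samples": res.n_samples,
        "mean_cc": res.mean_cc,
        "std_cc": res.std_cc,
        "success": res.success,
    }


def stage_synchronous(config: RunConfig, out: Path) -> pd.DataFrame:
    cascades = read_cascades(_require(out / "cascades.jsonl", "cascades"))
    by_cat = _load_category_expression(config)
    rows = []
    for i, c in enumerate(cascades):
        if c.category not in by_cat:
            log.warning("cascade %s: no expression for category %r, skipped",
                        c.cascade_id, c.category)
            continue
        ep = dataclasses.replace(config.eval, seed=_cascade_seed(config.seed, 1, i))
        try:
            res = evaluate_cascade(c, by_cat[c.category], ep, config.train)
        except ValidationError as exc:
            log.warning("cascade %s skipped: %s", c.cascade_id, exc)
            continue
        rows.append(_result_row(c, res))
    df = pd.DataFrame(rows, columns=["cascade_id", "target_gene", "category",
                                     "n_samples", "mean_cc", "std_cc", "success"])
    _write_tsv(df, out / "eval_synchronous.tsv")
    return df


def stage_asynchronous(config: RunConfig, out: Path) -> pd.DataFrame:
    cascades = read_cascades(_require(out / "cascades.jsonl", "cascades"))
    sync = pd.read_csv(_require(out / "eval_synchronous.tsv", "synchronous"),
                       sep="\t")
    sync_cc = dict(zip(sync["cascade_id"], sync["mean_cc"]))
    by_cat = _load_category_expression(config)
    shift_dir = out / "shifts"
    shift_dir.mkdir(exist_ok=True)
    rows = []
    for i, c in enumerate(cascades):
        if c.category not in by_cat:
            continue
        ep = dataclasses.replace(config.eval, seed=_cascade_seed(config.seed, 2, i))
        try:
            sr = search_shifts(c, by_cat[c.category], ep, config.train,
                               cap=config.shift_cap,
                               null_shuffles=config.n_shuffles)
        except ValidationError as exc:
            log.warning("cascade %s: shift search skipped: %s", c.cascade_id, exc)
            continue
        per_rows = []
        for a, r in sr.results.items():
            per_rows.append({
                "shifts": ",".join(str(k) for k in a.shifts),
                "mean_cc": np.nan if r is None else r.mean_cc,
                "std_cc": np.nan if r is None else r.std_cc,
                "success": False if r is None else r.success,
                "MAX": sr.max_shift,
            })
        _write_tsv(pd.DataFrame(per_rows),
                   shift_dir / f"{c.cascade_id.replace(':', '_')}.tsv")
        rows.append({
            "cascade_id": c.cascade_id,
            "target_gene": c.target_gene,
            "category": c.category,
            "best_shifts": ",".join(str(k) for k in sr.best.shifts),
            "best_mean_cc": sr.best_result.mean_cc,
            "sync_mean_cc": sync_cc.get(c.cascade_id, np.nan),
            "n_successes": len(sr.successes),
            "null_max_cc": np.nan if sr.null is None else sr.null.max_shuffled_cc,
            "null_verdict": None if sr.null is None else sr.null.verdict,
        })
    df = pd.DataFrame(rows)
    _write_tsv(df, out / "shifts_summary.tsv")
    if len(df):
        comp = pd.DataFrame({
            "metric": ["mean_sync_cc", "mean_async_cc", "n_improved", "n_total"],
            "value": [df["sync_mean_cc"].mean(), df["best_mean_cc"].mean(),
                      int((df["best_mean_cc"] > df["sync_mean_cc"]).sum()), len(df)],
        })
        _write_tsv(comp, out / "sync_vs_async.tsv")
    return df


def stage_dimers(config: RunConfig, out: Path) -> pd.DataFrame:
    modules = read_modules(_require(out / "modules.tsv", "modules"))
    by_cat = _load_category_expression(config)
    binding = data_io.read_binding(config.binding)
    ppi = data_io.read_ppi(config.ppi)
    fedges = _filtered_edges(config)
    tf_pool = sorted({t for t, _ in fedges} | {g for _, g in fedges})
    rows = []
    counter = 0
    for mod in modules:
        if len(mod.regulators) != 1 or mod.category not in by_cat:
            continue
        anchor = next(iter(mod.regulators))
        expr = by_cat[mod.category]
        candidates = [c for c in propose_partners(
            anchor, ppi, binding, expr, mod.category, config.constitutive)
            if c.usable]
        anchor_up = upstream_regulators(anchor, fedges)
        if not anchor_up or len(anchor_up) > config.max_upper:
            continue
        for cand in candidates:
            for gene in sorted(mod.genes):
                counter += 1
                base = Cascade(
                    target_gene=gene, middle_tfs=(anchor,),
                    upper_tfs=tuple(sorted(anchor_up)),
                    input_edges=frozenset((u, anchor) for u in anchor_up),
                    category=mod.category, source_module=mod.module_id)
                try:
                    dimer = augment_cascade(base, cand.partner_tf, fedges,
                                            config.max_upper)
                except (CascadeExcluded, ValidationError) as exc:
                    log.warning("module %d gene %s: augmentation failed: %s",
                                mod.module_id, gene, exc)
                    continue
                ep = dataclasses.replace(
                    config.eval, seed=_cascade_seed(config.seed, 3, counter))
                try:
                    single_res = evaluate_cascade(base, expr, ep, config.train)
                    dimer_res = evaluate_cascade(dimer, expr, ep, config.train)
                    controls = random_partner_control(
                        base, cand.partner_tf, tf_pool, fedges,
                        n_controls=config.n_controls,
                        seed=_cascade_seed(config.seed, 4, counter),
                        max_upper=config.max_upper)
                    control_ccs = [
                        evaluate_cascade(cc, expr, ep, config.train).mean_cc
                        for _, cc in controls]
                except ValidationError as exc:
                    log.warning("module %d gene %s: dimer evaluation skipped: %s",
                                mod.module_id, gene, exc)
                    continue
                rows.append({
                    "module_id": mod.module_id,
                    "category": mod.category,
                    "target_gene": gene,
                    "anchor": anchor,
                    "partner": cand.partner_tf,
                    "single_mean_cc": single_res.mean_cc,
                    "dimer_mean_cc": dimer_res.mean_cc,
                    "control_mean_cc": float(np.mean(control_ccs)),
                    "dimer_success": dimer_res.success,
                })
    df = pd.DataFrame(rows)
    _write_tsv(df, out / "dimers.tsv")
    return df


def stage_null(config: RunConfig, out: Path) -> pd.DataFrame:
    cascades = read_cascades(_require(out / "cascades.jsonl", "cascades"))
    by_cat = _load_category_expression(config)
    rows = []
    for i, c in enumerate(cascades):
        if c.category not in by_cat:
            continue
        ep = dataclasses.replace(config.eval, seed=_cascade_seed(config.seed, 1, i))
        try:
            comp = shuffle_null(c, by_cat[c.category], ep, config.train,
                                n_shuffles=config.n_shuffles)
        except ValidationError as exc:
            log.warning("cascade %s: null skipped: %s", c.cascade_id, exc)
            continue
        rows.append({
            "cascade_id": c.cascade_id,
            "target_gene": c.target_gene,
            "category": c.category,
            "mean_cc": comp.observed.mean_cc,
            "null_max_cc": comp.max_shuffled_cc,
            "verdict": comp.verdict,
        })
    df = pd.DataFrame(rows)
    _write_tsv(df, out / "null.tsv")
    return df


def summarize(results: list[EvalResult] | pd.DataFrame,
              threshold: float = 0.70) -> pd.DataFrame:
    """Per-category model counts and CC statistics (the pie-chart data)."""
    if isinstance(results, pd.DataFrame):
        df = results
    else:
        df = pd.DataFrame([
            {"category": r.cascade.category if r.cascade else "",
             "mean_cc": r.mean_cc} for r in results])
    if df.empty:
        return pd.DataFrame(columns=["category", "n_models", "n_success",
                                     "fraction_success", "mean_cc", "median_cc"])
    rows = []
    for cat, grp in df.groupby("category", sort=True):
        n = len(grp)
        n_success = int((grp["mean_cc"] > threshold).sum())
        rows.append({
            "category": cat,
            "n_models": n,
            "n_success": n_success,
            "fraction_success": n_success / n,
            "mean_cc": grp["mean_cc"].mean(),
            "median_cc": grp["mean_cc"].median(),
        })
    return pd.DataFrame(rows)


def cc_histogram(mean_ccs, bin_width: float = 0.1) -> pd.DataFrame:
    edges = np.arange(-1.0, 1.0 + bin_width / 2, bin_width)
    counts, _ = np.histogram(np.asarray(list(mean_ccs), dtype=float), bins=edges)
    return pd.DataFrame({
        "bin_low": edges[:-1].round(6),
        "bin_high": edges[1:].round(6),
        "count": counts,
    })


def stage_report(config: RunConfig, out: Path) -> pd.DataFrame:
    sync = pd.read_csv(_require(out / "eval_synchronous.tsv", "synchronous"),
                       sep="\t")
    summary = summarize(sync, config.eval.success_threshold)
    _write_tsv(summary, out / "summary.tsv")
    _write_tsv(cc_histogram(sync["mean_cc"]) if len(sync) else cc_histogram([]),
               out / "cc_histogram.tsv")
    return summary


_STAGE_FUNCS = {
    "modules": stage_modules,
    "cascades": stage_cascades,
    "synchronous": stage_synchronous,
    "asynchronous": stage_asynchronous,
    "dimers": stage_dimers,
    "null": stage_null,
    "report": stage_report,
}


def run_pipeline(config: RunConfig, stages: set[str] | list[str]) -> dict[str, object]:
    """Execute the requested stages in dependency order."""
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValidationError(f"unknown stage(s) {sorted(unknown)}; valid: {STAGES}")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.log_parameters()
    outputs = {}
    for stage in STAGES:
        if stage in stages:
            log.info("running stage %s", stage)
            outputs[stage] = _STAGE_FUNCS[stage](config, out)
    return outputs
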