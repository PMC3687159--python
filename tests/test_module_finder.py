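import itertools

import numpy as np
import pytest

from cascann.data_io import BindingPValueMatrix
from cascann.errors import ValidationError
from cascann.module_finder import (GeneModule, GramParams, filter_missingness,
                                   find_core_sets, find_modules,
                                   read_modules, refine_and_extend,
                                   write_modules)

from conftest import make_expr


def binding_of(tfs, genes, default=0.5, hits=()):
    """hits: iterable of (tf, gene, p)."""
    p = np.full((len(tfs), len(genes)), default, dtype=float)
    for t, g, v in hits:
        p[tfs.index(t), genes.index(g)] = v
    return BindingPValueMatrix(tfs=list(tfs), genes=list(genes), pvalues=p)


def exhaustive_cores(binding, admissible, params):
    """Independent oracle: enumerate every regulator subset, compute its
    stringent core, and keep the maximal regulator set for each distinct
    core gene set."""
    by_core = {}
    for r in range(1, len(binding.tfs) + 1):
        for subset in itertools.combinations(binding.tfs, r):
            core = frozenset(
                g for g in admissible
                if all(binding.pvalue(t, g) <= params.stringent_p for t in subset))
            if len(core) >= params.min_core_size:
                prev = by_core.get(core)
                if prev is None or len(subset) > len(prev):
                    by_core[core] = frozenset(subset)
    return {(tfs, core) for core, tfs in by_core.items()}


class TestMissingness:
    def test_complete_gene_kept(self):
        expr = make_expr(np.zeros((1, 10)))
        b = binding_of(["t"], ["g1"])
        assert filter_missingness(expr, b) == {"g1"}

    def test_thirty_percent_missing_rejected(self):
        vals = np.zeros((1, 10))
        vals[0, :3] = np.nan
        b = binding_of(["t"], ["g1"])
        assert filter_missingness(make_expr(vals), b) == frozenset()

    def test_exactly_twenty_percent_kept(self):
        # boundary is strict "more than": 2 of 10 missing is admissible
        vals = np.zeros((1, 10))
        vals[0, :2] = np.nan
        b = binding_of(["t"], ["g1"])
        assert filter_missingness(make_expr(vals), b) == {"g1"}

    def test_gene_without_binding_rejected(self):
        expr = make_expr(np.zeros((1, 10)))
        b = binding_of(["t"], ["other"])
        assert filter_missingness(expr, b) == frozenset()

    def test_binding_missingness_counts(self):
        expr = make_expr(np.zeros((1, 10)))
        p = np.full((10, 1), 0.5)
        p[:3, 0] = np.nan  # 30% of binding missing
        b = BindingPValueMatrix(tfs=[f"t{i}" for i in range(10)], genes=["g1"],
                                pvalues=p)
        assert filter_missingness(expr, b) == frozenset()


class TestCoreSets:
    def test_all_ones_empty(self):
        b = binding_of(["t1", "t2"], ["g1", "g2", "g3"], default=1.0)
        assert find_core_sets(b, frozenset(["g1", "g2", "g3"])) == []

    def test_four_gene_core(self):
        genes = ["g1", "g2", "g3", "g4"]
        hits = [(t, g, 1e-4) for t in ("t1", "t2") for g in genes]
        b = binding_of(["t1", "t2", "t3"], genes, hits=hits)
        cores = find_core_sets(b, frozenset(genes))
        assert cores == [(frozenset({"t1", "t2"}), frozenset(genes))]
        assert cores[0] in exhaustive_cores(b, frozenset(genes), GramParams())

    def test_small_core_dropped(self):
        b = binding_of(["t1"], ["g1", "g2"],
                       hits=[("t1", "g1", 1e-4), ("t1", "g2", 1e-4)])
        assert find_core_sets(b, frozenset(["g1", "g2"])) == []

    def test_matches_exhaustive_oracle(self, planted_module_bundle):
        b = planted_module_bundle.binding
        params = GramParams()
        expr = planted_module_bundle.expression
        admissible = filter_missingness(expr, b, params)
        got = set(find_core_sets(b, admissible, params))
        assert got == exhaustive_cores(b, admissible, params)

    def test_tightening_stringent_p_never_adds_cores(self, planted_module_bundle):
        b = planted_module_bundle.binding
        admissible = frozenset(b.genes)
        loose = {r for r, _ in find_core_sets(b, admissible,
                                              GramParams(stringent_p=0.01))}
        tight = {r for r, _ in find_core_sets(b, admissible,
                                              GramParams(stringent_p=0.001))}
        assert tight <= loose


class TestRefineExtend:
    def _core_setup(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 8)
        vals = np.vstack([base + rng.normal(0, 0.05, 8) for _ in range(4)])
        genes = [f"g{i+1}" for i in range(4)]
        expr = make_expr(vals, genes=genes)
        hits = [("t1", g, 1e-4) for g in genes[:3]]
        b = binding_of(["t1"], genes, hits=hits)
        return expr, b, genes

    def test_coherent_stringent_gene_added(self):
        expr, b, genes = self._core_setup()
        core = (frozenset({"t1"}), frozenset(genes[:3]))
        # g4 tracks the mean profile; give it a stringent p-value
        b.pvalues[0, 3] = 1e-4
        mod = refine_and_extend(core, expr, b, frozenset(genes))
        assert "g4" in mod.genes

    def test_p_one_candidate_not_added(self):
        expr, b, genes = self._core_setup()
        core = (frozenset({"t1"}), frozenset(genes[:3]))
        b.pvalues[0, 3] = 1.0
        mod = refine_and_extend(core, expr, b, frozenset(genes))
        assert "g4" not in mod.genes

    def test_returns_none_when_refinement_underflows(self):
        rng = np.random.default_rng(1)
        expr = make_expr(rng.normal(0, 1, (3, 8)))  # mutually incoherent
        b = binding_of(["t1"], expr.genes,
                       hits=[("t1", g, 1e-4) for g in expr.genes])
        core = (frozenset({"t1"}), frozenset(expr.genes))
        assert refine_and_extend(core, expr, b, frozenset(expr.genes),
                                 GramParams(coherence_radius=1e-6)) is None


class TestFindModules:
    def test_empty_binding(self):
        expr = make_expr(np.zeros((3, 8)))
        b = BindingPValueMatrix(tfs=[], genes=[], pvalues=np.empty((0, 0)))
        assert find_modules(expr, b) == []

    def test_planted_module_recovered_exactly(self, planted_module_bundle):
        bundle = planted_module_bundle
        mods = find_modules(bundle.expression, bundle.binding, category="A")
        assert len(mods) == 1
        assert mods[0].genes == frozenset(bundle.truth.module_genes)
        assert mods[0].regulators == frozenset(bundle.truth.cascade.middle_tfs)
        assert mods[0].module_id == 1

    def test_two_disjoint_planted_modules(self):
        rng = np.random.default_rng(7)
        base1, base2 = rng.normal(0, 1, (2, 12))
        vals = np.vstack(
            [base1 + rng.normal(0, 0.05, 12) for _ in range(3)]
            + [base2 + rng.normal(0, 0.05, 12) for _ in range(3)]
            + [rng.normal(0, 1, 12) for _ in range(6)])
        genes = [f"g{i+1}" for i in range(12)]
        expr = make_expr(vals, genes=genes)
        hits = [("t1", g, 1e-4) for g in genes[:3]] + \
               [("t2", g, 1e-4) for g in genes[3:6]]
        b = binding_of(["t1", "t2"], genes, hits=hits)
        mods = find_modules(expr, b)
        assert len(mods) == 2
        recovered = {m.regulators: m.genes for m in mods}
        assert recovered[frozenset({"t1"})] == frozenset(genes[:3])
        assert recovered[frozenset({"t2"})] == frozenset(genes[3:6])

    def test_module_invariants(self, planted_module_bundle):
        bundle = planted_module_bundle
        params = GramParams()
        admissible = filter_missingness(bundle.expression, bundle.binding, params)
        for m in find_modules(bundle.expression, bundle.binding, params):
            assert len(m.genes) >= params.min_core_size
            assert m.genes <= admissible

    def test_round_trip(self, tmp_path, planted_module_bundle):
        mods = find_modules(planted_module_bundle.expression,
                            planted_module_bundle.binding, category="A")
        write_modules(mods, tmp_path / "m.tsv")
        back = read_modules(tmp_path / "m.tsv")
        assert [(m.module_id, m.regulators, m.genes, m.category) for m in back] \
            == [(m.module_id, m.regulators, m.genes, m.category) for m in mods]


def test_params_validated():
    with pytest.raises(ValidationError):
        GramParams(stringent_p=0.05, relaxed_p=0.01)
    with pytest.raises(ValidationError):
        GramParams(missing_frac_max=1.0)
    with pytest.raises(ValidationError):
        GeneModule(module_id=1, regulators=frozenset(), genes=frozenset({"g"}),
                   category="A")
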