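import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import hypergeom

from pleiokit.coexpression import ModuleAssignment
from pleiokit.diffexpr import DEThresholds
from pleiokit.pleiotropy import (
    classify_conservation,
    fc_distribution_test,
    fraction_in_enriched_terms,
    go_enrichment,
    pleiotropy_value,
    summarize_tf,
    target_enrichment,
    threshold_sweep,
)


def _assignment(labels: dict) -> ModuleAssignment:
    return ModuleAssignment(
        labels=pd.Series(labels), eigengenes=pd.DataFrame()
    )


def _spread(genes, n_modules, offset=0):
    """Assign genes round-robin over exactly n_modules module ids."""
    return {g: offset + 1 + (i % n_modules) for i, g in enumerate(genes)}


def _deg_table(universe, degs, lfc=None):
    lfc = lfc or {}
    return pd.DataFrame(
        {
            "base_mean": 10.0,
            "log2fc_raw": [lfc.get(g, 1.0 if g in degs else 0.0) for g in universe],
            "log2fc_shrunk": [lfc.get(g, 1.0 if g in degs else 0.0) for g in universe],
            "wald_p": [1e-8 if g in degs else 0.9 for g in universe],
            "padj": [1e-6 if g in degs else 0.95 for g in universe],
        },
        index=pd.Index(universe),
    )


class TestPleiotropyValue:
    def test_module_dispersion_counts(self):
        # 151 DEGs spread over exactly 35 modules, 34 over 16
        genes_a = [f"a{i}" for i in range(151)]
        genes_b = [f"b{i}" for i in range(34)]
        labels = {**_spread(genes_a, 35), **_spread(genes_b, 16, offset=40)}
        assignment = _assignment(labels)
        assert pleiotropy_value(genes_a, assignment) == 35
        assert pleiotropy_value(genes_b, assignment) == 16

    def test_boundary_cases(self):
        assignment = _assignment({"g1": 1, "g2": 1, "g3": 0})
        assert pleiotropy_value([], assignment) == 0
        assert pleiotropy_value(["g1", "g2"], assignment) == 1
        # unassigned DEGs are ignored
        assert pleiotropy_value(["g1", "g3"], assignment) == 1

    def test_missing_gene_error_names_it(self):
        assignment = _assignment({"g1": 1})
        with pytest.raises(KeyError, match="ghost"):
            pleiotropy_value(["ghost"], assignment)

    @given(st.integers(0, 2**31 - 1))
    def test_monotone_under_set_inclusion(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(40)]
        assignment = _assignment(dict(zip(genes, rng.integers(0, 8, 40))))
        subset = [g for g in genes if rng.random() < 0.4]
        superset = subset + [g for g in genes if g not in subset and rng.random() < 0.5]
        assert pleiotropy_value(subset, assignment) <= pleiotropy_value(
            superset, assignment
        )


class TestClassifyConservation:
    def test_identical_deg_sets_are_fully_conserved(self):
        universe = [f"g{i}" for i in range(20)]
        degs = set(universe[:8])
        cats = classify_conservation(_deg_table(universe, degs), _deg_table(universe, degs))
        assert (cats == "conserved").all() and len(cats) == 8

    def test_disjoint_deg_sets_are_fully_nonconserved(self):
        universe = [f"g{i}" for i in range(20)]
        cats = classify_conservation(
            _deg_table(universe, set(universe[:8])),
            _deg_table(universe, set(universe[10:15])),
        )
        assert (cats == "nonconserved").all()

    def test_partition_is_exact(self):
        universe = [f"g{i}" for i in range(30)]
        a_degs = set(universe[:12])
        b_degs = set(universe[6:18])
        cats = classify_conservation(_deg_table(universe, a_degs), _deg_table(universe, b_degs))
        assert set(cats.index) == a_degs
        assert (cats == "conserved").sum() + (cats == "nonconserved").sum() == 12

    def test_missing_gene_in_other_background_raises(self):
        universe = [f"g{i}" for i in range(10)]
        with pytest.raises(KeyError):
            classify_conservation(
                _deg_table(universe, {"g0"}), _deg_table(universe[1:], set())
            )

    def test_direction_matched_rule_is_stricter(self):
        universe = ["g0", "g1"]
        a = _deg_table(universe, {"g0", "g1"}, lfc={"g0": 1.0, "g1": 1.0})
        b = _deg_table(universe, {"g0", "g1"}, lfc={"g0": 1.0, "g1": -1.0})
        default = classify_conservation(a, b)
        directional = classify_conservation(a, b, rule="significant_both_same_direction")
        assert (default == "conserved").sum() == 2
        assert (directional == "conserved").sum() == 1

    def test_conserved_pleiotropy_partition_of_a_crz1_like_fixture(self):
        # 151 A-DEGs of which 16 replicate in B; conserved genes span 7
        # modules and the 135 nonconserved span 33 (union = 35 modules)
        genes = [f"g{i}" for i in range(151)]
        conserved, nonconserved = genes[:16], genes[16:]
        labels = {**_spread(conserved, 7), **_spread(nonconserved, 33, offset=2)}
        assignment = _assignment(labels)
        universe = genes + ["extra"]
        summary = summarize_tf(
            "CRZ1",
            _deg_table(universe, set(genes)),
            _deg_table(universe, set(conserved)),
            assignment,
        )
        assert summary.n_deg == 151
        assert summary.n_conserved == 16
        assert summary.n_nonconserved == 135
        assert summary.pleiotropy_conserved == 7
        assert summary.pleiotropy_nonconserved == 33
        assert summary.pleiotropy_overall == 35


class TestThresholdSweep:
    def _contrasts(self):
        universe = [f"g{i}" for i in range(30)]
        a = _deg_table(universe, set(universe[:10]))
        b = _deg_table(universe, set(universe[:6]))
        b.loc[universe[4], "padj"] = 0.03  # conserved only at looser padj
        b.loc[universe[5], "padj"] = 0.03
        labels = dict(zip(universe, [1 + i % 5 for i in range(30)]))
        return {"TF1": (a, b)}, _assignment(labels)

    def test_degenerate_grid_matches_direct_classification(self):
        contrasts, assignment = self._contrasts()
        sweep = threshold_sweep(contrasts, assignment, [DEThresholds()])
        summary = summarize_tf("TF1", *contrasts["TF1"], assignment)
        assert sweep.loc[0, "median_pleiotropy_conserved"] == summary.pleiotropy_conserved
        assert sweep.loc[0, "median_conserved_fraction"] == pytest.approx(
            summary.conserved_fraction
        )

    def test_loosening_b_thresholds_grows_conserved_sets(self):
        contrasts, _ = self._contrasts()
        a, b = contrasts["TF1"]
        strict = classify_conservation(a, b, thresholds_b=DEThresholds(1.2, 0.01))
        loose = classify_conservation(a, b, thresholds_b=DEThresholds(1.2, 0.05))
        strict_set = set(strict.index[strict == "conserved"])
        loose_set = set(loose.index[loose == "conserved"])
        assert strict_set < loose_set

    def test_empty_grid_rejected(self):
        contrasts, assignment = self._contrasts()
        with pytest.raises(ValueError):
            threshold_sweep(contrasts, assignment, [])


class TestFcDistribution:
    def _pairs(self, cons, noncons, cls="activator"):
        return pd.DataFrame(
            {
                "tf": "t",
                "gene": [f"g{i}" for i in range(len(cons) + len(noncons))],
                "log2fc": np.concatenate([cons, noncons]),
                "category": ["conserved"] * len(cons) + ["nonconserved"] * len(noncons),
                "regulator_class": cls,
            }
        )

    def test_identical_samples_give_zero_statistic(self):
        x = np.linspace(-1, 1, 50)
        res = fc_distribution_test(self._pairs(x, x), "activator")
        assert res["statistic"] == 0.0 and res["p_value"] == 1.0

    def test_separated_distributions_detected(self):
        rng = np.random.default_rng(0)
        res = fc_distribution_test(
            self._pairs(rng.normal(-1, 0.2, 200), rng.normal(0, 1, 200)), "activator"
        )
        assert res["p_value"] < 1e-6
        assert res["median_sign_conserved"] == -1

    def test_statistic_equals_bruteforce_ecdf_gap(self):
        cons = np.array([0.1, -0.5, 1.2, 0.3])
        noncons = np.array([-0.2, 0.4, 0.9])
        res = fc_distribution_test(self._pairs(cons, noncons), "activator")
        grid = np.concatenate([cons, noncons])
        gaps = [
            abs((cons <= v).mean() - (noncons <= v).mean()) for v in grid
        ]
        assert np.isclose(res["statistic"], max(gaps), atol=1e-12)

    def test_empty_category_raises(self):
        with pytest.raises(ValueError, match="conserved"):
            fc_distribution_test(self._pairs([], [0.1, 0.2]), "activator")


class TestTargetEnrichment:
    def _printed_fixture(self):
        # contingency counts: 94/872 conserved targets, 68/6867 nonconserved
        rows = []
        for i in range(872):
            rows.append({"tf": "t", "gene": f"c{i}", "category": "conserved"})
        for i in range(6867):
            rows.append({"tf": "t", "gene": f"n{i}", "category": "nonconserved"})
        pairs = pd.DataFrame(rows)
        targets = {"t": {f"c{i}" for i in range(94)} | {f"n{i}" for i in range(68)}}
        return pairs, targets

    def test_printed_contingency_percentages(self):
        pairs, targets = self._printed_fixture()
        res = target_enrichment(pairs, targets, 535900, 4778)
        assert res["proportions_pct"]["conserved"] == 10.8
        assert res["proportions_pct"]["nonconserved"] == 1.0
        assert res["proportions_pct"]["background"] == 0.9
        assert res["test_p"] < 1e-10  # conserved strongly enriched over nonconserved

    def test_zero_targets_give_zero_percent(self):
        pairs = pd.DataFrame(
            {
                "tf": "t",
                "gene": [f"g{i}" for i in range(40)],
                "category": ["conserved"] * 20 + ["nonconserved"] * 20,
            }
        )
        res = target_enrichment(pairs, {"t": set()}, 1000, 0, method="fisher")
        assert res["proportions_pct"]["conserved"] == 0.0
        assert res["proportions_pct"]["nonconserved"] == 0.0
        assert res["proportions_pct"]["background"] == 0.0


class TestGoEnrichment:
    def test_whole_universe_term_never_enriched(self):
        universe = [f"g{i}" for i in range(50)]
        res = go_enrichment(universe[:10], {"all": set(universe)}, universe)
        assert res.loc[0, "fold_enrichment"] == 1.0
        assert not res.loc[0, "enriched"]

    def test_hypergeometric_tail_matches_bruteforce_sum(self):
        universe = [f"g{i}" for i in range(100)]
        term = set(universe[:10])
        degs = universe[:5] + universe[20:25]  # k=5 of n=10
        res = go_enrichment(degs, {"term": term}, universe)
        assert res.loc[0, "fold_enrichment"] == pytest.approx(5.0)
        brute = sum(hypergeom.pmf(k, 100, 10, 10) for k in range(5, 11))
        assert res.loc[0, "p_value"] == pytest.approx(brute, abs=1e-12)
        frac = fraction_in_enriched_terms(degs, res, {"term": term})
        assert frac == pytest.approx(0.5)

    def test_empty_deg_set_gives_empty_result(self):
        res = go_enrichment([], {"t": {"g0"}}, ["g0", "g1"])
        assert len(res) == 0
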