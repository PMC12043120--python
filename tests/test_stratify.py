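import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

from immunoscape.io import ExpressionMatrix, GeneSetCollection
from immunoscape.stratify import (
    DEResult,
    differential_expression,
    enrichment_hypergeometric,
    induction_attenuation,
    mann_whitney_p,
    rank_plot_data,
    tercile_stratify,
)


def _matrix(rows: dict[str, list[float]], samples=None) -> ExpressionMatrix:
    values = pd.DataFrame(rows).T.astype(float)
    values.columns = samples or [f"S{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(values, pd.Series("A", index=values.columns))


class TestTercileStratify:
    def test_nine_samples_split_evenly(self):
        v = pd.Series(range(1, 10), index=[f"S{i}" for i in range(9)], dtype=float)
        labels = tercile_stratify(v)
        assert (labels.value_counts() == 3).all()
        assert set(labels[v <= 3]) == {"low"}
        assert set(labels[v >= 7]) == {"high"}

    def test_floor_convention_n10(self):
        v = pd.Series(range(10), index=[f"S{i}" for i in range(10)], dtype=float)
        counts = tercile_stratify(v).value_counts()
        assert counts["low"] == 3 and counts["high"] == 3 and counts["mid"] == 4

    def test_all_ties_resolved_by_sample_id(self):
        v = pd.Series(1.0, index=[f"S{i}" for i in range(6)])
        labels = tercile_stratify(v)
        assert labels[["S0", "S1"]].tolist() == ["low", "low"]
        assert labels[["S2", "S3"]].tolist() == ["mid", "mid"]
        assert labels[["S4", "S5"]].tolist() == ["high", "high"]

    @pytest.mark.parametrize("n", [3, 4, 5, 7, 11, 30])
    def test_group_sizes_always_floor_n_over_3(self, n, rng):
        v = pd.Series(rng.normal(size=n), index=[f"S{i:02d}" for i in range(n)])
        counts = tercile_stratify(v).value_counts()
        assert counts.get("low", 0) == n // 3
        assert counts.get("high", 0) == n // 3

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            tercile_stratify(pd.Series([1.0, 2.0], index=["a", "b"]))


class TestMannWhitney:
    def test_separated_groups_exact(self):
        """A entirely below B: U = 0, two-sided exact p = 2/C(6,3) = 0.1."""
        assert mann_whitney_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_all_tied_returns_one(self):
        assert mann_whitney_p([2, 2], [2, 2]) == 1.0

    def test_tied_hand_example(self):
        """Pooled [1,1,1,2] split 2/2: every assignment gives |U - 2| = 1, so p = 1."""
        assert mann_whitney_p([1, 1], [1, 2]) == 1.0

    def test_exact_matches_scipy_without_ties(self, rng):
        for _ in range(30):
            n1, n2 = rng.integers(2, 7, size=2)
            a = rng.normal(size=n1)
            b = rng.normal(size=n2)
            ours = mann_whitney_p(a, b)
            theirs = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            assert ours == pytest.approx(theirs, abs=1e-12)

    def test_asymptotic_close_to_exact_at_moderate_n(self, rng):
        a = rng.normal(size=8)
        b = rng.normal(size=8)
        exact = mann_whitney_p(a, b)
        approx = mann_whitney_p(np.concatenate([a, [a.mean()]]), b)  # n1=9 -> asymptotic branch
        assert abs(exact - approx) < 0.15

    def test_null_calibration(self, rng):
        """Asymptotic two-sided p is uniform enough: 5% +/- 1 rejections at alpha=0.05."""
        hits = 0
        total = 3000
        for _ in range(total):
            a = rng.normal(size=30)
            b = rng.normal(size=30)
            hits += mann_whitney_p(a, b) < 0.05
        assert hits / total == pytest.approx(0.05, abs=0.01)


class TestDifferentialExpression:
    def test_identical_groups_null(self):
        m = _matrix({"G1": [1, 2, 3, 1, 2, 3], "G2": [5, 5, 5, 5, 5, 5]})
        de = differential_expression(m, ["S0", "S1", "S2"], ["S3", "S4", "S5"])
        assert (de.table["log2_fc"] == 0).all()
        assert (de.table["p"] == 1.0).all()

    def test_median_ratio_fold_change(self):
        m = _matrix({"G1": [7, 7, 7, 3, 3, 3]})
        de = differential_expression(m, ["S0", "S1", "S2"], ["S3", "S4", "S5"], pseudocount=1.0)
        assert de.lfc_of("G1") == pytest.approx(1.0)  # log2(8/4)

    def test_separated_groups_exact_p(self):
        m = _matrix({"G1": [1, 2, 3, 4, 5, 6]})
        de = differential_expression(m, ["S0", "S1", "S2"], ["S3", "S4", "S5"])
        assert de.table["p"].iloc[0] == pytest.approx(0.1)

    def test_antisymmetry(self, rng):
        rows = {f"G{i}": rng.lognormal(size=12).tolist() for i in range(10)}
        m = _matrix(rows)
        a, b = [f"S{i}" for i in range(6)], [f"S{i}" for i in range(6, 12)]
        de_ab = differential_expression(m, a, b)
        de_ba = differential_expression(m, b, a)
        np.testing.assert_allclose(de_ab.table["log2_fc"], -de_ba.table["log2_fc"], atol=1e-12)
        np.testing.assert_allclose(de_ab.table["p"], de_ba.table["p"], atol=1e-12)

    def test_overlapping_or_empty_groups_rejected(self):
        m = _matrix({"G1": [1, 2, 3, 4]})
        with pytest.raises(ValueError, match="overlap"):
            differential_expression(m, ["S0", "S1"], ["S1", "S2"])
        with pytest.raises(ValueError, match="non-empty"):
            differential_expression(m, [], ["S1"])

    def test_null_calibration(self, rng):
        """Same-distribution groups give ~5% of genes with p < 0.05 over 10 seeds."""
        hits, total = 0, 0
        for seed in range(10):
            local = np.random.default_rng(seed)
            rows = {f"G{i}": local.lognormal(size=40).tolist() for i in range(120)}
            m = _matrix(rows)
            a = [f"S{i}" for i in range(20)]
            b = [f"S{i}" for i in range(20, 40)]
            de = differential_expression(m, a, b)
            hits += int((de.table["p"] < 0.05).sum())
            total += len(de.table)
        assert hits / total == pytest.approx(0.05, abs=0.01)


class TestRankPlot:
    def _de(self, lfcs: dict[str, float]) -> DEResult:
        genes = list(lfcs)
        return DEResult(pd.DataFrame({
            "gene": genes,
            "median_A": 1.0, "median_B": 1.0,
            "log2_fc": [lfcs[g] for g in genes],
            "p": 0.5, "q": 0.5,
        }))

    def test_highlight_all_genes_p_one(self):
        de = self._de({"G1": 1.0, "G2": 0.5})
        _, p = rank_plot_data(de, {"G1", "G2"})
        assert p == 1.0

    def test_single_top_gene_one_sided_p(self):
        """One in-set gene with the top fold-change among 10: one-sided p = 1/10."""
        de = self._de({f"G{i}": float(i) for i in range(10)})
        _, p = rank_plot_data(de, {"G9"}, alternative="greater")
        assert p == pytest.approx(0.1)

    def test_sort_stable_on_ties(self):
        de = self._de({"GB": 1.0, "GA": 1.0, "GC": 2.0})
        tab, _ = rank_plot_data(de, {"GC"})
        assert tab["gene"].tolist() == ["GC", "GA", "GB"]

    def test_empty_intersection_rejected(self):
        de = self._de({"G1": 1.0, "G2": 0.0})
        with pytest.raises(ValueError):
            rank_plot_data(de, {"ZZZ"})


class TestHypergeometricEnrichment:
    def test_single_extreme_outcome(self):
        universe = {f"G{i}" for i in range(20)}
        setA = {f"G{i}" for i in range(5)}
        sets = GeneSetCollection({"SETA": setA})
        out = enrichment_hypergeometric(setA, sets, universe)
        assert out["p"].iloc[0] == pytest.approx(1 / comb(20, 5), rel=1e-9)

    def test_set_equals_universe_p_one(self):
        universe = {f"G{i}" for i in range(10)}
        sets = GeneSetCollection({"ALL": set(universe)})
        out = enrichment_hypergeometric({"G0", "G1"}, sets, universe)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_zero_overlap_p_one(self):
        universe = {f"G{i}" for i in range(10)}
        sets = GeneSetCollection({"S": {"G8", "G9"}})
        out = enrichment_hypergeometric({"G0", "G1"}, sets, universe)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_selected_outside_universe_rejected(self):
        sets = GeneSetCollection({"S": {"G1"}})
        with pytest.raises(ValueError):
            enrichment_hypergeometric({"ZZ"}, sets, {"G1", "G2"})

    def test_matches_combinatorial_sum(self, rng):
        """Upper-tail p equals the explicit sum of hypergeometric terms for N <= 25."""
        for _ in range(25):
            n_uni = int(rng.integers(5, 26))
            universe = {f"G{i}" for i in range(n_uni)}
            big_k = int(rng.integers(1, n_uni + 1))
            n_sel = int(rng.integers(1, n_uni + 1))
            members = set(rng.choice(sorted(universe), size=big_k, replace=False))
            selected = set(rng.choice(sorted(universe), size=n_sel, replace=False))
            k = len(members & selected)
            out = enrichment_hypergeometric(selected, GeneSetCollection({"S": members}), universe)
            expected = sum(
                comb(big_k, j, exact=True) * comb(n_uni - big_k, n_sel - j, exact=True)
                for j in range(k, min(big_k, n_sel) + 1)
            ) / comb(n_uni, n_sel, exact=True)
            assert out["p"].iloc[0] == pytest.approx(expected, rel=1e-9)


class TestInductionAttenuation:
    def _de(self, lfcs: dict[str, float]) -> DEResult:
        return DEResult(pd.DataFrame({
            "gene": list(lfcs), "median_A": 1.0, "median_B": 1.0,
            "log2_fc": list(lfcs.values()), "p": 0.5, "q": 0.5,
        }))

    def test_identical_contrasts(self):
        de = self._de({"G1": 1.0, "G2": 2.0})
        table, med, p = induction_attenuation(de, de, ["G1", "G2"])
        assert (table["delta"] == 0).all() and med == 0 and p == 1.0

    def test_single_gene_delta(self):
        d1 = self._de({"G1": 2.0})
        d2 = self._de({"G1": 0.5})
        table, med, _ = induction_attenuation(d1, d2, ["G1"])
        assert table["delta"].iloc[0] == pytest.approx(1.5) and med == pytest.approx(1.5)

    def test_all_positive_deltas_binomial_p(self):
        genes = {f"G{i}": 1.0 for i in range(10)}
        d1 = self._de({g: v + 0.5 for g, v in genes.items()})
        d2 = self._de(genes)
        _, _, p = induction_attenuation(d1, d2, list(genes))
        assert p == pytest.approx(2 * 0.5**10)

    def test_missing_gene_rejected(self):
        d1 = self._de({"G1": 1.0})
        with pytest.raises(KeyError):
            induction_attenuation(d1, d1, ["G1", "G2"])
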