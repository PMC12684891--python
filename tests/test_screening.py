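"""Screening statistics: occurrence rates, association tests, rank comparisons,
sufficiency gate and PERMANOVA."""

import itertools

import numpy as np
import pytest
from scipy import stats
from scipy.spatial.distance import pdist

from plastrisk import (
    CauseOfDeath,
    NecropsyDataset,
    PlasticCategory,
    Taxon,
    association_test,
    data_sufficiency,
    frequency_of_occurrence,
    generate_dataset,
    load_group_comparison,
    mortality_given_ingestion,
    permanova_bray_curtis,
)
from plastrisk.simulate import Law, SimulationConfig, TrueParameters
from conftest import make_record

H, R = PlasticCategory.HARD, PlasticCategory.RUBBER


def fisher_2x2_exhaustive(table):
    """Independent oracle: enumerate the hypergeometric distribution over all
    tables with the observed margins; two-sided p sums probabilities <= observed."""
    a, b = table[0]
    c, d = table[1]
    row1, col1, n = a + b, a + c, a + b + c + d
    probs = []
    p_obs = None
    for aa in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        pr = stats.hypergeom.pmf(aa, n, col1, row1)
        probs.append(pr)
        if aa == a:
            p_obs = pr
    return float(sum(pr for pr in probs if pr <= p_obs * (1 + 1e-7)))


class TestFrequencyOfOccurrence:
    def test_all_zero(self):
        ds = NecropsyDataset([make_record(f"z{i}") for i in range(4)])
        fo = frequency_of_occurrence(ds, Taxon.SEA_TURTLE)
        assert (fo == 0).all()

    def test_one_of_three(self):
        ds = NecropsyDataset(
            [make_record("a", loads={H: (2, 0.1)}), make_record("b"), make_record("c")]
        )
        fo = frequency_of_occurrence(ds, Taxon.SEA_TURTLE)
        assert fo["hard"] == pytest.approx(100 / 3)
        assert fo["TOTAL"] == pytest.approx(100 / 3)

    def test_total_bounds_categories(self, toy_dataset):
        fo = frequency_of_occurrence(toy_dataset, Taxon.SEA_TURTLE)
        assert (fo >= 0).all() and (fo <= 100).all()
        assert fo["TOTAL"] >= fo.drop("TOTAL").max()

    def test_empty_taxon_errors(self, toy_dataset):
        with pytest.raises(ValueError, match="no records"):
            frequency_of_occurrence(toy_dataset, Taxon.MARINE_MAMMAL)


class TestMortalityGivenIngestion:
    def test_rates(self):
        records = [
            make_record(f"m{i}", loads={R: (1, 0.1)}) for i in range(8)
        ] + [
            make_record(f"k{i}", cause=CauseOfDeath.KD, attributed=[R], loads={R: (5, 1.0)})
            for i in range(2)
        ]
        table = mortality_given_ingestion(NecropsyDataset(records), Taxon.SEA_TURTLE)
        assert table.loc["rubber", "kd_pct"] == pytest.approx(20.0)
        assert table.loc["rubber", "pd_pct"] == pytest.approx(0.0)

    def test_never_ingested_absent(self, toy_dataset):
        table = mortality_given_ingestion(toy_dataset, Taxon.SEA_TURTLE)
        assert "foam" not in table.index
        assert "TOTAL" in table.index


class TestAssociationTest:
    def test_fisher_matches_exhaustive_enumeration(self):
        table = [[8, 2], [1, 5]]
        name, _, p = association_test(table)
        assert name == "fisher"
        assert p == pytest.approx(0.03497, abs=5e-5)
        assert p == pytest.approx(fisher_2x2_exhaustive(table), rel=1e-9)

    def test_fisher_equals_oracle_on_all_small_tables(self):
        rng = np.random.default_rng(0)
        tables = [
            t for t in itertools.product(range(7), repeat=4) if 0 < sum(t) <= 16
        ]
        tables = [tables[i] for i in rng.choice(len(tables), 300, replace=False)]
        for a, b, c, d in tables:
            t = [[a, b], [c, d]]
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            name, _, p = association_test(t, {"force": "fisher"})
            assert p == pytest.approx(fisher_2x2_exhaustive(t), rel=1e-9), t

    def test_balanced_table_chi2_zero(self):
        name, stat, p = association_test([[50, 50], [50, 50]])
        assert name == "chi2" and stat == 0.0 and p == pytest.approx(1.0)

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError, match="zero margin"):
            association_test([[3, 0], [5, 0]])

    def test_rule_switches_on_expected_cells(self):
        # large balanced counts -> chi2; tiny counts -> fisher
        assert association_test([[40, 10], [12, 38]])[0] == "chi2"
        assert association_test([[3, 1], [1, 4]])[0] == "fisher"


class TestLoadGroupComparison:
    def test_separated_groups(self):
        h, p, dunn = load_group_comparison({"KND": [1, 2, 3], "KD": [10, 11, 12]})
        assert p < 0.05
        row = dunn.iloc[0]
        # KD rank mean above KND: z sign tells the direction
        z = row.z if row.group_a == "KD" else -row.z
        assert z > 0

    def test_identical_values_convention(self):
        h, p, _ = load_group_comparison({"a": [5, 5, 5], "b": [5, 5, 5]})
        assert h == 0.0 and p == 1.0

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(3)
        groups = {g: rng.normal(i, 1, 10) for i, g in enumerate("abcd")}
        for method in ("holm", "bonferroni"):
            _, _, dunn = load_group_comparison(groups, p_adjust=method)
            assert (dunn.p_adjusted >= dunn.p_raw - 1e-12).all()

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two nonempty groups"):
            load_group_comparison({"a": [1, 2], "b": []})


class TestDataSufficiency:
    def test_too_few_deaths(self):
        records = [make_record(f"n{i}", loads={H: (1, 0.1)}) for i in range(20)]
        records += [
            make_record(f"k{i}", cause=CauseOfDeath.KD, attributed=[H], loads={H: (9, 2.0)})
            for i in range(4)
        ]
        verdict = data_sufficiency(NecropsyDataset(records), Taxon.SEA_TURTLE, H)
        assert not verdict.sufficient
        assert any("fewer than 5 deaths" in r for r in verdict.reasons)

    def test_strong_synthetic_effect_is_sufficient(self):
        ds = generate_dataset(SimulationConfig(n=600, seed=21))
        verdict = data_sufficiency(ds, Taxon.SEA_TURTLE, None)
        assert verdict.sufficient, verdict.reasons
        assert verdict.n_deaths >= 5 and verdict.dunn_p_kd_vs_knd < 0.05

    def test_null_loads_usually_insufficient(self):
        # KD loads drawn from the same law as KND loads: gate should fail
        rng = np.random.default_rng(5)
        records = [
            make_record(f"n{i}", loads={H: (int(c), 0.1 * c)} if c else None)
            for i, c in enumerate(rng.poisson(3, 60))
        ]
        records += [
            make_record(
                f"k{i}",
                cause=CauseOfDeath.KD,
                attributed=[H],
                loads={H: (max(1, int(c)), 0.1 * max(1, c))},
            )
            for i, c in enumerate(rng.poisson(3, 8))
        ]
        verdict = data_sufficiency(NecropsyDataset(records), Taxon.SEA_TURTLE, H)
        assert not verdict.sufficient

    def test_verdict_invariant(self):
        ds = generate_dataset(SimulationConfig(n=400, seed=9))
        v = data_sufficiency(ds, Taxon.SEA_TURTLE, None)
        if v.sufficient:
            assert v.n_deaths >= 5 and v.dunn_p_kd_vs_knd < 0.05 and v.ordered_medians


class TestPermanova:
    def _two_groups(self, seed=1, n=12):
        rng = np.random.default_rng(seed)
        X = np.vstack(
            [
                rng.dirichlet([4, 3, 2, 1], n) * rng.gamma(5, 1, (n, 1)),
                rng.dirichlet([1, 2, 3, 4], n) * rng.gamma(5, 1, (n, 1)),
            ]
        )
        return X, np.array(["a"] * n + ["b"] * n)

    def test_matches_scikit_bio(self):
        skbio = pytest.importorskip("skbio")
        from scipy.spatial.distance import squareform

        X, labels = self._two_groups()
        f_ours, p_ours = permanova_bray_curtis(X, labels, n_permutations=999, seed=0)
        dm = skbio.stats.distance.DistanceMatrix(squareform(pdist(X, "braycurtis")))
        res = skbio.stats.distance.permanova(dm, labels, permutations=999)
        assert f_ours == pytest.approx(res["test statistic"], rel=1e-10)
        assert abs(p_ours - res["p-value"]) < 0.05  # both permutation p's of the same F

    def test_disjoint_rows_have_dissimilarity_one(self):
        d = pdist(np.array([[1.0, 0.0], [0.0, 1.0]]), "braycurtis")
        assert d[0] == pytest.approx(1.0)

    def test_exhaustive_enumeration_matches(self):
        rng = np.random.default_rng(2)
        X = np.abs(rng.normal(1, 0.5, (6, 3)))
        labels = np.array([0, 0, 0, 1, 1, 1])
        _, p_all = permanova_bray_curtis(X, labels, n_permutations="all")
        _, p_mc = permanova_bray_curtis(X, labels, n_permutations=100000, seed=3)
        assert p_mc == pytest.approx(p_all, abs=0.01)

    def test_row_order_invariance(self):
        X, labels = self._two_groups(seed=4)
        f1, p1 = permanova_bray_curtis(X, labels, n_permutations=499, seed=7)
        order = np.random.default_rng(8).permutation(len(labels))
        f2, p2 = permanova_bray_curtis(X[order], labels[order], n_permutations=499, seed=7)
        assert f1 == pytest.approx(f2, rel=1e-10)
        assert abs(p1 - p2) < 0.05

    def test_label_name_invariance(self):
        X, labels = self._two_groups(seed=6)
        renamed = np.where(labels == "a", "group_one", "group_two")
        f1, _ = permanova_bray_curtis(X, labels, n_permutations=99, seed=1)
        f2, _ = permanova_bray_curtis(X, renamed, n_permutations=99, seed=1)
        assert f1 == pytest.approx(f2, rel=1e-12)

    def test_degenerate_inputs_rejected(self):
        X = np.ones((4, 3))
        with pytest.raises(ValueError, match="at least two individuals"):
            permanova_bray_curtis(X, ["a", "a", "a", "b"])
        X[0] = 0.0
        with pytest.raises(ValueError, match="all-zero"):
            permanova_bray_curtis(X, ["a", "a", "b", "b"])
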