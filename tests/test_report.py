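"""Phenotype/abundance tables, group statistics, sample UMAP, ROC."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm
from sklearn.metrics import roc_auc_score

from cytopipe import (
    Dataset,
    abundance_table,
    group_compare,
    phenotype_table,
    roc_analysis,
    sample_umap,
)
from cytopipe.errors import InfeasibilityError, ParameterError

from conftest import make_sample


def labeled_sample(rng, sample_id, group, cluster_sizes, centers):
    """One sample whose events sit at fixed per-cluster intensities."""
    events, labels = [], []
    for cid, n in cluster_sizes.items():
        events.append(np.full((n, len(centers[cid])), centers[cid]))
        labels.extend([cid] * n)
    s = make_sample(np.vstack(events), sample_id, group,
                    labels=[f"M{i+1}" for i in range(len(next(iter(centers.values()))))])
    s.set_tag("cluster", np.array(labels))
    return s


def test_phenotype_table_medians(rng):
    s = labeled_sample(rng, "S1", "g", {1: 3, 2: 2},
                       {1: (0.9, 0.1), 2: (0.2, 0.8)})
    # give cluster 1 an odd spread on M1: {0.1, 0.5, 0.9} -> median 0.5
    s.events[:3, 0] = [0.1, 0.5, 0.9]
    ds = Dataset([s], {"S1": "g"})
    tbl = phenotype_table(ds, ["M1", "M2"])
    assert list(tbl.index) == [1, 2]
    assert tbl.loc[1, "M1"] == pytest.approx(0.5)
    assert tbl.loc[2, "M2"] == pytest.approx(0.8)


def test_abundance_table_rows_sum_100(rng):
    s1 = labeled_sample(rng, "S1", "g1", {1: 25, 2: 75}, {1: (0.9,), 2: (0.1,)})
    s2 = labeled_sample(rng, "S2", "g2", {1: 100}, {1: (0.9,), 2: (0.1,)})
    ds = Dataset([s1, s2], {"S1": "g1", "S2": "g2"})
    tbl = abundance_table(ds)
    assert tbl.loc["S1", 1] == pytest.approx(25.0)
    assert tbl.loc["S2", 2] == 0.0  # zero-filled for absent cluster
    sums = tbl.drop(columns="group").sum(axis=1)
    np.testing.assert_allclose(sums, 100.0, atol=1e-6)
    assert list(tbl["group"]) == ["g1", "g2"]


def test_abundance_table_excludes_unclustered_sample(rng):
    s1 = labeled_sample(rng, "S1", "g", {1: 10}, {1: (0.5,)})
    s2 = make_sample(rng.normal(size=(10, 1)), "S2", "g", labels=["M1"])
    s2.set_tag("cluster", np.zeros(10, dtype=int))
    ds = Dataset([s1, s2], {"S1": "g", "S2": "g"})
    with pytest.warns(UserWarning, match="S2"):
        tbl = abundance_table(ds)
    assert list(tbl.index) == ["S1"]


def abundances_for_groups(rng, n_per_group, offset=40.0):
    rows, groups = {}, {}
    for g, base in (("disease", offset), ("control", 10.0)):
        for i in range(n_per_group):
            sid = f"{g}_{i}"
            a = max(min(base + rng.normal(0, 2), 95.0), 1.0)
            rest = 100.0 - a
            rows[sid] = [a, rest * 0.6, rest * 0.4]
            groups[sid] = g
    df = pd.DataFrame.from_dict(rows, orient="index", columns=[1, 2, 3])
    df.index.name = "sample_id"
    df["group"] = [groups[sid] for sid in df.index]
    return df


class TestGroupCompare:
    def test_identical_groups_null(self, rng):
        vals = rng.uniform(10, 30, 5)
        rows = {f"A{i}": vals for i in range(4)}
        rows.update({f"B{i}": vals for i in range(4)})
        df = pd.DataFrame.from_dict(rows, orient="index",
                                    columns=[1, 2, 3, 4, 5])
        df["group"] = ["A"] * 4 + ["B"] * 4
        out = group_compare(df)
        np.testing.assert_allclose(out["p_adjusted"], 1.0, atol=1e-9)

    def test_designed_difference_detected(self, rng):
        df = abundances_for_groups(rng, 10)
        out = group_compare(df).set_index("cluster")
        assert out.loc[1, "p_adjusted"] < 0.01
        assert out.loc[1, "test"] == "wilcoxon_rank_sum"
        assert out.loc[1, "median_disease"] > out.loc[1, "median_control"]

    def test_three_groups_kruskal(self, rng):
        rows = {f"S{i}": rng.uniform(0, 100, 2) for i in range(9)}
        df = pd.DataFrame.from_dict(rows, orient="index", columns=[1, 2])
        df["group"] = ["A", "A", "A", "B", "B", "B", "C", "C", "C"]
        out = group_compare(df)
        assert set(out["test"]) == {"kruskal_wallis"}

    def test_degenerate_groups_rejected(self, rng):
        df = abundances_for_groups(rng, 1)
        with pytest.raises(ParameterError):
            group_compare(df)


class TestSampleUmap:
    def test_groups_separate(self, rng):
        df = abundances_for_groups(rng, 8, offset=80.0)
        out = sample_umap(df, seed=0, n_neighbors=4)
        from sklearn.metrics import silhouette_score

        coords = out[["UMAP1", "UMAP2"]].to_numpy()
        assert silhouette_score(coords, out["group"]) > 0.5
        assert list(out.index) == list(df.index)

    def test_outlier_flagged(self, rng):
        df = abundances_for_groups(rng, 6)
        df.loc[df.index[0], [1, 2, 3]] = [0.5, 0.5, 99.0]  # far from everyone
        out = sample_umap(df, seed=0, n_neighbors=3)
        assert bool(out["outlier"].iloc[0])
        assert not out["outlier"].all()  # flagging, not wholesale rejection

    def test_metadata_joined(self, rng):
        df = abundances_for_groups(rng, 4)
        meta = pd.DataFrame({"sample_id": df.index, "age": range(len(df))})
        out = sample_umap(df, metadata=meta, seed=0, n_neighbors=3)
        assert "age" in out.columns

    def test_too_few_samples(self, rng):
        df = abundances_for_groups(rng, 2)[:3]
        with pytest.raises(InfeasibilityError):
            sample_umap(df, n_neighbors=15)


class TestRoc:
    def test_perfect_separation(self):
        values = {f"P{i}": 10.0 + i for i in range(5)}
        values.update({f"N{i}": float(i) for i in range(5)})
        groups = {k: ("pos" if k.startswith("P") else "neg") for k in values}
        res = roc_analysis(values, groups, "pos")
        assert res.auc == 1.0
        # Youden cutoff separates the classes
        assert 4.0 < res.youden_cutoff <= 10.0

    def test_null_auc_near_half(self, rng):
        x = rng.normal(size=2000)
        groups = {f"S{i}": ("a" if i % 2 else "b") for i in range(2000)}
        values = {f"S{i}": x[i] for i in range(2000)}
        res = roc_analysis(values, groups, "a")
        assert abs(res.auc - 0.5) < 0.03

    def test_binormal_closed_form(self, rng):
        n = 2000
        values = {f"P{i}": v for i, v in enumerate(rng.normal(2, 1, n))}
        values.update({f"N{i}": v for i, v in enumerate(rng.normal(0, 1, n))})
        groups = {k: ("pos" if k.startswith("P") else "neg") for k in values}
        res = roc_analysis(values, groups, "pos")
        assert res.auc == pytest.approx(norm.cdf(np.sqrt(2)), abs=0.02)

    def test_trapezoid_equals_rank_auc_and_sklearn(self, rng):
        x = rng.normal(size=200)
        y = rng.integers(0, 2, 200)
        y[0], y[1] = 0, 1  # both classes present
        values = {f"S{i}": x[i] for i in range(200)}
        groups = {f"S{i}": ("pos" if y[i] else "neg") for i in range(200)}
        res = roc_analysis(values, groups, "pos")
        # trapezoidal area under the empirical curve (tie-free data);
        # cutoffs ascend, so reverse to walk the curve from (0,0) to (1,1)
        fpr = np.concatenate([[0.0], (1 - res.specificity)[::-1], [1.0]])
        tpr = np.concatenate([[0.0], res.sensitivity[::-1], [1.0]])
        trap = np.trapezoid(tpr, fpr)
        assert abs(trap - res.auc) < 1e-12
        assert res.auc == pytest.approx(roc_auc_score(y, x), abs=1e-12)

    def test_sensitivity_specificity_monotone(self, rng):
        x = rng.normal(size=100)
        values = {f"S{i}": x[i] for i in range(100)}
        groups = {f"S{i}": ("pos" if i % 3 else "neg") for i in range(100)}
        res = roc_analysis(values, groups, "pos")
        assert np.all(np.diff(res.sensitivity) <= 0)  # cutoffs ascending
        assert np.all(np.diff(res.specificity) >= 0)
        assert np.all((res.sensitivity >= 0) & (res.sensitivity <= 1))

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            roc_analysis({"A": 1.0, "B": 2.0}, {"A": "g", "B": "g"}, "g")


def test_permuted_labels_give_uniform_pvalues(rng):
    # under the null, rank-sum p-values for one cluster across label
    # permutations are uniform (KS test)
    from scipy.stats import kstest

    df = abundances_for_groups(rng, 10)
    labels = df["group"].to_numpy().copy()
    ps = []
    for _ in range(300):
        df["group"] = rng.permutation(labels)
        ps.append(group_compare(df).set_index("cluster").loc[1, "p"])
    df["group"] = labels
    assert kstest(ps, "uniform").pvalue > 0.01
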