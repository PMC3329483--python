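import math
import random

import numpy as np
import pandas as pd
import pytest

from dupmod.featscan import (
    EmpiricalDistribution,
    clustering_score,
    enumerate_subsets,
    feature_ccdf,
    feature_correlation_report,
    score_dendrogram,
    subset_scan,
)
from dupmod.measures import FeatureVector
from dupmod.netclust import DistanceMatrix, mcquitty_cluster


def fv(name, label, **values):
    base = dict(m=3, q=0.5, s_rel=0.4, h_conn=0.8, h_mod=0.5, nmi=0.3)
    base.update(values)
    return FeatureVector(name=name, class_label=label, **base)


class TestClusteringScore:
    def test_perfect_separation_scores_zero(self):
        assignment = {"p1": 1, "p2": 1, "d1": 2, "n1": 2}
        classes = {"p1": "PPI", "p2": "PPI", "d1": "DMC", "n1": "NGD"}
        raw, norm = clustering_score(assignment, classes)
        assert raw == 0 and norm == 0.0

    def test_mixed_cluster_product(self):
        assignment = {f"x{i}": 1 for i in range(5)}
        classes = {"x0": "PPI", "x1": "PPI", "x2": "PPI", "x3": "DMC", "x4": "DMC"}
        raw, norm = clustering_score(assignment, classes)
        assert raw == 6
        assert norm == 1.0  # everything in one cluster is the worst case

    def test_worked_two_cluster_example(self):
        assignment = {"p1": 1, "p2": 1, "n1": 1, "p3": 2, "d1": 2}
        classes = {"p1": "PPI", "p2": "PPI", "p3": "PPI", "n1": "NGD", "d1": "DMC"}
        raw, norm = clustering_score(assignment, classes)
        assert raw == 3
        assert norm == pytest.approx(0.5)

    def test_bystanders_do_not_count(self):
        assignment = {"p": 1, "s": 1, "o": 1, "d": 2}
        classes = {"p": "PPI", "s": "SCN", "o": "OTHER", "d": "DMC"}
        raw, norm = clustering_score(assignment, classes)
        assert raw == 0 and norm == 0.0

    def test_missing_group_gives_nan_normalizer(self):
        assignment = {"a": 1, "b": 1}
        classes = {"a": "PPI", "b": "PPI"}
        raw, norm = clustering_score(assignment, classes)
        assert raw == 0 and math.isnan(norm)

    def test_invariant_under_cluster_relabeling(self):
        rng = random.Random(1)
        labels = [f"v{i}" for i in range(12)]
        classes = {l: rng.choice(["PPI", "NGD", "DMC", "SCN"]) for l in labels}
        assignment = {l: rng.randrange(4) for l in labels}
        relabel = {c: 10 - c for c in set(assignment.values())}
        shuffled = {l: relabel[c] for l, c in assignment.items()}
        assert clustering_score(assignment, classes) == clustering_score(shuffled, classes)

    def test_stand_in_groups(self):
        assignment = {"n": 1, "d": 1}
        classes = {"n": "NGD", "d": "DMC"}
        raw, norm = clustering_score(assignment, classes, group_a={"NGD"}, group_b={"DMC"})
        assert raw == 1 and norm == 1.0


class TestEnumerateSubsets:
    def test_zero_elimination(self):
        assert enumerate_subsets(("a", "b", "c"), 0) == [("a", "b", "c")]

    def test_binomial_sum_three(self):
        subsets = enumerate_subsets(("a", "b", "c"), 2)
        assert len(subsets) == 7
        assert subsets[0] == ("a", "b", "c")
        assert all(len(s) >= 1 for s in subsets)

    def test_binomial_sum_eight_features_eliminate_five(self):
        names = tuple(f"f{i}" for i in range(8))
        subsets = enumerate_subsets(names, 5)
        assert len(subsets) == sum(math.comb(8, k) for k in range(6)) == 219
        assert len(set(subsets)) == 219  # no duplicates

    def test_invalid_depth(self):
        with pytest.raises(ValueError):
            enumerate_subsets(("a", "b"), 2)


class TestSubsetScan:
    def separated_cohort(self):
        # the two classes differ in every component, so any projection separates
        fvs = []
        rng = random.Random(0)
        for i in range(5):
            jitter = 0.01 * rng.random()
            fvs.append(fv(f"ppi{i}", "PPI", m=12, q=0.8 + jitter, s_rel=0.1,
                          h_conn=0.9, h_mod=0.7, nmi=0.1 + jitter))
            jitter = 0.01 * rng.random()
            fvs.append(fv(f"dmc{i}", "DMC", m=3, q=0.2 + jitter, s_rel=0.6,
                          h_conn=0.3, h_mod=0.2, nmi=0.9 - jitter))
        return fvs

    def test_perfectly_separated_classes_score_zero_everywhere(self):
        table = subset_scan(self.separated_cohort(), k_cut=2, max_eliminate=2)
        assert (table["normalized"] == 0.0).all()

    def test_table_size_matches_enumeration(self):
        table = subset_scan(self.separated_cohort(), k_cut=2, max_eliminate=3)
        assert len(table) == sum(math.comb(6, k) for k in range(4))

    def test_requires_both_groups(self):
        fvs = [fv("a", "PPI"), fv("b", "SCN")]
        with pytest.raises(ValueError):
            subset_scan(fvs, k_cut=2, max_eliminate=1)

    def test_informative_feature_beats_noise(self):
        # one separating component among noise: using all features still
        # separates at least as well as the scan's worst noise-only subsets
        better = 0
        for trial in range(20):
            rng = random.Random(trial)
            fvs = []
            for i in range(4):
                fvs.append(fv(f"p{i}", "PPI", q=0.9 + 0.01 * rng.random(),
                              m=rng.randrange(2, 9), s_rel=rng.random(),
                              h_conn=rng.random(), h_mod=rng.random(), nmi=rng.random()))
                fvs.append(fv(f"d{i}", "DMC", q=0.1 + 0.01 * rng.random(),
                              m=rng.randrange(2, 9), s_rel=rng.random(),
                              h_conn=rng.random(), h_mod=rng.random(), nmi=rng.random()))
            table = subset_scan(fvs, k_cut=2, max_eliminate=1)
            full = table.loc[table["size"] == 6, "normalized"].iloc[0]
            dropped_noise = table.loc[
                (table["size"] == 5) & table["subset"].str.contains("q"), "normalized"
            ]
            better += (full <= dropped_noise.max())
        assert better >= 18


class TestMonochromeSubtrees:
    def test_pure_cherries_score_zero(self):
        d = np.array(
            [
                [0.0, 1.0, 8.0, 8.5],
                [1.0, 0.0, 8.2, 8.7],
                [8.0, 8.2, 0.0, 1.1],
                [8.5, 8.7, 1.1, 0.0],
            ]
        )
        dend = mcquitty_cluster(DistanceMatrix(labels=("p1", "p2", "d1", "d2"), d=d))
        classes = {"p1": "PPI", "p2": "PPI", "d1": "DMC", "d2": "DMC"}
        score = score_dendrogram(dend, classes, k_cut=2, monochrome_subtrees=True)
        assert score.raw == 0


class TestCcdf:
    def make_table(self):
        return pd.DataFrame(
            {
                "subset": ["a+b", "a+c", "b+c", "a", "b", "c"],
                "raw": [0, 1, 2, 0, 1, 2],
                "normalized": [0.0, 0.5, 1.0, 0.0, 0.5, 1.0],
                "size": [2, 2, 2, 1, 1, 1],
            }
        )

    def test_restricts_to_absent_subsets(self):
        dist = feature_ccdf(self.make_table(), "a")
        # rows without 'a': b+c, b, c with scores 1.0, 0.5, 1.0
        assert dist.cdf(0.5) == pytest.approx(1 / 3)
        assert dist.ccdf(0.5) == pytest.approx(2 / 3)

    def test_ccdf_above_max_is_zero(self):
        dist = feature_ccdf(self.make_table(), "a")
        assert dist.ccdf(1.0) == 0.0
        assert dist.ccdf(2.0) == 0.0

    def test_empirical_counts(self):
        dist = EmpiricalDistribution(scores=np.array([0.0, 1.0, 2.0]))
        assert dist.ccdf(0.0) == pytest.approx(2 / 3)

    def test_monotone_and_complementary(self):
        rng = np.random.default_rng(2)
        dist = EmpiricalDistribution(scores=np.sort(rng.uniform(0, 1, 40)))
        xs = np.linspace(-0.2, 1.2, 101)
        vals = [dist.ccdf(x) for x in xs]
        assert all(0.0 <= v <= 1.0 for v in vals)
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))
        assert all(dist.cdf(x) + dist.ccdf(x) == pytest.approx(1.0) for x in xs)

    def test_unknown_feature_rejected(self):
        with pytest.raises(KeyError):
            feature_ccdf(self.make_table(), "zz")

    def test_informative_features_dominate_noise(self):
        # cohort with two informative and six noise components: the CCDFs of
        # scores observed without an informative feature must dominate those
        # of the noise features
        rng = random.Random(7)
        fvs = []
        for i in range(5):
            extras = {f"x{j}": rng.random() for j in range(4)}
            fvs.append(FeatureVector(name=f"p{i}", class_label="PPI",
                                     m=rng.randrange(2, 9), q=0.9 + 0.005 * i,
                                     s_rel=rng.random(), h_conn=rng.random(),
                                     h_mod=rng.random(), nmi=0.85 + 0.005 * i,
                                     extras=extras))
            extras = {f"x{j}": rng.random() for j in range(4)}
            fvs.append(FeatureVector(name=f"d{i}", class_label="DMC",
                                     m=rng.randrange(2, 9), q=0.1 + 0.005 * i,
                                     s_rel=rng.random(), h_conn=rng.random(),
                                     h_mod=rng.random(), nmi=0.15 + 0.005 * i,
                                     extras=extras))
        table = subset_scan(fvs, k_cut=2, max_eliminate=3)
        names = fvs[0].feature_names
        grid = np.linspace(0, 1, 21)
        def curve(feat):
            dist = feature_ccdf(table, feat, feature_names=names)
            return np.array([dist.ccdf(x) for x in grid])
        informative = [curve("q"), curve("nmi")]
        noise = [curve(f"x{j}") for j in range(4)]
        for inf in informative:
            for noi in noise:
                assert (inf >= noi - 1e-9).all()
                assert inf.sum() > noi.sum()


class TestCorrelationReport:
    def test_duplicated_and_negated_features(self):
        rng = random.Random(0)
        fvs = []
        for i in range(30):
            q = rng.random()
            fvs.append(FeatureVector(name=f"n{i}", class_label="NGD", m=3, q=q,
                                     s_rel=q, h_conn=1 - q, h_mod=rng.random(),
                                     nmi=rng.random()))
        report = feature_correlation_report(fvs)
        corr = report["NGD"]
        assert corr.loc["q", "s_rel"] == pytest.approx(1.0)
        assert corr.loc["q", "h_conn"] == pytest.approx(-1.0)

    def test_independent_features_uncorrelated(self):
        rng = random.Random(1)
        fvs = [FeatureVector(name=f"n{i}", class_label="SCN", m=rng.randrange(2, 20),
                             q=rng.random(), s_rel=rng.random(), h_conn=rng.random(),
                             h_mod=rng.random(), nmi=rng.random())
               for i in range(200)]
        corr = feature_correlation_report(fvs)["SCN"]
        off_diag = corr.to_numpy()[~np.eye(len(corr), dtype=bool)]
        assert np.abs(off_diag).max() < 0.2  # ~3 sigma at n=200

    def test_zero_variance_feature_is_nan(self):
        fvs = [FeatureVector(name=f"n{i}", class_label="DMC", m=4, q=0.5,
                             s_rel=0.1 * i, h_conn=0.5, h_mod=0.5, nmi=0.5)
               for i in range(5)]
        corr = feature_correlation_report(fvs)["DMC"]
        assert math.isnan(corr.loc["q", "s_rel"])

    def test_small_classes_skipped_with_warning(self):
        fvs = [fv("a", "PPI"), fv("b", "PPI")]
        with pytest.warns(UserWarning):
            report = feature_correlation_report(fvs)
        assert report == {}
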