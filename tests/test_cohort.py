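import numpy as np
import pandas as pd
import pytest

from netvb import (
    CohortSpec,
    FitParams,
    backward_regression,
    choose_k_gap,
    cohort_to_frame,
    gen_cohort,
    kmeans_fingerprint,
    network_contrast,
    select_features,
)
from netvb.cohort import NETWORKS, SubjectRecord, encode_class, frame_to_cohort


def _flat_subject(sid, group, value=1.0, age=70.0, sex="F"):
    p = FitParams(G=value, J_NMDA=value, w_plus=value, J_i=value)
    return SubjectRecord(
        id=sid,
        group=group,
        phenotype=group,
        age=age,
        sex=sex,
        mmse=28.0,
        domain_scores={},
        params={n: p for n in NETWORKS},
    )


class TestNetworkContrast:
    def test_identical_values_give_zero_contrast(self):
        cohort = [_flat_subject(f"s{i}", "HC") for i in range(5)]
        res = network_contrast(cohort, "G", "DMN", covariates=(), n_boot=99, seed=0)
        assert res["HC"].mean_difference == pytest.approx(0.0)

    def test_recovers_injected_group_offset(self):
        rng = np.random.default_rng(0)
        cohort = []
        for g, offset in (("HC", 0.0), ("AD", 0.5)):
            for i in range(20):
                base = {n: 1.0 + rng.normal(0, 0.1) for n in NETWORKS}
                base["DMN"] += offset
                cohort.append(
                    SubjectRecord(
                        id=f"{g}{i}",
                        group=g,
                        phenotype=g,
                        age=float(rng.uniform(60, 80)),
                        sex="F" if i % 2 else "M",
                        mmse=28.0,
                        domain_scores={},
                        params={
                            n: FitParams(G=base[n], J_NMDA=0.15, w_plus=1.4, J_i=1.0)
                            for n in NETWORKS
                        },
                    )
                )
        res = network_contrast(cohort, "G", "DMN", n_boot=999, seed=1)
        # true contrast for AD: offset * 6/5... DMN gets +0.5, others' mean unchanged
        assert res["AD"].ci_low <= 0.5 + 0.0 <= res["AD"].ci_high + 0.1
        assert abs(res["HC"].mean_difference) < 0.15
        assert res["AD"].mean_difference > res["HC"].mean_difference + 0.2

    def test_bootstrap_ci_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        cohort = [
            _flat_subject(f"s{i}", "HC", value=float(1 + rng.random())) for i in range(8)
        ]
        r1 = network_contrast(cohort, "J_i", "AN", n_boot=200, seed=9)
        r2 = network_contrast(cohort, "J_i", "AN", n_boot=200, seed=9)
        assert r1["HC"] == r2["HC"]

    def test_small_group_rejected(self):
        cohort = [_flat_subject("a", "HC"), _flat_subject("b", "HC")]
        with pytest.raises(ValueError, match="fewer than 3"):
            network_contrast(cohort, "G", "DMN")

    def test_ci_brackets_mean(self):
        rng = np.random.default_rng(5)
        cohort = [
            _flat_subject(f"s{i}", "HC", value=float(1 + rng.random()))
            for i in range(10)
        ]
        r = network_contrast(cohort, "G", "LN", n_boot=500, seed=0)["HC"]
        assert r.ci_low <= r.mean_difference <= r.ci_high


class TestBackwardRegression:
    def test_perfect_fit_retains_predictor_with_unit_r2(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 3)), columns=["x1", "x2", "x3"])
        res = backward_regression(X["x1"].to_numpy(), X)
        assert "x1" in res.retained
        assert res.r2 == pytest.approx(1.0)

    def test_single_true_predictor_recovered(self):
        # the true predictor is always kept; the exact set {x1} occurs with
        # probability ~(1-alpha)^5 ~ 0.77, since each of the five noise
        # predictors is retained with probability ~alpha
        exact = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(
                rng.standard_normal((40, 6)), columns=[f"x{i}" for i in range(1, 7)]
            )
            y = 2.0 * X["x1"].to_numpy() + 0.5 * rng.standard_normal(40)
            res = backward_regression(y, X)
            assert "x1" in res.retained
            exact += res.retained == ("x1",)
        assert exact >= 60

    def test_pure_noise_mostly_empties_the_model(self):
        empty = 0
        for seed in range(60):
            rng = np.random.default_rng(1000 + seed)
            X = pd.DataFrame(
                rng.standard_normal((40, 6)), columns=[f"x{i}" for i in range(6)]
            )
            y = rng.standard_normal(40)
            empty += backward_regression(y, X).retained == ()
        assert empty > 30  # large majority under per-step alpha = 0.05

    def test_retained_set_invariant_to_column_order(self, rng):
        X = pd.DataFrame(rng.standard_normal((50, 4)), columns=list("dcba"))
        y = 1.5 * X["b"].to_numpy() + 0.3 * rng.standard_normal(50)
        r1 = backward_regression(y, X)
        r2 = backward_regression(y, X[list("abcd")])
        assert r1.retained == r2.retained

    def test_constant_predictor_rejected(self, rng):
        X = pd.DataFrame({"x1": rng.standard_normal(20), "x2": np.ones(20)})
        with pytest.raises(ValueError, match="constant"):
            backward_regression(rng.standard_normal(20), X)

    def test_rank_deficiency_reported(self, rng):
        a = rng.standard_normal(20)
        X = pd.DataFrame({"x1": a, "x2": 2 * a, "x3": rng.standard_normal(20)})
        with pytest.raises(ValueError, match="rank"):
            backward_regression(rng.standard_normal(20), X)


class TestSelectFeatures:
    @staticmethod
    def _informative_frame(rng, n=90, n_feat=6):
        y = np.repeat([0, 1, 2], n // 3)
        F = pd.DataFrame(
            rng.standard_normal((n, n_feat)),
            columns=[f"f{i}" for i in range(n_feat)],
        )
        for c in F.columns:
            F[c] += 1.2 * y
        labels = np.array(["HC", "AD", "FTD"])[y]
        return F, labels

    def test_six_informative_features_reduced_to_three(self, rng):
        F, labels = self._informative_frame(rng)
        sel = select_features(F, labels)
        assert len(sel) == 3

    def test_duplicate_feature_cannot_survive_with_its_copy(self, rng):
        F, labels = self._informative_frame(rng, n_feat=4)
        F["dup"] = F["f0"]
        sel = select_features(F, labels)
        assert not ({"f0", "dup"} <= set(sel))

    def test_low_class_correlation_feature_dropped(self, rng):
        F, labels = self._informative_frame(rng, n_feat=4)
        # residualize the noise feature against the class so its class
        # correlation is exactly zero (below the 0.1 cutoff)
        y = encode_class(labels)
        yc = y - y.mean()
        noise = rng.standard_normal(len(F))
        noise = noise - yc * (np.dot(noise, yc) / np.dot(yc, yc))
        F["noise"] = noise
        sel = select_features(F, labels)
        assert "noise" not in sel

    def test_invariant_to_affine_feature_rescaling(self, rng):
        F, labels = self._informative_frame(rng)
        sel1 = select_features(F, labels, seed=0)
        F2 = F.copy()
        F2["f1"] = F2["f1"] * 37.0 - 4.0
        sel2 = select_features(F2, labels, seed=0)
        assert sel1 == sel2

    def test_single_class_rejected(self, rng):
        F, _ = self._informative_frame(rng)
        with pytest.raises(ValueError, match="two diagnostic classes"):
            select_features(F, ["HC"] * len(F))

    def test_class_encoding_order(self):
        codes = encode_class(["FTD", "HC", "AD", "HC"])
        np.testing.assert_array_equal(codes, [2, 0, 1, 0])


class TestGapStatisticAndKMeans:
    def test_three_separated_clusters_detected(self):
        rng = np.random.default_rng(0)
        centers = np.array([[0, 0], [10, 0], [0, 10.0]])
        X = np.vstack([c + rng.standard_normal((20, 2)) for c in centers])
        k = choose_k_gap(pd.DataFrame(X), k_max=6, B=20, seed=0)
        assert k == 3

    def test_single_gaussian_yields_one_cluster(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((40, 2))
        k = choose_k_gap(pd.DataFrame(X), k_max=5, B=20, seed=0)
        assert k == 1

    def test_k_within_bounds_on_arbitrary_data(self, rng):
        X = rng.standard_normal((30, 3))
        k = choose_k_gap(pd.DataFrame(X), k_max=6, B=10, seed=0)
        assert 1 <= k <= 6

    def test_degenerate_data_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            choose_k_gap(pd.DataFrame(np.ones((20, 2))), k_max=3, B=5, seed=0)

    def test_kmeans_k1_returns_feature_mean(self, rng):
        F = pd.DataFrame(rng.standard_normal((10, 2)), columns=["a", "b"])
        model = kmeans_fingerprint(F, k=1, seed=0)
        assert set(model.labels.values()) == {0}
        np.testing.assert_allclose(model.centroids[0], F.mean().to_numpy(), atol=1e-8)

    def test_kmeans_recovers_planted_partition(self):
        rng = np.random.default_rng(2)
        centers = np.array([[0, 0], [8, 0], [0, 8.0]])
        X = np.vstack([c + 0.5 * rng.standard_normal((15, 2)) for c in centers])
        F = pd.DataFrame(X, columns=["a", "b"], index=[f"s{i}" for i in range(45)])
        model = kmeans_fingerprint(F, k=3, seed=0)
        labels = np.array([model.labels[f"s{i}"] for i in range(45)])
        truth = np.repeat([0, 1, 2], 15)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, labels) == 1.0

    def test_kmeans_deterministic_given_seed(self, rng):
        F = pd.DataFrame(rng.standard_normal((20, 3)))
        m1 = kmeans_fingerprint(F, k=2, seed=5)
        m2 = kmeans_fingerprint(F, k=2, seed=5)
        assert m1.labels == m2.labels

    def test_k_exceeding_cohort_rejected(self, rng):
        F = pd.DataFrame(rng.standard_normal((4, 2)))
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_fingerprint(F, k=5, seed=0)


class TestCohortFrameRoundTrip:
    def test_frame_round_trip(self):
        cohort, _ = gen_cohort(CohortSpec(n_per_group={"HC": 4, "AD": 4}, seed=0))
        df = cohort_to_frame(cohort)
        back = frame_to_cohort(df)
        assert [s.id for s in back] == [s.id for s in cohort]
        assert back[0].params["DMN"] == cohort[0].params["DMN"]
        assert back[2].domain_scores == cohort[2].domain_scores
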