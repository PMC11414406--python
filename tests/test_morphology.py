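from itertools import chain, combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pleiokit.morphology import (
    PROFILES,
    OBS_COLUMNS,
    TraitClusterAssignment,
    TraitStudy,
    affinity_propagation,
    detect_altered_traits,
    quantile_normalize,
    replicate_reproducibility,
    trait_pleiotropy_value,
)


class TestQuantileNormalize:
    def test_hand_computed_two_column_example(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(df)
        assert np.allclose(out["a"], [2.5, 3.5, 4.5])
        assert np.allclose(out["b"], [2.5, 3.5, 4.5])

    def test_identical_distributions_are_a_fixed_point(self):
        df = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [1.0, 2.0, 3.0]})
        out = quantile_normalize(df)
        pd.testing.assert_frame_equal(out, df)

    @given(st.integers(0, 10**6))
    def test_columns_share_sorted_values_afterwards(self, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.normal(0, 1, (15, 4)))
        out = quantile_normalize(df)
        ref = np.sort(out.iloc[:, 0].to_numpy())
        for c in out.columns[1:]:
            assert np.allclose(np.sort(out[c].to_numpy()), ref)

    def test_rank_order_preserved_per_column(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(0, 1, (20, 3)))
        out = quantile_normalize(df)
        for c in df.columns:
            assert (df[c].rank() == out[c].rank()).all()

    def test_constant_column_maps_to_median_reference(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        out = quantile_normalize(df)
        assert np.allclose(out["b"], out["b"].iloc[0])
        assert out["b"].iloc[0] == pytest.approx(np.median(out["a"]))


def _ap_bruteforce(S, preference):
    """Exhaustive best-exemplar-set search maximizing the net similarity."""
    n = S.shape[0]
    Sp = S.copy()
    np.fill_diagonal(Sp, preference)
    best_score, best_labels = -np.inf, None
    for size in range(1, n + 1):
        for exemplars in combinations(range(n), size):
            labels = [max(exemplars, key=lambda e: Sp[i, e]) if i not in exemplars else i
                      for i in range(n)]
            score = sum(Sp[i, labels[i]] for i in range(n) if i not in exemplars)
            score += sum(Sp[e, e] for e in exemplars)
            if score > best_score:
                best_score, best_labels = score, labels
    return best_labels


class TestAffinityPropagation:
    def test_single_point_is_its_own_exemplar(self):
        points = pd.DataFrame([[1.0, 2.0]], index=["t1"])
        res = affinity_propagation(points)
        assert res.cluster_count == 1 and res.exemplars[0] == "t1"

    def test_two_tight_triplets_match_bruteforce_partition(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.05, (3, 2))
        b = rng.normal(5, 0.05, (3, 2)) + [5, 0]
        points = pd.DataFrame(np.vstack([a, b]), index=[f"t{i}" for i in range(6)])
        res = affinity_propagation(points)
        X = points.to_numpy()
        S = -((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
        pref = np.median(S[~np.eye(6, dtype=bool)])
        brute = _ap_bruteforce(S, np.median(S))
        # compare partitions, not label values
        def partition(labels):
            return frozenset(
                frozenset(i for i, l in enumerate(labels) if l == lab)
                for lab in set(labels)
            )
        assert res.cluster_count == 2
        assert partition(res.labels.to_numpy()) == partition(brute)

    def test_duplicated_points_co_cluster(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, (4, 3))
        points = pd.DataFrame(
            np.vstack([base, base[0]]), index=["a", "b", "c", "d", "a_copy"]
        )
        res = affinity_propagation(points)
        assert res.labels["a"] == res.labels["a_copy"]


def _toy_trait_study(shift=0.0, n_traits=6, seed=0):
    rng = np.random.default_rng(seed)
    rows, meta = [], []
    for gt in ("WT", "TFX"):
        for bio in (1, 2, 3):
            for tech in (1, 2, 3):
                vals = 10.0 + rng.normal(0, 1, n_traits)
                if gt == "TFX":
                    vals[:2] += shift
                rows.append(vals)
                meta.append(
                    {
                        "background": "BY",
                        "genotype": gt,
                        "bio_rep": bio,
                        "tech_rep": tech,
                        "batch": f"b{bio}",
                    }
                )
    obs = pd.concat(
        [pd.DataFrame(meta), pd.DataFrame(rows, columns=[f"T{i}" for i in range(n_traits)])],
        axis=1,
    )
    return TraitStudy(observations=obs, trait_ids=[f"T{i}" for i in range(n_traits)])


class TestAlteredTraits:
    def test_identical_knockout_and_wildtype_not_altered(self):
        study = _toy_trait_study(shift=0.0, seed=1)
        obs = study.observations
        ko = obs[obs["genotype"] == "WT"].copy()
        ko["genotype"] = "TFX"
        null_study = TraitStudy(
            observations=pd.concat([obs[obs["genotype"] == "WT"], ko], ignore_index=True),
            trait_ids=study.trait_ids,
        )
        table = detect_altered_traits(null_study, "TFX", "BY", PROFILES["methods"])
        assert not table["is_altered"].any()
        assert (table["lrt_p"] > 0.9).all()

    def test_planted_five_sd_shift_is_detected(self):
        study = _toy_trait_study(shift=5.0, seed=2)
        table = detect_altered_traits(study, "TFX", "BY", PROFILES["methods"])
        assert table.loc["T0", "is_altered"] and table.loc["T1", "is_altered"]
        assert (table.loc[["T0", "T1"], "lrt_p"] < 0.01).all()

    def test_profile_must_be_passed_explicitly(self):
        study = _toy_trait_study(shift=5.0)
        with pytest.raises(TypeError):
            detect_altered_traits(study, "TFX", "BY")
        assert set(PROFILES) == {"methods", "results"}
        table = detect_altered_traits(study, "TFX", "BY", PROFILES["results"])
        assert (table["profile"] == "results").all()


class TestTraitPleiotropy:
    def test_cluster_dispersion_counts(self):
        # 46 altered traits spanning 16 clusters; 122 spanning 23
        t46 = [f"x{i}" for i in range(46)]
        t122 = [f"y{i}" for i in range(122)]
        labels = {t: 1 + i % 16 for i, t in enumerate(t46)}
        labels.update({t: 30 + i % 23 for i, t in enumerate(t122)})
        clusters = TraitClusterAssignment(labels=pd.Series(labels), exemplars={})
        assert trait_pleiotropy_value(t46, clusters) == 16
        assert trait_pleiotropy_value(t122, clusters) == 23
        assert trait_pleiotropy_value([], clusters) == 0

    def test_unknown_trait_raises(self):
        clusters = TraitClusterAssignment(labels=pd.Series({"t1": 1}), exemplars={})
        with pytest.raises(KeyError, match="ghost"):
            trait_pleiotropy_value(["ghost"], clusters)


class TestReplicateReproducibility:
    def test_duplicated_replicate_has_unit_correlation(self):
        study = _toy_trait_study(shift=3.0, n_traits=8, seed=3)
        obs = study.observations
        dup = obs[(obs["genotype"] == "TFX") & (obs["bio_rep"] == 1)].copy()
        dup["bio_rep"] = 2
        dup["batch"] = "b1"
        rest = obs[~((obs["genotype"] == "TFX") & (obs["bio_rep"] == 2))]
        study2 = TraitStudy(
            observations=pd.concat([rest, dup], ignore_index=True),
            trait_ids=study.trait_ids,
        )
        table = replicate_reproducibility(study2, "TFX", "BY", normalize=False)
        pair = table[(table["rep_a"] == 1) & (table["rep_b"] == 2)]
        assert pair["pearson_r"].iloc[0] == pytest.approx(1.0)

    def test_independent_noise_replicates_decorrelate(self):
        study = _toy_trait_study(shift=0.0, n_traits=184, seed=4)
        table = replicate_reproducibility(study, "TFX", "BY", normalize=False)
        assert (table["pearson_r"].abs() < 0.3).all()

    def test_matches_textbook_covariance_formula(self):
        study = _toy_trait_study(shift=2.0, n_traits=5, seed=5)
        table = replicate_reproducibility(study, "TFX", "BY", normalize=False)
        obs = study.observations
        def fc(bio):
            ko = obs[(obs["genotype"] == "TFX") & (obs["bio_rep"] == bio)]
            wt = obs[(obs["genotype"] == "WT") & (obs["batch"] == f"b{bio}")]
            return (ko[study.trait_ids].mean() / wt[study.trait_ids].mean()).to_numpy()
        a, b = fc(1), fc(2)
        expected = np.sum((a - a.mean()) * (b - b.mean())) / np.sqrt(
            np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2)
        )
        pair = table[(table["rep_a"] == 1) & (table["rep_b"] == 2)]
        assert pair["pearson_r"].iloc[0] == pytest.approx(expected, abs=1e-12)


def test_mixed_model_null_calibration():
    """Type-I rate of the LRT at nominal 0.05 under a pure-null simulation."""
    from pleiokit.synthetic_data import SimulationConfig, generate_morphology_study

    cfg = SimulationConfig(
        n_traits=1000, n_trait_clusters=50, n_tfs=1, trait_alteration_sd_units=0.0, seed=5
    )
    study, _ = generate_morphology_study(cfg)
    table = detect_altered_traits(study, "TF01", "BY", PROFILES["results"])
    rate = (table["lrt_p"] < 0.05).mean()
    assert 0.03 <= rate <= 0.07
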