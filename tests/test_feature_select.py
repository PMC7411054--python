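"""mRMR ranking, relevance, replicate AUC and the one-SD stopping rule,
each checked against independent brute-force oracles on small instances."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenoprofiler.feature_select import (
    EmptySelectionError,
    choose_k,
    compute_relevance,
    mrmr_rank,
    prefilter_wells,
    replicate_auc,
    select_signature,
)
from phenoprofiler.preprocess import descriptor_columns


def make_profiles(X, treatments, n_live=500, controls=None):
    df = pd.DataFrame(X, columns=[f"d{j}" for j in range(X.shape[1])])
    df.insert(0, "plate_id", "P1")
    df.insert(1, "batch_id", "B1")
    df.insert(2, "well", [f"W{i}" for i in range(len(df))])
    df.insert(3, "compound_id", [t.split("@")[0] for t in treatments])
    df.insert(4, "concentration_uM", [float(t.split("@")[1]) if "@" in t else 0.0 for t in treatments])
    df.insert(5, "treatment_id", treatments)
    df.insert(6, "is_control", [t.startswith("DMSO") for t in treatments])
    df.insert(7, "n_live", n_live)
    return df


class TestPrefilter:
    def _profiles(self, rng, n_ctrl=30, n_samp=20, shift=6.0, n_live=500):
        X = rng.normal(0, 1, (n_ctrl + n_samp, 5))
        X[n_ctrl:] += shift
        tids = ["DMSO@0"] * n_ctrl + [f"C{i}@1" for i in range(n_samp)]
        return make_profiles(X, tids, n_live=n_live)

    def test_well_at_control_mean_removed(self):
        rng = np.random.default_rng(0)
        prof = self._profiles(rng)
        ctrl_mean = prof[prof["is_control"]][descriptor_columns(prof)].mean()
        prof.loc[len(prof) - 1, descriptor_columns(prof)] = ctrl_mean.to_numpy()
        out = prefilter_wells(prof)
        assert prof.loc[len(prof) - 1, "well"] not in set(out["well"])

    def test_cell_count_boundary(self):
        rng = np.random.default_rng(1)
        prof = self._profiles(rng)
        n_live = np.full(len(prof), 500)
        n_live[-1] = 99  # removed
        n_live[-2] = 100  # retained
        prof["n_live"] = n_live
        out = prefilter_wells(prof)
        wells = set(out["well"])
        assert prof.iloc[-1]["well"] not in wells
        assert prof.iloc[-2]["well"] in wells

    def test_winsorization_clips_to_percentiles(self):
        rng = np.random.default_rng(2)
        prof = self._profiles(rng, n_samp=100)
        prof.loc[len(prof) - 1, "d0"] = 1e6  # one extreme outlier
        out = prefilter_wells(prof)
        vals_before = prof.set_index("well").loc[out["well"], "d0"].to_numpy()
        # brute-force 99th percentile (linear interpolation between order stats)
        v = np.sort(vals_before)
        h = 0.99 * (len(v) - 1)
        expected = v[int(h)] + (h - int(h)) * (v[int(h) + 1] - v[int(h)])
        assert out["d0"].max() == pytest.approx(expected)

    def test_all_wells_removed_raises(self):
        rng = np.random.default_rng(3)
        prof = self._profiles(rng, shift=0.0, n_live=50)  # every well under-counted
        with pytest.raises(EmptySelectionError):
            prefilter_wells(prof)


class TestRelevance:
    def test_constant_feature_zero(self):
        X = np.ones((8, 2))
        X[:, 1] = np.random.default_rng(0).normal(size=8)
        prof = make_profiles(X, [f"T{i // 2}@1" for i in range(8)])
        rel = compute_relevance(prof)
        assert rel["d0"] == 0.0

    def test_matches_anova_oracle(self):
        # 3 treatments x 2 wells; oracle = scipy one-way ANOVA per feature
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (6, 4)) + np.repeat(rng.normal(0, 2, (3, 4)), 2, axis=0)
        prof = make_profiles(X, [f"T{i // 2}@1" for i in range(6)])
        rel = compute_relevance(prof)
        F = np.array(
            [stats.f_oneway(*(X[2 * g : 2 * g + 2, j] for g in range(3))).statistic for j in range(4)]
        )
        np.testing.assert_allclose(rel.to_numpy(), F / F.max(), rtol=1e-10)

    def test_max_relevance_is_one(self, small_result):
        prof = small_result.profiles
        from phenoprofiler.feature_select import prefilter_wells

        pre = prefilter_wells(prof)
        rel = compute_relevance(pre)
        assert rel.max() == pytest.approx(1.0)
        assert (rel >= 0).all() and (rel <= 1).all()


def brute_force_mrmr(X, relevance):
    """Independent greedy oracle: python loops + scipy pearsonr."""
    n = X.shape[1]
    remaining = list(range(n))
    order = []
    while remaining:
        best, best_score = None, -np.inf
        for f in remaining:
            red = 0.0
            for g in order:
                if np.std(X[:, f]) == 0 or np.std(X[:, g]) == 0:
                    continue
                red = max(red, abs(stats.pearsonr(X[:, f], X[:, g])[0]))
            score = relevance[f] * (1.0 - red)
            if score > best_score + 1e-12:
                best, best_score = f, score
        order.append(best)
        remaining.remove(best)
    return order


class TestMrmr:
    def test_first_feature_is_most_relevant(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(12, 5))
        prof = make_profiles(X, [f"T{i // 2}@1" for i in range(12)])
        rel = compute_relevance(prof)
        ranking = mrmr_rank(prof, rel)
        assert ranking.features[0] == rel.idxmax()
        assert ranking.relevance[0] == pytest.approx(1.0)
        assert ranking.redundancy[0] == 0.0

    def test_exact_duplicate_scores_zero(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=(12, 3)) + np.repeat(rng.normal(0, 2, (6, 3)), 2, axis=0)
        X = np.column_stack([base, base[:, 0]])  # d3 duplicates d0
        prof = make_profiles(X, [f"T{i // 2}@1" for i in range(12)])
        ranking = mrmr_rank(prof, compute_relevance(prof))
        fr = ranking.to_frame().set_index("feature")
        dup = "d3" if fr.index.get_loc("d0") < fr.index.get_loc("d3") else "d0"
        assert fr.loc[dup, "redundancy"] == pytest.approx(1.0)
        assert fr.loc[dup, "score"] == pytest.approx(0.0)
        positive = fr[fr["score"] > 1e-9]
        assert fr.index.get_loc(dup) > max(fr.index.get_loc(f) for f in positive.index)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        group = np.repeat(rng.normal(0, 1.5, (8, 2)), 3, axis=0)
        informative = group + rng.normal(0, 0.5, (24, 2))
        duplicate = informative[:, [0]] * 1.01 + rng.normal(0, 0.05, (24, 1))
        noise = rng.normal(size=(24, 2))
        X = np.column_stack([informative, duplicate, noise])
        prof = make_profiles(X, [f"T{i // 3}@1" for i in range(24)])
        rel = compute_relevance(prof)
        ranking = mrmr_rank(prof, rel)
        oracle = brute_force_mrmr(X, rel.to_numpy())
        assert ranking.features == [f"d{j}" for j in oracle]

    def test_redundancy_recorded_at_selection_is_nondecreasing_score_consistent(self, small_result):
        prof = prefilter_wells(small_result.profiles)
        rel = compute_relevance(prof)
        ranking = mrmr_rank(prof, rel)
        np.testing.assert_allclose(
            ranking.score, ranking.relevance * (1.0 - ranking.redundancy), atol=1e-12
        )


class TestReplicateAuc:
    def _profiles(self, rng, n_treat=5, n_rep=4, n_feat=6, spread=2.0):
        centers = rng.normal(0, spread, (n_treat, n_feat))
        X = np.repeat(centers, n_rep, axis=0) + rng.normal(0, 0.3, (n_treat * n_rep, n_feat))
        tids = [f"T{i}@1" for i in range(n_treat) for _ in range(n_rep)]
        return make_profiles(X, tids)

    def test_perfect_separation(self):
        rng = np.random.default_rng(0)
        prof = self._profiles(rng, spread=50.0)
        mean, sd = replicate_auc(prof, descriptor_columns(prof), seed=0)
        assert mean == 1.0

    def test_no_structure_gives_half(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 8))
        prof = make_profiles(X, [f"T{i % 10}@1" for i in range(40)])
        mean, _ = replicate_auc(prof, descriptor_columns(prof), seed=1)
        assert abs(mean - 0.5) < 0.12

    def test_matches_all_pairs_mann_whitney(self):
        """On <= 20 wells all pairs are enumerated: the AUC must equal the
        exhaustive Mann-Whitney U statistic over replicate vs non-replicate
        pair correlations."""
        rng = np.random.default_rng(2)
        prof = self._profiles(rng, n_treat=5, n_rep=4)
        desc = descriptor_columns(prof)
        mean, sd = replicate_auc(prof, desc, max_pairs=10_000, seed=3)
        assert sd == 0.0  # full enumeration -> no sampling variability

        X = prof[desc].to_numpy()
        tids = prof["treatment_id"].to_numpy()
        rep, non = [], []
        for i, j in itertools.combinations(range(len(X)), 2):
            r = stats.pearsonr(X[i], X[j])[0]
            (rep if tids[i] == tids[j] else non).append(r)
        u = stats.mannwhitneyu(rep, non, alternative="two-sided").statistic
        assert mean == pytest.approx(u / (len(rep) * len(non)))

    def test_single_well_treatments_raise(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(5, 4))
        prof = make_profiles(X, [f"T{i}@1" for i in range(5)])
        with pytest.raises(ValueError):
            replicate_auc(prof, descriptor_columns(prof))


class TestChooseK:
    def test_one_sd_rule_example(self):
        # max mean 0.91 at k=20 with SD 0.02 -> threshold 0.89 -> k=10
        assert choose_k([5, 10, 20], [0.80, 0.90, 0.91], [0.01, 0.02, 0.02]) == 10

    def test_constant_curve_takes_minimum(self):
        assert choose_k([1, 5, 10], [0.9, 0.9, 0.9], [0.0, 0.0, 0.0]) == 1

    def test_nan_sizes_never_chosen(self):
        assert choose_k([1, 2, 4], [np.nan, 0.85, 0.86], [0.0, 0.05, 0.01]) == 2


class TestSelectSignature:
    def test_signature_is_ranking_prefix_and_k_recorded(self, small_result):
        sig = small_result.signature
        prof = prefilter_wells(small_result.profiles)
        ranking = mrmr_rank(prof, compute_relevance(prof))
        assert sig.features == ranking.features[: sig.k]
        assert 1 <= sig.k <= len(ranking.features)

    def test_k_small_relative_to_descriptor_count(self, small_result):
        n_desc = len(descriptor_columns(small_result.profiles))
        assert small_result.signature.k < n_desc / 2

    def test_planted_structure_recovered(self, small_result):
        """Selected features should be dominated by informative raw features
        and avoid picking several members of one redundant block."""
        roles = small_result.truth.feature_roles.set_index("feature")

        def raw(desc):
            return desc.rsplit("_", 1)[0] if desc.endswith(("mean", "median")) else None

        sel = [raw(f) for f in small_result.signature.features if raw(f) is not None]
        informative = [f for f in sel if roles.loc[f, "role"] == "informative"]
        assert len(informative) >= 0.8 * len(sel)
        # at most one raw feature per redundant block among the selected
        blocks = {}
        for f in sel:
            role = roles.loc[f]
            block = role["parent"] if role["role"] == "redundant" else f
            blocks.setdefault(block, set()).add(f)
        red_parents = set(roles.loc[roles["role"] == "redundant", "parent"])
        for block, members in blocks.items():
            if block in red_parents:
                assert len(members) <= 1

    def test_deterministic(self, small_result):
        prof = prefilter_wells(small_result.profiles)
        ranking = mrmr_rank(prof, compute_relevance(prof))
        s1 = select_signature(ranking, prof, seed=42)
        s2 = select_signature(ranking, prof, seed=42)
        assert s1.features == s2.features and s1.k == s2.k
        c1 = pd.DataFrame(s1.auc_curve)
        c2 = pd.DataFrame(s2.auc_curve)
        pd.testing.assert_frame_equal(c1, c2)  # NaN-aware bitwise equality
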