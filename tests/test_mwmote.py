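"""MWMOTE oversampling against brute-force oracles on small planar data."""

from __future__ import annotations

import numpy as np
import pytest

from evsig.exceptions import ValidationError
from evsig.mwmote import (
    ImbalancedSet,
    MWMOTEParams,
    informative_sets,
    oversample,
    selection_weights,
)


def brute_force_sets(X, y_min, params):
    """Exhaustive-search recomputation of the three informative sets."""
    X = np.asarray(X, dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mu) / sd
    n = len(Z)

    def dist(i, j):
        return float(np.linalg.norm(Z[i] - Z[j]))

    def knn(i, candidates, k):
        ranked = sorted(candidates, key=lambda j: (dist(i, j), j))
        return ranked[:k]

    minority = [i for i in range(n) if y_min[i]]
    majority = [i for i in range(n) if not y_min[i]]
    filtered = [
        i
        for i in minority
        if any(y_min[j] for j in knn(i, [j for j in range(n) if j != i], params.k1))
    ]
    borderline = sorted({j for i in filtered for j in knn(i, majority, params.k2)})
    k3 = params.k3 if params.k3 is not None else max(1, len(minority) // 2)
    informative = sorted({i for j in borderline for i in knn(j, minority, k3)})
    return filtered, borderline, informative, Z


def brute_force_weights(Z, borderline, informative, params):
    p = Z.shape[1]
    weights = np.zeros(len(informative))
    for j in borderline:
        cf = []
        for i in informative:
            d = float(np.linalg.norm(Z[j] - Z[i]))
            cf.append(params.c_max if d == 0 else min(p / d, params.c_th) / params.c_th * params.c_max)
        cf = np.asarray(cf)
        weights += cf * (cf / cf.sum())
    return weights / weights.sum()


def planar_instance(seed=0, n_min=8, n_maj=22):
    rng = np.random.default_rng(seed)
    Xmin = rng.normal([0, 0], 0.8, size=(n_min, 2))
    Xmaj = rng.normal([3, 0], 1.2, size=(n_maj, 2))
    X = np.vstack([Xmin, Xmaj])
    y = np.array(["pos"] * n_min + ["neg"] * n_maj)
    return ImbalancedSet(X, y, minority_label="pos")


class TestInformativeSets:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_sets_match_exhaustive_search_oracle(self, seed):
        data = planar_instance(seed)
        params = MWMOTEParams(k1=5, k2=3, k3=4)
        filt, border, info = informative_sets(data, params)
        o_filt, o_border, o_info, _ = brute_force_sets(
            data.features, data.minority_mask, params
        )
        assert list(filt) == o_filt
        assert list(border) == o_border
        assert list(info) == o_info

    def test_separated_clusters_keep_all_minority(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 0.3, (6, 2)), rng.normal(10, 0.3, (14, 2))])
        y = np.array(["pos"] * 6 + ["neg"] * 14)
        filt, border, _ = informative_sets(ImbalancedSet(X, y, "pos"), MWMOTEParams())
        assert list(filt) == list(range(6))
        assert len(border) > 0 and all(j >= 6 for j in border)

    def test_lone_minority_point_filtered_as_noise(self):
        # point 0 sits inside the majority cloud; points 1-3 cluster far away
        X = np.array(
            [[5.0, 5.0]] + [[0, 0], [0.1, 0], [0, 0.1]]
            + [[5 + dx, 5 + dy] for dx in (-0.2, 0, 0.2) for dy in (-0.2, 0, 0.2)]
        )
        y = np.array(["pos"] * 4 + ["neg"] * 9)
        filt, _, _ = informative_sets(ImbalancedSet(X, y, "pos"), MWMOTEParams(k1=3))
        assert 0 not in filt and {1, 2, 3} <= set(filt)


class TestSelectionWeights:
    def test_single_informative_point_gets_probability_one(self):
        X = np.array([[0.0, 0], [0.2, 0], [3, 0], [3.2, 0], [3.4, 0], [3.1, 0.2], [2.9, 0.1]])
        y = np.array(["pos", "pos", "neg", "neg", "neg", "neg", "neg"])
        data = ImbalancedSet(X, y, "pos")
        params = MWMOTEParams(k1=2, k2=2, k3=1)
        sets = informative_sets(data, params)
        probs = selection_weights(data, sets, params)
        if len(sets[2]) == 1:
            assert probs[0] == pytest.approx(1.0)
        assert probs.sum() == pytest.approx(1.0)

    def test_symmetric_minority_points_get_equal_weight(self):
        # two minority points mirror-symmetric about the majority cluster axis
        X = np.array([[0.0, 1.0], [0.0, -1.0], [2.0, 0.6], [2.0, -0.6], [2.5, 0.0]])
        y = np.array(["pos", "pos", "neg", "neg", "neg"])
        data = ImbalancedSet(X, y, "pos")
        params = MWMOTEParams(k1=3, k2=2, k3=2)
        probs = selection_weights(data, informative_sets(data, params), params)
        assert probs == pytest.approx([0.5, 0.5])

    @pytest.mark.parametrize("seed", [0, 3])
    def test_weights_match_hand_computed_oracle(self, seed):
        data = planar_instance(seed, n_min=6, n_maj=14)
        params = MWMOTEParams(k1=4, k2=2, k3=3)
        sets = informative_sets(data, params)
        probs = selection_weights(data, sets, params)
        _, o_border, o_info, Z = brute_force_sets(data.features, data.minority_mask, params)
        oracle = brute_force_weights(Z, o_border, o_info, params)
        np.testing.assert_allclose(probs, oracle, atol=1e-12)


class TestOversample:
    def test_zero_synthetic_is_identity(self):
        data = planar_instance()
        out = oversample(data, MWMOTEParams(n_synthetic=0))
        assert out is data

    def test_default_run_balances_classes_exactly(self):
        data = planar_instance(seed=2)
        out = oversample(data, MWMOTEParams(seed=9))
        n_min, n_maj = out.counts()
        assert n_min == n_maj
        assert len(out.labels) == len(data.labels) + (22 - 8)

    def test_synthetic_rows_are_convex_combinations_of_minority_parents(self):
        data = planar_instance(seed=4)
        out = oversample(data, MWMOTEParams(seed=1))
        syn = np.flatnonzero(out.is_synthetic)
        assert len(syn) > 0
        minority_idx = set(np.flatnonzero(data.minority_mask))
        for s in syn:
            a, b = out.parent_a[s], out.parent_b[s]
            assert a in minority_idx and b in minority_idx  # no majority contamination
            xa, xb, xs = data.features[a], data.features[b], out.features[s]
            seg = xb - xa
            if np.allclose(seg, 0):
                np.testing.assert_allclose(xs, xa)
                continue
            t = float(np.dot(xs - xa, seg) / np.dot(seg, seg))
            assert -1e-9 <= t <= 1 + 1e-9
            np.testing.assert_allclose(xs, xa + t * seg, atol=1e-9)

    def test_one_dimensional_synthetic_values_stay_in_cluster_range(self):
        # two separated 1-D minority clusters; synthetic points must not
        # bridge them (interpolation stays inside the parent cluster)
        X = np.array([[0.0], [0.1], [0.2], [5.0], [5.1], [5.2]]
                     + [[x] for x in np.linspace(10, 12, 12)])
        y = np.array(["pos"] * 6 + ["neg"] * 12)
        data = ImbalancedSet(X, y, "pos")
        out = oversample(data, MWMOTEParams(k1=3, k2=2, k3=3, n_synthetic=10, seed=0))
        for s in np.flatnonzero(out.is_synthetic):
            v = out.features[s, 0]
            assert (0.0 - 1e-9 <= v <= 0.2 + 1e-9) or (5.0 - 1e-9 <= v <= 5.2 + 1e-9)

    def test_seeded_reproducibility(self):
        data = planar_instance(seed=6)
        a = oversample(data, MWMOTEParams(seed=42))
        b = oversample(data, MWMOTEParams(seed=42))
        np.testing.assert_array_equal(a.features, b.features)
        np.testing.assert_array_equal(a.parent_a, b.parent_a)

    def test_singleton_minority_cannot_interpolate(self):
        X = np.vstack([[[0, 0]], np.random.default_rng(0).normal(3, 1, (6, 2))])
        y = np.array(["pos"] + ["neg"] * 6)
        with pytest.raises(ValidationError, match="single original member"):
            oversample(ImbalancedSet(X, y, "pos"), MWMOTEParams(k1=2))
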