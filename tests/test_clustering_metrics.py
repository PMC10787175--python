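"""Metric implementations versus independent brute-force oracles."""

import itertools
import math

import numpy as np
import pytest

from spotapa.clustering_metrics import (
    external_metrics, internal_metrics, inverse_distance_weights, knn_weights, morans_i,
)
from spotapa.io_formats import SpotLayout


# ---------------------------------------------------------------------------
# oracles: written straight from the definitions, no shared code with the
# implementations under test
# ---------------------------------------------------------------------------

def oracle_external(pred, ref):
    n = len(pred)
    tp = fp = fn = tn = 0
    for i, j in itertools.combinations(range(n), 2):
        same_p = pred[i] == pred[j]
        same_r = ref[i] == ref[j]
        if same_p and same_r:
            tp += 1
        elif same_p and not same_r:
            fp += 1
        elif not same_p and same_r:
            fn += 1
        else:
            tn += 1
    total = tp + fp + fn + tn
    jaccard = tp / (tp + fp + fn) if (tp + fp + fn) else 1.0
    # ARI via pair counts
    sum_a = tp + fp
    sum_b = tp + fn
    expected = sum_a * sum_b / total if total else 0.0
    max_index = (sum_a + sum_b) / 2
    ari = 1.0 if max_index == expected else (tp - expected) / (max_index - expected)
    # purity
    purity = 0
    for c in set(pred):
        members = [ref[i] for i in range(n) if pred[i] == c]
        purity += max(members.count(r) for r in set(members))
    purity /= n
    # NMI with arithmetic-mean normalization
    def entropy(labels):
        h = 0.0
        for c in set(labels):
            p = labels.count(c) / n
            h -= p * math.log(p)
        return h

    mi = 0.0
    for cp in set(pred):
        for cr in set(ref):
            nij = sum(1 for i in range(n) if pred[i] == cp and ref[i] == cr)
            if nij:
                pi = pred.count(cp) / n
                pj = ref.count(cr) / n
                mi += (nij / n) * math.log((nij / n) / (pi * pj))
    denom = (entropy(list(pred)) + entropy(list(ref))) / 2
    nmi = 1.0 if denom == 0 else mi / denom
    return {"ari": ari, "jaccard": jaccard, "nmi": nmi, "purity": purity}


def oracle_internal(X, labels):
    X = np.asarray(X, float)
    groups = sorted(set(labels))
    idx = {g: [i for i, l in enumerate(labels) if l == g] for g in groups}
    cent = {g: X[idx[g]].mean(axis=0) for g in groups}
    n, k = len(labels), len(groups)

    def d(a, b):
        return math.dist(a, b)

    sig = {g: np.mean([d(X[i], cent[g]) for i in idx[g]]) for g in groups}
    dbi = np.mean([
        max((sig[g] + sig[h]) / d(cent[g], cent[h]) for h in groups if h != g)
        for g in groups
    ])

    overall = X.mean(axis=0)
    between = sum(len(idx[g]) * d(cent[g], overall) ** 2 for g in groups)
    within = sum(d(X[i], cent[g]) ** 2 for g in groups for i in idx[g])
    ch = (between / (k - 1)) / (within / (n - k))

    sils = []
    for i in range(n):
        gi = labels[i]
        own = [j for j in idx[gi] if j != i]
        if not own:
            sils.append(0.0)
            continue
        a = np.mean([d(X[i], X[j]) for j in own])
        b = min(np.mean([d(X[i], X[j]) for j in idx[g]]) for g in groups if g != gi)
        sils.append((b - a) / max(a, b))
    silhouette = float(np.mean(sils))

    inter = min(
        d(X[i], X[j])
        for g, h in itertools.combinations(groups, 2)
        for i in idx[g] for j in idx[h]
    )
    diam = max(
        max((d(X[i], X[j]) for i, j in itertools.combinations(idx[g], 2)), default=0.0)
        for g in groups
    )
    dunn = inter / diam
    return {"dbi": dbi, "ch": ch, "silhouette": silhouette, "dunn": dunn}


def oracle_moran(values, W):
    values = np.asarray(values, float)
    n = len(values)
    z = values - values.mean()
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            num += W[i, j] * z[i] * z[j]
            s0 += W[i, j]
    return (n / s0) * num / (z ** 2).sum()


# ---------------------------------------------------------------------------
# external metrics
# ---------------------------------------------------------------------------

class TestExternalMetrics:
    def test_identity(self):
        m = external_metrics([1, 1, 2, 2], [1, 1, 2, 2])
        assert m == {"ari": 1.0, "jaccard": 1.0, "nmi": 1.0, "purity": 1.0}

    def test_label_permutation_invariance(self):
        m = external_metrics([1, 1, 2, 2], [2, 2, 1, 1])
        assert m["ari"] == pytest.approx(1.0)

    def test_purity_majority(self):
        m = external_metrics([1, 1, 1], ["A", "A", "B"])
        assert m["purity"] == pytest.approx(2 / 3)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            external_metrics([1, 2], [1, 2, 3])

    def test_exhaustive_n4_three_labels(self):
        labelings = list(itertools.product(range(3), repeat=4))
        for pred in labelings:
            for ref in labelings:
                got = external_metrics(list(pred), list(ref))
                exp = oracle_external(list(pred), list(ref))
                for key in exp:
                    assert got[key] == pytest.approx(exp[key], abs=1e-12), (
                        key, pred, ref)

    def test_exhaustive_n6_two_labels(self):
        labelings = list(itertools.product(range(2), repeat=6))
        rng = np.random.default_rng(0)
        refs = [labelings[i] for i in rng.choice(len(labelings), size=8, replace=False)]
        for pred in labelings:
            for ref in refs:
                got = external_metrics(list(pred), list(ref))
                exp = oracle_external(list(pred), list(ref))
                for key in exp:
                    assert got[key] == pytest.approx(exp[key], abs=1e-12)

    def test_relabeling_invariance_random(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            pred = rng.integers(0, 3, size=10).tolist()
            ref = rng.integers(0, 3, size=10).tolist()
            m1 = external_metrics(pred, ref)
            remap = {0: "x", 1: "y", 2: "z"}
            m2 = external_metrics([remap[p] for p in pred], ref)
            assert m1 == pytest.approx(m2)

    def test_ari_near_zero_under_independence(self):
        rng = np.random.default_rng(2)
        aris = [
            external_metrics(rng.integers(0, 3, 60).tolist(),
                             rng.integers(0, 3, 60).tolist())["ari"]
            for _ in range(300)
        ]
        assert abs(np.mean(aris)) < 0.02


# ---------------------------------------------------------------------------
# internal metrics
# ---------------------------------------------------------------------------

class TestInternalMetrics:
    def test_well_separated_pairs(self):
        X = np.array([[0, 0], [0, 0.1], [10, 10], [10, 10.1]])
        m = internal_metrics(X, [0, 0, 1, 1])
        assert m["silhouette"] > 0.9
        assert m["dunn"] > 1

    def test_zero_scatter_dbi(self):
        X = np.array([[0, 0], [0, 0], [5, 5], [5, 5]])
        m = internal_metrics(X, [0, 0, 1, 1])
        assert m["dbi"] == 0.0

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            internal_metrics(np.eye(3), [0, 0, 0])

    @pytest.mark.parametrize("trial", range(100))
    def test_random_instances_match_oracle(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(5, 9))
        X = rng.normal(size=(n, 2))
        while True:
            labels = rng.integers(0, 2, size=n).tolist()
            if len(set(labels)) == 2:
                break
        got = internal_metrics(X, labels)
        exp = oracle_internal(X, labels)
        for key in exp:
            assert got[key] == pytest.approx(exp[key], abs=1e-10), key

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(8, 2))
        labels = [0, 0, 0, 0, 1, 1, 1, 1]
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        X2 = X @ R.T + np.array([3.0, -2.0])
        m1 = internal_metrics(X, labels)
        m2 = internal_metrics(X2, labels)
        for key in m1:
            assert m1[key] == pytest.approx(m2[key], abs=1e-9)


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------

def _line_layout(n):
    return SpotLayout(spot_ids=[f"s{i}" for i in range(n)],
                      x=np.arange(float(n)), y=np.zeros(n))


class TestMoransI:
    def test_positive_on_two_block_gradient(self):
        layout = _line_layout(10)
        values = [0] * 5 + [1] * 5
        res = morans_i(values, layout, weight_scheme="knn", knn_k=2, n_perm=0)
        assert res["I"] > 0

    def test_negative_on_checkerboard(self, square_layout):
        values = [(int(x) + int(y)) % 2 for x, y in
                  zip(square_layout.x, square_layout.y)]
        res = morans_i(values, square_layout, weight_scheme="knn", knn_k=4, n_perm=0)
        assert res["I"] < 0

    @pytest.mark.parametrize("trial", range(100))
    def test_random_matches_double_loop_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = 10
        layout = SpotLayout(spot_ids=[f"s{i}" for i in range(n)],
                            x=rng.random(n) * 5, y=rng.random(n) * 5)
        values = rng.random(n)
        W = knn_weights(layout, k=3)
        got = morans_i(values, layout, weights=W, n_perm=0)["I"]
        assert got == pytest.approx(oracle_moran(values, W), abs=1e-10)

    def test_affine_invariance(self):
        rng = np.random.default_rng(33)
        layout = _line_layout(12)
        values = rng.random(12)
        i1 = morans_i(values, layout, n_perm=0)["I"]
        i2 = morans_i(5.0 * values - 2.0, layout, n_perm=0)["I"]
        assert i1 == pytest.approx(i2, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            morans_i([1.0] * 5, _line_layout(5), n_perm=0)

    def test_permutation_p_value_floor(self):
        layout = _line_layout(8)
        values = [1, 0, 1, 0, 1, 0, 1, 0]  # strong negative autocorrelation
        res = morans_i(values, layout, weight_scheme="knn", knn_k=2,
                       n_perm=99, seed=0)
        # observed I is far below the permutations, so nearly all exceed it
        assert res["p_perm"] > 0.9

    def test_p_value_uses_b_plus_one(self):
        layout = _line_layout(10)
        values = list(np.linspace(0, 1, 10))
        res = morans_i(values, layout, weight_scheme="knn", knn_k=2,
                       n_perm=99, seed=1)
        assert res["p_perm"] >= 1 / 100
        assert res["p_perm"] == pytest.approx(round(res["p_perm"] * 100) / 100)

    def test_inverse_distance_scheme(self):
        layout = _line_layout(6)
        W = inverse_distance_weights(layout)
        assert W[0, 1] == pytest.approx(1.0)
        assert W[0, 2] == pytest.approx(0.5)
        assert np.all(np.diag(W) == 0)
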