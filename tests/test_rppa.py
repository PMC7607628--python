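"""RPPA normalization, the composite pathway score, paired deltas,
downmodulation calls, and centroid-linkage clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage

from pi3ktrial.rppa import (
    DEFAULT_KEY_ANTIBODIES,
    DEFAULT_NODE_MAP,
    NEGATIVE_NODES,
    POSITIVE_NODES,
    NodeMap,
    PairedDelta,
    RppaMatrix,
    cluster,
    downmodulation_call,
    normalize_matrix,
    paired_delta,
    pi3k_score,
)

ALL_ANTIBODIES = [a for abs_ in DEFAULT_NODE_MAP.values() for a in abs_]


def _matrix(values: dict, normalized=False) -> RppaMatrix:
    return RppaMatrix(values=pd.DataFrame(values), normalized=normalized)


def _score_matrix(sample_vectors: dict) -> RppaMatrix:
    df = pd.DataFrame(sample_vectors, index=ALL_ANTIBODIES)
    return RppaMatrix(values=df, normalized=True)


def test_normalize_constant_row_becomes_zero():
    m = _matrix({"s1": [3.0], "s2": [3.0], "s3": [3.0], "s4": [3.0]})
    out = normalize_matrix(m)
    assert (out.values.to_numpy() == 0).all()
    assert out.normalized


def test_normalize_three_point_row_oracle():
    """Row [1,2,3]: median 2 removed, then /SD(ddof=1)=1 → [−1, 0, 1]."""
    m = _matrix({"s1": [1.0], "s2": [2.0], "s3": [3.0]})
    out = normalize_matrix(m)
    np.testing.assert_allclose(out.values.to_numpy().ravel(), [-1.0, 0.0, 1.0])


def test_normalize_idempotent(rng):
    m = RppaMatrix(values=pd.DataFrame(rng.normal(size=(6, 8))))
    once = normalize_matrix(m)
    twice = normalize_matrix(once)
    pd.testing.assert_frame_equal(once.values, twice.values)


def test_normalize_rows_have_zero_median_unit_sd(rng):
    m = RppaMatrix(values=pd.DataFrame(rng.normal(size=(10, 7))))
    out = normalize_matrix(m).values
    np.testing.assert_allclose(out.median(axis=1), 0.0, atol=1e-12)
    np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-12)


def test_normalize_requires_two_samples():
    with pytest.raises(ValueError):
        normalize_matrix(_matrix({"only": [1.0, 2.0]}))


def test_rppa_matrix_rejects_missing_cells():
    with pytest.raises(ValueError):
        RppaMatrix(values=pd.DataFrame({"s1": [1.0, np.nan]}))


def test_pi3k_score_zero_sample_and_formula_arithmetic():
    zero = {a: 0.0 for a in ALL_ANTIBODIES}
    pos_one = dict(zero)
    for node in POSITIVE_NODES:
        for a in DEFAULT_NODE_MAP[node]:
            pos_one[a] = 1.0
    m = _score_matrix({"z": pd.Series(zero), "p": pd.Series(pos_one)})
    nm = NodeMap()
    assert pi3k_score(m, nm, "z") == pytest.approx(0.0)
    assert pi3k_score(m, nm, "p") == pytest.approx(6.0)


def test_pi3k_score_matches_hand_summed_oracle(rng):
    vec = pd.Series(rng.normal(size=len(ALL_ANTIBODIES)), index=ALL_ANTIBODIES)
    m = _score_matrix({"s": vec})
    nm = NodeMap()
    expected = 0.0
    for node in POSITIVE_NODES:
        expected += np.mean([vec[a] for a in DEFAULT_NODE_MAP[node]])
    for node in NEGATIVE_NODES:
        expected -= np.mean([vec[a] for a in DEFAULT_NODE_MAP[node]])
    assert pi3k_score(m, nm, "s") == pytest.approx(expected, abs=1e-12)


def test_pi3k_score_is_linear(rng):
    x = pd.Series(rng.normal(size=len(ALL_ANTIBODIES)), index=ALL_ANTIBODIES)
    y = pd.Series(rng.normal(size=len(ALL_ANTIBODIES)), index=ALL_ANTIBODIES)
    a, b = 2.5, -0.7
    m = _score_matrix({"x": x, "y": y, "combo": a * x + b * y})
    nm = NodeMap()
    assert pi3k_score(m, nm, "combo") == pytest.approx(
        a * pi3k_score(m, nm, "x") + b * pi3k_score(m, nm, "y"), abs=1e-10
    )


def test_pi3k_score_requires_normalized_matrix():
    m = _matrix({"s1": [1.0], "s2": [2.0]})
    with pytest.raises(ValueError):
        pi3k_score(m, NodeMap(), "s1")


def test_pi3k_score_unknown_sample():
    zero = {a: 0.0 for a in ALL_ANTIBODIES}
    m = _score_matrix({"z": pd.Series(zero)})
    with pytest.raises(KeyError):
        pi3k_score(m, NodeMap(), "missing")


def test_node_map_requires_all_nodes():
    with pytest.raises(ValueError):
        NodeMap(mapping={"pAkt": ("AKT_pS473",)})


def test_paired_delta_identity_and_offset(rng):
    base = pd.Series(rng.normal(size=len(ALL_ANTIBODIES)), index=ALL_ANTIBODIES)
    m = _score_matrix({"bl": base, "same": base, "zero": base * 0.0})
    deltas = paired_delta(m, [("p1", "bl", "same"), ("p2", "zero", "bl")])
    assert np.allclose(deltas[0].delta, 0.0)
    np.testing.assert_allclose(deltas[1].delta, base)
    with pytest.raises(KeyError):
        paired_delta(m, [("p3", "bl", "nope")])


@pytest.mark.parametrize(
    "shift,expected",
    [(-0.5, True), (0.0, False), (0.5, False)],
)
def test_downmodulation_strict_negativity(shift, expected):
    delta = pd.Series(0.0, index=ALL_ANTIBODIES)
    delta.loc[list(DEFAULT_KEY_ANTIBODIES)] = -1.0
    delta.loc[DEFAULT_KEY_ANTIBODIES[0]] = shift  # one node moved
    pdelta = PairedDelta("p", "b", "t", delta)
    assert downmodulation_call(pdelta) is expected


def test_downmodulation_missing_antibody_is_config_error():
    delta = pd.Series(-1.0, index=ALL_ANTIBODIES[:3])
    with pytest.raises(KeyError):
        downmodulation_call(PairedDelta("p", "b", "t", delta))


def test_cluster_identical_samples_merge_at_zero():
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [9.0, 1.0, 4.0]})
    dend = cluster(df, axis="samples", distance="euclidean")
    assert dend.merges[0][:3] == (0, 1, 0.0)


def test_cluster_planted_groups_merge_within_group_first():
    rng = np.random.default_rng(0)
    centers = np.array([[0, 0], [10, 0], [0, 10], [10, 10]], dtype=float)
    pts = np.vstack([c + rng.normal(0, 0.1, size=(2, 2)) for c in centers])
    df = pd.DataFrame(pts.T, columns=[f"s{i}" for i in range(8)])
    dend = cluster(df, axis="samples", distance="euclidean")
    first_two = [set(m[:2]) for m in dend.merges[:2]]
    within = [{0, 1}, {2, 3}, {4, 5}, {6, 7}]
    for pair in first_two:
        assert pair in within


def _brute_force_centroid(x: np.ndarray, metric: str):
    """O(n^3) reference: recompute the full centroid-distance matrix each step."""
    def dist(u, v):
        if metric == "euclidean":
            return float(np.linalg.norm(u - v))
        du, dv = u - u.mean(), v - v.mean()
        return float(1 - np.dot(du, dv) / (np.linalg.norm(du) * np.linalg.norm(dv)))

    clusters = {i: [i] for i in range(len(x))}
    next_id = len(x)
    merges = []
    while len(clusters) > 1:
        ids = sorted(clusters)
        best = None
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                a, b = ids[i], ids[j]
                d = dist(x[clusters[a]].mean(axis=0), x[clusters[b]].mean(axis=0))
                if best is None or d < best[0] - 1e-15:
                    best = (d, a, b)
        d, a, b = best
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        merges.append((a, b, d, len(clusters[next_id])))
        next_id += 1
    return merges


@pytest.mark.parametrize("metric", ["euclidean", "correlation"])
def test_cluster_matches_brute_force_oracle(metric, rng):
    x = rng.normal(size=(5, 4))
    df = pd.DataFrame(x.T, columns=[f"s{i}" for i in range(5)])
    dend = cluster(df, axis="samples", distance=metric, warn_inversions=False)
    expected = _brute_force_centroid(x, metric)
    assert len(dend.merges) == len(expected)
    for got, want in zip(dend.merges, expected):
        assert got[0] == want[0] and got[1] == want[1]
        assert got[2] == pytest.approx(want[2], abs=1e-12)
        assert got[3] == want[3]


def test_cluster_matches_scipy_euclidean_centroid(rng):
    x = rng.normal(size=(6, 4))
    df = pd.DataFrame(x.T, columns=[f"s{i}" for i in range(6)])
    dend = cluster(df, axis="samples", distance="euclidean", warn_inversions=False)
    Z = linkage(x, method="centroid")
    np.testing.assert_allclose([m[2] for m in dend.merges], Z[:, 2], atol=1e-9)


def test_cluster_permutation_invariance(rng):
    """Permuting input columns preserves merge heights and partitions."""
    x = rng.normal(size=(6, 5))
    names = [f"s{i}" for i in range(6)]
    df = pd.DataFrame(x.T, columns=names)
    perm = [3, 0, 5, 1, 4, 2]
    dfp = df[[names[i] for i in perm]]

    def partitions(dend):
        n = len(dend.labels)
        members = {i: frozenset([dend.labels[i]]) for i in range(n)}
        parts = []
        for k, (a, b, h, _) in enumerate(dend.merges):
            members[n + k] = members[a] | members[b]
            parts.append((round(h, 9), members[n + k]))
        return sorted(parts)

    d1 = cluster(df, axis="samples", distance="euclidean", warn_inversions=False)
    d2 = cluster(dfp, axis="samples", distance="euclidean", warn_inversions=False)
    assert partitions(d1) == partitions(d2)


def test_cluster_requires_two_items():
    with pytest.raises(ValueError):
        cluster(pd.DataFrame({"a": [1.0, 2.0]}), axis="samples")


def test_newick_roundtrip_structure():
    df = pd.DataFrame(
        {"a": [0.0, 0.0], "b": [0.1, 0.0], "c": [5.0, 5.0], "d": [5.1, 5.0]}
    )
    dend = cluster(df, axis="samples", distance="euclidean")
    nwk = dend.to_newick()
    assert nwk.endswith(";")
    for name in "abcd":
        assert name in nwk
    # two tight pairs must be sister leaves
    assert set(dend.merges[0][:2]) in ({0, 1}, {2, 3})
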