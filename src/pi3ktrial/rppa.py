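"""Reverse-phase protein array (RPPA) pathway analysis.

An RPPA matrix holds log2 protein levels, antibodies as rows and samples as
columns.  Rows are normalized by median-centering and scaling to unit
standard deviation (n−1 denominator); constant rows become all-zero.

The composite PI3K pathway score sums six positive-arm effector nodes and
subtracts the two negative regulators:

    score = [pAkt + pmTOR + pGSK3 + pS6K + pS6 + p4EBP1] − [INPP4B + PTEN]

where each node's value is the mean of the normalized antibodies mapped to
it.  Paired baseline / on-treatment biopsies yield per-antibody delta
vectors (on-treatment minus baseline); "integral downmodulation" is called
when every key downstream node — AKT S473, S6 S235/S236, S6 S240/S244,
4EBP1 S65 and 4EBP1 T37/T46 — moves strictly below zero.

Hierarchical clustering uses centroid linkage: at each step the pair of
clusters with the smallest centroid distance merges (ties broken by the
smallest cluster indices).  Default distance is 1 − Pearson correlation,
configurable to Euclidean.  Centroid linkage can produce non-monotone merge
heights; these are flagged, never repaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RppaMatrix",
    "NodeMap",
    "PairedDelta",
    "Dendrogram",
    "POSITIVE_NODES",
    "NEGATIVE_NODES",
    "DEFAULT_NODE_MAP",
    "DEFAULT_KEY_ANTIBODIES",
    "normalize_matrix",
    "pi3k_score",
    "paired_delta",
    "downmodulation_call",
    "cluster",
]

POSITIVE_NODES = ("pAkt", "pmTOR", "pGSK3", "pS6K", "pS6", "p4EBP1")
NEGATIVE_NODES = ("INPP4B", "PTEN")

# Default antibody naming follows RPPA core-facility conventions; pAkt uses
# the S473 site (the site tracked in the downmodulation panel), overridable
# through a custom NodeMap.
DEFAULT_NODE_MAP: dict[str, tuple[str, ...]] = {
    "pAkt": ("AKT_pS473",),
    "pmTOR": ("MTOR_pS2448",),
    "pGSK3": ("GSK3AB_pS21_S9",),
    "pS6K": ("P70S6K_pT389",),
    "pS6": ("S6_pS235_S236", "S6_pS240_S244"),
    "p4EBP1": ("4EBP1_pS65", "4EBP1_pT37_T46"),
    "INPP4B": ("INPP4B",),
    "PTEN": ("PTEN",),
}

# Key downstream nodes whose joint strict decrease defines integral
# pathway downmodulation in a paired biopsy.
DEFAULT_KEY_ANTIBODIES = (
    "AKT_pS473",
    "S6_pS235_S236",
    "S6_pS240_S244",
    "4EBP1_pS65",
    "4EBP1_pT37_T46",
)


@dataclass
class RppaMatrix:
    """Antibody × sample matrix of log2 protein levels."""

    values: pd.DataFrame  # index = antibodies, columns = samples
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("RPPA matrix contains missing cells")

    @property
    def antibodies(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class NodeMap:
    """Mapping from score nodes to the antibodies quantifying them."""

    mapping: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_NODE_MAP)
    )

    def __post_init__(self) -> None:
        missing = [n for n in POSITIVE_NODES + NEGATIVE_NODES if n not in self.mapping]
        if missing:
            raise ValueError(f"NodeMap lacks nodes: {missing}")
        for node, abs_ in self.mapping.items():
            if not abs_:
                raise ValueError(f"node {node!r} maps to no antibodies")

    def antibodies_for(self, node: str) -> tuple[str, ...]:
        return tuple(self.mapping[node])


@dataclass(frozen=True)
class PairedDelta:
    patient_id: str
    baseline_sample: str
    ontx_sample: str
    delta: pd.Series  # per antibody, on-treatment minus baseline


def normalize_matrix(m: RppaMatrix) -> RppaMatrix:
    """Median-center each antibody row and scale it to unit SD (ddof=1).

    Rows with zero spread become all-zero.  Idempotent: normalized rows
    (median 0, SD 1) are fixed points.
    """
    if m.values.shape[1] < 2:
        raise ValueError("need at least 2 samples to normalize (SD undefined)")
    centered = m.values.sub(m.values.median(axis=1), axis=0)
    sd = centered.std(axis=1, ddof=1)
    out = centered.div(sd.where(sd > 0, np.inf), axis=0)
    return RppaMatrix(values=out, normalized=True)


def _node_value(m: RppaMatrix, node_map: NodeMap, node: str, sample: str) -> float:
    abs_ = node_map.antibodies_for(node)
    missing = [a for a in abs_ if a not in m.values.index]
    if missing:
        raise KeyError(f"node {node!r}: antibodies absent from matrix: {missing}")
    return float(m.values.loc[list(abs_), sample].mean())


def pi3k_score(m: RppaMatrix, node_map: NodeMap, sample: str) -> float:
    """Composite PI3K pathway score for one sample of a normalized matrix."""
    if not m.normalized:
        raise ValueError("pi3k_score requires a normalized matrix")
    if sample not in m.values.columns:
        raise KeyError(f"sample {sample!r} not in matrix")
    pos = sum(_node_value(m, node_map, n, sample) for n in POSITIVE_NODES)
    neg = sum(_node_value(m, node_map, n, sample) for n in NEGATIVE_NODES)
    return pos - neg


def paired_delta(
    m: RppaMatrix, pairs: Sequence[tuple[str, str, str]]
) -> list[PairedDelta]:
    """On-treatment minus baseline columns for each (patient, baseline, ontx)."""
    out = []
    for patient, baseline, ontx in pairs:
        for s in (baseline, ontx):
            if s not in m.values.columns:
                raise KeyError(f"sample {s!r} (patient {patient}) not in matrix")
        out.append(
            PairedDelta(
                patient_id=patient,
                baseline_sample=baseline,
                ontx_sample=ontx,
                delta=m.values[ontx] - m.values[baseline],
            )
        )
    return out


def downmodulation_call(
    delta: PairedDelta,
    key_antibodies: Sequence[str] = DEFAULT_KEY_ANTIBODIES,
) -> bool:
    """True iff every key-node antibody decreased strictly on treatment."""
    missing = [a for a in key_antibodies if a not in delta.delta.index]
    if missing:
        raise KeyError(f"key antibodies absent from delta vector: {missing}")
    return bool((delta.delta.loc[list(key_antibodies)] < 0).all())


# ---------------------------------------------------------------------------
# centroid-linkage hierarchical clustering


@dataclass(frozen=True)
class Dendrogram:
    """Binary merge tree: n−1 merges over n leaves, scipy-style indexing.

    Merge i joins cluster ids ``merges[i][0]`` and ``merges[i][1]`` (ids
    < n are leaves, id n+i is the cluster formed by merge i) at height
    ``merges[i][2]`` with ``merges[i][3]`` members.  ``monotone`` is False
    when centroid linkage produced a height inversion.
    """

    labels: tuple[str, ...]
    merges: tuple[tuple[int, int, float, int], ...]
    monotone: bool

    @property
    def leaf_order(self) -> tuple[str, ...]:
        order: list[str] = []

        def walk(node: int) -> None:
            n = len(self.labels)
            if node < n:
                order.append(self.labels[node])
            else:
                a, b, _, _ = self.merges[node - n]
                walk(a)
                walk(b)

        walk(len(self.labels) + len(self.merges) - 1) if self.merges else order.extend(
            self.labels
        )
        return tuple(order)

    def to_newick(self) -> str:
        """Newick string; branch lengths are height differences (clamped at 0)."""
        n = len(self.labels)

        def height(node: int) -> float:
            return 0.0 if node < n else self.merges[node - n][2]

        def render(node: int, parent_h: float) -> str:
            bl = max(parent_h - height(node), 0.0)
            if node < n:
                return f"{self.labels[node]}:{bl:g}"
            a, b, h, _ = self.merges[node - n]
            return f"({render(a, h)},{render(b, h)}):{bl:g}"

        if not self.merges:
            return f"({','.join(self.labels)});"
        root = n + len(self.merges) - 1
        a, b, h, _ = self.merges[root - n]
        return f"({render(a, h)},{render(b, h)});"


def _centroid_distance(u: np.ndarray, v: np.ndarray, metric: str) -> float:
    if metric == "euclidean":
        return float(np.linalg.norm(u - v))
    if metric == "correlation":
        du, dv = u - u.mean(), v - v.mean()
        denom = np.linalg.norm(du) * np.linalg.norm(dv)
        if denom == 0:
            return 0.0 if np.allclose(u, v) else 1.0
        return float(1.0 - np.dot(du, dv) / denom)
    raise ValueError(f"unknown distance metric {metric!r}")


def cluster(
    m: RppaMatrix | pd.DataFrame,
    axis: str = "samples",
    distance: str = "correlation",
    warn_inversions: bool = True,
) -> Dendrogram:
    """Agglomerative centroid-linkage clustering of samples or antibodies.

    At each step the two clusters whose centroids (means of member vectors
    in value space) are closest merge; ties break toward the smallest pair
    of cluster ids.  Heights are the centroid distances at merge time and
    may invert (non-monotone); flagged via ``Dendrogram.monotone``.
    """
    values = m.values if isinstance(m, RppaMatrix) else m
    if axis == "samples":
        data = values.T
    elif axis == "antibodies":
        data = values
    else:
        raise ValueError(f"axis must be 'samples' or 'antibodies', got {axis!r}")
    labels = tuple(str(i) for i in data.index)
    x = data.to_numpy(dtype=float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items to cluster")

    centroids: dict[int, np.ndarray] = {i: x[i].copy() for i in range(n)}
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    active = list(range(n))
    merges: list[tuple[int, int, float, int]] = []
    monotone = True
    last_h = -np.inf
    next_id = n
    while len(active) > 1:
        best = None
        for ii in range(len(active)):
            for jj in range(ii + 1, len(active)):
                a, b = active[ii], active[jj]
                d = _centroid_distance(centroids[a], centroids[b], distance)
                if best is None or d < best[0] - 1e-15:
                    best = (d, a, b)
        d, a, b = best
        if d < last_h - 1e-12:
            monotone = False
        last_h = d
        size = sizes[a] + sizes[b]
        centroids[next_id] = (
            sizes[a] * centroids[a] + sizes[b] * centroids[b]
        ) / size
        sizes[next_id] = size
        merges.append((a, b, d, size))
        active = [c for c in active if c not in (a, b)] + [next_id]
        next_id += 1
    dend = Dendrogram(labels=labels, merges=tuple(merges), monotone=monotone)
    if warn_inversions and not monotone:
        import warnings

        warnings.warn("centroid linkage produced non-monotone merge heights")
    return dend
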