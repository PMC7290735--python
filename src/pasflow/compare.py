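"""Cross-arm comparison of pathway activation profiles.

At each time point every pathway receives exactly one category from the
signs of its group PAS in the two surgical arms: common (same sign),
unique to one arm (signed in one arm, neutral in the other), inverse
(opposite signs), or neutral.  Inverse pathways whose activation magnitude
reaches a threshold (default 0.1) are flagged as strongly inversely
regulated.  The module also provides the sample-level summaries used to
inspect profiles: average-linkage hierarchical clustering (Pearson or
Euclidean distance), PCA and an ordered Pearson correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .pas import PASProfile

CATEGORIES = (
    "common_activated",
    "common_silenced",
    "unique_nHx_activated",
    "unique_nHx_silenced",
    "unique_eHx_activated",
    "unique_eHx_silenced",
    "inverse",
    "neutral",
)

__all__ = [
    "CATEGORIES",
    "RegulationCall",
    "TimepointSummary",
    "classify_timepoint",
    "aggregate_unique_counts",
    "strong_inverse_set",
    "hierarchical_clustering",
    "dendrogram_newick",
    "pca_projection",
    "correlation_matrix",
]


@dataclass(frozen=True)
class RegulationCall:
    """One pathway's regulation status at one time point across the two arms."""

    pathway_id: str
    time_h: int
    pas_nHx: float
    pas_eHx: float
    status_nHx: Literal["activated", "silenced", "neutral"]
    status_eHx: Literal["activated", "silenced", "neutral"]
    category: str
    strong_inverse: bool

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        opposite = (
            self.status_nHx != "neutral"
            and self.status_eHx != "neutral"
            and self.status_nHx != self.status_eHx
        )
        if (self.category == "inverse") != opposite:
            raise ValueError(
                f"category {self.category!r} inconsistent with statuses "
                f"({self.status_nHx}, {self.status_eHx}) for {self.pathway_id!r}"
            )
        if self.strong_inverse and self.category != "inverse":
            raise ValueError("strong_inverse requires category 'inverse'")


@dataclass(frozen=True)
class TimepointSummary:
    """Per-category pathway counts at one time point.

    ``activated_total`` counts pathways activated in at least one arm with
    no conflict (common + unique of either arm); ``overlap_fraction`` is the
    share of those common to both arms.
    """

    time_h: int
    counts: dict[str, int]
    n_pathways: int

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories {sorted(unknown)}")
        if sum(self.counts.values()) != self.n_pathways:
            raise ValueError(
                f"category counts sum to {sum(self.counts.values())}, "
                f"expected {self.n_pathways}"
            )

    @property
    def activated_total(self) -> int:
        return (self.counts.get("common_activated", 0)
                + self.counts.get("unique_nHx_activated", 0)
                + self.counts.get("unique_eHx_activated", 0))

    @property
    def silenced_total(self) -> int:
        return (self.counts.get("common_silenced", 0)
                + self.counts.get("unique_nHx_silenced", 0)
                + self.counts.get("unique_eHx_silenced", 0))

    @property
    def overlap_fraction(self) -> float:
        total = self.activated_total
        return self.counts.get("common_activated", 0) / total if total else float("nan")

    @classmethod
    def from_counts(cls, time_h: int, n_pathways: int, **counts: int) -> "TimepointSummary":
        """Build a summary from named category counts; the remainder is neutral."""
        counts = {k: v for k, v in counts.items() if v}
        counts.setdefault("neutral", 0)
        counts["neutral"] += n_pathways - sum(counts.values())
        return cls(time_h=time_h, counts=counts, n_pathways=n_pathways)


def _status(pas: float, fdr: float, gate: str, alpha: float) -> str:
    if gate == "fdr" and fdr > alpha:
        return "neutral"
    if pas > 0:
        return "activated"
    if pas < 0:
        return "silenced"
    return "neutral"


def classify_timepoint(
    profile_nHx: PASProfile,
    profile_eHx: PASProfile,
    time_h: int,
    gate: Literal["sign", "fdr"] = "sign",
    alpha: float = 0.05,
    strong_threshold: float = 0.1,
    strong_criterion: Literal["per_arm_magnitude", "difference"] = "per_arm_magnitude",
) -> tuple[list[RegulationCall], TimepointSummary]:
    """Categorize every pathway by its group PAS signs in the two arms.

    ``gate='sign'`` (default) calls a pathway activated/silenced from the
    PAS sign alone; ``gate='fdr'`` additionally requires group FDR <= alpha.
    Strong inverse regulation requires opposite signs plus a magnitude
    criterion: by default the larger per-arm |PAS| must reach
    ``strong_threshold`` (inclusive); ``'difference'`` instead thresholds
    |PAS_nHx - PAS_eHx|.
    """
    ids = profile_nHx.pathway_ids
    if ids != profile_eHx.pathway_ids:
        raise ValueError("profiles cover different pathway sets")
    calls: list[RegulationCall] = []
    for pid in ids:
        pn = float(profile_nHx.group_pas[pid])
        pe = float(profile_eHx.group_pas[pid])
        sn = _status(pn, float(profile_nHx.fdr[pid]), gate, alpha)
        se = _status(pe, float(profile_eHx.fdr[pid]), gate, alpha)
        if sn != "neutral" and se != "neutral":
            category = f"common_{sn}" if sn == se else "inverse"
        elif sn != "neutral":
            category = f"unique_nHx_{sn}"
        elif se != "neutral":
            category = f"unique_eHx_{se}"
        else:
            category = "neutral"
        strong = False
        if category == "inverse":
            magnitude = (max(abs(pn), abs(pe)) if strong_criterion == "per_arm_magnitude"
                         else abs(pn - pe))
            strong = magnitude >= strong_threshold
        calls.append(RegulationCall(pid, time_h, pn, pe, sn, se, category, strong))
    counts = {c: 0 for c in CATEGORIES}
    for call in calls:
        counts[call.category] += 1
    counts = {k: v for k, v in counts.items() if v or k == "neutral"}
    return calls, TimepointSummary(time_h=time_h, counts=counts, n_pathways=len(ids))


def aggregate_unique_counts(
    summaries: Iterable[TimepointSummary], arm: str, direction: str
) -> int:
    """Total arm-specific pathway count across time points.

    A pathway unique at two time points is counted at both — the totals are
    sums of per-time-point counts, not a union over pathways.
    """
    if arm not in ("nHx", "eHx"):
        raise ValueError(f"arm must be 'nHx' or 'eHx', got {arm!r}")
    if direction not in ("activated", "silenced"):
        raise ValueError(f"direction must be 'activated' or 'silenced', got {direction!r}")
    summaries = list(summaries)
    times = [s.time_h for s in summaries]
    if len(times) != len(set(times)):
        raise ValueError(f"duplicate time points in summaries: {sorted(times)}")
    key = f"unique_{arm}_{direction}"
    return sum(s.counts.get(key, 0) for s in summaries)


def strong_inverse_set(
    calls: Iterable[RegulationCall],
    threshold: float = 0.1,
    criterion: Literal["per_arm_magnitude", "difference"] = "per_arm_magnitude",
) -> list[RegulationCall]:
    """Inversely regulated pathways meeting the magnitude criterion (inclusive >=)."""
    out = []
    for call in calls:
        if call.category != "inverse":
            continue
        magnitude = (max(abs(call.pas_nHx), abs(call.pas_eHx))
                     if criterion == "per_arm_magnitude"
                     else abs(call.pas_nHx - call.pas_eHx))
        if magnitude >= threshold:
            out.append(call)
    return out


def _pearson_distance(matrix: np.ndarray, columns: Sequence[str]) -> np.ndarray:
    sd = matrix.std(axis=0)
    bad = [c for c, s in zip(columns, sd) if s == 0]
    if bad:
        raise ValueError(f"constant column(s) under Pearson distance: {bad}")
    return pdist(matrix.T, metric="correlation")  # 1 - r


def hierarchical_clustering(
    profile_matrix: pd.DataFrame,
    distance: Literal["pearson", "euclidean"] = "pearson",
    linkage: str = "average",
) -> tuple[np.ndarray, list[str]]:
    """Average-linkage clustering of samples (columns) of a PAS matrix.

    Pearson distance is 1 − r.  Columns are pre-sorted lexicographically so
    that equal-height merges break ties deterministically by sample id.
    Returns the scipy linkage matrix and the leaf order as sample ids.
    """
    if profile_matrix.shape[1] < 2:
        raise ValueError("need at least two samples to cluster")
    ordered = profile_matrix[sorted(profile_matrix.columns)]
    x = ordered.to_numpy(dtype=float)
    if distance == "pearson":
        dist = _pearson_distance(x, list(ordered.columns))
    elif distance == "euclidean":
        dist = pdist(x.T, metric="euclidean")
    else:
        raise ValueError(f"unknown distance {distance!r}")
    z = hierarchy.linkage(dist, method=linkage)
    leaves = hierarchy.leaves_list(z)
    return z, [ordered.columns[i] for i in leaves]


def dendrogram_newick(z: np.ndarray, labels: Sequence[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree with branch lengths."""
    tree = hierarchy.to_tree(z)

    def walk(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist).rsplit(":", 1)[0] + ";"


def pca_projection(
    profile_matrix: pd.DataFrame, k: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Project samples (columns) onto the first ``k`` principal components.

    The matrix is centered per pathway internally; returns the coordinates
    (samples x k) and the explained-variance fractions, non-increasing.
    """
    if profile_matrix.shape[0] < 2:
        raise ValueError("need at least two pathways (rows) for PCA")
    x = profile_matrix.to_numpy(dtype=float).T  # samples x pathways
    x = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(x.shape) * np.finfo(float).eps)) if s.size else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")
    var = s**2
    explained = var[:k] / var.sum()
    coords = pd.DataFrame(
        u[:, :k] * s[:k],
        index=list(profile_matrix.columns),
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return coords, explained


def correlation_matrix(profile_matrix: pd.DataFrame) -> pd.DataFrame:
    """Sample-by-sample Pearson correlations, ordered by clustering leaf order."""
    x = profile_matrix.to_numpy(dtype=float)
    sd = x.std(axis=0)
    bad = [c for c, s in zip(profile_matrix.columns, sd) if s == 0]
    if bad:
        raise ValueError(f"constant sample(s): {bad}")
    corr = np.corrcoef(x.T)
    cols = list(profile_matrix.columns)
    df = pd.DataFrame(corr, index=cols, columns=cols)
    _, order = hierarchical_clustering(profile_matrix, distance="pearson")
    return df.loc[order, order]
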