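"""Cluster-number diagnostics: consensus CDF, delta area, item-consensus,
cluster-consensus and Rand indices.

A good K shows a near-binary consensus matrix: the empirical CDF of its
off-diagonal entries rises steeply at 0, stays flat, and rises steeply
again toward 1. The area under that CDF grows as K increases; the relative
gain ("delta area") flattens once additional clusters stop adding real
structure. Item-consensus (a subject's mean consensus with each cluster's
members) flags ambiguous subjects. All diagnostics are emitted as tidy
tables ready for any plotting layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .consensus import ConsensusResult
from .io_model import ConfigurationError

__all__ = [
    "ConsensusDiagnostics",
    "consensus_cdf",
    "delta_area",
    "item_consensus",
    "cluster_consensus",
    "rand_index",
    "adjusted_rand_index",
    "compute_diagnostics",
    "save_diagnostics",
]

CDF_GRID = np.linspace(0.0, 1.0, 101)  # step 0.01


def consensus_cdf(M: np.ndarray) -> tuple[pd.DataFrame, float]:
    """Empirical CDF of the strictly-upper-triangle consensus entries.

    The diagonal (identically 1) is excluded so it cannot distort the
    ascent toward 1. Returns a (x, F) table on a 101-point grid over [0, 1]
    and the trapezoidal area under the CDF.
    """
    M = np.asarray(M, dtype=float)
    n = M.shape[0]
    if n < 2:
        raise ConfigurationError("consensus CDF needs at least 2 subjects")
    v = np.sort(M[np.triu_indices(n, k=1)])
    F = np.searchsorted(v, CDF_GRID, side="right") / v.size
    area = float(np.trapezoid(F, CDF_GRID))
    return pd.DataFrame({"x": CDF_GRID, "F": F}), area


def delta_area(areas: Mapping[int, float]) -> dict[int, float]:
    """Relative change in area under the consensus CDF across K.

    For the smallest K the delta is the area itself; for larger K it is
    (A(K) - A(K-1)) / A(K-1). Requires consecutive K values; a zero
    previous area makes the delta undefined (reported as NaN).
    """
    Ks = sorted(areas)
    if Ks != list(range(Ks[0], Ks[-1] + 1)):
        raise ConfigurationError(f"delta area needs consecutive K values, got {Ks}")
    out: dict[int, float] = {}
    for i, K in enumerate(Ks):
        if i == 0:
            out[K] = float(areas[K])
        else:
            prev = areas[K - 1]
            out[K] = float((areas[K] - prev) / prev) if prev > 0 else float("nan")
    return out


def item_consensus(M: np.ndarray, labels: Sequence[int], subjects: Sequence | None = None) -> pd.DataFrame:
    """Mean consensus of each subject with the members of each cluster.

    For subject i and cluster c the value is the mean of ``M[i, j]`` over
    the members j of c with j != i (a subject's own entry is excluded). A
    subject's value against its own singleton cluster is undefined (NaN).
    """
    M = np.asarray(M, dtype=float)
    labels = np.asarray(labels)
    n = M.shape[0]
    if len(labels) != n:
        raise ConfigurationError("labels must cover all subjects in M")
    ids = list(subjects) if subjects is not None else list(range(n))
    clusters = sorted(pd.unique(labels).tolist())
    for c in clusters:
        if np.sum(labels == c) == 0:  # pragma: no cover - unique() excludes this
            raise ConfigurationError(f"empty cluster {c}")
    rows = []
    for i in range(n):
        for c in clusters:
            members = np.flatnonzero((labels == c) & (np.arange(n) != i))
            value = float(np.mean(M[i, members])) if members.size else float("nan")
            rows.append({"subject": ids[i], "cluster": c, "consensus": value,
                         "own_cluster": bool(labels[i] == c)})
    return pd.DataFrame(rows)


def cluster_consensus(M: np.ndarray, labels: Sequence[int]) -> pd.DataFrame:
    """Mean within-cluster consensus per cluster (pairs only; singleton -> NaN)."""
    M = np.asarray(M, dtype=float)
    labels = np.asarray(labels)
    rows = []
    for c in sorted(pd.unique(labels).tolist()):
        members = np.flatnonzero(labels == c)
        if members.size >= 2:
            sub = M[np.ix_(members, members)]
            value = float(np.mean(sub[np.triu_indices(members.size, k=1)]))
        else:
            value = float("nan")
        rows.append({"cluster": c, "size": int(members.size), "consensus": value})
    return pd.DataFrame(rows)


def _align_labels(labels_a, labels_b) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(labels_a, pd.Series) and isinstance(labels_b, pd.Series):
        if set(labels_a.index) != set(labels_b.index):
            raise ConfigurationError("labelings cover different subject sets")
        labels_b = labels_b.reindex(labels_a.index)
        return labels_a.to_numpy(), labels_b.to_numpy()
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ConfigurationError("labelings have different lengths")
    return a, b


def rand_index(labels_a, labels_b) -> float:
    """Plain Rand index: fraction of subject pairs on which two partitions
    agree (same cluster in both, or different in both).

    Computed from the contingency table by pair counting; symmetric and
    invariant to label renaming. Series inputs are aligned on their index.
    """
    a, b = _align_labels(labels_a, labels_b)
    n = len(a)
    if n < 2:
        raise ConfigurationError("Rand index needs at least 2 subjects")
    ct = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy()
    same_both = sum(comb(int(x), 2) for x in ct.ravel())
    same_a = sum(comb(int(x), 2) for x in ct.sum(axis=1))
    same_b = sum(comb(int(x), 2) for x in ct.sum(axis=0))
    total = comb(n, 2)
    disagreements = (same_a - same_both) + (same_b - same_both)
    return (total - disagreements) / total


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Adjusted Rand index (permutation-model chance correction)."""
    a, b = _align_labels(labels_a, labels_b)
    return float(adjusted_rand_score(a, b))


@dataclass
class ConsensusDiagnostics:
    """Tidy diagnostic tables for a consensus result."""

    cdf_table: pd.DataFrame          # columns: K, x, F
    areas: dict[int, float]          # K -> area under CDF
    deltas: dict[int, float]         # K -> delta area
    item_table: pd.DataFrame         # columns: K, subject, cluster, consensus, own_cluster
    cluster_table: pd.DataFrame      # columns: K, cluster, size, consensus

    def area_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "K": sorted(self.areas),
                "area": [self.areas[K] for K in sorted(self.areas)],
                "delta_area": [self.deltas.get(K, float("nan")) for K in sorted(self.areas)],
            }
        )


def compute_diagnostics(result: ConsensusResult) -> ConsensusDiagnostics:
    """Consensus CDF, areas, delta areas and item-/cluster-consensus per K."""
    cdf_parts, item_parts, cluster_parts = [], [], []
    areas: dict[int, float] = {}
    for K in result.K_range:
        kc = result.by_K[K]
        cdf, area = consensus_cdf(kc.matrix)
        cdf.insert(0, "K", K)
        cdf_parts.append(cdf)
        areas[K] = area
        item = item_consensus(kc.matrix, kc.final_labels.to_numpy(), result.subjects)
        item.insert(0, "K", K)
        item_parts.append(item)
        cl = cluster_consensus(kc.matrix, kc.final_labels.to_numpy())
        cl.insert(0, "K", K)
        cluster_parts.append(cl)
    Ks = sorted(areas)
    consecutive = Ks == list(range(Ks[0], Ks[-1] + 1))
    deltas = delta_area(areas) if consecutive and len(Ks) >= 1 else {Ks[0]: areas[Ks[0]]}
    return ConsensusDiagnostics(
        cdf_table=pd.concat(cdf_parts, ignore_index=True),
        areas=areas,
        deltas=deltas,
        item_table=pd.concat(item_parts, ignore_index=True),
        cluster_table=pd.concat(cluster_parts, ignore_index=True),
    )


def save_diagnostics(diag: ConsensusDiagnostics, out_dir: str | Path) -> None:
    """Write the diagnostic tables as CSVs: cdf.csv, areas.csv,
    item_consensus.csv, cluster_consensus.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    diag.cdf_table.to_csv(out / "cdf.csv", index=False)
    diag.area_frame().to_csv(out / "areas.csv", index=False)
    diag.item_table.to_csv(out / "item_consensus.csv", index=False)
    diag.cluster_table.to_csv(out / "cluster_consensus.csv", index=False)
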