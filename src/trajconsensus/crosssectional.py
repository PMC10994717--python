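"""Consensus clustering for cross-sectional mixed-type data.

Cross-sectional tables (one row per subject) do not need the longitudinal
mixture machinery: the base clusterer is hierarchical clustering on the
Gower dissimilarity, a mixed-type distance averaging range-scaled absolute
differences (continuous) and 0/1 mismatches (categorical). The consensus
and diagnostic machinery is shared with the longitudinal module.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .consensus import (
    ConsensusResult,
    KConsensus,
    build_consensus_matrix,
    final_hierarchical_partition,
)
from .io_model import ConfigurationError, VariableSpec
from .famd import _specs_for
from .mixture import canonicalize_labels

logger = logging.getLogger(__name__)

__all__ = ["gower_dissimilarity", "crosssectional_consensus_cluster"]


def gower_dissimilarity(
    rows: pd.DataFrame,
    variables: Sequence[VariableSpec] | None = None,
) -> np.ndarray:
    """Gower dissimilarity matrix for mixed-type rows.

    Continuous variables contribute |x_i - x_j| / range, categorical ones a
    0/1 mismatch; the dissimilarity is the unweighted mean over variables.
    Zero-range continuous variables carry no information and are excluded
    with a warning. The result is symmetric with zero diagonal and entries
    in [0, 1].
    """
    specs = _specs_for(rows, variables)
    n = len(rows)
    if n < 2:
        raise ConfigurationError("Gower dissimilarity needs at least 2 rows")
    total = np.zeros((n, n))
    used = 0
    for v in specs:
        if v.is_continuous:
            x = np.asarray(pd.to_numeric(rows[v.name]), dtype=float)
            rng = float(x.max() - x.min())
            if rng <= 0:
                logger.warning("zero-range continuous variable %r excluded from Gower", v.name)
                continue
            total += np.abs(x[:, None] - x[None, :]) / rng
        else:
            x = rows[v.name].astype(str).to_numpy()
            total += (x[:, None] != x[None, :]).astype(float)
        used += 1
    if used == 0:
        raise ConfigurationError("no usable variables for Gower dissimilarity")
    return total / used


def _hierarchical_cut(D: np.ndarray, K: int, linkage: str) -> np.ndarray:
    condensed = squareform((D + D.T) / 2.0, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    return canonicalize_labels(hierarchy.fcluster(Z, t=K, criterion="maxclust"))


def _pam_cut(D: np.ndarray, K: int, rng: np.random.Generator, max_iter: int = 50) -> np.ndarray:
    """Small alternating k-medoids (PAM-style) on a precomputed distance matrix."""
    n = D.shape[0]
    medoids = list(rng.choice(n, size=K, replace=False))
    for _ in range(max_iter):
        assign = np.argmin(D[:, medoids], axis=1)
        new_medoids = []
        for k in range(K):
            members = np.flatnonzero(assign == k)
            if members.size == 0:
                new_medoids.append(medoids[k])
                continue
            costs = D[np.ix_(members, members)].sum(axis=1)
            new_medoids.append(int(members[np.argmin(costs)]))
        if new_medoids == medoids:
            break
        medoids = new_medoids
    assign = np.argmin(D[:, medoids], axis=1)
    return canonicalize_labels(assign + 1)


def crosssectional_consensus_cluster(
    rows: pd.DataFrame,
    K_range: Sequence[int],
    *,
    id_col: str | None = None,
    variables: Sequence[VariableSpec] | None = None,
    reps: int = 100,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    linkage: str = "average",
    inner: str = "hierarchical",
    rep_offset: int = 0,
) -> ConsensusResult:
    """Consensus clustering of cross-sectional mixed-type rows.

    Per run: subsample subjects without replacement, compute the Gower
    dissimilarity on the subsample, cluster it (average-linkage
    hierarchical by default; ``inner="pam"`` for k-medoids) cut at K, and
    feed the assignments into the shared consensus machinery. The final
    partition per K cuts the hierarchical clustering of 1 - consensus.
    """
    if inner not in ("hierarchical", "pam"):
        raise ConfigurationError(f"inner must be 'hierarchical' or 'pam', got {inner!r}")
    if not (0 < subsample_fraction <= 1):
        raise ConfigurationError(f"subsample_fraction must be in (0, 1], got {subsample_fraction}")
    if reps < 1:
        raise ConfigurationError(f"reps must be >= 1, got {reps}")
    if id_col is not None:
        subjects = list(rows[id_col])
        value_rows = rows.drop(columns=[id_col])
    else:
        subjects = list(rows.index)
        value_rows = rows
    if len(set(subjects)) != len(subjects):
        raise ConfigurationError("duplicate subject ids in cross-sectional rows")
    n = len(subjects)
    m = math.ceil(subsample_fraction * n)
    K_range = sorted(int(K) for K in K_range)
    for K in K_range:
        if K > m:
            raise ConfigurationError(
                f"K={K} exceeds the subsample size ceil({subsample_fraction} * {n}) = {m}"
            )
    specs = _specs_for(value_rows, variables)

    by_K: dict[int, KConsensus] = {}
    for K in K_range:
        run_assignments = []
        runs_meta = []
        for rep in range(reps):
            rng = np.random.default_rng([int(seed), int(K), int(rep_offset + rep)])
            chosen = rng.choice(n, size=m, replace=False)
            chosen.sort()
            sampled = [subjects[i] for i in chosen]
            D = gower_dissimilarity(value_rows.iloc[chosen], specs)
            if inner == "hierarchical":
                labels = _hierarchical_cut(D, K, linkage)
            else:
                labels = _pam_cut(D, K, rng)
            run_assignments.append((sampled, labels))
            runs_meta.append(
                {"K": K, "rep": rep_offset + rep,
                 "subjects": [str(s) for s in sampled],
                 "labels": [int(l) for l in labels]}
            )
        M, N, warnings = build_consensus_matrix(run_assignments, subjects)
        labels, Z = final_hierarchical_partition(M, K, linkage=linkage)
        by_K[K] = KConsensus(
            K=K, matrix=M, counts=N,
            final_labels=pd.Series(labels, index=pd.Index(subjects, name="subject"), name="cluster"),
            linkage_matrix=Z, runs=runs_meta, n_skipped=0, warnings=warnings,
        )
    settings = {
        "mode": "crosssectional",
        "K_range": K_range,
        "reps": reps,
        "subsample_fraction": subsample_fraction,
        "seed": int(seed),
        "rep_offset": int(rep_offset),
        "linkage": linkage,
        "inner": inner,
        "n_subjects": n,
        "subsample_size": m,
    }
    return ConsensusResult(subjects=subjects, K_range=K_range, by_K=by_K, settings=settings)
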