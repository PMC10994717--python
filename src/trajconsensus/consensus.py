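"""Subsample-based consensus clustering for longitudinal mixture models.

Consensus clustering (in the Monti resampling sense) runs the base
clusterer many times on random subject subsamples and records, for every
pair of subjects, the fraction of co-sampled runs in which the pair landed
in the same cluster. That consensus matrix is then clustered once more by
hierarchical clustering of the distance 1 - consensus, giving the final
partition for each candidate cluster number K. Stability of the entries
near 0/1 is the signal that K fits the data (see the diagnostics module).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io_model import ConfigurationError, LongitudinalDataset
from .mixture import (
    DegenerateModelError,
    build_time_basis,
    canonicalize_labels,
    fit_longitudinal_mixture,
    posterior_assignments,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ConsensusResult",
    "KConsensus",
    "longitudinal_consensus_cluster",
    "build_consensus_matrix",
    "final_hierarchical_partition",
    "merge_consensus",
    "save_consensus",
]

LINKAGE_METHODS = ("average", "single", "complete", "ward")


@dataclass
class KConsensus:
    """Consensus results for one candidate cluster count K."""

    K: int
    matrix: np.ndarray            # subjects x subjects consensus fractions
    counts: np.ndarray            # co-sampling counts (denominators)
    final_labels: pd.Series       # subject -> cluster (1..K)
    linkage_matrix: np.ndarray    # scipy merge history
    runs: list[dict] = field(default_factory=list)  # per-run subsample + labels
    n_skipped: int = 0
    warnings: list[str] = field(default_factory=list)


@dataclass
class ConsensusResult:
    """Per-K consensus matrices, final partitions and run provenance."""

    subjects: list
    K_range: list[int]
    by_K: dict[int, KConsensus]
    settings: dict

    def labels_frame(self) -> pd.DataFrame:
        """Wide table: subject_id plus one cluster column per K."""
        out = pd.DataFrame({"subject_id": self.subjects})
        for K in self.K_range:
            out[f"cluster_K{K}"] = self.by_K[K].final_labels.to_numpy()
        return out


def build_consensus_matrix(
    run_assignments: Sequence[tuple[Sequence, Sequence[int]]],
    subjects: Sequence,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Accumulate connectivity and co-sampling counts over runs.

    ``run_assignments`` is a list of ``(sampled_subjects, labels)`` pairs,
    the labels covering exactly the sampled subjects in order. Returns
    ``(M, N, warnings)`` where ``M[i, j]`` is the fraction of runs sampling
    both i and j in which they were co-clustered, ``N`` holds the
    denominators, and pairs never co-sampled get ``M = N = 0`` and a
    warning.
    """
    subjects = list(subjects)
    index = {s: i for i, s in enumerate(subjects)}
    n = len(subjects)
    conn = np.zeros((n, n))
    count = np.zeros((n, n))
    for sampled, labels in run_assignments:
        sampled = list(sampled)
        labels = np.asarray(labels)
        if len(sampled) != len(labels):
            raise ConfigurationError("labels must cover exactly the sampled subjects")
        unknown = [s for s in sampled if s not in index]
        if unknown:
            raise ConfigurationError(f"labels supplied for unsampled/unknown subjects: {unknown}")
        idx = np.fromiter((index[s] for s in sampled), dtype=np.intp, count=len(sampled))
        same = (labels[:, None] == labels[None, :]).astype(float)
        conn[np.ix_(idx, idx)] += same
        count[np.ix_(idx, idx)] += 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        M = np.where(count > 0, conn / np.maximum(count, 1.0), 0.0)
    warnings: list[str] = []
    never = np.argwhere((count == 0) & ~np.eye(n, dtype=bool))
    if len(never):
        pairs = sorted({(min(i, j), max(i, j)) for i, j in never})
        sample = ", ".join(f"({subjects[i]}, {subjects[j]})" for i, j in pairs[:5])
        msg = f"{len(pairs)} subject pair(s) never co-sampled (consensus set to 0): {sample}"
        warnings.append(msg)
        logger.warning(msg)
    return M, count, warnings


def final_hierarchical_partition(
    M: np.ndarray,
    K: int,
    *,
    linkage: str = "average",
) -> tuple[np.ndarray, np.ndarray]:
    """Cut a hierarchical clustering of distance 1 - M into K clusters.

    Returns ``(labels, linkage_matrix)`` with labels canonicalized by
    decreasing cluster size (ties by first subject). If the maxclust cut
    yields fewer than K non-empty clusters this is logged as a warning.
    """
    n = M.shape[0]
    if K > n:
        raise ConfigurationError(f"K={K} exceeds number of subjects ({n})")
    if linkage not in LINKAGE_METHODS:
        raise ConfigurationError(f"linkage must be one of {LINKAGE_METHODS}, got {linkage!r}")
    D = 1.0 - M
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    condensed = squareform(D, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    raw = hierarchy.fcluster(Z, t=K, criterion="maxclust")
    labels = canonicalize_labels(raw)
    found = len(np.unique(labels))
    if found < K:
        logger.warning("dendrogram cut yielded %d < K=%d non-empty clusters", found, K)
    return labels, Z


def longitudinal_consensus_cluster(
    ds: LongitudinalDataset,
    K_range: Sequence[int],
    *,
    reps: int = 100,
    subsample_fraction: float = 0.8,
    df: int = 3,
    penalty_weight: float = 0.0,
    seed: int = 0,
    linkage: str = "average",
    n_init: int = 1,
    max_iter: int = 200,
    tol: float = 1e-6,
    min_variance: float = 1e-10,
    variance_floor: float = 0.0,
    rep_offset: int = 0,
) -> ConsensusResult:
    """Consensus clustering of a reduced longitudinal dataset.

    For each K in ``K_range`` and each of ``reps`` runs, a fraction
    ``subsample_fraction`` of the subjects is drawn without replacement
    (all their visits travel with them), the K-component spline mixture is
    fitted on the subsample, and the MAP assignments are recorded. The
    per-K consensus matrix is the elementwise ratio of co-clustering to
    co-sampling counts; the final partition cuts an average-linkage
    hierarchical clustering of 1 - consensus at K.

    Runs are fully reproducible from ``seed``: the run for (K, rep) uses an
    RNG stream derived from ``(seed, K, rep_offset + rep)``, so two batches
    with matching offsets can be merged exactly (:func:`merge_consensus`).
    A run whose mixture degenerates even after restarts is skipped with a
    warning and the counts are adjusted (``reps`` is an upper bound).
    """
    bad = [v.name for v in ds.variables if not v.is_continuous]
    if bad:
        raise ConfigurationError(
            f"consensus clustering expects continuous (reduced) variables; categorical: {bad}"
        )
    if not (0 < subsample_fraction <= 1):
        raise ConfigurationError(f"subsample_fraction must be in (0, 1], got {subsample_fraction}")
    if reps < 1:
        raise ConfigurationError(f"reps must be >= 1, got {reps}")
    subjects = ds.subjects
    n = len(subjects)
    m = math.ceil(subsample_fraction * n)
    K_range = sorted(int(K) for K in K_range)
    for K in K_range:
        if K > m:
            raise ConfigurationError(
                f"K={K} exceeds the subsample size ceil({subsample_fraction} * {n}) = {m}"
            )

    basis = build_time_basis(ds.times, df=df, penalty_weight=penalty_weight)
    subj_array = np.asarray(subjects, dtype=object)

    by_K: dict[int, KConsensus] = {}
    for K in K_range:
        run_assignments: list[tuple[list, np.ndarray]] = []
        runs_meta: list[dict] = []
        n_skipped = 0
        for rep in range(reps):
            rng = np.random.default_rng([int(seed), int(K), int(rep_offset + rep)])
            chosen = rng.choice(n, size=m, replace=False)
            chosen.sort()
            sampled = list(subj_array[chosen])
            sub = ds.subset_subjects(sampled)
            try:
                fit = fit_longitudinal_mixture(
                    sub, K, basis=basis, seed=rng, max_iter=max_iter,
                    tol=tol, n_init=n_init, min_variance=min_variance,
                    variance_floor=variance_floor,
                )
            except DegenerateModelError as exc:
                n_skipped += 1
                logger.warning("run (K=%d, rep=%d) skipped: %s", K, rep_offset + rep, exc)
                continue
            labels = posterior_assignments(fit)
            labels = labels.reindex(sampled)
            run_assignments.append((sampled, labels.to_numpy()))
            runs_meta.append(
                {
                    "K": K,
                    "rep": rep_offset + rep,
                    "subjects": [str(s) for s in sampled],
                    "labels": [int(l) for l in labels.to_numpy()],
                    "loglik": fit.loglik,
                    "converged": bool(fit.converged),
                }
            )
        if not run_assignments:
            raise DegenerateModelError(f"all {reps} runs degenerate for K={K}")
        M, N, warnings = build_consensus_matrix(run_assignments, subjects)
        labels, Z = final_hierarchical_partition(M, K, linkage=linkage)
        by_K[K] = KConsensus(
            K=K,
            matrix=M,
            counts=N,
            final_labels=pd.Series(labels, index=pd.Index(subjects, name="subject"), name="cluster"),
            linkage_matrix=Z,
            runs=runs_meta,
            n_skipped=n_skipped,
            warnings=warnings,
        )

    settings = {
        "K_range": K_range,
        "reps": reps,
        "subsample_fraction": subsample_fraction,
        "df": df,
        "penalty_weight": penalty_weight,
        "seed": int(seed),
        "rep_offset": int(rep_offset),
        "linkage": linkage,
        "n_init": n_init,
        "max_iter": max_iter,
        "tol": tol,
        "min_variance": min_variance,
        "variance_floor": variance_floor,
        "n_subjects": n,
        "subsample_size": m,
    }
    return ConsensusResult(subjects=subjects, K_range=K_range, by_K=by_K, settings=settings)


def merge_consensus(a: ConsensusResult, b: ConsensusResult, *, linkage: str | None = None) -> ConsensusResult:
    """Count-weighted merge of two consensus batches over the same subjects.

    ``M_merged * N_merged = M_a * N_a + M_b * N_b`` elementwise; the final
    partitions are recomputed from the merged matrices. Running one batch of
    ``reps = R1 + R2`` equals merging batches of R1 and R2 run with
    ``rep_offset`` 0 and R1 and the same seed.
    """
    if list(a.subjects) != list(b.subjects):
        raise ConfigurationError("cannot merge consensus results over different subjects")
    if a.K_range != b.K_range:
        raise ConfigurationError("cannot merge consensus results over different K ranges")
    linkage = linkage or a.settings.get("linkage", "average")
    by_K: dict[int, KConsensus] = {}
    for K in a.K_range:
        ka, kb = a.by_K[K], b.by_K[K]
        counts = ka.counts + kb.counts
        conn = ka.matrix * ka.counts + kb.matrix * kb.counts
        with np.errstate(invalid="ignore", divide="ignore"):
            M = np.where(counts > 0, conn / np.maximum(counts, 1.0), 0.0)
        labels, Z = final_hierarchical_partition(M, K, linkage=linkage)
        by_K[K] = KConsensus(
            K=K, matrix=M, counts=counts,
            final_labels=pd.Series(labels, index=pd.Index(a.subjects, name="subject"), name="cluster"),
            linkage_matrix=Z,
            runs=ka.runs + kb.runs,
            n_skipped=ka.n_skipped + kb.n_skipped,
            warnings=ka.warnings + kb.warnings,
        )
    settings = dict(a.settings)
    settings["reps"] = a.settings.get("reps", 0) + b.settings.get("reps", 0)
    settings["merged_from"] = [a.settings, b.settings]
    return ConsensusResult(subjects=list(a.subjects), K_range=list(a.K_range), by_K=by_K, settings=settings)


def save_consensus(result: ConsensusResult, out_dir: str | Path) -> None:
    """Serialize a ConsensusResult to a directory.

    Layout: ``settings.json``; per-K ``consensus_K<k>.csv`` (square, subject
    ids as row/column headers); ``labels.csv`` (subject_id, cluster per K);
    ``runs.jsonl`` (one line per run: subsample + labels) for provenance.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    settings = dict(result.settings)
    settings["warnings"] = {K: result.by_K[K].warnings for K in result.K_range}
    settings["n_skipped"] = {K: result.by_K[K].n_skipped for K in result.K_range}
    (out / "settings.json").write_text(json.dumps(settings, indent=1, default=str))
    ids = [str(s) for s in result.subjects]
    for K in result.K_range:
        mat = pd.DataFrame(result.by_K[K].matrix, index=ids, columns=ids)
        mat.to_csv(out / f"consensus_K{K}.csv")
    result.labels_frame().to_csv(out / "labels.csv", index=False)
    with (out / "runs.jsonl").open("w") as fh:
        for K in result.K_range:
            for run in result.by_K[K].runs:
                fh.write(json.dumps(run) + "\n")
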