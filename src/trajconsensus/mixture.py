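"""Finite mixture of multivariate spline regressions over time, fitted by EM.

The model: each latent component k has, for every response j (typically a
FAMD factor score), its own smooth mean trajectory b(t)'beta_{k,j} with
Gaussian noise variance sigma2_{k,j}. Responses are treated as independent
given the component (they are orthogonal factor scores, which partially
justifies this). Repeated measurements are grouped at the subject level:
the component membership is a property of the subject, so the E-step
responsibility of subject i multiplies the likelihoods of *all* of i's
visits across all responses,

    r_{i,k} ∝ pi_k * prod_{t in visits(i)} prod_j N(y_{i,t,j} | b(t)'beta_{k,j}, sigma2_{k,j}).

The M-step is a per-(component, response) weighted least squares with the
subject responsibilities replicated over the subject's rows, plus the usual
weighted residual variance and prior updates. The time smoother is a
natural cubic regression spline with knots at quantiles of the observed
times (a low-rank smoother; with the few visit times typical of cohort
studies its span matches any other low-rank smoother), with an optional
second-derivative roughness penalty.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .io_model import ConfigurationError, LongitudinalDataset

logger = logging.getLogger(__name__)

__all__ = [
    "SplineBasis",
    "MixtureFit",
    "DegenerateModelError",
    "build_time_basis",
    "fit_longitudinal_mixture",
    "posterior_assignments",
]


class DegenerateModelError(RuntimeError):
    """A component's residual variance collapsed and restarts did not help."""


@dataclass
class SplineBasis:
    """Natural cubic regression spline basis over time, intercept included.

    ``df`` counts the intercept: df=1 is the intercept-only basis, df=2
    spans {1, t}, df>=3 adds natural cubic spline terms with knots at
    quantiles of the distinct training times.
    """

    knots: np.ndarray
    df: int
    times: np.ndarray
    basis_matrix: np.ndarray
    penalty: np.ndarray | None = None
    penalty_weight: float = 0.0

    def evaluate(self, times: np.ndarray) -> np.ndarray:
        """Evaluate the basis functions at new time points."""
        return _natural_spline_design(np.asarray(times, dtype=float), self.knots, self.df)

    @property
    def effective_penalty(self) -> np.ndarray | None:
        if self.penalty is None or self.penalty_weight <= 0:
            return None
        return self.penalty_weight * self.penalty


def _natural_spline_design(t: np.ndarray, knots: np.ndarray, df: int) -> np.ndarray:
    n = len(t)
    if df == 1:
        return np.ones((n, 1))
    if df == 2:
        return np.column_stack([np.ones(n), t])
    # natural cubic truncated-power basis: 1, t, N_3..N_df with df knots
    K = len(knots)
    xi = knots

    def d(k: int, x: np.ndarray) -> np.ndarray:
        num = np.maximum(x - xi[k], 0.0) ** 3 - np.maximum(x - xi[K - 1], 0.0) ** 3
        return num / (xi[K - 1] - xi[k])

    cols = [np.ones(n), t]
    dK2 = d(K - 2, t)
    for k in range(K - 2):
        cols.append(d(k, t) - dK2)
    return np.column_stack(cols)


def _penalty_matrix(knots: np.ndarray, df: int, n_grid: int = 2001) -> np.ndarray:
    """Integrated squared second derivative of each basis pair, by quadrature."""
    if df <= 2:
        return np.zeros((df, df))
    lo, hi = float(knots[0]), float(knots[-1])
    grid = np.linspace(lo, hi, n_grid)
    h = grid[1] - grid[0]
    B = _natural_spline_design(grid, knots, df)
    # central second differences; endpoints dropped
    D2 = (B[2:] - 2 * B[1:-1] + B[:-2]) / h**2
    inner = np.linspace(lo + h, hi - h, n_grid - 2)
    Omega = np.zeros((df, df))
    for a in range(df):
        for b in range(a, df):
            val = np.trapezoid(D2[:, a] * D2[:, b], inner)
            Omega[a, b] = Omega[b, a] = val
    return Omega


def build_time_basis(
    times: Sequence[float] | np.ndarray,
    df: int = 3,
    penalty_weight: float = 0.0,
) -> SplineBasis:
    """Build the spline basis for a vector of (per-row) observation times.

    If there are fewer distinct times than ``df``, the basis dimension is
    reduced to the number of distinct times with a logged warning. The
    optional roughness penalty (``penalty_weight > 0``) is the matrix of
    integrated squared second derivatives, scaled by ``penalty_weight``;
    the default 0 yields unpenalized regression splines.
    """
    if df < 1:
        raise ConfigurationError(f"df must be >= 1, got {df}")
    t = np.asarray(times, dtype=float)
    distinct = np.unique(t)
    if len(distinct) < df:
        logger.warning(
            "only %d distinct time values; reducing spline df from %d to %d",
            len(distinct), df, len(distinct),
        )
        df = len(distinct)
    if df >= 3:
        knots = np.quantile(distinct, np.linspace(0.0, 1.0, df))
    else:
        knots = np.array([distinct.min(), distinct.max()]) if len(distinct) > 1 else distinct.copy()
    B = _natural_spline_design(t, knots, df)
    if np.linalg.matrix_rank(B) < df:  # pragma: no cover - guarded by knot placement
        raise ConfigurationError("spline basis is rank deficient on the training times")
    penalty = _penalty_matrix(knots, df) if penalty_weight > 0 else None
    return SplineBasis(
        knots=knots, df=df, times=t, basis_matrix=B,
        penalty=penalty, penalty_weight=float(penalty_weight),
    )


@dataclass
class MixtureFit:
    """EM-fitted K-component mixture of spline regressions.

    ``coefficients`` has shape (K, J, df); ``variances`` (K, J);
    ``responsibilities`` (#subjects, K), one row per subject (not per
    visit), each summing to 1. ``bic = -2 loglik + n_parameters *
    log(#subjects)`` with ``n_parameters = (K-1) + K*J*(df+1)`` (df spline
    coefficients plus one variance per component x response).
    """

    K: int
    priors: np.ndarray
    coefficients: np.ndarray
    variances: np.ndarray
    responsibilities: np.ndarray
    subjects: list
    response_names: list[str]
    basis: SplineBasis
    loglik_trace: np.ndarray
    loglik: float
    n_parameters: int
    bic: float
    converged: bool
    n_iter: int
    n_restarts: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "K": self.K,
                "priors": self.priors.tolist(),
                "coefficients": self.coefficients.tolist(),
                "variances": self.variances.tolist(),
                "loglik_trace": self.loglik_trace.tolist(),
                "loglik": self.loglik,
                "n_parameters": self.n_parameters,
                "bic": self.bic,
                "converged": self.converged,
                "n_iter": self.n_iter,
                "response_names": list(self.response_names),
            },
            indent=1,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def _em_once(
    Y: np.ndarray,
    B: np.ndarray,
    subject_idx: np.ndarray,
    n_subjects: int,
    K: int,
    rng: np.random.Generator,
    *,
    max_iter: int,
    tol: float,
    penalty: np.ndarray | None,
    min_variance: float,
    variance_floor: float,
) -> dict | None:
    """One EM run from random Dirichlet responsibilities.

    Returns None if a component's variance collapses below ``min_variance``
    (degenerate run); the caller decides whether to restart.
    """
    n_rows, J = Y.shape
    df = B.shape[1]
    R = rng.dirichlet(np.ones(K), size=n_subjects)  # subject responsibilities
    trace: list[float] = []
    loglik = -np.inf
    converged = False
    priors = np.full(K, 1.0 / K)
    beta = np.zeros((K, J, df))
    sigma2 = np.ones((K, J))
    for it in range(max_iter):
        # ---- M-step from current responsibilities
        W = R[subject_idx]  # n_rows x K
        priors = R.mean(axis=0)
        for k in range(K):
            w = W[:, k]
            Bw = B * w[:, None]
            G = B.T @ Bw
            if penalty is not None:
                G = G + penalty
            rhs = Bw.T @ Y
            try:
                bk = np.linalg.solve(G, rhs)
            except np.linalg.LinAlgError:
                bk, *_ = np.linalg.lstsq(G, rhs, rcond=None)
            beta[k] = bk.T
            resid = Y - B @ bk
            wsum = max(w.sum(), 1e-300)
            sigma2[k] = (w[:, None] * resid**2).sum(axis=0) / wsum
        if variance_floor > 0:
            sigma2 = np.maximum(sigma2, variance_floor)
        if np.any(sigma2 < min_variance):
            return None
        # ---- E-step
        row_ll = np.empty((n_rows, K))
        for k in range(K):
            resid = Y - B @ beta[k].T
            row_ll[:, k] = -0.5 * np.sum(
                np.log(2 * np.pi * sigma2[k]) + resid**2 / sigma2[k], axis=1
            )
        subj_ll = np.zeros((n_subjects, K))
        np.add.at(subj_ll, subject_idx, row_ll)
        A = np.log(priors)[None, :] + subj_ll
        per_subject = logsumexp(A, axis=1)
        new_loglik = float(per_subject.sum())
        R = np.exp(A - per_subject[:, None])
        trace.append(new_loglik)
        if np.isfinite(loglik) and abs(new_loglik - loglik) <= tol * (abs(loglik) + 1e-12):
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik
    return {
        "priors": priors,
        "beta": beta,
        "sigma2": sigma2,
        "R": R,
        "trace": np.asarray(trace),
        "loglik": loglik,
        "converged": converged,
        "n_iter": len(trace),
    }


def fit_longitudinal_mixture(
    responses: LongitudinalDataset,
    K: int,
    *,
    basis: SplineBasis | None = None,
    df: int = 3,
    penalty_weight: float = 0.0,
    seed: int | np.random.Generator = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
    n_init: int = 5,
    min_variance: float = 1e-10,
    variance_floor: float = 0.0,
    max_restarts: int = 5,
) -> MixtureFit:
    """Fit the K-component longitudinal mixture by EM.

    ``responses`` must contain only continuous variables (e.g. FAMD
    scores). Initialization draws subject responsibilities from a symmetric
    Dirichlet; the best of ``n_init`` runs by final log-likelihood is
    returned, and all randomness derives from ``seed``. A run whose
    residual variance collapses below ``min_variance`` is restarted with a
    fresh sub-seed up to ``max_restarts`` times, then a
    :class:`DegenerateModelError` is raised. For (near-)noise-free data a
    positive ``variance_floor`` clamps the variances instead, keeping the
    model proper without tripping the degeneracy check.
    """
    bad = [v.name for v in responses.variables if not v.is_continuous]
    if bad:
        raise ConfigurationError(f"responses must be continuous; categorical: {bad}")
    if K < 1:
        raise ConfigurationError(f"K must be >= 1, got {K}")
    subjects = responses.subjects
    n_subjects = len(subjects)
    if K > n_subjects:
        raise ConfigurationError(f"K={K} exceeds number of subjects ({n_subjects})")

    Y = responses.values().to_numpy(dtype=float)
    codes = pd.Categorical(
        responses.data[responses.id_col], categories=subjects
    ).codes.astype(np.intp)
    if basis is None:
        basis = build_time_basis(responses.times, df=df, penalty_weight=penalty_weight)
        B = basis.basis_matrix
    else:
        B = basis.evaluate(responses.times)
    penalty = basis.effective_penalty

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    best: dict | None = None
    restarts_used = 0
    for _ in range(n_init):
        result = None
        for attempt in range(max_restarts + 1):
            run_rng = np.random.default_rng(rng.integers(2**31))
            result = _em_once(
                Y, B, codes, n_subjects, K, run_rng,
                max_iter=max_iter, tol=tol, penalty=penalty,
                min_variance=min_variance, variance_floor=variance_floor,
            )
            if result is not None:
                break
            restarts_used += 1
            logger.warning("degenerate component variance; restarting EM (attempt %d)", attempt + 1)
        if result is None:
            raise DegenerateModelError(
                f"component variance collapsed below {min_variance} in all "
                f"{max_restarts + 1} attempts (K={K}); consider fewer components "
                "or a higher min_variance"
            )
        if best is None or result["loglik"] > best["loglik"]:
            best = result

    assert best is not None
    J = Y.shape[1]
    n_parameters = (K - 1) + K * J * (basis.df + 1)
    bic = -2.0 * best["loglik"] + n_parameters * np.log(n_subjects)
    return MixtureFit(
        K=K,
        priors=best["priors"],
        coefficients=best["beta"],
        variances=best["sigma2"],
        responsibilities=best["R"],
        subjects=subjects,
        response_names=[v.name for v in responses.variables],
        basis=basis,
        loglik_trace=best["trace"],
        loglik=best["loglik"],
        n_parameters=n_parameters,
        bic=float(bic),
        converged=best["converged"],
        n_iter=best["n_iter"],
        n_restarts=restarts_used,
    )


def posterior_assignments(fit: MixtureFit) -> pd.Series:
    """MAP cluster label per subject, with canonical labels.

    Ties in the posterior go to the lowest component index. Labels are then
    canonicalized so they do not depend on the arbitrary component order:
    clusters are numbered 1, 2, ... by decreasing size, ties broken by the
    position of the cluster's first subject.
    """
    R = fit.responsibilities
    raw = np.argmax(R, axis=1)  # argmax takes the lowest index on exact ties
    return pd.Series(
        canonicalize_labels(raw), index=pd.Index(fit.subjects, name="subject"),
        name="cluster",
    )


def canonicalize_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..K by decreasing size; ties by first occurrence."""
    raw = np.asarray(raw)
    uniq = pd.unique(raw)
    sizes = {u: int(np.sum(raw == u)) for u in uniq}
    first = {u: int(np.argmax(raw == u)) for u in uniq}
    order = sorted(uniq, key=lambda u: (-sizes[u], first[u]))
    mapping = {u: i + 1 for i, u in enumerate(order)}
    return np.asarray([mapping[u] for u in raw], dtype=int)
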