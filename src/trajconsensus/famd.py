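"""Factor Analysis of Mixed Data (FAMD).

FAMD is the principal-component method for tables mixing continuous and
categorical variables: continuous columns are standardized (unit variance),
each categorical variable is expanded into indicator columns weighted by
1/sqrt(level proportion) and centered, and the combined matrix is decomposed
by SVD. Continuous variables then each contribute inertia 1 and a
categorical variable with q levels contributes inertia q - 1, so both types
are balanced in the decomposition. Factor scores are orthogonal continuous
components suitable as responses for downstream model-based clustering.

The per-group reduction (:func:`reduce_by_groups`) fits one FAMD per named
variable group on the stacked long-format rows (subject x visit), so a
single loading set serves every time point and the scores keep their
longitudinal structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import (
    CATEGORICAL,
    CONTINUOUS,
    ConfigurationError,
    LongitudinalDataset,
    VariableSpec,
)

__all__ = [
    "FAMDModel",
    "fit_famd",
    "transform_famd",
    "reduce_by_groups",
    "regress_out_covariates",
    "encode_mixed",
]

_RANK_TOL = 1e-10


@dataclass
class FAMDModel:
    """Fitted FAMD: standardization parameters, loadings and eigenvalues.

    ``eigenvalues`` holds the *full* spectrum of the decomposition (its sum
    equals #continuous + sum_j (q_j - 1)); ``loadings`` and ``scores`` are
    truncated to ``n_components``. Component signs are fixed so that each
    component's largest-magnitude loading is positive.
    """

    variables: tuple[VariableSpec, ...]
    continuous_means: dict[str, float]
    continuous_sds: dict[str, float]
    level_proportions: dict[str, dict[str, float]]
    column_labels: tuple[str, ...]
    loadings: np.ndarray        # p_expanded x n_components
    eigenvalues: np.ndarray     # full spectrum, non-increasing
    n_components: int
    scores: np.ndarray          # n_train x n_components

    @property
    def total_inertia(self) -> float:
        return float(np.sum(self.eigenvalues))

    def explained_inertia(self) -> np.ndarray:
        return self.eigenvalues / self.total_inertia

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "variables": [
                {"name": v.name, "kind": v.kind, "levels": list(v.levels) if v.levels else None}
                for v in self.variables
            ],
            "continuous_means": self.continuous_means,
            "continuous_sds": self.continuous_sds,
            "level_proportions": self.level_proportions,
            "column_labels": list(self.column_labels),
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "n_components": self.n_components,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FAMDModel":
        d = json.loads(text)
        variables = tuple(
            VariableSpec(v["name"], v["kind"], tuple(v["levels"]) if v["levels"] else None)
            for v in d["variables"]
        )
        return cls(
            variables=variables,
            continuous_means={k: float(v) for k, v in d["continuous_means"].items()},
            continuous_sds={k: float(v) for k, v in d["continuous_sds"].items()},
            level_proportions={k: {l: float(p) for l, p in v.items()} for k, v in d["level_proportions"].items()},
            column_labels=tuple(d["column_labels"]),
            loadings=np.asarray(d["loadings"], dtype=float),
            eigenvalues=np.asarray(d["eigenvalues"], dtype=float),
            n_components=int(d["n_components"]),
            scores=np.empty((0, int(d["n_components"]))),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "FAMDModel":
        return cls.from_json(Path(path).read_text())


def _specs_for(df: pd.DataFrame, variables: Sequence[VariableSpec] | None) -> tuple[VariableSpec, ...]:
    if variables is not None:
        return tuple(variables)
    out: list[VariableSpec] = []
    for c in df.columns:
        if pd.api.types.is_numeric_dtype(df[c]):
            out.append(VariableSpec(str(c), CONTINUOUS))
        else:
            levels = tuple(sorted({str(v) for v in pd.unique(df[c])}))
            out.append(VariableSpec(str(c), CATEGORICAL, levels))
    return tuple(out)


def encode_mixed(
    df: pd.DataFrame,
    variables: Sequence[VariableSpec],
    continuous_means: Mapping[str, float],
    continuous_sds: Mapping[str, float],
    level_proportions: Mapping[str, Mapping[str, float]],
) -> tuple[np.ndarray, list[str]]:
    """Build the weighted, centered FAMD design matrix for ``df``.

    Continuous variable x -> (x - mean)/sd. Categorical level l with
    proportion p_l -> (1{x = l} - p_l)/sqrt(p_l). Returns the matrix and the
    expanded column labels (``name`` for continuous, ``name=level`` for
    indicator columns).
    """
    cols: list[np.ndarray] = []
    labels: list[str] = []
    n = len(df)
    for v in variables:
        if v.is_continuous:
            x = np.asarray(pd.to_numeric(df[v.name]), dtype=float)
            cols.append((x - continuous_means[v.name]) / continuous_sds[v.name])
            labels.append(v.name)
        else:
            values = df[v.name].astype(str).to_numpy()
            props = level_proportions[v.name]
            unknown = sorted(set(values) - set(props))
            if unknown:
                raise ConfigurationError(
                    f"variable {v.name!r}: unseen categorical level(s) {unknown}"
                )
            for level in v.levels or ():
                p = props[level]
                ind = (values == level).astype(float)
                cols.append((ind - p) / np.sqrt(p))
                labels.append(f"{v.name}={level}")
    Z = np.column_stack(cols) if cols else np.empty((n, 0))
    return Z, labels


def fit_famd(
    ds_rows: pd.DataFrame | LongitudinalDataset,
    n_components: int | None = None,
    *,
    variables: Sequence[VariableSpec] | None = None,
) -> FAMDModel:
    """Fit FAMD to a table of mixed-type rows.

    Parameters
    ----------
    ds_rows
        Either a plain DataFrame of observation columns or a
        :class:`LongitudinalDataset` (its stacked value rows are used and
        its specs are taken unless ``variables`` is given).
    n_components
        Number of components to keep; defaults to the full rank.

    Raises
    ------
    ConfigurationError
        On a constant continuous variable (named), a declared-but-unobserved
        categorical level, fewer than 2 rows, or ``n_components`` above the
        rank of the decomposition.
    """
    if isinstance(ds_rows, LongitudinalDataset):
        if variables is None:
            variables = ds_rows.variables
        df = ds_rows.values()
    else:
        df = ds_rows
        variables = _specs_for(df, variables)
    variables = tuple(variables)
    n = len(df)
    if n < 2:
        raise ConfigurationError("FAMD needs at least 2 rows")

    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    proportions: dict[str, dict[str, float]] = {}
    for v in variables:
        if v.is_continuous:
            x = np.asarray(pd.to_numeric(df[v.name]), dtype=float)
            mu = float(np.mean(x))
            sd = float(np.std(x))  # population sd: inertia of the column is exactly 1
            if sd <= 0:
                raise ConfigurationError(f"continuous variable {v.name!r} is constant")
            means[v.name] = mu
            sds[v.name] = sd
        else:
            values = df[v.name].astype(str).to_numpy()
            props = {}
            for level in v.levels or ():
                p = float(np.mean(values == level))
                if p <= 0:
                    raise ConfigurationError(
                        f"categorical variable {v.name!r}: declared level {level!r} never observed"
                    )
                props[level] = p
            proportions[v.name] = props

    Z, labels = encode_mixed(df, variables, means, sds, proportions)
    U, s, Vt = np.linalg.svd(Z / np.sqrt(n), full_matrices=False)
    eigenvalues = s**2
    rank = int(np.sum(s > _RANK_TOL * max(s[0], 1.0))) if s.size else 0
    if n_components is None:
        n_components = rank
    if n_components < 1 or n_components > rank:
        raise ConfigurationError(
            f"n_components={n_components} outside [1, rank={rank}]"
        )
    V = Vt.T[:, :n_components].copy()
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(n_components):
        j = int(np.argmax(np.abs(V[:, k])))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
    scores = Z @ V
    return FAMDModel(
        variables=variables,
        continuous_means=means,
        continuous_sds=sds,
        level_proportions=proportions,
        column_labels=tuple(labels),
        loadings=V,
        eigenvalues=eigenvalues,
        n_components=int(n_components),
        scores=scores,
    )


def transform_famd(model: FAMDModel, new_rows: pd.DataFrame) -> np.ndarray:
    """Project new mixed-type rows onto the fitted components.

    Uses the training means/sds/level proportions, so transforming the
    training rows reproduces the training scores. Unseen categorical levels
    raise a :class:`ConfigurationError` naming the level.
    """
    Z, _ = encode_mixed(
        new_rows, model.variables, model.continuous_means,
        model.continuous_sds, model.level_proportions,
    )
    return Z @ model.loadings


def _auto_n_components(eigenvalues: np.ndarray, threshold: float = 0.70) -> int:
    share = np.cumsum(eigenvalues) / np.sum(eigenvalues)
    return int(np.searchsorted(share, threshold - 1e-12) + 1)


def reduce_by_groups(
    ds: LongitudinalDataset,
    groups: Mapping[str, str] | None = None,
    n_components: int | Mapping[str, int] | str = "auto",
    *,
    inertia_threshold: float = 0.70,
) -> tuple[LongitudinalDataset, dict[str, FAMDModel]]:
    """Per-group FAMD on the stacked long-format rows.

    ``groups`` maps each variable name to a group name and must partition the
    dataset's variables (defaults to ``ds.groups``; if that is also missing,
    all variables form one group ``"all"``). ``n_components`` is an integer
    (same for every group), a mapping group -> count, or ``"auto"``: the
    smallest count explaining at least ``inertia_threshold`` of the group's
    total inertia.

    Returns the reduced dataset — continuous variables named
    ``<group>_dim<k>`` on the same subject/time rows — and the fitted
    per-group models.
    """
    if groups is None:
        groups = ds.groups
    if groups is None:
        groups = {v.name: "all" for v in ds.variables}
    declared = set(groups)
    names = set(ds.variable_names)
    missing = sorted(names - declared)
    extra = sorted(declared - names)
    if missing:
        raise ConfigurationError(f"variables in no group: {missing}")
    if extra:
        raise ConfigurationError(f"grouped variables not in dataset: {extra}")

    group_names: list[str] = []
    for v in ds.variables:  # preserve variable order for group ordering
        g = groups[v.name]
        if g not in group_names:
            group_names.append(g)

    spec_by_name = {v.name: v for v in ds.variables}
    out_cols: dict[str, np.ndarray] = {}
    models: dict[str, FAMDModel] = {}
    out_specs: list[VariableSpec] = []
    for g in group_names:
        members = [v.name for v in ds.variables if groups[v.name] == g]
        sub = ds.data[members]
        model_full = fit_famd(sub, None, variables=[spec_by_name[m] for m in members])
        if isinstance(n_components, str):
            if n_components != "auto":
                raise ConfigurationError(f"n_components must be int, mapping or 'auto', got {n_components!r}")
            m = _auto_n_components(model_full.eigenvalues, inertia_threshold)
        elif isinstance(n_components, Mapping):
            if g not in n_components:
                raise ConfigurationError(f"n_components mapping lacks group {g!r}")
            m = int(n_components[g])
        else:
            m = int(n_components)
        m = min(m, model_full.loadings.shape[1])
        model = fit_famd(sub, m, variables=[spec_by_name[mem] for mem in members])
        models[g] = model
        for k in range(m):
            col = f"{g}_dim{k + 1}"
            out_cols[col] = model.scores[:, k]
            out_specs.append(VariableSpec(col, CONTINUOUS))

    frame = pd.DataFrame(
        {ds.id_col: ds.data[ds.id_col], ds.time_col: ds.data[ds.time_col], **out_cols}
    )
    reduced = LongitudinalDataset(
        data=frame, id_col=ds.id_col, time_col=ds.time_col,
        variables=tuple(out_specs), groups=None,
    )
    return reduced, models


def regress_out_covariates(
    scores: pd.DataFrame,
    covariates: pd.DataFrame | None,
) -> pd.DataFrame:
    """Replace each score column by its OLS residual on the covariates.

    Covariates are indicator-expanded if categorical and an intercept is
    always included, so the residual columns are centered and have zero
    correlation with every covariate column. With an empty covariate set the
    scores are simply centered.

    Raises
    ------
    ConfigurationError
        If the covariate design matrix (intercept included) is rank
        deficient — which also rejects zero-variance covariates.
    """
    Y = scores.to_numpy(dtype=float)
    n = Y.shape[0]
    if covariates is None or covariates.shape[1] == 0:
        resid = Y - Y.mean(axis=0, keepdims=True)
        return pd.DataFrame(resid, index=scores.index, columns=scores.columns)
    if len(covariates) != n:
        raise ConfigurationError(
            f"covariates have {len(covariates)} rows, scores have {n}"
        )
    num_cols = [c for c in covariates.columns if pd.api.types.is_numeric_dtype(covariates[c])]
    cat_cols = [c for c in covariates.columns if c not in num_cols]
    X_parts = [np.ones((n, 1))]
    if num_cols:
        X_parts.append(covariates[num_cols].to_numpy(dtype=float))
    if cat_cols:
        dummies = pd.get_dummies(covariates[cat_cols].astype(str), drop_first=True)
        X_parts.append(dummies.to_numpy(dtype=float))
    X = np.hstack(X_parts)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ConfigurationError(
            "covariate matrix is rank deficient (collinear or constant covariate)"
        )
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return pd.DataFrame(resid, index=scores.index, columns=scores.columns)
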