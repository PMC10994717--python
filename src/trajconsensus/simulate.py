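"""Synthetic longitudinal mixed-type questionnaire-like data with known groups.

The generator emulates a cohort study in which each subject answers several
questionnaire scales at a handful of visits. Each *latent scale* follows a
group-specific linear (optionally curved) trajectory over time plus a
subject-level random intercept; the observed items load on their scale and
add independent Gaussian noise. Half the items per scale are reported as
continuous scores, the other half are discretized into ordered levels (a
Likert-style rating), giving a mixed-type table. Group separation is
parameterized in noise-sd units of the slope spacing, so fixtures can state
"separation >= 4 sigma" directly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io_model import (
    CATEGORICAL,
    CONTINUOUS,
    ConfigurationError,
    LongitudinalDataset,
    VariableSpec,
)

__all__ = ["SimulationConfig", "simulate_longitudinal_mixed", "save_simulation"]


@dataclass
class SimulationConfig:
    """Parameters of the questionnaire-like generator.

    Defaults describe the standard study condition: 2 latent scales, 5
    continuous + 5 five-level ordinal items per scale, 4 visits at t = 0,
    1, 2, 3, unit noise, group slopes spaced ``separation = 2.5`` noise-sd
    apart, and a subject random intercept of 0.5 noise-sd.
    """

    n_subjects: int = 100
    n_groups: int = 2
    n_visits: int = 4
    n_scales: int = 2
    n_continuous_items: int = 5
    n_ordinal_items: int = 5
    n_ordinal_levels: int = 5
    loading: float = 1.0
    noise_sd: float = 1.0
    separation: float = 2.5            # slope spacing between groups, in noise-sd units
    curvature: float = 0.0             # group-specific quadratic coefficient spacing
    group_proportions: tuple[float, ...] | None = None
    random_intercept_sd_factor: float = 0.5
    visit_times: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (2 <= self.n_groups <= 4):
            raise ConfigurationError(f"n_groups must be in {{2, 3, 4}}, got {self.n_groups}")
        for name in ("n_subjects", "n_visits", "n_scales"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_continuous_items < 0 or self.n_ordinal_items < 0:
            raise ConfigurationError("item counts must be non-negative")
        if self.n_continuous_items + self.n_ordinal_items < 1:
            raise ConfigurationError("need at least one item per scale")
        if self.n_ordinal_levels < 2:
            raise ConfigurationError("ordinal items need >= 2 levels")
        if self.n_groups > self.n_subjects:
            raise ConfigurationError(
                f"more groups ({self.n_groups}) than subjects ({self.n_subjects})"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.group_proportions is not None:
            p = np.asarray(self.group_proportions, dtype=float)
            if len(p) != self.n_groups:
                raise ConfigurationError("group_proportions length must equal n_groups")
            if np.any(p <= 0) or abs(p.sum() - 1.0) > 1e-8:
                raise ConfigurationError("group_proportions must be positive and sum to 1")
        if self.visit_times is not None and len(self.visit_times) != self.n_visits:
            raise ConfigurationError("visit_times length must equal n_visits")

    @property
    def times(self) -> np.ndarray:
        if self.visit_times is not None:
            return np.asarray(self.visit_times, dtype=float)
        return np.arange(self.n_visits, dtype=float)

    @property
    def proportions(self) -> np.ndarray:
        if self.group_proportions is not None:
            return np.asarray(self.group_proportions, dtype=float)
        return np.full(self.n_groups, 1.0 / self.n_groups)

    @property
    def slope_spacing(self) -> float:
        """Separation between adjacent group slopes, in response units."""
        return self.separation * self.noise_sd if self.noise_sd > 0 else self.separation

    def group_slopes(self) -> np.ndarray:
        """Per (group, scale) slope. On even scales the slopes increase with
        the group index, on odd scales they decrease, so every pair of groups
        is separated by at least one slope spacing on every scale."""
        G, S = self.n_groups, self.n_scales
        delta = self.slope_spacing
        slopes = np.empty((G, S))
        base = np.arange(G, dtype=float)
        base -= base.mean()
        for s in range(S):
            order = base if s % 2 == 0 else base[::-1]
            slopes[:, s] = order * delta
        return slopes

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        d = json.loads(text)
        for key in ("group_proportions", "visit_times"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def simulate_longitudinal_mixed(
    cfg: SimulationConfig,
) -> tuple[LongitudinalDataset, pd.Series]:
    """Generate a dataset and the true group labels (deterministic per seed).

    Per subject: a group is drawn from the configured proportions, and per
    scale a random intercept ``N(0, (0.5 * noise_sd)^2)``. The latent value
    at visit time t is ``intercept + slope[group, scale] * t + curvature
    term``. Continuous items are ``loading * latent + N(0, noise_sd^2)``;
    ordinal items use the same construction thresholded into
    equal-probability bins under the zero-separation baseline distribution
    (with ``noise_sd = 0`` the bins fall back to equal-frequency quantiles
    of the realized values).

    Returns the long-format dataset (with a ``scale<k>`` variable grouping
    attached for per-group FAMD) and a Series subject -> group in 1..G.
    """
    rng = np.random.default_rng(cfg.seed)
    n, G, S, V = cfg.n_subjects, cfg.n_groups, cfg.n_scales, cfg.n_visits
    times = cfg.times
    groups = rng.choice(G, size=n, p=cfg.proportions)
    slopes = cfg.group_slopes()
    intercepts = rng.normal(0.0, cfg.random_intercept_sd_factor * cfg.noise_sd, size=(n, S))
    curv = cfg.curvature * (np.arange(G) - (G - 1) / 2.0)

    # latent value per (subject, scale, visit)
    latent = (
        intercepts[:, :, None]
        + slopes[groups][:, :, None] * times[None, None, :]
        + curv[groups][:, None, None] * times[None, None, :] ** 2
    )

    subject_ids = np.array([f"S{i + 1:04d}" for i in range(n)])
    id_rows = np.repeat(subject_ids, V)
    time_rows = np.tile(times, n)
    latent_rows = latent.transpose(0, 2, 1).reshape(n * V, S)  # rows follow subject x visit

    baseline_var = (cfg.loading * cfg.random_intercept_sd_factor * cfg.noise_sd) ** 2 + cfg.noise_sd**2
    baseline_sd = float(np.sqrt(baseline_var))
    q = np.linspace(0.0, 1.0, cfg.n_ordinal_levels + 1)[1:-1]

    columns: dict[str, np.ndarray] = {}
    variables: list[VariableSpec] = []
    var_groups: dict[str, str] = {}
    levels = tuple(str(l + 1) for l in range(cfg.n_ordinal_levels))
    for s in range(S):
        scale_name = f"scale{s + 1}"
        for j in range(cfg.n_continuous_items):
            name = f"{scale_name}_cont{j + 1}"
            noise = rng.normal(0.0, cfg.noise_sd, size=n * V)
            columns[name] = cfg.loading * latent_rows[:, s] + noise
            variables.append(VariableSpec(name, CONTINUOUS))
            var_groups[name] = scale_name
        for j in range(cfg.n_ordinal_items):
            name = f"{scale_name}_ord{j + 1}"
            noise = rng.normal(0.0, cfg.noise_sd, size=n * V)
            u = cfg.loading * latent_rows[:, s] + noise
            if baseline_sd > 0:
                thresholds = norm.ppf(q, loc=0.0, scale=baseline_sd)
            else:
                thresholds = np.quantile(u, q)
            codes = np.searchsorted(thresholds, u, side="right")
            columns[name] = np.array([levels[c] for c in codes], dtype=object)
            variables.append(VariableSpec(name, CATEGORICAL, levels))
            var_groups[name] = scale_name

    frame = pd.DataFrame({"subject_id": id_rows, "time": time_rows, **columns})
    ds = LongitudinalDataset(
        data=frame, id_col="subject_id", time_col="time",
        variables=tuple(variables), groups=var_groups,
    )
    labels = pd.Series(
        groups + 1, index=pd.Index(subject_ids, name="subject"), name="group"
    )
    return ds, labels


def save_simulation(
    ds: LongitudinalDataset, labels: pd.Series, cfg: SimulationConfig, out_prefix: str | Path
) -> None:
    """Write ``<prefix>_data.csv``, ``<prefix>_labels.csv`` and
    ``<prefix>_config.json``."""
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    ds.data.to_csv(f"{prefix}_data.csv", index=False)
    labels.rename_axis("subject_id").reset_index().to_csv(f"{prefix}_labels.csv", index=False)
    Path(f"{prefix}_config.json").write_text(cfg.to_json())
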