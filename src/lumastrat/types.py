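"""Core data containers shared across the pipeline.

Expression matrices are stored genes x samples, matching the tab-separated
files the pipeline reads and writes (first column = gene id, remaining
columns = sample ids). Survival tables carry recurrence-free survival in
months and a binary event flag (1 = recurrence, 0 = censored).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SurvivalTable",
    "CohortTruth",
    "SimulationConfig",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples real-valued matrix with identifiers and a scale tag.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by gene id, columns by sample id.
    scale_tag : str
        ``"zscore"`` for median-Z-score scale inputs, ``"minmax"`` after
        reference min-max renormalization, ``"counts"`` for count-like
        positive values (normal-tissue simulations).
    """

    data: pd.DataFrame
    scale_tag: str = "zscore"

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.data.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.data.size and not np.isfinite(self.data.to_numpy(float)).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        """Genes x samples float array."""
        return self.data.to_numpy(float)

    def samples_by_genes(self) -> np.ndarray:
        """Samples x genes float array (sklearn orientation)."""
        return self.values.T


@dataclass
class SurvivalTable:
    """Per-sample follow-up: (time in months, event flag)."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if not (len(self.sample_ids) == len(self.time) == len(self.event)):
            raise ValueError("sample_ids, time and event must align")
        if self.time.size and (not np.isfinite(self.time).all() or (self.time < 0).any()):
            raise ValueError("survival times must be finite and non-negative")
        if not np.isin(self.event, [0, 1]).all():
            raise ValueError("event flags must be 0 or 1")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "rfs_months": self.time, "rfs_event": self.event}
        )

    def subset(self, mask: np.ndarray) -> "SurvivalTable":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return SurvivalTable(
            [self.sample_ids[i] for i in idx], self.time[idx], self.event[idx]
        )


@dataclass
class CohortTruth:
    """Ground truth planted by the simulator.

    ``subgroup_label`` is 0 for the low-hazard (better-prognosis) subgroup and
    1 for the high-hazard one. ``module_assignment`` maps gene id -> module
    number, 0 meaning unassigned.
    """

    subgroup_label: np.ndarray
    latent_means: np.ndarray  # (2, latent_dim)
    deg_gene_ids: set
    module_assignment: dict
    hazard_rates: tuple
    censoring_horizon: float
    #: sampled per-sample latent coordinates (samples x latent_dim); kept for
    #: recovery diagnostics, not serialized.
    latent: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.subgroup_label = np.asarray(self.subgroup_label, dtype=int)
        self.latent_means = np.asarray(self.latent_means, dtype=float)
        self.deg_gene_ids = set(self.deg_gene_ids)
        if any(h <= 0 for h in self.hazard_rates):
            raise ValueError("hazard rates must be positive")

    def to_json(self) -> str:
        return json.dumps(
            {
                "subgroup_label": self.subgroup_label.tolist(),
                "latent_means": self.latent_means.tolist(),
                "deg_gene_ids": sorted(self.deg_gene_ids),
                "module_assignment": {str(k): int(v) for k, v in self.module_assignment.items()},
                "hazard_rates": list(self.hazard_rates),
                "censoring_horizon": self.censoring_horizon,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "CohortTruth":
        d = json.loads(text)
        return cls(
            subgroup_label=np.asarray(d["subgroup_label"], dtype=int),
            latent_means=np.asarray(d["latent_means"], dtype=float),
            deg_gene_ids=set(d["deg_gene_ids"]),
            module_assignment={k: int(v) for k, v in d["module_assignment"].items()},
            hazard_rates=tuple(d["hazard_rates"]),
            censoring_horizon=float(d["censoring_horizon"]),
        )


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort generator.

    Defaults encode the study conditions exercised throughout the test suite:
    a 1,000-gene, 600-sample discovery cohort with two latent subgroups
    separated by four z-score units, a subgroup hazard ratio of 2.5 and a
    censoring horizon tuned so roughly 60% of samples experience recurrence.
    """

    n_genes: int = 1000
    n_samples: int = 600
    latent_dim: int = 8
    subgroup_separation: float = 4.0  # delta, z-score units
    noise_sd: float = 1.0
    module_count: int = 5
    module_size: int = 50
    intra_module_correlation: float = 0.6  # rho
    hazard_ratio: float = 2.5
    event_fraction: float = 0.6
    censoring_horizon: float = 120.0  # months
    platform_scale_range: tuple = (0.6, 1.4)
    platform_offset_range: tuple = (-0.5, 0.5)
    n_signal_dims: int = 2
    n_reference_samples: int = 80
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "latent_dim", "module_count", "module_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_samples < 0:
            raise ValueError("n_samples must be non-negative")
        if not 0.0 <= self.intra_module_correlation <= 1.0:
            raise ValueError("intra_module_correlation must lie in [0, 1]")
        if self.hazard_ratio < 1.0:
            raise ValueError("hazard_ratio must be >= 1")
        if not 0.0 < self.event_fraction < 1.0:
            raise ValueError("event_fraction must lie in (0, 1)")
        if self.n_signal_dims > self.latent_dim:
            raise ValueError("n_signal_dims cannot exceed latent_dim")
        lo, hi = self.platform_scale_range
        if lo <= 0 or hi < lo:
            raise ValueError("platform_scale_range must be positive and ordered")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["platform_scale_range"] = list(self.platform_scale_range)
        d["platform_offset_range"] = list(self.platform_offset_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("platform_scale_range", "platform_offset_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)
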