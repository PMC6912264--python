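"""The six analysis datasets: missing-value neglect plus repeated imputation.

Zero intensities (below-detection measurements) are handled along two
routes run in parallel:

* **dataset 1** — the log2 matrix unchanged, missing entries simply
  neglected by the downstream per-protein tests;
* **datasets 2..(1+n)** — independently seeded copies where every missing
  entry in sample column *s* is drawn from a down-shifted normal
  ``Normal(mu_s - downshift * sd_s, (width * sd_s)^2)`` with ``mu_s`` and
  ``sd_s`` the mean and (n-1) standard deviation of the *observed* values in
  that column — the Perseus-style left-censored imputation with its default
  parameters width = 0.3 and downshift = 1.8, repeated five times by
  default so no single fabricated draw dominates the calls.

Observed entries are never modified; imputed values are not truncated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_filter import ValidationError


@dataclass(frozen=True)
class ImputationParams:
    """Down-shifted-normal imputation parameters (multipliers of the per-column sd)."""

    width: float = 0.3
    downshift: float = 1.8
    n_imputations: int = 5
    base_seed: int = 0
    per_column: bool = True  # whole-matrix moments when False

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValidationError(f"width must be > 0, got {self.width}")
        if self.downshift < 0:
            raise ValidationError(f"downshift must be >= 0, got {self.downshift}")
        if self.n_imputations < 1:
            raise ValidationError(f"n_imputations must be >= 1, got {self.n_imputations}")


@dataclass(frozen=True)
class Dataset:
    """One analysis matrix: id 1 neglects missing values, ids >= 2 are imputed."""

    id: int
    kind: str  # "missing_neglect" | "imputed"
    matrix: pd.DataFrame
    seed: int | None = None


@dataclass(frozen=True)
class DatasetCollection:
    datasets: tuple[Dataset, ...]
    params: ImputationParams

    def __iter__(self):
        return iter(self.datasets)

    def __len__(self) -> int:
        return len(self.datasets)

    @property
    def dataset1(self) -> Dataset:
        return self.datasets[0]

    @property
    def imputed(self) -> tuple[Dataset, ...]:
        return self.datasets[1:]


def build_missing_dataset(logm: pd.DataFrame) -> Dataset:
    """Dataset 1: the log2 matrix as-is, missing entries neglected downstream."""
    return Dataset(id=1, kind="missing_neglect", matrix=logm.copy())


def impute_left_censored(
    logm: pd.DataFrame, params: ImputationParams, seed: int, dataset_id: int = 2
) -> Dataset:
    """One imputed dataset: fill every missing cell from the down-shifted normal.

    Deterministic given the seed. Requires >= 2 observed values per sample
    column (the column sd is undefined below that).
    """
    values = logm.to_numpy(dtype=float).copy()
    missing = np.isnan(values)
    rng = np.random.default_rng(seed)
    if params.per_column:
        n_obs = (~missing).sum(axis=0)
        short = np.flatnonzero(n_obs < 2)
        if short.size:
            raise ValidationError(
                "imputation needs >=2 observed values per sample; offending sample(s): "
                + ", ".join(str(logm.columns[j]) for j in short)
            )
        mu = np.nanmean(values, axis=0)
        sd = np.nanstd(values, axis=0, ddof=1)
        loc = (mu - params.downshift * sd)[None, :]
        scale = (params.width * sd)[None, :]
    else:
        obs = values[~missing]
        if obs.size < 2:
            raise ValidationError("imputation needs >=2 observed values in the matrix")
        loc = obs.mean() - params.downshift * obs.std(ddof=1)
        scale = params.width * obs.std(ddof=1)
    draws = rng.normal(np.broadcast_to(loc, values.shape), np.broadcast_to(scale, values.shape))
    values[missing] = draws[missing]
    filled = pd.DataFrame(values, index=logm.index, columns=logm.columns)
    return Dataset(id=dataset_id, kind="imputed", matrix=filled, seed=seed)


def build_dataset_collection(logm: pd.DataFrame, params: ImputationParams) -> DatasetCollection:
    """Dataset 1 plus ``n_imputations`` imputed datasets seeded base_seed+1..+n."""
    datasets = [build_missing_dataset(logm)]
    for i in range(1, params.n_imputations + 1):
        datasets.append(
            impute_left_censored(logm, params, seed=params.base_seed + i, dataset_id=1 + i)
        )
    return DatasetCollection(tuple(datasets), params)
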