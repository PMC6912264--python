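"""Per-protein one-way ANOVA contrasts and fold changes.

For each protein, a one-way ANOVA is fit over the four treatment-by-duration
groups and two planned contrasts are tested, one per duration:
si-hVDAC1 minus si-NT at short duration, and the same at long duration.
Inference uses the pooled mean-square error across all groups contributing
>= 2 observed values (not a Welch two-group test):

    MSE = sum_g SS_g / (N_obs - g_obs)
    t   = (mean_A - mean_B) / sqrt(MSE * (1/n_A + 1/n_B))

with a two-sided p from Student's t on ``N_obs - g_obs`` degrees of
freedom. In dataset 1 (missing values neglected) a contrast is evaluable
only when both contrast groups retain >= 2 observed values and the residual
df is >= 1; otherwise the result is marked undefined rather than raised.
Imputed datasets have no missing values, so every result is defined.

Fold changes are signed linear: FC = 2^d for d >= 0 and -2^(-d) for d < 0,
where d is the difference of group means on the log2 scale (a geometric-mean
ratio on the raw scale); |FC| >= 1 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .impute import Dataset, DatasetCollection
from .io_filter import DURATIONS

RESULT_COLUMNS = [
    "accession", "contrast", "dataset", "p", "delta_log2", "fc", "n_a", "n_b", "df", "defined",
]


@dataclass(frozen=True)
class ContrastSpec:
    """A planned treatment contrast within one duration: si-hVDAC1 vs si-NT."""

    id: str
    group_a: tuple[str, str]
    group_b: tuple[str, str]

    def __post_init__(self) -> None:
        if self.group_a[1] != self.group_b[1]:
            raise ValueError("contrast groups must share a duration")


def default_contrasts() -> list[ContrastSpec]:
    return [
        ContrastSpec(dur, ("si-hVDAC1", dur), ("si-NT", dur)) for dur in DURATIONS
    ]


def fold_change(delta_log2: float) -> float:
    """Signed linear fold change of a log2 difference (NaN propagates)."""
    if np.isnan(delta_log2):
        return np.nan
    if delta_log2 >= 0:
        return float(2.0 ** delta_log2)
    return float(-(2.0 ** (-delta_log2)))


def anova_contrast(
    values_by_group: dict[tuple[str, str], np.ndarray],
    contrast: ContrastSpec,
) -> tuple[float, float, float]:
    """Pooled-MSE contrast t-test for a single protein.

    Parameters
    ----------
    values_by_group
        Observed log2 values per (treatment, duration) group; NaNs allowed
        and dropped. Groups with < 2 observations are dropped from the MSE
        pool.

    Returns
    -------
    (p_value, delta_log2, residual_df)
        All NaN when the contrast is not evaluable. ``MSE = 0`` with a
        nonzero difference yields the boundary p = 0.
    """
    obs = {
        g: np.asarray(v, dtype=float)[~np.isnan(np.asarray(v, dtype=float))]
        for g, v in values_by_group.items()
    }
    pool = {g: v for g, v in obs.items() if len(v) >= 2}
    a = pool.get(contrast.group_a)
    b = pool.get(contrast.group_b)
    if a is None or b is None:
        return np.nan, np.nan, np.nan
    n_tot = sum(len(v) for v in pool.values())
    df = n_tot - len(pool)
    if df < 1:
        return np.nan, np.nan, np.nan
    ss = sum(float(((v - v.mean()) ** 2).sum()) for v in pool.values())
    mse = ss / df
    delta = float(a.mean() - b.mean())
    se2 = mse * (1.0 / len(a) + 1.0 / len(b))
    if se2 == 0.0:
        p = 1.0 if delta == 0.0 else 0.0
    else:
        t = delta / np.sqrt(se2)
        p = float(2.0 * stats.t.sf(abs(t), df))
    return p, delta, float(df)


def _group_columns(sheet: pd.DataFrame) -> dict[tuple[str, str], list[str]]:
    sheet = sheet[sheet["included"]]
    return {
        (t, d): grp["sample_id"].tolist()
        for (t, d), grp in sheet.groupby(["treatment", "duration"], sort=False)
    }


def analyze_dataset(
    ds: Dataset,
    sheet: pd.DataFrame,
    contrasts: list[ContrastSpec] | None = None,
) -> pd.DataFrame:
    """Run both contrasts for every protein of one dataset (vectorized).

    Returns a tidy frame with one row per (protein, contrast):
    ``accession contrast dataset p delta_log2 fc n_a n_b df defined``.
    """
    contrasts = contrasts or default_contrasts()
    groups = _group_columns(sheet)
    m = ds.matrix
    x = {g: m[cols].to_numpy(dtype=float) for g, cols in groups.items()}

    n = {g: (~np.isnan(v)).sum(axis=1) for g, v in x.items()}
    mean = {
        g: np.where(n[g] > 0, np.nansum(v, axis=1) / np.maximum(n[g], 1), np.nan)
        for g, v in x.items()
    }
    # per-group within sum of squares, counting only groups with >=2 observations
    ss = {}
    for g, v in x.items():
        with np.errstate(invalid="ignore"):
            dev = v - mean[g][:, None]
        ss[g] = np.nansum(dev ** 2, axis=1)
    contributes = {g: n[g] >= 2 for g in x}
    n_tot = sum(np.where(contributes[g], n[g], 0) for g in x)
    g_obs = sum(contributes[g].astype(int) for g in x)
    df = n_tot - g_obs
    pooled_ss = sum(np.where(contributes[g], ss[g], 0.0) for g in x)
    with np.errstate(invalid="ignore", divide="ignore"):
        mse = np.where(df >= 1, pooled_ss / np.maximum(df, 1), np.nan)

    frames = []
    for c in contrasts:
        na, nb = n[c.group_a], n[c.group_b]
        ok = (na >= 2) & (nb >= 2) & (df >= 1)
        delta = mean[c.group_a] - mean[c.group_b]
        with np.errstate(invalid="ignore", divide="ignore"):
            se2 = mse * (1.0 / na + 1.0 / nb)
            t = delta / np.sqrt(se2)
            p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1))
        # MSE == 0 boundary: p = 0 unless the difference is also 0
        zero_se = ok & (se2 == 0.0)
        p = np.where(zero_se, np.where(delta == 0.0, 1.0, 0.0), p)
        p = np.where(ok, p, np.nan)
        delta = np.where(ok, delta, np.nan)
        fc = np.where(delta >= 0, 2.0 ** delta, -(2.0 ** (-delta)))
        frames.append(pd.DataFrame({
            "accession": m.index,
            "contrast": c.id,
            "dataset": ds.id,
            "p": p,
            "delta_log2": delta,
            "fc": np.where(np.isnan(delta), np.nan, fc),
            "n_a": na,
            "n_b": nb,
            "df": np.where(ok, df, np.nan),
            "defined": ok,
        }))
    return pd.concat(frames, ignore_index=True)


def analyze_collection(
    collection: DatasetCollection,
    sheet: pd.DataFrame,
    contrasts: list[ContrastSpec] | None = None,
) -> pd.DataFrame:
    """Contrast results for every dataset of the collection, concatenated."""
    return pd.concat(
        [analyze_dataset(ds, sheet, contrasts) for ds in collection],
        ignore_index=True,
    )
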