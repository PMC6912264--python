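"""Log2 transform and sample-level quality control.

The QC stage codifies the inspection used to drop exceptional replicates:
PCA of the samples (computed on proteins observed in every sample, centered
per protein, unscaled — QC must not depend on the imputation under test),
per-sample signal-distribution summaries, a sample dendrogram (Pearson
dissimilarity, complete linkage), and an explicit outlier rule on the
PC1-PC2 plane: a sample is flagged when its distance from its group
centroid exceeds ``median + k_mad * MAD`` of within-group distances pooled
across groups. Flags are advisory; exclusion is a separate, confirmed step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from scipy.stats import median_abs_deviation
from sklearn.decomposition import PCA

from .io_filter import ValidationError

logger = logging.getLogger("proteoconsensus")


def log2_transform(table: pd.DataFrame) -> pd.DataFrame:
    """Map raw intensities to log2; zeros become missing (NaN). No pseudocount."""
    if (table.to_numpy() < 0).any():
        raise ValidationError("intensity table contains negative values")
    with np.errstate(divide="ignore"):
        out = np.log2(table.where(table > 0))
    return out


def median_normalize(logm: pd.DataFrame) -> pd.DataFrame:
    """Opt-in pre-step: align per-sample medians of observed log2 values to
    the grand median. Off by default — the core pipeline applies none."""
    med = logm.median()
    return logm - med + med.median()


@dataclass
class QCReport:
    """Per-sample QC surfaces for one log2 matrix."""

    scores: pd.DataFrame              # samples x PC1..PCk
    explained_variance_ratio: np.ndarray
    summaries: pd.DataFrame           # per sample: median, iqr, n_observed
    sample_linkage: np.ndarray        # scipy linkage over samples
    leaf_order: list[str]
    n_complete_rows: int

    def to_dict(self) -> dict:
        return {
            "scores": self.scores.round(6).to_dict(orient="index"),
            "explained_variance_ratio": [round(float(v), 6) for v in self.explained_variance_ratio],
            "summaries": self.summaries.round(6).to_dict(orient="index"),
            "leaf_order": self.leaf_order,
            "n_complete_rows": self.n_complete_rows,
        }


def qc_summaries(logm: pd.DataFrame, sheet: pd.DataFrame, k: int = 2) -> QCReport:
    """PCA scores, signal summaries and a sample dendrogram.

    PCA uses only proteins observed in all samples; rows are centered (the
    per-protein mean is removed) and not scaled. If fewer complete rows than
    ``k`` are available, k is reduced with a warning.
    """
    if logm.shape[1] < 2:
        raise ValidationError("QC requires at least 2 samples")
    complete = logm.dropna(axis=0)
    n_complete = len(complete)
    k_eff = min(k, n_complete, logm.shape[1])
    if k_eff < k:
        logger.warning("qc_summaries: reducing k from %d to %d (only %d complete rows)", k, k_eff, n_complete)
    if k_eff == 0:
        raise ValidationError("no complete protein rows; PCA impossible")

    x = complete.to_numpy().T  # samples x proteins
    pca = PCA(n_components=k_eff, svd_solver="full")
    scores = pca.fit_transform(x)
    scores_df = pd.DataFrame(
        scores, index=logm.columns, columns=[f"PC{i + 1}" for i in range(k_eff)]
    )

    q1 = logm.quantile(0.25)
    q3 = logm.quantile(0.75)
    summaries = pd.DataFrame(
        {
            "median": logm.median(),
            "iqr": q3 - q1,
            "n_observed": logm.notna().sum(),
        }
    )

    if n_complete >= 2:
        corr = complete.corr(method="pearson").to_numpy()
        diss = 1.0 - corr
        np.fill_diagonal(diss, 0.0)
        diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
        z = linkage(squareform(diss, checks=False), method="complete")
        order = [logm.columns[i] for i in leaves_list(z)]
    else:  # sample correlations undefined on <2 complete rows
        logger.warning("qc_summaries: too few complete rows for a sample dendrogram")
        z = np.empty((0, 4))
        order = list(logm.columns)
    return QCReport(scores_df, pca.explained_variance_ratio_, summaries, z, order, n_complete)


def flag_outlier_samples(report: QCReport, sheet: pd.DataFrame, k_mad: float = 3.0) -> list[str]:
    """Flag samples far from their group's center in the PC1-PC2 plane.

    Each sample's Euclidean distance is taken from its group's
    component-wise *median* (a mean centroid is dragged by the very outlier
    being hunted, masking it in triplicate groups). Distances are pooled
    across groups of size >= 3 — a group of <= 2 samples cannot single out
    an outlier and is skipped, with a log entry — and a sample is flagged
    when its distance exceeds ``median + k_mad * MAD`` of the pooled
    distances, with both statistics computed on the square-root distance
    scale (variance-stabilizing for planar distances, whose raw distribution
    is right-skewed) and the MAD normal-consistent. Deterministic given the
    report; invariant under sample order; ``k_mad = inf`` disables flagging.
    """
    pcs = [c for c in ("PC1", "PC2") if c in report.scores.columns]
    sheet = sheet[sheet["included"]]
    dists: dict[str, float] = {}
    eligible: list[str] = []
    for (_, _), grp in sheet.groupby(["treatment", "duration"], sort=False):
        ids = [s for s in grp["sample_id"] if s in report.scores.index]
        pts = report.scores.loc[ids, pcs].to_numpy()
        center = np.median(pts, axis=0)
        d = np.linalg.norm(pts - center, axis=1)
        for sid, di in zip(ids, d):
            dists[sid] = float(di)
        if len(ids) >= 3:
            eligible.extend(ids)
        else:
            logger.info("flag_outlier_samples: group of size %d skipped (%s)", len(ids), ids)
    if not eligible or not np.isfinite(k_mad):
        return []
    pool = np.sqrt([dists[s] for s in eligible])
    cutoff = float(np.median(pool) + k_mad * median_abs_deviation(pool, scale="normal"))
    return sorted(s for s in eligible if np.sqrt(dists[s]) > cutoff)


def apply_exclusions(
    logm: pd.DataFrame, sheet: pd.DataFrame, excluded: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop excluded sample columns and update the sheet's ``included`` flags.

    Every (treatment, duration) group must retain >= 2 samples afterwards —
    the contrast t-statistic is undefined below that.
    """
    if not excluded:
        return logm.copy(), sheet.copy()
    unknown = set(excluded) - set(sheet["sample_id"])
    if unknown:
        raise ValidationError(f"cannot exclude unknown sample id(s): {sorted(unknown)}")
    sheet = sheet.copy()
    sheet.loc[sheet["sample_id"].isin(excluded), "included"] = False
    kept = sheet[sheet["included"]]
    sizes = kept.groupby(["treatment", "duration"]).size()
    if (sizes < 2).any() or sizes.shape[0] < 4:
        raise ValidationError(
            f"exclusion leaves a group with <2 samples: {sizes.to_dict()}"
        )
    out = logm.drop(columns=[c for c in excluded if c in logm.columns])
    return out, sheet
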