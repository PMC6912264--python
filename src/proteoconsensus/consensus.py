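"""Consensus differential-expression calling across the six datasets.

A (protein, contrast) "passes" one dataset when p < alpha AND |FC| > fc_abs
(both strictly). The consensus rule calls a protein differentially
expressed when it passes in dataset 1 (missing values neglected), OR in
more than 3 — i.e. >= ``min_imputed_pass`` = 4 — of the 5 imputed datasets.
A not-evaluable dataset-1 result counts as not passing (the imputed route
remains available).

Two safeguards the vote needs in practice:

* sign coherence — the imputed route fires only when >= ``min_imputed_pass``
  of the passing imputed datasets agree in direction, so a protein cannot
  be called on contradictory fold changes;
* representative statistics — the reported FC and p are medians across the
  imputed datasets (dataset-1 values are carried alongside when defined),
  since the per-dataset values differ only in the fabricated draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_filter import ValidationError

CALL_COLUMNS = [
    "accession", "contrast", "de", "direction", "route",
    "n_imputed_pass", "dataset1_pass", "rep_fc", "rep_p", "dataset1_fc", "dataset1_p",
]


@dataclass(frozen=True)
class Thresholds:
    """Per-dataset significance thresholds and the consensus vote count."""

    alpha: float = 0.05
    fc_abs: float = 1.5
    min_imputed_pass: int = 4

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.fc_abs <= 1.0:
            raise ValidationError(f"fc_abs must be > 1, got {self.fc_abs}")
        if self.min_imputed_pass < 0:
            raise ValidationError(f"min_imputed_pass must be >= 0, got {self.min_imputed_pass}")


def call_de(results: pd.DataFrame, thresholds: Thresholds = Thresholds()) -> pd.DataFrame:
    """Apply the consensus rule to a tidy contrast-result table.

    ``results`` must cover the same set of dataset ids for every
    (protein, contrast); dataset 1 is the missing-neglect route, all other
    ids are imputed datasets.
    """
    required = {"accession", "contrast", "dataset", "p", "fc", "delta_log2", "defined"}
    missing = required - set(results.columns)
    if missing:
        raise ValidationError(f"results table lacks column(s): {sorted(missing)}")
    ids_per_key = results.groupby(["accession", "contrast"])["dataset"].agg(frozenset)
    if ids_per_key.nunique() != 1:
        raise ValidationError("inconsistent dataset coverage across (protein, contrast) pairs")
    dataset_ids = sorted(ids_per_key.iloc[0])
    if 1 not in dataset_ids:
        raise ValidationError("results must include dataset 1 (missing-neglect route)")
    n_imp = len(dataset_ids) - 1
    if thresholds.min_imputed_pass > n_imp and n_imp > 0:
        raise ValidationError(
            f"min_imputed_pass={thresholds.min_imputed_pass} exceeds {n_imp} imputed datasets"
        )

    r = results.copy()
    r["pass"] = (
        r["defined"].fillna(False).astype(bool)
        & (r["p"] < thresholds.alpha)
        & (r["fc"].abs() > thresholds.fc_abs)
    )

    rows = []
    for (acc, contrast), grp in r.groupby(["accession", "contrast"], sort=False):
        d1 = grp[grp["dataset"] == 1].iloc[0]
        imp = grp[grp["dataset"] != 1]
        d1_defined = bool(d1["defined"])
        d1_pass = bool(d1["pass"])
        imp_pass = imp[imp["pass"]]
        n_pass = len(imp_pass)
        n_up = int((imp_pass["delta_log2"] > 0).sum())
        n_down = int((imp_pass["delta_log2"] < 0).sum())
        imputed_route = max(n_up, n_down) >= thresholds.min_imputed_pass and n_imp > 0
        de = d1_pass or imputed_route

        if d1_pass and imputed_route:
            route = "both"
        elif d1_pass:
            route = "dataset1"
        elif imputed_route:
            route = "imputed_consensus"
        else:
            route = "none"

        direction = "undefined"
        if de:
            passing = pd.concat([imp_pass, grp[(grp["dataset"] == 1) & grp["pass"]]])
            med = float(passing["delta_log2"].median())
            direction = "up" if med > 0 else "down"

        rows.append({
            "accession": acc,
            "contrast": contrast,
            "de": de,
            "direction": direction,
            "route": route,
            "n_imputed_pass": n_pass,
            "dataset1_pass": d1_pass if d1_defined else None,
            "rep_fc": float(imp["fc"].median()) if len(imp) else (float(d1["fc"]) if d1_defined else np.nan),
            "rep_p": float(imp["p"].median()) if len(imp) else (float(d1["p"]) if d1_defined else np.nan),
            "dataset1_fc": float(d1["fc"]) if d1_defined else np.nan,
            "dataset1_p": float(d1["p"]) if d1_defined else np.nan,
        })
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def summarize_calls(calls: pd.DataFrame) -> dict:
    """Per-contrast DE counts, up/down split, and the cross-contrast union."""
    out: dict = {"contrasts": {}, "union": []}
    for contrast, grp in calls.groupby("contrast", sort=False):
        de = grp[grp["de"]]
        n_de = len(de)
        n_up = int((de["direction"] == "up").sum())
        n_down = int((de["direction"] == "down").sum())
        out["contrasts"][contrast] = {
            "n_tested": len(grp),
            "n_de": n_de,
            "n_up": n_up,
            "n_down": n_down,
            "fraction_down": (n_down / n_de) if n_de else None,
        }
    out["union"] = sorted(calls.loc[calls["de"], "accession"].unique().tolist())
    out["n_union"] = len(out["union"])
    return out
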