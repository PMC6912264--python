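"""Synthetic xenograft-proteomics data generator.

Emulates the statistical structure of a label-free LC-MS/MS protein
quantification experiment on a human-tumor xenograft: a mixture of human
(tumor) and mouse (stroma) proteins, four experimental groups formed by
crossing siRNA treatment (si-NT vs. si-hVDAC1) with treatment duration
(short vs. long), replicate tumors per group, log-normal intensities,
a configurable fraction of truly differentially expressed proteins, and
intensity-dependent (left-censored, MNAR) dropout producing the zero
intensities typical of such tables.

The missingness mechanism is deliberately *not* the down-shifted normal
used by the imputation stage: dropout is generated mechanistically, with a
sigmoid detection probability in the log2 intensity, so that imputation is
tested against a model it does not assume.

One designated replicate (replicate 1 of each long-duration group) can be
shifted by ``outlier_sample_shift`` log2 units to plant an "exceptional"
sample pair for the QC-exclusion path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_filter import DURATIONS, GROUPS, TREATMENTS, GeneSet, GeneSetDB

CONTRASTS = DURATIONS  # one contrast per duration


class ConfigError(ValueError):
    """A simulation parameter is outside its domain."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic experiment.

    All intensity-scale parameters are in log2 units. Defaults emulate a
    quantification of ~1,845 human proteins plus mouse stroma, triplicate
    tumors per group, and roughly 10% of human proteins carrying a true
    treatment effect in at least one duration.
    """

    n_human_proteins: int = 1845
    n_mouse_proteins: int = 400
    replicates_per_group: int = 3
    baseline_log2_mean: float = 25.0
    protein_level_sd: float = 2.5
    baseline_log2_sd: float = 0.5
    de_fraction: float = 0.06
    effect_log2_range: tuple[float, float] = (0.8, 3.0)
    censor_midpoint: float = 21.5
    censor_steepness: float = 1.0
    outlier_sample_shift: float = 0.0
    seed: int = 0
    groups: tuple[tuple[str, str], ...] = field(default=GROUPS)

    def __post_init__(self) -> None:
        for name in ("n_human_proteins", "n_mouse_proteins", "replicates_per_group"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be a positive count, got {getattr(self, name)}")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ConfigError(f"de_fraction must lie in [0, 1], got {self.de_fraction}")
        lo, hi = self.effect_log2_range
        if lo < 0 or hi < lo:
            raise ConfigError(f"effect_log2_range must be nonnegative and ordered, got {self.effect_log2_range}")
        for name in ("protein_level_sd", "baseline_log2_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative, got {getattr(self, name)}")
        if set(self.groups) != set(GROUPS):
            raise ConfigError(f"groups must be the 4 treatment x duration cells, got {self.groups}")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def apply_mnar_censoring(
    log2_matrix: pd.DataFrame,
    midpoint: float,
    steepness: float,
    seed: int,
) -> pd.DataFrame:
    """Set entries of a log2 matrix to missing with intensity-dependent probability.

    Each finite entry x is independently censored (set to NaN) with
    probability ``sigmoid(steepness * (midpoint - x))``: low intensities
    drop out preferentially (left censoring, MNAR). ``midpoint = -inf``
    disables censoring; ``steepness = inf`` gives a hard detection limit at
    the midpoint. The uniform draws depend only on the seed and matrix
    shape, so raising the midpoint under the same seed can only add missing
    entries.
    """
    if math.isnan(midpoint) or math.isnan(steepness):
        raise ConfigError("censor_midpoint/censor_steepness must not be NaN")
    values = log2_matrix.to_numpy(dtype=float)
    if midpoint == -math.inf:
        return log2_matrix.copy()
    with np.errstate(invalid="ignore"):
        arg = steepness * (midpoint - values)
        # inf * 0 at x == midpoint under a hard limit: the boundary is observed
        arg = np.where(np.isnan(arg), -np.inf, arg)
        p_missing = _sigmoid(arg)
    rng = np.random.default_rng(seed)
    u = rng.random(values.shape)
    out = np.where(u < p_missing, np.nan, values)
    return pd.DataFrame(out, index=log2_matrix.index, columns=log2_matrix.columns)


def _sample_ids(config: SimConfig) -> pd.DataFrame:
    rows = []
    for treatment, duration in config.groups:
        for rep in range(1, config.replicates_per_group + 1):
            rows.append({
                "sample_id": f"{treatment}_{duration}_r{rep}",
                "treatment": treatment,
                "duration": duration,
                "replicate": rep,
                "included": True,
            })
    return pd.DataFrame(rows)


def simulate_experiment(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one experiment.

    Returns
    -------
    (intensities, annotations, sheet, truth)
        ``intensities``: proteins x samples raw table (0 = not detected).
        ``annotations``: accession / gene / organism / unique_peptides.
        ``sheet``: sample sheet spanning the 4 groups.
        ``truth``: per protein, organism, true baseline and, per contrast
        (duration), the true DE flag and signed log2 effect (0 when not DE).

    Deterministic given the config (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    n_h, n_m = config.n_human_proteins, config.n_mouse_proteins
    n = n_h + n_m
    width = max(4, len(str(n)))
    accessions = [f"HP{i:0{width}d}" for i in range(1, n_h + 1)] + [
        f"MP{i:0{width}d}" for i in range(1, n_m + 1)
    ]
    genes = [f"HGENE{i}" for i in range(1, n_h + 1)] + [f"MGENE{i}" for i in range(1, n_m + 1)]
    organism = ["human"] * n_h + ["mouse"] * n_m

    annots = pd.DataFrame(
        {
            "gene": genes,
            "organism": organism,
            # mostly multi-peptide identifications, a few single/zero
            "unique_peptides": rng.choice([0, 1, 2, 3, 5, 8], size=n, p=[0.05, 0.2, 0.25, 0.2, 0.2, 0.1]),
        },
        index=pd.Index(accessions, name="accession"),
    )

    baselines = rng.normal(config.baseline_log2_mean, config.protein_level_sd, size=n)
    lo, hi = config.effect_log2_range
    de = rng.random((n, len(CONTRASTS))) < config.de_fraction
    magnitudes = rng.uniform(lo, hi, size=de.shape)
    signs = rng.choice([-1.0, 1.0], size=de.shape)
    effects = np.where(de, signs * magnitudes, 0.0)

    sheet = _sample_ids(config)
    cols = sheet["sample_id"].tolist()
    log2 = np.empty((n, len(cols)))
    for j, (_, s) in enumerate(sheet.iterrows()):
        mean = baselines.copy()
        if s["treatment"] == "si-hVDAC1":
            mean = mean + effects[:, CONTRASTS.index(s["duration"])]
        if s["duration"] == "long" and s["replicate"] == 1:
            mean = mean + config.outlier_sample_shift
        log2[:, j] = rng.normal(mean, config.baseline_log2_sd)

    log2_df = pd.DataFrame(log2, index=annots.index, columns=cols)
    censor_seed = int(rng.integers(0, 2**31 - 1))
    log2_df = apply_mnar_censoring(log2_df, config.censor_midpoint, config.censor_steepness, censor_seed)

    intensities = np.power(2.0, log2_df)
    intensities = intensities.fillna(0.0)

    truth = pd.DataFrame(
        {
            "gene": genes,
            "organism": organism,
            "baseline_log2": baselines,
            "de_short": de[:, CONTRASTS.index("short")],
            "effect_short": effects[:, CONTRASTS.index("short")],
            "de_long": de[:, CONTRASTS.index("long")],
            "effect_long": effects[:, CONTRASTS.index("long")],
        },
        index=annots.index,
    )
    return intensities, annots, sheet, truth


def simulate_gene_sets(
    truth: pd.DataFrame,
    n_terms: int,
    size_range: tuple[int, int],
    n_enriched_terms: int,
    seed: int,
    enrichment_odds: float = 8.0,
) -> GeneSetDB:
    """Build a GMT-serializable collection over the truth table's gene universe.

    ``n_enriched_terms`` of the ``n_terms`` terms oversample genes that are
    truly DE in either contrast, with sampling weight ``enrichment_odds``
    relative to non-DE genes; the remaining terms are uniform draws. The
    planted status and odds are recorded in each term's description field
    (``enriched odds=...`` vs ``null``).
    """
    lo, hi = size_range
    universe = truth["gene"].tolist()
    if not 1 <= lo <= hi <= len(universe):
        raise ConfigError(
            f"size_range {size_range} incompatible with universe of {len(universe)} genes"
        )
    if not 0 <= n_enriched_terms <= n_terms:
        raise ConfigError("n_enriched_terms must lie in [0, n_terms]")
    rng = np.random.default_rng(seed)
    is_de = (truth["de_short"] | truth["de_long"]).to_numpy()
    weights = np.where(is_de, enrichment_odds, 1.0)
    weights = weights / weights.sum()

    db = GeneSetDB()
    for i in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        enriched = i < n_enriched_terms
        if enriched and is_de.any():
            members = rng.choice(universe, size=size, replace=False, p=weights)
            desc = f"enriched odds={enrichment_odds:g}"
        else:
            members = rng.choice(universe, size=size, replace=False)
            desc = "null"
        db.sets.append(GeneSet(f"TERM{i + 1:04d}", desc, tuple(sorted(members))))
    return db
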