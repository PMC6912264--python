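"""Downstream surfaces: clustering, volcano tables, gene-set enrichment.

* Hierarchical clustering of the DE proteins on standardized (per-row
  z-scored) expression, with Pearson dissimilarity (1 - r between protein
  profiles) and complete linkage.
* Volcano tables: per protein, the log2 difference / signed FC, -log10 p,
  and strict threshold flags matching the consensus thresholds.
* Gene-set enrichment: one-sided Fisher's exact test of each term against a
  background universe (by default the quantified proteins that survived the
  ingest filter, not the whole genome), Benjamini-Hochberg FDR, and the
  reporting filter q < 0.05 with more than 4 DE proteins in the term.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .consensus import Thresholds
from .io_filter import GeneSetDB, ValidationError

logger = logging.getLogger("proteoconsensus")


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def standardize(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Per-row z-scores ((x - mean)/sd, sd with n-1); zero-sd rows become all
    zeros and are returned in the flag list."""
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    flat = sd.index[(sd == 0) | sd.isna()].tolist()
    safe_sd = sd.replace(0, np.nan)
    out = matrix.sub(mean, axis=0).div(safe_sd, axis=0)
    out.loc[flat] = 0.0
    if flat:
        logger.info("standardize: %d constant rows set to zero", len(flat))
    return out, flat


def cluster_proteins(standardized: pd.DataFrame) -> dict:
    """Complete-linkage agglomeration on Pearson dissimilarity between rows.

    Rows are sorted by accession before linkage, which fixes the merge order
    under input permutations and ties; zero-variance rows cannot define a
    correlation and are excluded with a log entry.

    Returns ``{"linkage": Z, "leaf_order": [...], "labels": [...],
    "excluded": [...]}`` with Z in scipy linkage format.
    """
    if len(standardized) < 2:
        raise ValidationError("clustering needs at least 2 proteins")
    m = standardized.sort_index()
    var = m.var(axis=1, ddof=1)
    excluded = var.index[(var == 0) | var.isna()].tolist()
    if excluded:
        logger.info("cluster_proteins: excluding %d zero-variance rows", len(excluded))
        m = m.drop(index=excluded)
    if len(m) < 2:
        raise ValidationError("fewer than 2 variable proteins to cluster")
    corr = np.corrcoef(m.to_numpy())
    diss = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(diss, 0.0)
    z = linkage(squareform(diss, checks=False), method="complete")
    labels = m.index.tolist()
    order = [labels[i] for i in leaves_list(z)]
    return {"linkage": z, "leaf_order": order, "labels": labels, "excluded": excluded}


def linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage as a Newick string (branch lengths = height deltas)."""
    from scipy.cluster.hierarchy import to_tree

    root = to_tree(z)

    def walk(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(root, root.dist) + ";"


# ---------------------------------------------------------------------------
# volcano
# ---------------------------------------------------------------------------

def volcano_table(results: pd.DataFrame, thresholds: Thresholds = Thresholds()) -> pd.DataFrame:
    """Per-protein volcano rows for one dataset's results of one contrast.

    Flags use the same strict inequalities as the consensus rule: p exactly
    at alpha or |FC| exactly at the cutoff does not pass.
    """
    out = results[["accession", "contrast", "dataset", "p", "delta_log2", "fc"]].copy()
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(out["p"])
    out["pass_p"] = out["p"] < thresholds.alpha
    out["pass_fc"] = out["fc"].abs() > thresholds.fc_abs
    out["pass_both"] = out["pass_p"] & out["pass_fc"]
    return out


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def fisher_enrichment(
    de_genes: set[str],
    background: set[str],
    db: GeneSetDB,
) -> pd.DataFrame:
    """One-sided (over-representation) Fisher's exact test per gene set.

    Term membership is intersected with the background before testing. The
    2x2 table per term is (DE in term, DE not in term, background-only in
    term, background-only not in term). Adds BH-FDR q-values.
    """
    de_genes = set(de_genes)
    background = set(background)
    stray = de_genes - background
    if stray:
        raise ValidationError(f"DE genes outside the background universe: {sorted(stray)[:10]}")
    n_bg = len(background)
    n_de = len(de_genes)
    rows = []
    for gs in db:
        term_bg = set(gs.genes) & background
        a = len(de_genes & term_bg)
        b = n_de - a
        c = len(term_bg) - a
        d = n_bg - n_de - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        odds = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
        rows.append({
            "term": gs.term,
            "description": gs.description,
            "n_de_in_term": a,
            "n_de": n_de,
            "n_bg_in_term": len(term_bg),
            "n_bg": n_bg,
            "odds_ratio": odds,
            "p": float(p),
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
    else:
        out["q"] = pd.Series(dtype=float)
    return out


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.isnan(p).any() or (p < 0).any() or (p > 1).any()):
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def filter_terms(
    rows: pd.DataFrame, q_max: float = 0.05, min_de_in_term: int = 4
) -> pd.DataFrame:
    """Reporting filter: q strictly below ``q_max`` AND strictly more than
    ``min_de_in_term`` DE proteins in the term."""
    keep = (rows["q"] < q_max) & (rows["n_de_in_term"] > min_de_in_term)
    return rows.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# figures (report layer)
# ---------------------------------------------------------------------------

def plot_volcano(vt: pd.DataFrame, path, thresholds: Thresholds = Thresholds()) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    colors = np.where(vt["pass_both"], "crimson", "grey")
    ax.scatter(vt["delta_log2"], vt["neg_log10_p"], s=6, c=colors, alpha=0.6, lw=0)
    ax.axhline(-np.log10(thresholds.alpha), ls="--", lw=0.8, c="k")
    for s in (1, -1):
        ax.axvline(s * np.log2(thresholds.fc_abs), ls="--", lw=0.8, c="k")
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_heatmap(standardized: pd.DataFrame, clustering: dict, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = standardized.loc[clustering["leaf_order"]]
    fig, ax = plt.subplots(figsize=(6, max(3, len(ordered) * 0.04)))
    im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-2, vmax=2)
    ax.set_xticks(range(ordered.shape[1]))
    ax.set_xticklabels(ordered.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="standardized expression")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_enrichment_bars(rows: pd.DataFrame, path, top: int = 15) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shown = rows.nsmallest(top, "q")
    fig, ax = plt.subplots(figsize=(6, max(2, 0.3 * len(shown))))
    with np.errstate(divide="ignore"):
        ax.barh(shown["term"], -np.log10(shown["q"]), color="steelblue")
    ax.set_xlabel("-log10 q (BH-FDR)")
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
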