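"""Input/output and protein-inclusion filtering.

Reads and validates the three input artifacts of the pipeline — a
protein-level intensity table (TSV; zero intensity means "not detected"),
a sample sheet (CSV) describing the 2x2 treatment-by-duration design, and
gene-set collections in GMT format — and applies the protein-inclusion
rules: organism selection plus a minimum unique-peptide count, and the
human/mouse partition used when a xenograft mixes proteins of two species.

Table contracts
---------------
Intensity TSV header:  ``accession  gene  organism  unique_peptides  <s1> ... <sn>``
Sample sheet CSV:      ``sample_id,treatment,duration,replicate,included``
GMT:                   ``term<TAB>description<TAB>member1<TAB>member2...``
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("proteoconsensus")

ANNOTATION_COLUMNS = ["accession", "gene", "organism", "unique_peptides"]
TREATMENTS = ("si-NT", "si-hVDAC1")
DURATIONS = ("short", "long")
#: The four ANOVA groups: treatment x duration.
GROUPS = tuple((t, d) for d in DURATIONS for t in TREATMENTS)


class FormatError(ValueError):
    """A file does not follow the documented layout."""


class ValidationError(ValueError):
    """A file parses but violates a content contract."""


@dataclass(frozen=True)
class GeneSet:
    term: str
    description: str
    genes: tuple[str, ...]


@dataclass
class GeneSetDB:
    """A flat collection of gene sets (symbols, not accessions)."""

    sets: list[GeneSet] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def term_map(self) -> dict[str, set[str]]:
        return {gs.term: set(gs.genes) for gs in self.sets}


# ---------------------------------------------------------------------------
# intensity table
# ---------------------------------------------------------------------------

def read_intensity_table(
    path: str | Path,
    dialect: dict[str, str] | None = None,
    drop_all_zero: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a protein intensity TSV into (intensities, annotations).

    Parameters
    ----------
    path
        Tab-separated file whose first columns are the annotation columns
        (see ``ANNOTATION_COLUMNS``) followed by one column per sample.
    dialect
        Optional mapping from the canonical annotation column names to the
        names actually used in the file, e.g. ``{"accession": "Protein ID"}``.
    drop_all_zero
        Remove rows with zero intensity in every sample (they carry no
        information for any downstream route); the count is logged.

    Returns
    -------
    (intensities, annotations)
        ``intensities``: DataFrame indexed by accession, one float column per
        sample, values >= 0 with 0 meaning not detected. ``annotations``:
        DataFrame indexed by accession with gene / organism /
        unique_peptides columns.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    rename = {v: k for k, v in (dialect or {}).items()}
    df = df.rename(columns=rename)

    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")

    dup = df["accession"][df["accession"].duplicated()].unique().tolist()
    if dup:
        raise ValidationError(f"{path}: duplicate accession(s): {', '.join(dup)}")

    sample_cols = [c for c in df.columns if c not in ANNOTATION_COLUMNS]
    if not sample_cols:
        raise FormatError(f"{path}: no sample columns after annotations")

    annots = df[ANNOTATION_COLUMNS].set_index("accession")
    annots["unique_peptides"] = pd.to_numeric(annots["unique_peptides"], errors="raise").astype(int)

    values = df[sample_cols].apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & df[sample_cols].notna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: malformed numeric cell at row {r + 2} (accession "
            f"{df['accession'].iloc[r]!r}), column {sample_cols[c]!r}"
        )
    intens = values.astype(float)
    intens.index = df["accession"]

    neg = intens.lt(0)
    if neg.any().any():
        r, c = np.argwhere(neg.to_numpy())[0]
        raise ValidationError(
            f"{path}: negative intensity at accession {intens.index[r]!r}, "
            f"sample {sample_cols[c]!r}"
        )

    if drop_all_zero:
        all_zero = intens.eq(0).all(axis=1)
        if all_zero.any():
            logger.info("dropping %d all-zero protein rows at ingest", int(all_zero.sum()))
            intens = intens.loc[~all_zero]
            annots = annots.loc[intens.index]
    return intens, annots


def write_intensity_table(path: str | Path, table: pd.DataFrame, annots: pd.DataFrame) -> None:
    """Serialize (intensities, annotations) back to the documented TSV layout."""
    out = annots.reindex(table.index).reset_index()
    out.columns = ANNOTATION_COLUMNS
    out = pd.concat([out, table.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read and validate a sample sheet CSV."""
    sheet = pd.read_csv(path, dtype={"sample_id": str, "treatment": str, "duration": str})
    required = ["sample_id", "treatment", "duration", "replicate"]
    missing = [c for c in required if c not in sheet.columns]
    if missing:
        raise FormatError(f"{path}: sample sheet missing column(s): {', '.join(missing)}")
    if "included" not in sheet.columns:
        sheet["included"] = True
    sheet["included"] = sheet["included"].astype(bool)
    return validate_sample_sheet(sheet)


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    if sheet["sample_id"].duplicated().any():
        dup = sheet["sample_id"][sheet["sample_id"].duplicated()].tolist()
        raise ValidationError(f"duplicate sample id(s): {dup}")
    bad_t = set(sheet["treatment"]) - set(TREATMENTS)
    bad_d = set(sheet["duration"]) - set(DURATIONS)
    if bad_t or bad_d:
        raise ValidationError(f"unknown treatment/duration levels: {bad_t | bad_d}")
    seen = set(zip(sheet["treatment"], sheet["duration"]))
    if seen != set(GROUPS):
        raise ValidationError(f"sample sheet must span all 4 groups; found {sorted(seen)}")
    return sheet


def write_sample_sheet(path: str | Path, sheet: pd.DataFrame) -> None:
    sheet.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# protein filters
# ---------------------------------------------------------------------------

def filter_proteins(
    table: pd.DataFrame,
    annots: pd.DataFrame,
    organism: str | None = "human",
    min_unique_peptides: int = 1,
) -> pd.DataFrame:
    """Keep rows of a given organism with >= ``min_unique_peptides`` unique peptides.

    ``organism=None`` is a wildcard. Row order is preserved; the filter is a
    pure row predicate (idempotent). An empty result is a warning, not an
    error.
    """
    if not annots.index.is_unique:
        raise ValidationError("annotations index is not unique")
    missing = table.index.difference(annots.index)
    if len(missing):
        raise ValidationError(f"annotations do not cover all rows: {list(missing[:5])}")
    ann = annots.loc[table.index]
    keep = ann["unique_peptides"] >= min_unique_peptides
    if organism is not None:
        keep &= ann["organism"] == organism
    out = table.loc[keep]
    if out.empty:
        logger.warning(
            "filter_proteins(organism=%r, min_unique_peptides=%d) retained no rows",
            organism, min_unique_peptides,
        )
    return out


def partition_by_organism(table: pd.DataFrame, annots: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Split a table into per-organism tables (disjoint cover of the input)."""
    ann = annots.loc[table.index]
    return {
        org: table.loc[ann["organism"] == org]
        for org in pd.unique(ann["organism"])
    }


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gene_sets(path: str | Path) -> GeneSetDB:
    """Parse a standard GMT file; duplicate members within a term are dropped."""
    db = GeneSetDB()
    n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has <3 tab-separated fields")
            term, desc, *members = fields
            members = [m for m in members if m]
            uniq = list(dict.fromkeys(members))
            n_dup += len(members) - len(uniq)
            if not uniq:
                raise FormatError(f"{path}:{lineno}: term {term!r} has no members")
            db.sets.append(GeneSet(term, desc, tuple(uniq)))
    if n_dup:
        logger.info("read_gene_sets: de-duplicated %d member symbols", n_dup)
    return db


def write_gene_sets(path: str | Path, db: GeneSetDB) -> None:
    with open(path, "w") as fh:
        for gs in db.sets:
            fh.write("\t".join([gs.term, gs.description, *gs.genes]) + "\n")
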