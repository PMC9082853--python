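"""Conversion of study-specific QTL summary tables to canonical distances.

The analysis consumes one record per molecular trait: the lead variant, the
cognate gene's TSS on the same chromosome, and their absolute base-pair
distance.  This module applies the study-type-specific filtering rules —
primary/strongest association per trait, intrachromosomal pairs only, a
|Z|-score floor for eQTL studies, and the single-interacting-gene rule for
metabolite QTLs — and emits the canonical distance table (columns
``trait``, ``chrom``, ``dist``, ``strength``).

Coordinates are 1-based; distances are strand-agnostic absolute
differences.  Genome-build harmonisation is upstream curation: all inputs
must already share one build, which is recorded in provenance only.

Column mapping from a study's native header to the canonical names is
driven by a small schema mapping (optionally loaded from YAML) so new
studies need no code change.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CANONICAL_COLUMNS",
    "load_study_table",
    "filter_intrachromosomal_primary",
    "filter_eqtl_zscore",
    "filter_metabolite_single_gene",
    "compute_distances",
]

logger = logging.getLogger(__name__)

#: canonical column names; a study schema maps native headers onto these
CANONICAL_COLUMNS = (
    "trait", "variant_chrom", "variant_pos", "gene_chrom", "gene_tss",
    "strength", "pvalue", "rank", "dist",
)

_PRIMARY_RANKS = {1, "1", "primary", "Primary", "PRIMARY", True}

EQTL_Z_THRESHOLD = 5.4485       # |Z| giving p just under 5e-8
GWAS_P_THRESHOLD = 5e-8


def load_study_table(path: str | Path, schema: dict | str | Path | None = None) -> pd.DataFrame:
    """Read a study summary table and rename columns per a schema mapping.

    ``schema`` maps canonical names to the study's native column names and
    may be a dict or a YAML file holding one.  Columns already canonical
    pass through; unmapped extra columns are preserved.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    if schema is not None:
        if not isinstance(schema, dict):
            with open(schema) as fh:
                schema = yaml.safe_load(fh)
        missing = [src for src in schema.values() if src not in df.columns]
        if missing:
            raise ValueError(f"schema refers to absent column(s): {missing}")
        df = df.rename(columns={src: dst for dst, src in schema.items()})
    return df


def _reject(frames: list[pd.DataFrame], rows: pd.DataFrame, reason: str) -> None:
    if len(rows):
        out = rows.copy()
        out["reason"] = reason
        frames.append(out)


def _pick_strongest(group: pd.DataFrame) -> pd.Series:
    """Deterministic argmax: strength desc, then distance asc, then position."""
    g = group.copy()
    if "dist" not in g or g["dist"].isna().all():
        g["dist"] = (g["variant_pos"] - g["gene_tss"]).abs()
    order = g.sort_values(
        ["strength", "dist", "variant_pos"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    return order.iloc[0]


def filter_intrachromosomal_primary(
    records: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep, per trait, the strongest intrachromosomal association.

    Records whose variant and cognate gene sit on different chromosomes are
    dropped first.  Where a ``rank`` column flags the primary association it
    is honoured; the strongest surviving record per trait is then retained
    (max ``strength``, ties broken by smaller distance, then by variant
    position).  When a trait maps to several genes, chromosome matching
    naturally keeps the pairing whose gene shares the variant's chromosome;
    traits with more than one same-chromosome gene candidate keep only the
    strongest pairing.

    Returns ``(kept, rejected)`` where every dropped input row appears
    exactly once in ``rejected`` with a ``reason`` code.
    """
    df = records.copy().reset_index(drop=True)
    rejects: list[pd.DataFrame] = []

    has_coords = df["variant_chrom"].notna() & df["gene_chrom"].notna()
    inter = has_coords & (df["variant_chrom"].astype(str) != df["gene_chrom"].astype(str))
    _reject(rejects, df[inter], "interchromosomal")
    df = df[~inter]

    if "rank" in df.columns and df["rank"].notna().any():
        nonprimary = df["rank"].notna() & ~df["rank"].isin(_PRIMARY_RANKS)
        _reject(rejects, df[nonprimary], "not_primary")
        df = df[~nonprimary]

    kept_rows = []
    for _, group in df.groupby("trait", sort=True):
        best = _pick_strongest(group)
        kept_rows.append(best)
        losers = group.drop(index=best.name)
        _reject(rejects, losers, "not_strongest")
    kept = pd.DataFrame(kept_rows).reset_index(drop=True) if kept_rows else df.iloc[0:0]
    rejected = (pd.concat(rejects, ignore_index=True)
                if rejects else df.iloc[0:0].assign(reason=pd.Series(dtype=str)))
    return kept, rejected


def filter_eqtl_zscore(
    records: pd.DataFrame,
    threshold: float = EQTL_Z_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the eQTL |Z| floor (inclusive) and keep the top eQTL per gene.

    ``strength`` must hold the Z-score; the genome-wide-significance default
    threshold corresponds to p < 5e-8.
    """
    df = records.copy().reset_index(drop=True)
    rejects: list[pd.DataFrame] = []
    weak = df["strength"].abs() < threshold
    _reject(rejects, df[weak], "below_z_threshold")
    df = df[~weak].copy()
    df["strength"] = df["strength"].abs()
    kept, rej2 = filter_intrachromosomal_primary(df)
    rejects.append(rej2)
    rejected = pd.concat([r for r in rejects if len(r)], ignore_index=True) \
        if any(len(r) for r in rejects) else df.iloc[0:0].assign(reason=pd.Series(dtype=str))
    return kept, rejected


def filter_metabolite_single_gene(
    records: pd.DataFrame,
    interacting_genes: pd.DataFrame,
    p_threshold: float = GWAS_P_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Metabolite-QTL rule: unique interacting gene per chromosome.

    ``interacting_genes`` maps each metabolite (column ``trait``) to its
    biochemically interacting genes (``gene``, ``gene_chrom``, ``gene_tss``).
    A (metabolite, chromosome) pair is eligible only when exactly one
    interacting gene lies on that chromosome; the strongest association
    (smallest ``pvalue``) per eligible pair is kept if p < ``p_threshold``
    (strict).  Metabolites absent from the map are dropped with a warning.
    """
    df = records.copy().reset_index(drop=True)
    rejects: list[pd.DataFrame] = []

    known = df["trait"].isin(interacting_genes["trait"])
    if (~known).any():
        logger.warning("%d record(s) for metabolites absent from the interacting-gene map",
                       int((~known).sum()))
    _reject(rejects, df[~known], "metabolite_not_in_map")
    df = df[known]

    per_chrom = interacting_genes.groupby(["trait", "gene_chrom"], sort=False).size()
    unique_pairs = per_chrom[per_chrom == 1].reset_index()[["trait", "gene_chrom"]]
    gene_lookup = interacting_genes.merge(unique_pairs, on=["trait", "gene_chrom"])

    merged = df.merge(
        gene_lookup[["trait", "gene", "gene_chrom", "gene_tss"]],
        left_on=["trait", "variant_chrom"], right_on=["trait", "gene_chrom"],
        how="left", suffixes=("", "_map"),
    )
    no_unique = merged["gene"].isna()
    _reject(rejects, df[no_unique.values], "no_unique_interacting_gene")
    merged = merged[~no_unique].copy()
    merged["gene_chrom"] = merged["variant_chrom"]

    kept_rows = []
    for _, group in merged.groupby(["trait", "variant_chrom"], sort=True):
        order = group.sort_values(["pvalue", "variant_pos"], kind="mergesort")
        best = order.iloc[0]
        _reject(rejects, group.drop(index=best.name), "not_strongest_on_chromosome")
        if best["pvalue"] < p_threshold:
            kept_rows.append(best)
        else:
            _reject(rejects, group.loc[[best.name]], "above_p_threshold")
    kept = pd.DataFrame(kept_rows).reset_index(drop=True) if kept_rows else merged.iloc[0:0]
    rejected = pd.concat([r for r in rejects if len(r)], ignore_index=True) \
        if any(len(r) for r in rejects) else df.iloc[0:0].assign(reason=pd.Series(dtype=str))
    return kept, rejected


def compute_distances(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Derive the canonical distance table from filtered records.

    A precomputed ``dist`` column passes through unchanged; otherwise the
    distance is ``|variant_pos - gene_tss|``.  Records with neither are
    rejected with a reason code.  Output columns: ``trait``, ``chrom``,
    ``dist`` and, when available, ``strength``.
    """
    df = records.copy().reset_index(drop=True)
    rejects: list[pd.DataFrame] = []

    has_dist = df["dist"].notna() if "dist" in df.columns else pd.Series(False, index=df.index)
    has_pos = (df.get("variant_pos", pd.Series(np.nan, index=df.index)).notna()
               & df.get("gene_tss", pd.Series(np.nan, index=df.index)).notna())
    bad = ~(has_dist | has_pos)
    _reject(rejects, df[bad], "no_distance_information")
    df = df[~bad].copy()
    has_dist = has_dist[~bad]

    derived = (df["variant_pos"] - df["gene_tss"]).abs() if has_pos.any() else np.nan
    df["dist"] = np.where(has_dist, df.get("dist", np.nan), derived)
    df["dist"] = df["dist"].astype(np.int64)

    chrom = df["variant_chrom"] if "variant_chrom" in df.columns else df.get("gene_chrom")
    out = pd.DataFrame({
        "trait": df["trait"],
        "chrom": chrom if chrom is not None else pd.NA,
        "dist": df["dist"],
    })
    if "strength" in df.columns:
        out["strength"] = df["strength"].values
    rejected = pd.concat(rejects, ignore_index=True) \
        if rejects else df.iloc[0:0].assign(reason=pd.Series(dtype=str))
    return out.reset_index(drop=True), rejected
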