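"""Conserved-single-copy (CSC) orthogroup circumscription, two-step hit-table
assignment, copy-number profiling and gene-set overlap accounting.

Orthogroup membership tables are plain DataFrames with columns
``gene_id, genome_id, orthogroup_id`` (the tabular output shape of an
OrthoMCL-style clustering; clustering itself is out of scope here). Hit
tables carry ``query_id, orthogroup_id, score, e_value`` — one table per
search method (hmmscan --tblout and BLAST outfmt 6 both reduce to this shape).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

ORTHOGROUP_COLUMNS = ["gene_id", "genome_id", "orthogroup_id"]
HIT_COLUMNS = ["query_id", "orthogroup_id", "score", "e_value"]


def validate_orthogroup_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ORTHOGROUP_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"orthogroup table lacks columns: {missing}")
    sub = table[ORTHOGROUP_COLUMNS]
    if sub.isna().any().any() or (sub.astype(str) == "").any().any():
        raise ValueError("orthogroup table contains empty fields")
    if sub["gene_id"].duplicated().any():
        dupes = sub.loc[sub["gene_id"].duplicated(), "gene_id"].tolist()[:5]
        raise ValueError(f"duplicate gene_ids in orthogroup table: {dupes}")
    return sub


def classify_single_copy(
    table: pd.DataFrame, reference_genomes: Sequence[str]
) -> frozenset:
    """Orthogroups with exactly one gene in every reference genome.

    Genes from genomes outside the reference scaffold never affect the
    classification. Raises if a named reference genome is absent from the
    table entirely.
    """
    table = validate_orthogroup_table(table)
    reference_genomes = list(reference_genomes)
    if not reference_genomes:
        raise ValueError("reference genome list must be non-empty")
    present = set(table["genome_id"])
    absent = [g for g in reference_genomes if g not in present]
    if absent:
        raise ValueError(f"reference genomes absent from table: {absent}")
    counts = (
        table[table["genome_id"].isin(reference_genomes)]
        .groupby(["orthogroup_id", "genome_id"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=reference_genomes, fill_value=0)
    )
    csc = counts.index[(counts == 1).all(axis=1)]
    return frozenset(csc)


def best_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Reduce a hit table to the best hit per query: highest score, ties by
    smallest e-value, then lexicographic orthogroup id."""
    missing = [c for c in HIT_COLUMNS if c not in hits.columns]
    if missing:
        raise ValueError(f"hit table lacks columns: {missing}")
    if (hits["e_value"] < 0).any():
        raise ValueError("e_value must be >= 0")
    ordered = hits.sort_values(
        ["query_id", "score", "e_value", "orthogroup_id"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    return ordered.drop_duplicates("query_id", keep="first")


def assign_orthogroup(
    hmm_hits: pd.DataFrame,
    blast_hits: pd.DataFrame,
    e_cutoff: float = 1e-5,
) -> pd.DataFrame:
    """Two-step orthogroup assignment: the best hmm hit governs; BLAST hits
    past the e-value cutoff are ignored and the surviving best BLAST hit only
    sets an agreement flag.

    Returns a DataFrame ``query_id, orthogroup_id, agree`` — ``agree`` is
    pandas-nullable boolean (NA when the query has no surviving BLAST hit);
    queries with no hmm hit are absent (unassigned).
    """
    hmm_best = best_hits(hmm_hits)
    blast_kept = blast_hits[blast_hits["e_value"] <= e_cutoff]
    blast_best = (
        best_hits(blast_kept) if len(blast_kept) else blast_kept
    )
    blast_map = dict(zip(blast_best["query_id"], blast_best["orthogroup_id"])) if len(
        blast_best
    ) else {}
    out = hmm_best[["query_id", "orthogroup_id"]].copy()
    agree = [
        (blast_map[q] == og) if q in blast_map else pd.NA
        for q, og in zip(out["query_id"], out["orthogroup_id"])
    ]
    out["agree"] = pd.array(agree, dtype="boolean")
    return out.reset_index(drop=True)


@dataclass
class CopyNumberSummary:
    per_orthogroup: pd.Series  # mean copies per genome, one value per orthogroup
    overall_mean: float
    minimum: float
    maximum: float


def copy_number_summary(
    table: pd.DataFrame,
    orthogroup_set: Iterable[str],
    genomes: Sequence[str],
) -> CopyNumberSummary:
    """Mean copy number per genome for each orthogroup in the set (zeros
    included for genomes lacking the orthogroup), and the overall mean of
    those per-orthogroup means with its min/max."""
    table = validate_orthogroup_table(table)
    ogs = sorted(set(orthogroup_set))
    if not ogs:
        raise ValueError("orthogroup set must be non-empty")
    unknown = set(ogs) - set(table["orthogroup_id"])
    if unknown:
        raise ValueError(f"orthogroups absent from table: {sorted(unknown)[:5]}")
    genomes = list(genomes)
    counts = (
        table[table["orthogroup_id"].isin(ogs) & table["genome_id"].isin(genomes)]
        .groupby(["orthogroup_id", "genome_id"])
        .size()
        .unstack(fill_value=0)
        .reindex(index=ogs, columns=genomes, fill_value=0)
    )
    per_og = counts.mean(axis=1)
    return CopyNumberSummary(
        per_orthogroup=per_og,
        overall_mean=float(per_og.mean()),
        minimum=float(per_og.min()),
        maximum=float(per_og.max()),
    )


def _pct(count: int, denom: int) -> float:
    """Percentage to 1 decimal, round-half-up (matches printed values)."""
    if denom == 0:
        return float("nan")
    exact = Decimal(count) * 100 / Decimal(denom)
    return float(exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class OverlapSummary:
    n_a: int
    n_b: int
    n_both: int
    n_a_only: int
    n_b_only: int
    pct_both_of_a: float
    pct_both_of_b: float
    pct_a_only_of_a: float
    pct_b_only_of_b: float


def set_overlap(set_a, set_b, mapping: Optional[dict] = None) -> OverlapSummary:
    """Counts and percentages of the overlap between two gene/orthogroup
    sets. An optional ``mapping`` (element -> orthogroup) is applied to both
    sets before comparison (the convention linking BUSCOs to orthogroups is
    an explicit input, never inferred). Percentages are reported to one
    decimal with round-half-up; counts are exact.
    """
    a = frozenset(mapping[x] for x in set_a) if mapping else frozenset(set_a)
    b = frozenset(mapping[x] for x in set_b) if mapping else frozenset(set_b)
    if not a or not b:
        raise ValueError("both sets must be non-empty")
    both = a & b
    return OverlapSummary(
        n_a=len(a),
        n_b=len(b),
        n_both=len(both),
        n_a_only=len(a - b),
        n_b_only=len(b - a),
        pct_both_of_a=_pct(len(both), len(a)),
        pct_both_of_b=_pct(len(both), len(b)),
        pct_a_only_of_a=_pct(len(a - b), len(a)),
        pct_b_only_of_b=_pct(len(b - a), len(b)),
    )
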