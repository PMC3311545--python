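"""Gene-level intron scoring and intronless-enrichment tests.

Genes are scored from their cognate transcripts: by default a gene counts
as intronless only if ALL of its transcripts are intron-free (configurable
to ANY). Enrichment between groups is assessed with a Pearson chi-squared
test on the 2x2 with/without-intron table.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2

ANNOTATION_COLUMNS = ("transcript_id", "gene_id", "n_introns", "length_bp")


class StructureError(ValueError):
    """Raised for malformed annotations or degenerate tables."""


@dataclass
class GeneStructureSummary:
    group: str
    n_genes: int
    n_intronless: int
    fraction_intronless: float
    mean_introns_per_gene: float


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a transcript annotation table (TSV or GFF3).

    TSV columns: transcript_id, gene_id, n_introns, length_bp. For GFF3,
    transcripts are mRNA features with a gene Parent, and the intron count
    of a transcript is its exon count minus one.
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _read_gff3(path)
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "gene_id": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise StructureError(f"{path}: missing column(s) {missing}")
    if df["transcript_id"].duplicated().any():
        raise StructureError(f"{path}: duplicate transcript ids")
    return df


def _read_gff3(path: Path) -> pd.DataFrame:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    rows = []
    for tx in db.features_of_type("mRNA"):
        exons = list(db.children(tx, featuretype="exon"))
        parents = tx.attributes.get("Parent", [])
        gene_id = parents[0] if parents else tx.id
        rows.append(
            {
                "transcript_id": tx.id,
                "gene_id": gene_id,
                "n_introns": max(len(exons) - 1, 0),
                "length_bp": sum(e.end - e.start + 1 for e in exons)
                or tx.end - tx.start + 1,
            }
        )
    if not rows:
        raise StructureError(f"{path}: no mRNA features found")
    return pd.DataFrame(rows)


def gene_intron_status(
    annotations: pd.DataFrame,
    transcript_to_gene: Mapping[str, str] | None = None,
    rule: str = "all",
) -> dict[str, bool]:
    """Score genes as intronless from their transcripts.

    rule="all": a gene is intronless iff every cognate transcript has zero
    introns; rule="any": iff at least one transcript has zero introns.
    """
    if rule not in ("all", "any"):
        raise StructureError(f"unknown rule {rule!r}")
    df = annotations
    if transcript_to_gene is not None:
        unknown = [
            t for t in df["transcript_id"] if t not in transcript_to_gene
        ]
        if unknown:
            raise StructureError(
                f"transcripts with unknown gene: {sorted(unknown)[:10]}"
            )
        gene_ids = df["transcript_id"].map(transcript_to_gene)
    else:
        gene_ids = df["gene_id"]
    intronless = df["n_introns"].to_numpy() == 0
    grouped = pd.Series(intronless).groupby(gene_ids.to_numpy())
    agg = grouped.all() if rule == "all" else grouped.any()
    return {str(g): bool(v) for g, v in agg.items()}


def gene_intron_counts(
    annotations: pd.DataFrame, per_gene: str = "max"
) -> dict[str, float]:
    """Intron count per gene: max over transcripts (default) or their mean."""
    if per_gene not in ("max", "mean"):
        raise StructureError(f"unknown per_gene mode {per_gene!r}")
    grouped = annotations.groupby("gene_id")["n_introns"]
    agg = grouped.max() if per_gene == "max" else grouped.mean()
    return {str(g): float(v) for g, v in agg.items()}


def chi2_2x2(
    a: int, b: int, c: int, d: int, yates: bool = False
) -> tuple[float, float]:
    """Pearson chi-squared on the 2x2 table [[a, b], [c, d]], 1 df."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise StructureError("table counts must be non-negative")
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    total = table.sum()
    if (row == 0).any() or (col == 0).any():
        raise StructureError("chi-squared table has a zero margin")
    expected = np.outer(row, col) / total
    diff = np.abs(table - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff**2 / expected).sum())
    p = float(chi2.sf(stat, df=1))
    return stat, p


def compare_groups(
    status: Mapping[str, bool],
    groups: Mapping[str, set[str] | list[str]],
    intron_counts: Mapping[str, float] | None = None,
    reference: str = "all",
    yates: bool = False,
) -> tuple[list[GeneStructureSummary], pd.DataFrame]:
    """Summarize intronless fractions per group and test each against a
    reference group (by default "all", the full status map).

    Returns (summaries, tests) where tests holds one chi-squared row per
    non-reference, non-empty group.
    """
    full_groups: dict[str, set[str]] = {
        name: set(members) for name, members in groups.items()
    }
    if reference not in full_groups:
        full_groups[reference] = set(status)
    unknown = {
        g for members in full_groups.values() for g in members
    } - set(status)
    if unknown:
        raise StructureError(
            f"genes without intron status: {sorted(unknown)[:10]}"
        )

    summaries = []
    for name, members in full_groups.items():
        n = len(members)
        n_intronless = sum(1 for g in members if status[g])
        mean_introns = float("nan")
        if intron_counts is not None and n:
            mean_introns = float(
                np.mean([intron_counts[g] for g in members])
            )
        summaries.append(
            GeneStructureSummary(
                group=name,
                n_genes=n,
                n_intronless=n_intronless,
                fraction_intronless=n_intronless / n if n else float("nan"),
                mean_introns_per_gene=mean_introns,
            )
        )

    by_name = {s.group: s for s in summaries}
    ref = by_name[reference]
    rows = []
    for s in summaries:
        if s.group == reference or s.n_genes == 0:
            continue
        stat, p = chi2_2x2(
            s.n_intronless,
            s.n_genes - s.n_intronless,
            ref.n_intronless,
            ref.n_genes - ref.n_intronless,
            yates=yates,
        )
        rows.append(
            {
                "group": s.group,
                "reference": reference,
                "chi2": stat,
                "p_value": p,
            }
        )
    return summaries, pd.DataFrame(
        rows, columns=["group", "reference", "chi2", "p_value"]
    )


def summaries_to_frame(
    summaries: list[GeneStructureSummary],
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": s.group,
                "n_genes": s.n_genes,
                "n_intronless": s.n_intronless,
                "fraction_intronless": s.fraction_intronless,
                "mean_introns_per_gene": s.mean_introns_per_gene,
            }
            for s in summaries
        ]
    )
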