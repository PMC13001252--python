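"""Ordered-library assembly: gene mapping, redundancy selection, statistics.

Once deconvolution has placed insertion mutants in wells, each insertion is
mapped to the ORF it disrupts.  The *gene fraction* locates the insertion
within its gene relative to the translational start: 0 at the start codon,
approaching 1 at the stop, computed strand-aware.  Per gene, up to three
mutants with distinct insertion sites are kept (most-upstream first); the
rank-1 entry -- the most upstream insertion, most likely to disrupt the
product -- forms the consolidated one-mutant-per-gene collection.

The redundancy-accuracy model: if a single mutant's annotation is correct
with probability p (estimated here from independent re-sequencing of a
random sample of mutants), a gene represented by k independent insertions is
correctly covered with probability ``a_k = 1 - (1-p)^k``.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "ESSENTIALITY_CLASSES",
    "GeneModel",
    "GeneHit",
    "AccuracyModel",
    "as_gene_table",
    "locate_in_gene",
    "gene_hits_for_assignments",
    "build_collection",
    "redundancy_counts",
    "total_mutants",
    "coverage_report",
    "fraction_histogram",
    "expected_accuracy",
    "percent",
    "round_half_up",
]

ESSENTIALITY_CLASSES = ("non-essential", "high-fitness", "essential", "unknown")


@dataclass(frozen=True)
class GeneModel:
    """Annotated ORF: 1-based inclusive interval, strand, essentiality class."""

    gene_id: str
    start: int
    end: int
    strand: str
    essentiality: str = "unknown"

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad interval for {self.gene_id}: [{self.start},{self.end}]")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.essentiality not in ESSENTIALITY_CLASSES:
            raise ValueError(f"unknown essentiality class {self.essentiality!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GeneHit:
    """An insertion inside a gene, with its strand-aware gene fraction."""

    gene_id: str
    fraction: float


def as_gene_table(genes) -> pd.DataFrame:
    """Normalize a gene annotation to a DataFrame (gene_id, start, end, strand,
    essentiality); accepts a DataFrame or an iterable of :class:`GeneModel`."""
    if isinstance(genes, pd.DataFrame):
        df = genes.copy()
        if "essentiality" not in df.columns:
            df["essentiality"] = "unknown"
        return df[["gene_id", "start", "end", "strand", "essentiality"]]
    return pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "essentiality": g.essentiality,
            }
            for g in genes
        ]
    )


def _gene_tree(genes: pd.DataFrame) -> IntervalTree:
    tree = IntervalTree()
    for row in genes.itertuples(index=False):
        tree[row.start: row.end + 1] = row  # interval end is exclusive
    return tree


def gene_fraction(position: int, start: int, end: int, strand: str) -> float:
    """Strand-aware relative position within a gene, in [0, 1).

    0 at the translational start (gene start on +, gene end on -), with the
    gene length in bp as denominator.
    """
    length = end - start + 1
    if strand == "+":
        return (position - start) / length
    return (end - position) / length


def locate_in_gene(position: int, genes) -> list[GeneHit]:
    """All genes containing a position (empty list = intergenic).

    Genes normally do not overlap; when they do, one hit per containing gene
    is returned and the caller chooses.
    """
    if position < 1:
        raise ValueError("position must be >= 1")
    table = as_gene_table(genes)
    hits = []
    for row in table.itertuples(index=False):
        if row.start <= position <= row.end:
            hits.append(
                GeneHit(row.gene_id, gene_fraction(position, row.start, row.end, row.strand))
            )
    return hits


def gene_hits_for_assignments(assignments: pd.DataFrame, genes) -> pd.DataFrame:
    """Vectorized gene lookup for an assignments table.

    ``assignments`` must carry ``position`` (and is typically the output of
    :func:`tnarray.deconvolve.assignments_frame` restricted to assigned
    sites).  Returns one row per (site, containing gene), with intergenic
    sites keeping a single row with NA gene_id.
    """
    table = as_gene_table(genes)
    tree = _gene_tree(table)
    rows = []
    for site_id, row in assignments.iterrows():
        pos = int(row["position"])
        overlaps = tree[pos]
        if not overlaps:
            rows.append({"site_id": site_id, "gene_id": pd.NA, "gene_fraction": np.nan,
                         "essentiality": pd.NA})
            continue
        for iv in sorted(overlaps, key=lambda iv: iv.data.gene_id):
            g = iv.data
            rows.append(
                {
                    "site_id": site_id,
                    "gene_id": g.gene_id,
                    "gene_fraction": gene_fraction(pos, g.start, g.end, g.strand),
                    "essentiality": g.essentiality,
                }
            )
    hits = pd.DataFrame(rows).set_index("site_id")
    return hits.join(assignments, how="left")


def build_collection(
    assignments: pd.DataFrame, genes, max_redundancy: int = 3
) -> pd.DataFrame:
    """Select the redundant ordered collection from assigned sites.

    Per gene, up to ``max_redundancy`` entries with distinct insertion sites
    are kept, by ascending gene fraction (ties by position then site_id);
    ranks are 1-based and the rank-1 (most upstream) entry carries the
    ``consolidated`` flag.  Intergenic assignments are retained as controls
    (NA gene, rank 1, not consolidated).
    """
    assigned = assignments[assignments["status"].isin(["auto", "triangulated"])]
    hits = gene_hits_for_assignments(assigned, genes)
    genic = hits[hits["gene_id"].notna()].copy()
    intergenic = hits[hits["gene_id"].isna()].copy()

    out = []
    for gene_id, grp in genic.groupby("gene_id", sort=True):
        grp = grp.reset_index().sort_values(
            ["gene_fraction", "position", "site_id"]
        ).drop_duplicates(subset="position")
        for rank, (_, row) in enumerate(grp.head(max_redundancy).iterrows(), start=1):
            rec = row.to_dict()
            rec["rank"] = rank
            rec["consolidated"] = rank == 1
            rec["intergenic"] = False
            out.append(rec)
    for _, row in intergenic.reset_index().iterrows():
        rec = row.to_dict()
        rec["rank"] = 1
        rec["consolidated"] = False
        rec["intergenic"] = True
        out.append(rec)
    cols = [
        "site_id", "gene_id", "gene_fraction", "essentiality", "position", "strand",
        "status", "plate_row", "plate_col", "well_row", "well_col", "rank",
        "consolidated", "intergenic",
    ]
    manifest = pd.DataFrame(out)
    if len(manifest):
        manifest = manifest[[c for c in cols if c in manifest.columns]]
    return manifest.reset_index(drop=True)


def redundancy_counts(manifest: pd.DataFrame) -> dict[int, int]:
    """Number of genes represented by exactly k mutants, k = 1, 2, 3, ..."""
    genic = manifest[~manifest["intergenic"]]
    per_gene = genic.groupby("gene_id")["rank"].max()
    return {int(k): int(v) for k, v in per_gene.value_counts().sort_index().items()}


def total_mutants(counts_by_redundancy: dict[int, int]) -> int:
    """Mutant entries implied by redundancy counts: sum over k of k * n_k."""
    return int(sum(k * n for k, n in counts_by_redundancy.items()))


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (0.05 at the last digit rounds away from zero)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage rounded half-up to ``ndigits`` decimals."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_up(100.0 * numerator / denominator, ndigits)


_STRATA = ("non-essential", "high-fitness", "essential")


def coverage_report(hit_gene_ids: Iterable[str], genes) -> pd.DataFrame:
    """Stratified ORF coverage: hit / missing counts and percentages.

    ``hit_gene_ids`` is any iterable of gene ids with >= 1 assigned insertion
    (e.g. a manifest's gene_id column).  Percentages are rounded half-up to
    one decimal.  Rows: one per essentiality stratum present, plus 'total'.
    """
    table = as_gene_table(genes)
    hit = set(pd.Series(list(hit_gene_ids)).dropna())
    rows = []
    strata = [s for s in _STRATA if (table["essentiality"] == s).any()]
    if set(table["essentiality"]) - set(_STRATA):
        strata.append("unknown")
    for stratum in strata + ["total"]:
        sub = table if stratum == "total" else table[
            table["essentiality"] == stratum
            if stratum != "unknown"
            else ~table["essentiality"].isin(_STRATA)
        ]
        n_total = len(sub)
        n_hit = int(sub["gene_id"].isin(hit).sum())
        rows.append(
            {
                "stratum": stratum,
                "orfs_hit": n_hit,
                "orfs_missing": n_total - n_hit,
                "total": n_total,
                "pct_hit": percent(n_hit, n_total) if n_total else 0.0,
                "pct_missing": percent(n_total - n_hit, n_total) if n_total else 100.0,
            }
        )
    return pd.DataFrame(rows).set_index("stratum")


def fraction_histogram(
    hits: pd.DataFrame, bin_width: float = 0.05, by_essentiality: bool = True
) -> pd.DataFrame:
    """Bin genic insertion fractions on [0, 1), left-closed right-open bins.

    ``hits`` needs a ``gene_fraction`` column (and ``essentiality`` when
    stratifying).  Returns a DataFrame indexed by bin left edge with one
    column per stratum (or a single 'all' column).
    """
    n_bins = round(1.0 / bin_width)
    if abs(n_bins * bin_width - 1.0) > 1e-9:
        raise ValueError("bin_width must divide 1 evenly")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    genic = hits[hits["gene_fraction"].notna()]
    groups = (
        {s: genic[genic["essentiality"] == s] for s in genic["essentiality"].dropna().unique()}
        if by_essentiality
        else {"all": genic}
    )
    out = {}
    for name, grp in sorted(groups.items()):
        counts, _ = np.histogram(grp["gene_fraction"].to_numpy(), bins=edges)
        out[name] = counts
    return pd.DataFrame(out, index=pd.Index(edges[:-1].round(10), name="bin_left"))


@dataclass(frozen=True)
class AccuracyModel:
    """Per-mutant annotation accuracy p; a_k = 1 - (1-p)^k for k-fold redundancy."""

    p_correct: float = 40 / 53

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_correct <= 1.0:
            raise ValueError("p_correct must be in [0, 1]")

    def a(self, k: int, ndigits: int | None = None) -> float:
        val = 1.0 - (1.0 - self.p_correct) ** k
        return round_half_up(val, ndigits) if ndigits is not None else val


def expected_accuracy(
    model: AccuracyModel,
    redundancy_shares: dict[int, float] | Sequence[float],
    round_ak: int | None = None,
) -> float:
    """Share-weighted probability that a gene is correctly represented.

    ``redundancy_shares`` maps k -> share of genes with k insertions (or a
    sequence for k = 1, 2, ...); shares must sum to 1.  ``round_ak`` rounds
    each a_k half-up to that many decimals before weighting (useful to match
    percentages quoted to fixed precision).
    """
    if not isinstance(redundancy_shares, dict):
        redundancy_shares = {k + 1: s for k, s in enumerate(redundancy_shares)}
    total = sum(redundancy_shares.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"redundancy shares must sum to 1, got {total}")
    return float(
        sum(share * model.a(k, round_ak) for k, share in redundancy_shares.items())
    )
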