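"""Toy-scale junction-read mapping and the pool x insertion count matrix.

Pooled-library sequencing yields, per pool, reads that start with the
transposon end and continue into genomic flank.  At desk scale we trim the
transposon end by exact match and place the flank on the reference by exact
search on both strands; real-data users load a precomputed count table
instead (:func:`read_count_matrix` validates it against the design).

Position convention: an insertion site is recorded as the 1-based genome
coordinate of the first flank base 3' of the transposon junction *on the
read's strand*.  For a forward-orientation read that is the first (lowest)
coordinate of the match; for a reverse-orientation read it is the last
(highest) coordinate of the reverse-complement match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from .design import PoolingDesign

__all__ = [
    "InsertionSite",
    "PoolCountMatrix",
    "LocateResult",
    "extract_junction",
    "locate_fragments",
    "tally_counts",
    "map_pools",
    "read_count_matrix",
    "write_count_matrix",
]


@dataclass(frozen=True, order=True)
class InsertionSite:
    """A transposon-genome junction: 1-based position plus flank orientation."""

    position: int
    orientation: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.orientation not in ("+", "-"):
            raise ValueError(f"orientation must be + or -, got {self.orientation!r}")


@dataclass
class PoolCountMatrix:
    """Read counts per (insertion site x pool).

    ``counts`` is indexed by site_id with one integer column per pool of the
    design, columns in the design's canonical pool order; ``sites`` carries
    per-site metadata (position, strand) on the same index.
    """

    counts: pd.DataFrame
    sites: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.sites.index):
            raise ValueError("counts and sites must share an index")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("read counts must be non-negative")

    @property
    def n_sites(self) -> int:
        return len(self.counts)

    @property
    def pool_ids(self) -> tuple[str, ...]:
        return tuple(self.counts.columns)

    def validate_against(self, design: PoolingDesign) -> None:
        if tuple(self.counts.columns) != design.pools:
            raise ValueError(
                "count matrix columns do not match the design's pools "
                f"({len(self.counts.columns)} vs {design.n_pools})"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([self.sites, self.counts], axis=1)


def extract_junction(
    read: str, transposon_end: str, min_fragment: int = 20
) -> str | None:
    """Trim the transposon end off a read; return the genomic flank or None.

    The first exact occurrence of ``transposon_end`` is used; the suffix
    after it is returned when at least ``min_fragment`` bp long.
    """
    if not read or not transposon_end:
        raise ValueError("read and transposon_end must be non-empty")
    read = read.upper()
    idx = read.find(transposon_end.upper())
    if idx < 0:
        return None
    fragment = read[idx + len(transposon_end):]
    return fragment if len(fragment) >= min_fragment else None


@dataclass
class LocateResult:
    """Outcome of exact-match placement of a batch of flank fragments."""

    sites: list[InsertionSite] = field(default_factory=list)
    n_ambiguous: int = 0
    n_unmapped: int = 0


def _occurrences(haystack: str, needle: str) -> list[int]:
    """All 0-based (possibly overlapping) match starts."""
    out, start = [], 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def locate_fragments(fragments: Iterable[str], genome: str) -> LocateResult:
    """Place flank fragments on the reference by exact search on both strands.

    A fragment with exactly one match (counting both strands) yields a site;
    zero matches count as unmapped, two or more as ambiguous (excluded).
    """
    if not genome:
        raise ValueError("genome must be non-empty")
    genome = genome.upper()
    result = LocateResult()
    for frag in fragments:
        frag = frag.upper()
        fwd = _occurrences(genome, frag)
        rev = _occurrences(genome, reverse_complement(frag))
        total = len(fwd) + len(rev)
        if total == 0:
            result.n_unmapped += 1
        elif total > 1:
            result.n_ambiguous += 1
        elif fwd:
            result.sites.append(InsertionSite(fwd[0] + 1, "+"))
        else:
            # junction base = highest genome coordinate of the rev-comp match
            result.sites.append(InsertionSite(rev[0] + len(frag), "-"))
    return result


def _merge_sites(
    sites: Sequence[InsertionSite], merge_window: int
) -> dict[InsertionSite, InsertionSite]:
    """Map each site to its cluster representative (smallest position).

    Single-linkage clustering per orientation: consecutive sorted positions
    at most ``merge_window`` apart join one cluster.
    """
    mapping: dict[InsertionSite, InsertionSite] = {}
    for orient in ("+", "-"):
        positions = sorted({s.position for s in sites if s.orientation == orient})
        rep = None
        prev = None
        for pos in positions:
            if rep is None or pos - prev > merge_window:
                rep = pos
            mapping[InsertionSite(pos, orient)] = InsertionSite(rep, orient)
            prev = pos
    return mapping


def tally_counts(
    located: Mapping[str, Sequence[InsertionSite]],
    design: PoolingDesign,
    merge_window: int = 0,
) -> PoolCountMatrix:
    """Tally located fragments per pool into a :class:`PoolCountMatrix`.

    ``located`` maps pool id -> located sites (one entry per fragment).
    Sites are collapsed by (position, orientation); with ``merge_window`` > 0,
    nearby positions (junction jitter) collapse onto the smallest position of
    their cluster.  Site ids are assigned in position order.
    """
    unknown = set(located) - set(design.pools)
    if unknown:
        raise ValueError(f"pool ids not in design: {sorted(unknown)}")
    all_sites = [s for sites in located.values() for s in sites]
    rep_of = _merge_sites(all_sites, merge_window)
    reps = sorted(set(rep_of.values()))
    site_ids = {rep: f"S{i + 1:05d}" for i, rep in enumerate(reps)}
    counts = pd.DataFrame(
        0, index=pd.Index([site_ids[r] for r in reps], name="site_id"),
        columns=list(design.pools), dtype=np.int64,
    )
    for pool, sites in located.items():
        for s in sites:
            counts.loc[site_ids[rep_of[s]], pool] += 1
    sites_df = pd.DataFrame(
        {
            "position": [r.position for r in reps],
            "strand": [r.orientation for r in reps],
        },
        index=counts.index,
    )
    return PoolCountMatrix(counts, sites_df)


def map_pools(
    fastq_by_pool: Mapping[str, str | Path],
    genome: str,
    transposon_end: str,
    design: PoolingDesign,
    min_fragment: int = 20,
    merge_window: int = 0,
) -> PoolCountMatrix:
    """FASTQ-per-pool -> count matrix: trim, locate, tally."""
    from Bio import SeqIO

    located: dict[str, list[InsertionSite]] = {}
    for pool, path in fastq_by_pool.items():
        frags = []
        for rec in SeqIO.parse(str(path), "fastq"):
            frag = extract_junction(str(rec.seq), transposon_end, min_fragment)
            if frag is not None:
                frags.append(frag)
        located[pool] = locate_fragments(frags, genome).sites
    return tally_counts(located, design, merge_window)


_META_COLS = ("position", "strand")


def write_count_matrix(matrix: PoolCountMatrix, path: str | Path) -> None:
    """Write the count matrix as TSV: site_id, position, strand, one column per pool."""
    matrix.to_frame().to_csv(path, sep="\t", index_label="site_id")


def read_count_matrix(path: str | Path, design: PoolingDesign) -> PoolCountMatrix:
    """Load a count-matrix TSV and validate its pool columns against the design."""
    df = pd.read_csv(path, sep="\t", index_col="site_id")
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    counts = df.drop(columns=list(_META_COLS))
    if set(counts.columns) != set(design.pools):
        raise ValueError("count table pools do not match the design")
    counts = counts[list(design.pools)].astype(np.int64)
    matrix = PoolCountMatrix(counts, df[list(_META_COLS)].copy())
    matrix.validate_against(design)
    return matrix
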