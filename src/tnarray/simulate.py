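"""Synthetic study generator: genome, annotation, picking, pooled counts.

Everything downstream of wet-lab work can be exercised on data from this
module: a random GC-rich genome with non-overlapping annotated genes
(essentiality classes apportioned exactly), colony picking into the plate
grid (with duplicate clones and essentiality-aware insertion placement), and
a forward noise model for pooled sequencing counts.

Noise model (per site x pool cell):

* member pools (union of the four pools of each well holding the site) draw
  a negative-binomial count around ``depth * pool factor * multiplicity``
  (lognormal per-pool depth factors model uneven pooling/sequencing);
* each member cell independently drops to zero with probability ``dropout``;
* each non-member cell receives Poisson(``background_mean``) contamination
  with probability ``background_rate``.

All randomness derives from child streams of one seed, and the contamination
rate enters only as a threshold on a pre-drawn uniform matrix: for a fixed
seed, raising ``background_rate`` contaminates a superset of cells and
changes nothing else.  ``NoiseModel.noise_free()`` gives exact deterministic
member counts with no contamination or dropout, the reference condition
under which deconvolution must recover every singly-placed site.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .assembly import ESSENTIALITY_CLASSES, as_gene_table, gene_fraction
from .design import PoolingDesign, WellAddress
from .mapping import PoolCountMatrix

__all__ = [
    "ReferenceBundle",
    "TruthPlacement",
    "NoiseModel",
    "generate_reference",
    "simulate_picking",
    "simulate_pool_counts",
    "write_pool_fastqs",
    "apportion",
]

_BASES = np.array(list("ACGT"))


def apportion(n: int, proportions: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n items to the given proportions."""
    if n < 0:
        raise ValueError("n must be >= 0")
    props = np.asarray(proportions, dtype=float)
    if props.min() < 0 or abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must be non-negative and sum to 1")
    quotas = n * props
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts.tolist()


@dataclass
class ReferenceBundle:
    """Synthetic genome + annotation (stand-in for a real reference)."""

    genome: str
    genes: pd.DataFrame  # gene_id, start, end, strand, essentiality
    seed: int

    @property
    def genome_length(self) -> int:
        return len(self.genome)

    def write_fasta(self, path: str | Path, name: str = "synthetic_chromosome") -> None:
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        rec = SeqRecord(Seq(self.genome), id=name, description="synthetic reference")
        seqio_write([rec], str(path), "fasta")

    def write_gff3(self, path: str | Path, seqid: str = "synthetic_chromosome") -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write(f"##sequence-region {seqid} 1 {self.genome_length}\n")
            for g in self.genes.itertuples(index=False):
                attrs = f"ID={g.gene_id};essentiality={g.essentiality}"
                fh.write(
                    f"{seqid}\ttnarray\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )

    def write_gene_table(self, path: str | Path) -> None:
        self.genes.to_csv(path, sep="\t", index=False)


def generate_reference(
    n_genes: int = 120,
    gene_length_distribution: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    intergenic_fraction: float = 0.10,
    essentiality_proportions: Sequence[float] = (0.832, 0.042, 0.126),
    seed: int = 0,
    gc_content: float = 0.67,
) -> ReferenceBundle:
    """Random genome with non-overlapping genes and exact class proportions.

    ``essentiality_proportions`` orders (non-essential, high-fitness,
    essential); label counts follow largest-remainder apportionment, and
    labels are shuffled over genes.  Gene lengths default to a lognormal
    with ~900 bp mean (floored at 120 bp); the genome length is the total
    gene length divided by (1 - intergenic_fraction), with intergenic bp
    spread over the n_genes + 1 gaps.  Deterministic given the seed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0.0 <= intergenic_fraction < 1.0:
        raise ValueError("intergenic_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    if gene_length_distribution is None:
        def gene_length_distribution(r: np.random.Generator, size: int) -> np.ndarray:
            return np.maximum(120, r.lognormal(mean=6.7, sigma=0.45, size=size)).astype(int)
    lengths = np.asarray(gene_length_distribution(rng, n_genes), dtype=int)
    if (lengths < 1).any():
        raise ValueError("gene lengths must be positive")
    total_genic = int(lengths.sum())
    genome_length = int(round(total_genic / (1.0 - intergenic_fraction)))
    intergenic_total = genome_length - total_genic
    if intergenic_total < 0:
        raise ValueError("gene lengths exceed the requested genome length")
    gaps = rng.multinomial(intergenic_total, np.full(n_genes + 1, 1.0 / (n_genes + 1)))

    counts = apportion(n_genes, essentiality_proportions)
    labels = np.repeat(ESSENTIALITY_CLASSES[:3], counts)
    rng.shuffle(labels)

    rows = []
    pos = 1
    width = len(str(n_genes))
    for i in range(n_genes):
        pos += int(gaps[i])
        start = pos
        end = start + int(lengths[i]) - 1
        rows.append(
            {
                "gene_id": f"gene_{i + 1:0{width}d}",
                "start": start,
                "end": end,
                "strand": "+" if rng.random() < 0.5 else "-",
                "essentiality": labels[i],
            }
        )
        pos = end + 1
    genes = pd.DataFrame(rows)

    p = np.array([(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2])
    genome = "".join(rng.choice(_BASES, size=genome_length, p=p))
    return ReferenceBundle(genome=genome, genes=genes, seed=seed)


@dataclass
class TruthPlacement:
    """Ground truth: insertion sites and the wells each clone was picked into.

    ``sites`` is indexed by site_id (position, strand); ``wells`` has one row
    per filled well (site_id, plate_row, plate_col, well_row, well_col).  A
    site with several wells models duplicate picks of one clone.
    """

    sites: pd.DataFrame
    wells: pd.DataFrame

    def wells_of(self, site_id: str) -> list[WellAddress]:
        sub = self.wells[self.wells["site_id"] == site_id]
        return [
            WellAddress(int(r.plate_row), int(r.plate_col), int(r.well_row), int(r.well_col))
            for r in sub.itertuples(index=False)
        ]

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def write_tsv(self, path: str | Path) -> None:
        merged = self.wells.merge(self.sites.reset_index(), on="site_id")
        merged.to_csv(path, sep="\t", index=False)


def _policy_ok(
    position: int, genes: pd.DataFrame, policy: str, end_fraction: float = 0.1
) -> bool:
    ess = genes[genes["essentiality"] == "essential"]
    for g in ess.itertuples(index=False):
        if g.start <= position <= g.end:
            if policy == "exclude":
                return False
            if policy == "ends-only":
                f = gene_fraction(position, g.start, g.end, g.strand)
                return f < end_fraction or f >= 1.0 - end_fraction
    return True


def simulate_picking(
    reference: ReferenceBundle,
    design: PoolingDesign,
    n_picked: int,
    duplicate_rate: float = 0.36,
    essential_policy: str = "allow",
    seed: int = 0,
) -> TruthPlacement:
    """Pick colonies into wells in plate order, with duplicate clones.

    Each pick is a fresh uniform insertion position (orientation random),
    except with probability ``duplicate_rate`` an already-picked clone is
    re-picked into the next free well.  ``essential_policy``: ``allow`` (no
    constraint), ``exclude`` (no insertions inside essential genes) or
    ``ends-only`` (insertions in essential genes restricted to the terminal
    10% of the gene, the pattern expected when only near-terminal disruption
    of an essential ORF is viable).
    """
    if n_picked > design.capacity:
        raise ValueError(f"n_picked {n_picked} exceeds design capacity {design.capacity}")
    if essential_policy not in ("allow", "exclude", "ends-only"):
        raise ValueError(f"unknown essential_policy {essential_policy!r}")
    if not 0.0 <= duplicate_rate < 1.0:
        raise ValueError("duplicate_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    genes = as_gene_table(reference.genes)
    G = reference.genome_length

    positions: list[int] = []
    strands: list[str] = []
    used_positions: set[int] = set()
    well_rows = []
    wells_iter = design.iter_wells()
    width = len(str(max(n_picked, 1)))
    for _ in range(n_picked):
        well = next(wells_iter)
        if positions and rng.random() < duplicate_rate:
            site_idx = int(rng.integers(0, len(positions)))
        else:
            while True:
                pos = int(rng.integers(1, G + 1))
                if pos in used_positions:
                    continue
                if _policy_ok(pos, genes, essential_policy):
                    break
            positions.append(pos)
            strands.append("+" if rng.random() < 0.5 else "-")
            used_positions.add(pos)
            site_idx = len(positions) - 1
        well_rows.append(
            {
                "site_idx": site_idx,
                "plate_row": well.plate_row,
                "plate_col": well.plate_col,
                "well_row": well.well_row,
                "well_col": well.well_col,
            }
        )

    order = np.argsort(positions, kind="stable")
    site_ids = [""] * len(positions)
    for rank, idx in enumerate(order):
        site_ids[idx] = f"S{rank + 1:0{width}d}"
    sites = pd.DataFrame(
        {"position": positions, "strand": strands},
        index=pd.Index(site_ids, name="site_id"),
    ).sort_values("position")
    wells = pd.DataFrame(well_rows)
    wells.insert(0, "site_id", [site_ids[i] for i in wells.pop("site_idx")])
    return TruthPlacement(sites=sites, wells=wells)


@dataclass(frozen=True)
class NoiseModel:
    """Forward model parameters for pooled sequencing counts.

    depth_per_pool: expected member-read count per (site, pool).
    depth_sd: lognormal sigma of per-pool depth factors (0 = even pools).
    dispersion: negative-binomial size parameter for member counts;
        ``None`` means deterministic counts equal to the expected depth.
    background_rate: probability a non-member cell receives contamination.
    background_mean: Poisson mean of a contaminated cell.
    dropout: probability a member cell reads zero.
    """

    depth_per_pool: float = 500.0
    depth_sd: float = 0.25
    dispersion: float | None = 5.0
    background_rate: float = 0.005
    background_mean: float = 3.0
    dropout: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.background_rate <= 1.0:
            raise ValueError("background_rate must be in [0, 1]")
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout must be in [0, 1]")
        if self.background_mean < 0:
            raise ValueError("background_mean must be >= 0")
        if self.dispersion is not None and self.dispersion <= 0:
            raise ValueError("dispersion must be > 0 (or None for deterministic counts)")
        if self.depth_sd < 0:
            raise ValueError("depth_sd must be >= 0")

    @classmethod
    def noise_free(cls, depth_per_pool: float = 500.0, seed: int = 0) -> "NoiseModel":
        """Deterministic member counts, even pools, no contamination or dropout."""
        return cls(
            depth_per_pool=depth_per_pool,
            depth_sd=0.0,
            dispersion=None,
            background_rate=0.0,
            background_mean=0.0,
            dropout=0.0,
            seed=seed,
        )


def simulate_pool_counts(
    placement: TruthPlacement,
    design: PoolingDesign,
    noise: NoiseModel | None = None,
) -> PoolCountMatrix:
    """Draw the pool x insertion count matrix implied by a placement.

    Member pools are the union (with multiplicity) of the four pools of each
    well holding a site.  See the module docstring for the noise model and
    its common-random-number determinism guarantees.
    """
    noise = noise or NoiseModel()
    pools = list(design.pools)
    pool_index = {p: j for j, p in enumerate(pools)}
    site_ids = list(placement.sites.index)
    site_index = {s: i for i, s in enumerate(site_ids)}
    n_sites, n_pools = len(site_ids), len(pools)

    mult = np.zeros((n_sites, n_pools), dtype=np.int64)
    for r in placement.wells.itertuples(index=False):
        well = WellAddress(int(r.plate_row), int(r.plate_col), int(r.well_row), int(r.well_col))
        i = site_index[r.site_id]
        for p in design.pools_for_well(well):
            mult[i, pool_index[p]] += 1

    ss = np.random.SeedSequence(noise.seed)
    r_depth, r_member, r_drop, r_cmask, r_cval = (
        np.random.default_rng(c) for c in ss.spawn(5)
    )
    if noise.depth_sd > 0:
        factors = r_depth.lognormal(mean=-noise.depth_sd**2 / 2, sigma=noise.depth_sd,
                                    size=n_pools)
    else:
        factors = np.ones(n_pools)
    mean = noise.depth_per_pool * factors[None, :] * mult
    member = mult > 0

    counts = np.zeros((n_sites, n_pools), dtype=np.int64)
    if noise.dispersion is None:
        counts[member] = np.round(mean[member]).astype(np.int64)
    else:
        r = noise.dispersion
        p = r / (r + mean[member])
        counts[member] = r_member.negative_binomial(r, p)
    if noise.dropout > 0:
        dropped = member & (r_drop.random((n_sites, n_pools)) < noise.dropout)
        counts[dropped] = 0
    # contamination: mask from a pre-drawn uniform so a higher rate with the
    # same seed contaminates a superset of cells without moving anything else
    u = r_cmask.random((n_sites, n_pools))
    v = r_cval.poisson(noise.background_mean, size=(n_sites, n_pools))
    contaminated = (~member) & (u < noise.background_rate)
    counts[contaminated] += v[contaminated]

    counts_df = pd.DataFrame(
        counts, index=pd.Index(site_ids, name="site_id"), columns=pools
    )
    return PoolCountMatrix(counts_df, placement.sites.copy())


def write_pool_fastqs(
    placement: TruthPlacement,
    design: PoolingDesign,
    reference: ReferenceBundle,
    out_dir: str | Path,
    transposon_end: str,
    read_length: int = 40,
    reads_per_member: int = 3,
) -> dict[str, Path]:
    """Emit noise-free per-pool junction-read FASTQ files.

    Each read is the transposon end followed by genomic flank taken at the
    site in its recorded orientation; every member (site, pool) pair yields
    ``reads_per_member`` identical reads.  Returns pool id -> file path.
    Useful for round-trip tests of the read-mapping path.
    """
    from Bio.Seq import reverse_complement

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome = reference.genome
    flank_len = read_length - len(transposon_end)
    if flank_len < 1:
        raise ValueError("read_length must exceed the transposon end length")

    reads_by_pool: dict[str, list[str]] = {p: [] for p in design.pools}
    for site_id, srow in placement.sites.iterrows():
        pos, strand = int(srow["position"]), srow["strand"]
        if strand == "+":
            flank = genome[pos - 1: pos - 1 + flank_len]
        else:
            flank = reverse_complement(genome[max(0, pos - flank_len): pos])
        read = transposon_end + flank
        for well in placement.wells_of(site_id):
            for pool in design.pools_for_well(well):
                reads_by_pool[pool].extend([read] * reads_per_member)

    paths = {}
    for pool, reads in reads_by_pool.items():
        path = out_dir / f"{pool}.fastq"
        with open(path, "w") as fh:
            for i, read in enumerate(reads):
                fh.write(f"@{pool}_{i}\n{read}\n+\n{'I' * len(read)}\n")
        paths[pool] = path
    return paths
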