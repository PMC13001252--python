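"""File-format helpers: annotation, genome and design serialization."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .design import PoolingDesign

__all__ = [
    "read_genome_fasta",
    "read_annotation",
    "read_design_yaml",
    "write_design_yaml",
    "design_table",
]


def read_genome_fasta(path: str | Path) -> str:
    """First sequence of a FASTA file as an uppercase string."""
    from Bio import SeqIO

    rec = next(SeqIO.parse(str(path), "fasta"))
    return str(rec.seq).upper()


def _read_annotation_gff3(path: str | Path) -> pd.DataFrame:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.features_of_type("gene"):
        rows.append(
            {
                "gene_id": feat.id,
                "start": feat.start,
                "end": feat.end,
                "strand": feat.strand,
                "essentiality": feat.attributes.get("essentiality", ["unknown"])[0],
            }
        )
    return pd.DataFrame(rows)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Gene table from GFF3 (``essentiality`` attribute) or TSV.

    The TSV needs columns gene_id, start, end, strand and optionally
    essentiality (default 'unknown').
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _read_annotation_gff3(path)
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation TSV missing columns: {sorted(missing)}")
    if "essentiality" not in df.columns:
        df["essentiality"] = "unknown"
    return df[["gene_id", "start", "end", "strand", "essentiality"]]


def read_design_yaml(path: str | Path) -> PoolingDesign:
    with open(path) as fh:
        return PoolingDesign.from_dict(yaml.safe_load(fh))


def write_design_yaml(design: PoolingDesign, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(design.to_dict(), fh, sort_keys=False)


def design_table(design: PoolingDesign) -> pd.DataFrame:
    """The full well -> pool table (one row per well, one column per axis pool)."""
    rows = []
    for well in design.iter_wells():
        rows.append(
            {
                "plate_row": well.plate_row,
                "plate_col": well.plate_col,
                "well_row": well.well_row_label,
                "well_col": well.well_col,
                "pool_wc": design.pool_name("WELL_COL", well.well_col),
                "pool_wr": design.pool_name("WELL_ROW", well.well_row),
                "pool_pc": design.pool_name("PLATE_COL", well.plate_col),
                "pool_pr": design.pool_name("PLATE_ROW", well.plate_row),
            }
        )
    return pd.DataFrame(rows)
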