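"""Gene TSS annotations and variant position lists.

Gene expression classes (up / down / constitutive / other) come from an
upstream differential-expression analysis and are consumed here as labels.
Variants are single positions (0-based) with unique ids.
"""

from __future__ import annotations

import pandas as pd

EXPR_CLASSES = ("up", "down", "constitutive", "other")

GENE_COLUMNS = ["gene_id", "chrom", "tss", "strand", "expr_class"]
VARIANT_COLUMNS = ["chrom", "pos", "id"]


def validate_genes(genes: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in GENE_COLUMNS if c not in genes.columns]
    if missing:
        raise ValueError(f"gene table missing columns: {missing}")
    if (genes["tss"] < 0).any():
        raise ValueError("gene TSS positions must be >= 0")
    bad = set(genes["expr_class"]) - set(EXPR_CLASSES)
    if bad:
        raise ValueError(f"unknown expression classes: {sorted(bad)}")
    if genes["gene_id"].duplicated().any():
        raise ValueError("duplicate gene ids")
    return genes


def read_genes_tsv(path) -> pd.DataFrame:
    """Read a TSV with columns gene_id, chrom, tss, strand, expr_class."""
    genes = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    return validate_genes(genes)


def write_genes_tsv(genes: pd.DataFrame, path) -> None:
    validate_genes(genes)[GENE_COLUMNS].to_csv(path, sep="\t", index=False)


def validate_variants(variants: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in VARIANT_COLUMNS if c not in variants.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    if (variants["pos"] < 0).any():
        raise ValueError("variant positions must be >= 0")
    if variants["id"].duplicated().any():
        raise ValueError("duplicate variant ids")
    return variants


def read_variants(path) -> pd.DataFrame:
    """Read variants from BED3+name (chrom, start, end, id) or a two-column
    (chrom, pos[, id]) TSV; returns columns chrom, pos, id."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) >= 4:  # BED3+name
                rows.append((fields[0], int(fields[1]), fields[3]))
            elif len(fields) >= 2:
                vid = fields[2] if len(fields) > 2 else f"var{lineno}"
                rows.append((fields[0], int(fields[1]), vid))
            else:
                raise ValueError(f"{path}:{lineno}: too few fields for a variant")
    return validate_variants(pd.DataFrame(rows, columns=VARIANT_COLUMNS))


def write_variants_bed(variants: pd.DataFrame, path) -> None:
    validate_variants(variants)
    with open(path, "w") as fh:
        for row in variants.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t{row.id}\n")
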