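"""Positional classification of significant loci against gene models.

Loci are classified as genic, within an upstream window (5' of the gene
start on the coding strand), or distal; genic wins over upstream
("considered once and genic only"). Coordinates are 1-based closed, as in
GFF3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class GeneSet:
    """Gene records: id, chrom, start, end (1-based closed), strand."""

    genes: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene_id", "chrom", "start", "end", "strand"}
        missing = required - set(self.genes.columns)
        if missing:
            raise ValueError(f"gene table missing columns: {sorted(missing)}")
        if (self.genes["start"] >= self.genes["end"]).any():
            raise ValueError("gene start must be < end")
        bad = ~self.genes["strand"].isin(["+", "-"])
        if bad.any():
            raise ValueError("strand must be '+' or '-'")


def read_gff3_genes(path) -> GeneSet:
    """Gene records (type == 'gene') from a GFF3 file."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID", attrs.get("Name", parts[8]))
            rows.append(
                (gene_id, parts[0], int(parts[3]), int(parts[4]), parts[6])
            )
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    return GeneSet(genes=df)


def classify_positions(
    loci: pd.DataFrame, genes: GeneSet, upstream_bp: int = 5000
) -> pd.DataFrame:
    """Classify each locus (chrom, pos) as genic / upstream5kb / distal.

    Upstream windows are strand-aware and exclude the gene body: for a +
    gene [start, end] the window is [start - upstream_bp, start - 1]; for a
    - gene it is [end + 1, end + upstream_bp]. A locus inside any gene is
    genic only, even if it also sits upstream of another gene; all genes
    hit (genic) or pointed to (upstream) are listed.
    """
    gt = genes.genes
    out_class = []
    out_genes = []
    for row in loci.itertuples(index=False):
        chrom, pos = row.chrom, int(row.pos)
        sub = gt[gt["chrom"] == chrom]
        genic_hits = sub[(sub["start"] <= pos) & (pos <= sub["end"])]
        if len(genic_hits):
            out_class.append("genic")
            out_genes.append(sorted(genic_hits["gene_id"].tolist()))
            continue
        plus = sub[
            (sub["strand"] == "+")
            & (sub["start"] - upstream_bp <= pos)
            & (pos <= sub["start"] - 1)
        ]
        minus = sub[
            (sub["strand"] == "-")
            & (sub["end"] + 1 <= pos)
            & (pos <= sub["end"] + upstream_bp)
        ]
        upstream_hits = sorted(
            set(plus["gene_id"]).union(minus["gene_id"])
        )
        if upstream_hits:
            out_class.append("upstream5kb")
            out_genes.append(upstream_hits)
        else:
            out_class.append("distal")
            out_genes.append([])
    out = loci.copy().reset_index(drop=True)
    out["class"] = out_class
    out["genes"] = out_genes
    return out


def position_summary(counts: dict[str, int]) -> pd.DataFrame:
    """Counts and integer percentages per positional class."""
    order = ["distal", "upstream5kb", "genic"]
    total = sum(counts.get(c, 0) for c in order)
    if any(counts.get(c, 0) < 0 for c in order):
        raise ValueError("counts must be non-negative")
    if total == 0:
        return pd.DataFrame(columns=["class", "count", "percent"])
    rows = [
        (c, counts.get(c, 0), int(round(100.0 * counts.get(c, 0) / total)))
        for c in order
    ]
    return pd.DataFrame(rows, columns=["class", "count", "percent"])


def gene_lists(
    classified_by_method: dict[str, pd.DataFrame],
) -> tuple[dict[str, set], pd.DataFrame]:
    """Unique gene ids per method plus the pairwise intersection table."""
    per_method: dict[str, set] = {}
    for method, df in classified_by_method.items():
        genes: set = set()
        for gl in df["genes"]:
            genes.update(gl)
        per_method[method] = genes
    methods = sorted(per_method)
    rows = []
    for i, a in enumerate(methods):
        for b in methods[i + 1:]:
            inter = sorted(per_method[a] & per_method[b])
            rows.append((a, b, len(inter), inter))
    table = pd.DataFrame(
        rows, columns=["method_a", "method_b", "n_shared", "shared_genes"]
    )
    return per_method, table
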