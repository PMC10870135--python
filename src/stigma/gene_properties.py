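"""Gene-intrinsic features: population constraint metrics and GC content.

Constraint metrics follow the gnomAD column vocabulary (pLI, pRec, pNull and
the synonymous / missense / LoF Z scores). GC content is computed for the gene
body and for a promoter window spanning 500 bp upstream and 100 bp downstream
of the transcription start site. The property table is a pandas DataFrame
indexed by gene with the canonical columns :data:`CONSTRAINT_COLUMNS` +
``gc_gene`` / ``gc_promoter`` / ``ortholog_confidence``; missing values are
NaN and are imputed downstream, never here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .errors import CoordinateError, SchemaError

logger = logging.getLogger(__name__)

CONSTRAINT_COLUMNS = ["pLI", "pRec", "pNull", "syn_z", "mis_z", "lof_z"]
PROPERTY_COLUMNS = CONSTRAINT_COLUMNS + ["gc_gene", "gc_promoter",
                                         "ortholog_confidence"]
_GENE_COLUMN_ALIASES = ("gene", "gene_id", "gene_symbol", "gene_name")
_VALID_BASES = set("ACGTNacgtn")


@dataclass
class GeneModel:
    """One transcript-collapsed gene model, 1-based inclusive coordinates."""

    gene: str
    chrom: str
    strand: str
    gene_start: int
    gene_end: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.gene_start > self.gene_end:
            raise ValueError(f"gene_start > gene_end for {self.gene}")

    @property
    def tss(self) -> int:
        return self.gene_start if self.strand == "+" else self.gene_end


def load_constraint_table(path: str | Path) -> pd.DataFrame:
    """Read a gnomAD-style constraint TSV into the canonical property schema.

    Column matching is case-insensitive. Duplicate gene rows are resolved by
    keeping the row with the fewest missing constraint fields (ties: first
    occurrence). pLI + pRec + pNull outside [0.99, 1.01] is logged, not fatal.
    """
    raw = pd.read_csv(path, sep="\t")
    lower = {c.lower(): c for c in raw.columns}
    gene_col = next((lower[a] for a in _GENE_COLUMN_ALIASES if a in lower), None)
    if gene_col is None:
        raise SchemaError(
            f"constraint table needs a gene column (one of {_GENE_COLUMN_ALIASES})"
        )
    table = pd.DataFrame({"gene": raw[gene_col].astype(str)})
    for canon in CONSTRAINT_COLUMNS + ["ortholog_confidence"]:
        src = lower.get(canon.lower())
        table[canon] = pd.to_numeric(raw[src], errors="coerce") if src else np.nan

    n_missing = table[CONSTRAINT_COLUMNS].isna().sum(axis=1)
    table = (
        table.assign(_miss=n_missing)
        .sort_values(["gene", "_miss"], kind="mergesort")
        .drop_duplicates("gene", keep="first")
        .drop(columns="_miss")
        .set_index("gene")
        .sort_index()
    )

    triple = table[["pLI", "pRec", "pNull"]].dropna()
    total = triple.sum(axis=1)
    bad = total[(total < 0.99) | (total > 1.01)]
    if len(bad):
        logger.warning(
            "pLI+pRec+pNull outside [0.99, 1.01] for %d genes (e.g. %s)",
            len(bad), list(bad.index[:3]),
        )
    if table["ortholog_confidence"].isna().all():
        table = table.drop(columns="ortholog_confidence")
    return table


def gc_fraction(seq: str) -> float:
    """G+C count over non-N bases; NaN if every base is N."""
    if len(seq) == 0:
        raise ValueError("empty sequence")
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(f"non-IUPAC nucleotide character {sorted(bad)[0]!r}")
    upper = seq.upper()
    denom = len(upper) - upper.count("N")
    if denom == 0:
        return float("nan")
    return (upper.count("G") + upper.count("C")) / denom


def promoter_interval(
    gm: GeneModel,
    upstream: int = 500,
    downstream: int = 100,
    chrom_length: int | None = None,
) -> tuple[int, int]:
    """Promoter window around the TSS, 1-based inclusive, strand-aware.

    On + the window is [tss - upstream, tss + downstream - 1]; on - it is the
    mirror [tss - downstream + 1, tss + upstream]. The TSS base itself counts
    toward the downstream segment, giving upstream + downstream bp unclipped.
    """
    if chrom_length is not None and not (1 <= gm.tss <= chrom_length):
        raise CoordinateError(
            f"TSS {gm.tss} of {gm.gene} outside chromosome {gm.chrom} "
            f"(length {chrom_length})"
        )
    if gm.strand == "+":
        start, end = gm.tss - upstream, gm.tss + downstream - 1
    else:
        start, end = gm.tss - downstream + 1, gm.tss + upstream
    clipped_start = max(start, 1)
    clipped_end = min(end, chrom_length) if chrom_length is not None else end
    if (clipped_start, clipped_end) != (start, end):
        logger.warning(
            "promoter of %s clipped to chromosome bounds [%d, %d]",
            gm.gene, clipped_start, clipped_end,
        )
    return clipped_start, clipped_end


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTNacgtn", "TGCANtgcan"))[::-1]


def gene_gc_features(
    fasta: str | Path,
    models: list[GeneModel],
    upstream: int = 500,
    downstream: int = 100,
) -> pd.DataFrame:
    """GC fractions of gene body and promoter for each gene model.

    Genes on contigs absent from the FASTA get missing values with a warning.
    The minus-strand promoter is reverse-complemented before the GC count
    (a no-op for the metric, kept for interface generality).
    """
    ref = Fasta(str(fasta))
    rows = {}
    for gm in models:
        if gm.chrom not in ref:
            logger.warning("contig %s of gene %s absent from FASTA", gm.chrom, gm.gene)
            rows[gm.gene] = (np.nan, np.nan)
            continue
        chrom_len = len(ref[gm.chrom])
        body = str(ref[gm.chrom][gm.gene_start - 1:gm.gene_end])
        p_start, p_end = promoter_interval(gm, upstream, downstream, chrom_len)
        prom = str(ref[gm.chrom][p_start - 1:p_end])
        if gm.strand == "-":
            prom = _revcomp(prom)
        rows[gm.gene] = (gc_fraction(body), gc_fraction(prom))
    out = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=["gc_gene", "gc_promoter"])
    out.index.name = "gene"
    return out.sort_index()


def read_gene_models(path: str | Path, fmt: str = "bed") -> list[GeneModel]:
    """Gene models from BED6 (0-based half-open, converted) or GTF."""
    path = Path(path)
    models: list[GeneModel] = []
    if fmt == "bed":
        bed = pd.read_csv(path, sep="\t", header=None,
                          names=["chrom", "start", "end", "name", "score", "strand"])
        for rec in bed.itertuples(index=False):
            models.append(GeneModel(gene=str(rec.name), chrom=str(rec.chrom),
                                    strand=str(rec.strand),
                                    gene_start=int(rec.start) + 1,
                                    gene_end=int(rec.end)))
    elif fmt == "gtf":
        import gffutils

        db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                                keep_order=True, merge_strategy="merge")
        for feat in db.features_of_type("gene"):
            gene = feat.attributes.get("gene_id", [feat.id])[0]
            models.append(GeneModel(gene=gene, chrom=feat.seqid, strand=feat.strand,
                                    gene_start=feat.start, gene_end=feat.end))
    else:
        raise ValueError(f"unknown gene-model format '{fmt}'")
    return models


def merge_properties(
    constraints: pd.DataFrame,
    gc: pd.DataFrame | None = None,
    orthologs: pd.DataFrame | None = None,
    all_genes: list[str] | None = None,
) -> pd.DataFrame:
    """Outer-join the property blocks on gene.

    ``all_genes`` (e.g. the expression gene universe) extends the index so
    genes without any properties appear as all-missing rows for downstream
    imputation.
    """
    parts = [constraints]
    if gc is not None:
        parts.append(gc)
    if orthologs is not None:
        parts.append(orthologs)
    merged = pd.concat(parts, axis=1, join="outer")
    if merged.columns.duplicated().any():
        merged = merged.T.groupby(level=0).first().T
    if all_genes is not None:
        merged = merged.reindex(merged.index.union(pd.Index(all_genes)))
    for col in PROPERTY_COLUMNS:
        if col not in merged.columns and col != "ortholog_confidence":
            merged[col] = np.nan
    order = [c for c in PROPERTY_COLUMNS if c in merged.columns]
    merged = merged[order].astype(float)
    merged.index.name = "gene"
    return merged.sort_index()
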