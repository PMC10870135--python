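"""Construction of the positive and negative training classes.

The positive class is the curated disease gene list minus ubiquitously
expressed genes: a gene whose reference pseudobulk expression sits within one
standard deviation of its own cross-sub-trajectory mean in more than
``max_similar`` sub-trajectories is considered ubiquitous and removed. The
negative class is the set of housekeeping genes that are LoF tolerant in the
constraint table (pNull > pRec and pNull > pLI, strict).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError

logger = logging.getLogger(__name__)


@dataclass
class TrainingClasses:
    positive: set[str]
    negative: set[str]
    provenance: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene", "class", "reason"])
    )

    def __post_init__(self) -> None:
        overlap = self.positive & self.negative
        if overlap:
            raise ConfigurationError(f"classes overlap: {sorted(overlap)[:5]}")

    @property
    def all_training_genes(self) -> set[str]:
        return self.positive | self.negative

    def write_provenance(self, path: str | Path) -> None:
        self.provenance.to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> list[str]:
    """One-gene-per-line TSV; a first line literally named 'gene' is a header."""
    genes = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            tok = line.strip().split("\t")[0]
            if not tok or (i == 0 and tok.lower() in {"gene", "gene_id"}):
                continue
            genes.append(tok)
    return genes


def read_reference_pseudobulk(path: str | Path) -> pd.DataFrame:
    """Genes x sub-trajectories mean-expression table (gene index column)."""
    ref = pd.read_csv(path, sep="\t", index_col=0)
    ref.index = ref.index.astype(str)
    return ref.astype(float)


def ubiquity_filter(
    candidates: set[str] | list[str],
    ref: pd.DataFrame,
    max_similar: int = 10,
) -> tuple[set[str], pd.DataFrame]:
    """Remove genes whose expression is 'the same' (within +/- 1 SD of the
    gene's own mean) in more than ``max_similar`` sub-trajectories.

    A flat gene (sigma = 0) counts every sub-trajectory as 'same'. Candidates
    absent from the reference pass through with a recorded reason. Returns the
    surviving set and a provenance frame (gene, class, reason).
    """
    n_subtraj = ref.shape[1]
    if n_subtraj < max_similar + 1:
        logger.warning(
            "reference has %d sub-trajectories; ubiquity rule (> %d) is vacuous",
            n_subtraj, max_similar,
        )
    survivors: set[str] = set()
    records = []
    for gene in sorted(set(map(str, candidates))):
        if gene not in ref.index:
            survivors.add(gene)
            records.append((gene, "positive", "not_in_reference"))
            continue
        vals = ref.loc[gene].to_numpy(dtype=float)
        mu = vals.mean()
        sigma = vals.std(ddof=0)
        n_same = n_subtraj if sigma == 0 else int(
            np.sum((vals >= mu - sigma) & (vals <= mu + sigma))
        )
        if n_same > max_similar:
            records.append((gene, "excluded", "ubiquitous_expression"))
        else:
            survivors.add(gene)
            records.append((gene, "positive", "passed_ubiquity_filter"))
    prov = pd.DataFrame(records, columns=["gene", "class", "reason"])
    return survivors, prov


def select_negative_class(
    housekeeping: set[str] | list[str],
    props: pd.DataFrame,
) -> tuple[set[str], pd.DataFrame]:
    """LoF-tolerant housekeeping genes: pNull > pRec and pNull > pLI (strict).

    Genes with missing constraint metrics are excluded with a recorded reason;
    class eligibility never rests on imputed values.
    """
    selected: set[str] = set()
    records = []
    for gene in sorted(set(map(str, housekeeping))):
        if gene not in props.index:
            records.append((gene, "excluded", "no_constraint_record"))
            continue
        row = props.loc[gene]
        pli, prec, pnull = row.get("pLI"), row.get("pRec"), row.get("pNull")
        if any(pd.isna(v) for v in (pli, prec, pnull)):
            records.append((gene, "excluded", "missing_constraint"))
            continue
        if pnull > prec and pnull > pli:
            selected.add(gene)
            records.append((gene, "negative", "lof_tolerant"))
        else:
            records.append((gene, "excluded", "not_lof_tolerant"))
    if not selected:
        raise ConfigurationError("negative class is empty")
    prov = pd.DataFrame(records, columns=["gene", "class", "reason"])
    return selected, prov


def build_training_classes(
    disease_genes: set[str] | list[str],
    housekeeping: set[str] | list[str],
    ref: pd.DataFrame,
    props: pd.DataFrame,
    max_similar: int = 10,
) -> TrainingClasses:
    """Positive = ubiquity-filtered disease genes; negative = tolerant
    housekeeping genes. A gene on both input lists is assigned to the positive
    class with a warning."""
    positive, pos_prov = ubiquity_filter(disease_genes, ref, max_similar=max_similar)
    negative, neg_prov = select_negative_class(housekeeping, props)
    conflict = positive & negative
    for gene in sorted(conflict):
        logger.warning("gene %s in both lists; assigned to positive class", gene)
        negative.discard(gene)
        neg_prov.loc[neg_prov["gene"] == gene, ["class", "reason"]] = (
            "excluded", "assigned_to_positive_class",
        )
    if not positive:
        raise ConfigurationError("positive class is empty")
    if not negative:
        raise ConfigurationError("negative class is empty")
    prov = pd.concat([pos_prov, neg_prov], ignore_index=True)
    return TrainingClasses(positive=positive, negative=negative, provenance=prov)
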