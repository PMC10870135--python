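"""End-to-end pipeline from input files to a fitted results object.

Thin orchestration over the library modules: read + QC + normalize the
expression matrix, assemble gene properties from the constraint table and the
genome sequence, build the training classes, and fit the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import gene_properties as gp
from . import io_qc, training_classes as tc
from .model import HyperparameterGrid, StigmaModel, StigmaResults

DEFAULT_INPUT_NAMES = {
    "matrix": "matrix.mtx",
    "cell_meta": "cell_meta.tsv",
    "constraints": "constraints.tsv",
    "fasta": "genome.fa",
    "bed": "genes.bed",
    "disease_genes": "disease_genes.tsv",
    "housekeeping_genes": "housekeeping_genes.tsv",
    "reference": "reference_pseudobulk.tsv",
}


@dataclass
class PipelineInputs:
    am: io_qc.AnnotatedMatrix
    props: pd.DataFrame
    classes: tc.TrainingClasses


def load_inputs(
    input_dir: str | Path,
    qc: io_qc.QCConfig | None = None,
    matrix_format: str = "mtx",
    with_gc: bool = True,
) -> PipelineInputs:
    """Read the five inputs from a directory laid out like a generated
    fixture, apply QC and cluster filters, and normalize."""
    d = Path(input_dir)
    qc = qc or io_qc.QCConfig()
    am = io_qc.read_expression(d / DEFAULT_INPUT_NAMES["matrix"],
                               d / DEFAULT_INPUT_NAMES["cell_meta"],
                               format=matrix_format)
    am = io_qc.qc_filter(am, qc)
    am = io_qc.cluster_fraction_filter(am, qc)
    am = io_qc.normalize(am)

    constraints = gp.load_constraint_table(d / DEFAULT_INPUT_NAMES["constraints"])
    gc = None
    fasta = d / DEFAULT_INPUT_NAMES["fasta"]
    bed = d / DEFAULT_INPUT_NAMES["bed"]
    if with_gc and fasta.exists() and bed.exists():
        models = gp.read_gene_models(bed, fmt="bed")
        gc = gp.gene_gc_features(fasta, models)
    props = gp.merge_properties(constraints, gc, all_genes=list(am.gene_ids))

    disease = tc.read_gene_list(d / DEFAULT_INPUT_NAMES["disease_genes"])
    housekeeping = tc.read_gene_list(d / DEFAULT_INPUT_NAMES["housekeeping_genes"])
    ref = tc.read_reference_pseudobulk(d / DEFAULT_INPUT_NAMES["reference"])
    classes = tc.build_training_classes(disease, housekeeping, ref, props)
    return PipelineInputs(am=am, props=props, classes=classes)


def run_pipeline(
    inputs: PipelineInputs,
    seed: int = 0,
    feature_blocks: str = "full",
    pseudotime_mode: str = "precomputed",
    grid: HyperparameterGrid | None = None,
    params: dict | None = None,
    folds: int = 5,
) -> StigmaResults:
    model = StigmaModel.from_annotated_matrix(
        inputs.am, inputs.props, inputs.classes,
        feature_blocks=feature_blocks, pseudotime_mode=pseudotime_mode,
        grid=grid, folds=folds, seed=seed,
    )
    return model.fit(seed=seed, params=params)
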