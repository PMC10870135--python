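"""Synthetic single-cell datasets with planted ground truth.

The generator emulates the statistical structure the classifier exploits:
disease-like genes are expressed in one or two home clusters with a temporal
modulation along pseudotime and carry intolerant constraint metrics, while
housekeeping-like genes are flat across clusters and time, LoF tolerant by
construction, and ubiquitous in the reference pseudobulk. A configurable
number of disease-like genes are withheld from the labeled gene lists so that
genome-wide prediction can be evaluated against known plants. Counts follow a
negative binomial (gamma-Poisson) noise model. Disease-like genes are
amplitude-normalized so their population-average expression matches the flat
genes — the planted signal lives in cluster and pseudotime structure, not in
the pseudo-bulk mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import ConfigurationError
from .gene_properties import GeneModel
from .io_qc import AnnotatedMatrix

TEMPORAL_SHAPES = ("bump", "ramp", "switch")


@dataclass
class SimulationConfig:
    """Study conditions of the default synthetic scenario."""

    n_clusters: int = 3
    cells_per_cluster: int = 300
    n_stages: int = 4
    n_disease_genes: int = 100
    n_housekeeping_genes: int = 300
    n_noise_genes: int = 600
    n_heldout_disease_genes: int = 100  # planted unlabeled, drawn from noise budget
    nb_dispersion: float = 0.5
    disease_effect: float = 4.0
    temporal_only_fraction: float = 0.3  # disease genes specific in time, not space
    bursty_flat_fraction: float = 0.5    # flat genes with scrambled structured rates
    temporal_shape: str = "bump"
    seed: int = 0
    n_subtrajectories: int = 20
    gene_length: int = 300
    genes_per_contig: int = 200

    def __post_init__(self) -> None:
        for name in ("n_clusters", "cells_per_cluster", "n_stages",
                     "n_disease_genes", "n_housekeeping_genes", "n_noise_genes"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.disease_effect <= 1:
            raise ConfigurationError("disease_effect must exceed 1")
        if self.temporal_shape not in TEMPORAL_SHAPES:
            raise ConfigurationError(f"temporal_shape must be one of {TEMPORAL_SHAPES}")
        if self.n_heldout_disease_genes >= self.n_noise_genes:
            raise ConfigurationError(
                "held-out disease genes are drawn from the noise budget"
            )
        if self.n_clusters > self.cells_per_cluster * self.n_clusters:
            raise ConfigurationError("more clusters than cells")


@dataclass
class SimulatedDataset:
    am: AnnotatedMatrix
    constraints: pd.DataFrame
    disease_genes: list[str]
    housekeeping_genes: list[str]
    reference: pd.DataFrame
    truth: pd.DataFrame
    gene_models: list[GeneModel]
    contigs: dict[str, str]
    config: SimulationConfig = field(repr=False, default=None)


def _temporal_weight(shape: str, t: np.ndarray, t0: float) -> np.ndarray:
    if shape == "bump":
        return np.exp(-((t - t0) ** 2) / (2 * 0.12**2))
    if shape == "ramp":
        return t
    return (t > t0).astype(float)  # switch


def _specific_reference_profile(rng: np.random.Generator, n: int, h: float
                                ) -> np.ndarray:
    """Graded tri-level profile (absent / intermediate / high sub-trajectories)
    that passes the one-SD ubiquity band rule by construction."""
    n_low = max(1, round(0.35 * n))
    n_high = max(1, round(0.35 * n))
    n_mid = n - n_low - n_high
    levels = np.concatenate([
        np.full(n_low, 0.02 * h),
        np.full(n_mid, 0.5 * h),
        np.full(n_high, h),
    ])
    rng.shuffle(levels)
    return np.maximum(levels + rng.normal(0, 0.02 * h, size=n), 0.0)


def _ubiquitous_reference_profile(rng: np.random.Generator, n: int, c: float
                                  ) -> np.ndarray:
    """Flat profile with one moderate spike: >10 sub-trajectories fall inside
    the one-SD band, so the ubiquity rule removes it."""
    vals = c * (1.0 + rng.normal(0, 0.03, size=n))
    vals[rng.integers(n)] *= 2.5
    return np.maximum(vals, 0.0)


def _intolerant_constraints(rng, n):
    pli = rng.beta(5, 1, n)
    prec = rng.beta(2, 2, n)
    pnull = rng.beta(1, 5, n)
    total = pli + prec + pnull
    return pd.DataFrame({
        "pLI": pli / total, "pRec": prec / total, "pNull": pnull / total,
        "syn_z": rng.normal(0, 1, n),
        "mis_z": rng.normal(2, 1, n),
        "lof_z": rng.normal(3, 1, n),
    })


def _tolerant_constraints(rng, n):
    pnull = rng.beta(5, 1, n)
    prec = rng.beta(1, 5, n)
    pli = rng.beta(1, 5, n)
    total = pli + prec + pnull
    frame = pd.DataFrame({
        "pLI": pli / total, "pRec": prec / total, "pNull": pnull / total,
        "syn_z": rng.normal(0, 1, n),
        "mis_z": rng.normal(0, 1, n),
        "lof_z": rng.normal(-0.5, 1, n),
    })
    # enforce pNull strictly dominant: swap in the max of the triple
    triple = frame[["pLI", "pRec", "pNull"]].to_numpy()
    order = np.sort(triple, axis=1)
    frame["pNull"] = order[:, 2]
    frame["pRec"] = order[:, 0]
    frame["pLI"] = order[:, 1]
    return frame


def _uniform_constraints(rng, n):
    triple = rng.dirichlet([1.0, 1.0, 1.0], size=n)
    return pd.DataFrame({
        "pLI": triple[:, 0], "pRec": triple[:, 1], "pNull": triple[:, 2],
        "syn_z": rng.normal(0, 1.5, n),
        "mis_z": rng.normal(0, 1.5, n),
        "lof_z": rng.normal(0, 1.5, n),
    })


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Generate the five linked inputs plus truth labels, deterministically."""
    rng = np.random.default_rng(cfg.seed)
    n_plain_noise = cfg.n_noise_genes - cfg.n_heldout_disease_genes
    roles = (["disease"] * cfg.n_disease_genes
             + ["disease_unlabeled"] * cfg.n_heldout_disease_genes
             + ["housekeeping"] * cfg.n_housekeeping_genes
             + ["noise"] * n_plain_noise)
    roles = np.array(roles, dtype=object)
    rng.shuffle(roles)
    n_genes = len(roles)
    gene_ids = np.array([f"G{i:05d}" for i in range(n_genes)], dtype=object)

    # ------- cells -------
    n_cells = cfg.n_clusters * cfg.cells_per_cluster
    clusters = np.repeat([f"C{j + 1}" for j in range(cfg.n_clusters)],
                         cfg.cells_per_cluster)
    t = rng.uniform(0, 1, n_cells)
    stage_idx = np.minimum((t * cfg.n_stages).astype(int), cfg.n_stages - 1)
    stage_labels = [f"E{9.5 + i:g}" for i in range(cfg.n_stages)]
    stages = np.array(stage_labels, dtype=object)[stage_idx]

    doublet = rng.uniform(0.0, 0.18, n_cells)
    doublet[rng.uniform(size=n_cells) < 0.01] = rng.uniform(0.21, 0.4)
    pct_mito = rng.uniform(0.0, 8.0, n_cells)
    pct_mito[rng.uniform(size=n_cells) < 0.01] = rng.uniform(10.5, 20.0)
    pct_ribo = rng.uniform(5.0, 40.0, n_cells)
    pct_ribo[rng.uniform(size=n_cells) < 0.005] = rng.uniform(50.5, 70.0)

    # ------- expression rates -------
    cluster_codes = np.repeat(np.arange(cfg.n_clusters), cfg.cells_per_cluster)
    rates = np.empty((n_cells, n_genes))
    home_clusters = np.empty(n_genes, dtype=object)
    t0s = np.full(n_genes, np.nan)
    base_mean = np.empty(n_genes)
    disease_like = np.isin(roles, ["disease", "disease_unlabeled"])

    def structured_rate() -> tuple[np.ndarray, np.ndarray, float, float]:
        """Rate vector of a cluster/time-specific gene, population mean m."""
        m = rng.lognormal(np.log(2.0), 0.4)
        if rng.uniform() < cfg.temporal_only_fraction:
            homes = np.arange(cfg.n_clusters)  # specific in time only
        else:
            n_home = int(rng.integers(1, 3))
            homes = rng.choice(cfg.n_clusters, size=n_home, replace=False)
        t0 = rng.uniform(0.15, 0.85)
        w = 0.05 + cfg.disease_effect * np.isin(cluster_codes, homes) * \
            _temporal_weight(cfg.temporal_shape, t, t0)
        return m * w / w.mean(), homes, t0, m

    alpha = np.empty(n_genes)
    base_alpha = max(cfg.nb_dispersion, 1e-8)
    for g in range(n_genes):
        role = roles[g]
        if disease_like[g]:
            rates[:, g], homes, t0, m = structured_rate()
            home_clusters[g] = ",".join(f"C{h + 1}" for h in sorted(homes))
            t0s[g] = t0
            alpha[g] = base_alpha
        elif role == "housekeeping":
            home_clusters[g] = ""
            if rng.uniform() < cfg.bursty_flat_fraction:
                # same cell-level rate multiset as a structured gene, but
                # scrambled across cells: identical pseudo-bulk moments with
                # zero cluster/time association
                r, _, _, m = structured_rate()
                rates[:, g] = rng.permutation(r)
                alpha[g] = base_alpha
            else:
                m = rng.lognormal(np.log(2.5), 0.9)
                rates[:, g] = m
                alpha[g] = rng.lognormal(np.log(0.8), 0.7)
        else:  # plain noise
            m = rng.lognormal(np.log(2.3), 0.5)
            mult = rng.lognormal(0.0, 0.3, cfg.n_clusters)
            w = mult[cluster_codes]
            rates[:, g] = m * w / w.mean()
            home_clusters[g] = ""
            alpha[g] = rng.lognormal(np.log(0.8), 0.7)
        base_mean[g] = m

    lam = rng.gamma(1.0 / alpha[None, :], alpha[None, :] * rates)
    counts = sp.csr_matrix(rng.poisson(lam).astype(np.int64))

    cell_meta = pd.DataFrame({
        "cell_id": [f"cell_{i:05d}" for i in range(n_cells)],
        "cluster": clusters,
        "stage": stages,
        "pseudotime": t,
        "doublet_score": doublet,
        "pct_mito": pct_mito,
        "pct_ribo": pct_ribo,
    })
    am = AnnotatedMatrix(counts=counts, cell_meta=cell_meta, gene_ids=gene_ids)

    # ------- constraint metrics -------
    parts = []
    for mask, maker in ((disease_like, _intolerant_constraints),
                        (roles == "housekeeping", _tolerant_constraints),
                        (roles == "noise", _uniform_constraints)):
        block = maker(rng, int(mask.sum()))
        block.index = gene_ids[mask]
        parts.append(block)
    constraints = pd.concat(parts).loc[gene_ids]
    constraints["ortholog_confidence"] = rng.beta(5, 2, n_genes)
    # a fraction of plain-noise genes lack any constraint record
    noise_ids = gene_ids[roles == "noise"]
    drop = rng.choice(noise_ids, size=len(noise_ids) // 10, replace=False)
    constraints = constraints.drop(index=drop)
    constraints.index.name = "gene"

    # ------- reference pseudobulk -------
    n_sub = cfg.n_subtrajectories
    ref = np.empty((n_genes, n_sub))
    for g in range(n_genes):
        if disease_like[g]:
            ref[g] = _specific_reference_profile(rng, n_sub,
                                                 rng.lognormal(np.log(5.0), 0.4))
        elif roles[g] == "housekeeping":
            ref[g] = _ubiquitous_reference_profile(rng, n_sub,
                                                   rng.lognormal(np.log(3.0), 0.3))
        else:
            ref[g] = rng.lognormal(0.0, 0.5, n_sub)
    reference = pd.DataFrame(ref, index=pd.Index(gene_ids, name="gene"),
                             columns=[f"traj_{j + 1:02d}" for j in range(n_sub)])

    # ------- synthetic contigs and gene models -------
    slot = cfg.gene_length + 900
    contigs: dict[str, str] = {}
    gene_models: list[GeneModel] = []
    bases = np.array(list("ACGT"))
    for c_start in range(0, n_genes, cfg.genes_per_contig):
        chrom = f"chr_sim_{c_start // cfg.genes_per_contig + 1}"
        n_on = min(cfg.genes_per_contig, n_genes - c_start)
        length = 2000 + n_on * slot
        contigs[chrom] = "".join(rng.choice(bases, size=length))
        for i in range(n_on):
            g = c_start + i
            start = 1001 + i * slot
            gene_models.append(GeneModel(
                gene=str(gene_ids[g]), chrom=chrom,
                strand="+" if rng.uniform() < 0.5 else "-",
                gene_start=start, gene_end=start + cfg.gene_length - 1,
            ))

    truth = pd.DataFrame({
        "gene": gene_ids,
        "role": roles,
        "home_clusters": home_clusters,
        "t0": t0s,
        "base_mean": base_mean,
    })
    return SimulatedDataset(
        am=am,
        constraints=constraints,
        disease_genes=sorted(gene_ids[roles == "disease"]),
        housekeeping_genes=sorted(gene_ids[roles == "housekeeping"]),
        reference=reference,
        truth=truth,
        gene_models=gene_models,
        contigs=contigs,
        config=cfg,
    )


def write_fixture(sim: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write every input in the exact format the readers consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / fname for name, fname in {
        "matrix": "matrix.mtx",
        "genes": "genes.tsv",
        "barcodes": "barcodes.tsv",
        "cell_meta": "cell_meta.tsv",
        "constraints": "constraints.tsv",
        "fasta": "genome.fa",
        "bed": "genes.bed",
        "disease_genes": "disease_genes.tsv",
        "housekeeping_genes": "housekeeping_genes.tsv",
        "reference": "reference_pseudobulk.tsv",
        "truth": "truth.tsv",
    }.items()}

    scipy.io.mmwrite(str(paths["matrix"]), sim.am.counts.T.tocoo())
    paths["genes"].write_text("".join(f"{g}\n" for g in sim.am.gene_ids))
    paths["barcodes"].write_text(
        "".join(f"{b}\n" for b in sim.am.cell_meta["cell_id"])
    )
    sim.am.cell_meta.to_csv(paths["cell_meta"], sep="\t", index=False)
    sim.constraints.to_csv(paths["constraints"], sep="\t")
    with open(paths["fasta"], "w") as fh:
        for chrom, seq in sim.contigs.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    with open(paths["bed"], "w") as fh:
        for gm in sim.gene_models:
            fh.write(f"{gm.chrom}\t{gm.gene_start - 1}\t{gm.gene_end}\t"
                     f"{gm.gene}\t0\t{gm.strand}\n")
    paths["disease_genes"].write_text(
        "gene\n" + "".join(f"{g}\n" for g in sim.disease_genes))
    paths["housekeeping_genes"].write_text(
        "gene\n" + "".join(f"{g}\n" for g in sim.housekeeping_genes))
    sim.reference.to_csv(paths["reference"], sep="\t")
    sim.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


@dataclass
class ClassFixture:
    """Training-class construction fixture mirroring the published counts:
    88 candidate disease genes of which one is ubiquitously expressed, and 643
    LoF-tolerant housekeeping genes."""

    disease_genes: list[str]
    housekeeping_genes: list[str]
    reference: pd.DataFrame
    constraints: pd.DataFrame
    features: pd.DataFrame  # per-gene feature vectors for balancing


def simulate_class_fixture(
    seed: int = 0,
    n_disease: int = 88,
    n_ubiquitous: int = 1,
    n_housekeeping: int = 643,
    n_subtrajectories: int = 20,
    n_features: int = 12,
) -> ClassFixture:
    rng = np.random.default_rng(seed)
    disease = [f"D{i:04d}" for i in range(n_disease)]
    housekeeping = [f"H{i:04d}" for i in range(n_housekeeping)]

    profiles = {}
    ubiquitous = set(rng.choice(disease, size=n_ubiquitous, replace=False))
    for g in disease:
        h = rng.lognormal(np.log(5.0), 0.4)
        profiles[g] = (
            _ubiquitous_reference_profile(rng, n_subtrajectories, h)
            if g in ubiquitous
            else _specific_reference_profile(rng, n_subtrajectories, h)
        )
    for g in housekeeping:
        profiles[g] = _ubiquitous_reference_profile(
            rng, n_subtrajectories, rng.lognormal(np.log(3.0), 0.3))
    reference = pd.DataFrame.from_dict(profiles, orient="index")
    reference.columns = [f"traj_{j + 1:02d}" for j in range(n_subtrajectories)]
    reference.index.name = "gene"

    cons_d = _intolerant_constraints(rng, n_disease)
    cons_d.index = disease
    cons_h = _tolerant_constraints(rng, n_housekeeping)
    cons_h.index = housekeeping
    constraints = pd.concat([cons_d, cons_h])
    constraints.index.name = "gene"

    genes = disease + housekeeping
    offsets = np.where(np.arange(len(genes)) < n_disease, 1.0, 0.0)
    features = pd.DataFrame(
        rng.normal(0, 1, (len(genes), n_features)) + offsets[:, None],
        index=pd.Index(genes, name="gene"),
        columns=[f"f{j}" for j in range(n_features)],
    )
    return ClassFixture(
        disease_genes=disease,
        housekeeping_genes=housekeeping,
        reference=reference,
        constraints=constraints,
        features=features,
    )
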