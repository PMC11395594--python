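"""Synthetic methylation cohorts with planted, recoverable ground truth.

The generator emulates the study design the pipeline is built for: a cohort
with known ages and a binary early/late disease stage, a beta-value matrix in
which a small set of CpG sites tracks age, a second small set shifts with
disease stage, and everything else is noise; a gene annotation mapping CpGs
to synthetic gene symbols; a confidence-weighted interaction network with one
planted dense module hosting the stage-informative genes; and a GMT
collection in which one set names the planted module among size-matched
decoys.  Every downstream stage of the pipeline can then be tested by
*recovery*: the attribution screen should surface the planted sites, the
graph clustering the planted module, and the final marker panel the planted
stage CpGs.

Generative model, per CpG j and sample i (logit scale, so betas stay inside
(0, 1) without clipping):

    logit(beta_ij) = logit(b0_j) + s_j * (age_i - mean age)
                     + delta * stage_i * [j stage-informative]
                     + eps_ij,   eps_ij ~ Normal(0, noise_sd^2)

b0_j ~ Uniform(0.1, 0.9) keeps baselines away from the boundaries; slopes
s_j ~ Uniform(-age_slope_range, +age_slope_range) for age-informative sites.
Stage-informative sites carry an age slope *and* the stage shift — the
markers the pipeline hunts for are, as in the underlying biology, found
among aging-relevant sites, which is what makes them visible to the
age-attribution screen upstream of the network analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.special import expit, logit

from .data_io import (
    BetaMatrix, CohortTable, CpGAnnotation, GeneNetwork, GeneSetCollection,
    write_beta_matrix, write_cohort, write_annotation, write_edges, write_gmt,
)
import pandas as pd
import networkx as nx


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic cohort.

    Defaults describe the reference desk-scale cohort used throughout the
    test-suite recovery experiments: 400 samples x 2000 CpGs with 50
    age-informative sites (per-year logit slope up to 0.04), 30
    stage-informative sites (logit shift 1.0 for late stage), logit-scale
    noise sd 0.3, and a 12-gene planted module in a 200-gene network with
    background edge probability 0.03 densified to 0.9 inside the module.
    """

    n_samples: int = 400
    n_cpgs: int = 2000
    n_age_sites: int = 50
    age_slope_range: float = 0.04     # per-year, logit scale
    noise_sd: float = 0.3             # logit scale
    age_range: tuple[float, float] = (40.0, 90.0)  # years
    n_stage_sites: int = 30
    stage_delta: float = 1.0          # logit-scale shift for late stage
    n_genes: int = 200
    planted_module_size: int = 12
    background_edge_prob: float = 0.03
    module_edge_prob: float = 0.9
    module_assign_prob: float = 1.0   # P(stage CpG lands on a module gene)
    n_pathways: int = 8
    disease: str = "degenerative"
    seed: int = 0

    def __post_init__(self) -> None:
        counts = dict(n_samples=self.n_samples, n_cpgs=self.n_cpgs,
                      n_age_sites=self.n_age_sites, n_stage_sites=self.n_stage_sites,
                      n_genes=self.n_genes, planted_module_size=self.planted_module_size,
                      n_pathways=self.n_pathways)
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.n_age_sites + self.n_stage_sites > self.n_cpgs:
            raise ValueError("n_age_sites + n_stage_sites exceeds n_cpgs")
        for name in ("background_edge_prob", "module_edge_prob", "module_assign_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.module_edge_prob <= self.background_edge_prob:
            raise ValueError("module_edge_prob must exceed background_edge_prob")
        if self.noise_sd < 0 or self.age_slope_range < 0:
            raise ValueError("noise_sd and age_slope_range must be >= 0")
        if not self.age_range[0] <= self.age_range[1]:
            raise ValueError("age_range must be (low, high) with low <= high")

    def cpg_ids(self) -> list[str]:
        return [f"cg{i:06d}" for i in range(self.n_cpgs)]

    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]


@dataclass
class GroundTruth:
    """Planted signal locations, the generative parameters behind them, and
    the gene-level structure — everything a recovery test needs."""

    age_site_ids: list[str] = field(default_factory=list)
    stage_site_ids: list[str] = field(default_factory=list)
    baselines: dict[str, float] = field(default_factory=dict)    # b0_j
    age_slopes: dict[str, float] = field(default_factory=dict)   # s_j (0 if none)
    mean_age: float = 0.0
    module_gene_ids: list[str] = field(default_factory=list)
    cpg_to_gene: dict[str, str] = field(default_factory=dict)
    pathways: dict[str, list[str]] = field(default_factory=dict)

    def merged_with(self, other: "GroundTruth") -> "GroundTruth":
        out = GroundTruth(**asdict(self))
        for name in ("module_gene_ids", "cpg_to_gene", "pathways"):
            if getattr(other, name):
                setattr(out, name, getattr(other, name))
        if other.age_site_ids and not out.age_site_ids:
            out.age_site_ids = other.age_site_ids
        return out


def simulate_cohort(spec: SimulationSpec) -> tuple[BetaMatrix, CohortTable, GroundTruth]:
    """Draw ages, stages and the beta matrix under the planted-signal model."""
    rng = np.random.default_rng([int(spec.seed), 0])
    n, m = spec.n_samples, spec.n_cpgs
    cpg_ids = spec.cpg_ids()
    sample_ids = [f"S{i:04d}" for i in range(n)]

    ages = rng.uniform(spec.age_range[0], spec.age_range[1], size=n)
    stages = np.zeros(n, dtype=int)
    stages[rng.permutation(n)[: n // 2]] = 1  # balanced classes

    chosen = rng.choice(m, size=spec.n_age_sites + spec.n_stage_sites, replace=False)
    age_idx = np.sort(chosen[: spec.n_age_sites])
    stage_idx = np.sort(chosen[spec.n_age_sites:])

    b0 = rng.uniform(0.1, 0.9, size=m)
    slopes = np.zeros(m)
    informative = np.concatenate([age_idx, stage_idx])
    slopes[informative] = rng.uniform(-spec.age_slope_range, spec.age_slope_range,
                                      size=informative.size)

    mean_age = float(ages.mean())
    z = logit(b0)[:, None] + slopes[:, None] * (ages - mean_age)[None, :]
    z[stage_idx] += spec.stage_delta * stages[None, :]
    if spec.noise_sd > 0:
        z += rng.normal(0.0, spec.noise_sd, size=(m, n))
    beta = BetaMatrix(cpg_ids, sample_ids, expit(z))

    cohort = CohortTable(pd.DataFrame({
        "sample_id": sample_ids,
        "age": np.round(ages, 4),
        "disease": spec.disease,
        "stage": stages,
    }))
    truth = GroundTruth(
        age_site_ids=[cpg_ids[i] for i in age_idx],
        stage_site_ids=[cpg_ids[i] for i in stage_idx],
        baselines={cpg_ids[i]: float(b0[i]) for i in range(m)},
        age_slopes={cpg_ids[i]: float(slopes[i]) for i in range(m)},
        mean_age=mean_age,
    )
    return beta, cohort, truth


def simulate_annotation_network(
    spec: SimulationSpec, stage_site_ids: list[str],
) -> tuple[CpGAnnotation, GeneNetwork, GeneSetCollection, GroundTruth]:
    """Assign CpGs to genes (stage CpGs preferentially onto the planted
    module), wire the interaction network, and emit the gene-set collection
    with the module set among size-matched decoys."""
    if spec.planted_module_size > spec.n_genes:
        raise ValueError("planted_module_size exceeds n_genes")
    rng = np.random.default_rng([int(spec.seed), 1])
    genes = spec.gene_ids()
    cpg_ids = spec.cpg_ids()
    stage_set = set(stage_site_ids)

    module_genes = sorted(rng.choice(spec.n_genes, size=spec.planted_module_size,
                                     replace=False))
    module_gene_ids = [genes[i] for i in module_genes]

    cpg_to_gene: dict[str, str] = {}
    stage_counter = 0
    for i, cpg in enumerate(cpg_ids):
        gene = genes[i % spec.n_genes]
        if cpg in stage_set and rng.random() < spec.module_assign_prob:
            gene = module_gene_ids[stage_counter % len(module_gene_ids)]
            stage_counter += 1
        cpg_to_gene[cpg] = gene

    annotation = CpGAnnotation(pd.DataFrame({
        "cpg_id": cpg_ids,
        "chromosome": "chr1",
        "position": [1000 + 100 * i for i in range(len(cpg_ids))],
        "gene": [cpg_to_gene[c] for c in cpg_ids],
    }))

    g = nx.Graph()
    g.add_nodes_from(genes)
    module_set = set(module_gene_ids)
    for a in range(spec.n_genes):
        for b in range(a + 1, spec.n_genes):
            in_module = genes[a] in module_set and genes[b] in module_set
            p = spec.module_edge_prob if in_module else spec.background_edge_prob
            if rng.random() < p:
                g.add_edge(genes[a], genes[b],
                           confidence=float(np.round(rng.uniform(0.5, 1.0), 3)))
    network = GeneNetwork(g)

    sets: dict[str, set[str]] = {"DEGENERATIVE_MODULE": set(module_gene_ids)}
    non_module = [x for x in genes if x not in module_set]
    for k in range(spec.n_pathways - 1):
        decoy = rng.choice(len(non_module), size=spec.planted_module_size,
                           replace=False)
        sets[f"DECOY_PATHWAY_{k:02d}"] = {non_module[i] for i in decoy}
    collection = GeneSetCollection(sets, universe=set(genes))

    truth = GroundTruth(
        stage_site_ids=list(stage_site_ids),
        module_gene_ids=module_gene_ids,
        cpg_to_gene=cpg_to_gene,
        pathways={name: sorted(members) for name, members in sets.items()},
    )
    return annotation, network, collection, truth


@dataclass
class SimulatedData:
    """One fully wired synthetic study."""

    spec: SimulationSpec
    beta: BetaMatrix
    cohort: CohortTable
    annotation: CpGAnnotation
    network: GeneNetwork
    gene_sets: GeneSetCollection
    truth: GroundTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write every artifact in the data_io formats; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "beta": outdir / "beta.tsv",
            "cohort": outdir / "cohort.tsv",
            "annotation": outdir / "annotation.tsv",
            "edges": outdir / "edges.tsv",
            "gmt": outdir / "pathways.gmt",
            "truth": outdir / "truth.json",
        }
        write_beta_matrix(self.beta, paths["beta"])
        write_cohort(self.cohort, paths["cohort"])
        write_annotation(self.annotation, paths["annotation"])
        write_edges(self.network, paths["edges"])
        write_gmt(self.gene_sets, paths["gmt"])
        import json
        paths["truth"].write_text(json.dumps(asdict(self.truth), indent=1,
                                             sort_keys=True) + "\n")
        return paths


def simulate_all(spec: SimulationSpec) -> SimulatedData:
    beta, cohort, truth_c = simulate_cohort(spec)
    annotation, network, gene_sets, truth_n = simulate_annotation_network(
        spec, truth_c.stage_site_ids)
    return SimulatedData(spec, beta, cohort, annotation, network, gene_sets,
                         truth_c.merged_with(truth_n))
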